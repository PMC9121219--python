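"""Raw digitizer pen-event streams.

A drawing session is an ordered series of pen events sampled at the
tablet's rate (180 Hz for the reference device).  Each event carries the
pen-tip position on the drawing surface (mm), the normalized pen pressure,
the pen's horizontal and vertical inclinations (degrees), and the hover
distance of the tip above the surface (mm, zero while drawing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd

#: Column order of the pen-event CSV dialect.
PEN_CSV_COLUMNS = ("t_s", "x_mm", "y_mm", "pressure", "incl_h_deg", "incl_v_deg", "hover_mm")


@dataclass(frozen=True)
class DeviceProfile:
    """Physical characteristics of the capturing tablet.

    Defaults mirror a professional pen display: 180 Hz sampling, a
    252 x 186 mm active area, 8192 pressure levels and 1-degree
    inclination resolution.
    """

    sampling_rate_hz: float = 180.0
    surface_width_mm: float = 252.0
    surface_height_mm: float = 186.0
    pressure_levels: int = 8192
    inclination_resolution_deg: float = 1.0

    def __post_init__(self) -> None:
        for name in ("sampling_rate_hz", "surface_width_mm", "surface_height_mm",
                     "pressure_levels", "inclination_resolution_deg"):
            if not getattr(self, name) > 0:
                raise ValueError(f"DeviceProfile.{name} must be strictly positive")

    @property
    def dt_s(self) -> float:
        """Nominal sampling period in seconds."""
        return 1.0 / self.sampling_rate_hz


class PenSample(NamedTuple):
    """One timestamped pen event."""

    t: float
    x: float
    y: float
    pressure: float
    incl_h: float
    incl_v: float
    hover: float


@dataclass
class PenStream:
    """A session-long ordered series of pen events.

    Invariants (checked at construction): strictly increasing timestamps,
    pressure in [0, 1], and mutual exclusion of contact and hover
    (``pressure > 0`` implies ``hover == 0``).
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    pressure: np.ndarray
    incl_h: np.ndarray
    incl_v: np.ndarray
    hover: np.ndarray
    device: DeviceProfile = field(default_factory=DeviceProfile)

    def __post_init__(self) -> None:
        for name in ("t", "x", "y", "pressure", "incl_h", "incl_v", "hover"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.t.size
        if any(getattr(self, name).size != n
               for name in ("x", "y", "pressure", "incl_h", "incl_v", "hover")):
            raise ValueError("all PenStream channels must have equal length")
        if n == 0:
            raise ValueError("empty pen stream")
        if not np.all(np.isfinite(self.t)):
            raise ValueError("non-finite timestamps")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(self.pressure < 0) or np.any(self.pressure > 1):
            raise ValueError("pressure must lie in [0, 1]")
        if np.any(self.hover < 0):
            raise ValueError("hover distance must be nonnegative")
        if np.any((self.pressure > 0) & (self.hover > 0)):
            raise ValueError("on-surface samples (pressure > 0) must have hover = 0")

    def __len__(self) -> int:
        return self.t.size

    def __getitem__(self, i: int) -> PenSample:
        return PenSample(self.t[i], self.x[i], self.y[i], self.pressure[i],
                         self.incl_h[i], self.incl_v[i], self.hover[i])

    def __iter__(self) -> Iterator[PenSample]:
        return (self[i] for i in range(len(self)))

    @property
    def on_surface(self) -> np.ndarray:
        """Boolean mask of samples in contact with the surface."""
        return self.pressure > 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_s": self.t, "x_mm": self.x, "y_mm": self.y,
            "pressure": self.pressure, "incl_h_deg": self.incl_h,
            "incl_v_deg": self.incl_v, "hover_mm": self.hover,
        })

    @classmethod
    def from_frame(cls, frame: pd.DataFrame,
                   device: DeviceProfile | None = None) -> "PenStream":
        missing = [c for c in PEN_CSV_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"malformed pen-event table, missing columns: {missing}")
        return cls(
            t=frame["t_s"].to_numpy(float),
            x=frame["x_mm"].to_numpy(float),
            y=frame["y_mm"].to_numpy(float),
            pressure=frame["pressure"].to_numpy(float),
            incl_h=frame["incl_h_deg"].to_numpy(float),
            incl_v=frame["incl_v_deg"].to_numpy(float),
            hover=frame["hover_mm"].to_numpy(float),
            device=device if device is not None else DeviceProfile(),
        )


def write_pen_csv(stream: PenStream, path: str | Path) -> None:
    """Write a pen stream to CSV in the fixed column order.

    Floats are serialized with shortest round-trip repr, so a
    write -> read cycle reproduces every channel to numeric precision.
    """
    if len(stream) == 0:
        raise ValueError("refusing to write an empty pen stream")
    stream.to_frame().to_csv(path, index=False, columns=list(PEN_CSV_COLUMNS))


def read_pen_csv(path: str | Path, device: DeviceProfile | None = None) -> PenStream:
    """Read a pen-event CSV written by :func:`write_pen_csv`.

    Validates the header, strictly increasing timestamps and nonnegative
    pressure (via the :class:`PenStream` invariants).
    """
    frame = pd.read_csv(path)
    return PenStream.from_frame(frame, device=device)
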