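"""Drawing-process feature extraction.

Six features summarize how a participant draws, independently of what is
drawn: mean drawing speed, speed variability (coefficient of variation),
pressure variability (median absolute deviation), the standard deviations
of the pen's horizontal and vertical inclinations, and the pause:drawing
duration ratio.  Speed-based features are computed from instantaneous
pen-tip speeds within strokes; pauses comprise within-stroke dwells (pen
held inside a 0.25-mm radius for more than 100 ms) and pen-up gaps
between strokes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .stream import PenStream, read_pen_csv

#: Canonical feature order used throughout the package.
FEATURE_NAMES = ("speed_mean", "speed_cv", "pressure_mad",
                 "incl_h_sd", "incl_v_sd", "pause_ratio")

#: Pause-detection defaults: dwell radius (mm) and minimum duration (s).
PAUSE_RADIUS_MM = 0.25
PAUSE_MIN_DURATION_S = 0.1


@dataclass(frozen=True)
class Stroke:
    """Maximal contiguous run of on-surface samples, by stream index (inclusive)."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("stroke start index must not exceed end index")

    def n_samples(self) -> int:
        return self.end - self.start + 1

    def duration(self, stream: PenStream) -> float:
        return float(stream.t[self.end] - stream.t[self.start])

    def path_length(self, stream: PenStream) -> float:
        sl = slice(self.start, self.end + 1)
        return float(np.hypot(np.diff(stream.x[sl]), np.diff(stream.y[sl])).sum())


@dataclass(frozen=True)
class Pause:
    """A detected pause: a within-stroke dwell or a between-strokes pen-up gap."""

    kind: str  # "within_stroke" | "between_strokes"
    start_t: float
    end_t: float

    def __post_init__(self) -> None:
        if self.kind not in ("within_stroke", "between_strokes"):
            raise ValueError(f"unknown pause kind {self.kind!r}")
        if self.end_t < self.start_t:
            raise ValueError("pause must have nonnegative duration")

    @property
    def duration(self) -> float:
        return self.end_t - self.start_t


@dataclass(frozen=True)
class FeatureVector:
    """The six drawing features for one session."""

    speed_mean: float
    speed_cv: float
    pressure_mad: float
    incl_h_sd: float
    incl_v_sd: float
    pause_ratio: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])


def segment_strokes(stream: PenStream) -> list[Stroke]:
    """Split a stream into strokes: maximal runs with pressure > 0."""
    if len(stream) == 0:
        raise ValueError("empty stream")
    on = np.concatenate(([0], (stream.pressure > 0).astype(np.int8), [0]))
    edges = np.flatnonzero(np.diff(on))
    # edges alternate run-start, run-end(+1)
    return [Stroke(int(s), int(e) - 1) for s, e in zip(edges[::2], edges[1::2])]


def instantaneous_speeds(stream: PenStream,
                         strokes: Sequence[Stroke]) -> np.ndarray:
    """Per-sample-pair pen-tip speeds (mm/s) within strokes.

    One speed per consecutive on-surface sample pair inside a stroke;
    pairs spanning stroke boundaries are excluded.  No smoothing is
    applied, and the time step is taken from the timestamps.
    """
    usable = [s for s in strokes if s.n_samples() >= 2]
    if not usable:
        raise ValueError("need at least one stroke with >= 2 samples")
    chunks = []
    for s in usable:
        sl = slice(s.start, s.end + 1)
        dt = np.diff(stream.t[sl])
        if np.any(dt <= 0):
            raise ValueError("non-positive time step between consecutive samples")
        chunks.append(np.hypot(np.diff(stream.x[sl]), np.diff(stream.y[sl])) / dt)
    return np.concatenate(chunks)


def speed_features(speeds: np.ndarray) -> tuple[float, float]:
    """Mean speed and its coefficient of variation (sample SD / mean)."""
    speeds = np.asarray(speeds, dtype=float)
    if speeds.size < 2:
        raise ValueError("need >= 2 speed samples")
    mean = float(speeds.mean())
    sd = float(speeds.std(ddof=1))
    if mean == 0.0:
        if sd == 0.0:
            return 0.0, 0.0
        raise ValueError("coefficient of variation undefined: zero mean, nonzero SD")
    return mean, sd / mean


def pressure_mad(stream: PenStream, strokes: Sequence[Stroke]) -> float:
    """Median absolute deviation of on-surface pressure (raw MAD, no constant)."""
    p = _on_surface_channel(stream, strokes, stream.pressure, minimum=1)
    return float(np.median(np.abs(p - np.median(p))))


def inclination_sds(stream: PenStream,
                    strokes: Sequence[Stroke]) -> tuple[float, float]:
    """Sample SDs of the horizontal and vertical inclinations on-surface.

    Angles are treated as plain real quantities in degrees (no circular
    statistics).
    """
    h = _on_surface_channel(stream, strokes, stream.incl_h, minimum=2)
    v = _on_surface_channel(stream, strokes, stream.incl_v, minimum=2)
    return float(h.std(ddof=1)), float(v.std(ddof=1))


def _on_surface_channel(stream: PenStream, strokes: Sequence[Stroke],
                        channel: np.ndarray, minimum: int) -> np.ndarray:
    if not strokes:
        raise ValueError("no on-surface samples")
    idx = np.concatenate([np.arange(s.start, s.end + 1) for s in strokes])
    if idx.size < minimum:
        raise ValueError(f"need >= {minimum} on-surface samples")
    return channel[idx]


def detect_pauses(stream: PenStream, strokes: Sequence[Stroke],
                  radius_mm: float = PAUSE_RADIUS_MM,
                  min_duration_s: float = PAUSE_MIN_DURATION_S) -> list[Pause]:
    """Detect within-stroke dwells and between-strokes pen-up gaps.

    Within a stroke, a greedy anchor scan is used: starting from anchor
    sample ``i``, the window is extended to the last sample ``j`` such
    that every sample ``i..j`` lies within ``radius_mm`` of sample ``i``'s
    position.  If the window lasts strictly longer than
    ``min_duration_s`` a pause ``[t_i, t_j]`` is emitted and the scan
    restarts at ``j + 1``; otherwise the anchor advances to ``i + 1``.
    Pauses are overlap-free by construction.  Between consecutive
    strokes, one pause per pen-up gap is reported with no minimum
    duration.
    """
    if not strokes:
        raise ValueError("pause detection requires at least one stroke")
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    if min_duration_s <= 0:
        raise ValueError("minimum pause duration must be positive")
    pauses: list[Pause] = []
    r2 = radius_mm * radius_mm
    for s in strokes:
        pauses.extend(_scan_stroke(stream.t, stream.x, stream.y,
                                   s.start, s.end, r2, min_duration_s))
    for a, b in zip(strokes[:-1], strokes[1:]):
        pauses.append(Pause("between_strokes",
                            float(stream.t[a.end]), float(stream.t[b.start])))
    return sorted(pauses, key=lambda p: p.start_t)


def _scan_kernel(t, x, y, start, end, r2, min_duration):
    """Greedy anchor scan over one stroke; returns (i, j) index pairs."""
    out_i = np.empty(end - start + 1, dtype=np.int64)
    out_j = np.empty(end - start + 1, dtype=np.int64)
    m = 0
    i = start
    while i <= end:
        j = i
        k = i + 1
        while k <= end:
            dx = x[k] - x[i]
            dy = y[k] - y[i]
            if dx * dx + dy * dy > r2:
                break
            j = k
            k += 1
        if t[j] - t[i] > min_duration:
            out_i[m] = i
            out_j[m] = j
            m += 1
            i = j + 1
        else:
            i += 1
    return out_i[:m], out_j[:m]


try:  # hot loop; compiled when numba is available, plain Python otherwise
    from numba import njit

    _scan_kernel = njit(cache=False)(_scan_kernel)
except ImportError:  # pragma: no cover
    pass


def _scan_stroke(t: np.ndarray, x: np.ndarray, y: np.ndarray,
                 start: int, end: int, r2: float,
                 min_duration: float) -> list[Pause]:
    ii, jj = _scan_kernel(t, x, y, start, end, r2, min_duration)
    return [Pause("within_stroke", float(t[i]), float(t[j]))
            for i, j in zip(ii, jj)]


def pause_ratio(stream: PenStream, strokes: Sequence[Stroke],
                pauses: Sequence[Pause]) -> float:
    """Total pause time over total active drawing time.

    Numerator: all pause durations (within-stroke and between-strokes).
    Denominator: total stroke duration minus within-stroke pause time,
    i.e. time spent in drawing motion (dwelling is not drawing).
    """
    total_pause = sum(p.duration for p in pauses)
    within = sum(p.duration for p in pauses if p.kind == "within_stroke")
    stroke_time = sum(s.duration(stream) for s in strokes)
    denom = stroke_time - within
    if denom <= 0:
        raise ValueError("total drawing-motion duration must be positive")
    return total_pause / denom


def extract_features(stream: PenStream,
                     radius_mm: float = PAUSE_RADIUS_MM,
                     min_duration_s: float = PAUSE_MIN_DURATION_S) -> FeatureVector:
    """Compute the six drawing features for one session.

    Partial (truncated) sessions are processed as-is as long as they
    contain at least one stroke with two samples.
    """
    strokes = segment_strokes(stream)
    speeds = instantaneous_speeds(stream, strokes)
    speed_mean, speed_cv = speed_features(speeds)
    pmad = pressure_mad(stream, strokes)
    ih_sd, iv_sd = inclination_sds(stream, strokes)
    pauses = detect_pauses(stream, strokes, radius_mm, min_duration_s)
    ratio = pause_ratio(stream, strokes, pauses)
    return FeatureVector(speed_mean=speed_mean, speed_cv=speed_cv,
                         pressure_mad=pmad, incl_h_sd=ih_sd,
                         incl_v_sd=iv_sd, pause_ratio=ratio)


def features_frame(streams: Iterable[tuple[str, PenStream]]) -> pd.DataFrame:
    """Feature table for many sessions: one row per (participant_id, stream)."""
    rows = []
    for pid, stream in streams:
        row = {"participant_id": pid}
        row.update(extract_features(stream).as_dict())
        rows.append(row)
    return pd.DataFrame(rows, columns=["participant_id", *FEATURE_NAMES])


class DrawingFeatureExtractor(TransformerMixin, BaseEstimator):
    """Stateless transformer mapping pen streams to the six drawing features.

    ``transform`` accepts an iterable of :class:`PenStream` objects or
    paths to pen-event CSV files and returns an ``(n_sessions, 6)``
    feature matrix in :data:`FEATURE_NAMES` order.
    """

    def __init__(self, radius_mm: float = PAUSE_RADIUS_MM,
                 min_duration_s: float = PAUSE_MIN_DURATION_S):
        self.radius_mm = radius_mm
        self.min_duration_s = min_duration_s

    def fit(self, X, y=None):  # noqa: D102 - stateless
        return self

    def transform(self, X) -> np.ndarray:
        rows = []
        for item in X:
            stream = item if isinstance(item, PenStream) else read_pen_csv(item)
            rows.append(extract_features(
                stream, self.radius_mm, self.min_duration_s).as_array())
        return np.vstack(rows)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_NAMES, dtype=object)
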