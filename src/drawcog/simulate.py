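"""Synthetic pen-stream cohorts with a latent-cognition linkage.

Generates two demographically distinct cohorts of trail-making-like
drawing sessions (25 targets, 24 connecting strokes) whose kinematic
generating parameters depend on a latent global-cognition score.  The
cognition score (0-30 scale) is drawn first, standardized within-cohort,
and mapped linearly on the log scale to the generating dispersions, so
that strictly positive quantities stay positive and the induced
feature-score correlations can be targeted directly.

The per-feature effect strengths are parameterized by *target partial
correlations*: with participant-level log-normal noise of spread
``noise_sd``, a coefficient ``beta = noise_sd * r / sqrt(1 - r^2)``
yields a population correlation of ``r`` between the score and the
log-generating parameter, up to the (small) sampling noise of feature
extraction from a finite session.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .features import FEATURE_NAMES
from .stream import DeviceProfile, PenStream

__all__ = [
    "CohortConfig", "EffectConfig", "SessionPlan", "Dwell",
    "generate_cohort", "iter_cohort", "simulate_session",
    "make_session_plan", "metadata_frame",
]

#: Baseline kinematic generating parameters (population medians for a
#: cognitively average participant).  Units match the extracted features.
BASELINE_PARAMS = {
    "speed_mean": 30.0,    # mm/s
    "speed_cv": 0.55,      # dimensionless
    "pressure_mad": 0.06,  # normalized pressure units
    "incl_h_sd": 8.0,      # degrees
    "incl_v_sd": 6.0,      # degrees
    "pause_ratio": 0.45,   # dimensionless
}

#: Fraction of on-surface time spent in planned within-stroke dwells.
#: Kept constant (not cognition-linked) so dwell zeros contribute a fixed,
#: solvable floor to the pooled speed CV.
DWELL_TIME_FRACTION = 0.03

#: AR(1) coefficients for the smoothed noise channels (at 180 Hz).
AR_SPEED, AR_PRESSURE, AR_INCLINATION = 0.9, 0.97, 0.99

#: Gaussian MAD-to-SD factor: MAD of a normal equals 0.6745 sigma.
_NORMAL_MAD = 0.6744897501960817


@dataclass(frozen=True)
class CohortConfig:
    """Demographic recipe for one cohort."""

    name: str
    n_participants: int
    age_mean_years: float = 83.4
    age_sd_years: float = 6.9
    prop_female: float = 0.71
    edu_mean_years: float = 16.3
    edu_sd_years: float = 2.3
    moca_mean: float = 24.4
    moca_sd: float = 3.2
    moca_range: tuple[int, int] = (16, 30)

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        for name in ("age_sd_years", "edu_sd_years", "moca_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        lo, hi = self.moca_range
        if not (0 <= lo <= hi <= 30):
            raise ValueError("moca_range must satisfy 0 <= low <= high <= 30")
        if not 0 <= self.prop_female <= 1:
            raise ValueError("prop_female must lie in [0, 1]")

    @classmethod
    def us_like(cls, n_participants: int = 200, name: str = "us") -> "CohortConfig":
        """Older, more educated cohort (age 83.4 (6.9), 71% female, 16.3 y education)."""
        return cls(name=name, n_participants=n_participants)

    @classmethod
    def japan_like(cls, n_participants: int = 200, name: str = "japan") -> "CohortConfig":
        """Younger cohort (age 73.3 (4.5), 51% female, 13.8 y education)."""
        return cls(name=name, n_participants=n_participants,
                   age_mean_years=73.3, age_sd_years=4.5, prop_female=0.51,
                   edu_mean_years=13.8, edu_sd_years=2.0,
                   moca_mean=24.4, moca_sd=2.6)


def _default_targets() -> dict[str, float]:
    return {
        "speed_mean": 0.0,
        "speed_cv": -0.42,
        "pressure_mad": -0.34,
        "incl_h_sd": 0.33,
        "incl_v_sd": 0.17,
        "pause_ratio": -0.49,
    }


@dataclass(frozen=True)
class EffectConfig:
    """Cognition-to-kinematics linkage strengths.

    ``target_r`` holds the intended feature-score partial correlations
    (defaults follow the calibration sign pattern: negative for speed CV,
    pause ratio and pressure dispersion; positive for the inclination
    dispersions; zero for mean speed).  ``strength_scale = 0`` disables
    every association.  ``age_confound > 0`` switches on a demographic
    confound: age then loads on both the cognition score and the mean
    drawing speed, which covariate adjustment should remove.
    """

    target_r: dict[str, float] = field(default_factory=_default_targets)
    noise_sd: float = 0.25
    strength_scale: float = 1.0
    age_confound: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        unknown = set(self.target_r) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown features in target_r: {sorted(unknown)}")
        for name, r in self.target_r.items():
            if not -1 < r < 1:
                raise ValueError(f"target_r[{name!r}] must lie in (-1, 1)")
        if not 0 <= self.age_confound < 1:
            raise ValueError("age_confound must lie in [0, 1)")

    def coefficient(self, feature: str) -> float:
        """Log-scale slope of the generating parameter on the standardized score."""
        r = self.target_r.get(feature, 0.0)
        return self.strength_scale * self.noise_sd * r / math.sqrt(1.0 - r * r)


@dataclass(frozen=True)
class Dwell:
    """Planned within-stroke stationary hold."""

    stroke: int
    onset_frac: float  # fraction of the stroke's path length
    duration_s: float

    def __post_init__(self) -> None:
        if not 0 <= self.onset_frac < 1:
            raise ValueError("dwell onset fraction must lie in [0, 1)")
        if self.duration_s < 0:
            raise ValueError("dwell duration must be nonnegative")


@dataclass(frozen=True)
class SessionPlan:
    """Everything needed to synthesize one drawing session.

    25 targets connected by 24 strokes by default; ``gap_durations_s``
    holds the pen-up gap after each stroke except the last.
    """

    target_positions: np.ndarray          # (n_targets, 2) mm
    stroke_speeds_mm_s: np.ndarray        # (n_targets - 1,)
    speed_log_sd: float                   # within-stroke AR(1) log-speed spread
    dwells: tuple[Dwell, ...]
    gap_durations_s: np.ndarray           # (n_targets - 2,)
    pressure_base: float
    pressure_disp: float                  # target on-surface pressure MAD
    incl_h_base_deg: float
    incl_h_disp_deg: float                # target SD
    incl_v_base_deg: float
    incl_v_disp_deg: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "target_positions",
                           np.asarray(self.target_positions, dtype=float))
        object.__setattr__(self, "stroke_speeds_mm_s",
                           np.asarray(self.stroke_speeds_mm_s, dtype=float))
        object.__setattr__(self, "gap_durations_s",
                           np.asarray(self.gap_durations_s, dtype=float))
        n = self.target_positions.shape[0]
        if n < 2 or self.target_positions.shape[1] != 2:
            raise ValueError("need at least 2 planar targets")
        if self.stroke_speeds_mm_s.shape != (n - 1,):
            raise ValueError("need one nominal speed per stroke (n_targets - 1)")
        if np.any(self.stroke_speeds_mm_s <= 0):
            raise ValueError("stroke speeds must be positive")
        if self.gap_durations_s.shape != (max(n - 2, 0),):
            raise ValueError("need one pen-up gap per internal stroke boundary")
        if np.any(self.gap_durations_s < 0):
            raise ValueError("gap durations must be nonnegative")
        if self.speed_log_sd < 0 or self.pressure_disp < 0 \
                or self.incl_h_disp_deg < 0 or self.incl_v_disp_deg < 0:
            raise ValueError("dispersions must be nonnegative")
        if not 0 < self.pressure_base <= 1:
            raise ValueError("pressure base must lie in (0, 1]")
        for d in self.dwells:
            if not 0 <= d.stroke < n - 1:
                raise ValueError("dwell references a nonexistent stroke")
        total = self.total_planned_duration_s()
        if self.dwells and max(d.duration_s for d in self.dwells) > total:
            raise ValueError("a dwell exceeds the total planned session length")
        if self.gap_durations_s.size and self.gap_durations_s.max() > total:
            raise ValueError("a pen-up gap exceeds the total planned session length")

    @property
    def stroke_count(self) -> int:
        return self.target_positions.shape[0] - 1

    def stroke_lengths_mm(self) -> np.ndarray:
        return np.hypot(*np.diff(self.target_positions, axis=0).T)

    def total_planned_duration_s(self) -> float:
        move = float((self.stroke_lengths_mm() / self.stroke_speeds_mm_s).sum())
        dwell = sum(d.duration_s for d in self.dwells)
        gaps = float(self.gap_durations_s.sum())
        return move + dwell + gaps


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    """Stationary AR(1) series of length n with marginal SD ``sd``."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    innov = rng.normal(0.0, sd * math.sqrt(1.0 - phi * phi), size=n)
    innov[0] = rng.normal(0.0, sd)
    return lfilter([1.0], [1.0, -phi], innov)


def _scatter_targets(rng: np.random.Generator, device: DeviceProfile,
                     n_targets: int = 25, margin_mm: float = 10.0,
                     min_spacing_mm: float = 20.0) -> np.ndarray:
    """Rejection-sample target positions with a minimum mutual spacing."""
    lo = np.array([margin_mm, margin_mm])
    hi = np.array([device.surface_width_mm - margin_mm,
                   device.surface_height_mm - margin_mm])
    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < n_targets:
        p = rng.uniform(lo, hi)
        if all(np.hypot(*(p - q)) >= min_spacing_mm for q in pts):
            pts.append(p)
        attempts += 1
        if attempts > 200 * n_targets:
            # dense layouts: restart with a fresh scatter
            pts, attempts = [], 0
    return np.vstack(pts)


def make_session_plan(params: dict[str, float], device: DeviceProfile,
                      rng: np.random.Generator, n_targets: int = 25) -> SessionPlan:
    """Translate generating parameters into a concrete session plan.

    Solves the within-stroke log-speed spread so that the pooled speed CV
    (including the near-zero dwell samples and the between-stroke speed
    spread) realizes ``params['speed_cv']``, and sizes the dwell/gap
    budget so the realized pause:drawing ratio tracks
    ``params['pause_ratio']``.
    """
    targets = _scatter_targets(rng, device, n_targets=n_targets)
    lengths = np.hypot(*np.diff(targets, axis=0).T)
    v = max(params["speed_mean"], 1.0)
    between_sd = 0.08
    stroke_speeds = v * np.exp(rng.normal(0.0, between_sd, size=lengths.size)
                               - 0.5 * between_sd ** 2)
    move_time = float((lengths / stroke_speeds).sum())

    # within-stroke dwell budget: constant small fraction of drawing time
    dwell_total = DWELL_TIME_FRACTION * move_time
    n_dwells = max(2, int(round(dwell_total / 0.3)))
    raw = rng.uniform(0.15, 0.45, size=n_dwells)
    durations = raw * (dwell_total / raw.sum())
    dwell_strokes = rng.choice(lengths.size, size=n_dwells, replace=False) \
        if n_dwells <= lengths.size else rng.integers(0, lengths.size, size=n_dwells)
    dwells = tuple(Dwell(int(k), float(rng.uniform(0.1, 0.9)), float(d))
                   for k, d in zip(dwell_strokes, durations))

    # pen-up gaps absorb the remaining pause budget
    gap_total = max(params["pause_ratio"] * move_time - dwell_total, 0.0)
    n_gaps = max(n_targets - 2, 0)
    weights = np.exp(rng.normal(0.0, 0.6, size=n_gaps))
    gaps = weights * (gap_total / weights.sum()) if n_gaps else np.empty(0)
    gaps = np.maximum(gaps, 3.0 * device.dt_s)

    # pooled CV decomposition: cv_tot^2 = (cv_move^2 + d) / (1 - d), where d
    # is the dwell share of on-surface time and cv_move collects the
    # between-stroke and within-stroke multiplicative spreads.
    d_frac = dwell_total / (move_time + dwell_total)
    cv_move_sq = max(params["speed_cv"] ** 2 * (1.0 - d_frac) - d_frac, 1e-4)
    log_var = math.log1p(cv_move_sq) - between_sd ** 2
    speed_log_sd = math.sqrt(max(log_var, 1e-4))

    pressure_base = float(np.clip(0.55 + rng.normal(0.0, 0.03), 0.3, 0.8))
    return SessionPlan(
        target_positions=targets,
        stroke_speeds_mm_s=stroke_speeds,
        speed_log_sd=speed_log_sd,
        dwells=dwells,
        gap_durations_s=gaps,
        pressure_base=pressure_base,
        pressure_disp=params["pressure_mad"],
        incl_h_base_deg=float(np.clip(60.0 + rng.normal(0.0, 4.0), 25.0, 155.0)),
        incl_h_disp_deg=params["incl_h_sd"],
        incl_v_base_deg=float(np.clip(55.0 + rng.normal(0.0, 4.0), 25.0, 85.0)),
        incl_v_disp_deg=params["incl_v_sd"],
    )


def simulate_session(plan: SessionPlan, device: DeviceProfile,
                     seed: int | np.random.Generator) -> PenStream:
    """Render a session plan into a raw pen stream at the device rate.

    Strokes traverse consecutive targets at their nominal speed modulated
    by AR(1) multiplicative log-noise; planned dwells hold the pen within
    a fraction of the pause radius; pen-up gaps emit zero-pressure
    samples with a positive hover bump.  Pressure and inclinations are
    AR(1)-smoothed around their baselines and quantized to the device
    resolution.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    dt = device.dt_s
    lengths = plan.stroke_lengths_mm()
    dwell_by_stroke: dict[int, list[Dwell]] = {}
    for d in plan.dwells:
        dwell_by_stroke.setdefault(d.stroke, []).append(d)

    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    on: list[np.ndarray] = []
    hover: list[np.ndarray] = []
    sig = plan.speed_log_sd
    for k in range(plan.stroke_count):
        p0 = plan.target_positions[k]
        p1 = plan.target_positions[k + 1]
        L = lengths[k]
        v = plan.stroke_speeds_mm_s[k]
        direction = (p1 - p0) / L
        # arc-length increments with multiplicative AR(1) log-noise
        n_est = int(math.ceil(L / (v * dt) * math.exp(3.0 * sig))) + 16
        w = _ar1(rng, n_est, AR_SPEED, sig)
        ds = v * np.exp(w - 0.5 * sig * sig) * dt
        s = np.cumsum(ds)
        n_move = int(np.searchsorted(s, L, side="left")) + 1
        if n_move > n_est:  # noise ran slow; extend deterministically
            extra = int(math.ceil((L - s[-1]) / (v * dt))) + 1
            s = np.concatenate([s, s[-1] + v * dt * np.arange(1, extra + 1)])
            n_move = int(np.searchsorted(s, L, side="left")) + 1
        s = s[:n_move]
        s[-1] = L
        arc = np.concatenate(([0.0], s[:-1]))  # stroke starts exactly at p0
        pos = p0[None, :] + arc[:, None] * direction[None, :]
        # splice dwells in by arc-length onset
        for dw in sorted(dwell_by_stroke.get(k, []), key=lambda d: d.onset_frac,
                         reverse=True):
            n_hold = int(round(dw.duration_s / dt))
            if n_hold == 0:
                continue
            at = int(np.searchsorted(arc, dw.onset_frac * L))
            at = min(at, pos.shape[0] - 1)
            jitter = rng.normal(0.0, 0.005, size=(n_hold, 2))
            hold = pos[at][None, :] + jitter
            pos = np.vstack([pos[:at + 1], hold, pos[at + 1:]])
        xs.append(pos[:, 0]); ys.append(pos[:, 1])
        on.append(np.ones(pos.shape[0], dtype=bool))
        hover.append(np.zeros(pos.shape[0]))
        if k < plan.stroke_count - 1 and plan.gap_durations_s.size:
            n_gap = int(round(plan.gap_durations_s[k] / dt))
            if n_gap > 0:
                drift = rng.normal(0.0, 0.15, size=(n_gap, 2))
                gp = p1[None, :] + np.cumsum(drift, axis=0) * 0.2
                bump = 3.0 * np.sin(np.pi * (np.arange(1, n_gap + 1)) / (n_gap + 1))
                xs.append(gp[:, 0]); ys.append(gp[:, 1])
                on.append(np.zeros(n_gap, dtype=bool))
                hover.append(np.maximum(bump, 0.1))

    x = np.concatenate(xs)
    y = np.concatenate(ys)
    on_mask = np.concatenate(on)
    hover_arr = np.concatenate(hover)
    n = x.size
    t = np.arange(n) * dt

    # pressure: AR(1) around the baseline, quantized to device levels
    step = 1.0 / (device.pressure_levels - 1)
    p = plan.pressure_base + _ar1(rng, n, AR_PRESSURE,
                                  plan.pressure_disp / _NORMAL_MAD)
    p = np.clip(np.round(p / step) * step, step, 1.0)
    p[~on_mask] = 0.0
    hover_arr[on_mask] = 0.0

    res = device.inclination_resolution_deg
    ih = plan.incl_h_base_deg + _ar1(rng, n, AR_INCLINATION, plan.incl_h_disp_deg)
    iv = plan.incl_v_base_deg + _ar1(rng, n, AR_INCLINATION, plan.incl_v_disp_deg)
    ih = np.clip(np.round(ih / res) * res, 0.0, 180.0)
    iv = np.clip(np.round(iv / res) * res, 0.0, 90.0)

    return PenStream(t=t, x=np.clip(x, 0.0, device.surface_width_mm),
                     y=np.clip(y, 0.0, device.surface_height_mm),
                     pressure=p, incl_h=ih, incl_v=iv, hover=hover_arr,
                     device=device)


def _draw_participant_meta(pid: str, cohort: CohortConfig, effect: EffectConfig,
                           rng: np.random.Generator) -> dict:
    """Demographics, score and kinematic generating parameters (no session)."""
    age = float(np.clip(rng.normal(cohort.age_mean_years, cohort.age_sd_years),
                        65.0, 105.0))
    sex = int(rng.random() < cohort.prop_female)  # 1 = female
    education = float(np.clip(rng.normal(cohort.edu_mean_years, cohort.edu_sd_years),
                              6.0, 24.0))
    age_z = ((age - cohort.age_mean_years) / cohort.age_sd_years
             if cohort.age_sd_years > 0 else 0.0)

    c = effect.age_confound
    u = rng.normal()
    moca_raw = cohort.moca_mean + cohort.moca_sd * (math.sqrt(1.0 - c * c) * u
                                                    - c * age_z)
    lo, hi = cohort.moca_range
    moca = int(np.clip(np.round(moca_raw), lo, hi))
    z = (moca - cohort.moca_mean) / cohort.moca_sd if cohort.moca_sd > 0 else 0.0

    params = {}
    for name in FEATURE_NAMES:
        eps = rng.normal(0.0, effect.noise_sd)
        params[name] = BASELINE_PARAMS[name] * math.exp(
            effect.coefficient(name) * z + eps)
    if c > 0:  # older participants draw more slowly (confound on speed)
        params["speed_mean"] *= math.exp(-0.5 * c * age_z)

    meta = {"participant_id": pid, "cohort": cohort.name, "age": age,
            "sex": sex, "education_years": education, "moca": moca}
    meta.update({f"g_{k}": v for k, v in params.items()})
    return meta


def _draw_participant(pid: str, cohort: CohortConfig, effect: EffectConfig,
                      device: DeviceProfile, rng: np.random.Generator
                      ) -> tuple[PenStream, dict]:
    meta = _draw_participant_meta(pid, cohort, effect, rng)
    params = {k[2:]: v for k, v in meta.items() if k.startswith("g_")}
    plan = make_session_plan(params, device, rng)
    stream = simulate_session(plan, device, rng)
    return stream, meta


def cohort_parameters(cohort: CohortConfig, effect: EffectConfig,
                      seed: int) -> pd.DataFrame:
    """Cohort metadata and generating parameters without session synthesis.

    Draws exactly the same demographics, scores and kinematic generating
    parameters as :func:`generate_cohort` for the same seed (columns
    ``g_<feature>``), skipping the pen-stream rendering.  Useful for
    cheap calibration checks of the cognition linkage itself.
    """
    children = np.random.SeedSequence(seed).spawn(cohort.n_participants)
    width = len(str(cohort.n_participants))
    rows = [_draw_participant_meta(f"{cohort.name}-{i + 1:0{width}d}", cohort,
                                   effect, np.random.default_rng(child))
            for i, child in enumerate(children)]
    return pd.DataFrame(rows)


def iter_cohort(cohort: CohortConfig, effect: EffectConfig,
                device: DeviceProfile, seed: int
                ) -> Iterator[tuple[PenStream, dict]]:
    """Yield (stream, metadata) pairs one participant at a time.

    Each participant uses an independent child RNG spawned from ``seed``,
    so output is reproducible and independent of consumption order.
    """
    children = np.random.SeedSequence(seed).spawn(cohort.n_participants)
    width = len(str(cohort.n_participants))
    for i, child in enumerate(children):
        pid = f"{cohort.name}-{i + 1:0{width}d}"
        yield _draw_participant(pid, cohort, effect, device,
                                np.random.default_rng(child))


def generate_cohort(cohort: CohortConfig, effect: EffectConfig,
                    device: DeviceProfile | None = None,
                    seed: int = 0) -> list[tuple[PenStream, dict]]:
    """Materialize a full cohort of synthetic sessions with metadata."""
    if device is None:
        device = DeviceProfile()
    return list(iter_cohort(cohort, effect, device, seed))


def metadata_frame(records: list[tuple[PenStream, dict]] | list[dict]) -> pd.DataFrame:
    """Cohort metadata table (participant_id, cohort, age, sex, education, MoCA)."""
    metas = [m if isinstance(m, dict) else m[1] for m in records]
    return pd.DataFrame(metas)
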