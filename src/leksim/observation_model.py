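"""Observation layer: lek attendance and imperfect detection.

A site's true head counts are first thinned by annual lek attendance
(availability), then each of the two survey occasions records a
Binomial(N_LEK, p) count.  Attendance is redrawn each year (annual
attendance, not within-season emigration), so N_LEK is held fixed across the
two occasions of a year — within-year closure.

Attendance modes
----------------
``perfect``        everyone attends (N_LEK equals the true site total).
``age_sex_fixed``  SY males 0.60, ASY males 0.80, females 0.30, each with
                   truncated-normal annual noise (SD 0.1).
``density``        all males attend with gamma = min(1, K / N_males) — leks
                   saturate at carrying capacity K males — with the same
                   SD 0.1 noise; females keep their fixed rate.

Detection modes: perfect, fixed p, Uniform(low, high) drawn per site / per
year / per site-year, and a linear year trend clamped at a floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import truncated_normal
from .demographic_core import SiteState

__all__ = [
    "AttendanceModel",
    "DetectionModel",
    "AttendanceDraw",
    "LekObservation",
    "density_gamma",
    "sample_attendance",
    "detection_schedule",
    "observe_counts",
    "ATTENDANCE_MODES",
    "DETECTION_MODES",
]

ATTENDANCE_MODES = ("perfect", "age_sex_fixed", "density")
DETECTION_MODES = (
    "perfect",
    "fixed",
    "uniform_by_site",
    "uniform_by_year",
    "uniform_by_site_year",
    "decreasing_trend",
)


@dataclass(frozen=True)
class AttendanceModel:
    """Annual lek-attendance regime for one scenario."""

    mode: str = "age_sex_fixed"
    male_sy: tuple[float, float] = (0.60, 0.10)
    male_asy: tuple[float, float] = (0.80, 0.10)
    female: tuple[float, float] = (0.30, 0.10)
    carrying_capacity: int = 25
    density_sd: float = 0.10

    def __post_init__(self) -> None:
        if self.mode not in ATTENDANCE_MODES:
            raise ValueError(f"mode must be one of {ATTENDANCE_MODES}, got {self.mode!r}")
        for name in ("male_sy", "male_asy", "female"):
            mean, sd = getattr(self, name)
            if not 0.0 <= mean <= 1.0 or sd < 0:
                raise ValueError(f"{name}: invalid attendance probability {(mean, sd)}")
        if self.carrying_capacity <= 0 or int(self.carrying_capacity) != self.carrying_capacity:
            raise ValueError("carrying_capacity must be a positive integer")


@dataclass(frozen=True)
class DetectionModel:
    """Per-occasion detection regime for one scenario."""

    mode: str = "fixed"
    p: float = 1.0
    low: float = 0.25
    high: float = 0.75
    start: float = 0.75
    step: float = 0.03
    floor: float = 0.25

    def __post_init__(self) -> None:
        for name in ("p", "low", "high", "start", "floor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}: probability {v} outside [0, 1]")
        if self.mode not in DETECTION_MODES:
            raise ValueError(f"mode must be one of {DETECTION_MODES}, got {self.mode!r}")
        if self.low > self.high:
            raise ValueError("low must be <= high")
        if self.floor > self.start:
            raise ValueError("floor must be <= start")


@dataclass(frozen=True)
class AttendanceDraw:
    """Attendance outcome for one site-year."""

    female_sy: int
    female_asy: int
    male_sy: int
    male_asy: int

    @property
    def males(self) -> int:
        return self.male_sy + self.male_asy

    @property
    def n_lek(self) -> int:
        return self.female_sy + self.female_asy + self.male_sy + self.male_asy


@dataclass(frozen=True)
class LekObservation:
    """Attending abundance and the occasion counts for one site-year."""

    n_lek: int
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.n_lek < 0:
            raise ValueError("N_LEK must be >= 0")
        if any(c < 0 or c > self.n_lek for c in self.counts):
            raise ValueError("occasion counts must satisfy 0 <= count <= N_LEK")


def density_gamma(carrying_capacity: int, male_total: int) -> float:
    """Density-dependent male attendance probability gamma = min(1, K/N).

    Everyone attends while the male population is at or below the lek's
    carrying capacity K; above it, attendance scales as K / N so the
    expected number of attending males saturates at K.
    """
    if carrying_capacity <= 0:
        raise ValueError("carrying capacity K must be > 0")
    if male_total < 0:
        raise ValueError("male_total must be >= 0")
    if male_total <= carrying_capacity:
        return 1.0
    return carrying_capacity / male_total


def sample_attendance(
    state: SiteState, model: AttendanceModel, rng: np.random.Generator
) -> AttendanceDraw:
    """Draw one year's lek attendance for a site.

    Class probabilities are realized once per site-year with truncated-normal
    noise, then each individual attends independently.
    """
    if model.mode == "perfect":
        return AttendanceDraw(
            state.female_sy, state.female_asy, state.male_sy, state.male_asy
        )
    if model.mode == "age_sex_fixed":
        p_msy = float(truncated_normal(rng, *model.male_sy, 0.0, 1.0))
        p_masy = float(truncated_normal(rng, *model.male_asy, 0.0, 1.0))
    else:  # density: one gamma for all males, replacing the age-specific rates
        gamma = density_gamma(model.carrying_capacity, state.males)
        p_msy = p_masy = float(truncated_normal(rng, gamma, model.density_sd, 0.0, 1.0))
    p_f = float(truncated_normal(rng, *model.female, 0.0, 1.0))
    return AttendanceDraw(
        female_sy=int(rng.binomial(state.female_sy, p_f)),
        female_asy=int(rng.binomial(state.female_asy, p_f)),
        male_sy=int(rng.binomial(state.male_sy, p_msy)),
        male_asy=int(rng.binomial(state.male_asy, p_masy)),
    )


def detection_schedule(
    model: DetectionModel,
    n_sites: int,
    n_years: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Realize the (site x year) detection-probability matrix for one run."""
    if n_sites <= 0 or n_years <= 0:
        raise ValueError("n_sites and n_years must be positive")
    shape = (n_sites, n_years)
    if model.mode == "perfect":
        return np.ones(shape)
    if model.mode == "fixed":
        return np.full(shape, model.p)
    if model.mode == "decreasing_trend":
        years = np.arange(n_years)
        p_t = np.maximum(model.floor, model.start - model.step * years)
        return np.broadcast_to(p_t, shape).copy()
    if rng is None:
        raise ValueError(f"mode {model.mode!r} needs an rng")
    if model.mode == "uniform_by_site":
        return np.broadcast_to(
            rng.uniform(model.low, model.high, (n_sites, 1)), shape
        ).copy()
    if model.mode == "uniform_by_year":
        return np.broadcast_to(
            rng.uniform(model.low, model.high, (1, n_years)), shape
        ).copy()
    # uniform_by_site_year
    return rng.uniform(model.low, model.high, shape)


def observe_counts(
    n_lek: int,
    p: float,
    rng: np.random.Generator,
    n_occasions: int = 2,
) -> np.ndarray:
    """Repeated within-year counts: i.i.d. Binomial(N_LEK, p) per occasion.

    The same N_LEK and the same p apply to every occasion of the year
    (within-year closure).
    """
    if n_lek < 0:
        raise ValueError("N_LEK must be >= 0")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    return rng.binomial(n_lek, p, size=n_occasions).astype(np.int64)
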