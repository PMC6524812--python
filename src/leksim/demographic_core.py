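"""Individual-based demographic core for a declining lekking grouse population.

Each site carries an age- (second-year SY vs after-second-year ASY) and
sex-structured head count.  One simulated year runs the life cycle in the
fixed order reproduction -> annual mortality -> aging; lek attendance is an
observation-side process and lives in :mod:`leksim.observation_model`.

Vital rates are parameterized by their literature means and SDs
(:class:`VitalRateSpec`); every site-year realizes one stochastic value per
rate (truncated-normal environmental noise), and all individuals at the site
share those realized rates while their fates remain independent Bernoulli
trials (drawn as binomials per demographic cell).

Fecundity follows the two-nesting-attempt chain

    F_j = [NP * C1 * S1_j + (1 - S1_j) * R * C2 * S2_j] * cs * js * 0.5 * h

for age class j, where NP is nesting propensity, C1/C2 first/second clutch
sizes, S1_j/S2_j age-specific nest success, R the renesting probability, cs
chick survival, js juvenile survival, h per-egg hatchability and 0.5 the
offspring sex ratio.  Note that NP weights only the first-nest term: the
renesting pathway is conditioned on first-nest failure alone, and the
stage-wise simulator is built to match that expectation exactly
(:func:`expected_fecundity` is its closed form).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from ._rng import truncated_normal

__all__ = [
    "VitalRateSpec",
    "RealizedRates",
    "SiteState",
    "default_vital_rates",
    "draw_realized_rates",
    "expected_fecundity",
    "reproduce",
    "apply_mortality",
    "advance_age",
    "step_year",
    "simulate_site",
    "trajectories_to_frame",
    "PROBABILITY_PARAMS",
    "CLUTCH_PARAMS",
]

#: parameters that are probabilities (realized values truncated to [0, 1])
PROBABILITY_PARAMS: tuple[str, ...] = (
    "male_adult_survival",
    "female_survival_breeding",
    "female_survival_nonbreeding",
    "nest_propensity",
    "nest1_SY",
    "nest1_ASY",
    "renest",
    "nest2_SY",
    "nest2_ASY",
    "hatch",
    "chick_survival",
    "juvenile_survival",
    "attendance_SY_male",
    "attendance_ASY_male",
    "attendance_female",
)

#: parameters measured in eggs (realized values truncated to [0, inf))
CLUTCH_PARAMS: tuple[str, ...] = ("clutch1", "clutch2")

_ALL_PARAMS = PROBABILITY_PARAMS + CLUTCH_PARAMS


@dataclass(frozen=True)
class VitalRateSpec:
    """(mean, sd) for every demographic and attendance rate.

    Defaults are the Kansas lesser prairie-chicken literature estimates;
    clutch sizes are in eggs, everything else is a probability.  Hatchability
    has no published SD and is treated as fixed (sd = 0).
    """

    male_adult_survival: tuple[float, float] = (0.45, 0.06)
    female_survival_breeding: tuple[float, float] = (0.49, 0.05)
    female_survival_nonbreeding: tuple[float, float] = (0.73, 0.04)
    nest_propensity: tuple[float, float] = (0.95, 0.04)
    clutch1: tuple[float, float] = (10.80, 2.17)
    nest1_SY: tuple[float, float] = (0.47, 0.04)
    nest1_ASY: tuple[float, float] = (0.44, 0.05)
    renest: tuple[float, float] = (0.33, 0.15)
    clutch2: tuple[float, float] = (8.17, 2.02)
    nest2_SY: tuple[float, float] = (0.50, 0.01)
    nest2_ASY: tuple[float, float] = (0.33, 0.08)
    hatch: tuple[float, float] = (0.93, 0.0)
    chick_survival: tuple[float, float] = (0.26, 0.01)
    juvenile_survival: tuple[float, float] = (0.54, 0.09)
    attendance_SY_male: tuple[float, float] = (0.60, 0.10)
    attendance_ASY_male: tuple[float, float] = (0.80, 0.10)
    attendance_female: tuple[float, float] = (0.30, 0.10)

    def __post_init__(self) -> None:
        for name in _ALL_PARAMS:
            mean, sd = getattr(self, name)
            if sd < 0:
                raise ValueError(f"{name}: sd must be >= 0, got {sd}")
            if name in PROBABILITY_PARAMS and not 0.0 <= mean <= 1.0:
                raise ValueError(f"{name}: probability mean must be in [0, 1], got {mean}")
            if name in CLUTCH_PARAMS and mean <= 0:
                raise ValueError(f"{name}: clutch mean must be > 0, got {mean}")

    def items(self) -> Iterator[tuple[str, tuple[float, float]]]:
        for name in _ALL_PARAMS:
            yield name, getattr(self, name)

    def with_zero_sd(self) -> "VitalRateSpec":
        """Copy of the spec with all environmental variation switched off."""
        return VitalRateSpec(**{k: (m, 0.0) for k, (m, sd) in self.items()})

    def replace(self, **updates: tuple[float, float]) -> "VitalRateSpec":
        return dataclasses.replace(self, **updates)

    @classmethod
    def from_dict(cls, values: dict) -> "VitalRateSpec":
        """Build from ``{name: {"mean": m, "sd": s}}`` (partial overrides allowed)."""
        kwargs = {}
        for name, entry in values.items():
            if name not in _ALL_PARAMS:
                raise KeyError(f"unknown vital-rate parameter: {name!r}")
            if isinstance(entry, dict):
                kwargs[name] = (float(entry["mean"]), float(entry.get("sd", 0.0)))
            else:
                mean, sd = entry
                kwargs[name] = (float(mean), float(sd))
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {name: {"mean": m, "sd": s} for name, (m, s) in self.items()}


def default_vital_rates() -> VitalRateSpec:
    """The default vital-rate table (literature means and SDs)."""
    return VitalRateSpec()


@dataclass(frozen=True)
class RealizedRates:
    """One realized value per vital-rate parameter for a given site-year."""

    male_adult_survival: float
    female_survival_breeding: float
    female_survival_nonbreeding: float
    nest_propensity: float
    clutch1: float
    nest1_SY: float
    nest1_ASY: float
    renest: float
    clutch2: float
    nest2_SY: float
    nest2_ASY: float
    hatch: float
    chick_survival: float
    juvenile_survival: float
    attendance_SY_male: float
    attendance_ASY_male: float
    attendance_female: float

    def __post_init__(self) -> None:
        for name in PROBABILITY_PARAMS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}: realized probability {v} outside [0, 1]")
        for name in CLUTCH_PARAMS:
            if getattr(self, name) < 0:
                raise ValueError(f"{name}: realized clutch size must be >= 0")

    @classmethod
    def from_means(cls, spec: VitalRateSpec) -> "RealizedRates":
        return cls(**{name: mean for name, (mean, _) in spec.items()})


def draw_realized_rates(spec: VitalRateSpec, rng: np.random.Generator) -> RealizedRates:
    """Realize every rate for one site-year.

    Each parameter is drawn independently from a normal with the spec's mean
    and SD, truncated to [0, 1] for probabilities and [0, inf) for clutch
    sizes; sd = 0 parameters are returned at their mean.
    """
    means = np.array([m for _, (m, _) in spec.items()])
    sds = np.array([s for _, (_, s) in spec.items()])
    n_prob = len(PROBABILITY_PARAMS)
    values = np.empty_like(means)
    values[:n_prob] = truncated_normal(rng, means[:n_prob], sds[:n_prob], 0.0, 1.0)
    values[n_prob:] = truncated_normal(rng, means[n_prob:], sds[n_prob:], 0.0, np.inf)
    return RealizedRates(**dict(zip(_ALL_PARAMS, values)))


@dataclass(frozen=True)
class SiteState:
    """Integer head counts by sex x age class at one site in one year."""

    female_sy: int
    female_asy: int
    male_sy: int
    male_asy: int
    year: int = 1

    def __post_init__(self) -> None:
        for name in ("female_sy", "female_asy", "male_sy", "male_asy"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name}: counts must be non-negative integers, got {v}")
        if self.year < 1:
            raise ValueError("year index is 1-based")

    @property
    def females(self) -> int:
        return self.female_sy + self.female_asy

    @property
    def males(self) -> int:
        return self.male_sy + self.male_asy

    @property
    def total(self) -> int:
        return self.females + self.males

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.female_sy, self.female_asy, self.male_sy, self.male_asy], dtype=np.int64
        )


def expected_fecundity(rates: RealizedRates, age: str) -> float:
    """Expected recruits per female of one sex, for age class ``age``.

    Closed form of the stage-wise reproductive chain (see module docstring);
    the renesting term is weighted by first-nest failure alone.
    """
    if age == "SY":
        s1, s2 = rates.nest1_SY, rates.nest2_SY
    elif age == "ASY":
        s1, s2 = rates.nest1_ASY, rates.nest2_ASY
    else:
        raise ValueError(f"age must be 'SY' or 'ASY', got {age!r}")
    nests = (
        rates.nest_propensity * rates.clutch1 * s1
        + (1.0 - s1) * rates.renest * rates.clutch2 * s2
    )
    return nests * rates.chick_survival * rates.juvenile_survival * 0.5 * rates.hatch


def _round_clutch(value: float) -> int:
    """Per-female clutch: realized site-year value rounded half-up, >= 0."""
    return max(int(np.floor(value + 0.5)), 0)


def reproduce(
    state: SiteState, rates: RealizedRates, rng: np.random.Generator
) -> tuple[int, int]:
    """Simulate the reproductive chain; returns (female, male) recruits.

    Recruits already include first-year (chick + juvenile) survival and enter
    the next census as SY birds — they do not additionally pass through
    :func:`apply_mortality` in their birth year.
    """
    c1 = _round_clutch(rates.clutch1)
    c2 = _round_clutch(rates.clutch2)
    eggs = 0
    for n_females, s1, s2 in (
        (state.female_sy, rates.nest1_SY, rates.nest2_SY),
        (state.female_asy, rates.nest1_ASY, rates.nest2_ASY),
    ):
        if n_females == 0:
            continue
        first_success = rng.binomial(n_females, s1)
        layers = rng.binomial(first_success, rates.nest_propensity)
        eggs += layers * c1
        renesters = rng.binomial(n_females - first_success, rates.renest)
        second_success = rng.binomial(renesters, s2)
        eggs += second_success * c2
    if eggs == 0:
        return (0, 0)
    hatched = rng.binomial(eggs, rates.hatch)
    chicks = rng.binomial(hatched, rates.chick_survival)
    juveniles = rng.binomial(chicks, rates.juvenile_survival)
    females = rng.binomial(juveniles, 0.5)
    return (int(females), int(juveniles - females))


def apply_mortality(
    state: SiteState, rates: RealizedRates, rng: np.random.Generator
) -> SiteState:
    """Annual mortality: independent Bernoulli survival per individual.

    Males survive with the adult male rate; females with the product of
    breeding- and non-breeding-season survival.
    """
    p_female = rates.female_survival_breeding * rates.female_survival_nonbreeding
    p_male = rates.male_adult_survival
    return SiteState(
        female_sy=int(rng.binomial(state.female_sy, p_female)),
        female_asy=int(rng.binomial(state.female_asy, p_female)),
        male_sy=int(rng.binomial(state.male_sy, p_male)),
        male_asy=int(rng.binomial(state.male_asy, p_male)),
        year=state.year,
    )


def advance_age(state: SiteState, recruits: tuple[int, int]) -> SiteState:
    """Aging: surviving SY become ASY; recruits become next year's SY."""
    rec_f, rec_m = recruits
    if rec_f < 0 or rec_m < 0:
        raise ValueError("recruit counts must be non-negative")
    return SiteState(
        female_sy=rec_f,
        female_asy=state.female_asy + state.female_sy,
        male_sy=rec_m,
        male_asy=state.male_asy + state.male_sy,
        year=state.year + 1,
    )


def step_year(
    state: SiteState, spec: VitalRateSpec, rng: np.random.Generator
) -> SiteState:
    """Advance one site by one year: realize rates, reproduce, kill, age."""
    rates = draw_realized_rates(spec, rng)
    recruits = reproduce(state, rates, rng)
    survivors = apply_mortality(state, rates, rng)
    return advance_age(survivors, recruits)


def simulate_site(
    spec: VitalRateSpec,
    rng: np.random.Generator,
    n_years: int,
    init: SiteState | None = None,
) -> np.ndarray:
    """Census trajectory of one site: (n_years, 4) int array.

    Columns are [female_sy, female_asy, male_sy, male_asy]; row t is the
    pre-breeding census of year t+1 (the observation layer sees these counts
    before the year's demographic transition).  Default initial state is 50
    females + 50 males at a 60:40 ASY:SY ratio.
    """
    if init is None:
        init = SiteState(female_sy=20, female_asy=30, male_sy=20, male_asy=30)
    out = np.zeros((n_years, 4), dtype=np.int64)
    state = init
    for t in range(n_years):
        out[t] = state.as_array()
        if t < n_years - 1:
            if state.total == 0:
                # extinction is absorbing; skip the RNG work
                state = SiteState(0, 0, 0, 0, year=state.year + 1)
            else:
                state = step_year(state, spec, rng)
    return out


def trajectories_to_frame(class_counts: np.ndarray):
    """Tidy table of simulated trajectories.

    ``class_counts`` has shape (sims, sites, years, 4); returns a DataFrame
    with columns simulation, site, year, sex, age_class, count (1-based
    simulation/site/year indices).
    """
    import pandas as pd

    s, i, t, c = class_counts.shape
    if c != 4:
        raise ValueError("last axis must hold the four sex x age classes")
    sims, sites, years, cls = np.meshgrid(
        np.arange(1, s + 1), np.arange(1, i + 1), np.arange(1, t + 1), np.arange(4),
        indexing="ij",
    )
    sex = np.array(["female", "female", "male", "male"])
    age = np.array(["SY", "ASY", "SY", "ASY"])
    return pd.DataFrame(
        {
            "simulation": sims.ravel(),
            "site": sites.ravel(),
            "year": years.ravel(),
            "sex": sex[cls.ravel()],
            "age_class": age[cls.ravel()],
            "count": class_counts.ravel(),
        }
    )
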