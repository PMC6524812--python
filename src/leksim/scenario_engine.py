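"""Scenario grid and the simulate -> observe pipeline.

Thirteen monitoring scenarios combine a lek-attendance regime with a
detection regime (the "N" variants flag that the resulting two-occasion
counts are meant for the N-mixture analysis; the simulated data are the
same).  Scenario 1 is the base model — perfect attendance and perfect
detection — so its counts equal true abundance.

Per-(simulation, site) random streams are split between the demographic
process and the observation layer, so all scenarios sharing a master seed
have bit-identical true trajectories and differ only in how they are
observed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _rng
from .demographic_core import SiteState, VitalRateSpec, default_vital_rates, simulate_site
from .observation_model import (
    AttendanceModel,
    DetectionModel,
    detection_schedule,
    observe_counts,
    sample_attendance,
)

__all__ = [
    "ScenarioConfig",
    "SimulationResult",
    "ExtinctionSummary",
    "scenario_config",
    "run_scenario",
    "extinction_summary",
    "SCENARIO_DESCRIPTIONS",
]

SCENARIO_DESCRIPTIONS: dict[int, str] = {
    1: "Perfect lek attendance and perfect detection",
    2: "Proportion of males attend, but not density-based lek attendance",
    3: "Perfect lek attendance, p < 1 (0.5)",
    4: "Density-based lek attendance (p = 0.5)",
    5: "Fixed detection p = 0.25",
    6: "Fixed detection p = 0.375",
    7: "Fixed detection p = 0.5",
    8: "Randomly varied detection (site only)",
    9: "Randomly varied detection (year only)",
    10: "Randomly varied detection (site + year)",
    11: "Trend in detection (0.75 decreasing to 0.25)",
    12: "Density-based lek attendance and p < 1 (0.5)",
    13: "Density-based lek attendance and p randomly drawn (year only)",
}

_PERFECT_ATT = AttendanceModel(mode="perfect")
_AGE_SEX_ATT = AttendanceModel(mode="age_sex_fixed")
_DENSITY_ATT = AttendanceModel(mode="density")

_SCENARIO_TABLE: dict[int, tuple[AttendanceModel, DetectionModel]] = {
    1: (_PERFECT_ATT, DetectionModel(mode="perfect")),
    2: (_AGE_SEX_ATT, DetectionModel(mode="perfect")),
    3: (_PERFECT_ATT, DetectionModel(mode="fixed", p=0.5)),
    4: (_DENSITY_ATT, DetectionModel(mode="fixed", p=0.5)),
    5: (_AGE_SEX_ATT, DetectionModel(mode="fixed", p=0.25)),
    6: (_AGE_SEX_ATT, DetectionModel(mode="fixed", p=0.375)),
    7: (_AGE_SEX_ATT, DetectionModel(mode="fixed", p=0.5)),
    8: (_AGE_SEX_ATT, DetectionModel(mode="uniform_by_site")),
    9: (_AGE_SEX_ATT, DetectionModel(mode="uniform_by_year")),
    10: (_AGE_SEX_ATT, DetectionModel(mode="uniform_by_site_year")),
    11: (_AGE_SEX_ATT, DetectionModel(mode="decreasing_trend")),
    12: (_DENSITY_ATT, DetectionModel(mode="fixed", p=0.5)),
    13: (_DENSITY_ATT, DetectionModel(mode="uniform_by_year")),
}


@dataclass(frozen=True)
class ScenarioConfig:
    """One scenario row plus the simulation settings used to run it."""

    scenario_id: int
    attendance: AttendanceModel
    detection: DetectionModel
    nmixture: bool = False
    n_sims: int = 100
    n_sites: int = 300
    n_years: int = 25
    n_occasions: int = 2
    init_female_sy: int = 20
    init_female_asy: int = 30
    init_male_sy: int = 20
    init_male_asy: int = 30
    vital_rates: VitalRateSpec = field(default_factory=default_vital_rates)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.scenario_id <= 13:
            raise ValueError("scenario id must be in 1..13")
        if self.nmixture and self.scenario_id in (1, 2):
            raise ValueError(
                f"scenario {self.scenario_id} has no N-mixture variant (p = 1)"
            )
        for name in ("n_sims", "n_sites", "n_years", "n_occasions"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def label(self) -> str:
        return f"{self.scenario_id}N" if self.nmixture else str(self.scenario_id)

    def initial_state(self) -> SiteState:
        return SiteState(
            female_sy=self.init_female_sy,
            female_asy=self.init_female_asy,
            male_sy=self.init_male_sy,
            male_asy=self.init_male_asy,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["vital_rates"] = self.vital_rates.to_dict()
        return d


def scenario_config(
    scenario_id: int,
    nmixture: bool = False,
    *,
    vital_rates: VitalRateSpec | None = None,
    **overrides,
) -> ScenarioConfig:
    """Materialize one scenario (attendance x detection) from the grid.

    ``overrides`` may adjust the simulation settings (n_sims, n_sites,
    n_years, master_seed, ...); the attendance/detection combination itself
    is fixed by the scenario id.
    """
    if scenario_id not in _SCENARIO_TABLE:
        raise ValueError(f"scenario id must be in 1..13, got {scenario_id}")
    attendance, detection = _SCENARIO_TABLE[scenario_id]
    return ScenarioConfig(
        scenario_id=scenario_id,
        attendance=attendance,
        detection=detection,
        nmixture=nmixture,
        vital_rates=vital_rates if vital_rates is not None else default_vital_rates(),
        **overrides,
    )


@dataclass
class SimulationResult:
    """Arrays from one scenario run.

    Shapes: ``class_counts`` (sims, sites, years, 4) with the four sex x age
    cells; ``n_lek`` and ``p`` (sims, sites, years); ``counts`` (sims,
    sites, years, occasions).
    """

    config: ScenarioConfig
    class_counts: np.ndarray
    n_lek: np.ndarray
    counts: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        s, i, t = self.n_lek.shape
        if self.class_counts.shape != (s, i, t, 4):
            raise ValueError("class_counts shape mismatch")
        if self.counts.shape[:3] != (s, i, t) or self.p.shape != (s, i, t):
            raise ValueError("counts/p shape mismatch")
        if (self.counts > self.n_lek[..., None]).any():
            raise ValueError("occasion counts exceed attending abundance")
        if (self.n_lek > self.true_total).any():
            raise ValueError("attending abundance exceeds true abundance")

    @property
    def true_total(self) -> np.ndarray:
        """True site abundance, both sexes: (sims, sites, years)."""
        return self.class_counts.sum(axis=-1)

    @property
    def true_male(self) -> np.ndarray:
        return self.class_counts[..., 2:].sum(axis=-1)

    @property
    def true_female(self) -> np.ndarray:
        return self.class_counts[..., :2].sum(axis=-1)

    @property
    def max_counts(self) -> np.ndarray:
        """Per-site-year maximum over occasions: (sims, sites, years)."""
        return self.counts.max(axis=-1)

    def counts_frame(self) -> pd.DataFrame:
        """Tidy occasion counts: simulation, site, year, occasion, count."""
        s, i, t, j = self.counts.shape
        sims, sites, years, occ = np.meshgrid(
            np.arange(1, s + 1),
            np.arange(1, i + 1),
            np.arange(1, t + 1),
            np.arange(1, j + 1),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "simulation": sims.ravel(),
                "site": sites.ravel(),
                "year": years.ravel(),
                "occasion": occ.ravel(),
                "count": self.counts.ravel(),
            }
        )

    def truth_frame(self) -> pd.DataFrame:
        """Companion truth table (evaluation only — estimators must not read it)."""
        s, i, t = self.n_lek.shape
        sims, sites, years = np.meshgrid(
            np.arange(1, s + 1), np.arange(1, i + 1), np.arange(1, t + 1), indexing="ij"
        )
        return pd.DataFrame(
            {
                "simulation": sims.ravel(),
                "site": sites.ravel(),
                "year": years.ravel(),
                "true_total": self.true_total.ravel(),
                "true_male": self.true_male.ravel(),
                "n_lek": self.n_lek.ravel(),
                "p": self.p.ravel(),
            }
        )

    def save(self, directory: str | Path) -> None:
        """Write counts.csv, truth.csv and a JSON run manifest."""
        from . import __version__

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.counts_frame().to_csv(directory / "counts.csv", index=False)
        self.truth_frame().to_csv(directory / "truth.csv", index=False)
        manifest = {
            "package": "leksim",
            "version": __version__,
            "config": self.config.to_dict(),
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def run_scenario(config: ScenarioConfig) -> SimulationResult:
    """Run the full simulate -> observe pipeline for one scenario.

    For every simulation and site: simulate the demographic trajectory, then
    for each year draw lek attendance and the two occasion counts from the
    site's observation stream and the simulation's detection schedule.
    Fully reproducible from (master seed, simulation, site).
    """
    S, I, T, J = config.n_sims, config.n_sites, config.n_years, config.n_occasions
    class_counts = np.zeros((S, I, T, 4), dtype=np.int32)
    n_lek = np.zeros((S, I, T), dtype=np.int32)
    counts = np.zeros((S, I, T, J), dtype=np.int32)
    p_real = np.zeros((S, I, T), dtype=np.float32)
    init = config.initial_state()
    for s in range(S):
        p_mat = detection_schedule(
            config.detection, I, T, rng=_rng.detection_rng(config.master_seed, s)
        )
        p_real[s] = p_mat
        for i in range(I):
            proc = _rng.process_rng(config.master_seed, s, i)
            traj = simulate_site(config.vital_rates, proc, T, init=init)
            class_counts[s, i] = traj
            obs = _rng.observation_rng(config.master_seed, s, i)
            for t in range(T):
                state = SiteState(*map(int, traj[t]), year=t + 1)
                att = sample_attendance(state, config.attendance, obs)
                n_lek[s, i, t] = att.n_lek
                counts[s, i, t] = observe_counts(att.n_lek, p_mat[i, t], obs, J)
    return SimulationResult(
        config=config, class_counts=class_counts, n_lek=n_lek, counts=counts, p=p_real
    )


@dataclass(frozen=True)
class ExtinctionSummary:
    """Site-level extinction and pooled pseudo-extinction statistics."""

    n_sims: int
    n_sites: int
    site_extinctions: int
    pooled_final: np.ndarray  # (n_sims,) total abundance summed over sites at year T

    @property
    def n_site_sims(self) -> int:
        return self.n_sims * self.n_sites

    @property
    def extinct_fraction(self) -> float:
        return self.site_extinctions / self.n_site_sims

    @property
    def max_pooled_final(self) -> int:
        return int(self.pooled_final.max())


def extinction_summary(result: SimulationResult) -> ExtinctionSummary:
    """Count site-simulations extinct by the final year and pool year-T totals.

    Extinction (site total = 0) is absorbing, so a site-simulation is extinct
    by year T iff its final-year total is 0.
    """
    totals = result.true_total
    S, I, _ = totals.shape
    final = totals[..., -1]
    return ExtinctionSummary(
        n_sims=S,
        n_sites=I,
        site_extinctions=int((final == 0).sum()),
        pooled_final=final.sum(axis=1),
    )
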