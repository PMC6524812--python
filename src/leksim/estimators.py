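"""Bayesian trend estimators for lek-count data.

Two hierarchical models share the latent multiplicative-growth process
``N[i,t] = N[i,t-1] * lam[i,t]`` with ``lam[i,t] ~ Gamma(r, beta)``
moment-matched to a long-term mean growth rate ``lambda_bar`` and SD
``sigma_lambda`` (priors Gamma(0.1, 0.1) and Gamma(3, 1)):

* the **state-space model** observes the per-site-year maximum count as
  ``y ~ Poisson(N)`` — no detection correction;
* the **N-mixture model** observes both occasion counts as
  ``y_j ~ Binomial(X, p)`` with integer latent ``X ~ Poisson(N)`` and a
  Beta(1, 1) prior on detection ``p`` (within-year closure assumed).

All sites are fitted jointly (shared lambda_bar, sigma_lambda).  Sampling is
the package's own Metropolis-within-Gibbs engine (:mod:`leksim._gibbs`);
posterior correctness is established by parameter-recovery checks on data
simulated from the models themselves, in the test suite.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._gibbs import ChainDraws, run_chain

__all__ = [
    "GrowthPrior",
    "MCMCSettings",
    "GrowthPosterior",
    "LatentAbundance",
    "ConvergenceWarning",
    "gamma_shape_rate",
    "fit_state_space",
    "fit_nmixture",
    "counts_table",
]


class ConvergenceWarning(UserWarning):
    """Raised (as a warning) when the R-hat diagnostic exceeds its threshold."""


def gamma_shape_rate(lambda_bar: float, sigma_lambda: float) -> tuple[float, float]:
    """Moment-matched Gamma(shape r, rate beta) for the growth multipliers.

    ``r = lambda_bar**2 / sigma_lambda**2`` and
    ``beta = lambda_bar / sigma_lambda**2``, so Gamma(r, beta) has mean
    ``lambda_bar`` and SD ``sigma_lambda``.
    """
    if lambda_bar <= 0 or sigma_lambda <= 0:
        raise ValueError("lambda_bar and sigma_lambda must be > 0")
    v = sigma_lambda**2
    return (lambda_bar**2 / v, lambda_bar / v)


@dataclass(frozen=True)
class GrowthPrior:
    """Hyperpriors of the growth process, as Gamma(shape, rate) pairs."""

    lambda_bar: tuple[float, float] = (0.10, 0.10)
    sigma_lambda: tuple[float, float] = (3.0, 1.0)

    def shape_rate(self, lambda_bar: float, sigma_lambda: float) -> tuple[float, float]:
        return gamma_shape_rate(lambda_bar, sigma_lambda)


@dataclass(frozen=True)
class MCMCSettings:
    """Sampler settings.

    Defaults: 3 chains of 2,000 warmup + 2,000 kept draws; convergence is
    flagged when the rank-normalized split R-hat of lambda_bar or
    sigma_lambda exceeds ``rhat_threshold``.  ``p_structure`` chooses the
    detection parameterization of the N-mixture fit (shared p by default —
    two occasions only weakly identify finer structure; ``by_year`` matches
    annual detection summaries; ``by_site_year`` is the fully saturated
    Beta(1,1)-per-cell form).
    """

    chains: int = 3
    warmup: int = 2000
    draws: int = 2000
    seed: int = 0
    p_structure: str = "shared"
    init_upper_factor: float = 10.0
    rhat_threshold: float = 1.05
    store_latent: str = "total"  # "total" or "full"

    def __post_init__(self) -> None:
        if self.chains < 1 or self.warmup < 0 or self.draws < 1:
            raise ValueError("invalid chain/warmup/draw counts")
        if self.p_structure not in ("shared", "by_year", "by_site_year"):
            raise ValueError(f"unknown p_structure {self.p_structure!r}")
        if self.store_latent not in ("total", "full"):
            raise ValueError("store_latent must be 'total' or 'full'")


@dataclass(frozen=True)
class LatentAbundance:
    """Full latent-abundance draws (chains, draws, sites, years), N > 0.

    ``growth_rates`` returns the implied lam[i,t] = N[i,t]/N[i,t-1]; the
    multiplicative recursion holds for every draw by construction.
    """

    n: np.ndarray

    def __post_init__(self) -> None:
        if self.n.ndim != 4 or (self.n <= 0).any():
            raise ValueError("latent N must be a positive (C, D, I, T) array")

    def growth_rates(self) -> np.ndarray:
        return self.n[..., 1:] / self.n[..., :-1]


@dataclass
class GrowthPosterior:
    """Posterior draws and summaries from one fit.

    Draw arrays are chain-major: ``lambda_bar``/``sigma_lambda`` (C, D),
    ``n_total`` (C, D, T) holding the posterior of total latent abundance
    summed over sites, and for the N-mixture ``p_year`` (C, D, T) and
    ``x_total`` (C, D, T).  ``lambda_bar_sim`` is the plain mean of the
    lambda_bar draws over all kept iterations.
    """

    model: str
    lambda_bar: np.ndarray
    sigma_lambda: np.ndarray
    n_total: np.ndarray
    settings: MCMCSettings
    p_year: np.ndarray | None = None
    x_total: np.ndarray | None = None
    latent: LatentAbundance | None = None
    rhat: dict = field(default_factory=dict)
    accept_rates: list = field(default_factory=list)

    @property
    def lambda_bar_sim(self) -> float:
        return float(self.lambda_bar.mean())

    @property
    def converged(self) -> bool:
        thr = self.settings.rhat_threshold
        return all(v <= thr for v in self.rhat.values() if np.isfinite(v))

    def credible_interval(self, name: str = "lambda_bar", prob: float = 0.95):
        draws = getattr(self, name).ravel()
        a = (1.0 - prob) / 2.0
        return tuple(np.quantile(draws, [a, 1.0 - a]))

    def n_total_interval(self, prob: float = 0.95) -> np.ndarray:
        """Per-year (T, 2) credible bounds of total latent abundance."""
        a = (1.0 - prob) / 2.0
        flat = self.n_total.reshape(-1, self.n_total.shape[-1])
        return np.quantile(flat, [a, 1.0 - a], axis=0).T

    def summary(self) -> pd.DataFrame:
        rows = {}
        named = {"lambda_bar": self.lambda_bar, "sigma_lambda": self.sigma_lambda}
        if self.p_year is not None:
            named["p_mean"] = self.p_year.mean(axis=-1)
        for name, draws in named.items():
            flat = draws.ravel()
            rows[name] = {
                "mean": flat.mean(),
                "sd": flat.std(ddof=1),
                "2.5%": np.quantile(flat, 0.025),
                "50%": np.quantile(flat, 0.5),
                "97.5%": np.quantile(flat, 0.975),
                "rhat": self.rhat.get(name, np.nan),
            }
        return pd.DataFrame(rows).T

    def to_json(self, path: str | Path) -> None:
        payload = {
            "model": self.model,
            "lambda_bar_sim": self.lambda_bar_sim,
            "summary": self.summary().to_dict(orient="index"),
            "n_total_mean": self.n_total.reshape(-1, self.n_total.shape[-1])
            .mean(axis=0)
            .tolist(),
            "n_total_interval": self.n_total_interval().tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def counts_table(frame: pd.DataFrame, simulation: int | None = None) -> np.ndarray:
    """Pivot a tidy counts table into an (I, T, J) occasion array.

    The frame must have columns site, year, occasion, count (1-based), and
    optionally simulation (select one with ``simulation=``).
    """
    if "simulation" in frame.columns:
        if simulation is not None:
            frame = frame[frame["simulation"] == simulation]
        elif frame["simulation"].nunique() > 1:
            raise ValueError("frame holds several simulations; pass simulation=")
    sites = np.sort(frame["site"].unique())
    years = np.sort(frame["year"].unique())
    occs = np.sort(frame["occasion"].unique())
    pivot = frame.set_index(["site", "year", "occasion"])["count"]
    idx = pd.MultiIndex.from_product([sites, years, occs])
    values = pivot.reindex(idx, fill_value=-1).to_numpy(dtype=np.int64)
    return values.reshape(len(sites), len(years), len(occs))


def _compute_rhat(per_chain: dict[str, np.ndarray]) -> dict:
    if next(iter(per_chain.values())).shape[0] < 2:
        return {}
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset({k: v for k, v in per_chain.items()})
        rh = az.rhat(ds)
    return {k: float(rh[k].values) for k in per_chain}


def _finalize(model: str, chains: list[ChainDraws], settings: MCMCSettings) -> GrowthPosterior:
    lb = np.stack([c.lambda_bar for c in chains])
    sg = np.stack([c.sigma_lambda for c in chains])
    nt = np.stack([c.n_total for c in chains])
    post = GrowthPosterior(
        model=model,
        lambda_bar=lb,
        sigma_lambda=sg,
        n_total=nt,
        settings=settings,
        p_year=np.stack([c.p_year for c in chains]) if chains[0].p_year is not None else None,
        x_total=np.stack([c.x_total for c in chains]) if chains[0].x_total is not None else None,
        latent=(
            LatentAbundance(np.stack([c.n_full for c in chains]))
            if chains[0].n_full is not None
            else None
        ),
        accept_rates=[c.accept_rates for c in chains],
    )
    post.rhat = _compute_rhat({"lambda_bar": lb, "sigma_lambda": sg})
    if not post.converged:
        warnings.warn(
            f"{model} fit: R-hat exceeded {settings.rhat_threshold}: {post.rhat}",
            ConvergenceWarning,
            stacklevel=3,
        )
    return post


def _chain_rngs(settings: MCMCSettings) -> list[np.random.Generator]:
    root = np.random.SeedSequence((int(settings.seed), 4242))
    return [np.random.default_rng(s) for s in root.spawn(settings.chains)]


def fit_state_space(
    counts: np.ndarray, settings: MCMCSettings | None = None
) -> GrowthPosterior:
    """Fit the state-space model to max counts.

    ``counts`` is either the (I, T) table of per-site-year maximum counts or
    the (I, T, J) occasion table, in which case the maximum over occasions
    is taken here.  Entries < 0 are treated as missing.
    """
    settings = settings or MCMCSettings()
    y = np.asarray(counts)
    if y.ndim == 3:
        y = y.max(axis=2)
    if y.ndim != 2:
        raise ValueError("counts must be (sites, years) or (sites, years, occasions)")
    chains = [
        run_chain(
            model="statespace",
            y=y.astype(np.int64),
            y_occ=None,
            p_structure=settings.p_structure,
            warmup=settings.warmup,
            draws=settings.draws,
            rng=rng,
            init_upper_factor=settings.init_upper_factor,
            store_latent=settings.store_latent,
        )
        for rng in _chain_rngs(settings)
    ]
    return _finalize("statespace", chains, settings)


def fit_nmixture(
    occasion_counts: np.ndarray, settings: MCMCSettings | None = None
) -> GrowthPosterior:
    """Fit the N-mixture model to the (I, T, J) two-occasion count table."""
    settings = settings or MCMCSettings()
    y_occ = np.asarray(occasion_counts)
    if y_occ.ndim != 3:
        raise ValueError("occasion_counts must be (sites, years, occasions)")
    if (y_occ < 0).any():
        raise ValueError("N-mixture fit requires complete occasion counts")
    y = y_occ.max(axis=2).astype(np.int64)
    chains = [
        run_chain(
            model="nmixture",
            y=y,
            y_occ=y_occ.astype(np.int64),
            p_structure=settings.p_structure,
            warmup=settings.warmup,
            draws=settings.draws,
            rng=rng,
            init_upper_factor=settings.init_upper_factor,
            store_latent=settings.store_latent,
        )
        for rng in _chain_rngs(settings)
    ]
    return _finalize("nmixture", chains, settings)
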