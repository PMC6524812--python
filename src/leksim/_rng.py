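"""Reproducible random-stream plumbing.

One master seed spawns independent streams keyed by purpose so that process
trajectories, attendance/observation draws, detection schedules and MCMC
chains never share a stream.  Scaling the number of sites or simulations
leaves all other streams untouched, and the demographic process at a given
(simulation, site) is bit-identical across scenarios that share a master
seed.
"""

from __future__ import annotations

import numpy as np

# domain tags keeping the keyed streams disjoint
_PROCESS = 11
_OBSERVE = 13
_DETECT = 17
_FIT = 29


def _rng(*key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(tuple(int(k) for k in key)))


def process_rng(master_seed: int, sim: int, site: int) -> np.random.Generator:
    """Stream driving the demographic process at one (simulation, site)."""
    return _rng(master_seed, _PROCESS, sim, site)


def observation_rng(master_seed: int, sim: int, site: int) -> np.random.Generator:
    """Stream driving lek attendance and counts at one (simulation, site)."""
    return _rng(master_seed, _OBSERVE, sim, site)


def detection_rng(master_seed: int, sim: int) -> np.random.Generator:
    """Stream driving the site x year detection-probability schedule."""
    return _rng(master_seed, _DETECT, sim)


def fit_seed(master_seed: int, *key: int) -> int:
    """A derived integer seed (< 2**31) for an MCMC fit."""
    ss = np.random.SeedSequence((int(master_seed), _FIT) + tuple(int(k) for k in key))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))


def truncated_normal(
    rng: np.random.Generator,
    mean,
    sd,
    low: float = 0.0,
    high: float = np.inf,
) -> np.ndarray:
    """Draw from Normal(mean, sd) truncated to [low, high], elementwise.

    Zero-sd entries return their mean.  Rejection sampling; at the small
    coefficients of variation used here acceptance is near 1, and a hard cap
    falls back to clipping so the call always terminates.
    """
    scalar = np.isscalar(mean) and np.isscalar(sd)
    mean = np.atleast_1d(np.asarray(mean, dtype=float))
    sd = np.atleast_1d(np.asarray(sd, dtype=float))
    mean, sd = np.broadcast_arrays(mean, sd)
    out = mean.copy()
    active = sd > 0
    if not np.any(active):
        out = np.clip(out, low, high)
        return float(out[0]) if scalar else out
    draw = rng.normal(mean, np.where(active, sd, 0.0))
    bad = active & ((draw < low) | (draw > high))
    for _ in range(100):
        if not np.any(bad):
            break
        draw[bad] = rng.normal(mean[bad], sd[bad])
        bad = active & ((draw < low) | (draw > high))
    out[active] = np.clip(draw[active], low, high)
    out[~active] = np.clip(out[~active], low, high)
    return float(out[0]) if scalar else out
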