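"""Structured-config (YAML/JSON) overrides for simulations.

A config file may carry a ``vital_rates`` block (parameter -> {mean, sd})
and a ``simulation`` block with ScenarioConfig overrides, e.g.::

    vital_rates:
      chick_survival: {mean: 0.30, sd: 0.01}
    simulation:
      n_sims: 10
      n_sites: 50
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .demographic_core import VitalRateSpec, default_vital_rates

__all__ = ["load_config", "load_vital_rates"]

_SIM_KEYS = {"n_sims", "n_sites", "n_years", "n_occasions", "master_seed"}


def _read(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text) or {}


def load_vital_rates(path: str | Path) -> VitalRateSpec:
    """Vital rates from a config file; unlisted parameters keep defaults."""
    data = _read(path)
    overrides = data.get("vital_rates", data)
    base = default_vital_rates().to_dict()
    base.update(overrides or {})
    return VitalRateSpec.from_dict(base)


def load_config(path: str | Path) -> tuple[VitalRateSpec, dict]:
    """Returns (vital rates, simulation-setting overrides)."""
    data = _read(path)
    rates = load_vital_rates(path)
    sim = {k: v for k, v in (data.get("simulation") or {}).items() if k in _SIM_KEYS}
    return rates, sim
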