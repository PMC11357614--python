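"""YAML (de)serialization of run and sweep configurations.

One fixed dialect: a flat mapping with an optional ``tmap`` sub-mapping for
the thermal interpolation and a ``topology`` sub-mapping (``n_B_per_end``,
``n_A``).  Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import yaml

from .errors import ParameterError
from .forcefield import ChainTopology, ThermalMap
from .phase_diagram import SweepConfig
from .simulate import RunConfig

__all__ = ["load_run_config", "load_sweep_config", "dump_config"]


def _build(cls, data: dict, **extra):
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ParameterError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data, **extra)


def _pop_tmap(data: dict):
    if "tmap" in data:
        return _build(ThermalMap, data.pop("tmap"))
    return None


def load_run_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text())
    topo = _build(ChainTopology, data.pop("topology"))
    tmap = _pop_tmap(data)
    if tmap is not None:
        data["tmap"] = tmap
    return _build(RunConfig, data, topology=topo)


def load_sweep_config(path) -> SweepConfig:
    data = yaml.safe_load(Path(path).read_text())
    tmap = _pop_tmap(data)
    if tmap is not None:
        data["tmap"] = tmap
    for key in ("temperatures", "ratios"):
        if key in data:
            data[key] = tuple(data[key])
    return _build(SweepConfig, data)


def dump_config(config, path) -> None:
    """Write a RunConfig or SweepConfig back to YAML (replayable)."""
    if isinstance(config, RunConfig):
        data = config.to_dict()
        data["topology"] = {
            "n_B_per_end": data.pop("n_B_per_end"),
            "n_A": data.pop("n_A"),
        }
    elif isinstance(config, SweepConfig):
        data = {
            "temperatures": list(config.temperatures),
            "ratios": list(config.ratios),
        }
        for k in (
            "replicates", "n_chains", "volume_fraction", "dt", "gamma",
            "n_warmup", "n_equil", "n_prod", "stride", "master_seed",
        ):
            data[k] = getattr(config, k)
        data["tmap"] = {
            k: getattr(config.tmap, k)
            for k in (
                "t_min", "t_max", "eps_AA_at_tmin", "eps_AA_at_tmax",
                "eps_AB_at_tmin", "eps_AB_at_tmax", "form",
            )
        }
    else:
        raise ParameterError(f"cannot serialize {type(config).__name__}")
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
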