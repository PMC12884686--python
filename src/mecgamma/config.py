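"""YAML (de)serialization of parameter sets.

Config files hold one block per component, e.g.::

    pv_cell: {cm: 50.0, g_na: 14000.0, ...}
    e_cell: {cm: 60.0, ...}
    connectivity: {n_i: 100, p_ii: 0.3, ...}
    drive: {freq: 8.0, peak_i_mean: 4.0, ...}
    synapses: {ii_e_rev: -75.0, ...}

Omitted fields keep their defaults, so a config only needs to state what
it changes.
"""

from __future__ import annotations

import dataclasses

import yaml

from .cells import ECellParams, PVCellParams
from .network import ConnectivitySpec
from .simulate import DriveSpec, SynapseParams

__all__ = ["load_config", "dump_config", "SECTIONS"]

SECTIONS = {
    "pv_cell": PVCellParams,
    "e_cell": ECellParams,
    "connectivity": ConnectivitySpec,
    "drive": DriveSpec,
    "synapses": SynapseParams,
}


def _build(cls, data: dict):
    if cls is ConnectivitySpec and "delay_range" in data:
        data = dict(data, delay_range=tuple(data["delay_range"]))
    return cls(**data)


def load_config(path) -> dict:
    """Read a YAML config; returns {section: dataclass instance}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out = {}
    for name, cls in SECTIONS.items():
        out[name] = _build(cls, raw.get(name, {}) or {})
    unknown = set(raw) - set(SECTIONS)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    return out


def dump_config(config: dict, path) -> None:
    """Write {section: dataclass} to YAML (full field listing)."""
    raw = {}
    for name, obj in config.items():
        d = dataclasses.asdict(obj)
        d.pop("kinetics", None)  # gating tables are code-level constants
        raw[name] = {k: (list(v) if isinstance(v, tuple) else v)
                     for k, v in d.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
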