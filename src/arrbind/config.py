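"""Run configuration for the analysis pipeline.

A run is described by one YAML file naming the inputs (topology, replica
trajectories, optional reference complex and nonbonded parameter table),
the named atom selections, cutoffs and window schemes.  Every value has an
explicit default; the resolved configuration (defaults filled in) is logged
and hashed so that output tables can be traced back to the exact settings
that produced them.
"""

from __future__ import annotations

import copy
import hashlib
import json
import pathlib
from dataclasses import dataclass

import yaml

__all__ = ["ConfigError", "RunConfig", "load_run_config", "DEFAULTS"]


class ConfigError(ValueError):
    """Raised for malformed configuration before any computation starts."""


DEFAULTS: dict = {
    "topology": None,
    "trajectories": [],
    "trajectory_format": None,
    "dt_ns": None,
    "reference": None,            # defaults to the topology itself
    "params_tsv": None,
    "structures": [],             # for structure-metrics
    "output_dir": "arrbind_out",
    "seed": 0,
    "selections": {},             # name -> selection expression
    "windows": {"length_ns": 500.0, "burn_in_ns": 500.0, "intervals": None},
    "contacts": {"cutoff_nm": 0.5, "residues": "icl3", "target": "membrane"},
    "geometry": {
        "tm_bundle": "tm_bundle", "nlobe": "nlobe", "clobe": "clobe",
        "fit": "receptor_fit", "disengage_threshold_nm": 5.3,
        "d_edges": [4.0, 5.4, 0.025], "alpha_edges": [-40.0, 50.0, 1.0],
    },
    "energetics": {"cutoff_nm": 1.2, "window_ns": 100.0, "burn_in_ns": 500.0,
                   "group_a": "icl3", "group_b": "membrane",
                   "permittivity": 1.0},
    "helicity": {"chain": "R", "resids": [137, 146],
                 "phi_window": [-100.0, -30.0], "psi_window": [-80.0, -5.0],
                 "min_run": 4},
    "simulate": {"n_frames": 5000, "dt_ns": 0.1},
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


@dataclass
class RunConfig:
    data: dict
    path: pathlib.Path | None = None

    def __getitem__(self, key):
        return self.data[key]

    def get(self, key, default=None):
        return self.data.get(key, default)

    @property
    def config_hash(self) -> str:
        canon = json.dumps(self.data, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def resolve_path(self, value) -> pathlib.Path:
        p = pathlib.Path(value)
        if not p.is_absolute() and self.path is not None:
            p = self.path.parent / p
        return p

    def require_file(self, key: str) -> pathlib.Path:
        value = self.data.get(key)
        if not value:
            raise ConfigError(f"configuration key {key!r} is required")
        p = self.resolve_path(value)
        if not p.exists():
            raise ConfigError(f"{key}: file not found: {p}")
        return p

    def require_files(self, key: str) -> list[pathlib.Path]:
        values = self.data.get(key) or []
        if isinstance(values, (str, pathlib.Path)):
            values = [values]
        if not values:
            raise ConfigError(f"configuration key {key!r} needs at least one "
                              "entry")
        out = []
        for v in values:
            p = self.resolve_path(v)
            if not p.exists():
                raise ConfigError(f"{key}: file not found: {p}")
            out.append(p)
        return out


def load_run_config(source, path=None) -> RunConfig:
    """Load a RunConfig from a YAML path, mapping, or None (pure defaults)."""
    if source is None:
        return RunConfig(copy.deepcopy(DEFAULTS), path)
    if isinstance(source, (str, pathlib.Path)):
        p = pathlib.Path(source)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        try:
            raw = yaml.safe_load(p.read_text()) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"config file {p} is not valid YAML: {exc}")
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {p} must contain a mapping")
        return RunConfig(_merge(DEFAULTS, raw), p)
    if isinstance(source, dict):
        return RunConfig(_merge(DEFAULTS, source), path)
    raise ConfigError(f"cannot build a RunConfig from {type(source)!r}")
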