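"""Pipeline configuration: defaults, schema validation, manifest helpers.

Every analysis threshold default matches the study conventions: 25% panel
exclusion rule, 0.90 trajectory reliability threshold with 50 runs dropping
20% of participants, 7-fold jackknife with 100 iterations, 1000 label
permutations, and the 4-day delivery window for the labor classifier.
"""

from __future__ import annotations

import hashlib
import json
from copy import deepcopy

import yaml

DEFAULTS = {
    "seed": 0,
    "n_women": 700,
    "panel": None,  # None -> full default panel
    "stages": {
        "simulate": True,
        "preprocess": True,
        "trajectories": True,
        "rmasca": True,
        "lateterm": True,
    },
    "preprocess": {
        "reference_lot": "L1",
        "exclusion_threshold": 0.25,
        "outlier_quantile": 0.999,
    },
    "outliers": {"removals": []},
    "trajectories": {
        "n_runs": 50,
        "drop_frac": 0.20,
        "rho_threshold": 0.90,
        "n_basis": 10,
    },
    "rmasca": {
        "n_folds": 7,
        "n_iter": 100,
        "group": None,
        "group_ref": None,
        "n_components": 2,
    },
    "lateterm": {
        "n_perm": 1000,
        "window_days": 4,
        "n_orth": 1,
        "holdout": 0.10,
    },
}

# (type, lower bound, upper bound); None bound = unbounded
_SCHEMA = {
    "seed": (int, 0, 2**31 - 1),
    "n_women": (int, 2, None),
    "panel": ((list, type(None)), None, None),
    "stages.simulate": (bool, None, None),
    "stages.preprocess": (bool, None, None),
    "stages.trajectories": (bool, None, None),
    "stages.rmasca": (bool, None, None),
    "stages.lateterm": (bool, None, None),
    "preprocess.reference_lot": (str, None, None),
    "preprocess.exclusion_threshold": (float, 0.0, 1.0),
    "preprocess.outlier_quantile": (float, 0.5, 1.0),
    "outliers.removals": (list, None, None),
    "trajectories.n_runs": (int, 1, None),
    "trajectories.drop_frac": (float, 0.0, 0.95),
    "trajectories.rho_threshold": (float, 0.0, 1.0),
    "trajectories.n_basis": (int, 4, 50),
    "rmasca.n_folds": (int, 2, None),
    "rmasca.n_iter": (int, 1, None),
    "rmasca.group": ((str, type(None)), None, None),
    "rmasca.group_ref": ((str, type(None)), None, None),
    "rmasca.n_components": (int, 1, 10),
    "lateterm.n_perm": (int, 1, None),
    "lateterm.window_days": (int, 0, None),
    "lateterm.n_orth": (int, 0, 10),
    "lateterm.holdout": (float, 0.01, 0.5),
}


class ConfigError(ValueError):
    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n" + "\n".join(self.errors))


def _walk(d, prefix=""):
    for k, v in d.items():
        path = f"{prefix}{k}"
        if isinstance(v, dict):
            yield from _walk(v, path + ".")
        else:
            yield path, v


def validate_config(raw: dict | str | None) -> dict:
    """Merge user config over defaults; collect *all* schema violations.

    ``raw`` may be a mapping, a YAML string, or None (full defaults).
    Unknown keys are rejected; raises :class:`ConfigError` with every
    problem enumerated by path.
    """
    if raw is None:
        raw = {}
    if isinstance(raw, str):
        raw = yaml.safe_load(raw) or {}
    if not isinstance(raw, dict):
        raise ConfigError(["top level must be a mapping"])
    cfg = deepcopy(DEFAULTS)
    errors = []
    for path, value in _walk(raw):
        if path not in _SCHEMA:
            errors.append(f"{path}: unknown key")
            continue
        typ, lo, hi = _SCHEMA[path]
        if typ is float and isinstance(value, int) and not isinstance(value, bool):
            value = float(value)
        if not isinstance(value, typ) or (typ is int and isinstance(value, bool)):
            errors.append(f"{path}: expected {typ}, got {type(value).__name__}")
            continue
        if value is not None and not isinstance(value, (list, str, bool)):
            if lo is not None and value < lo:
                errors.append(f"{path}: {value} below minimum {lo}")
                continue
            if hi is not None and value > hi:
                errors.append(f"{path}: {value} above maximum {hi}")
                continue
        node = cfg
        *parents, leaf = path.split(".")
        for p in parents:
            node = node[p]
        node[leaf] = value
    if errors:
        raise ConfigError(errors)
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
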