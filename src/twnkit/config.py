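"""Run configuration: defaults, YAML loading and validation.

The config is a nested key-value file; unknown keys are rejected and all
validation problems are reported together.  Units are Angstrom and
kcal/mol throughout.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .energetics import COULOMB_CONSTANT, PotentialParams
from .errors import ConfigError

DEFAULTS: dict = {
    "potential": {
        "A": 582000.0,
        "C": 595.0,
        "q_O": -0.834,
        "q_H": 0.417,
        "coulomb_constant": COULOMB_CONSTANT,
    },
    "hbond": {
        "threshold_kcal": -2.25,
        "prefilter_A": 3.5,
    },
    "rings": {
        "min_size": 3,
        "max_size": 6,
        "chordless": True,
    },
    "site": {
        "center": None,       # [x, y, z] A; null = reference-ligand centroid
        "radius": 25.0,
    },
    "assignment": {
        "cutoff_A": 5.0,
        "lprime_cutoff_A": None,  # null = same as cutoff_A
    },
    "grid": {
        "spacing_A": 0.5,
        "water_radius_A": 1.4,
        "com_cutoff_A": 2.0,
        "mode": "coverage",
    },
    "inputs": {
        "frames": None,
        "frames_format": None,    # null = infer from suffix
        "ligand": None,
        "ligand_format": None,
        "regions": None,
    },
    "output": {
        "dir": "twn_out",
        "overlays": False,
    },
    "seed": 0,
}

# (path, predicate, message) range checks applied after merging
_CHECKS = [
    (("potential", "A"), lambda v: v > 0, "must be positive"),
    (("potential", "C"), lambda v: v > 0, "must be positive"),
    (("potential", "coulomb_constant"), lambda v: v > 0, "must be positive"),
    (("hbond", "threshold_kcal"), lambda v: v < 0, "must be negative"),
    (("hbond", "prefilter_A"), lambda v: v >= 3.2, "must be >= 3.2 A"),
    (("rings", "min_size"), lambda v: 3 <= v <= 6, "must be in 3..6"),
    (("rings", "max_size"), lambda v: 3 <= v <= 6, "must be in 3..6"),
    (("site", "radius"), lambda v: v > 0, "must be positive"),
    (("assignment", "cutoff_A"), lambda v: v > 0, "must be positive"),
    (("grid", "spacing_A"), lambda v: v > 0, "must be positive"),
    (("grid", "water_radius_A"), lambda v: v > 0, "must be positive"),
    (("grid", "com_cutoff_A"), lambda v: v > 0, "must be positive"),
    (("grid", "mode"), lambda v: v in ("coverage", "tanimoto"),
     "must be 'coverage' or 'tanimoto'"),
]


@dataclass
class RunConfig:
    """Validated analysis parameters with defaults filled in."""

    values: dict = field(default_factory=lambda: copy.deepcopy(DEFAULTS))

    def __getitem__(self, key: str):
        return self.values[key]

    def potential_params(self) -> PotentialParams:
        p = self.values["potential"]
        h = self.values["hbond"]
        return PotentialParams(
            A=p["A"], C=p["C"], q_o=p["q_O"], q_h=p["q_H"],
            coulomb_constant=p["coulomb_constant"],
            hbond_threshold=h["threshold_kcal"],
            distance_prefilter=h["prefilter_A"],
        )

    def flat(self) -> dict[str, object]:
        """Flattened ``section.key -> value`` view for audit logging."""
        out: dict[str, object] = {}

        def walk(prefix, d):
            for k, v in d.items():
                if isinstance(v, dict):
                    walk(f"{prefix}{k}.", v)
                else:
                    out[f"{prefix}{k}"] = v

        walk("", self.values)
        return out


def _merge(defaults: dict, user: dict, path: str, problems: list[str]) -> dict:
    merged = {}
    for key, dval in defaults.items():
        here = f"{path}{key}"
        if key in user:
            uval = user[key]
            if isinstance(dval, dict):
                if isinstance(uval, dict):
                    merged[key] = _merge(dval, uval, here + ".", problems)
                else:
                    problems.append(f"{here}: expected a mapping")
                    merged[key] = copy.deepcopy(dval)
            else:
                merged[key] = _coerce(dval, uval, here, problems)
        else:
            merged[key] = copy.deepcopy(dval)
    for key in user:
        if key not in defaults:
            problems.append(f"{path}{key}: unknown key")
    return merged


def _coerce(default, value, path, problems):
    if value is None or default is None:
        return value
    if isinstance(default, bool):
        if isinstance(value, bool):
            return value
        problems.append(f"{path}: expected true/false, got {value!r}")
        return default
    if isinstance(default, (int, float)) and isinstance(value, (int, float)) \
            and not isinstance(value, bool):
        return type(default)(value) if isinstance(default, float) else value
    if isinstance(default, str) and isinstance(value, str):
        return value
    if type(default) is type(value):
        return value
    problems.append(
        f"{path}: expected {type(default).__name__}, got {type(value).__name__}"
    )
    return default


def validate_config(source: str | Path | dict | None = None) -> RunConfig:
    """Load and validate a config mapping or YAML file.

    Missing keys take defaults; unknown keys, wrong types and out-of-range
    values are reported collectively in a single :class:`ConfigError`.
    An empty file yields all defaults.
    """
    if source is None:
        user: dict = {}
    elif isinstance(source, dict):
        user = copy.deepcopy(source)
    else:
        path = Path(source)
        if not path.exists():
            raise ConfigError(f"no such config file: {path}")
        try:
            user = yaml.safe_load(path.read_text()) or {}
        except yaml.YAMLError as err:
            raise ConfigError(f"{path}: not valid YAML: {err}") from err
        if not isinstance(user, dict):
            raise ConfigError(f"{path}: config must be a mapping")

    problems: list[str] = []
    merged = _merge(DEFAULTS, user, "", problems)
    for keypath, pred, msg in _CHECKS:
        v = merged
        for k in keypath:
            v = v[k]
        if v is not None and not pred(v):
            problems.append(f"{'.'.join(keypath)}: value {v!r} {msg}")
    if merged["rings"]["min_size"] > merged["rings"]["max_size"]:
        problems.append("rings: min_size exceeds max_size")
    center = merged["site"]["center"]
    if center is not None and (
        not isinstance(center, (list, tuple)) or len(center) != 3
    ):
        problems.append("site.center: expected [x, y, z]")
    if problems:
        raise ConfigError(
            "invalid configuration:\n  " + "\n  ".join(sorted(problems))
        )
    return RunConfig(values=merged)
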