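"""Configuration loading, validation, and run manifests.

Configs are YAML or JSON mappings of the model constants and protocol
settings; missing fields fall back to the standard constants used across
the protocols (D = 0.2/h, kappa = 0.005/h, gamma = 0.9, mu0 = 0.5/h,
survival threshold 0.01, horizon 200 h). Validation collects every
violation before raising, so a broken config is reported in full.

Every CLI run writes a :class:`RunManifest` next to its tables: command,
fully resolved configuration, master seed, package version and timestamps
— enough to re-execute the run bit-exactly.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError

__all__ = ["DEFAULTS", "load_config", "resolve_config", "RunManifest", "write_results"]

DEFAULTS = {
    "D": 0.2,
    "kappa": 0.005,
    "gamma": 0.9,
    "mu0": 0.5,
    "eta": 0.0,
    "threshold": 0.01,
    "t_max": 200.0,
    "composition": "multiplicative",
    "seed": 0,
}

_VALIDATORS = {
    "D": lambda v: v >= 0 or "D must be non-negative",
    "kappa": lambda v: v >= 0 or "kappa must be non-negative",
    "gamma": lambda v: v >= 0 or "gamma must be non-negative",
    "mu0": lambda v: v > 0 or "mu0 must be positive",
    "eta": lambda v: v >= 0 or "eta must be non-negative",
    "threshold": lambda v: v > 0 or "threshold must be positive",
    "t_max": lambda v: v > 0 or "t_max must be positive",
    "composition": lambda v: v in ("multiplicative", "additive")
    or "composition must be 'multiplicative' or 'additive'",
    "seed": lambda v: (isinstance(v, int) and v >= 0) or "seed must be a non-negative integer",
}


def resolve_config(overrides: dict | None = None) -> dict:
    """Apply defaults and validate; raises ConfigError listing every problem."""
    cfg = dict(DEFAULTS)
    if overrides:
        cfg.update(overrides)
    problems = []
    for key, check in _VALIDATORS.items():
        value = cfg[key]
        if key != "composition" and key != "seed":
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                problems.append(f"{key}: expected a number, got {value!r}")
                continue
        result = check(value)
        if result is not True:
            problems.append(f"{key}: {result}")
    if problems:
        raise ConfigError(problems)
    return cfg


def load_config(path) -> dict:
    """Parse a YAML/JSON config file and resolve it against the defaults."""
    path = Path(path)
    if not path.exists():
        raise ConfigError([f"config file not found: {path}"])
    text = path.read_text()
    try:
        doc = yaml.safe_load(text) or {}  # YAML is a JSON superset
    except yaml.YAMLError as exc:
        raise ConfigError([f"could not parse {path}: {exc}"]) from exc
    if not isinstance(doc, dict):
        raise ConfigError([f"config root must be a mapping, got {type(doc).__name__}"])
    return resolve_config(doc)


def _package_version() -> str:
    try:
        from importlib.metadata import version

        return version("hgtlv")
    except Exception:
        return "unknown"


@dataclass
class RunManifest:
    """Provenance record written alongside every result set."""

    command: str
    config: dict
    seed: int
    version: str = field(default_factory=_package_version)
    created: str = field(
        default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat()
    )
    outputs: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "command": self.command,
            "config": self.config,
            "seed": self.seed,
            "version": self.version,
            "created": self.created,
            "outputs": list(self.outputs),
        }


def write_results(tables: dict, manifest: RunManifest, out_dir) -> list:
    """Write each table as ``<name>.csv`` plus ``manifest.json``.

    Empty tables still produce a header-only CSV; row order is whatever
    the caller fixed (all callers emit deterministically ordered frames).
    Returns the file inventory, which is also recorded in the manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inventory = []
    for name, frame in tables.items():
        target = out / f"{name}.csv"
        frame.to_csv(target, index=False)
        inventory.append(str(target))
    manifest.outputs = inventory + [str(out / "manifest.json")]
    (out / "manifest.json").write_text(json.dumps(manifest.to_dict(), indent=2))
    return manifest.outputs
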