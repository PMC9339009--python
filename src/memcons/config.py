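"""Experiment configuration loading and validation."""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import scipy
import yaml

EXPERIMENTS = ("simulate", "network_check", "perturb", "hetero",
               "capacity_scan")

# keys every experiment needs; experiment-specific requirements below
_REQUIRED: dict[str, tuple[str, ...]] = {
    "simulate": ("tau", "lam_tau", "b"),
    "network_check": ("N", "f"),
    "perturb": ("tau", "lam_tau", "b", "kind"),
    "hetero": ("alpha", "r0", "b"),
    "capacity_scan": ("tau", "lam_tau", "b", "N_grid"),
}


class ConfigError(ValueError):
    pass


@dataclass
class ExperimentConfig:
    """A validated experiment description.

    ``parameters`` mirrors the keyword arguments of the corresponding
    library entry point; unknown experiments and missing required keys
    are rejected up front with a message naming the offending keys.
    """

    experiment: str
    parameters: dict = field(default_factory=dict)
    output_dir: str = "."
    seed: int = 0

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ConfigError(
                f"unknown experiment {self.experiment!r}; "
                f"expected one of {', '.join(EXPERIMENTS)}")
        missing = [k for k in _REQUIRED[self.experiment]
                   if k not in self.parameters]
        if missing:
            raise ConfigError(
                f"experiment {self.experiment!r} is missing required "
                f"parameter(s): {', '.join(missing)}")
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")


def load_config(path: str | Path) -> ExperimentConfig:
    """Read a YAML experiment file."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "experiment" not in raw:
        raise ConfigError(f"{path}: expected a mapping with an "
                          "'experiment' key")
    return ExperimentConfig(
        experiment=raw["experiment"],
        parameters=raw.get("parameters", {}),
        output_dir=raw.get("output_dir", "."),
        seed=int(raw.get("seed", 0)),
    )


def write_manifest(out_dir: str | Path, experiment: str, parameters: dict,
                   seed: int) -> Path:
    """Record everything needed for a byte-identical re-run."""
    from . import __version__
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "experiment": experiment,
        "parameters": parameters,
        "seed": seed,
        "versions": {"memcons": __version__, "numpy": np.__version__,
                     "scipy": scipy.__version__,
                     "python": platform.python_version()},
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, default=str))
    return path
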