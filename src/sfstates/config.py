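"""Run configuration and provenance.

Defaults reproduce the analysis parameters the pipeline is built around:
ion cutoff 1.4 Å, oxygen cutoff 3.2 Å, cavity probe starting 2 Å below the
lower boundary of S4 and extending 20 Å intracellularly with 0.5 Å spacing,
cluster-count candidates 2–15. Precedence: built-in defaults < YAML config
file < explicit overrides (CLI flags).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .errors import ArgumentError

__version__ = "0.1.0"


@dataclass
class RunConfig:
    structure: str | None = None
    topology: str | None = None
    trajectory: str | None = None
    site_scheme: str = "herg"
    d_c_ion: float = 1.4          # Å
    d_c_oxygen: float = 3.2       # Å
    cavity_offset: float = 2.0    # Å below the lower boundary of S4
    cavity_length: float = 20.0   # Å toward the intracellular side
    cavity_spacing: float = 0.5   # Å between axis points
    k_min: int = 2
    k_max: int = 15
    stride: int = 1
    frame_interval: float = 0.01  # ns between stored frames
    seed: int = 0
    output_dir: str = "."

    def k_candidates(self) -> range:
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ArgumentError(
                f"invalid k range [{self.k_min}, {self.k_max}]")
        return range(self.k_min, self.k_max + 1)


def load_config(path: str | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus overrides."""
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ArgumentError(f"config file {path} must hold a mapping")
        unknown = set(loaded) - {f.name for f in
                                 dataclasses.fields(RunConfig)}
        if unknown:
            raise ArgumentError(f"unknown config keys: {sorted(unknown)}")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**values)


def provenance_record(config: RunConfig) -> dict:
    """Machine-readable record sufficient to reproduce deterministic runs."""
    payload = dataclasses.asdict(config)
    digest = hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()).hexdigest()
    return {"config": payload, "config_sha256": digest,
            "seed": config.seed, "version": __version__}
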