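"""Run configuration and reproducibility plumbing.

A single YAML document (optionally overridden by CLI flags) selects the
workflow stage, the input/output paths and the SAEM settings.  Every
stochastic stage receives an explicit seed derived from one master seed
through ``numpy.random.SeedSequence`` spawning, and each run writes a
JSON manifest (configuration echo, derived seeds, package versions and
input hashes) so deterministic stages re-run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import yaml

from .saem.engine import SaemSettings

__all__ = ["RunConfig", "stage_seed", "write_manifest"]

STAGES = ("simulate", "fit-iv", "fit-sequential", "select-covariates",
          "diagnose", "vpc", "screen-correlations")

#: fixed spawn index per stage so stage seeds are independent and stable
_STAGE_INDEX = {name: i for i, name in enumerate(STAGES)}


@dataclass
class RunConfig:
    stage: str
    output_dir: str = "runs"
    dataset: Optional[str] = None
    model: Optional[str] = None
    design: str = "reference"
    seed: int = 0
    verbosity: int = 1
    saem: SaemSettings = field(default_factory=SaemSettings)

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValueError(
                f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if isinstance(self.saem, dict):
            self.saem = SaemSettings(**self.saem)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive the stage's integer seed from the master seed (stable scheme)."""
    ss = np.random.SeedSequence(master_seed).spawn(len(STAGES))
    return int(ss[_STAGE_INDEX[stage]].generate_state(1)[0] % (2 ** 31))


def _hash_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(config: RunConfig, out_dir, inputs: Dict[str, str],
                   extra: Optional[dict] = None) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    import saempk
    manifest = {
        "config": config.to_dict(),
        "stage_seed": stage_seed(config.seed, config.stage),
        "versions": {
            "saempk": saempk.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
        "input_hashes": {k: _hash_file(v) for k, v in inputs.items()
                         if v and Path(v).exists()},
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
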