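"""Run configuration: YAML schema, validation, and run manifests.

Every CLI run validates its configuration against a strict schema (unknown
keys are rejected with field-level messages) and writes a ``manifest.json``
recording the configuration hash, master seed, package/library versions and
SHA-256 checksums of every input file, so any run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy
import pandas
import sklearn
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .fsriel import FoBaConfig, FSRIELConfig

__all__ = ["RunConfig", "load_config", "write_manifest", "file_sha256"]


class FoBaSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    eta: float = Field(0.005, gt=0)
    nu: float = Field(0.5, ge=0, lt=1)
    max_features: int = Field(20, ge=1)
    cv: int = Field(3, ge=2)
    cv_repeats: int = Field(1, ge=1)
    objective: str = Field("hinge", pattern="^(hinge|accuracy)$")


class LearnerSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    fraction: float = Field(0.02, gt=0, le=1)
    inner_k: int = Field(3, ge=2)
    c_grid: list[float] = Field(default_factory=lambda: [0.01, 0.1, 1.0, 10.0])

    @field_validator("c_grid")
    @classmethod
    def _nonempty(cls, v: list[float]) -> list[float]:
        if not v:
            raise ValueError("c_grid must be non-empty")
        return v


class RunConfig(BaseModel):
    """Top-level configuration for all subcommands."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    fraction: float = Field(0.02, gt=0, le=1)
    inner_k: int = Field(3, ge=2)
    foba: FoBaSettings = Field(default_factory=FoBaSettings)
    learners: LearnerSettings = Field(default_factory=LearnerSettings)
    k: int = Field(5, ge=2)
    repeats: int = Field(10, ge=1)
    stability_threshold: int = Field(10, ge=1)
    baseline_k: int | None = None
    verbosity: int = Field(1, ge=0, le=2)

    def fsriel_config(self, seed: int | None = None) -> FSRIELConfig:
        return FSRIELConfig(
            fraction=self.fraction,
            inner_k=self.inner_k,
            c_grid=tuple(self.learners.c_grid),
            foba=FoBaConfig(
                eta=self.foba.eta,
                nu=self.foba.nu,
                max_features=self.foba.max_features,
                cv=self.foba.cv,
                cv_repeats=self.foba.cv_repeats,
                objective=self.foba.objective,
            ),
            seed=self.seed if seed is None else seed,
        )


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML config; ``None`` yields all defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    config: RunConfig,
    seed: int,
    inputs: dict[str, str | Path],
    extra: dict | None = None,
) -> Path:
    """Write manifest.json with config hash, seed, versions and input checksums."""
    from . import __version__

    cfg_json = config.model_dump_json()
    manifest = {
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": seed,
        "versions": {
            "connsel": __version__,
            "python": platform.python_version(),
            "numpy": numpy.__version__,
            "pandas": pandas.__version__,
            "scikit-learn": sklearn.__version__,
        },
        "inputs": {
            name: {"path": str(p), "sha256": file_sha256(p)}
            for name, p in inputs.items()
            if Path(p).is_file()
        },
    }
    if extra:
        manifest.update(extra)
    out = Path(out_dir) / "manifest.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
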