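"""Flat, typed run configuration with fail-fast validation.

Unknown keys are rejected (catching typos in threshold names), thresholds
must lie in [0, 1], and declared input paths must exist before any compute
starts. Defaults carry the screen's standard operating points: QED >= 0.35,
prediction score > 0.82, degree bins of at least 100 nodes, 1000 null
iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import yaml

from .errors import ValidationError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    interactome: str
    cti: str
    disease: str
    qed: str | None = None
    annotations: str | None = None
    node_mapping: str | None = None
    qed_threshold: float = 0.35
    score_threshold: float = 0.82
    min_bin_size: int = 100
    n_iterations: int = 1000
    seed: int = 0
    sigma_tolerance: float = 1e-12
    output_dir: str = "netprox_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        try:
            raw = yaml.safe_load(path.read_text())
        except OSError as exc:
            raise ValidationError(f"cannot read config {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ValidationError(f"config {path} is not a key-value document")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        missing = {"interactome", "cti", "disease"} - set(raw)
        if missing:
            raise ValidationError(f"config missing required key(s): {sorted(missing)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in ("qed_threshold", "score_threshold"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {val}")
        if self.n_iterations < 2:
            raise ValidationError("n_iterations must be >= 2")
        if self.min_bin_size < 1:
            raise ValidationError("min_bin_size must be >= 1")
        for name in ("interactome", "cti", "disease", "qed", "annotations", "node_mapping"):
            val = getattr(self, name)
            if val is not None and not Path(val).exists():
                raise ValidationError(f"input path for {name!r} does not exist: {val}")
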