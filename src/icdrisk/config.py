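"""Pipeline configuration: defaults, JSON/YAML loading, validation."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Everything a full run needs beyond the input tables.

    ``evaluated_set`` selects which assessments enter the evaluation:
    ``"rated"`` keeps those with clinical_score > 0 (the basis on which the
    cross-validation is defined), ``"all"`` keeps everything.
    """

    k: int = 10
    seed: int = 0
    variant: str = "normalized-ratio"
    theta: float = 0.5
    mode: str = "binary"
    cv_unit: str = "assessment"
    evaluated_set: str = "rated"
    simulate: dict | None = None  # generator overrides; None = use input CSVs

    def validate(self) -> "PipelineConfig":
        problems = []
        if self.k < 2:
            problems.append(f"k must be >= 2, got {self.k}")
        if self.variant not in ("normalized-ratio", "raw-ratio"):
            problems.append(f"variant must be normalized-ratio|raw-ratio, got {self.variant!r}")
        if not (0.0 < self.theta < 1.0):
            problems.append(f"theta must lie in (0, 1), got {self.theta}")
        if self.mode not in ("binary", "weighted"):
            problems.append(f"mode must be binary|weighted, got {self.mode!r}")
        if self.cv_unit not in ("assessment", "patient"):
            problems.append(f"cv_unit must be assessment|patient, got {self.cv_unit!r}")
        if self.evaluated_set not in ("rated", "all"):
            problems.append(f"evaluated_set must be rated|all, got {self.evaluated_set!r}")
        if problems:
            raise ValueError("invalid configuration:\n  " + "\n  ".join(problems))
        return self

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a config file (JSON or YAML by extension); None gives defaults."""
    if path is None:
        return PipelineConfig().validate()
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
    return PipelineConfig(**data).validate()
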