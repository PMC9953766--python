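"""Pipeline configuration: one dataclass, YAML round-trip, stable hashing.

Defaults equal the pipeline's published constants (448-pixel patches with a
50-pixel overlap, 0.5 segmentation and decision thresholds, a 30% hold-out,
5 folds with an 80/20 inner split, partial-AUC cutoff 0.40, erosion radius 3,
10 importance repeats).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .cascade import CLASSIFIER_KINDS

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    seed: int = 0
    patch_size: int = 448
    overlap: int = 50
    seg_threshold: float = 0.5
    decision_threshold: float = 0.5
    test_fraction: float = 0.30
    folds: int = 5
    inner_train_fraction: float = 0.8
    classifier_kinds: list[str] = field(
        default_factory=lambda: list(CLASSIFIER_KINDS))
    segmenter: str = "heuristic"       # dotted path or builtin mock name
    level0: str = "tiny_image"         # dotted path or builtin name
    partial_auc_cutoff: float = 0.40
    erosion_radius: int = 3
    importance_repeats: int = 10
    pairing: str = "foldwise"

    def __post_init__(self) -> None:
        for name in ("test_fraction", "inner_train_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        for name in ("seg_threshold", "decision_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        unknown = set(self.classifier_kinds) - set(CLASSIFIER_KINDS)
        if unknown:
            raise ValueError(f"unknown classifier kinds: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def manifest(self) -> dict:
        import dermcascade

        return {"config": asdict(self), "config_hash": self.config_hash(),
                "version": dermcascade.__version__}
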