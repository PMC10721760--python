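"""Pipeline configuration: every named threshold in one validated object."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .profiles import MIN_LENGTH, MIN_SELF_SCORE, SCORE_FLOOR, MIN_OTHER_SPECIES
from .cladepp import CLADE_MIN_SPECIES, DEFAULT_CUT_GRID

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Thresholds, classifier settings and seeds for a full run.

    Defaults are the analysis constants: 40-aa length filter, 80-bit
    self-score filter, 24.6-bit floor, >=5 supporting proteomes, 10-species
    clade eligibility, top 1% candidates, 20% missingness cap, 3-sigma
    outlier rule, MLP (180, 90, 40) with lr 1e-4 / alpha 0.1, RF with 55
    trees of depth 15.
    """

    # profile construction
    min_length: int = MIN_LENGTH
    min_self_score: float = MIN_SELF_SCORE
    score_floor: float = SCORE_FLOOR
    min_other_species: int = MIN_OTHER_SPECIES
    # clade-wise clustering
    clade_min_species: int = CLADE_MIN_SPECIES
    cut_grid: tuple[int, ...] = DEFAULT_CUT_GRID
    min_cluster_size: int = 3
    top_fraction: float = 0.01
    # ML validation
    max_missing_fraction: float = 0.20
    sigma: float = 3.0
    test_fraction: float = 0.2
    mlp_hidden: tuple[int, ...] = (180, 90, 40)
    mlp_learning_rate: float = 1e-4
    mlp_alpha: float = 0.1
    rf_n_estimators: int = 55
    rf_max_depth: int = 15
    # reproducibility
    seed: int = 0

    def validate(self) -> None:
        positive = {
            "min_length": self.min_length,
            "score_floor": self.score_floor,
            "min_other_species": self.min_other_species,
            "clade_min_species": self.clade_min_species,
            "min_cluster_size": self.min_cluster_size,
            "sigma": self.sigma,
            "mlp_learning_rate": self.mlp_learning_rate,
            "mlp_alpha": self.mlp_alpha,
            "rf_n_estimators": self.rf_n_estimators,
            "rf_max_depth": self.rf_max_depth,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.min_self_score < 0:
            raise ValueError("min_self_score must be non-negative")
        if not 0.0 < self.top_fraction <= 1.0:
            raise ValueError(f"top_fraction must be in (0, 1], got {self.top_fraction}")
        if not 0.0 <= self.max_missing_fraction < 1.0:
            raise ValueError("max_missing_fraction must be in [0, 1)")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")
        if not self.cut_grid:
            raise ValueError("cut_grid must be non-empty")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("cut_grid", "mlp_hidden"):
            if key in data:
                data[key] = tuple(data[key])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def asdict(self) -> dict:
        d = asdict(self)
        d["cut_grid"] = list(self.cut_grid)
        d["mlp_hidden"] = list(self.mlp_hidden)
        return d
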