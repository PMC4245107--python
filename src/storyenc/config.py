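"""Run configuration: one validated record tying the pipeline together.

Every CLI invocation reads a :class:`RunConfig` (YAML file plus flag
overrides) and writes the exact configuration used next to its outputs, so
any result directory is reproducible from its own provenance copy.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import numpy as np
import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # paths
    annotations: str | None = None
    feature_sets: str | None = None
    fmri: list[str] = field(default_factory=list)
    outdir: str = "out"
    # model
    tr: float = 2.0
    n_lags: int = 4
    penalty_grid: list[float] = field(
        default_factory=lambda: [float(v) for v in np.logspace(0, 7, 8)])
    inner_folds: int = 5
    # evaluation
    n_folds: int = 10
    trim: int | None = None
    seg_len: int = 20
    n_pairings: int = 10
    # searchlight
    feature_set: str | None = None
    edge_voxels: int = 5
    stride: int = 1
    min_voxels: int = 10
    smoothing_fwhm: float = 0.0
    # stats
    fdr_level: float = 0.05
    n_permutations: int = 20
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.n_lags < 1:
            raise ValueError("n_lags must be >= 1")
        if not self.penalty_grid or any(v < 0 for v in self.penalty_grid):
            raise ValueError("penalty_grid must be non-empty and non-negative")
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.seg_len < 1:
            raise ValueError("seg_len must be >= 1")
        if self.n_pairings < 1:
            raise ValueError("n_pairings must be >= 1")
        if self.edge_voxels < 1 or self.edge_voxels % 2 == 0:
            raise ValueError("edge_voxels must be odd and >= 1")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.smoothing_fwhm < 0:
            raise ValueError("smoothing_fwhm must be non-negative")
        if not 0 < self.fdr_level < 1:
            raise ValueError("fdr_level must lie in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def replace(self, **overrides) -> "RunConfig":
        d = asdict(self)
        d.update({k: v for k, v in overrides.items() if v is not None})
        return RunConfig(**d)
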