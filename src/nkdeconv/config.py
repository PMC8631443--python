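"""Run configuration: one seed, every stage parameter, lossless YAML round-trip."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import yaml


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with the package defaults."""

    seed: int = 0
    outdir: str = "results/pipeline"
    # synthetic reference
    n_genes: int = 1000
    reps_per_leaf: int = 10
    marker_frac: float = 0.6
    effect_logfc: float = 2.0
    dispersion: float = 0.05
    # survival pool
    pool_n: int = 2000
    pool_median_days: float = 700.0
    pool_shape: float = 1.2
    # foreign cell type
    foreign_reps: int = 4
    # deconvolution / association
    backend: str = "nnls"
    nu_grid: list[float] = field(default_factory=lambda: [0.25, 0.5, 0.75])
    alpha: float = 0.05
    censor_fraction: float = 0.5
    # benchmark grid
    replicate_levels: list[int] = field(default_factory=lambda: [250, 500, 1000])
    slope_levels: list[float] = field(
        default_factory=lambda: [-1.0, -0.75, -0.5, -0.25, 0.0, 0.25, 0.5, 0.75, 1.0]
    )
    foreign_levels: list[float] = field(default_factory=lambda: [0.0, 0.4, 0.8])
    runs_per_condition: int = 63
    max_conditions: int | None = None  # truncate the grid for reduced runs

    def child_seed(self, stage: int) -> int:
        """Stable per-stage seed derived from the global seed."""
        return int(np.random.SeedSequence([self.seed, stage]).generate_state(1)[0] % (2**31))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def hash(self) -> str:
        payload = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
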