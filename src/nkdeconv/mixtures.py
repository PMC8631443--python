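"""Simulated bulk tissue mixtures with survival-linked cell-type proportions.

Each mixture is a proportion-weighted sum of CPM-normalized reference
profiles drawn at random from the compendium, optionally spiked with a
"foreign" cell type absent from the signature.  One focal cell type's
proportion is tied to progression-free survival on the logit scale: the
focal share of the leaf compartment q satisfies

    logit(q) = logit(q_baseline) + slope * z,

where z is the survival time standardized by the pool's mean and sd.
Working on the share scale keeps every proportion in (0, 1) and the leaf
compartment total exactly at 1 - foreign_prop for any slope.  Censoring is
emulated by halving the time-to-event and clearing the event flag for a
chosen fraction of mixtures.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit, logit as _logit

from .simulate import FOREIGN_LABEL, ForeignCells, ReferenceCompendium, SurvivalPool

#: default condition grid: 3 replicate counts x 9 slopes x 3 foreign fractions = 81
REPLICATE_LEVELS = (250, 500, 1000)
SLOPE_LEVELS = (-1.0, -0.75, -0.5, -0.25, 0.0, 0.25, 0.5, 0.75, 1.0)
FOREIGN_LEVELS = (0.0, 0.4, 0.8)

_EPS = 1e-6


@dataclass(frozen=True)
class SimulationCondition:
    n_replicates: int
    slope: float
    foreign_prop: float

    def __post_init__(self) -> None:
        if not 250 <= self.n_replicates <= 1000:
            raise ValueError("n_replicates must lie in [250, 1000]")
        if not -1.0 <= self.slope <= 1.0:
            raise ValueError("slope must lie in [-1, 1]")
        if not 0.0 <= self.foreign_prop <= 0.8:
            raise ValueError("foreign_prop must lie in [0, 0.8]")


@dataclass
class MixtureSample:
    """One simulated bulk sample with its ground truth."""

    expression: np.ndarray
    true_props: np.ndarray  # over leaves + foreign, sums to 1
    pfs_time: float
    event: int


@dataclass
class MixtureSet:
    """A run of simulated mixtures under one condition and focal type."""

    gene_index: list[str]
    cell_types: list[str]  # leaf names + "foreign" (last)
    expression: np.ndarray  # genes x samples
    proportions: np.ndarray  # samples x cell_types
    pfs_time: np.ndarray
    event: np.ndarray
    condition: SimulationCondition
    focal_type: str
    run_seed: int
    draw_indices: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]

    @property
    def samples(self) -> list[MixtureSample]:
        return [
            MixtureSample(
                expression=self.expression[:, i],
                true_props=self.proportions[i],
                pfs_time=float(self.pfs_time[i]),
                event=int(self.event[i]),
            )
            for i in range(self.n_samples)
        ]


def make_condition_grid() -> list[SimulationCondition]:
    """Full factorial grid over the default levels, in deterministic order."""
    return [
        SimulationCondition(n, s, f)
        for n, s, f in itertools.product(REPLICATE_LEVELS, SLOPE_LEVELS, FOREIGN_LEVELS)
    ]


def simulate_run(
    condition: SimulationCondition,
    compendium: ReferenceCompendium,
    survival_pool: SurvivalPool,
    focal_type: str,
    seed: int,
    foreign: ForeignCells | None = None,
    keep_draws: bool = False,
) -> MixtureSet:
    """Simulate one test run of ``condition.n_replicates`` tissue mixtures."""
    leaves = list(dict.fromkeys(compendium.cell_types))
    if focal_type not in leaves:
        raise ValueError(f"focal type {focal_type!r} is not a compendium cell type")
    if survival_pool.times.size < condition.n_replicates:
        raise ValueError("survival pool smaller than the number of replicates")
    f = condition.foreign_prop
    if f > 0 and (foreign is None or len(foreign) == 0):
        raise ValueError("foreign_prop > 0 requires foreign profiles")

    rng = np.random.default_rng(seed)
    n = condition.n_replicates
    times = rng.choice(survival_pool.times, size=n, replace=True)
    z = (times - survival_pool.times.mean()) / survival_pool.times.std()

    baseline = rng.dirichlet(np.ones(len(leaves)), size=n)  # shares within leaves
    focal_j = leaves.index(focal_type)
    q0 = np.clip(baseline[:, focal_j], _EPS, 1 - _EPS)
    q = expit(_logit(q0) + condition.slope * z)
    shares = baseline.copy()
    shares[:, focal_j] = 0.0
    rest = shares.sum(axis=1, keepdims=True)
    rest[rest == 0] = 1.0
    shares *= ((1.0 - q) / rest.ravel())[:, None]
    shares[:, focal_j] = q

    props = np.empty((n, len(leaves) + 1))
    props[:, : len(leaves)] = shares * (1.0 - f)
    props[:, -1] = f

    cell_types = leaves + [FOREIGN_LABEL]
    expr = np.zeros((compendium.n_genes, n))
    draws = np.empty((n, len(cell_types)), dtype=int) if keep_draws else None
    for j, ct in enumerate(cell_types):
        if ct == FOREIGN_LABEL:
            if f == 0:
                if keep_draws:
                    draws[:, j] = -1
                continue
            counts = np.stack([p.counts for p in foreign.profiles], axis=1).astype(float)
            cpm = counts / counts.sum(axis=0) * 1e6
        else:
            cpm = compendium.cpm(compendium.columns_for(ct))
        idx = rng.integers(0, cpm.shape[1], size=n)
        expr += cpm[:, idx] * props[:, j][None, :]
        if keep_draws:
            draws[:, j] = idx

    return MixtureSet(
        gene_index=list(compendium.gene_index),
        cell_types=cell_types,
        expression=expr,
        proportions=props,
        pfs_time=times.astype(float),
        event=np.ones(n, dtype=int),
        condition=condition,
        focal_type=focal_type,
        run_seed=seed,
        draw_indices=draws,
    )


def apply_censoring(
    mixtures: MixtureSet, fraction: float = 0.5, seed: int = 0
) -> MixtureSet:
    """Halve the time-to-event and clear the event flag for a random subset.

    Exactly ``floor(fraction * n)`` samples, chosen uniformly, are censored;
    the rest keep their original time with the event observed.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("censoring fraction must lie in [0, 1]")
    n = mixtures.n_samples
    k = int(np.floor(fraction * n))
    rng = np.random.default_rng(seed)
    censored = rng.choice(n, size=k, replace=False)
    times = mixtures.pfs_time.copy()
    events = np.ones(n, dtype=int)
    times[censored] /= 2.0
    events[censored] = 0
    return replace(mixtures, pfs_time=times, event=events)
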