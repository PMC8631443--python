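"""Synthetic reference data with the statistical structure the pipeline assumes.

Counts are negative-binomial (NB2: variance mu + phi*mu^2), the standard model
for RNA-seq counts across biological replicates.  Cell-type mean structure is
hierarchical: a shared per-gene baseline, lineage genes elevated across all
leaves of an internal taxonomy unit, and leaf-exclusive marker genes elevated
in a single leaf.  Every ordered pair of units compared during marker
selection therefore has its own block of cleanly discriminative genes.

Progression-free survival times are emulated with a right-skewed Weibull
stand-in scaled to a requested median; real patient times can be supplied to
downstream stages instead but are never required.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .taxonomy import CellTypeTaxonomy

FOREIGN_LABEL = "foreign"


@dataclass
class ReferenceProfile:
    """One labelled replicate: integer counts over the shared gene index."""

    sample_id: str
    cell_type: str
    counts: np.ndarray

    @property
    def library_size(self) -> int:
        return int(self.counts.sum())

    def __post_init__(self) -> None:
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.counts.sum() <= 0:
            raise ValueError("profile library size must be positive")


@dataclass
class CompendiumTruth:
    """Data-generating parameters stored alongside a simulated compendium."""

    mean: np.ndarray  # genes x leaves expected counts (before size factors)
    dispersion: np.ndarray  # per leaf
    marker_unit: dict[str, str]  # gene -> taxonomy unit it marks
    size_factors: np.ndarray  # per profile
    effect_logfc: float = 0.0


@dataclass
class ReferenceCompendium:
    """Labelled cell-type expression profiles over a shared gene index."""

    gene_index: list[str]
    counts: np.ndarray  # genes x samples, ints
    sample_ids: list[str]
    cell_types: list[str]  # per sample
    taxonomy: CellTypeTaxonomy | None = None
    truth: CompendiumTruth | None = None

    def __post_init__(self) -> None:
        g, n = self.counts.shape
        if g != len(self.gene_index):
            raise ValueError("gene index length does not match counts")
        if len(self.sample_ids) != n or len(self.cell_types) != n:
            raise ValueError("sample annotation length does not match counts")
        if self.taxonomy is not None:
            leaves = set(self.taxonomy.leaves)
            bad = set(self.cell_types) - leaves
            if bad:
                raise ValueError(f"profiles labelled with non-taxonomy types: {sorted(bad)}")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_profiles(self) -> int:
        return self.counts.shape[1]

    @property
    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def profiles(self) -> list[ReferenceProfile]:
        return [
            ReferenceProfile(sid, ct, self.counts[:, j])
            for j, (sid, ct) in enumerate(zip(self.sample_ids, self.cell_types))
        ]

    def columns_for(self, cell_type: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.cell_types) == np.str_(cell_type))

    def cpm(self, columns: np.ndarray | None = None) -> np.ndarray:
        """Counts-per-million matrix (genes x samples)."""
        cols = slice(None) if columns is None else columns
        sub = self.counts[:, cols].astype(float)
        lib = sub.sum(axis=0)
        return sub / lib * 1e6


@dataclass
class SurvivalPool:
    """A pool of positive progression-free survival times (days)."""

    times: np.ndarray
    source: str = "synthetic"

    def __post_init__(self) -> None:
        if np.any(self.times <= 0):
            raise ValueError("survival times must be positive")


@dataclass
class ForeignCells:
    """Profiles of a cell type deliberately absent from the taxonomy."""

    profiles: list[ReferenceProfile] = field(default_factory=list)
    mean: np.ndarray | None = None  # truth mean vector over the gene index
    dispersion: float = 0.05

    def __iter__(self):
        return iter(self.profiles)

    def __len__(self) -> int:
        return len(self.profiles)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB2 sample: variance mean + dispersion*mean^2."""
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _marker_units(taxonomy: CellTypeTaxonomy) -> list[str]:
    """Leaves first, then internal units that own >1 leaf (levels 1-2)."""
    units = list(taxonomy.leaves)
    for l1, branch in taxonomy.tree.items():
        if branch:
            units.append(l1)
            for l2, kids in branch.items():
                if kids:
                    units.append(l2)
    return units


def gen_reference_compendium(
    taxonomy: CellTypeTaxonomy,
    n_genes: int = 1000,
    reps_per_leaf: int | dict[str, int] = 10,
    marker_frac: float = 0.6,
    effect_logfc: float = 2.0,
    dispersion: float = 0.05,
    seed: int = 0,
    baseline_log_mean: float = math.log(100.0),
    baseline_log_sd: float = 1.0,
    size_factor_sd: float = 0.2,
) -> ReferenceCompendium:
    """Simulate a hierarchy-structured NB reference compendium.

    Each leaf receives ``ceil(marker_frac * n_genes / n_leaves)`` exclusive
    marker genes whose mean is ``exp(effect_logfc)``-fold the shared baseline;
    internal units at levels 1-2 receive the same quota of lineage genes
    elevated across all their descendant leaves.  Remaining genes are
    unstructured background.  The generating means, dispersions and marker
    assignments are stored in ``truth``.
    """
    if n_genes < 50:
        raise ValueError("n_genes must be >= 50")
    if effect_logfc <= 0:
        raise ValueError("effect_logfc must be positive")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    leaves = taxonomy.leaves
    if isinstance(reps_per_leaf, dict):
        reps = {leaf: int(reps_per_leaf.get(leaf, reps_per_leaf.get("default", 10))) for leaf in leaves}
    else:
        reps = {leaf: int(reps_per_leaf) for leaf in leaves}
    if min(reps.values()) < 2:
        raise ValueError("reps_per_leaf must be >= 2 for every leaf")

    units = _marker_units(taxonomy)
    quota = math.ceil(marker_frac * n_genes / len(leaves))
    if quota * len(units) > n_genes:
        raise ValueError(
            f"marker structure needs {quota * len(units)} genes "
            f"({quota} per unit x {len(units)} units) but n_genes={n_genes}"
        )

    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    gene_index = [f"gene{str(i).zfill(width)}" for i in range(n_genes)]
    baseline = rng.normal(baseline_log_mean, baseline_log_sd, n_genes)
    log_mean = np.tile(baseline[:, None], (1, len(leaves)))

    leaf_col = {leaf: j for j, leaf in enumerate(leaves)}
    marker_unit: dict[str, str] = {}
    for i, unit in enumerate(units):
        cols = [leaf_col[leaf] for leaf in taxonomy.descendant_leaves(unit)]
        genes = range(i * quota, (i + 1) * quota)
        for g in genes:
            marker_unit[gene_index[g]] = unit
            log_mean[g, cols] += effect_logfc

    mean = np.exp(log_mean)

    sample_ids: list[str] = []
    cell_types: list[str] = []
    cols_mean: list[np.ndarray] = []
    for leaf in leaves:
        for k in range(reps[leaf]):
            sample_ids.append(f"{leaf}_rep{k}")
            cell_types.append(leaf)
            cols_mean.append(mean[:, leaf_col[leaf]])
    n_samples = len(sample_ids)
    size_factors = rng.lognormal(0.0, size_factor_sd, n_samples)
    mu = np.stack(cols_mean, axis=1) * size_factors[None, :]
    counts = _nb_draw(rng, mu, dispersion)

    truth = CompendiumTruth(
        mean=mean,
        dispersion=np.full(len(leaves), dispersion),
        marker_unit=marker_unit,
        size_factors=size_factors,
        effect_logfc=effect_logfc,
    )
    return ReferenceCompendium(
        gene_index=gene_index,
        counts=counts,
        sample_ids=sample_ids,
        cell_types=cell_types,
        taxonomy=taxonomy,
        truth=truth,
    )


def gen_survival_pool(
    n: int,
    median_days: float = 700.0,
    shape: float = 1.2,
    seed: int = 0,
) -> SurvivalPool:
    """Weibull-distributed positive times scaled to the requested median.

    Shape 1.2 gives the right-skew typical of progression-free survival
    (mean > median); the scale is solved from the Weibull median
    ``scale * ln(2)^(1/shape)``.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    if median_days <= 0 or shape <= 0:
        raise ValueError("median_days and shape must be positive")
    rng = np.random.default_rng(seed)
    scale = median_days / math.log(2.0) ** (1.0 / shape)
    times = scale * rng.weibull(shape, n)
    times = np.maximum(times, 1e-6)  # Weibull support is open at 0
    return SurvivalPool(times=times, source="synthetic")


def gen_foreign_profiles(
    gene_index: list[str],
    reps: int,
    seed: int = 0,
    leaf_means: np.ndarray | None = None,
    dispersion: float = 0.05,
    library_size: float = 2e5,
    max_leaf_correlation: float = 0.9,
) -> ForeignCells:
    """NB profiles of a cell type outside the taxonomy ("foreign").

    Log-means are drawn independently of any leaf.  When ``leaf_means``
    (genes x leaves truth means) is supplied, the mean vector is redrawn with
    a shifted seed until its Pearson correlation with every leaf mean is
    below ``max_leaf_correlation``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    n_genes = len(gene_index)
    attempt = 0
    while True:
        rng = np.random.default_rng(seed + attempt)
        log_mean = rng.normal(math.log(100.0), 1.0, n_genes)
        mean = np.exp(log_mean)
        if leaf_means is None:
            break
        corrs = [
            abs(np.corrcoef(mean, leaf_means[:, j])[0, 1])
            for j in range(leaf_means.shape[1])
        ]
        if max(corrs) < max_leaf_correlation:
            break
        attempt += 1
        if attempt > 100:
            raise RuntimeError("could not draw a foreign profile distinct from all leaves")
    scale = library_size / mean.sum()
    profiles = [
        ReferenceProfile(
            sample_id=f"{FOREIGN_LABEL}_rep{k}",
            cell_type=FOREIGN_LABEL,
            counts=_nb_draw(rng, mean * scale, dispersion),
        )
        for k in range(reps)
    ]
    return ForeignCells(profiles=profiles, mean=mean, dispersion=dispersion)
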