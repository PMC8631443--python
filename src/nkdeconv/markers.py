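"""Hierarchical marker-gene selection and signature-matrix assembly.

Markers are chosen by pairwise credible-interval separation along the
taxonomy: at level 1 the root's children are compared, at level 2 the
siblings within each level-1 branch, at level 3 the siblings within each
level-2 branch.  For an ordered pair (A, B) a gene is a candidate when the
lower 95% credible bound of its mean in A exceeds the upper bound in B —
i.e. A's posterior interval lies wholly above B's.  The top 5, 10 and 20
positively-separated genes per ordered pair are kept at levels 1, 2 and 3
respectively, and the signature is the union across all levels and pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nbmodel import PosteriorSet
from .taxonomy import CellTypeTaxonomy

logger = logging.getLogger(__name__)

#: genes kept per ordered pair at taxonomy levels 1, 2, 3
TOP_K_PER_LEVEL: dict[int, int] = {1: 5, 2: 10, 3: 20}


@dataclass
class MarkerSet:
    """Ranked marker lists per (level, ordered unit pair)."""

    pair_markers: dict[tuple[int, str, str], list[str]] = field(default_factory=dict)

    @property
    def union(self) -> list[str]:
        """Deduplicated, sorted union of all per-pair lists."""
        out: set[str] = set()
        for genes in self.pair_markers.values():
            out.update(genes)
        return sorted(out)

    def pairs_at_level(self, level: int) -> dict[tuple[str, str], list[str]]:
        return {
            (a, b): genes
            for (lvl, a, b), genes in self.pair_markers.items()
            if lvl == level
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"level": lvl, "unit_a": a, "unit_b": b, "rank": r + 1, "gene": g}
            for (lvl, a, b), genes in self.pair_markers.items()
            for r, g in enumerate(genes)
        ]
        return pd.DataFrame(rows, columns=["level", "unit_a", "unit_b", "rank", "gene"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MarkerSet":
        out = cls()
        for (lvl, a, b), sub in df.groupby(["level", "unit_a", "unit_b"], sort=False):
            out.pair_markers[(int(lvl), str(a), str(b))] = list(
                sub.sort_values("rank")["gene"]
            )
        return out


@dataclass
class SignatureMatrix:
    """Marker-genes x cell-types basis of CPM-scale expression values."""

    genes: list[str]
    cell_types: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.genes), len(self.cell_types)):
            raise ValueError("signature values shape does not match labels")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicated gene in signature matrix")
        if np.any(self.values < 0):
            raise ValueError("signature values must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.genes, name="gene"),
                            columns=self.cell_types)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SignatureMatrix":
        return cls(genes=list(df.index), cell_types=list(df.columns),
                   values=df.to_numpy(dtype=float))

    @classmethod
    def from_tsv(cls, path) -> "SignatureMatrix":
        return cls.from_frame(pd.read_csv(path, sep="\t", index_col=0))


def _ranked_positive(posteriors: PosteriorSet, a: str, b: str, k: int) -> list[str]:
    """Top-k genes by descending separation(a, b), positive only.

    Ties in separation are broken lexicographically by gene name so the
    selection is reproducible.
    """
    sep = posteriors.separation(a, b)
    genes = np.asarray(posteriors.genes)
    order = np.lexsort((genes, -sep))
    ranked = order[sep[order] > 0]
    return [str(g) for g in genes[ranked[:k]]]


def select_markers(posteriors: PosteriorSet, taxonomy: CellTypeTaxonomy) -> MarkerSet:
    """Select markers for every ordered sibling pair at every level.

    ``posteriors`` must contain a fitted unit for every taxonomy unit that
    enters a comparison (leaves and internal units; see
    :func:`nkdeconv.nbmodel.fit_hierarchy_posteriors`).
    """
    needed = {u for _, scope in taxonomy.sibling_scopes() for u in scope}
    missing = {u for u in needed if u not in posteriors}
    if missing:
        raise ValueError(f"posteriors lack taxonomy units: {sorted(missing)}")

    out = MarkerSet()
    for level, scope in taxonomy.sibling_scopes():
        k = TOP_K_PER_LEVEL[level]
        for a in scope:
            for b in scope:
                if a != b:
                    out.pair_markers[(level, a, b)] = _ranked_positive(posteriors, a, b, k)
    return out


def build_signature_matrix(
    posteriors: PosteriorSet,
    markers: MarkerSet,
    taxonomy: CellTypeTaxonomy | None = None,
) -> SignatureMatrix:
    """Assemble the deconvolution basis from posterior mean expression.

    Rows are the sorted marker union; columns are the taxonomy leaves (or,
    without a taxonomy, every leaf unit present in the posteriors).  Rows
    that end up all-zero are dropped with a warning.
    """
    union = markers.union
    if not union:
        raise ValueError("marker union is empty; cannot build a signature matrix")
    cell_types = taxonomy.leaves if taxonomy is not None else list(posteriors.units)
    gi = {g: i for i, g in enumerate(posteriors.genes)}
    rows = [gi[g] for g in union]
    cols = np.stack([posteriors.mean_column(ct)[rows] for ct in cell_types], axis=1)
    keep = ~np.all(cols == 0, axis=1)
    if not keep.all():
        dropped = [g for g, k in zip(union, keep) if not k]
        logger.warning("dropping %d all-zero signature rows: %s", len(dropped), dropped)
    return SignatureMatrix(
        genes=[g for g, k in zip(union, keep) if k],
        cell_types=list(cell_types),
        values=cols[keep],
    )


def validate_activation_markers(
    posteriors: PosteriorSet,
    markers_of_interest: list[str],
    up_type: str,
    ref_type: str,
) -> pd.DataFrame:
    """Check that candidate activation markers are upregulated.

    For each gene, reports the credible-interval separation of ``up_type``
    over ``ref_type`` and flags the gene when the separation is positive
    (the activated phenotype's interval lies wholly above the reference).
    Genes absent from the posterior table are listed as missing.
    """
    sep_all = posteriors.separation(up_type, ref_type)
    gi = {g: i for i, g in enumerate(posteriors.genes)}
    records = []
    for gene in markers_of_interest:
        if gene not in gi:
            records.append({"gene": gene, "separation": np.nan, "flag": False, "missing": True})
        else:
            s = float(sep_all[gi[gene]])
            records.append({"gene": gene, "separation": s, "flag": s > 0, "missing": False})
    return pd.DataFrame.from_records(
        records, columns=["gene", "separation", "flag", "missing"]
    )
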