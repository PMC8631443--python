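"""TSV readers and writers for the pipeline's on-disk contracts.

Expression matrices are genes x samples TSVs with a gene-name first column;
clinical tables carry sample_id, pfs_days, event (0/1) and an optional
grade column.  Compendia round-trip as counts + sample-annotation +
taxonomy TSVs in one directory.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import ReferenceCompendium, SurvivalPool
from .taxonomy import CellTypeTaxonomy

logger = logging.getLogger(__name__)


def read_expression_matrix(path) -> pd.DataFrame:
    """Read a genes x samples TSV; duplicate gene rows are summed."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns")
    header_numeric = all(_is_number(c) for c in df.columns)
    if header_numeric:
        raise ValueError(f"{path}: missing header row (all column names numeric)")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(f"{path}: non-numeric cell at row {bad[0]!r}, column {col!r}")
        df[col] = coerced
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        logger.warning("aggregating duplicated gene rows by sum: %s", dups)
        df = df.groupby(level=0, sort=False).sum()
    return df


def _is_number(s) -> bool:
    try:
        float(s)
        return True
    except (TypeError, ValueError):
        return False


def write_expression_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def read_clinical_table(path) -> pd.DataFrame:
    """Read a clinical TSV: sample_id, pfs_days, event (0/1), optional grade."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "pfs_days", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if (df["pfs_days"] <= 0).any():
        raise ValueError(f"{path}: non-positive pfs_days")
    if not df["event"].isin([0, 1]).all():
        raise ValueError(f"{path}: event values must be 0 or 1")
    if "grade" in df.columns and not df["grade"].isin(["low", "high"]).all():
        raise ValueError(f"{path}: grade values must be 'low' or 'high'")
    return df


def align_clinical(
    expression: pd.DataFrame, clinical: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame, list[str]]:
    """Align clinical rows to expression columns by sample id.

    Returns (times, events, aligned clinical frame, unmatched sample ids).
    """
    clin = clinical.set_index("sample_id")
    matched = [s for s in expression.columns if s in clin.index]
    unmatched = [s for s in expression.columns if s not in clin.index]
    if unmatched:
        logger.warning("samples without clinical records: %s", unmatched)
    aligned = clin.loc[matched]
    return (
        aligned["pfs_days"].to_numpy(dtype=float),
        aligned["event"].to_numpy(dtype=int),
        aligned.reset_index(),
        unmatched,
    )


def write_taxonomy(taxonomy: CellTypeTaxonomy, path) -> None:
    pd.DataFrame(taxonomy.to_rows(), columns=["level1", "level2", "leaf"]).to_csv(
        path, sep="\t", index=False
    )


def read_taxonomy(path) -> CellTypeTaxonomy:
    df = pd.read_csv(path, sep="\t")
    return CellTypeTaxonomy.from_rows(
        [tuple(r) for r in df[["level1", "level2", "leaf"]].itertuples(index=False)]
    )


def write_compendium(compendium: ReferenceCompendium, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    counts = pd.DataFrame(
        compendium.counts, index=compendium.gene_index, columns=compendium.sample_ids
    )
    write_expression_matrix(counts, d / "counts.tsv")
    pd.DataFrame(
        {"sample_id": compendium.sample_ids, "cell_type": compendium.cell_types}
    ).to_csv(d / "samples.tsv", sep="\t", index=False)
    if compendium.taxonomy is not None:
        write_taxonomy(compendium.taxonomy, d / "taxonomy.tsv")


def read_compendium(directory) -> ReferenceCompendium:
    d = Path(directory)
    counts = read_expression_matrix(d / "counts.tsv")
    samples = pd.read_csv(d / "samples.tsv", sep="\t")
    taxonomy = read_taxonomy(d / "taxonomy.tsv") if (d / "taxonomy.tsv").exists() else None
    return ReferenceCompendium(
        gene_index=list(counts.index),
        counts=counts.to_numpy(dtype=np.int64),
        sample_ids=[str(s) for s in samples["sample_id"]],
        cell_types=[str(c) for c in samples["cell_type"]],
        taxonomy=taxonomy,
    )


def write_survival_pool(pool: SurvivalPool, path) -> None:
    pd.DataFrame({"pfs_days": pool.times}).to_csv(path, sep="\t", index=False)


def read_survival_pool(path, source: str = "file") -> SurvivalPool:
    df = pd.read_csv(path, sep="\t")
    return SurvivalPool(times=df["pfs_days"].to_numpy(dtype=float), source=source)
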