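"""Per-gene, per-cell-type negative-binomial expression model.

For each gene and cell-type unit the model treats replicate counts as
NB-distributed with a library-size offset (CPM scale) and summarizes the
posterior of the CPM-scale mean with an empirical-Bayes normal approximation
on the log-mean:

* the dispersion is estimated by method of moments and floored at 1e-6;
* a weakly-informative normal prior on the log-mean is shared across cell
  types of the same gene (prior mean = the gene's global log-CPM across the
  whole compendium, prior sd = 2 natural-log units);
* the likelihood is summarized by the Fisher information of the NB log-mean
  at the pooled estimate, and prior and likelihood are combined conjugately.

Equal-tailed 95% credible bounds are back-transformed to the CPM scale, so a
single replicate — or an all-zero gene, stabilized by a 0.5-read pseudo-count
— still yields finite, positive bounds.  The only downstream consumer is the
credible-interval separation used for marker selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import ReferenceCompendium
from .taxonomy import CellTypeTaxonomy

PSEUDO_READS = 0.5
PRIOR_SD = 2.0
DISPERSION_FLOOR = 1e-6
Z95 = 1.959963984540054


@dataclass(frozen=True)
class NBPosterior:
    """Posterior summary of one gene's mean expression in one cell type."""

    gene: str
    cell_type: str
    mean_est: float
    lower95: float
    upper95: float
    n_obs: int
    dispersion_est: float


class PosteriorSet:
    """Posterior summaries for every (gene, unit) pair, stored densely."""

    def __init__(
        self,
        genes: list[str],
        units: list[str],
        mean_est: np.ndarray,
        lower95: np.ndarray,
        upper95: np.ndarray,
        n_obs: np.ndarray,
        dispersion_est: np.ndarray,
    ):
        self.genes = list(genes)
        self.units = list(units)
        self.mean_est = mean_est
        self.lower95 = lower95
        self.upper95 = upper95
        self.n_obs = np.asarray(n_obs)
        self.dispersion_est = dispersion_est
        self._gene_idx = {g: i for i, g in enumerate(self.genes)}
        self._unit_idx = {u: j for j, u in enumerate(self.units)}

    def __contains__(self, unit: str) -> bool:
        return unit in self._unit_idx

    def record(self, gene: str, unit: str) -> NBPosterior:
        i, j = self._gene_idx[gene], self._unit_idx[unit]
        return NBPosterior(
            gene=gene,
            cell_type=unit,
            mean_est=float(self.mean_est[i, j]),
            lower95=float(self.lower95[i, j]),
            upper95=float(self.upper95[i, j]),
            n_obs=int(self.n_obs[j]),
            dispersion_est=float(self.dispersion_est[i, j]),
        )

    def separation(self, a: str, b: str) -> np.ndarray:
        """Vector of lower95(a) - upper95(b) over all genes."""
        ja, jb = self._unit_idx[a], self._unit_idx[b]
        return self.lower95[:, ja] - self.upper95[:, jb]

    def mean_column(self, unit: str) -> np.ndarray:
        return self.mean_est[:, self._unit_idx[unit]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j, u in enumerate(self.units):
            rows.append(
                pd.DataFrame(
                    {
                        "gene": self.genes,
                        "cell_type": u,
                        "mean_est": self.mean_est[:, j],
                        "lower95": self.lower95[:, j],
                        "upper95": self.upper95[:, j],
                        "n_obs": int(self.n_obs[j]),
                        "dispersion_est": self.dispersion_est[:, j],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PosteriorSet":
        genes = list(dict.fromkeys(df["gene"]))
        units = list(dict.fromkeys(df["cell_type"]))
        shape = (len(genes), len(units))
        mean = np.empty(shape)
        lo = np.empty(shape)
        hi = np.empty(shape)
        disp = np.empty(shape)
        n_obs = np.zeros(len(units), dtype=int)
        gi = {g: i for i, g in enumerate(genes)}
        for j, u in enumerate(units):
            sub = df[df["cell_type"] == u]
            idx = [gi[g] for g in sub["gene"]]
            mean[idx, j] = sub["mean_est"]
            lo[idx, j] = sub["lower95"]
            hi[idx, j] = sub["upper95"]
            disp[idx, j] = sub["dispersion_est"]
            n_obs[j] = int(sub["n_obs"].iloc[0])
        return cls(genes, units, mean, lo, hi, n_obs, disp)

    @classmethod
    def from_tsv(cls, path) -> "PosteriorSet":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def _fit_group(
    counts: np.ndarray, lib: np.ndarray, prior_mean: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit all genes of one replicate group; returns (mean, lo, hi, phi)."""
    total_lib = lib.sum()
    m_hat = (counts.sum(axis=1) + PSEUDO_READS) / total_lib * 1e6  # CPM
    theta_hat = np.log(m_hat)

    mu = m_hat[:, None] * lib[None, :] / 1e6  # expected counts per replicate
    resid = (counts - mu) ** 2 - mu
    phi = np.maximum(resid.sum(axis=1) / (mu**2).sum(axis=1), DISPERSION_FLOOR)

    info = (mu / (1.0 + phi[:, None] * mu)).sum(axis=1)  # Fisher info on log-mean
    prior_prec = 1.0 / PRIOR_SD**2
    post_prec = info + prior_prec
    theta_post = (info * theta_hat + prior_prec * prior_mean) / post_prec
    sd_post = 1.0 / np.sqrt(post_prec)

    mean = np.exp(theta_post)
    lo = np.exp(theta_post - Z95 * sd_post)
    hi = np.exp(theta_post + Z95 * sd_post)
    return mean, lo, hi, phi


def _global_log_cpm(compendium: ReferenceCompendium) -> np.ndarray:
    lib = compendium.library_sizes
    return np.log((compendium.counts.sum(axis=1) + PSEUDO_READS) / lib.sum() * 1e6)


def fit_posterior(
    compendium: ReferenceCompendium, units: dict[str, list[str]] | None = None
) -> PosteriorSet:
    """Fit the NB posterior for every (gene, unit).

    ``units`` maps a unit name to the leaf cell types whose replicates it
    pools; by default each observed leaf cell type is its own unit.  Raises
    on an empty compendium or on a unit with no replicates.
    """
    if compendium.n_profiles == 0:
        raise ValueError("empty compendium")
    if units is None:
        units = {ct: [ct] for ct in dict.fromkeys(compendium.cell_types)}

    prior_mean = _global_log_cpm(compendium)
    lib_all = compendium.library_sizes
    cts = np.asarray(compendium.cell_types)

    names = list(units)
    shape = (compendium.n_genes, len(names))
    mean = np.empty(shape)
    lo = np.empty(shape)
    hi = np.empty(shape)
    disp = np.empty(shape)
    n_obs = np.zeros(len(names), dtype=int)
    for j, name in enumerate(names):
        cols = np.flatnonzero(np.isin(cts, units[name]))
        if cols.size == 0:
            raise ValueError(f"unit {name!r} has no replicates in the compendium")
        mean[:, j], lo[:, j], hi[:, j], disp[:, j] = _fit_group(
            compendium.counts[:, cols].astype(float), lib_all[cols].astype(float), prior_mean
        )
        n_obs[j] = cols.size
    return PosteriorSet(compendium.gene_index, names, mean, lo, hi, n_obs, disp)


def fit_hierarchy_posteriors(
    compendium: ReferenceCompendium, taxonomy: CellTypeTaxonomy
) -> PosteriorSet:
    """Fit posteriors for every taxonomy unit at every level.

    Internal units (e.g. ``immune``) pool all replicates of their descendant
    leaves and are refit at the data level, matching how categories are
    compared during marker selection.
    """
    missing = set(taxonomy.leaves) - set(compendium.cell_types)
    if missing:
        raise ValueError(f"compendium lacks replicates for leaves: {sorted(missing)}")
    units: dict[str, list[str]] = {}
    for level, scope in taxonomy.sibling_scopes():
        for unit in scope:
            units.setdefault(unit, taxonomy.descendant_leaves(unit))
    for leaf in taxonomy.leaves:
        units.setdefault(leaf, [leaf])
    return fit_posterior(compendium, units=units)


def posterior_separation(a: NBPosterior, b: NBPosterior) -> float:
    """Credible-interval separation lower95(a) - upper95(b).

    Positive iff a's 95% credible interval lies wholly above b's.  Both
    records must describe the same gene in different cell types.
    """
    if a.gene != b.gene:
        raise ValueError(f"separation compares one gene, got {a.gene!r} vs {b.gene!r}")
    return a.lower95 - b.upper95
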