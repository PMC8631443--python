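"""Bulk expression deconvolution against a signature matrix.

Two backends estimate cell-type proportions from a CPM-scale bulk profile:

* ``nnls`` — non-negative least squares, an exact oracle on noise-free
  mixtures and the reference the SVR backend is validated against;
* ``svr`` — the CIBERSORT procedure: signature and mixture are z-scored with
  the joint mean/sd of the signature submatrix, a linear nu-support-vector
  regression is fitted for each nu in {0.25, 0.5, 0.75}, the nu with the
  lowest root-mean-square reconstruction error is kept, negative
  coefficients are truncated to zero and the rest renormalized to sum to 1
  (relative proportions, the quantity the survival stage consumes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls as _nnls
from sklearn.svm import NuSVR

DEFAULT_NU_GRID = (0.25, 0.5, 0.75)
MIN_GENE_OVERLAP = 0.5


@dataclass
class DeconvolutionResult:
    sample_id: str
    cell_types: list[str]
    proportions: np.ndarray
    fit_rmse: float
    chosen_nu: float | None = None
    degenerate: bool = False  # all-zero coefficients -> uniform fallback

    def __post_init__(self) -> None:
        if abs(self.proportions.sum() - 1.0) > 1e-9 or np.any(self.proportions < 0):
            raise ValueError("proportions must be a simplex vector")

    def as_series(self) -> pd.Series:
        return pd.Series(self.proportions, index=self.cell_types, name=self.sample_id)


def _restrict(signature, expression) -> tuple[np.ndarray, np.ndarray]:
    """Align expression to signature genes; error on < 50% overlap."""
    if isinstance(expression, pd.Series):
        idx = expression.index
        have = [g for g in signature.genes if g in idx]
        if len(have) < MIN_GENE_OVERLAP * len(signature.genes):
            raise ValueError(
                f"expression covers {len(have)}/{len(signature.genes)} signature genes "
                "(< 50% overlap)"
            )
        rows = [signature.genes.index(g) for g in have]
        return signature.values[rows], expression.loc[have].to_numpy(dtype=float)
    x = np.asarray(expression, dtype=float)
    if x.shape[0] != len(signature.genes):
        raise ValueError(
            "unlabelled expression vector must match the signature gene order; "
            "pass a pandas Series for partial gene coverage"
        )
    return signature.values, x


def _normalize(w: np.ndarray, cell_types: list[str], sample_id: str,
               rmse: float, nu: float | None) -> DeconvolutionResult:
    w = np.clip(w, 0.0, None)
    total = w.sum()
    if total <= 0:
        return DeconvolutionResult(
            sample_id=sample_id,
            cell_types=list(cell_types),
            proportions=np.full(len(cell_types), 1.0 / len(cell_types)),
            fit_rmse=rmse,
            chosen_nu=nu,
            degenerate=True,
        )
    return DeconvolutionResult(
        sample_id=sample_id,
        cell_types=list(cell_types),
        proportions=w / total,
        fit_rmse=rmse,
        chosen_nu=nu,
    )


def deconvolve_nnls(signature, expression, sample_id: str = "") -> DeconvolutionResult:
    """Non-negative least squares on CPM-scale inputs."""
    s, x = _restrict(signature, expression)
    w, rnorm = _nnls(s, x)
    rmse = rnorm / np.sqrt(s.shape[0])
    return _normalize(w, signature.cell_types, sample_id, rmse, None)


def deconvolve_svr(
    signature,
    expression,
    nu_grid: tuple[float, ...] = DEFAULT_NU_GRID,
    sample_id: str = "",
) -> DeconvolutionResult:
    """Linear nu-SVR deconvolution with RMSE-based nu selection."""
    s, x = _restrict(signature, expression)
    mu, sd = s.mean(), s.std()
    s_z = (s - mu) / sd
    x_z = (x - mu) / sd

    best: tuple[float, float, np.ndarray] | None = None  # (rmse, nu, coef)
    for nu in nu_grid:
        svr = NuSVR(kernel="linear", nu=nu, C=1.0)
        svr.fit(s_z, x_z)
        rmse = float(np.sqrt(np.mean((svr.predict(s_z) - x_z) ** 2)))
        if best is None or rmse < best[0]:
            best = (rmse, nu, svr.coef_.ravel().copy())
    rmse, nu, coef = best
    return _normalize(coef, signature.cell_types, sample_id, rmse, nu)


def batch_deconvolve(signature, expression_matrix: pd.DataFrame,
                     backend: str = "nnls", **kwargs) -> list[DeconvolutionResult]:
    """Deconvolve every column of a genes x samples matrix, in input order.

    Samples are independent, so results do not depend on execution order;
    per-sample failures are re-raised with the sample id attached.
    """
    solver = {"nnls": deconvolve_nnls, "svr": deconvolve_svr}[backend]
    out: list[DeconvolutionResult] = []
    for sid in expression_matrix.columns:
        try:
            out.append(solver(signature, expression_matrix[sid], sample_id=str(sid), **kwargs))
        except Exception as exc:
            raise RuntimeError(f"deconvolution failed for sample {sid!r}: {exc}") from exc
    return out


def proportions_frame(results: list[DeconvolutionResult]) -> pd.DataFrame:
    """Stack batch results into a samples x cell-types proportion table."""
    return pd.DataFrame([r.as_series() for r in results])


def deconvolve_mixtures(signature, mixtures, backend: str = "nnls", **kwargs) -> pd.DataFrame:
    """Estimate proportions for every sample of a simulated MixtureSet."""
    expr = pd.DataFrame(
        mixtures.expression,
        index=mixtures.gene_index,
        columns=[f"mix{i}" for i in range(mixtures.n_samples)],
    )
    return proportions_frame(batch_deconvolve(signature, expr, backend=backend, **kwargs))
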