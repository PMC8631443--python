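"""Survival statistics: Cox association, Kaplan-Meier, log-rank, BH, strata.

The association stage regresses progression-free survival on the
logit-transformed cell-type proportions in a single multiple Cox
proportional-hazards model (Efron tie handling) and calls a cell type
significant at a Wald p-value below alpha.  Kaplan-Meier median-split
stratification, the Mantel-Cox log-rank test, Benjamini-Hochberg adjustment
and rank-based grade comparisons mirror the downstream clinical analyses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
LOGIT_EPS = 1e-6


def logit_transform(p, eps: float = LOGIT_EPS):
    """log(p/(1-p)) with p clipped to [eps, 1-eps] so 0 and 1 stay finite."""
    p = np.clip(np.asarray(p, dtype=float), eps, 1.0 - eps)
    return np.log(p / (1.0 - p))


@dataclass
class AssociationResult:
    """Per cell type: Cox coefficient, Wald p-value, significance call."""

    table: pd.DataFrame  # index cell_type; columns coef, p_value, significant
    alpha: float
    dropped: list[str] = field(default_factory=list)

    def p_value(self, cell_type: str) -> float:
        return float(self.table.loc[cell_type, "p_value"])

    def significant(self, cell_type: str) -> bool:
        return bool(self.table.loc[cell_type, "significant"])


#: smallest proportion a bulk deconvolution can resolve; estimated zeros are
#: clipped here before the logit so they do not become high-leverage outliers
DETECTION_LIMIT = 1e-3


def cox_association(
    proportions: pd.DataFrame,
    times,
    events,
    alpha: float = DEFAULT_ALPHA,
    detection_limit: float = DETECTION_LIMIT,
) -> AssociationResult:
    """Multiple Cox regression of survival on logit proportions.

    ``proportions`` is samples x cell types on the proportion scale; all
    covariates enter one model jointly after logit transformation, with
    values clipped at ``detection_limit`` — deconvolution truncates small
    proportions to exact zero, and logit of a tighter floor would place
    those samples at an artificial extreme that inflates the Wald test.
    Zero-variance covariates (e.g. a cell type estimated identically across
    samples) are dropped with a warning; non-finite covariates raise with
    the offending cell type named.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(proportions) < 10:
        raise ValueError("cox_association needs at least 10 samples")
    if events.sum() < 1:
        raise ValueError("cox_association needs at least one observed event")

    x = pd.DataFrame(
        logit_transform(proportions.to_numpy(), eps=detection_limit),
        columns=proportions.columns,
        index=proportions.index,
    )
    for ct in x.columns:
        if not np.all(np.isfinite(x[ct])):
            raise ValueError(f"non-finite logit covariate for cell type {ct!r}")
    dropped = [ct for ct in x.columns if x[ct].var() < 1e-12]
    if dropped:
        logger.warning("dropping constant covariates: %s", dropped)
        x = x.drop(columns=dropped)

    df = x.copy()
    df["_time"] = times
    df["_event"] = events
    cph = CoxPHFitter(penalizer=0.0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="_time", event_col="_event")
    except ConvergenceError:
        # mild ridge as a deterministic fallback for ill-conditioned fits
        cph = CoxPHFitter(penalizer=0.01)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="_time", event_col="_event")

    table = pd.DataFrame(
        {
            "coef": cph.params_,
            "p_value": cph.summary["p"],
            "significant": cph.summary["p"] < alpha,
        }
    )
    table.index.name = "cell_type"
    return AssociationResult(table=table, alpha=alpha, dropped=dropped)


@dataclass
class KMCurve:
    """Product-limit survival estimate as a right-continuous step function."""

    event_times: np.ndarray  # distinct times with >= 1 observed event
    survival: np.ndarray  # S(t) just after each event time

    def __call__(self, t: float) -> float:
        i = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if i == 0 else float(self.survival[i - 1])

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.event_times.tolist(), self.survival.tolist()))


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Censored observations leave the risk set without contributing a step.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("km_estimate needs at least one observation")
    if np.any(times <= 0):
        raise ValueError("times must be positive")

    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    uniq = np.unique(times[events == 1])
    surv = []
    s = 1.0
    for t in uniq:
        at_risk = np.sum(times >= t)
        d = np.sum((times == t) & (events == 1))
        s *= 1.0 - d / at_risk
        surv.append(s)
    return KMCurve(event_times=uniq, survival=np.asarray(surv))


def logrank_test(group_labels, times, events) -> tuple[float, float]:
    """Mantel-Cox log-rank chi-square across k groups, p on (k-1) df."""
    labels = np.asarray(group_labels)
    groups = pd.unique(labels)
    if len(groups) < 2:
        raise ValueError("log-rank test needs at least two groups")
    res = multivariate_logrank_test(
        np.asarray(times, dtype=float), labels, np.asarray(events, dtype=int)
    )
    return float(res.test_statistic), float(res.p_value)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def median_split_strata(values_a, values_b=None, mode: str = "two_group") -> np.ndarray:
    """Median-split group labels; ties at the median are assigned to L.

    ``two_group`` labels samples L/H on one variable; ``four_group`` crosses
    two variables into L/L, L/H, H/L, H/H; ``hh_vs_rest`` collapses the
    cross to HH versus everything else.
    """
    a = np.asarray(values_a, dtype=float)
    if np.all(a == a[0]):
        raise ValueError("median split undefined: all values equal")
    ha = a > np.median(a)
    if mode == "two_group":
        return np.where(ha, "H", "L")
    if values_b is None:
        raise ValueError(f"mode {mode!r} requires a second variable")
    b = np.asarray(values_b, dtype=float)
    if np.all(b == b[0]):
        raise ValueError("median split undefined: all values equal")
    hb = b > np.median(b)
    if mode == "four_group":
        la = np.where(ha, "H", "L")
        lb = np.where(hb, "H", "L")
        return np.char.add(np.char.add(la, "/"), lb)
    if mode == "hh_vs_rest":
        return np.where(ha & hb, "HH", "rest")
    raise ValueError(f"unknown mode {mode!r}")


def group_abundance_compare(values, group_labels, test: str = "rank_sum") -> tuple[float, float]:
    """Rank-based two-group abundance comparison.

    ``rank_sum`` (default) is the Wilcoxon-Mann-Whitney test for independent
    groups with normal approximation and tie correction; ``signed_rank`` is
    the paired Wilcoxon test for matched groups of equal size.  Feed the
    resulting p-values to :func:`bh_adjust` when comparing many cell types.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    x = values[labels == groups[0]]
    y = values[labels == groups[1]]
    if min(x.size, y.size) < 2:
        raise ValueError("each group needs at least 2 observations")
    if test == "rank_sum":
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    elif test == "signed_rank":
        if x.size != y.size:
            raise ValueError("signed_rank requires paired groups of equal size")
        res = stats.wilcoxon(x, y)
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)


@dataclass
class SurvivalStrata:
    """A median-split stratification with its KM curves and log-rank test."""

    labels: np.ndarray
    curves: dict[str, KMCurve]
    statistic: float
    p_value: float


def stratified_survival(
    values_a, times, events, values_b=None, mode: str = "two_group"
) -> SurvivalStrata:
    """Median-split stratification + per-group KM + log-rank in one call."""
    labels = median_split_strata(values_a, values_b, mode=mode)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    curves = {
        str(g): km_estimate(times[labels == g], events[labels == g])
        for g in pd.unique(labels)
    }
    stat, p = logrank_test(labels, times, events)
    return SurvivalStrata(labels=labels, curves=curves, statistic=stat, p_value=p)
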