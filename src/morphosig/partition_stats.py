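"""Partition-level statistics: GLS model pair, Kendall's tau, summaries.

Per-character metrics (Pagel's lambda, ER Akaike weight, assigned rate)
and per-pair independence weights are compared across skeletal-region
partitions with a two-model Gaussian comparison: a null model in which
every partition's values come from one distribution (intercept only)
against an H1 model in which the focal partition alone is allowed a
different mean (intercept + focal indicator).  Both are fit by maximum
likelihood, so with no correlation structure the GLS reduces to ML-OLS
and the log-likelihoods have closed forms.  AIC uses 2 free parameters
for the null (mean, variance) and 3 for H1 (two means, variance); the
Akaike weight of H1 says whether the focal partition differs, and the
sign of the indicator coefficient says in which direction.

Rank correlations between metrics use Kendall's tau-b (tie-corrected),
a non-parametric choice that makes no normality assumption.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mk import aic, akaike_weights

__all__ = [
    "PartitionComparison",
    "CorrelationResult",
    "gls_compare",
    "kendall_tau",
    "partition_summary",
    "PartitionSummary",
]


@dataclass
class PartitionComparison:
    """Null-vs-H1 comparison of one metric for one focal partition."""

    metric: str
    focal: str
    n: int
    median_focal: float
    beta: float
    lnL_null: float
    lnL_h1: float
    aic_null: float
    aic_h1: float
    w_null: float
    w_h1: float
    direction: str  # higher | lower | none


def _gaussian_ml_loglik(resid: np.ndarray) -> float:
    """Closed-form ML log-likelihood of a Gaussian with fitted variance."""
    n = resid.size
    s2 = float(np.mean(resid**2))  # ML (biased) variance
    if s2 <= 0:
        raise ValueError("zero residual variance; degenerate ML fit")
    return -0.5 * n * (np.log(2.0 * np.pi * s2) + 1.0)


def gls_compare(values, labels, focal: str, metric: str = "") -> PartitionComparison:
    """Does the focal partition's metric differ from the other partitions?

    ``values`` are per-item metric values (items are characters, or pairs
    for the independence weight) and ``labels`` their partition labels.
    The H1 coefficient ``beta`` is the ML-OLS indicator coefficient,
    i.e. mean(focal) - mean(others).
    """
    y = np.asarray(values, dtype=float)
    labels = np.asarray([str(l) for l in labels])
    if y.size != labels.size:
        raise ValueError("values and labels must align")
    if y.size < 3:
        raise ValueError("need at least 3 items")
    mask = labels == focal
    if not mask.any():
        raise ValueError(f"focal partition {focal!r} has no items")
    if np.unique(labels).size < 2:
        raise ValueError("need at least 2 partitions")
    lnL_null = _gaussian_ml_loglik(y - y.mean())
    mu_focal = y[mask].mean()
    mu_rest = y[~mask].mean()
    fitted = np.where(mask, mu_focal, mu_rest)
    lnL_h1 = _gaussian_ml_loglik(y - fitted)
    beta = float(mu_focal - mu_rest)
    aic_null = aic(lnL_null, 2)
    aic_h1 = aic(lnL_h1, 3)
    w = akaike_weights([aic_null, aic_h1])
    if w[1] > w[0] and beta > 0:
        direction = "higher"
    elif w[1] > w[0] and beta < 0:
        direction = "lower"
    else:
        direction = "none"
    return PartitionComparison(
        metric, focal, int(y.size), float(np.median(y[mask])), beta,
        float(lnL_null), float(lnL_h1), float(aic_null), float(aic_h1),
        float(w[0]), float(w[1]), direction,
    )


@dataclass
class CorrelationResult:
    """Kendall tau-b with a two-sided p-value."""

    tau: float
    p: float
    n: int


def kendall_tau(x, y) -> CorrelationResult:
    """Tie-corrected Kendall rank correlation (tau-b), two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("tau undefined for a constant vector")
    res = stats.kendalltau(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), int(x.size))


@dataclass
class PartitionSummary:
    """Per-partition medians/counts and the cross-metric correlations."""

    table: pd.DataFrame                       # one row per partition
    lambda_vs_rate: CorrelationResult | None  # across characters
    lambda_vs_er_weight: CorrelationResult | None
    count_correlations: dict[str, CorrelationResult]  # across partitions


def partition_summary(assessments, pair_results, partitions) -> PartitionSummary:
    """Summarise per-character and per-pair metrics by partition.

    ``assessments`` are :class:`~morphosig.simmap.CharacterAssessment`
    records, ``pair_results`` :class:`~morphosig.pairs.PairResult`
    records; ``partitions`` maps character id -> partition label (used to
    fill labels that records lack).  Correlations across characters
    (lambda vs rate, lambda vs ER weight) and across partitions (character
    count vs each median) are attached when computable.
    """
    rows = []
    for a in assessments:
        part = a.partition or partitions.get(a.char_id)
        rows.append({"char_id": a.char_id, "partition": part, "lambda": a.lam,
                     "er_weight": a.er_weight, "rate": a.rate})
    chars = pd.DataFrame(rows)
    pair_rows = [{"partition": p.partition, "w_indep": p.w_indep}
                 for p in pair_results]
    pairs = pd.DataFrame(pair_rows) if pair_rows else pd.DataFrame(
        columns=["partition", "w_indep"])
    if chars.empty:
        raise ValueError("no character assessments to summarise")

    med = chars.groupby("partition").agg(
        n_characters=("char_id", "size"),
        median_lambda=("lambda", "median"),
        median_er_weight=("er_weight", "median"),
        median_rate=("rate", "median"),
    )
    if not pairs.empty:
        med = med.join(pairs.groupby("partition")["w_indep"].median()
                       .rename("median_w_indep"))
    else:
        med["median_w_indep"] = np.nan
    med = med.reset_index()

    def safe_tau(x, y):
        try:
            return kendall_tau(x, y)
        except ValueError:
            return None

    lam_rate = safe_tau(chars["lambda"], chars["rate"])
    lam_er = safe_tau(chars["lambda"], chars["er_weight"])
    count_corr: dict[str, CorrelationResult] = {}
    for col in ("median_lambda", "median_er_weight", "median_rate",
                "median_w_indep"):
        sub = med.dropna(subset=[col])
        if len(sub) >= 3:
            r = safe_tau(sub["n_characters"], sub[col])
            if r is not None:
                count_corr[col] = r
    return PartitionSummary(med, lam_rate, lam_er, count_corr)
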