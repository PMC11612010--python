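"""Interictal-vs-preictal statistical battery.

Each paired feature comparison is routed by a Shapiro-Wilk test on the
paired differences: normal differences go to the paired t-test, anything
else to the Wilcoxon signed-rank test (exact null distribution for small
samples without ties).  Effect sizes are paired Cohen's d
(mean of differences over their standard deviation).  Microstate map
topographies are compared with Kruskal-Wallis tests.

The significance level ``alpha`` is a plain configuration input (the kind of
value practitioners derive externally from a power analysis); a comparison
can additionally require ``|d|`` above a threshold before being flagged
significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sst

from .errors import LengthError


@dataclass
class StatTestResult:
    """Outcome of one feature comparison."""

    feature: str
    test: str                      # "paired-t" | "wilcoxon" | "kruskal" | "degenerate"
    p_value: float
    effect_size_cohens_d: float
    alpha_used: float
    significant: bool
    statistic: float = float("nan")


def cohens_d_paired(x: np.ndarray, y: np.ndarray) -> float:
    """Paired Cohen's d: mean(x - y) / sd(x - y) (sample sd, ddof=1)."""
    diff = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    sd = diff.std(ddof=1)
    if sd == 0:
        return 0.0
    return float(diff.mean() / sd)


def paired_compare(x: np.ndarray, y: np.ndarray, alpha: float = 0.05, *,
                   feature: str = "", d_threshold: float = 0.0,
                   normality_alpha: float = 0.05) -> StatTestResult:
    """Compare paired samples, routing by normality of the differences.

    Shapiro-Wilk is applied to ``x - y``; if its p exceeds
    ``normality_alpha`` the paired t-test is used, otherwise the Wilcoxon
    signed-rank test.  ``significant`` requires ``p < alpha`` and
    ``|d| > d_threshold``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 5:
        raise LengthError("paired comparison needs equal-length samples, n >= 5")
    diff = x - y
    d = cohens_d_paired(x, y)
    if np.all(diff == 0):
        return StatTestResult(feature, "degenerate", 1.0, 0.0, alpha, False, 0.0)
    sw_p = sst.shapiro(diff).pvalue
    if sw_p > normality_alpha:
        res = sst.ttest_rel(x, y)
        test, p, statistic = "paired-t", float(res.pvalue), float(res.statistic)
    else:
        method = "exact" if (x.size <= 25 and not np.any(diff == 0)) else "auto"
        res = sst.wilcoxon(x, y, method=method)
        test, p, statistic = "wilcoxon", float(res.pvalue), float(res.statistic)
    significant = bool(p < alpha and abs(d) > d_threshold)
    return StatTestResult(feature, test, p, d, alpha, significant, statistic)


def kruskal_wallis_maps(group_a: np.ndarray, group_b: np.ndarray,
                        alpha: float = 0.05, *,
                        feature: str = "") -> StatTestResult:
    """Kruskal-Wallis rank test between two groups of per-subject map statistics."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise LengthError("need at least 3 values per group")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return StatTestResult(feature, "degenerate", 1.0, 0.0, alpha, False, 0.0)
    h, p = sst.kruskal(a, b)
    # two-group unpaired effect size: Cohen's d with pooled sd
    na, nb = a.size, b.size
    sp = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    d = float((a.mean() - b.mean()) / sp) if sp > 0 else 0.0
    return StatTestResult(feature, "kruskal", float(p), d, alpha,
                          bool(p < alpha), float(h))


def compare_feature_table(interictal, preictal, alpha: float = 0.0005, *,
                          d_threshold: float = 0.3):
    """Run :func:`paired_compare` column-wise over two aligned DataFrames.

    Returns a tidy DataFrame (feature, test, p_value, cohens_d, significant)
    mirroring a per-feature statistics table.
    """
    import pandas as pd

    rows = []
    for col in interictal.columns:
        res = paired_compare(interictal[col].to_numpy(),
                             preictal[col].to_numpy(),
                             alpha, feature=col, d_threshold=d_threshold)
        rows.append({
            "feature": res.feature, "test": res.test, "p_value": res.p_value,
            "cohens_d": res.effect_size_cohens_d,
            "significant": res.significant,
        })
    return pd.DataFrame(rows)
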