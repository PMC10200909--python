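"""Shared statistical primitives.

Two-sample tests (Wilcoxon rank-sum, Welch t, Kolmogorov–Smirnov,
Kruskal–Wallis) wrap scipy; Benjamini–Hochberg wraps statsmodels. The DeLong
AUC machinery (variance of the Mann–Whitney AUC estimator via placement
values, Wald CIs, paired comparison of correlated AUCs) is implemented here.

The test-selection rule used throughout the differential analyses: a Welch
t-test when both groups pass a Shapiro–Wilk normality check (alpha = 0.05),
a Wilcoxon rank-sum test otherwise. All tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class TestResult:
    statistic: float
    pvalue: float
    method: str
    n1: int
    n2: int


@dataclass
class AUCComparison:
    auc1: float
    auc2: float
    var1: float
    var2: float
    covar: float
    z: float
    pvalue: float


# ---------------------------------------------------------------- two-sample


def rank_sum(a, b) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U); exact null distribution
    for small tie-free samples, tie-corrected normal approximation otherwise."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return TestResult(float(res.statistic), float(res.pvalue),
                      "wilcoxon-rank-sum", len(a), len(b))


def welch_t(a, b) -> TestResult:
    a, b = np.asarray(a, float), np.asarray(b, float)
    res = sps.ttest_ind(a, b, equal_var=False)
    return TestResult(float(res.statistic), float(res.pvalue),
                      "welch-t", len(a), len(b))


def ks_2samp(a, b) -> TestResult:
    a, b = np.asarray(a, float), np.asarray(b, float)
    res = sps.ks_2samp(a, b)
    return TestResult(float(res.statistic), float(res.pvalue),
                      "ks-2samp", len(a), len(b))


def kruskal_wallis(*groups) -> TestResult:
    res = sps.kruskal(*groups)
    return TestResult(float(res.statistic), float(res.pvalue),
                      "kruskal-wallis", len(groups[0]), len(groups[1]))


def is_normal(x, alpha: float = 0.05) -> bool:
    """Shapiro–Wilk normality check; degenerate samples count as non-normal."""
    x = np.asarray(x, float)
    if len(x) < 3 or np.ptp(x) == 0:
        return False
    return sps.shapiro(x).pvalue > alpha


def two_sample_test(a, b, normality_alpha: float = 0.05) -> TestResult:
    """Welch t when both groups look normal (Shapiro–Wilk), else rank-sum."""
    if is_normal(a, normality_alpha) and is_normal(b, normality_alpha):
        return welch_t(a, b)
    return rank_sum(a, b)


# ------------------------------------------------------------------------ BH


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values), in input
    order: q_(i) = min_{j >= i} m * p_(j) / j, capped at 1."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("NaN p-value passed to benjamini_hochberg")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# -------------------------------------------------------------------- DeLong


def _placement_values(pos, neg):
    """V10 (per-positive) and V01 (per-negative) placement values.

    V10[i] = fraction of negatives below positive i (+ half ties); the AUC is
    the mean of either vector.
    """
    pos = np.asarray(pos, float)
    neg = np.asarray(neg, float)
    v10 = np.empty(len(pos))
    v01 = np.empty(len(neg))
    order = np.argsort(neg, kind="mergesort")
    sneg = neg[order]
    lo = np.searchsorted(sneg, pos, side="left")
    hi = np.searchsorted(sneg, pos, side="right")
    v10 = (lo + 0.5 * (hi - lo)) / len(neg)
    orderp = np.argsort(pos, kind="mergesort")
    spos = pos[orderp]
    lo = np.searchsorted(spos, neg, side="left")
    hi = np.searchsorted(spos, neg, side="right")
    v01 = (len(pos) - hi + 0.5 * (hi - lo)) / len(pos)
    return v10, v01


def _split_scores(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    if labels.dtype.kind in "OUS":
        pos_mask = labels == "cancer"
        neg_mask = labels == "control"
    else:
        pos_mask = labels == 1
        neg_mask = labels == 0
    if pos_mask.sum() == 0 or neg_mask.sum() == 0:
        raise ValueError("both classes must be present")
    return scores[pos_mask], scores[neg_mask]


def auc(scores, labels) -> float:
    """AUC via the Mann–Whitney identity (ties counted 1/2)."""
    pos, neg = _split_scores(scores, labels)
    v10, _ = _placement_values(pos, neg)
    return float(v10.mean())


def delong_variance(scores, labels) -> tuple[float, float]:
    pos, neg = _split_scores(scores, labels)
    v10, v01 = _placement_values(pos, neg)
    a = v10.mean()
    s10 = v10.var(ddof=1) if len(pos) > 1 else 0.0
    s01 = v01.var(ddof=1) if len(neg) > 1 else 0.0
    return a, s10 / len(pos) + s01 / len(neg)


def delong_ci(scores, labels, level: float = 0.95) -> tuple[float, float, float]:
    """(auc, lo, hi): Wald interval on the AUC, truncated to [0, 1]."""
    a, var = delong_variance(scores, labels)
    z = sps.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return a, float(max(0.0, a - half)), float(min(1.0, a + half))


def delong_auc_test(scores1, scores2, labels) -> AUCComparison:
    """DeLong's paired test comparing two correlated AUCs computed on the
    same samples (e.g. two models scored on one cohort)."""
    pos1, neg1 = _split_scores(scores1, labels)
    pos2, neg2 = _split_scores(scores2, labels)
    v10_1, v01_1 = _placement_values(pos1, neg1)
    v10_2, v01_2 = _placement_values(pos2, neg2)
    a1, a2 = v10_1.mean(), v10_2.mean()
    m, n = len(pos1), len(neg1)

    def _cov(x, y):
        return float(np.cov(x, y, ddof=1)[0, 1]) if len(x) > 1 else 0.0

    var1 = _cov(v10_1, v10_1) / m + _cov(v01_1, v01_1) / n
    var2 = _cov(v10_2, v10_2) / m + _cov(v01_2, v01_2) / n
    cov12 = _cov(v10_1, v10_2) / m + _cov(v01_1, v01_2) / n
    var_diff = var1 + var2 - 2 * cov12
    if var_diff <= 0:
        z = 0.0 if np.isclose(a1, a2) else np.inf * np.sign(a1 - a2)
    else:
        z = (a1 - a2) / np.sqrt(var_diff)
    p = float(2 * sps.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    return AUCComparison(float(a1), float(a2), var1, var2, cov12, float(z), p)


# --------------------------------------------------- group differential table


def _vectorized_ranksum(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise two-sided Mann–Whitney U over (samples x features) blocks."""
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic", axis=0)
    return np.atleast_1d(res.statistic), np.atleast_1d(res.pvalue)


def groupwise_differential(
    cancer: pd.DataFrame,
    control: pd.DataFrame,
    alpha: float = 0.05,
    test: str = "wilcoxon",
    eps: float = 1e-9,
) -> pd.DataFrame:
    """Per-feature two-group differential table shared by the CNA-bin and
    end-motif analyses.

    For each feature (column): a two-sided test (``wilcoxon``, ``t``, or
    ``auto`` = t when both groups pass Shapiro–Wilk, else Wilcoxon);
    Benjamini–Hochberg across all features; log2 fold change of group means
    (eps-guarded); Z-score of the cancer group mean against the control
    mean/SD; and a category: "increase"/"decrease" when q <= alpha by the
    sign of log2FC, else "ns".
    """
    if not cancer.columns.equals(control.columns):
        raise ValueError("cancer and control matrices must share feature columns")
    if len(cancer) < 3 or len(control) < 3:
        raise ValueError("need >= 3 samples per group")
    a = cancer.to_numpy(float)
    b = control.to_numpy(float)
    nfeat = a.shape[1]

    stat = np.full(nfeat, np.nan)
    p = np.ones(nfeat)
    method = np.empty(nfeat, dtype=object)
    degenerate = np.array(
        [np.ptp(np.concatenate([a[:, j], b[:, j]])) == 0 for j in range(nfeat)]
    )
    live = ~degenerate
    method[degenerate] = "constant"

    if test == "wilcoxon":
        if live.any():
            s, pv = _vectorized_ranksum(a[:, live], b[:, live])
            stat[live], p[live] = s, pv
        method[live] = "wilcoxon-rank-sum"
    elif test == "t":
        if live.any():
            res = sps.ttest_ind(a[:, live], b[:, live], equal_var=False, axis=0)
            stat[live] = np.atleast_1d(res.statistic)
            p[live] = np.atleast_1d(res.pvalue)
        method[live] = "welch-t"
    elif test == "auto":
        for j in np.flatnonzero(live):
            r = two_sample_test(a[:, j], b[:, j])
            stat[j], p[j], method[j] = r.statistic, r.pvalue, r.method
    else:
        raise ValueError(f"unknown test {test!r}")
    p = np.nan_to_num(p, nan=1.0)

    q = benjamini_hochberg(p)
    mean_a = a.mean(axis=0)
    mean_b = b.mean(axis=0)
    sd_b = b.std(axis=0, ddof=1)
    log2fc = np.log2((mean_a + eps) / (mean_b + eps))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd_b > 0, (mean_a - mean_b) / sd_b, np.nan)
    category = np.where(
        q <= alpha, np.where(log2fc > 0, "increase", "decrease"), "ns"
    )
    category[degenerate] = "ns"
    return pd.DataFrame(
        {
            "feature": cancer.columns,
            "statistic": stat,
            "p": p,
            "q": q,
            "log2fc": log2fc,
            "category": category,
            "z": z,
            "method": method,
            "mean_cancer": mean_a,
            "mean_control": mean_b,
        }
    )
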