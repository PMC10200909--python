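"""Copy-number aberration (CNA) features from shallow-coverage bin counts.

Per sample: fragments are counted per retained bin, the count-vs-GC trend is
removed by local regression, the profile is normalized to sample median 1,
and isolated outlier bins are smoothed toward the local running median. The
resulting CNA value is a unitless relative coverage centered at 1.

Cohort level: per-bin Z-scores of cancer CNA values against the control
mean/SD, and significant gain/loss bins by a two-sided Wilcoxon rank-sum
test with Benjamini–Hochberg correction (q <= 0.05), categorized by the sign
of the cancer-vs-control log2 fold change.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .genome import GenomeModel, locate_bins
from .stats import groupwise_differential


def bin_read_counts(fragments: pd.DataFrame, model: GenomeModel) -> pd.Series:
    """Fragment count per retained bin (assignment by fragment start)."""
    idx = locate_bins(model, fragments["chrom"], fragments["start"])
    counts = np.bincount(idx, minlength=model.n_bins).astype(float)
    return pd.Series(counts[model.retained],
                     index=model.bin_labels(retained_only=True))


def gc_correct(counts: pd.Series, gc, frac: float = 0.3, eps: float = 1e-9) -> pd.Series:
    """Remove the count-vs-GC trend by lowess and rescale to trend units.

    corrected[b] = count[b] / max(trend(gc[b]), eps); on GC-independent
    counts this reduces to count / mean(count).
    """
    y = np.asarray(counts, float)
    x = np.asarray(gc, float)
    if len(y) != len(x):
        raise ValueError("counts and gc must be aligned")
    ok = ~np.isnan(x)
    if ok.sum() < 20:
        raise ValueError("fewer than 20 bins with defined GC; trend unreliable")
    trend = np.full(len(y), np.nan)
    trend[ok] = lowess(y[ok], x[ok], frac=frac, return_sorted=False)
    # lowess can undershoot at sparse extremes; clamp to keep ratios finite
    corrected = y / np.maximum(trend, eps)
    out = pd.Series(corrected, index=counts.index)
    out[~ok] = np.nan
    return out


def normalize_and_smooth(
    corrected: pd.Series, window: int = 11, n_mad: float = 4.0
) -> pd.Series:
    """Median-normalize and replace outlier bins with the local median.

    A bin is an outlier when |value - running median| over a centered
    ``window``-bin window exceeds ``n_mad`` times the window MAD (any
    deviation counts when the window MAD is zero, i.e. a spike in a flat
    background). The result is renormalized so the sample median is exactly 1.
    """
    v = np.asarray(corrected, float)
    med = np.nanmedian(v)
    if not np.isfinite(med) or med == 0:
        raise ValueError("sample median is zero or undefined; cannot normalize")
    v = v / med

    s = pd.Series(v)
    run_med = s.rolling(window, center=True, min_periods=1).median().to_numpy()
    run_mad = (
        s.rolling(window, center=True, min_periods=1)
        .apply(lambda w: np.nanmedian(np.abs(w - np.nanmedian(w))), raw=True)
        .to_numpy()
    )
    out = v.copy()
    with np.errstate(invalid="ignore"):
        is_out = np.abs(v - run_med) > n_mad * run_mad
    out[is_out] = run_med[is_out]

    final_med = np.nanmedian(out)
    if final_med > 0:
        out = out / final_med
    return pd.Series(out, index=corrected.index)


def cna_vector(
    fragments: pd.DataFrame,
    model: GenomeModel,
    gc_frac: float = 0.3,
    window: int = 11,
    n_mad: float = 4.0,
) -> pd.Series:
    """Full per-sample CNA pipeline: count, GC-correct (when the model has a
    GC track), normalize, smooth."""
    counts = bin_read_counts(fragments, model)
    if model.gc is not None:
        counts = gc_correct(counts, model.gc[model.retained], frac=gc_frac)
    return normalize_and_smooth(counts, window=window, n_mad=n_mad)


def cna_matrix(frames: dict[str, pd.DataFrame], model: GenomeModel, **kw) -> pd.DataFrame:
    return pd.DataFrame(
        {sid: cna_vector(df, model, **kw) for sid, df in frames.items()}
    ).T.rename_axis("sample_id")


def cna_zscores(cancer: pd.DataFrame, control: pd.DataFrame) -> pd.DataFrame:
    """Per-bin Z-scores of cancer CNA values against control mean and SD.

    Z[s, b] = (value[s, b] - mean_control[b]) / SD_control[b], with the
    sample SD (ddof=1) of the control group. Returned frame has one row per
    cancer sample plus a ``mean`` row of the group-mean Z; bins with zero
    control SD are NaN (flagged by the caller as degenerate).
    """
    if len(control) < 2:
        raise ValueError("need >= 2 control samples for a control SD")
    mu = control.mean(axis=0)
    sd = control.std(axis=0, ddof=1)
    sd = sd.where(sd > 0)
    z = (cancer - mu) / sd
    z.loc["mean"] = z.mean(axis=0)
    return z


def call_significant_bins(
    cancer: pd.DataFrame, control: pd.DataFrame, alpha: float = 0.05,
    test: str = "wilcoxon",
) -> pd.DataFrame:
    """Per-bin differential table (statistic, p, BH q, log2FC, category, Z).

    Default test is the two-sided Wilcoxon rank-sum; ``test="t"`` switches to
    Welch t (the heatmap-style variant), ``test="auto"`` applies the
    normality-gated rule.
    """
    return groupwise_differential(cancer, control, alpha=alpha, test=test)
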