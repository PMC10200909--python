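"""Genome-wide methylation (GWM) features.

Per sample and per retained genomic bin, the methylation ratio is

    ratio = (methylated C calls) / (methylated + unmethylated C calls)

summed over the CpG calls of every fragment assigned to the bin. Fragments
are assigned to the bin containing their start coordinate. Bins with zero
CpG calls are missing (NaN).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import GenomeModel, locate_bins
from .stats import ks_2samp


def gwm_vector(fragments: pd.DataFrame, model: GenomeModel) -> pd.Series:
    """Per-retained-bin methylation ratio for one sample's fragments.

    Returns a Series indexed by ``chrom:start-end`` bin labels; NaN where a
    bin received no CpG calls. Permutation-invariant in fragment order.
    """
    idx = locate_bins(model, fragments["chrom"], fragments["start"])
    meth = np.bincount(idx, weights=fragments["n_meth_cpg"], minlength=model.n_bins)
    total = np.bincount(idx, weights=fragments["n_total_cpg"], minlength=model.n_bins)
    with np.errstate(invalid="ignore"):
        ratio = np.where(total > 0, meth / np.where(total > 0, total, 1), np.nan)
    keep = model.retained
    return pd.Series(ratio[keep], index=model.bin_labels(retained_only=True),
                     dtype=float)


def gwm_matrix(frames: dict[str, pd.DataFrame], model: GenomeModel) -> pd.DataFrame:
    """Samples x retained-bins methylation-ratio matrix."""
    return pd.DataFrame(
        {sid: gwm_vector(df, model) for sid, df in frames.items()}
    ).T.rename_axis("sample_id")


def gwm_density_shift(group_a: pd.DataFrame, group_b: pd.DataFrame):
    """Compare the genome-wide methylation density of two groups.

    Per group, the mean methylation ratio is computed for each bin across
    samples (ignoring missing bins); the two per-bin mean profiles are then
    compared with a two-sample KS test. ``direction`` is the sign of
    (median_A - median_B): +1 for hypermethylation of group A relative to B,
    -1 for hypomethylation.

    Returns (TestResult, direction).
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups need at least one sample")
    mean_a = group_a.mean(axis=0, skipna=True).dropna()
    mean_b = group_b.mean(axis=0, skipna=True).dropna()
    if mean_a.empty or mean_b.empty:
        raise ValueError("all bins missing in one group")
    res = ks_2samp(mean_a.to_numpy(), mean_b.to_numpy())
    direction = int(np.sign(np.median(mean_a) - np.median(mean_b)))
    return res, direction
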