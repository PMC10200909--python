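"""Fragment-length (Flen) and 4-mer end-motif (EM) features.

Flen: the per-sample frequency (%) of each fragment length from 100 to
250 bp inclusive — a 151-dimensional vector; fragments outside the range are
excluded from numerator and denominator. Plasma cfDNA peaks near 167 bp
(nucleosome core + linker).

EM: the 4-nucleotide sequence at the fragment's informative 5' end, read
from the reference genome at the 5' end of the forward read (template-free
adapter tailing corrupts the reverse read's 5' end, so only the forward
read's end is used). Frequencies over the 256 possible 4-mers in
lexicographic order AAAA..TTTT form the per-sample EM vector (fractions
summing to 1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import groupwise_differential, ks_2samp

FLEN_MIN, FLEN_MAX = 100, 250
FLEN_DIM = FLEN_MAX - FLEN_MIN + 1

_BASES = "ACGT"
ALL_MOTIFS = [a + b + c + d for a in _BASES for b in _BASES for c in _BASES
              for d in _BASES]
MOTIF_INDEX = {m: i for i, m in enumerate(ALL_MOTIFS)}
EM_DIM = len(ALL_MOTIFS)

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ------------------------------------------------------------------- lengths


def flen_vector(fragments: pd.DataFrame) -> pd.Series:
    """151-dim fragment-length frequency vector in percent.

    Index = lengths 100..250; NaN-filled (and flagged by the caller) when no
    fragment falls in range.
    """
    lengths = (fragments["end"] - fragments["start"]).to_numpy()
    in_range = (lengths >= FLEN_MIN) & (lengths <= FLEN_MAX)
    idx = pd.RangeIndex(FLEN_MIN, FLEN_MAX + 1, name="length")
    if not in_range.any():
        return pd.Series(np.nan, index=idx)
    counts = np.bincount(lengths[in_range] - FLEN_MIN, minlength=FLEN_DIM)
    return pd.Series(100.0 * counts / counts.sum(), index=idx)


def flen_matrix(frames: dict[str, pd.DataFrame]) -> pd.DataFrame:
    return pd.DataFrame(
        {sid: flen_vector(df) for sid, df in frames.items()}
    ).T.rename_axis("sample_id")


def median_fragment_length(fragments: pd.DataFrame) -> float:
    lengths = (fragments["end"] - fragments["start"]).to_numpy()
    lengths = lengths[(lengths >= FLEN_MIN) & (lengths <= FLEN_MAX)]
    return float(np.median(lengths)) if len(lengths) else float("nan")


def flen_distribution_test(group_a: pd.DataFrame, group_b: pd.DataFrame):
    """KS test on the two groups' mean length profiles.

    Each group's Flen vectors are averaged per length; the two mean profiles
    are compared as weighted length distributions via a two-sample KS test on
    lengths resampled deterministically by profile weight (per-mille
    resolution). Also returns the median length of each mean profile.

    Returns (TestResult, median_a, median_b).
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    lengths = group_a.columns.to_numpy(int)

    def _expand(profile):
        w = np.maximum(profile.to_numpy(float), 0)
        reps = np.round(w / w.sum() * 10_000).astype(int)
        return np.repeat(lengths, reps)

    mean_a = group_a.mean(axis=0, skipna=True)
    mean_b = group_b.mean(axis=0, skipna=True)
    res = ks_2samp(_expand(mean_a), _expand(mean_b))
    return res, _profile_median(mean_a), _profile_median(mean_b)


def _profile_median(profile: pd.Series) -> float:
    w = np.maximum(profile.to_numpy(float), 0)
    cdf = np.cumsum(w) / w.sum()
    return float(profile.index[np.searchsorted(cdf, 0.5)])


def short_fragment_fraction(profile: pd.Series, below: int = 150) -> float:
    """Fraction of in-range mass at lengths < ``below`` (tumor-shortening
    readout; elevated in e.g. liver cancer)."""
    w = profile.to_numpy(float)
    return float(np.nansum(w[profile.index < below]) / np.nansum(w))


# -------------------------------------------------------------------- motifs


def extract_end_motifs(fragments: pd.DataFrame, reference) -> pd.Series:
    """Reference-derived 4-mer at each fragment's informative 5' end.

    For a '+' forward read the motif is reference[start, start+4); for '-'
    it is the reverse complement of reference[end-4, end) — the 5' end of the
    fragment on the template strand. Motifs containing N are missing (NaN).
    """
    from pyfaidx import Fasta

    fasta = reference if not isinstance(reference, (str, bytes)) else Fasta(str(reference))
    if ((fragments["end"] - fragments["start"]) < 4).any():
        raise ValueError("fragment shorter than 4 bp")
    out = np.empty(len(fragments), dtype=object)
    chroms = fragments["chrom"].to_numpy()
    starts = fragments["start"].to_numpy()
    ends = fragments["end"].to_numpy()
    strands = fragments["strand_fwd_read"].to_numpy()
    seq_cache = {c: str(fasta[c][:]).upper() for c in np.unique(chroms)}
    for i in range(len(fragments)):
        seq = seq_cache[chroms[i]]
        if strands[i] == "+":
            motif = seq[starts[i] : starts[i] + 4]
        else:
            motif = revcomp(seq[ends[i] - 4 : ends[i]])
        out[i] = motif if len(motif) == 4 and "N" not in motif else np.nan
    return pd.Series(out, index=fragments.index)


def attach_end_motifs(fragments: pd.DataFrame, reference) -> tuple[pd.DataFrame, int]:
    """Derive motifs from the reference; the derived value wins over any
    precomputed column. Returns (frame, number of mismatches with the
    precomputed motifs)."""
    derived = extract_end_motifs(fragments, reference)
    pre = fragments["end_motif"]
    both = pre.notna() & derived.notna()
    mismatches = int((pre[both] != derived[both]).sum())
    out = fragments.copy()
    out["end_motif"] = derived
    return out, mismatches


def em_vector(fragments: pd.DataFrame) -> pd.Series:
    """256-dim end-motif frequency vector (fractions, lexicographic order).

    Fragments with a missing motif are excluded from numerator and
    denominator. All validated fragments are counted regardless of length.
    """
    motifs = fragments["end_motif"].dropna()
    if motifs.empty:
        raise ValueError("no fragments with a usable end motif")
    idx = motifs.map(MOTIF_INDEX)
    if idx.isna().any():
        raise ValueError("invalid motif string in end_motif column")
    counts = np.bincount(idx.to_numpy(int), minlength=EM_DIM)
    return pd.Series(counts / counts.sum(), index=ALL_MOTIFS)


def em_matrix(frames: dict[str, pd.DataFrame]) -> pd.DataFrame:
    return pd.DataFrame(
        {sid: em_vector(df) for sid, df in frames.items()}
    ).T.rename_axis("sample_id")


def em_differential(
    cancer: pd.DataFrame, control: pd.DataFrame, alpha: float = 0.05,
    test: str = "auto",
) -> pd.DataFrame:
    """Per-motif differential table plus first-nucleotide grouping.

    Default test follows the normality-gated rule (Welch t when both groups
    pass Shapiro–Wilk, else Wilcoxon); BH across the 256 motifs. The returned
    frame adds a ``first_base`` column for A/C/G/T grouping of log2FC plots.
    """
    table = groupwise_differential(cancer, control, alpha=alpha, test=test)
    table["first_base"] = table["feature"].str[0]
    return table


def em_first_base_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Counts of significant increased/decreased motifs by first nucleotide."""
    return (
        table.groupby(["first_base", "category"]).size().unstack(fill_value=0)
        .reindex(list(_BASES), fill_value=0)
    )
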