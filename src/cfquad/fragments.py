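"""Canonical fragment-table and sample-manifest formats.

The pipeline's entry point is a TSV of aligned cfDNA fragments (one row per
fragment), not BAM/FASTQ: alignment is upstream of this package. Fragments are
handled in memory as pandas DataFrames with the columns in
:data:`FRAGMENT_COLUMNS`; methylation is carried as per-fragment CpG call
counts (``n_meth_cpg`` of ``n_total_cpg``), sufficient for bin-level ratios.

Coordinates are 0-based, half-open. ``strand_fwd_read`` is the strand the
forward (first) read aligned to, which fixes which fragment end carries the
informative 5' end motif. ``end_motif`` is either a 4-letter ACGT string or
"." for missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

FRAGMENT_COLUMNS = [
    "sample_id",
    "chrom",
    "start",
    "end",
    "strand_fwd_read",
    "n_meth_cpg",
    "n_total_cpg",
    "end_motif",
]

MANIFEST_COLUMNS = ["sample_id", "label", "cohort", "stage", "subtype"]
LABELS = {"cancer", "control"}
COHORTS = {"discovery", "validation"}
STAGES = {"I", "II", "IIIA", "NA"}
SUBTYPES = {"luminal A", "luminal B", "luminal B-HER2", "HER2", "TNBC", "NA"}

_MOTIF_OK = frozenset("ACGT")


@dataclass
class ValidationReport:
    """Outcome of fragment-table validation: every input row is either in
    ``frame`` or accounted for by a located diagnostic in ``errors``."""

    frame: pd.DataFrame
    errors: list[str]

    @property
    def n_valid(self) -> int:
        return len(self.frame)

    @property
    def n_invalid(self) -> int:
        return len(self.errors)


def _motif_valid(m) -> np.ndarray:
    s = pd.Series(m, dtype=object)
    missing = s.isna() | (s == ".")
    ok = s.map(
        lambda x: isinstance(x, str) and len(x) == 4 and set(x) <= _MOTIF_OK
    )
    return (missing | ok).to_numpy()


def validate_fragments(df: pd.DataFrame, model=None) -> ValidationReport:
    """Validate a fragment frame row-by-row against the schema and, if given,
    a :class:`~cfquad.genome.GenomeModel`.

    Invalid rows are dropped from the returned frame; each produces one
    diagnostic string carrying the 1-based file line number (header = line 1)
    when the frame came from :func:`read_fragment_table`, else the frame index.
    """
    missing = [c for c in FRAGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"fragment table missing column(s): {', '.join(missing)}")

    df = df.copy()
    df["end_motif"] = df["end_motif"].replace({".": np.nan})
    bad = {}

    def flag(mask, msg):
        for i in df.index[np.asarray(mask)]:
            bad.setdefault(i, msg)

    start = pd.to_numeric(df["start"], errors="coerce")
    end = pd.to_numeric(df["end"], errors="coerce")
    nm = pd.to_numeric(df["n_meth_cpg"], errors="coerce")
    nt = pd.to_numeric(df["n_total_cpg"], errors="coerce")
    flag(start.isna() | end.isna() | nm.isna() | nt.isna(), "non-numeric field")
    flag(end <= start, "end <= start")
    flag((nm < 0) | (nt < 0), "negative CpG count")
    flag(nm > nt, "n_meth_cpg > n_total_cpg")
    flag(~df["strand_fwd_read"].isin(["+", "-"]), "strand not in {+,-}")
    flag(~_motif_valid(df["end_motif"]), "malformed end_motif")

    if model is not None:
        known = df["chrom"].astype(str).isin(model._chrom_len)
        flag(~known, "unknown chromosome")
        lengths = df["chrom"].astype(str).map(model._chrom_len)
        in_range = (start >= 0) & (end <= lengths)
        flag(known & ~in_range.fillna(False), "coordinates outside chromosome")

    errors = [f"line {i + 2}: {msg}" for i, msg in sorted(bad.items())]
    ok = df.drop(index=list(bad)).reset_index(drop=True)
    ok = ok.astype(
        {"start": np.int64, "end": np.int64, "n_meth_cpg": np.int64,
         "n_total_cpg": np.int64, "sample_id": str, "chrom": str}
    )
    return ValidationReport(frame=ok[FRAGMENT_COLUMNS], errors=errors)


def read_fragment_table(path, model=None) -> ValidationReport:
    """Read and validate a fragment TSV (gzip-transparent, '#' comments
    skipped). Returns the validated frame plus per-row diagnostics."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str}, na_values=[])
    if df.empty and not set(FRAGMENT_COLUMNS) <= set(df.columns):
        raise ValueError(
            f"fragment table missing column(s): "
            f"{', '.join(c for c in FRAGMENT_COLUMNS if c not in df.columns)}"
        )
    return validate_fragments(df, model=model)


def write_fragment_table(df: pd.DataFrame, path, sort: bool = False) -> None:
    """Write fragments as TSV with deterministic column order and formatting;
    missing motifs written as ".". ``sort=True`` orders by (sample, chrom,
    start, end) for stable output from shuffled input."""
    out = df[FRAGMENT_COLUMNS].copy()
    if sort:
        out = out.sort_values(
            ["sample_id", "chrom", "start", "end"], kind="mergesort"
        ).reset_index(drop=True)
    out["end_motif"] = out["end_motif"].fillna(".")
    out.to_csv(path, sep="\t", index=False)


def read_manifest(path_or_frame) -> pd.DataFrame:
    """Read and validate a sample manifest.

    Required columns: sample_id, label. Optional: cohort (default discovery),
    stage (default NA), subtype (default NA). Vocabularies are enforced; in
    particular metastatic stage IV is rejected — the study design covers
    non-metastatic disease (stages I–IIIA) only.
    """
    if isinstance(path_or_frame, pd.DataFrame):
        df = path_or_frame.copy()
    else:
        df = pd.read_csv(path_or_frame, sep="\t", comment="#", dtype=str)
    for col, default in (("cohort", "discovery"), ("stage", "NA"), ("subtype", "NA")):
        if col not in df.columns:
            df[col] = default
        df[col] = df[col].fillna(default)
    missing = [c for c in ("sample_id", "label") if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing column(s): {', '.join(missing)}")

    dupes = df["sample_id"][df["sample_id"].duplicated()].unique()
    if len(dupes):
        raise ValueError(f"duplicate sample_id(s): {', '.join(map(str, dupes))}")
    for col, vocab in (
        ("label", LABELS), ("cohort", COHORTS), ("stage", STAGES), ("subtype", SUBTYPES)
    ):
        bad = sorted(set(df[col]) - vocab)
        if bad:
            extra = ""
            if col == "stage" and "IV" in bad:
                extra = " (metastatic stage IV samples are outside the assay's scope)"
            raise ValueError(f"invalid {col} value(s): {', '.join(bad)}{extra}")
    return df[MANIFEST_COLUMNS].reset_index(drop=True)


def write_manifest(df: pd.DataFrame, path) -> None:
    df[MANIFEST_COLUMNS].to_csv(path, sep="\t", index=False)


def check_manifest_covers(fragments: pd.DataFrame, manifest: pd.DataFrame) -> None:
    """Every fragment's sample_id must appear in the manifest."""
    orphan = set(fragments["sample_id"]) - set(manifest["sample_id"])
    if orphan:
        raise ValueError(
            f"fragments from sample(s) absent from manifest: {', '.join(sorted(orphan))}"
        )
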