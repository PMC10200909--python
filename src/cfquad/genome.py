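"""Genomic coordinate system: chromosome registry, 1-Mb style bin tiling,
blacklist masking and per-bin GC content.

All coordinates are 0-based, half-open (BED convention). Bins tile each
chromosome without overlap; the last bin of a chromosome may be shorter than
``bin_size``. Every genomic position maps to exactly one bin.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np


@dataclass
class GenomeModel:
    """Bin partition of a genome plus exclusion mask and optional GC track.

    Attributes
    ----------
    chromosomes : list of (name, length)
        Ordered chromosome registry; lengths in bp.
    bin_size : int
        Nominal bin width in bp.
    bin_chrom, bin_start, bin_end : ndarray
        Per-bin coordinates (half-open), in chromosome order then coordinate
        order.
    excluded : ndarray of bool
        True where a bin is masked out (blacklist overlap, all-N sequence).
    gc : ndarray of float or None
        GC fraction in [0, 1] per bin; NaN where undefined. None until a
        reference is supplied.
    """

    chromosomes: list[tuple[str, int]]
    bin_size: int
    bin_chrom: np.ndarray
    bin_start: np.ndarray
    bin_end: np.ndarray
    excluded: np.ndarray
    gc: np.ndarray | None = None
    _chrom_offset: dict[str, int] = field(default_factory=dict, repr=False)
    _chrom_len: dict[str, int] = field(default_factory=dict, repr=False)

    @property
    def n_bins(self) -> int:
        return len(self.bin_start)

    @property
    def retained(self) -> np.ndarray:
        """Boolean mask of bins kept for analysis."""
        return ~self.excluded

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())

    def bin_labels(self, retained_only: bool = False) -> list[str]:
        """``chrom:start-end`` identifiers, used as feature-matrix headers."""
        idx = np.flatnonzero(self.retained) if retained_only else range(self.n_bins)
        return [
            f"{self.bin_chrom[i]}:{self.bin_start[i]}-{self.bin_end[i]}" for i in idx
        ]

    def chrom_length(self, chrom: str) -> int:
        try:
            return self._chrom_len[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def replace(self, **kw) -> "GenomeModel":
        return dataclasses.replace(self, **kw)


def read_chrom_sizes(path) -> list[tuple[str, int]]:
    """Read a two-column UCSC chrom.sizes TSV (name, length)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, length = line.split("\t")[:2]
            out.append((name, int(length)))
    return out


def write_chrom_sizes(chromosomes, path) -> None:
    with open(path, "w") as fh:
        for name, length in chromosomes:
            fh.write(f"{name}\t{length}\n")


def build_genome_model(chrom_sizes, bin_size: int = 1_000_000) -> GenomeModel:
    """Tile each chromosome with non-overlapping ``bin_size`` bins.

    Parameters
    ----------
    chrom_sizes : sequence of (name, length) or mapping name -> length
        Chromosome registry; order is preserved and defines bin order.
    bin_size : int
        Bin width in bp (default 1 Mb).
    """
    if hasattr(chrom_sizes, "items"):
        chrom_sizes = list(chrom_sizes.items())
    chrom_sizes = [(str(n), int(l)) for n, l in chrom_sizes]
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    names = [n for n, _ in chrom_sizes]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate chromosome name(s): {', '.join(dupes)}")
    for name, length in chrom_sizes:
        if length <= 0:
            raise ValueError(f"non-positive length for chromosome {name!r}")

    chroms, starts, ends = [], [], []
    offsets, lens = {}, {}
    n_so_far = 0
    for name, length in chrom_sizes:
        offsets[name] = n_so_far
        lens[name] = length
        edges = np.arange(0, length, bin_size, dtype=np.int64)
        chroms.extend([name] * len(edges))
        starts.append(edges)
        ends.append(np.minimum(edges + bin_size, length))
        n_so_far += len(edges)
    bin_start = np.concatenate(starts)
    bin_end = np.concatenate(ends)
    return GenomeModel(
        chromosomes=chrom_sizes,
        bin_size=int(bin_size),
        bin_chrom=np.array(chroms, dtype=object),
        bin_start=bin_start,
        bin_end=bin_end,
        excluded=np.zeros(len(bin_start), dtype=bool),
        _chrom_offset=offsets,
        _chrom_len=lens,
    )


def locate_bin(model: GenomeModel, chrom: str, pos: int) -> int:
    """Index of the unique bin whose half-open interval contains ``pos``."""
    if chrom not in model._chrom_offset:
        raise KeyError(f"unknown chromosome {chrom!r}")
    length = model._chrom_len[chrom]
    if not 0 <= pos < length:
        raise ValueError(f"position {pos} outside {chrom} (length {length})")
    return model._chrom_offset[chrom] + int(pos) // model.bin_size


def locate_bins(model: GenomeModel, chrom, start) -> np.ndarray:
    """Vectorized :func:`locate_bin` for aligned arrays of chrom and start."""
    chrom = np.asarray(chrom, dtype=object)
    start = np.asarray(start, dtype=np.int64)
    offsets = np.array([model._chrom_offset[c] for c in chrom], dtype=np.int64)
    return offsets + start // model.bin_size


def read_bed(path) -> list[tuple[str, int, int]]:
    """Read a 3+ column BED file into (chrom, start, end) tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            out.append((fields[0], int(fields[1]), int(fields[2])))
    return out


def _merge_intervals(ivals):
    ivals = sorted(ivals)
    merged = []
    for s, e in ivals:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return merged


def apply_blacklist(
    model: GenomeModel, regions, max_overlap_fraction: float = 0.0
) -> GenomeModel:
    """Mark bins overlapping blacklist regions as excluded.

    A bin is excluded when its overlap with the union of ``regions`` exceeds
    ``max_overlap_fraction`` of the bin width. The default 0.0 excludes on any
    overlap. Idempotent; existing exclusions are preserved.

    Parameters
    ----------
    regions : iterable of (chrom, start, end) or a BED path
    """
    if isinstance(regions, (str, bytes)) or hasattr(regions, "read"):
        regions = read_bed(regions)
    by_chrom: dict[str, list] = {}
    for chrom, start, end in regions:
        if start >= end:
            raise ValueError(f"malformed interval {chrom}:{start}-{end} (start >= end)")
        if chrom not in model._chrom_offset:
            raise KeyError(f"blacklist chromosome {chrom!r} not in genome model")
        length = model._chrom_len[chrom]
        s, e = max(0, start), min(end, length)
        if s < e:
            by_chrom.setdefault(chrom, []).append((s, e))

    overlap = np.zeros(model.n_bins, dtype=np.int64)
    for chrom, ivals in by_chrom.items():
        off = model._chrom_offset[chrom]
        for s, e in _merge_intervals(ivals):
            first = s // model.bin_size
            last = (e - 1) // model.bin_size
            for b in range(first, last + 1):
                i = off + b
                overlap[i] += min(e, model.bin_end[i]) - max(s, model.bin_start[i])

    width = model.bin_end - model.bin_start
    excluded = model.excluded | (overlap > max_overlap_fraction * width)
    return model.replace(excluded=excluded)


def compute_bin_gc(model: GenomeModel, reference) -> GenomeModel:
    """Fill per-bin GC fraction from a FASTA reference.

    gc[b] = (G+C) / (A+C+G+T) over non-N bases of bin b. Bins whose sequence
    is entirely N get gc = NaN and are excluded.
    """
    from pyfaidx import Fasta

    fasta = reference if not isinstance(reference, (str, bytes)) else Fasta(str(reference))
    for name, _ in model.chromosomes:
        if name not in fasta:
            raise KeyError(f"chromosome {name!r} missing from reference")
    gc = np.full(model.n_bins, np.nan)
    excluded = model.excluded.copy()
    for i in range(model.n_bins):
        seq = str(fasta[str(model.bin_chrom[i])][
            int(model.bin_start[i]) : int(model.bin_end[i])
        ]).upper()
        at = seq.count("A") + seq.count("T")
        gcn = seq.count("G") + seq.count("C")
        if at + gcn == 0:
            excluded[i] = True
        else:
            gc[i] = gcn / (at + gcn)
    return model.replace(gc=gc, excluded=excluded)
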