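"""Synthetic cfDNA cohort generator.

Generates fragment tables, manifests and a ground-truth record for synthetic
cancer/control cohorts whose statistical structure mirrors the signals the
pipeline is built to detect:

* per-bin methylation-ratio shifts (breast-like global hypermethylation,
  liver-cancer-like global hypomethylation),
* per-bin copy gains/losses re-weighting where tumor-derived fragments land,
* 4-mer end-motif frequency perturbations (G-start enrichment and A-start
  depletion in cancer),
* a nucleosomal fragment-length mixture with mode 167 bp, with an excess of
  sub-150 bp fragments in the liver-cancer preset.

Tumor burden is modeled at the fragment level: each fragment of a cancer
sample is tumor-derived with probability ``tumor_fraction`` (per-sample,
drawn around a configurable mean — defaults emulate early-stage disease with
low circulating-tumor fractions). Identical spec + seed produces
byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fragments import FRAGMENT_COLUMNS, write_fragment_table, write_manifest
from .fragmentomics import ALL_MOTIFS, FLEN_MAX, FLEN_MIN, MOTIF_INDEX, revcomp
from .genome import GenomeModel, build_genome_model, write_chrom_sizes

UP_MOTIFS = ["GGAG", "GGAA", "GGGA", "GGTG", "GGCA"]
DOWN_MOTIFS = ["ATTT", "ATTA", "AATT", "AATA", "ACTT"]

# Qualitative subtype structure: genomically unstable subtypes carry strong
# copy-number and methylation shifts; luminal B / HER2 carry the end-motif
# signal. Magnitude scales multiply the preset effect sizes.
SUBTYPE_PRESETS = {
    "TNBC": {"cna": 1.5, "meth": 1.5, "em": 0.0},
    "HER2": {"cna": 1.0, "meth": 0.3, "em": 1.2},
    "luminal A": {"cna": 0.2, "meth": 0.3, "em": 0.3},
    "luminal B": {"cna": 0.3, "meth": 0.5, "em": 1.5},
    "luminal B-HER2": {"cna": 0.0, "meth": 1.2, "em": 0.4},
}


@dataclass
class MethylationSignal:
    control_bin_ratio: np.ndarray  # baseline ratio in [0,1] per retained bin
    cancer_shift: np.ndarray       # signed shift applied to tumor fragments

    def validate(self):
        r = self.control_bin_ratio
        if ((r < 0) | (r > 1)).any():
            raise ValueError("control_bin_ratio outside [0, 1]")


@dataclass
class CNASignal:
    gain_bins: np.ndarray = field(default_factory=lambda: np.array([], int))
    loss_bins: np.ndarray = field(default_factory=lambda: np.array([], int))
    copy_ratio_gain: float = 3.0
    copy_ratio_loss: float = 0.3

    def validate(self):
        if self.copy_ratio_gain <= 1 and len(self.gain_bins):
            raise ValueError("copy_ratio_gain must exceed 1")
        if not 0 <= self.copy_ratio_loss < 1 and len(self.loss_bins):
            raise ValueError("copy_ratio_loss must lie in [0, 1)")


@dataclass
class EndMotifSignal:
    control_motif_freq: np.ndarray          # 256-vector summing to 1
    cancer_factor: np.ndarray               # multiplicative per-motif factor

    def validate(self):
        f = self.control_motif_freq
        if abs(f.sum() - 1) > 1e-9 or (f < 0).any():
            raise ValueError("control_motif_freq must be a distribution")
        if (self.cancer_factor < 0).any():
            raise ValueError("negative motif perturbation factor")
        if (f * self.cancer_factor).sum() <= 0:
            raise ValueError("cancer motif distribution degenerate")

    def cancer_freq(self, scale: float = 1.0) -> np.ndarray:
        w = self.control_motif_freq * self.cancer_factor ** scale
        return w / w.sum()


@dataclass
class FlenSignal:
    control_pmf: np.ndarray   # over lengths 100..250 inclusive
    cancer_pmf: np.ndarray

    def validate(self):
        for pmf in (self.control_pmf, self.cancer_pmf):
            if len(pmf) != FLEN_MAX - FLEN_MIN + 1:
                raise ValueError("length pmf must cover 100..250 bp")
            if abs(pmf.sum() - 1) > 1e-9 or (pmf < 0).any():
                raise ValueError("length pmf must be a distribution")


@dataclass
class CohortSpec:
    genome: GenomeModel
    methylation: MethylationSignal
    cna: CNASignal
    end_motif: EndMotifSignal
    flen: FlenSignal
    n_cancer: int = 30
    n_control: int = 30
    fragments_per_sample: int = 200_000
    tumor_fraction_mean: float = 0.08
    tumor_fraction_sd: float = 0.02
    cpg_rate: float = 2.0
    gc_bias_amplitude: float = 0.0
    seed: int = 0
    preset: str = "custom"
    subtypes: list[str] | None = None

    def validate(self):
        if self.n_cancer < 0 or self.n_control < 0 or self.fragments_per_sample <= 0:
            raise ValueError("cohort sizes must be positive")
        self.methylation.validate()
        self.cna.validate()
        self.end_motif.validate()
        self.flen.validate()
        n_ret = int(self.genome.retained.sum())
        if len(self.methylation.control_bin_ratio) != n_ret:
            raise ValueError("methylation signal length != retained bins")
        for bins in (self.cna.gain_bins, self.cna.loss_bins):
            if len(bins) and (np.asarray(bins) >= n_ret).any():
                raise ValueError("CNA bin index outside retained bins")


@dataclass
class CohortResult:
    frames: dict[str, pd.DataFrame]
    manifest: pd.DataFrame
    truth: dict


# ------------------------------------------------------------------ presets


def default_genome(n_chrom: int = 5, chrom_length: int = 2_000_000,
                   bin_size: int = 50_000) -> GenomeModel:
    """Desk-scale synthetic genome: 5 x 2 Mb chromosomes at 50 kb bins
    (200 bins), standing in for the 1-Mb binned human autosomes."""
    return build_genome_model(
        [(f"chr{i + 1}", chrom_length) for i in range(n_chrom)], bin_size
    )


def _discretized_normal(mode: float, sd: float) -> np.ndarray:
    lengths = np.arange(FLEN_MIN, FLEN_MAX + 1)
    w = np.exp(-0.5 * ((lengths - mode) / sd) ** 2) + 1e-4
    return w / w.sum()


def _control_motif_freq() -> np.ndarray:
    # mild deterministic non-uniformity so the baseline is not exactly flat
    i = np.arange(len(ALL_MOTIFS))
    w = np.exp(0.25 * np.sin(2 * np.pi * i / 97.0))
    return w / w.sum()


def _control_bin_ratio(n_bins: int) -> np.ndarray:
    i = np.arange(n_bins)
    return 0.55 + 0.15 * np.sin(2 * np.pi * i / 37.0)


def cohort_spec(
    preset: str = "breast",
    n_cancer: int = 30,
    n_control: int = 30,
    fragments_per_sample: int = 200_000,
    tumor_fraction_mean: float | None = None,
    seed: int = 0,
    genome: GenomeModel | None = None,
    subtypes: list[str] | None = None,
) -> CohortSpec:
    """Build a :class:`CohortSpec` for one of the named presets.

    * ``breast``: global hypermethylation (+0.08 in tumor fragments), copy
      gains/losses on preset bins, G-start motif enrichment and A-start
      depletion; fragment lengths identical to control.
    * ``hcc``: global hypomethylation (-0.10), excess sub-150 bp fragments,
      no end-motif or copy-number perturbation.
    * ``null``: tumor fragments indistinguishable from normal ones.
    """
    genome = genome if genome is not None else default_genome()
    n_ret = int(genome.retained.sum())
    base_ratio = _control_bin_ratio(n_ret)
    motif_freq = _control_motif_freq()
    control_pmf = _discretized_normal(167.0, 9.0)
    factor = np.ones(len(ALL_MOTIFS))

    if preset == "breast":
        shift = np.full(n_ret, 0.08)
        for m in UP_MOTIFS:
            factor[MOTIF_INDEX[m]] = 1.8
        for m in DOWN_MOTIFS:
            factor[MOTIF_INDEX[m]] = 0.5
        # copy-number events span contiguous bin blocks (segment-like), wide
        # enough that the outlier smoother treats them as real structure
        cna = CNASignal(
            gain_bins=np.concatenate([np.arange(10, 16), np.arange(110, 116)]) % n_ret,
            loss_bins=np.arange(60, 68) % n_ret,
        )
        cancer_pmf = control_pmf
    elif preset == "hcc":
        shift = np.full(n_ret, -0.10)
        cna = CNASignal()
        cancer_pmf = 0.72 * control_pmf + 0.28 * _discretized_normal(142.0, 12.0)
        cancer_pmf = cancer_pmf / cancer_pmf.sum()
    elif preset == "null":
        shift = np.zeros(n_ret)
        cna = CNASignal()
        cancer_pmf = control_pmf
    else:
        raise ValueError(f"unknown preset {preset!r}")

    return CohortSpec(
        genome=genome,
        methylation=MethylationSignal(base_ratio, shift),
        cna=cna,
        end_motif=EndMotifSignal(motif_freq, factor),
        flen=FlenSignal(control_pmf, cancer_pmf),
        n_cancer=n_cancer,
        n_control=n_control,
        fragments_per_sample=fragments_per_sample,
        tumor_fraction_mean=(
            0.08 if tumor_fraction_mean is None else tumor_fraction_mean
        ),
        seed=seed,
        preset=preset,
        subtypes=subtypes,
    )


# --------------------------------------------------------------- generation


def sample_methylation(bin_ratio, n_cpg, rng) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-fragment methylation calls: n_meth ~ Binomial(n_cpg, ratio)."""
    n_cpg = np.asarray(n_cpg, int)
    if (n_cpg < 0).any():
        raise ValueError("n_cpg must be >= 0")
    ratio = np.clip(np.asarray(bin_ratio, float), 0.0, 1.0)
    return rng.binomial(n_cpg, ratio), n_cpg


def _placement_weights(spec: CohortSpec, tumor: bool, scale: float = 1.0):
    model = spec.genome
    keep = np.flatnonzero(model.retained)
    w = (model.bin_end - model.bin_start)[keep].astype(float)
    if spec.gc_bias_amplitude and model.gc is not None:
        from scipy.special import expit

        w = w * expit(spec.gc_bias_amplitude * (model.gc[keep] - 0.5)) * 2
    if tumor:
        mult = np.ones(len(keep))
        mult[spec.cna.gain_bins] = spec.cna.copy_ratio_gain ** scale
        mult[spec.cna.loss_bins] = spec.cna.copy_ratio_loss ** scale
        w = w * mult
    return keep, w / w.sum()


def generate_sample(
    spec: CohortSpec,
    sample_id: str,
    is_cancer: bool,
    tumor_fraction: float,
    rng: np.random.Generator,
    scales: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Generate one sample's fragment table (vectorized)."""
    scales = scales or {"cna": 1.0, "meth": 1.0, "em": 1.0}
    n = spec.fragments_per_sample
    model = spec.genome
    tumor = (
        rng.random(n) < tumor_fraction if is_cancer else np.zeros(n, dtype=bool)
    )

    keep, p_norm = _placement_weights(spec, tumor=False)
    bin_pos = np.empty(n, dtype=np.int64)  # index into retained bins
    n_tum = int(tumor.sum())
    if n_tum:
        _, p_tum = _placement_weights(spec, tumor=True, scale=scales["cna"])
        bin_pos[tumor] = rng.choice(len(keep), size=n_tum, p=p_tum)
    bin_pos[~tumor] = rng.choice(len(keep), size=n - n_tum, p=p_norm)
    bins = keep[bin_pos]

    lengths = np.empty(n, dtype=np.int64)
    all_lengths = np.arange(FLEN_MIN, FLEN_MAX + 1)
    if n_tum:
        lengths[tumor] = rng.choice(all_lengths, size=n_tum, p=spec.flen.cancer_pmf)
    lengths[~tumor] = rng.choice(all_lengths, size=n - n_tum, p=spec.flen.control_pmf)

    bstart = model.bin_start[bins]
    bend = model.bin_end[bins]
    start = rng.integers(bstart, bend)
    chrom = model.bin_chrom[bins]
    len_by_bin = np.array([model._chrom_len[c] for c in model.bin_chrom])
    start = np.minimum(start, len_by_bin[bins] - lengths)
    end = start + lengths

    strand = np.where(rng.random(n) < 0.5, "+", "-")

    motif_idx = np.empty(n, dtype=np.int64)
    if n_tum:
        motif_idx[tumor] = rng.choice(
            len(ALL_MOTIFS), size=n_tum, p=spec.end_motif.cancer_freq(scales["em"])
        )
    motif_idx[~tumor] = rng.choice(
        len(ALL_MOTIFS), size=n - n_tum, p=spec.end_motif.control_motif_freq
    )
    motifs = np.array(ALL_MOTIFS, dtype=object)[motif_idx]

    ratio = spec.methylation.control_bin_ratio[bin_pos].copy()
    ratio[tumor] += spec.methylation.cancer_shift[bin_pos[tumor]] * scales["meth"]
    n_total = rng.poisson(spec.cpg_rate, size=n)
    n_meth, _ = sample_methylation(ratio, n_total, rng)

    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "chrom": chrom,
            "start": start,
            "end": end,
            "strand_fwd_read": strand,
            "n_meth_cpg": n_meth,
            "n_total_cpg": n_total,
            "end_motif": motifs,
        },
        columns=FRAGMENT_COLUMNS,
    )


def generate_cohort(
    spec: CohortSpec,
    outdir: str | Path | None = None,
    cohort_label: str = "discovery",
    write_reference: bool = False,
) -> CohortResult:
    """Generate a full cohort: fragment tables, manifest, truth record.

    With ``outdir`` set, writes per-sample TSVs, manifest.tsv, truth.json,
    chrom.sizes and (optionally) a synthetic reference FASTA whose sequence
    at each fragment's informative 5' end matches the fragment's motif.
    """
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    master = np.random.default_rng(root.spawn(1)[0])

    ids, labels, subtypes, stages, tfs = [], [], [], [], []
    for i in range(spec.n_cancer):
        ids.append(f"cancer_{i + 1:03d}")
        labels.append("cancer")
        subtypes.append(
            spec.subtypes[i % len(spec.subtypes)] if spec.subtypes else "NA"
        )
        stages.append(["I", "II", "IIIA"][int(master.integers(3))])
        tf = master.normal(spec.tumor_fraction_mean, spec.tumor_fraction_sd)
        tfs.append(float(np.clip(tf, 0.01, 0.25)) if spec.tumor_fraction_mean > 0 else 0.0)
    for i in range(spec.n_control):
        ids.append(f"control_{i + 1:03d}")
        labels.append("control")
        subtypes.append("NA")
        stages.append("NA")
        tfs.append(0.0)

    frames: dict[str, pd.DataFrame] = {}
    child_seeds = root.spawn(1 + len(ids))[1:]
    for sid, label, subtype, tf, css in zip(ids, labels, subtypes, tfs, child_seeds):
        rng = np.random.default_rng(css)
        scales = SUBTYPE_PRESETS.get(subtype, {"cna": 1.0, "meth": 1.0, "em": 1.0})
        frames[sid] = generate_sample(
            spec, sid, label == "cancer", tf, rng, scales=scales
        )

    manifest = pd.DataFrame(
        {
            "sample_id": ids,
            "label": labels,
            "cohort": cohort_label,
            "stage": stages,
            "subtype": subtypes,
        }
    )
    truth = {
        "preset": spec.preset,
        "seed": spec.seed,
        "n_cancer": spec.n_cancer,
        "n_control": spec.n_control,
        "fragments_per_sample": spec.fragments_per_sample,
        "tumor_fraction": dict(zip(ids, tfs)),
        "methylation_shift_mean": float(spec.methylation.cancer_shift.mean()),
        "gain_bins": [int(b) for b in spec.cna.gain_bins],
        "loss_bins": [int(b) for b in spec.cna.loss_bins],
        "copy_ratio_gain": spec.cna.copy_ratio_gain,
        "copy_ratio_loss": spec.cna.copy_ratio_loss,
        "up_motifs": [
            ALL_MOTIFS[i] for i in np.flatnonzero(spec.end_motif.cancer_factor > 1)
        ],
        "down_motifs": [
            ALL_MOTIFS[i] for i in np.flatnonzero(spec.end_motif.cancer_factor < 1)
        ],
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if write_reference:
            frames = write_synthetic_reference(
                spec.genome, frames, seed=spec.seed, fasta_path=outdir / "reference.fa"
            )
        for sid, df in frames.items():
            write_fragment_table(df, outdir / f"{sid}.fragments.tsv.gz")
        write_manifest(manifest, outdir / "manifest.tsv")
        write_chrom_sizes(spec.genome.chromosomes, outdir / "chrom.sizes")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)

    return CohortResult(frames=frames, manifest=manifest, truth=truth)


def iter_samples(spec: CohortSpec, cohort_label: str = "discovery"):
    """Memory-light generator over (manifest_row, fragment frame)."""
    result = generate_cohort(spec, outdir=None, cohort_label=cohort_label)
    for _, row in result.manifest.iterrows():
        yield row, result.frames[row["sample_id"]]


# ---------------------------------------------------------------- reference


def write_synthetic_reference(
    model: GenomeModel,
    frames: dict[str, pd.DataFrame],
    seed: int,
    fasta_path: str | Path,
) -> dict[str, pd.DataFrame]:
    """Write a synthetic FASTA consistent with the cohort's end motifs.

    The genome is filled with random bases, then each fragment's drawn motif
    is stamped at its informative 5' end (first writer wins base-by-base).
    Afterwards every fragment's ``end_motif`` is re-read from the final
    sequence, so the reference-based extractor recovers the table's motif for
    100% of fragments. Intended for desk-scale cohorts; with heavy endpoint
    collisions the realized motif spectrum drifts from the nominal draw.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xFA57A]))
    bases = np.array(list("ACGT"))
    seqs = {
        name: rng.choice(bases, size=length).astype("<U1")
        for name, length in model.chromosomes
    }
    stamped = {name: np.zeros(length, dtype=bool) for name, length in model.chromosomes}

    for sid in sorted(frames):
        df = frames[sid]
        for chrom, start, end, strand, motif in zip(
            df["chrom"], df["start"], df["end"], df["strand_fwd_read"], df["end_motif"]
        ):
            if not isinstance(motif, str):
                continue
            if strand == "+":
                s, seq4 = start, motif
            else:
                s, seq4 = end - 4, revcomp(motif)
            free = ~stamped[chrom][s : s + 4]
            seqs[chrom][s : s + 4][free] = np.array(list(seq4))[free]
            stamped[chrom][s : s + 4] = True

    out_frames = {}
    for sid in frames:
        df = frames[sid].copy()
        motifs = []
        for chrom, start, end, strand in zip(
            df["chrom"], df["start"], df["end"], df["strand_fwd_read"]
        ):
            if strand == "+":
                m = "".join(seqs[chrom][start : start + 4])
            else:
                m = revcomp("".join(seqs[chrom][end - 4 : end]))
            motifs.append(m)
        df["end_motif"] = motifs
        out_frames[sid] = df

    with open(fasta_path, "w") as fh:
        for name, _ in model.chromosomes:
            fh.write(f">{name}\n")
            seq = "".join(seqs[name])
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    return out_frames
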