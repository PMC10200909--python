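# Methods

`cfquad` implements a multimodal analysis of cell-free DNA (cfDNA) fragment
records for cancer-vs-control classification. This note documents the models
and procedures, the parameters that matter, what the synthetic cohorts do and
do not emulate, and the numerical choices made where the design was open.

## Input model

The pipeline starts from *aligned fragment records*, not reads: one row per
sequenced cfDNA fragment with 0-based half-open coordinates, the strand the
forward (first) read aligned to, per-fragment CpG methylation call counts,
and optionally a precomputed 4-mer end motif. Alignment, trimming and
duplicate marking are upstream concerns. Carrying methylation as per-fragment
counts (`n_meth_cpg` of `n_total_cpg`) is exactly sufficient for bin-level
methylation ratios and keeps test fixtures small; site-level analyses are out
of scope.

The coordinate system is a `GenomeModel`: an ordered chromosome registry
tiled by non-overlapping bins (default 1 Mb; the synthetic genome uses 50 kb),
a blacklist-derived exclusion mask, and an optional per-bin GC track. Bin
counts are always derived from the supplied chromosome-sizes table and
blacklist — they are data-dependent, never hard-coded, because published bin
totals depend on unstated contig and filter choices. A bin is excluded when
its overlap with the blacklist union exceeds a configurable fraction of the
bin width (default: any overlap, the conservative choice).

## Feature families

**GWM (genome-wide methylation).** Per retained bin,
`ratio = sum(methylated C calls) / sum(total C calls)` over fragments whose
*start* falls in the bin. Start-coordinate assignment is unambiguous and
matches read-based pipelines; a fragment contributes to exactly one bin. Bins
with zero calls are missing and are mean-imputed inside the model pipeline
(training means only, to avoid leakage). Group-level comparison pools the
per-group mean ratio per bin and applies a two-sample KS test; the reported
direction is the sign of the difference of medians (positive =
hypermethylation of the first group).

**CNA (copy number).** Per sample: fragment counts per retained bin; a
lowess fit of count vs GC (span 0.3) divided out when a GC track exists;
normalization to sample median 1; and outlier smoothing — a bin whose
deviation from the 11-bin running median exceeds 4 window-MADs is replaced by
that median (any deviation counts when the window MAD is zero). The window
and MAD multiple are this package's choices; the upstream tooling this
emulates documents the step but not its parameters. Isolated single-bin
spikes are deliberately treated as artifacts; real copy-number events span
contiguous multi-bin segments and survive the smoother. Cohort level: per-bin
Z-scores against the control mean and sample SD, and gain/loss calls by
two-sided Wilcoxon rank-sum with Benjamini–Hochberg correction at q ≤ 0.05,
categorized by the sign of the cancer-vs-control log2 fold change of group
means (ε = 1e-9 guards zero means). A Welch-t variant is exposed for
heatmap-style Z-score displays.

**Flen (fragment length).** Frequencies (%) of each length 100–250 bp
inclusive — 151 dimensions; out-of-range fragments are excluded from both
numerator and denominator. Flen is extracted, tested (the liver-cancer
contrast shows the expected sub-150 bp excess; the breast contrast shows
none) but is *not* a base model by default, mirroring its lack of
breast-vs-control signal; a flag includes it.

**EM (end motifs).** The 4-mer at the fragment's informative 5' end, read
from the reference genome: for a '+' forward read, `ref[start, start+4)`;
for '−', the reverse complement of `ref[end-4, end)`. Only the forward
read's end is used because template-independent adapter tailing corrupts the
reverse read's 5' end. Motifs are indexed lexicographically AAAA..TTTT (256
dimensions, fractions summing to 1); motifs containing N are missing and
drop out of both numerator and denominator. All validated fragments are
counted regardless of length (a config flag can restrict to the 100–250 bp
window). Differential analysis per motif uses the normality-gated rule below
and BH across the 256 motifs, with a first-nucleotide (A/C/G/T) grouping of
the log2 fold changes.

## Statistical conventions

All tests are two-sided. The test-selection rule for differential features:
Welch t when *both* groups pass a Shapiro–Wilk normality check at α = 0.05,
Wilcoxon rank-sum otherwise (deterministic given the data; samples of < 3 or
zero range count as non-normal). BH adjustment uses the standard step-up
(via statsmodels, verified against an explicit sorting oracle). AUC
inference is the DeLong placement-value construction implemented in-package:
AUC by the Mann–Whitney identity with ties at 1/2, variance from per-class
placement-value sample variances, Wald CIs truncated to [0, 1], and a paired
z-test for correlated AUCs.

## Synthetic cohorts

The generator produces the *study conditions* every downstream stage is
tested against. Tumor burden is modeled at the fragment level: each fragment
of a cancer sample is tumor-derived with probability equal to the sample's
tumor fraction, drawn per sample from N(0.08, 0.02) clipped to [0.01, 0.25]
— the low circulating-tumor fractions of early-stage disease. Tumor-derived
fragments differ from normal ones in four ways:

* **Placement**: uniform over retained bins, re-weighted by per-bin copy
  ratios (gain 3.0, loss 0.3) on contiguous preset blocks (gains: bins
  10–15 and 110–115; losses: 60–67 of 200).
* **Methylation**: the bin's baseline ratio (a deterministic 0.40–0.70
  profile) shifted by +0.08 (breast preset) or −0.10 (liver preset), then
  clipped to [0, 1]; calls are Binomial(n_CpG, ratio) with n_CpG ~
  Poisson(2), typical for ~167 bp fragments.
* **End motif**: drawn from the control spectrum (mildly non-uniform,
  deterministic) re-weighted ×1.8 for the five enriched G-start motifs
  (GGAG, GGAA, GGGA, GGTG, GGCA) and ×0.5 for the five depleted A-start
  motifs (ATTT, ATTA, AATT, AATA, ACTT), renormalized.
* **Length**: a discretized normal with mode 167 bp and SD 9 (nucleosome +
  linker); the liver preset mixes in 28% of a short component at 142 bp.
  The breast preset's length distribution equals the control's.

Effect magnitudes are free parameters chosen once from a power sketch so
that the injected signals are recoverable at desk scale (tens of samples,
1e4–2e5 fragments each) under early-stage tumor fractions; no quantitative
effect sizes exist to copy from real cohorts. Subtype presets rescale the
three effect channels qualitatively (e.g. triple-negative: strong
copy-number and methylation, no motif shift; luminal B: strong motif shift,
weak copy-number).

The default synthetic genome is 5 chromosomes × 2 Mb at 50 kb bins
(200 bins), a desk-scale stand-in for 1 Mb-binned human autosomes. Seeds
fully determine output (byte-identical files). When asked, the generator
also writes a synthetic reference FASTA in which each fragment's drawn motif
is stamped at its informative 5' end (first writer wins base by base, and
every fragment's recorded motif is then re-read from the final sequence), so
the reference-based extractor recovers the table's motif for 100% of
fragments; with heavy endpoint collisions the realized spectrum drifts from
the nominal draw, so this mode is intended for small cohorts.

What the synthetic data does **not** emulate: sequencing errors and
bisulfite conversion chemistry, coverage waviness beyond an optional smooth
logistic GC bias, correlated neighboring-bin noise, batch effects, and
between-sample coverage heterogeneity. Passing tests therefore demonstrate
the pipeline's correctness and statistical calibration under the modeled
signal structure, not clinical performance on real plasma.

## Classification

For each feature family (GWM, CNA, EM) three algorithms are considered:
logistic regression, random forest, gradient-boosted trees. Hyperparameters
come from a grid search by stratified 10-fold CV maximizing ROC AUC (fold
count clamps to the minority class size on small cohorts; grids are small,
config-supplied defaults). Feature selection: tree models keep features with
importance ≥ 1e-4 and are refit on them; logistic regression picks the best
of L1/L2/no penalty by CV AUC. The combination model is an *unpenalized*
logistic regression on the three base probability scores. Its training
inputs are produced **out-of-fold** — each training sample is scored by a
base model that never saw it — because in-sample stacking is optimistic; a
`naive_stacking` switch reproduces the in-sample variant for comparison.
Base models are refit on the full training data after the OOF pass.

The decision cutoff is the smallest score threshold whose training-cohort
specificity reaches the requested floor (0.90 or 0.95); since specificity is
nondecreasing and sensitivity nonincreasing in the threshold, this is also
the max-sensitivity qualifying threshold. The cutoff is frozen on the
discovery cohort and applied unchanged to validation data. Evaluation
reports AUC with DeLong 95% CIs overall and per stratum (a stratum's cancers
vs *all* controls), detection rate (fraction of the stratum's cancers at or
above the cutoff), and specificity; strata with < 5 cancers are flagged
CI-unreliable. Strict train/validation separation is enforced by cohort
tags and tested by a tripwire (poisoning validation labels must not change
the fitted model).

A degenerate-input note: gradient-boosted trees with default
`min_child_weight` produce constant scores when CV folds shrink to a few
samples (the hessian floor forbids any split); a family with constant
out-of-fold scores is warned about and effectively ignored by the combiner,
and fitting fails only if *every* family is degenerate.

## Pipeline, determinism, problem sizes

`run-all` chains simulate → extract → differential → train → evaluate.
Every data artifact carries a provenance header (package version, seed,
hash of the analysis config; output paths are excluded from the hash).
Reruns of an identical config + seed are byte-identical, with one documented
exception: log files carry wall-clock timings. Model files are pickled
estimators plus a JSON summary (algorithms, CV AUCs, selected-feature
counts, cutoff).

The test suite and the acceptance script run the pipeline at desk scale,
chosen as the package's own verification sizes: signal recovery on a
30 + 30-sample breast cohort at 2×10⁵ fragments/sample; false-discovery
control on 100 label permutations of a 20 + 20 null cohort (200 bins, 256
motifs); stacked-model behavior over repeated seeds with 60 + 60 training
and 30 + 30 held-out samples at 10⁴ fragments/sample; determinism on a
small null run. The generator's own defaults (30 + 30 samples, 2×10⁵
fragments) stand in for cohorts of hundreds of plasma samples at ~20 M
read pairs each.

## Known limitations

* Fragment→bin assignment by start coordinate slightly blurs features for
  fragments straddling a bin boundary (< 0.5% of fragments at 50 kb bins).
* The KS test on per-bin *mean* profiles compares distributions of bin
  means, not per-sample distributions; sample-level tests are exposed
  separately.
* No segmentation or absolute copy-number calling; CNA features are
  relative coverage only.
* DeLong CIs are Wald-type and degenerate at AUC = 1 (zero width); small
  strata are flagged rather than bootstrapped.
* The motif-consistent synthetic reference is first-writer-wins; dense
  cohorts distort the realized motif spectrum, so consistency checks use
  small cohorts.
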