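# Methods

This note documents the statistical model behind `dosagecomp`, the
defaults and why they were chosen, what the synthetic cohorts do and do
not emulate, and the numerical conventions that matter for reproducing
results.

## Fold changes and the neutral reference

All downstream statistics are built on per-gene, per-sample log2 fold
changes relative to a *neutral group*: for each gene within each tumor
type, the samples whose DNA log2 copy-number ratio lies in
[−0.2, 0.2].  The reference for every layer is the median over that group
on the layer's native scale; linear layers (RNA abundances) are converted
as `l2fc = log2(value / reference)`, log2 layers (DNA ratio, TMT protein
ratio) as `l2fc = value − reference`.  Scales are an explicit input
contract (`OmicsMatrix.scale`) because public cohorts mix conventions —
RNA is typically linear FPKM-like, protein a log2 TMT ratio.

The DNA fold change is recomputed against the neutral group's own median
DNA ratio rather than assumed zero; this makes the pipeline robust to a
globally shifted ratio baseline.  Genes with fewer than `min_neutral = 5`
neutral samples carry no reference there: a median over fewer samples is
too unstable to anchor fold changes.

Two gene filters precede correlation analyses, both applied per tumor
type: the bottom 10% of genes by median RNA (removing exactly
`floor(0.10 · n_genes)` genes, ties broken by gene ID so the result is
deterministic), and genes whose DNA ratio sits inside (−0.02, 0.02) in
strictly more than 70% of samples (no usable dosage signal).

SCNA groups partition the DNA log2FC axis as deep loss (x < −0.65), loss
(−0.65 ≤ x < −0.2), neutral (−0.2 ≤ x ≤ 0.2), gain (0.2 < x ≤ 0.65) and
high gain (x > 0.65).  The conventional group definitions leave the
boundaries themselves ambiguous; we close the neutral bin on both sides to
match the neutral-group definition and resolve the outer boundaries
inward.

## Compensation score and bootstrap inference

`CS = sign(d) · (d − x)` for DNA fold change `d ≠ 0` and expression fold
change `x`; positive CS means buffering.  CS is undefined at `d = 0` and
is only computed outside the neutral group (whose bounds exclude 0); the
function still guards the degenerate input.

Group-level inference is fully bootstrap-based, mirroring standard
practice for medians of heavy-tailed fold-change data:

* *Median vs zero*: resample the cell's CS observations with replacement
  (default 10,000 times), one-tailed p = (1 + #{boot medians ≤ 0}) /
  (B + 1).
* *Class difference* (complex vs non-complex): both groups resampled
  independently; the two-tailed p recenters the bootstrap distribution at
  zero, p = 2·min(P*(stat* − stat ≥ stat), P*(stat* − stat ≤ stat)) with
  the (1+k)/(B+1) correction.  The tail construction is a design choice —
  the test is conventionally named but not specified to this level — and
  is the standard shift-invariant construction.
* Confidence intervals use the basic bootstrap, (2θ̂ − q0.975, 2θ̂ −
  q0.025).
* Benjamini–Hochberg FDR is applied jointly across all cells of one
  analysis family (per layer, across SCNA groups, classes and
  tumor types).  Family boundaries are configurable because no single
  convention is forced by the analysis.

Cells below `min_cell_size = 20` observations are reported as missing
rather than tested; bootstrap medians over smaller cells are unstable.
The bootstrap resamples gene × sample CS observations within a cell (a
per-gene collapse would weight genes equally instead of observations;
with roughly balanced designs the two agree in direction).

## Regulation profiles

Spearman's ρ is computed in-repo as the Pearson correlation of average
ranks so tie handling is explicit and testable against a hand-ranked
oracle; pairs with missing values are deleted pairwise and at least
`min_pairs = 10` complete pairs are required.  Per-gene DNA–RNA and
RNA–protein correlations are computed within each tumor type and combined
pan-cancer as the unweighted mean over contributing types (a
sample-size-weighted mean is available but off by default: the unweighted
mean is the convention for cross-cohort aggregation when cohort sizes are
roughly comparable).

The gene-level association between the two correlations is summarized by
representative points: the joint density f(DR, RP) is estimated by a
Gaussian KDE (Scott bandwidth) on a 100 × 100 grid, the DR range is split
into 40 windows, and each window contributes the RP of maximum density.
The OLS slope and the Spearman ρ of the representative points are the
association estimates.  Exactly collinear clouds make the KDE covariance
singular (and a zero bandwidth along the degenerate axis), so the
implementation detects a near-singular covariance or a degenerate density
and falls back to a 100 × 100 histogram density; the fallback is also
selectable directly.  Recovery of a noiseless linear cloud is then exact
to within one RP grid cell.

Regulation groups take the opposite tails at quantile q = 0.35 (type-7
linear-interpolation quantiles; genes at the realized cutoff are
included): group 1 = high DNA–RNA and low RNA–protein correlation (weak
RNA-level, strong protein-level regulation), group 2 the mirror image.
Realized cutoffs are data-dependent and are reported with the groups.

Pathway aggregation takes the median ρ over member genes (≥ 5 genes per
pathway) and associates the two pathway-level vectors by Spearman and
Pearson correlation; restrictions to complex-only or non-complex-only
genes check that an association is not carried by complex membership
alone.  Over-representation of a gene group in flat gene sets uses the
one-sided hypergeometric upper tail with BH adjustment.

## Aneuploidy and expression association

Segments (0-based half-open coordinates) are tiled into 100 kb windows
within arm boundaries; a window's ratio is the coverage-weighted mean of
overlapping segments, and windows covered by a single segment carry its
value exactly so that strict threshold comparisons are not perturbed by
rounding.  An arm needs ≥ 50% of its windows covered to be called; the
arm ratio is the mean over covered windows (a constant arm keeps its exact
value), with gain strictly above +0.2 and loss strictly below −0.2.  The
aneuploidy score is the count of non-neutral arms; uncalled arms
contribute zero.  Arm calling by thresholded window means is the simplest
faithful realization of the stated rule; re-segmentation or smoothing is
out of scope.

Per-gene association uses OLS, `expr ~ aneuploidy + covariates`, with
categorical covariates expanded to indicator contrasts and listwise
deletion of incomplete samples; the t-value of the aneuploidy coefficient
is the ranking statistic.  Fits with numerically zero residual variance
are flagged degenerate (signed infinite t) and excluded from ranking;
rank ties break by gene ID.  The cell-cycle covariate is the mean log2 RNA
over a user-supplied gene list (the canonical ~10-gene cell-cycle-entry
list is an input, not a hard-coded default); mitochondrial or other gene
exclusions are a generic annotation-driven mask applied before ranking.

Preranked enrichment follows the weighted Kolmogorov–Smirnov running sum:
hits advance by |score|^w (w = 1) normalized over the set, misses retreat
by 1/(N − N_hit), and the enrichment score is the extreme deviation (ties
between the positive and negative extreme resolve positive).  Null ES
values come from gene-label permutation (random same-size sets); the
nominal p uses the same-sign tail, NES divides by the mean same-sign null
magnitude, and FDR uses the standard sign-separated permutation estimate.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:

* Arm-level Bernoulli SCNA events (default rate 0.25 per arm) on a 39-arm
  genome (22 chromosomes, acrocentric p-arms absent), magnitudes
  |N(0.5, 0.15)| floored at 0.25 so every event is callable, random sign.
  Segments are emitted noiselessly (one per arm), so true arm calls are
  recoverable exactly; the gene-level DNA matrix adds small measurement
  noise (sd 0.05) as real copy-number ratios are never exactly zero.
* RNA responds to DNA with gene-specific attenuation `c_rna` and protein
  to RNA with `c_prot` (both in [0, 1]), plus Gaussian noise in log2 space
  — the simplest model consistent with log-ratio data, keeping analytic
  expectations closed-form: at zero noise the protein-layer CS equals
  `c_eff · |d|`.
* Complex genes default to strong protein buffering and quiet RNA
  (c_prot ≈ 0.6, c_rna ≈ 0.05, RNA noise × 0.6; ribosomal genes c_prot ≈
  0.95), non-complex genes the reverse (c_prot ≈ 0.2, c_rna ≈ 0.25) — the
  recoverable analogue of the observed complex/non-complex contrast, not a
  hard-coded result.
* Noise scales are drawn per pathway through a Gaussian copula whose
  correlation `pathway_coupling` couples RNA-noisy pathways to
  protein-quiet ones (−1) or protein-noisy ones (+1), which determines the
  sign of the pathway-level association between the two regulation layers.
* Cohort sizes default to 90 samples per tumor type (typical
  proteogenomic cohorts run 80–110) and three tumor types at desk scale;
  RNA baselines are log-normal (log2 mean 5, sd 1.5) so the bottom-10%
  expression filter has real work to do.

Not emulated: TMT ratio compression, batch effects, purity mixtures
(purity enters only as a covariate column), focal sub-arm events, and
multi-isoform protein collapse (inputs are assumed gene-level).  Passing
parameter-recovery tests therefore demonstrates correctness of the
estimators under the generative model, not robustness to those real-data
artifacts.

## Problem sizes and determinism

Test and acceptance runs use desk-scale cohorts (hundreds of genes,
40–100 samples per type, 1000–2000 bootstrap/permutation resamples for
calibration loops, 10,000 for single contrasts); these sizes put
Monte-Carlo error well inside the asserted bands while keeping the full
suite around a minute of compute.  All randomness flows through
`numpy.random.default_rng` seeds carried in configs or function
arguments, and every writer formats floats as `%.10g`, so identical
config + seed reproduce outputs byte-for-byte.

## Known limitations

* The bootstrap difference test assumes exchangeability within each
  group; strong gene–gene correlation within a cell (co-amplified
  neighbors) would make its p-values anti-conservative on real data.
* The density-slope estimator inherits KDE bandwidth sensitivity; the 40
  bins / 100 × 100 grid defaults are stable for n ≥ a few hundred genes
  but the slope of small profiles should be read with the representative
  points themselves.
* Permutation FDR for preranked enrichment pools null NES across sets of
  different sizes, the standard convention; very heterogeneous set sizes
  can bias it slightly in either direction.
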