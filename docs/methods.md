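# Methods

This note documents the models, estimators and numerical choices behind
`tfdosage`, and what the bundled synthetic data can and cannot establish
about real screens.

## The problem and the pipeline

A graded CRISPRi/CRISPRa screen modulates the dosage of a few *cis*
transcription factors across a wide, continuous range — each guide RNA
realizes a different dosage depending on its class and position relative
to the TSS — and reads out a targeted panel of *trans* genes by
single-cell RNA-seq. The analysis question is the shape of each trans
gene's dose-response: linear, sigmoid (saturating), non-monotonic, or
flat. The pipeline runs five stages: simulate (optional), preprocess,
fold-change estimation, dose-response modelling, downstream association
analyses. One global seed fans out to per-stage child seeds via
`numpy.random.SeedSequence.spawn`, so identical configuration and seed
give byte-identical outputs.

## Synthetic-data generator

The generator emulates the study design at the processed-matrix level; it
is the ground truth against which every estimator is validated.

**Design.** 96 guides by default (51 tiling, 8 TSS, 20 attenuated, 12
enhancer, 5 NTC) distributed round-robin over 4 cis genes, the last of
which is a negative control whose trans network is entirely flat. Both
modalities receive the full library; cells per (guide, modality) are
Poisson with mean 80 — the per-guide cell counts reported for this kind
of screen — giving ~15,400 cells at default scale before QC.

**Designed cis effects.** Tiling-guide efficacy is Gaussian in TSS offset
with modality-specific modes (+238 bp for interference, −99 bp for
activation; width 500 bp) and peak magnitudes 1.8 / 0.8 log2 units, so
realized effects span roughly −1.8 to +0.8 — the observed cis range of
such screens. Attenuated-guide efficacy decays exponentially with
mismatch-to-PAM distance; enhancer guides draw mid-magnitude effects
(0.2–0.6); NTC effects are zero unless an off-target spike is configured.
Interference effects are ≤ 0 and activation effects ≥ 0 by construction.
Per-guide multiplicative efficiency noise (uniform 0.6–1.0) breaks exact
symmetry between guides.

**Trans response curves.** Each (trans gene, cis gene) pair draws a curve
type from configurable proportions (default 30% linear, 45% sigmoid, 5%
non-monotonic, 20% unresponsive). Sigmoid truths use the same 4PL
parameterization as the fitting code with |d−c| ∈ [0.2, 2.0], |b| ∈
[2, 10], a ∈ [−0.5, 0.5]; non-monotonic truths are Gaussian bumps (height
0.3–1.0, width 0.3–0.6, peak in [−1, 0.2]). Every curve is shifted to pass
through (0, 0): observed responses are fold changes relative to NTC, so a
zero dosage change must produce zero response.

**Count model.** Expected count of gene *g* in cell *j* is
`baseline_g × libfactor_j × 2^effect`, where the effect is the guide's
designed cis log2FC for its target and the truth curve evaluated at that
log2FC for trans genes. Baselines are log-uniform on [1, 30] expected
UMI/cell (median cell depth ~900 UMIs over the ~94-gene panel, matching a
targeted-capture assay where a minority of cells fall below the 500-UMI QC
floor). Library factors are lognormal (σ = 0.35). Counts are negative
binomial with size 10 (variance μ + μ²/10): targeted hybridization-capture
UMI data is near-Poisson with modest overdispersion — size 2, an early
candidate, emulates sparse droplet data and is inconsistent with the
low-noise readout this assay produces. A `poisson_mode` flag gives the
Poisson limit for moment tests. Guide capture counts are background
Poisson(0.3) plus NB(mean 50) for true carriers; 5% of cells carry a
second guide; two modality marker transcripts (mean 8) leak 2% across
modalities; one always-zero and one highly expressed control transcript
round out the panel.

**What the generator does not emulate:** ambient RNA, doublet
transcriptomes (multi-guide cells are labelled, not mixed), batch/lane
effects, cell-cycle or growth-rate confounding, UMI saturation, and any
feedback of trans genes onto the cis gene. Passing tests therefore show
estimator correctness under the stated generative model, not robustness
to these real-data artifacts.

## Preprocessing

QC thresholds are strict inequalities (a 500-UMI, 50-gene cell survives);
the top-1% depth trim is applied after the two minimum filters, removing
`floor(0.01 n)` cells among survivors with ties broken by stable input
order. Guide calling fits a two-component univariate Gaussian mixture on
log2(count+1) per guide across the cells with a *positive* count — fitting
across all cells lets the mixture collapse onto the zero spike and call
"zero vs nonzero" instead of "ambient vs carrier". Because integer counts
make the fitted data a set of point masses, the mixture uses a covariance
floor (`reg_covar = 0.05`); guides whose component means are separated by
less than 2 log2 units yield no calls (ambient-vs-carrier separation is
several units). A cell carries a guide at posterior > 0.5; cells with
other than exactly one called guide are discarded. Modality is assigned
by the larger of the two marker transcripts' normalized expression, then
5% trims are applied (lowest interference-marker cells among interference
cells; highest interference-marker cells among activation cells).
Normalization is `ln(1 + count × 10⁴ / cell total)`; the 10⁴ scale factor
is the convention of the normalization method this reproduces.

## Fold changes

`logfc = ln(mean₁ + ε) − ln(mean₂ + ε)` with group means taken on the
depth-normalized **linear** scale (back-transformed from log1p values) —
the convention of the single-cell implementation this formula comes from.
Averaging the log values instead compresses every fold change (measured
attenuation: regression slope 0.27 instead of ~1 against designed
effects). ε = 10⁻⁹ guards zero means; genes with zero counts in both
groups get logfc 0, p 1, and a flag. The NTC reference pools all kept NTC
guides of the modality. Wilcoxon rank-sum tests use the exact null for
small untied groups, full enumeration for small tied groups, and the
tie- and continuity-corrected normal approximation otherwise; BH-FDR is
joint across all guide × gene × modality tests.

**Compositional bias.** With total-count normalization on a ~94-gene
panel where most genes respond, a strong cis perturbation shifts the
per-cell total and biases all fold changes slightly against the direction
of the net panel response. Measured at 200 cells/guide: regression slope
of estimated on designed cis log2FC ≈ 1.00–1.05, mean bias ≈ −0.04 ± 0.01.
An oracle experiment normalizing by the true library factor gives slope
0.997 and bias −0.004, confirming the estimator itself is unbiased; the
residual is a property of ratio normalization on small panels and affects
any analysis using it.

**NTC off-target screen.** Within each modality, every unordered NTC pair
is differentially tested (BH within the pair, across genes). A guide is
discarded when more than one of its comparisons shows more than one DE
gene at FDR < 0.05 and every gene recurring across those flagged
comparisons changes in a consistent direction (oriented to the guide).
With only two NTC guides the ">1 comparison" condition is unsatisfiable
and both are kept. Direction consistency is evaluated per gene; two
flagged comparisons with disjoint DE gene sets count as (vacuously)
consistent.

## Dose-response models

**Parameterization.** `y = c + (d−c)/(1+exp(b(x−a)))` with d ≥ c enforced
by post-fit canonicalization (swapping c↔d and negating b leaves the
model invariant). Under this convention a *negative* b encodes an
increasing curve, and the true slope at the inflection is −b(d−c)/4; b is
a shape parameter, not the literal slope.

**Fitting.** Bounded trust-region least squares with an analytic
Jacobian; bounds a ∈ [min x − 1, max x + 1], |b| ≤ 50, c, d within the
data range ± its span. Seven starts from data quantiles (inflection at
the x quartiles, asymptotes at the y 5th/95th percentiles in both
orientations, b at ∓4, ±8, and a near-linear start). Tolerances are
xtol = ftol = gtol = 10⁻⁸ with at most 100 function evaluations per
start: on flat (pure-noise) genes the optimizer otherwise crawls through
the degenerate valley where |b| grows and d−c shrinks at constant
residual (~1.4 s per fit), and the extra precision is far below the noise
floor of every recovered parameter. Multi-start also stops early when,
after three starts, the best fit explains under 2% of the variance around
the mean — flat data, where further starts only polish an uninformative
optimum. RSS is floored at 10⁻¹² (flagged) before the Gaussian ML AIC
`n(ln(2π·rss/n)+1) + 2(k+1)`, where k+1 counts the residual variance
(linear 3, sigmoid 5); only AIC differences are ever interpreted, so the
Gaussian constant is irrelevant to ΔAIC. ΔAIC thresholds: > 2 for counting
a response as nonlinear, > 0 for the enrichment contrast; both are named
constants.

**Cross-validation.** 10 random folds. Each fold's fit uses its own three
quantile starts — *not* a warm start from the full-data optimum, which
couples the folds, deflates the parameter SDs the responsiveness z-tests
divide by, and (measured) drops flat-gene specificity from 0.97 to 0.85.
Fold fits that fail, or whose |b| lands at the optimizer bound (a
degenerate step; the shape is unidentified), are dropped; parameter
means/SDs are taken over survivors and the held-out Pearson r pools all
held-out predictions.

**Responsiveness.** z = mean/SD over fold estimates: two-sided for b
against 0, one-sided for the asymptote range d−c against 0.05 log2 units.
Both p-value families are BH-adjusted per cis-gene network (per-network,
not global: each network is its own analysis); responsive requires both
adjusted p < 0.05. Genes with fewer than 3 surviving folds cannot be
tested and default to unresponsive. The z-test uses the SD of the 10 fold
estimates (not SD/√10); folds share 90% of their data, so the test is
anti-conservative in principle — the CV is a guard against overfitting,
not an exact inference.

**Non-monotonicity.** Candidates are genes at or above the within-network
95th percentile of ΔRMSE = RMSE(sigmoid) − RMSE(LOESS) (for an 88-gene
network this admits ~5 genes). Confirmation — the automated stand-in for
visual curve validation — requires both: (i) an interior extremum of the
LOESS curve with prominence ≥ max(0.05, 2 × LOESS RMSE); and (ii) raw-data
support: observations within a window (1/8 of the x-range) around the
extremum differ from those on *each* side by ≥ 0.05 in the reversing
direction with rank-sum p < 0.05 on both sides. A fixed 0.05 prominence
alone cannot separate real reversals from smoother wiggle: degree-2 LOESS
on sigmoid plateaus at noise SD 0.1 produces spurious prominences up to
~0.19, and top-ΔRMSE candidates are precisely the wiggliest fits. The
combined rule confirms all planted bells (height ≥ 0.3) and yielded zero
confirmations over two independent 20-seed all-monotonic blocks (a
residual false-confirmation rate of order 10⁻³ per gene remains — one
borderline dip was observed in a third block of 1,760 null genes).
Confirmed genes are predicted from the LOESS model.

**LOESS.** Local polynomial regression with tricube weights; span 0.75,
degree 2 by default (the smoothing defaults of the R implementation this
mirrors). The window is `ceil(span·n)` points and must cover at least
degree+1 points; prediction outside the observed x-range is flat
extrapolation, flagged.

**Prediction grid and restricted fits.** Default grid: 101 points on
[−1.83, 0.51], the empirically realized cis range being emulated. The
one-copy-restricted refit uses x ∈ [−1.0, +0.585] — log2(1/2) to
log2(3/2), i.e. one hypothetical copy lost to one gained — and is skipped
below 5 surviving points.

## Downstream analyses

Hierarchical clustering of the concatenated per-network prediction
vectors uses complete linkage on Euclidean distance (k = 6 by default).
Qualitative gene properties are tested per network and per sigmoid
parameter (a, b, c, d, range) with two-sided rank-sum tests between
flagged and unflagged genes; quantitative metrics with pairwise-complete
Pearson correlations; both BH-adjusted per network, and both excluding
non-responsive and non-monotonic genes first (their sigmoid parameters
are meaningless). Enrichment of nonlinear responses (ΔAIC > 0) in gene
sets uses two-sided Fisher exact tests with Haldane–Anscombe 0.5 in the
log-odds when a cell is zero (flagged; the exact p is computed on the
uncorrected table), BH per analysis family (disease sets and GWAS trait
sets separately). Cell-type profiles are z-scaled per gene across cell
types; perturbation-profile correlations are Pearson over shared trans
genes (cis genes excluded) with a 10% FDR flag. The cis-determinant
analysis runs a LOESS trend of cis log2FC against TSS offset (tiling and
TSS guides only) and reports the trend's extremum offset; interval
annotations are 0-based half-open with overlap defined by the guide's
offset coordinate, strand ignored.

The downstream module is exercised against synthetic annotation tables
and cell-type profiles with planted structure (housekeeping flags
enriched among small-range genes, pHaplo anti-correlated with range,
disease/GWAS sets enriched among nonlinear responders, one "maturation"
profile aligned with a chosen network's response) so that each test has a
known expected direction.

## Problem sizes and runtime

The default end-to-end run simulates ~15,400 cells × 94 genes × 96 guides
× 2 modalities and completes in under two minutes on one CPU; the
benchmark evaluations use 200 genes × 90 dose points per condition and
100-seed null replications for the NTC screen. These sizes were chosen to
match the emulated study's scale while keeping a full reproduction run in
the minutes range.

## Known limitations

- The responsiveness z-test inherits the anti-conservativeness of
  CV-derived SDs noted above.
- Compositional bias of total-count normalization (~−0.04 log2 on the
  strongest cis effects) is inherent to the method, not corrected.
- Non-monotonic detection is powered for reversals ≥ 0.3 log2 units at
  noise SD ~0.1; shallower reversals are deliberately not confirmed.
- The guide caller assumes a unimodal ambient background well below
  carrier capture; libraries with extreme ambient contamination would
  need the separation threshold revisited.
- The simulator's independence assumptions (no trans-trans coupling
  beyond the shared cis dose, no feedback) make network-level statistics
  cleaner than real data would be.
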