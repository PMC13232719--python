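# Methods

`spatial-ime` re-implements, as a reusable and tested pipeline, the
quantitative analyses used to compare the immune microenvironment of
minimally invasive (MI) versus highly invasive (HI) brain metastases:
composition profiling of segmented single-cell images, permutation-based
cell–cell interaction testing, cellular-neighborhood discovery, GeoMx
digital-spatial-profiling (DSP) matrix processing with differential
expression and preranked gene-set enrichment, and immunohistochemistry
scoring.  Because the per-cell imaging tables of the original cohorts are
not publicly deposited at that granularity, the package ships a
synthetic-data generator with known ground truth; all statistical claims
made by the test suite refer to those synthetic study conditions.

## Data model

A cell table is one row per segmented cell: `cell_id`, `image_id`,
continuous coordinates `x`, `y` in micrometres (1 pixel ≡ 1 µm; no
rasterization), a lineage label from a declared palette, and optional
per-marker intensities.  The default palette has 20 lineages: one cancer
lineage, eighteen resolvable stromal types, and an "Undefined" bucket for
cells the antibody panel cannot classify.  "Undefined" counts as stroma by
default — it is reported alongside the other stromal populations — and the
flag is configurable.  Image metadata carries the grouping keys: patient,
primary site, region (`core` inside the metastasis, `margin` at the
brain–tumor interface) and growth pattern (`MI`/`HI`).

## Composition profiling

Frequencies are percentages of stroma: the denominator is the count of
stromal cells in the image, cancer cells appear in neither numerator nor
denominator, so frequencies are invariant to tumor cellularity.  Two-group
comparisons use the two-tailed unpaired Student's t-test (Welch available
by flag); more than two groups use one-way ANOVA.  Raw p-values are
reported at α = 0.05 with no multiple-testing correction by default
(Benjamini–Hochberg optional), matching how such panels are usually
summarised per lineage and region.

## Cell–cell interaction and avoidance

Cells within **6 µm** are neighbours.  For an ordered pair (row → column)
the observed statistic is the mean number of "to"-type neighbours per
"from"-type cell (focal cell excluded) — the per-cell mean is invariant to
"from"-type abundance.  Lineage labels are permuted over the fixed
coordinate multiset (**50,000** permutations by default; one shuffle
re-scores every pair of the image).  The interaction score counts
permutations with a statistic strictly below the observed one, the
avoidance score those strictly above, and ties go to a separate bucket, so
`interaction + avoidance + ties = n_perm` exactly; since label frequencies
are preserved, these strict comparisons are carried out on integer
directed-edge counts, which makes tie handling exact and keeps one-type
images at score 0.  A pair is classified interacting (avoiding) when its
interaction (avoidance) score exceeds the cutoff, **25,000** of 50,000 —
i.e. the observed statistic lies above (below) the permutation median.

A consequence worth stating: under complete spatial randomness the score is
uniformly distributed by exchangeability, so the median-cutoff
classification labels roughly (1 − tie mass)/2 ≈ 35–45 % of null images per
direction at tissue-realistic densities.  The classification is therefore a
*direction* assignment used to aggregate score distributions, not a
significance call; significance enters only at the group level, where
per-image net scores `(interaction − avoidance)/n_perm ∈ [−1, 1]` are
compared between MI and HI with a two-tailed unpaired t-test
(Mann–Whitney by flag).  Net scores are mean-centred at zero under
randomness (verified by simulation), and planted attraction (strength 0.8
at a 6 µm kernel, 20 images per group) is detected with the correct
direction in every replicate.

## Cellular neighborhoods (CNs)

Each cell's window is its own lineage plus its **N = 10** nearest
neighbours (Euclidean, per image; ties at the N-th distance break toward
the lowest `cell_id`).  Windows include the focal cell, so rows sum to
N + 1.  Raw counts are clustered — with N fixed, counts and fractions
differ by a constant and give identical k-means partitions — by mini-batch
k-means (**K = 9** by default; k-means++ initialisation, batch size 1024,
up to 100 iterations, 10 initialisations, fixed seed; all recorded in the
run manifest).  The model is fit on margin images pooled across patients;
core images can be projected by nearest centroid.  Per-image CN prevalence
is reported in percent and normalised to sum to exactly 100: values are
snapped to a dyadic grid (multiples of 2⁻⁴⁰, a sub-10⁻¹² perturbation) on
which float64 addition is exact, and the largest entry absorbs the
residual.  CN numbering is arbitrary; reports identify CNs by their
centroid composition (e.g. the lymphoid-richest CN in the band-recovery
test).  Voronoi diagrams are computed from the cell coordinates and clipped
to the image bounding box (mirror-point construction), so edge cells get
finite polygons and the tessellation tiles the frame.

## GeoMx DSP processing

Pipeline order is fixed: probe collapse → LOQ → target filter → ROI QC →
rounding → differential expression → GSEA.

- **Probe collapse.** Each target is measured by 1–5 probes; the target
  value per region of interest (ROI) is the geometric mean of its probe
  counts.  When a probe group contains a zero, 0.5 is added to every count
  of that group before the log (groups without zeros are untouched, so
  `{4, 9} → 6` exactly).
- **Limit of quantification.** Per ROI, LOQ = geometric mean of the 88
  negative-control probes times the squared geometric SD
  (`exp(2·sd(ln neg))`): "two standard deviations above the geometric
  mean" read multiplicatively, the coherent convention for lognormal
  spike-ins.  An additive-SD variant exists behind `mode="arithmetic"`.
- **Filtering and QC.** Targets with no value above the LOQ in any ROI are
  excluded (one ROI above suffices); ROIs below a configurable total-count
  threshold are dropped with their totals logged.
- **Differential expression.** The geometric-mean matrix is rounded to
  integers; size factors are median-of-ratios; each gene gets a two-group
  negative-binomial GLM (log link, size-factor offset) with per-gene
  dispersion by Cox–Reid adjusted profile maximum likelihood
  (method-of-moments fallback) and a Wald test on the condition
  coefficient, referred to a t distribution with n − 2 degrees of freedom.
  The two small-sample corrections matter: with ~6 ROIs per group, plain
  profile-ML dispersion plus a normal reference is anticonservative
  (~9–10 % of null genes at p < 0.05); with them the null suite shows ~5 %
  at p < 0.05 and no Benjamini–Hochberg rejections at padj < 0.1 in 19–20
  of 20 null replicates.  log2 fold changes are MI relative to the HI
  baseline; significance is padj < 0.1.  On small simulated matrices the
  log2 fold changes agree with the pydeseq2 reimplementation of DESeq2 to
  < 0.1 (correlation > 0.99), which serves as the independent cross-check.
- **Heatmap matrix.** For significant genes, counts are library-size
  normalised (scaled to the median library), log10-transformed with
  pseudocount 1, and z-scored per gene across ROIs with the sample-SD
  (ddof = 1) convention; constant genes map to all-zero rows.
- **Preranked GSEA.** Genes are ranked by log2 fold change; the enrichment
  score is the extreme deviation of the weighted Kolmogorov–Smirnov running
  sum (hit steps ∝ |metric|, weight exponent 1; uniform miss steps; exact
  ± ties resolve positive).  The null is gene-label permutation (sample
  permutation is impossible for a preranked metric); p-values and the
  normalised ES are sign-stratified, with BH adjustment across sets.  Gene
  sets are read from GMT; sets overlapping the universe in fewer than two
  genes are skipped.

## IHC / IHF scoring

Gates are conjunctions of marker thresholds (e.g. CD8⁺CD4⁻PanCK⁻),
evaluated independently — a cell may match several gates, because marker
combinations rather than an exclusive partition are quantified.  Gated
fractions use the PanCK-negative (stromal) denominator.  The H-score of an
ROI is staining intensity (0–3) × percent positive cells, bounded by 300;
the margin/core ratio averages ROI H-scores within each region first, then
divides (a zero core mean yields an explicit undefined flag, never
infinity).  Rank correlations between per-sample summaries use Spearman's
coefficient with tie-corrected ranks; the p-value uses the t-approximation
for n > 10 and the exact permutation distribution (all n! orderings,
two-sided) for small n.

## Synthetic data: what it emulates, and what it does not

The tissue generator places each lineage as a homogeneous Poisson process
per zone of a disc-plus-annulus geometry (core disc, margin band, outer
brain), with intensities in points/mm² chosen to resemble a moderately
cellular metastasis (~2,000 cells/mm² core).  Pairwise attraction is
implemented by relocating a fraction `strength` of the "child" type next
to random "parent" cells (Neyman–Scott style), avoidance by distance
thinning; both give monotone, seed-stable control of the planted effect.
Neighborhood domains overwrite the lineage mixture inside a region (and can
thin it, emulating acellular zones), providing an exact ground-truth
partition.  The DSP generator draws negative-binomial target counts split
across 1–5 probes, lognormal negative controls, and plants group log2 fold
changes.  The intensity-panel generator uses a bounded uniform negative
component and a strictly separated lognormal positive component so that
threshold gating has exact ground truth.

Deliberately not modelled: segmentation errors and lineage misassignment,
marker spillover, anisotropic tissue architecture, 3-D effects, probe-level
sequence biases and batch effects.  Passing tests therefore demonstrate the
correctness and calibration of the algorithms under these idealised
conditions, not robustness of biological conclusions to real-data
artefacts.

## Problem sizes and numerical choices

Calibration suites use 200 randomly labelled images of ~500 cells (three
exchangeable types, 1 mm² frame) at 5,000 permutations, power suites 20
replicate two-group experiments of 20 images each at 1,000 permutations;
DE suites use 300–500 targets with 6–8 ROIs per condition and 20
replicates.  The lymphoid-band experiment uses the cohort's margin group
sizes (6 MI vs 16 HI images).  Monte-Carlo checks use 3–4 binomial
standard errors depending on the number of simultaneous assertions.
Duplicate coordinates in Voronoi input are jittered by 10⁻⁹ µm with a
warning; degenerate images (fewer than N + 1 cells) fall back to all
available cells and are flagged.  All randomised operations take explicit
seeds and are bit-reproducible; every CLI run writes a JSON manifest with
the configuration, seed and library versions.

## Known limitations

- The interaction classification inherits the published median-score
  cutoff; as noted above it is not a significance test per image, and
  analyses should rely on the group-level comparison of net scores.
- Per-gene dispersion is estimated without information sharing across
  genes; with very few ROIs per group, confidence intervals are wider than
  those of empirical-Bayes pipelines.
- The exact Spearman permutation p-value enumerates n! orderings and is
  practical only for n ≤ 10 (the implementation switches automatically).
- GSEA uses gene-label permutation, which treats genes as exchangeable and
  ignores inter-gene correlation.
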