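# Methods

This note documents the models, defaults and numerical choices behind each
module, what the synthetic generators do and do not emulate, and the known
limitations.

## 3D morphometrics (`morph3d`)

**Segmentation.** The seed mask is built by an ordered sequence:
per-slice 3×3 median filter (despeckle), 3D Gaussian smoothing
(sigma 1 voxel), binarization (Otsu on a 256-bin histogram by default, a
manual threshold is supported), hole filling with a 6-connected
background, binary opening and closing with a ball structuring element of
radius 1 voxel, and a second despeckle. The named steps of the original
imaging protocol do not fix the kernels; these are the simplest standard
choices and are all configurable through `SegmentationParams`.

**Region growing.** Thin dendritic protrusions are easily lost to
median filtering and opening, so the seed mask is grown against the
despeckled image: for each seed component, any voxel connected to it
(26-connectivity by default) whose intensity lies within a tolerance of
the component's mean seed intensity is absorbed. The default tolerance is
twice a robust (MAD-based) estimate of the background SD. Growth is a
connected-component operation on a fixed acceptability field, so the
result is deterministic and independent of visit order, and always a
superset of the seed.

**Inclusion criteria.** A cell is kept when it contains at least one
nucleus centroid (nuclei segmented by Otsu on the nuclei channel) and
touches no volume boundary. The third customary criterion — the detected
shape matching the raw image — is human judgment; it is
emitted as an overlap fraction between the cell mask and the
Otsu-binarised reference for review and is never applied automatically.

**Measurement.** Volume is voxel count × voxel volume. The surface is a
marching-cubes triangulation at iso-level 0.5 with voxel spacing applied
to the vertices; the mask is lightly Gaussian-smoothed (sigma 1 voxel)
before meshing because meshing a raw binary grid overestimates the area
of curved surfaces by the staircase factor (~9% for a ball of radius 20;
~0.3% after smoothing). Labels thin enough that smoothing would erase
them fall back to the raw mask and small labels are flagged degenerate.
The diameter is the maximum Feret diameter — the largest pairwise
distance between surface vertices, computed on the convex hull; maximum
Feret is the standard reading of "diameter" among 3D morphometry tools,
though conventions vary. Anisotropic stacks
can be resampled to isotropic spacing (linear interpolation) with
`resample_isotropic`; `measure_cell` also accepts an explicit spacing.

On digitized solids these choices give sphericity and roundness within
5% of the closed forms for balls of radius ≥ 15 voxels and roundness
within 10% of bc/a² for ellipsoids up to 4:1 aspect ratio; the end-to-end
pipeline recovers noiseless phantom volumes within ~2%.

**Group comparison.** Pairwise two-sided Wilcoxon rank-sum tests on each
shape metric, BH-FDR adjusted across all (metric, pair) comparisons, with
fold changes of group medians.

## Enrichment (`enrichment`)

**Preranked GSEA.** The enrichment score is the signed extremum of the
weighted Kolmogorov–Smirnov running sum: hits increment by
|score|^w / Σ|score_hits|^w, misses decrement by 1/(N − |S|). The default
weight exponent is 1 (classic weighted GSEA). Ties in the ranking are
broken by gene name so results are deterministic. The null is gene-label
permutation (random sets of the same size), appropriate at the small
sample sizes this pipeline targets; the default is 1000 permutations from
a seeded generator. NES divides the ES by the mean |ES| of same-sign
permutations; if no permutation shares the sign, NES is reported missing
with a warning. The permutation p-value uses an add-one correction over
the same-sign permutations, so its attainable floor is
1/(n_same_sign + 1) and p ∈ (0, 1].

**ssGSEA.** Genes are ranked by within-sample expression (descending,
name tie-break); the score is the sum over all positions of the weighted
hit ECDF (weights = rank^alpha with the top gene at rank N; default
alpha 0.25) minus the unweighted miss ECDF. With an all-gene set the miss
ECDF has no mass and contributes zero. At alpha 0 the score is purely
rank-based and invariant to monotone transformations of expression.

**Subset scores.** A CAF subset score is NES(up) − NES(down) for one
ranked profile, positive only when the profile matches the subset in both
directions; the per-patient variant is ssGSEA(up) − ssGSEA(down). Under a
random signature the score is centred at zero; with concordant planted
signatures it is positive in ≥ 95% of replicates (both checked in the
acceptance suite).

**Signatures.** Subset-vs-rest two-sided Wilcoxon rank-sum per gene on
library-size-normalised expression (counts per 10k), BH adjustment, and
strict thresholds: up = log2FC > 0.25 and adjusted p < 0.05, down
symmetric. Fold changes use means of normalised expression with a
pseudocount of 1.

**TF concordance.** The fraction of transcription factors whose
enrichment signs agree, over the union of significant TFs in the two
profiles; a TF significant in only one profile counts as discordant.
Conventions for this comparison vary upstream (union vs intersection
denominator, significance cutoff), so the definition used is returned in
the metadata alongside the number.

## qPCR state score (`state_score`)

Relative expression is −(Ct_gene − Ct_reference); the reference is RPL37A
in the default panel (myCAF genes ACTA2, COL1A1, TAGLN; IL-iCAF genes
IL6, IL24, CXCL8, TMEM158). The composite score of a condition is

    raw = mean_i(w_my_i · q_i) − mean_j(w_IL_j · q_j)

with unit weights by default (in-vivo log2FC weights can be supplied),
then normalised by subtracting the baseline condition's mean raw score.
There is no single canonical algebra for composites of this kind, so the
functional form is a pluggable strategy
(`weighted_mean_diff` default; `weighted_sum_diff` and
`abs_weight_mean_diff` variants) and the strategy used is recorded in the
output metadata. Scores are computed per replicate; condition comparisons
use pairwise Welch t-tests with BH adjustment.

## Ligand-receptor consensus (`lri`)

Interactions are identified by (ligand, receptor, sender, receiver),
case-normalised. CellPhoneDB-like tables pass at p < 0.05 (strict);
NATMI-like tables keep the top 20% per receiving cell type ranked by
√(weight × specificity), with ceil rounding (the source protocol does not
state the rounding) and deterministic tie-breaks (score, then
ligand/receptor name); Scriabin-like per-patient tables pass when
significant (p < 0.05) in ≥ 3 distinct patients — only significant
detections count. The ≥ 3-patient recurrence rule applies to the
per-patient dialect only, since the pooled methods have no patient axis.
The consensus method count is the number of passing methods (0–3), sorted
by count then NATMI score; the output is independent of input row order.

## Explant quantification (`explant`)

Cells are QC-filtered on closed intervals of nucleus area and total DAPI
signal (bounds are configuration, not constants). Marker positivity uses
Otsu's threshold on a 256-bin histogram of total per-cell marker
intensity; calls are strictly-greater-than, and double positivity (e.g.
PDPN⁺α-SMA⁺) is the conjunction. The between-class variance is flat
across an empty gap between modes, so the threshold is the centre of the
maximising plateau rather than its first bin — on well-separated bimodal
data this lands midway between the modes. The percentage-change statistic
is, by default, the median over treated cells of
100 · (x − median(control)) / median(control); an alternative
(difference of group medians over the control median) is available behind
a flag, and the definition used is recorded in the output. Because either
convention is defensible, rank-sum tests on both raw intensities and
per-cell percentage changes are emitted. The upstream cell-detection
parameters (background radius 13 µm, sigma 3.0, cell expansion 8.5 µm,
etc.) are shipped as documented defaults only; detection itself is out of
scope and the module starts from exported per-cell tables.

## Survival (`survival`)

Relative abundance of two CAF subsets is the difference of their
per-patient subset scores. Stratification cuts at the empirical 1/3 and
2/3 quantiles (linear interpolation); ties go to the lower stratum, so a
degenerate constant vector is all "low" with a warning. Kaplan-Meier
estimation and the k-sample log-rank test are delegated to lifelines;
only complete-case rows are used, with the dropped count logged. Whether
cross-stratum p-values should be overall or pairwise is a reporting
choice; the overall k-sample test is the default and pairwise tests are
emitted alongside.

## Synthetic data (`synth`)

Every generator is a pure function of its arguments including the seed,
and returns ground truth with the data.

* **Volumes**: balls, prolate spheroids and dendritic cells (ball body
  plus axis-aligned cylindrical protrusions) painted at constant
  intensity over a dim background with additive Gaussian noise; one
  nucleus ball of a quarter of the cell's minor axis at each centroid, so
  the "contains a nucleus" criterion is always decidable. Truth metrics
  are closed-form for balls and spheroids (prolate/oblate surface area
  exact, Thomsen approximation otherwise); dendritic cells have no tidy
  closed form for overlapping solids, so their truth is measured from the
  exact truth mask.
* **Counts**: negative binomial in the (mean, dispersion)
  parameterisation (variance μ + 0.5 μ² by default), log-normal gene-level
  base means around 5, four subsets of 50 cells, 25 planted markers per
  subset elevated 2 log2 in their subset only. These defaults make marker
  recovery a fair but non-trivial test of the signature builder.
* **qPCR**: Ct constructed so that −(Ct_gene − Ct_ref) equals a baseline
  level plus the planted log2 effect plus Gaussian noise (SD 0.2 cycles),
  3 replicates.
* **LRI**: at zero noise, planted interactions pass all three method
  rules and four low-scoring decoys per true are emitted in the same
  receiver so the NATMI top-20% (ceil) keeps exactly the trues; noise
  removes each true's evidence per method, and grants decoys spurious
  evidence, independently with the given probability.
* **Marker tables**: two-mode Gaussian mixtures (modes 100/300, SD 10,
  60/40 weights — the asymmetric weights keep the group median inside a
  mode, where the median percentage-change statistic is stable); the
  treated group is scaled by 1 + shift/100.
* **Survival**: exponential event times per stratum with independent
  uniform censoring; the censoring bound is solved numerically so the
  expected censored fraction equals the requested rate.

Not emulated: optics (PSF, attenuation with depth), doublets/ambient RNA,
batch effects, primer efficiencies, correlated censoring. Passing tests
on these generators therefore demonstrates correctness of the
computations under their stated assumptions, not robustness to every
artefact of real microscopes, sequencers or cohorts.

## Problem sizes and reproducibility

The test and acceptance workloads use phantom volumes of ~64×96×96
voxels, 1000-gene counts with 50 cells per subset, 200–500 permutations
per enrichment call (vectorised over permutations), 200 replicates for
null-calibration checks, and 40 seeds for log-rank power checks — sizes
at which every result is stable yet the whole suite runs in well under a
minute per module. All randomness flows through `numpy.random.default_rng`
seeded per call; orchestrated runs derive per-stage seeds from the run
seed by hashing, and the run manifest records the seed, parameters and
SHA-256 of every artifact, making repeated runs byte-identical.

## Known limitations

* Surface-area and diameter estimates are meaningful for labels a few
  voxels across or larger; single-voxel labels are flagged degenerate.
* The gene-label permutation null ignores inter-gene correlation; NES
  magnitudes are comparable within a run, not across datasets.
* The qPCR composite assumes the reference gene is unaffected by the
  conditions; no primer-efficiency correction is applied.
* Tertile stratification with heavily tied scores produces unbalanced
  strata by design (ties go low) and warns rather than failing.
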