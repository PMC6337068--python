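# Methods

`gliograde` implements an automated, interpretable grading workflow for
diffuse gliomas (WHO grades II, III, IV) operating on H&E tile images and a
per-patient Ki-67 immunohistochemistry count. This note documents the models
and procedures, the parameters that matter, what the synthetic cohort does
and does not emulate, and the design choices taken where the design was
genuinely open.

## Pipeline

1. **ROI identification** (`roi`). A slide image is partitioned into
   non-overlapping square tiles (default 5120 px for real slides; the
   synthetic desk scale uses 512 px). Partial edge tiles are dropped rather
   than padded, so every tile has equal area and the raw nucleus count ranks
   tiles identically to nuclear density. Nuclei are detected per tile and the
   k = 5 highest-count tiles become the ROIs; ties break in row-major order
   so selection is deterministic, and increasing k only appends tiles.

2. **Nuclei segmentation** (`segmentation`). RGB is converted to optical
   density per channel, OD = −log10((pixel+1)/256), and unmixed with the
   Ruifrok–Johnston H&E stain basis. The haematoxylin channel is thresholded
   (Otsu by default, with a floor of 0.15 OD so blank tiles yield no false
   foreground), opened with a 1-px disk, and split by marker-controlled
   watershed on the negative Euclidean distance transform; markers are
   distance-transform maxima separated by ≥ 7 px. Regions under 40 px² are
   discarded and labels renumbered 1..N. The distance-transform watershed
   (rather than a gradient watershed) is used because it reliably separates
   touching, roughly convex nuclei. Regions are 4-connected; perimeters use
   the Crofton estimator; axes and eccentricity come from second central
   moments. All pixel-unit parameters scale linearly with resolution
   (`SegmentationParams.scaled`). The choice to segment the deconvolved
   haematoxylin channel rather than plain grayscale is deliberate: it is the
   nuclear stain, and it makes staining features and detection consistent.

3. **Feature extraction** (`features`). Per case, pooled over the selected
   ROIs:
   * 24 *visual* features — mean and SD of 7 nuclear morphology measures
     (area, perimeter, major axis, minor axis, circularity 4πA/P²,
     eccentricity, solidity), 5 staining summaries (mean nuclear
     haematoxylin OD, mean within-nucleus intensity SD, mean eosin OD in a
     2-px perinuclear ring, nucleus-to-background gray contrast, mean
     per-nucleus chromatin entropy), and 5 spatial-pattern statistics
     (nucleus count, density, mean and SD of centroid nearest-neighbour
     distance, Clark–Evans index = observed mean NN distance over the
     complete-spatial-randomness expectation 0.5/√density). The perinuclear
     eosin ring is measured around the union of nuclei rather than per
     nucleus; at 2 px the two differ only where nuclei nearly touch.
   * 171 *sub-visual* features — 13 first-order statistics (mean, median,
     SD, variance, skewness, kurtosis, min, max, range, 10th/90th
     percentiles, IQR, Shannon entropy over a 64-bin histogram) on each of
     the gray, haematoxylin-OD and eosin-OD channels (39), and 11 grey-level
     co-occurrence properties (contrast, dissimilarity, homogeneity, energy
     = ΣP², correlation, entropy, cluster shade, cluster prominence, maximum
     probability, sum average, difference variance) at 4 angles × 3
     distances (1, 2, 4 px) on the gray channel quantized to 32 levels, with
     symmetric normalized matrices (132). Sub-visual vectors are averaged
     across the k ROIs, one vector per patient. Degenerate inputs: skewness
     and kurtosis of a zero-variance sample are defined as 0; a constant
     image has entropy 0; GLCM correlation of a zero-variance matrix is
     defined as 1.
   * 1 *IHC* feature — the Ki-67 proliferative index PI = positive/total ×
     100, stored in percent.

   The published battery is counted (24 and 171) but never enumerated; the
   decomposition above is this package's canonical reconstruction, chosen to
   sum exactly to those counts and to include every feature the per-case
   explanations name (SD of perimeter, SD of major axis, nucleus count,
   pattern and GLCM texture features). The full 196-column ledger is
   emitted as `feature_ledger.json` with every run.

4. **Feature selection** (`selection`). Features are ranked by
   random-forest mean impurity decrease (500 trees, normalized to sum 1) and
   reduced by backward elimination: each round drops the lowest
   ⌈0.2 × current⌉ features, capped so the count never undershoots the
   target, and records stratified 5-fold CV accuracy. Sub-visual features
   pass through two sequential stages, 171 → 50 → 15 (the intermediate size
   of 50 is a config-exposed choice; only the two-stage structure and the
   final 15 are fixed by design); visual features one stage, 24 → 11. Ki-67
   is never subject to elimination. The model table is therefore always
   11 + 15 + 1 = 27 features wide.

5. **Grading** (`grading`). Four families — random forest, gradient-boosted
   trees, RBF-kernel SVM, and a one-hidden-layer MLP — are compared on
   identical repeated splits: 30 stratified 75/25 hold-out partitions
   (largest-remainder allocation, so a 116-case cohort splits 87/29).
   Hyperparameters are tuned per repeat by grid search with inner 5-fold
   stratified CV on training rows only; standardization lives inside the
   same pipeline and is fitted on training rows. Default grids are small on
   purpose: SVM C ∈ {0.1, 1, 10, 100}, γ ∈ {scale, 0.01, 0.1}; RF 200/500
   trees × depth {∞, 10}; GBDT rate {0.05, 0.1} × {100, 300} estimators;
   MLP hidden {16, 64} × L2 {1e-4, 1e-2}. Reported: accuracy, macro and
   weighted precision/recall/F1 as mean ± SD over repeats, per-grade
   accuracy (class-conditional recall, pooled; an empty confusion row is
   reported as missing, never 0), and the pooled confusion matrix. SVM
   class probabilities use pairwise-coupling (Platt) calibration, which the
   explainer requires. A separate `external_validation` helper scores a
   fixed hold-out set with each repeat's model, reported as mean ± SD.

6. **Explanation** (`explain`). For one case, features are standardized with
   training statistics and perturbed independently ~ Normal(0, 1) in
   standardized space (n = 5000 by default; the case itself is sample 0).
   Samples are weighted by exp(−d²/σ²) with σ = 0.75·√p. For each grade, the
   black-box probability is regressed on the K = 8 features with the largest
   absolute weighted correlation, using weighted ridge regression (penalty
   1.0; on a singular design the penalty is multiplied by 10 once). The
   fitted coefficients are the local probability slopes; the per-case
   contribution reported for a feature is the slope times the case's
   standardized deviation from the training mean, so the sign answers
   whether *this case's value* pushed the grade's probability up or down
   (a low Ki-67 supports grade II with a positive contribution even though
   the probability slope in Ki-67 is negative). Both are kept on the
   report; weighted R² reports local fit quality. Screening by weighted correlation plus ridge
   (instead of a LASSO path) is a deliberate divergence from canonical LIME:
   it is deterministic given the seed and has identical semantics for the
   linear-recovery guarantees tested here. Zero-variance features are held
   at the case value with a warning.

## Synthetic cohort

The generator (`synthetic`) produces a three-grade cohort with the study's
composition (146 cases: 49 / 45 / 52) and grade-dependent structure:

| grade | nuclei/tile | radius (px) | ecc. max | darkness | cluster frac. | Ki-67 PI (%) |
|-------|------------|-------------|----------|----------|---------------|--------------|
| II    | 150        | 6 ± 1       | 0.30     | 0.50     | 0.10          | 3.0 ± 2.1    |
| III   | 300        | 7 ± 2       | 0.60     | 0.60     | 0.30          | 11.8 ± 3.4   |
| IV    | 450        | 8 ± 3       | 0.80     | 0.75     | 0.50          | 15.8 ± 7.4   |

Ki-67 means/SDs are the published per-grade norms; the image parameters are
invented, chosen so grades are learnable but their feature distributions
overlap. Tiles are 512 px (all geometry is scale-free; 5120 px is the
real-slide constant). Nucleus count is Poisson; radii are Normal (clipped at
2 px); eccentricity uniform up to the profile maximum with area-preserving
semi-axes; a cluster fraction of nuclei is placed around Gaussian cluster
centres. Nuclei are rendered as haematoxylin absorbance (Beer–Lambert, exact
Ruifrok–Johnston vectors, darkness → OD amplitude with chromatin texture)
over an eosin background, plus Gaussian pixel noise, so stain deconvolution
is exact by construction. A minimum-separation factor of 0.7·(r_i+r_j)
allows partial overlap (exercising the watershed split path); a factor ≥ 1
gives strictly non-overlapping tiles for segmentation oracles. Per-case RNG
streams derive from the master seed as `master_seed + case_index`, never
global state.

Ki-67 counts: total ~ uniform[1000, 3000] (the counting protocol examines at
least 1000 cells); PI ~ Normal(mean, SD) **censored** (clipped) to [0, 100];
positive ~ Binomial(total, PI/100). Censoring rather than
rejection-renormalized truncation keeps the grade II empirical mean near the
nominal 3.0 (clipping shifts it to ≈ 3.07; renormalized truncation would
shift it to ≈ 3.33). PI is sampled once per case, matching a per-patient
Ki-67 protocol.

**What the generator does not emulate:** tissue architecture (necrosis,
microvascular proliferation, infiltration fronts), cytoplasm and stromal
texture, scanner/stain batch variation, mixed magnification, or ambiguous
histology near grade boundaries. The planted effects (especially the
density gap) make the synthetic grading task easier than clinical grading;
a high synthetic accuracy demonstrates that the pipeline's stages are
correct and leak-free, not that the published clinical accuracy transfers.
The synthetic magnification is arbitrary — no per-tile magnification is
specified for the source data — so all pixel-unit defaults are stated at
the 512-px scale and rescale linearly.

## Problem sizes and numerical choices

The default desk-scale configuration uses one 512-px tile per case (the ROI
stage then selects that tile; multi-tile slides are exercised separately),
which keeps a full 146-case feature build around a minute on one CPU while
leaving every stage's logic identical to real-slide mode. Determinism:
identical seeds give bitwise-identical images, counts, selections and
reports; all RNG is `numpy.random.default_rng` seeded per case/repeat/stage.
Tie-breaks are fixed everywhere (row-major tiles, stable sorts). CSV output
uses 12 significant digits, which round-trips the feature table losslessly
for analysis purposes.

## Known limitations

* Grade separation in the default profiles is strong; accuracy on the
  synthetic cohort sits near the ceiling and is not a clinical estimate.
* The watershed undercounts in heavily clustered grade IV tiles (merged
  nuclei); the count remains monotone in grade, which is what grading uses.
* GLCM features are computed on whole ROI tiles, not per nucleus; at the
  default scale this blends nuclear and background texture.
* The explainer assumes locally smooth class probabilities; for piecewise
  models the reports track the local piece only.
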