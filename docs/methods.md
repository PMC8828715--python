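# Methods

This note records the models, conventions and numerical choices behind
`radiofuse`, and what the synthetic validation does and does not show.

## Coordinate and intensity conventions

Volumes are 3D arrays with per-axis spacing in mm; voxel `(i, j, k)` sits
at `(i·sx, j·sy, k·sz)` (0-based, voxel-centre convention). The axial
view fixes the third axis, sagittal the first, coronal the second.
Source intensities are assumed CT-like in [0, 4096]; out-of-range values
are clipped with a warning before the linear map to [0, 255]. Normalised
view values stay continuous (no uint8 cast) so the nearest-neighbour
resize is the only quantisation applied.

## 2.5D representation

Each view is the single slice through the voxel nearest the ROI's
physical centroid (no slab averaging — the simplest reading of a
centroid-centred multiplanar representation; if the centroid slice misses
a concave ROI the view falls back to the ROI's in-plane projection). The
slice is cropped to the in-plane ROI bounding box (margin 0 by default),
resampled to isotropic pixels at the finer of the two in-plane spacings
(aspect ratio is only meaningful in physical units), zero-padded to
square with the content centred, and resized to 224×224 by
nearest-neighbour index mapping. Degenerate one-pixel planes are padded,
not rejected.

## Handcrafted catalogue (431 features)

19 first-order + 17 shape + 27 GLCM + 8 wavelet bands × (19 + 27) = 431.
The inventory is engineered to that stated dimensionality from the four
classical families; it is not item-by-item identical to any other
radiomics package and makes no bit-compatibility claim.

* **First-order (19)**: mean, median, min, max, range, variance, sd,
  median absolute deviation about the median, skewness, kurtosis, energy,
  RMS, fixed-bin entropy (32 equal-width bins over the ROI's own range,
  base 2), uniformity, 10th/90th percentiles, IQR, robust mean absolute
  deviation (mean |x − mean| within the p10–p90 slab), coefficient of
  variation (0 when the mean is 0). A constant ROI has entropy 0,
  uniformity 1, skewness/kurtosis 0 by convention.
* **Shape (17)**: voxel-count volume; exposed-face surface area (sum of
  foreground faces adjacent to background, exact for unions of voxels);
  surface-to-volume ratio; sphericity, two compactness variants and
  spherical disproportion computed from a marching-cubes mesh area
  (padded mask, level 0.5, spacing-aware); maximum 3D diameter (largest
  pairwise distance between surface-voxel centres); three PCA axis
  lengths (4√λ of the foreground coordinate covariance), elongation and
  flatness (√(λ2/λ1), √(λ3/λ1), defined as 1 for a single voxel);
  bounding-box extents and extent (volume / bbox volume). Two surface
  notions coexist deliberately: the exposed-face area is the exact
  voxel-union surface (a single voxel reports 6 mm²), while the mesh area
  tracks the true surface of smooth shapes, so sphericity of a digitised
  ball is near 1 instead of the ≈0.67 a staircase surface would give.
* **GLCM (27)**: ROI intensities quantised to 32 equal-width bins over
  the ROI range; co-occurrence counts accumulated over the 13 unique
  3D direction offsets at distance 1 and over both pair orders, then
  normalised once (a pair-count-weighted average over directions).
  Statistics: autocorrelation, cluster prominence/shade/tendency,
  contrast, correlation (1 for a degenerate matrix), difference
  average/entropy/variance, dissimilarity and homogeneity (the historical
  aliases of difference average and inverse difference, kept as separate
  catalogue entries as radiomics catalogues conventionally do), ID, IDM,
  IDMN, IDN, IMC1/IMC2, inverse variance, joint average/energy/entropy/
  variance, maximum probability, maximal correlation coefficient (√ of
  the second eigenvalue of the Markov kernel; 1 when fewer than two
  levels), sum average/entropy/variance. All logs base 2; degenerate
  cases are given finite conventional values so every feature is always
  finite.
* **Wavelet (368)**: single-level stationary (undecimated) 3D transform
  with Coiflet-1; axes are edge-padded to even length and cropped back,
  so all 8 bands (LLL…HHH) stay aligned with the original mask and the
  first-order + GLCM statistics are taken over exactly the ROI voxels.
  Volumes shorter than the filter length (6) on any axis are rejected.

## Deep blocks

The contract is a `ViewExtractor`: a named deterministic map from a
224×224 view to `width` numbers (default 2048, hence 6144 per block over
the three views, concatenated axial → sagittal → coronal). The built-in
extractor average-pools the view 8×, extracts all 5×5 patches, applies a
kernel bank (six fixed oriented edge/blob kernels plus seeded
unit-norm random projections, each with a seeded bias), rectifies and
global-average-pools. It is linear in intensity wherever the rectifier is
inactive, separates phantoms that differ in texture amplitude (so the
supervised selection has usable deep-block signal), and two different
seeds give distinct blocks, which is how the TL and FT roles are realised
in synthetic runs. A pretrained CNN can be plugged in behind the same
contract; network training, fine-tuning and augmentation are out of
scope.

## Selection chain

* **MAD filter**: per-feature median absolute deviation about the median
  across patients; features strictly below the `drop_quantile` (default
  0.25) of the MAD distribution are removed, and zero-MAD features are
  always removed. The quartile default mirrors the quartile-style gene
  filters; MAD is the dispersion criterion because it is robust to
  outlying patients, and the threshold is configurable.
* **mRMR (MID)**: features discretised to 3 states at mean ± sd; greedy
  forward selection maximising MI(feature; histology) − mean MI(feature;
  selected), ties broken by original column order. MI in nats from the
  joint contingency table, fully vectorised across candidates. Default
  k = 100.
* **LASSO**: features standardised; L1-penalised multinomial logistic
  model (saga) along a 100-value λ path log-spaced over 4 decades from
  1.1× the analytic all-zero bound (the safety factor keeps the top of
  the path strictly inside the zero region, where the solver would
  otherwise leave borderline coefficients). λ\* minimises the mean
  held-out multinomial deviance over stratified CV folds (10 by default;
  reduced with a warning when the smallest class is smaller). The
  signature is the set of features with any class coefficient above
  1e-8 at λ\*; an empty set is a valid outcome, reported as an empty
  signature rather than an error. Multinomial (not one-vs-rest) was
  chosen for the three histology classes; CV folds are seeded, so the
  whole chain is deterministic given the seed.

## Clinical association

k-means runs on z-scored signature columns (population sd; constant
columns are zeroed with a warning) to avoid scale dominance, k = 3,
best of 10 seeded restarts by within-cluster sum of squares, ≤1000
iterations. The χ² test is plain Pearson (no continuity correction) on
the clusters × observed-stages table with empty stage categories dropped
before computing df = (r − 1)(c − 1).

## Gene filtering

Probes mapping to zero or multiple distinct symbols are dropped; repeated
probes per gene are averaged. The three filters run sequentially —
variance, mean absolute expression (interpreted as the cross-patient mean
of the log-scale values), 16-bin histogram entropy over each gene's own
range (entropy 0 for a zero-range gene) — each dropping genes strictly
below the q-quantile (default 0.25) recomputed on the current survivors.
A consequence worth stating: with recomputed quantiles each stage removes
a fixed ~q fraction of its current survivors regardless of how correlated
the filter statistics are, so ~0.75³ of the genes survive by
construction; correlation between the statistics affects *which* genes
survive, not how many.

## RR calling and comparison

Spearman ρ is Pearson correlation on average ranks (ties handled); p uses
the t approximation with n − 2 df, which Monte-Carlo shows to have a
mildly liberal far tail at small n (≈0.0011–0.0012 realised rate at
α = 0.001, n = 40) — within the calibration band the suite asserts.
Zero-variance features or genes are skipped with a warning. The RR
threshold is raw p < 0.001 (matching the protocol the pipeline
implements); an optional Benjamini–Hochberg mode exists but is off by
default. RR strength comparisons are one-sided Welch t-tests on |ρ|,
stratified by correlation direction; a stratum empty in either table is
reported untestable rather than an error.

## Pre-ranked enrichment

Ranking metric is signed ρ, descending, ties broken lexicographically by
symbol. The ES is the classic weighted running sum (weight p = 1; p = 0
reduces to the unweighted KS statistic, which is what the brute-force
oracle in the tests checks). The null is random same-size gene subsets of
the ranked universe (phenotype permutation is impossible in a pre-ranked
setting); NES divides ES by the mean |null ES| of the same sign and the
permutation p-value is add-one smoothed, hence super-uniform under the
null by construction. Gene sets are filtered to an effective size
(|set ∩ universe|) within [15, 500]. Per signature, each feature's
ranking is restricted to its genes with RR p < 0.001; when fewer than 15
such genes exist the full ranking is used and flagged. A GO term "has an
RR with the signature" when its permutation p < 0.05 for at least one
feature, and the reported per-term value is the extreme-|NES| across
features with its contributing feature — the cross-feature combination
rule is this package's choice, as is the <15-gene fallback.

## Synthetic cohort generator

What it emulates: ellipsoidal tumours (strict voxel-centre inclusion, so
a 1 mm semi-axis ellipsoid at unit spacing is exactly one voxel) with a
seeded sum of four low-frequency sinusoids (wavelengths 8–20 mm) as
intra-tumour texture and Gaussian background noise, clipped to [0, 4096];
histology labels from texture-amplitude tertiles (so texture-sensitive
features carry the class signal the supervised stages condition on);
T stage from tumour-volume quartiles (so geometry features associate with
stage); expression on a log-microarray-like scale (means U(4, 12), sds
U(0.5, 2)).

Planted links couple a gene to the *realised* values of a named
handcrafted feature: the gene is a mixture of the feature's Gaussian rank
scores and independent rank noise, with the mixing weight chosen by grid
search so the sample Spearman correlation matches the target strength
(at |strength| = 1 the construction degenerates to an exact monotone copy
and the realised correlation is exactly ±1). Linked genes are then
monotonically remapped to a filter-safe marginal — uniform shape
(maximal histogram entropy), mean U(8, 12), sd U(1.2, 2) — which leaves
every rank statistic untouched while guaranteeing that planted genes
survive the quartile filters; this is the operational meaning of
"constructed non-degenerate". Non-link genes are generated independently
of all images. Tumour semi-axes default to 6–14 mm and are capped at half
the grid extent minus 1.5 mm so phantoms always fit.

Default pipeline conditions: 40 patients on a 44³ mm grid, 200 genes,
4 planted links at strength 0.6, 10 gene sets. Gene sets are drawn over
the pre-filter gene pool, so their default sizes (40–60) are chosen such
that the post-filter effective sizes stay above the 15-gene enrichment
floor; planted enriched sets (≥80% of members from planted genes) are
only constructed when the planted pool supports the smallest allowed set
size, otherwise the collection is all decoys.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: CT physics and lung anatomy (no realistic
point-spread, beam hardening, organ context), inter-reader segmentation
variability, batch effects and platform differences in expression,
correlated co-expression modules beyond the planted links, and any
biological meaning of the gene sets. Synthetic recovery rates are upper
bounds on what identical settings would achieve on real cohorts.

## Problem sizes and determinism

The validation suite runs everything at desk scale by design: phantoms of
26³–44³ voxels, cohorts of 10–80 patients, 40–300 genes, deep widths of
16–2048, 100–1000 permutations. The planted-recovery conditions (80
patients, strength 0.6, p < 0.001) follow the study conditions stated for
the method; the calibration checks aggregate over a few seeded cohorts
because the 431 handcrafted features are mutually correlated within one
cohort and only the seed-averaged false-positive rate is expected to
converge to α. Every stochastic component draws from
`numpy.random.default_rng` seeded either directly or via a stable
(global seed, stage name) hash, so cohorts, folds, k-means restarts and
permutation nulls are bit-reproducible; identical configuration implies a
byte-identical run report.

## Known limitations

* The handcrafted inventory matches the four stated families and the 431
  count, not any specific external package's item-by-item list; GLRLM/
  GLSZM families and multi-level wavelets are not implemented.
* The deep stand-in is a fixed filter bank: it preserves the pipeline's
  contracts and provides usable signal, but makes no claim of CNN-level
  representation quality.
* Spearman p-values use the t approximation; at very small n and extreme
  α it is mildly liberal (quantified above). Exact permutation p-values
  are not implemented.
* With three histology classes and small cohorts, the LASSO stage can
  legitimately return empty signatures for weak blocks; downstream stages
  report "not generated" for those rather than failing.
* The χ²-based stage association needs expected counts that are not too
  small; very small cohorts can produce sparse contingency tables where
  the asymptotic p-value is rough.
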