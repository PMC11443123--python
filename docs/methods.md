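# Methods notes

This note records the scientific and numerical choices behind the package —
what the model assumes, what the defaults mean, what the synthetic data does
and does not emulate, and where the design was genuinely open.

## Pipeline overview

A collection of statistical brain maps is reduced to a maps × parcels matrix
(mean statistic per parcel), embedded with UMAP into a low-dimensional
morphospace, and analysed through the lens of embedded distance: maps that
sit close together have similar anatomy, and each map can be *predicted*
from its distances to the rest. All downstream statistics (laterality, the
predictability brain map, null comparisons, decoding) operate on parcel
vectors or embedded coordinates, never on voxels, which keeps every stage
cheap and format-agnostic.

## Thresholding and parcellation

Meta-analytic z maps are cleaned with a one-sided cut at z = 3.4 (upper-tail
normal probability ≈ 3.37 × 10⁻⁴); values at or above the cut survive
unchanged, everything else becomes 0. The cut is idempotent and leaves the
grid untouched. Parcel reduction takes the arithmetic mean over **all**
voxels of a parcel, zeros included: this keeps the reduction linear in the
input volume, so thresholding and averaging interact predictably. A
nonzero-voxel mean is exposed (`mode="nonzero_mean"`) for workflows that
follow the other convention; the two differ exactly by the factor
(parcel size / suprathreshold count). Maps and atlases must share a grid to
1e-4 mm; resampling is always explicit (trilinear for statistic volumes,
nearest-neighbour for labels) because silent interpolation of label volumes
is a classic source of corrupted parcels.

## Embedding

UMAP with n_neighbors = 15, min_dist = 0.1, Euclidean metric, and 3 output
dimensions by default; no feature scaling is applied before embedding (a
standardization switch exists but is off). The embedding seed defaults to a
documented constant (0) and the fit is deterministic given (matrix, config,
seed); coordinates from different UMAP versions or seeds are **not**
comparable across machines, only the distance structure is. Persistence
avoids pickles: a model bundle stores the training matrix, config and
coordinates, and loading refits UMAP from those inputs and verifies the
recovered coordinates against the stored ones (1e-5). Out-of-sample maps are
placed with UMAP's transform, which never mutates the fitted space (asserted
by checksum).

Dimensionality selection mirrors how one would justify the 3D choice: for
each candidate dimensionality the full leave-one-out loop is run, per-map
mean absolute errors are compared pairwise with the two-sided Wilcoxon
signed-rank test (exact null for n ≤ 25 without zero differences, normal
approximation with continuity correction otherwise; Shapiro–Wilk normality
of the differences is reported, not enforced), and statistically
indistinguishable candidates are tie-broken by the higher mean
predictability index.

## Prediction and the predictability index

For target *t*, each parcel's reference values are regressed on
[1, −d] where d is the embedded Euclidean distance from each reference to
the target; the negation makes similarity load positively. The predicted
map is the *t statistic* of the distance regressor converted to z
(probit ∘ Student-t CDF, computed through the survival function on the
positive side for tail precision) and thresholded like the measured maps.
Numerical conventions: parcels constant across references get t = 0;
zero-residual fits are capped at the t value whose z image is 8.2 (where
the normal tail underflows double precision); z values are clamped to
|z| ≤ 8.2. A zero-variance distance vector (all references equidistant) is
an error, not a silent NaN.

The index is Pearson (leave-one-out) or Spearman (projected new maps, whose
scale is unknown) over all parcels. By default both sides are thresholded
before correlating, mirroring the cleaning of the measured maps; an
unthresholded variant correlates raw z predictions with raw measured values
and is the right choice when the measured values are not calibrated z
fields — the synthetic recovery analyses use it for exactly that reason
(under label permutation, thresholded predictions are all-zero and the
correlation would be undefined rather than ≈ 0).

An inverse-squared-distance interpolation backend is available as an
alternative predictor. It is deliberately **not** the default: it predicts
any target well — including permuted ones — because its prediction collapses
toward the corpus-mean map, so it carries no null behaviour. The t-map
regression self-normalizes (slope against background), which is what makes
the permutation control meaningful.

## Group statistics

Laterality is a paired two-sided t-test of per-map (mean left, mean right)
hemisphere means, df = n_maps − 1; midline parcels are excluded from the
pairing only. Exactly balanced hemispheres are reported as t = 0, p = 1
rather than 0/0. The predictability brain map regresses each parcel's
activation across maps on the per-map index and keeps the slope t
(df = n_maps − 2); no multiple-comparison correction is applied — the map is
descriptive. Gradient correlations are plain Spearman with average ranks;
spatially-informed inference (spin tests) is out of scope.

## Spatial nulls

Surrogates follow the variogram-matching recipe: permute the parcel values,
smooth the permutation with a Gaussian kernel of the inter-parcel distance
(candidate widths on a log-spaced grid spanning the observed distances),
rank-rescale to the empirical value multiset, and keep the width whose
semivariogram is closest (least squares over defined lag bins) to the
empirical one. Because rescaling is the last step, every surrogate carries
*exactly* the empirical values — the multiset invariant is structural, not
statistical. Distances default to Euclidean between parcel centroids; a
surface-geodesic matrix can be supplied instead where meshes are available.
The ensemble is collapsed to one representative null map either by
rank-rescaled per-parcel mean (default) or by regressing the empirical map
on the ensemble's top right-singular vectors (a reduced-rank form of
"predict the map from its surrogates"); with 1000 surrogates and only a few
hundred parcels a full regression on all surrogates is underdetermined,
which is why the reduced-rank variant exists.

## Topic model

tf-idf (raw counts × ln(N/df)) is applied to the term-document table first;
co-occurrence is the weighted table times its transpose, normalized to unit
mass for the PMI probabilities. PMI uses the natural log; pairs that never
co-occur are set to 0 before the log, and negative PMI is clipped at 0.
Ward clustering runs on the PPMI rows (squared-Euclidean merge objective);
cluster labels are renumbered by first appearance so identical inputs give
identical outputs. 12/25/55 are conventional broad/medium/fine resolutions,
not privileged values.

## Decoder

Frame series carry their GLM residual df as metadata; t frames are converted
voxelwise to z with the same t→z machinery, thresholded, and parcellated.
Frames with no suprathreshold voxel are flagged undecodable and receive a
sentinel term rather than an error. Nearest-term search is an exact scan in
embedding coordinates (506-map vocabularies do not need approximate search);
ties break by map order. Stimulus attribution shifts each timestamp by a
scalar hemodynamic delay and additionally credits an event for up to 5 s
after its offset (the lingering BOLD response); frames matching no window
are REST. The attribution is a partition: every frame gets exactly one
label.

## Synthetic data

The branch generator emulates the star-/neuron-shaped layout that map
collections exhibit after embedding: B rays leave a common hub, maps sit at
evenly spaced radii along the rays, and each map's parcel loading is a
Gaussian bump around its latent position over a cloud of parcel anchors
(centred, plane-projected, rescaled parcel centroids). Defaults — 3 planar
branches × 20 maps, 120 parcels, separation 10, kernel width 0.6 × separation,
anchor cloud at 0.3 × separation RMS radius, hub gap 0.35, peak amplitude 8,
no noise, seed 0 — were chosen once so that the collection is smooth,
branch-separable and z-like in scale.

Two geometric facts shaped those defaults and are worth knowing when
extending the generator. First, the distance-regression predictor is only
faithful when branches are mutually opposed (equal angles in a shared
plane): with orthogonal rays, distance from a target carries little
information about activation on other branches and the t-map tracks
proximity-trend shape rather than activation level. The `directions="axes"`
variant exists precisely to build intrinsically 3D stars for dimensionality
experiments. Second, maps too close to the hub are intrinsically ambiguous
between branches — hence the hub gap.

What the generator does **not** emulate: voxel-level noise structure,
haemodynamics, inter-subject variability, or the heavy-tailed sparse
profiles of real meta-analytic maps. Passing recovery tests therefore shows
the pipeline's statistical machinery is correct and self-consistent, not
that real map collections are as predictable as the synthetic ones.

The autocorrelated-field generator draws from a Gaussian process with
exponential covariance exp(−d/ℓ) over parcel centroids (Cholesky with
escalating jitter up to 1e-6 before failing). The corpus generator plants
contiguous term blocks and samples documents within one block; with zero
cross-block probability the co-occurrence matrix is exactly block-diagonal,
giving a sharp ground truth for clustering.

## Problem sizes and fixed seeds

Desk-scale analyses run at 60 maps × 120 parcels (recovery, decoding), 40
parcels (surrogates), 30 terms × 200 documents (topics); these sizes make
the full pipeline — including repeated embeddings — run in minutes on one
CPU while leaving every statistical property measurable. The default
synthetic collection and the default embedding seed are fixed, documented
constants defining the reference study conditions; stochastic repetitions
around them (permutation draws, surrogate fields, corpus draws) are seeded
per run.

## Known limitations

- UMAP transform of a *small batch* of duplicate queries can land a
  duplicate nearer to a neighbouring training point than to its original;
  transforming the full training matrix reproduces every map's position
  faithfully. Decoding accuracy statements are therefore batch-level.
- Embedded coordinates (and hence indices, mildly) depend on the UMAP seed;
  only distance-structure properties are stable across seeds.
- The surrogate kernel family is fixed to Gaussian-in-distance; matching
  very long-range or anisotropic autocorrelation may need a user-supplied
  geodesic distance matrix.
- Voxel-level regression is supported only through the parcel interface
  (paint parcel vectors back with `unparcellate`); true voxelwise designs
  with permutation inference are out of scope.
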