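# Methods

## Network model

A subject's anatomical network is a weighted undirected graph on R atlas
regions. Probabilistic tractography seeds `S` streamlines per voxel
(default S = 5000), so region `v` with `n(v)` voxels emits `S·n(v)`
streamlines; the directed edge strength `e(v,u) = m(v,u)/(S·n(v))` is the
fraction reaching region `u`. Because seed placement is randomized the two
directed estimates differ, and the undirected strength is their mean,
`E(v,u) = (e(v,u)+e(u,v))/2`, which lies in [0, 1]. Entries strictly below
τ = 0.01 are zeroed to suppress false-positive connections; entries equal
to τ survive (the threshold reads as a floor). Thresholding is applied
after symmetrization, i.e. on the adjacency matrix where the threshold is
defined. Zeroed entries are kept as zero-valued features rather than
dropped, so the feature space has fixed size R(R−1)/2 and feature indices
are comparable across subjects and folds — a prerequisite for intersecting
per-fold selections into consensus features.

The shipped parcellation is the 116-region AAL atlas with a lobe label per
region (frontal, limbic, parietal, temporal, occipital, subcortical,
cerebellum, vermis). The temporal set used by the mask-out analysis is
Heschl's gyrus, the superior/middle/inferior temporal gyri and both
temporal poles, bilaterally (12 regions, 1314 features). Mesial structures
(hippocampus, parahippocampal gyrus, amygdala, fusiform) are labeled
limbic and therefore not masked by default; because the convention is
carried entirely by the region table, a stricter mask including them is a
one-file change.

## Classification pipeline

All three stages are fitted on the training subjects of each
cross-validation fold only; the held-out subject never influences
selection, embedding or the classifier.

**Feature selection.** Pooled-variance two-sample t-test per feature,
two-sided, keep p < α. Defaults: α = 0.05 (the conventional level; the
method itself does not prescribe one), Student's pooled variance (a Welch
option exists). Features with zero variance in both groups and equal means
get t = 0, p = 1; zero variance with unequal means is maximally
significant. If nothing passes α, the `fallback_k` = 10 smallest-p
features are used (with a warning) so cross-validation never aborts — this
matters mainly inside permutation runs, where the null rarely clears α on
small problems.

**Locally linear embedding.** Standard three-step construction: k nearest
neighbors by Euclidean distance; barycentric reconstruction weights per
point (sum-to-one least squares, local Gram matrix regularized by
`reg_eps·trace(G)·I`, reg_eps = 1e-3, which is required whenever k exceeds
the local dimension); embedding from the d eigenvectors of
`M = (I−W)ᵀ(I−W)` with the smallest non-trivial eigenvalues. The constant
eigenvector (eigenvalue ≈ 0, forced by the sum-to-one constraint) is
discarded, and the embedding is normalized to the covariance constraint
`(1/N)YᵀY = I`, i.e. zero-mean unit-variance components. The
normalization choice is load-bearing: with unit-norm eigenvector columns
the coordinates scale as 1/√N, the RBF kernel with γ = 1/d is nearly
constant, and the SVM degenerates to the majority class. kNN search is a
brute-force exact scan — training sets here are tens of points, where a
scan beats tree indices.

Held-out subjects are embedded by the reconstruction-weight (Saul–Roweis)
out-of-sample extension: barycentric weights of the new point against its
k nearest training points, applied to those points' embeddings. A query
that coincides with a training point returns that point's embedding
exactly (the zero-error sum-to-one solution). Retraining the embedding
with the test point included would be the transductive alternative; the
out-of-sample extension is used because it keeps the fold's fit strictly
independent of the test subject.

Defaults: k = 12 neighbors and d = min(20, N_train − 2) dimensions when
not set explicitly; d is clamped to min(N_train − 1, #selected features).
On small training folds the automatic rule shrinks k to N_train − 2.

**Classifier.** Gaussian-RBF SVM with the solver family's defaults, C = 1
and γ = 1/d. Multi-class problems use one-against-one voting: each of the
three pairwise classifiers runs its own nested selection and embedding on
the training subjects of its class pair; a held-out subject receives the
majority-vote label, with 1-1-1 ties broken by the largest summed absolute
decision score and then the lowest class index.

## Evaluation and significance

GR is the overall fraction of correct held-out predictions; SS the
fraction of the positive (patient) class correct; SC the fraction of the
other class. These satisfy `GR·N = SS·N_pos + SC·N_neg` exactly. LOOCV is
the default scheme (N folds); k-fold (default stratified, k = 10) is
provided as the faster, higher-bias alternative. ROC curves pool the
signed SVM decision values of held-out subjects across folds.

The permutation test reruns the *entire* nested cross-validation under
uniformly permuted labels (class counts preserved) n_perm times (default
10,000) and reports p = (#null GR strictly greater than observed)/n_perm;
ties count as not-higher. The (count+1)/(n_perm+1) estimator is available
behind a flag, default off. Per-permutation RNG streams are derived from
(seed, permutation index), so serial and parallel runs agree bit for bit.

A caveat established with the synthetic null (see below): under LOOCV the
held-out subject's class is always the training minority (19 vs 20 in a
20+20 study), and the neighborhood-based out-of-sample step inherits a
slight tilt toward the fold-majority class, giving null accuracies a small
pessimistic bias (a few points below 50%) with substantial
dataset-to-dataset variance. This biases the observed GR and its
permutation null in the same direction, so the permutation p remains
calibrated; but raw null GR should not be expected to sit exactly at
chance.

## Synthetic data generator

The generator emulates the statistical structure the inference assumes,
not brain anatomy (no small-worldness, no hemispheric symmetry). A sparse
symmetric baseline adjacency is shared by all groups: each edge is present
with probability `density` = 0.15 (≈1000 of 6670 possible edges at
R = 116, a realistic post-threshold sparsity), with strengths uniform on
[0.02, 0.5]. `n_planted` = 10 connections are shifted between groups by
`delta` (default 2.0) in units of the subject noise SD
`sigma_subj` = 0.05. With three groups (default sizes 22/21/39), both
patient groups are diminished on every planted connection relative to
controls, and alternate planted connections are extra-diminished on the
left or the right, so all three pairwise contrasts are separable —
mirroring a disease that weakens connectivity with a lateralized
component. Planted edges are drawn only from baseline edges with enough
headroom that no group mean is clipped below τ.

Subjects are the group mean plus symmetric Gaussian noise on nonzero
edges, clipped to [0, 1]; structural zeros stay zero. The adjacency is
then inverted through the edge formula into directed counts
`m(v,u) = round(e·S·n(v))` with voxel counts uniform on {200..2000}, so
directed asymmetry arises only from the differing denominators — as it
does in real seed-count data — and network construction recovers the
adjacency to within 1/(S·min n) per entry. A count-level binomial mode
(`m ~ Binomial(S·n, e)`) exists for stress testing. Everything derives
from one master seed.

What passing tests on this generator do *not* show: robustness to
registration error, region-size confounds, distance-dependent tractography
bias, or correlated noise across edges — none of which the generator
models.

## Numerical and design choices

- Feature order is row-major over the upper triangle; region ids are
  0-based in memory, 1-based in files (AAL convention).
- Validation is strict: NaN anywhere in counts is a hard error, counts
  must satisfy `m(v,u) ≤ S·n(v)`, voxel counts must be ≥ 1.
- Eigenvector signs are fixed (largest-magnitude coordinate positive) so
  reruns are byte-identical.
- t-test selection uses `scipy.stats.ttest_ind`; degenerate (0/0) cases
  are post-processed as described above.
- Direction of a consensus feature's group difference is computed from
  full-dataset group means — it is reporting, not part of the nested
  classifier.
- Result JSONs are written with sorted keys and no timestamps; a rerun
  with the same seed is byte-identical, serial or parallel.

## Problem sizes used in the test suite

The suite exercises the full pipeline at reduced scale: unit fixtures use
R = 12–20 with 16–32 subjects; the null-calibration check runs 50
pure-noise replicates of a 20+20 study at full R = 116; planted-effect
recovery runs 20 replicates at delta = 2; the permutation-vs-enumeration
check uses a 6-subject toy where all 20 label assignments can be
enumerated exactly, against 10,000 Monte-Carlo permutations. The
acceptance script runs the full default study (82 subjects, 6670 features)
with a 200-replicate permutation test.

## Known limitations

- The t-test filter ignores feature correlations; strongly correlated
  connection pairs can crowd the selected set.
- LLE assumes locally linear structure and enough neighbors per class;
  with very small folds the automatic k/d shrinkage keeps it defined but
  the embedding is crude.
- LOOCV estimates have high variance, and the null-bias caveat above
  applies to any neighborhood-based out-of-sample mapping under LOOCV.
- No probability calibration, no class weighting, no hyperparameter
  search: the pipeline deliberately runs at the solver defaults.
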