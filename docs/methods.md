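# Methods

This note documents the models, conventions, and numerical choices behind
`wingmorph`, and what the synthetic data generator does and does not emulate.

## Superimposition

Ordinary Procrustes fits center both configurations, scale them to unit
centroid size, and rotate the moving one by the orthogonal matrix minimizing
the summed squared landmark distance (SVD of the cross-covariance; inside
the GPA loop the equivalent planar closed form θ = atan2(Σ cross, Σ dot) is
used for speed — the two agree to machine precision and the tests check it).
Reflections are never introduced (all fitted rotations have determinant +1):
all wings in the motivating design are same-side wings, so chirality is
constant.  A `allow_reflection` flag on the pairwise fit exists for
mixed-side data.

GPA uses full-Procrustes scaling: every specimen is fixed at unit centroid
size, so size lives entirely in CS and shape entirely in the residuals.
The consensus is initialized from the first (centered, scaled) configuration
and iterated until its root-summed-squared change falls below 1e-10
(maximum 100 iterations; non-convergence is an error).  Both thresholds are
far below any plausible digitization noise.  The final consensus is rotated
so its major principal axis lies along x, with the sign fixed by the largest
|x| landmark; this makes output orientation — and therefore every written
table — reproducible regardless of input orientation, which the similarity-
invariance tests rely on.

Shape variables are orthogonal tangent-plane projections at the consensus:
t = (I − cc′)x for the flattened aligned configuration x and unit consensus
vector c.  They have rank ≤ 2k − 4 (translations, rotation, and scale
removed); for the k = 10 wing scheme that is 16 dimensions.

## Size inference

Centroid-size summaries use the unbiased (n − 1) variance; a single-specimen
group reports its variance as missing, never zero.  The omnibus one-way
ANOVA F and all pairwise |mean differences| are referred to permutation
nulls (group labels shuffled without replacement, default B = 1000).
p-values use the add-one convention (b + 1)/(B + 1), so the smallest
attainable p is 1/(B + 1) and p can never be zero.  Pairwise p-values are
Bonferroni-multiplied by the number of pairs (6 for four groups), capped at
1.  The pairwise statistic is the absolute mean difference — scale-free and
standard for CS.  Significance letters come from the insert-and-absorb
compact-letter-display algorithm; groups sharing no letter differ at alpha.

## Shape inference

PCA of the shape variables is computed by SVD of the centered data matrix;
axes are ordered by decreasing eigenvalue and signed so each axis's
largest-magnitude loading is positive (reproducible factor maps).  For
discriminant and Mahalanobis work, components with eigenvalue
> 1e-12 × the largest are retained, capped at n − g − 1 so the pooled
within-group covariance S stays invertible; with n = 140 and g = 4 this
keeps the full 16-dimensional shape space.  If S is still singular it is
ridge-regularized (λ = 1e-8 · tr(S)/dim) with a logged warning; the
retention cap is the preferred path.

Canonical variate axes are eigenvectors of W⁻¹B (generalized symmetric
eigenproblem), normalized so within-group covariance is the identity in
discriminant space; for two groups the squared separation of group means
along DF1 then equals the Mahalanobis D², a relation the tests assert.

Pairwise Mahalanobis permutation tests shuffle specimens between the two
groups of each pair and recompute group means and the pooled S per shuffle;
the PC basis is *not* recomputed, because it is group-blind.  Adjustment is
Bonferroni over pairs, as for size.

Allometry is the OLS regression of the PC1 score on CS, fit per species
with sexes pooled (one r², in percent, per species); p is the slope t-test.

## Classification and identification

Both leave-one-out classifiers refit group statistics without the held-out
specimen but keep the GPA consensus and PC basis fixed: neither uses group
labels, and a full refit would change the consensus negligibly at n = 140
while making the held-out path inconsistent with the test-specimen path.
Size classification is per-group univariate normal maximum likelihood with
equal priors despite the unbalanced 50/50/20/20 design — per-group accuracy
should reflect the size distributions, not the sampling ratios.  Exact ties
in distance or likelihood are resolved toward the group earliest in
(species, sex) sort order.

Test specimens are identified in a *frozen* reference space: centered,
unit-scaled, rotated onto the reference consensus, tangent-projected there,
expressed in the reference PC basis, and assigned to the closest reference
group under the reference pooled covariance.  Identification never alters
the reference (no pooled re-GPA), so a reference specimen replayed as a test
reproduces its in-sample distances.

## Clustering

UPGMA is implemented directly (O(n³), size-weighted linkage update, merge
height = distance/2) rather than delegated to a library routine so that
ties among equally close pairs can be broken lexicographically by smallest
member label, making trees byte-reproducible.  Tests verify it against both
a from-scratch brute-force agglomerator and the average-linkage routine in
scipy.  Clustering operates on full tangent shape variables; Euclidean
distance is identical in any orthonormal basis, so PC truncation would
change nothing.

## Repeatability

The one-way random-effects (model II) ANOVA is applied to the jointly
superimposed replicate digitizations, with sums of squares pooled over all
2k Procrustes coordinates: MS_among (df n − 1) and MS_within (df n(m − 1)),
s²ₐ = (MS_a − MS_w)/m floored at zero with a warning, and
R = 100·s²ₐ/(s²ₐ + MS_w).  Pooling over coordinates yields one global index,
matching how wing-morphometry studies report a single repeatability
percentage.  The conventional 90 % re-digitization rule is exposed as a
pass/fail check (`ProcrustesAnovaResult.passes`), not an automated loop.

## Synthetic data

The generator emulates the reference study's design, not its pixels:

- **Design**: four (species, sex) groups, n = 50/50/20/20; group CS normal
  with means 3.94/3.93/2.99/3.07 mm and sds 0.28/0.33/0.12/0.20 mm
  (truncated at zero by redraw; at these parameters truncation is a > 9σ
  event).  The strong species size difference with within-species sex
  overlap reproduces the study's size structure.
- **Shape**: a fixed 10-landmark wing-like template (unit CS, centroid at
  origin); group mean-shape displacements act on the anterior (2–4) and
  posterior (8–10) margin landmarks, species vertically and sexes
  horizontally, each 3 landmark-noise sds per landmark by default.  With
  isotropic noise this puts between-group Mahalanobis distances near
  3·√6 ≈ 7.3 (adjacent) and ~10 (diagonal) — the scale the reference study
  reports — and makes shape classification nearly perfect while size
  classification stays mediocre, the study's central contrast.
- **Noise**: isotropic Gaussian landmark noise, default sd 0.01 in unit-CS
  shape units — the simplest model consistent with small elliptic scatter in
  factor maps.  Correlated landmark noise is deliberately out of scope; true
  per-landmark covariances are unknowable without the real coordinates.
- **Allometry**: displacement b·(CS − group mean) along a fixed unit tangent
  direction, orthogonalized against the similarity subspace (translations,
  rotation, scaling) so its magnitude survives re-centering/re-scaling and
  the variance-ratio oracle r² = b²·var(CS)/var(PC1) holds in closed form.
  An optional `major_axis_sd` adds size-independent variation along the same
  axis: real wing covariances are strongly anisotropic (the leading PC
  carries far more than an isotropic share), and without a dominant axis a
  small allometric signal cannot own PC1 at realistic n (the leading sample
  eigenvalue of isotropic noise in 16 dimensions at n = 100 is ~1.96× the
  per-dimension variance).  The default coefficient is zero, matching the
  negligible, non-significant allometry the study reports.
- **Nuisance transforms**: every generated configuration is scaled by its
  CS, randomly rotated, and translated, so superimposition is genuinely
  exercised end to end; replicate digitizations add iid coordinate error
  (default 0.004 mm ≈ 0.1× the shape scatter at CS ≈ 3.9 mm, which lands
  the repeatability index in the high 90s typical of careful digitizers)
  plus a fresh rotation/translation per replicate.

What passing tests show — and do not show: the pipeline's arithmetic,
invariances, calibration, and qualitative contrasts are verified on data
with known structure; the synthetic wings carry no real anatomical
covariance, digitizer bias, or image-scale error, so numerical agreement
with any particular field dataset is not implied.

## Problem sizes and determinism

Validation experiments are sized to run on one CPU in a few minutes: the
permutation-calibration study uses 200 null datasets of 20 + 20 specimens
with B = 200 permutations (B = 1000 remains the analysis default); oracle
comparisons use 50 random 6-taxon matrices and 5 random landmark pairs;
recovery studies use 50 seeds at n = 100.  Every random draw in the library
flows through a single integer seed per entry point, and rerunning any
pipeline stage with the same configuration reproduces its outputs byte for
byte.

## Known limitations

- 2-D landmarks only; no semilandmarks, outlines, or sliding.
- No thin-plate-spline deformation grids; mean-shape comparison is by
  overlay of aligned consensuses.
- No posterior membership probabilities — assignment is closest-group /
  maximum-likelihood, as in the workflow the package reproduces.
- UPGMA is the only linkage; the permutation machinery is the only
  multivariate test (no parametric MANOVA).
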