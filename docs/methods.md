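# Methods

This note documents the models, numerical choices and limitations of the
`subshape` pipeline in enough detail to reproduce or audit any stage.

## Surface model and operators

Structures are modelled as closed genus-0 triangle meshes in world
millimetres. Validation enforces: no degenerate faces, every directed
edge paired with its reverse (closed orientable 2-manifold), Euler
characteristic 2, and positive signed volume (outward orientation;
`oriented_copy` flips inward meshes).

The Laplace–Beltrami operator uses the standard cotangent stiffness
matrix S (off-diagonal −(cot α + cot β)/2 over the two angles opposite an
edge; zero row sums) with barycentric lumped mass m (one third of the
incident face area per vertex, summing to total surface area). Obtuse
triangles give negative edge weights and are kept as-is; a RuntimeWarning
fires when more than 1% of edge weights are negative, which flags a
poorly conditioned template rather than an error. The anisotropically
scaled default templates do trip this warning; the spectral tests confirm
the basis quality is unaffected at these aspect ratios.

Manifold harmonics are the K smallest eigenpairs of S φ = λ m φ
(`scipy.sparse.linalg.eigsh`, shift-invert at σ = −10⁻³, fixed start
vector for determinism; dense `eigh` fallback when K approaches the
vertex count). Eigenvectors are renormalized to mass-orthonormality
(ΦᵀMΦ = I within 10⁻⁸) and signs are fixed by making the
largest-magnitude entry positive (ties broken by lowest vertex index), so
features are reproducible across runs and platforms.

Vertex normals are angle-weighted averages of incident face normals —
robust to irregular valence and exact (within 2°) on sphere fixtures.

## Voxelization and overlap

A voxel is occupied iff its center lies inside the surface, decided by
parity of crossings of a +z ray per (x, y) grid column. Crossings are
gathered per triangle over the columns in its xy-bounding box using 2-D
barycentric tests; the ray grid is offset by a deterministic ~10⁻⁶·spacing
irrational shift so rays never hit vertices or edges exactly (odd
crossing counts would warn; the perturbation makes them unobserved in
practice). Accuracy: 0.5% volume error vs the analytic ellipsoid at
0.5 mm spacing. Overlap of two grids with identical geometry is reported
both as |test ∩ ref|/|ref| (the primary validation metric) and Dice.

Grid convention: 0-based indices, `origin` = world position of the center
of voxel (0,0,0), per-axis spacing. NIfTI I/O accepts axis-aligned
affines only; oblique volumes are rejected rather than resampled.

## Template-to-subject fitting

`laplacian_deform` deforms a rigidly pre-positioned template onto a
binary segmentation by iterating the least-squares problem

    min_v  ||L v − δ||² + w_t Σ_i ||v_i − b_i||²

with L the template's uniform graph Laplacian, δ = L v the differential
coordinates of the *current* iterate (so the surface may bend globally
while resisting local distortion), and b_i the nearest boundary point to
vertex i. Boundary points are the centers of voxel faces between occupied
and empty voxels — no marching cubes or surface extraction of the target
is needed — queried through a k-d tree. The data weight w_t doubles each
iteration from 0.5 (capped after 8 doublings), a ramp that lets the
surface approach the target before being pinned to it. Convergence is
declared when mean vertex motion drops below 10⁻³ of the voxel spacing;
non-convergence returns the best iterate with a warning. Connectivity is
shared with the template, never copied or modified.

On synthetic segmentations at 0.5 mm spacing this front end reaches
~99% overlap and recovers planted fields with vertex-wise correlation
≈ 0.98 (the acceptance suite asserts ≥ 0.90 and ≥ 0.8).

Size normalization is similarity Procrustes (closed-form Umeyama) of the
corresponded subject vertices onto the template, applied per structure
before projecting displacements onto the template's outward normals:
value_i = (subject_i − template_i) · n_i, positive outward. The order —
align first, then project — is fixed and tested. Subjects may also supply
pre-corresponded surfaces or raw fields directly, so the statistical
pipeline is usable without the geometric front end.

## Spectral features

The forward transform is the mass-weighted projection
β_k = Σ_i m_i φ_k(i) x_i (the adjoint with respect to the surface inner
product, making Parseval exact at full truncation); the inverse is
x̂ = Σ β_k φ_k. A plain Euclidean projection would differ only through
vertex-area inhomogeneity; the mass-weighted form is the standard choice
and is the one implemented. The cut-off N_c defaults to 70 coefficients
per structure; `choose_cutoff` provides the goodness-of-fit alternative
(smallest N_c whose reconstructions keep a target energy fraction,
default 0.9, averaged over training fields). Feature vectors concatenate
structures in the fixed order (hippocampus_L, hippocampus_R, amygdala_L,
amygdala_R); coefficients are deliberately not standardized before PCA,
and PCA is fit separately per feature set.

## Classifier

PCA is derived from the eigendecomposition of the total-scatter matrix;
the retained dimension is the smallest d whose cumulative explained
variance reaches the configured fraction (default 0.70), evaluated with a
10⁻⁹ tolerance so exact-boundary spectra (ten equal variances at 70% →
d = 7) resolve deterministically, and capped at the numerical rank. LDA
in the PCA space uses the pooled within-class scatter:
w ∝ S_w⁻¹(μ₊ − μ₋), unit norm, threshold at the midpoint of the projected
class means. The midpoint (prior-free) rule was chosen because the
published operating profile (high sensitivity, moderate specificity at
23/45 imbalance) is consistent with an unweighted threshold; a
priors-weighted variant is available via `priors_weighted=True`. Exact
ties in the decision score label the subject amyloid-positive — a
screening-oriented convention.

Incremental learning accumulates per-class counts, sums and second-moment
matrices and re-derives PCA+LDA after each batch. This is exact — a state
that absorbed any partition of the data is prediction-equivalent to batch
training on the union (scores agree to ~10⁻¹⁵ and labels exactly, which
the tests assert) — and costs O(p²) memory with p ≤ a few hundred. An
approximate eigenspace-merging scheme would update more cheaply but
break the equivalence contract; convergence behaviour rather than exact
equality in the original description suggests the approximate flavour,
and the exact variant is implemented here precisely because its
correctness is testable. Until both classes hold ≥ 2 subjects the state
only accumulates; the model is derived as soon as that minimum is met.

## Evaluation

Folds are stratified per class (sizes differ by ≤ 1 within each class),
preventing degenerate partitions at 23/45 imbalance; a partition whose
training side lacks a class is rejected. Metrics are computed on the
pooled out-of-fold predictions, which keeps confusion counts integral.
ROC pools decision scores over test folds; AUC is computed by rank
statistics (Mann–Whitney, ties ½) and equals brute-force pair counting.

The learning curve feeds batches of 10 subjects (500 random presentation
orders by default) through `partial_fit`, scoring the full test set after
every batch; because the update is exact, the final point coincides with
batch training for every order.

The permutation test permutes the labels used for *training* inside the
same k-fold procedure while scoring held-out subjects against their true
labels; the pooled CV accuracy is the statistic, and
p = (1 + #{null ≥ observed}) / (1 + n_perm) (the add-one estimator —
under which a reported p of 2·10⁻⁴ at 10,000 permutations corresponds to
exactly one null exceedance). Calibration is verified empirically: over
200 replicate null cohorts at 199 permutations each, the rejection rate
at α = 0.05 falls within [0.02, 0.08].

## Discriminative maps

The PCA-space axis w is lifted to feature space through the component
matrix, split into per-structure coefficient blocks, inverse-transformed
to vertex space and normalized to unit Euclidean norm per structure (four
maps for the combined feature set). Each map also carries its
pre-normalization energy share — the block's fraction of the squared
feature-space axis norm — which identifies the structures driving the
discrimination (shares sum to 1). Positive values mark vertices where
outward deformity votes amyloid-positive. No significance threshold is
attached: the map describes the classifier's sensitivity to each vertex,
not group-specific deformity. Export is ASCII PLY with a per-vertex
`quality` float (a hand-rolled writer/reader, because generic mesh
libraries do not round-trip arbitrary vertex scalars in ASCII PLY).

## Synthetic cohorts

`make_template` builds icosphere-based templates (10·4^s + 2 vertices)
anisotropically scaled to hippocampus-like (20×10×8 mm) and amygdala-like
(12×10×9 mm) proportions; the default subdivision level 3 gives 642
vertices per structure, so the combined feature vector is 4 × 70 = 280
coefficients. (This resolution is a deliberate desk-scale choice;
clinical meshes are typically an order of magnitude denser, which changes
compute cost but not the statistical structure of the features.)

A subject's field per structure is

    x = effect·1[positive] + Σ_k c_k φ_k + ε,

with c_k ~ N(0, v_k), v_k ∝ (k+1)^−1.5 (rank-based spectral decay; the
DC mode damped ×0.25 so pure size variation does not dominate), scaled so
the vertex RMS of the smooth component is `smooth_sd_mm`, and ε white
vertex noise. Defaults — 45 negatives / 23 positives, smooth SD 0.5 mm,
vertex noise 0.1 mm, effect amplitude 1.0 mm (2× the smooth SD) planted
on harmonics 1..12 with a bilaterally shared draw and net-inward
(atrophy) sign — are the study conditions the evaluation suites run
under. The decay exponent 1.5 concentrates subject variability in the
lowest harmonics, giving PCA spectra whose 70% dimension lands in the
teens at n = 68, a realistic regime for smooth anatomical variation. The
patch mode plants an inward geodesic-ball indicator (Euclidean-ball
approximation, valid on these convex templates), spectrally smoothed with
30 harmonics, and records the true vertex mask for region-recovery
scoring.

What the generator does *not* emulate: non-ellipsoidal anatomy and
subfield geometry, segmentation bias fields, registration error
correlated with shape, site/scanner effects, and covariate structure
(age, lesion load). Passing tests therefore demonstrate correctness of
the machinery and its statistical calibration, not clinical accuracy on
real data.

The PET table generator draws 28 VOI volumes and SUVRs rescaled so the
volume-weighted global ratio lands strictly on the intended side of the
1.5 threshold, guaranteeing an exact label round trip through
`amyloid_labels`.

## Problem sizes and seeds

All stochastic procedures take explicit seeds; cohort generation is a
pure function of (spec, seed), and the pipeline fans per-stage seeds out
of one master seed by hashing stage names. Test and acceptance workloads
use desk-scale problem sizes chosen as the package's own defaults:
permutation calibration runs 200 replicates × 199 permutations on
reduced-dimension features (hippocampal pair, N_c = 10) — p-value
calibration is dimension-independent — while power, geometry and
region-recovery suites run at the full 23/45, N_c = 70 configuration.
`scripts/acceptance.py` completes in about a minute.

## Known limitations

- Templates must be genus-0 and reasonably well-conditioned; there is no
  remeshing, and strongly obtuse meshes degrade the cotangent operator.
- `laplacian_deform` assumes rigid pre-positioning and a single connected
  target component; it does not handle large rotational misalignment.
- Per-structure Procrustes normalization removes global size per
  structure, not intracranial-volume scaling; with real data a global
  normalization may be preferable.
- The incremental scheme stores p×p accumulators; it is exact but not
  suited to p ≫ 10³.
- Two-class only, by design.
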