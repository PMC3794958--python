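# subshape

Individual-subject classification of amyloid status from subcortical
surface shape.

In subcortical vascular dementia (SVaD), roughly a third of patients carry
concomitant Alzheimer-type amyloid pathology ("mixed dementia"), which is
normally established with amyloid PET. Because amyloid pathology
preferentially deforms the hippocampus and amygdala, the shape of these
structures on routine T1 MRI carries a usable signal. `subshape`
implements that idea as a reusable, fully tested pipeline:

1. **Shape representation.** Each subject's structure surface is obtained
   by deforming a template mesh onto the subject's binary segmentation
   (Laplacian surface deformation), which gives vertex correspondence by
   construction. Shape is summarized as a *deformity field*: the signed
   displacement of each vertex along the template's outward normal
   (negative = atrophy), after per-structure similarity-Procrustes size
   normalization.
2. **Spectral features.** The field x on a template with mass weights
   m and Laplace–Beltrami eigenpairs (λ_k, φ_k) is expanded as
   β_k = Σ_i m_i φ_k(i) x_i and truncated at a cut-off frequency N_c
   (default 70 per structure), discarding high-frequency noise while
   keeping spatially coherent shape change. Feature vectors are the
   concatenated coefficient blocks of both hippocampi and/or both
   amygdalae.
3. **Classification.** PCA retains the smallest subspace explaining 70%
   of the variance (avoiding the n ≪ p singularity), then Fisher's LDA:
   w ∝ S_w⁻¹(μ₊ − μ₋), threshold at the midpoint of the projected class
   means. Training is *incremental*: the classifier accumulates exact
   per-class sufficient statistics, so absorbing data batch by batch is
   prediction-equivalent to batch retraining — the property that makes
   the method suitable for steadily growing clinical datasets.
4. **Evaluation.** Stratified 10-fold (or leave-one-out) cross-validation
   with sensitivity/specificity/accuracy, ROC/AUC via Mann–Whitney pair
   counting, incremental learning curves (random presentation orders,
   batches of 10), and a permutation test that re-runs the CV with
   shuffled training labels to attach a p-value to the observed accuracy.
5. **Discriminative regions.** The LDA axis is back-projected through the
   PCA components and the inverse harmonic transform to a unit-norm
   per-vertex map on each template, exportable as PLY for rendering.

Since clinical MRI/PET cohorts of this kind are not publicly available,
the package ships a first-class synthetic cohort generator
(`subshape.synthetic_data`) that emulates the relevant statistics:
corresponded template meshes, spatially smooth subject variability,
planted group effects, unbalanced 23/45 class sizes, segmentation
volumes and regional PET uptake tables.

## Worked example

```python
from subshape import (CohortSpec, make_templates, compute_bases,
                      simulate_cohort, feature_matrix, run_cv,
                      permutation_test)

spec = CohortSpec(effect_amplitude_mm=0.15, effect_order=4, seed=42)
templates = make_templates(spec)
bases = compute_bases(templates, 70)
cohort = simulate_cohort(spec, bases, templates)

for fset in ("hippocampal", "amygdalar", "combined"):
    X, ids, names = feature_matrix(cohort.fields, fset, bases, 70)
    cv = run_cv(X, cohort.labels, k=10, seed=0)
    print(f"{fset:12s} acc {cv.accuracy:.3f}  sens {cv.sensitivity:.3f}  "
          f"spec {cv.specificity:.3f}  AUC {cv.auc:.4f}")

X, _, _ = feature_matrix(cohort.fields, "combined", bases, 70)
pr = permutation_test(X, cohort.labels, n_perm=199, seed=0)
print(f"permutation p = {pr.p_value:.4f}")
```

prints

```
hippocampal  acc 0.765  sens 0.739  spec 0.778  AUC 0.8754
amygdalar    acc 0.721  sens 0.609  spec 0.778  AUC 0.7778
combined     acc 0.838  sens 0.783  spec 0.867  AUC 0.9159
permutation p = 0.0050
```

The cohort here plants a weak (0.15 mm RMS), low-frequency, bilaterally
symmetric group difference on all four structures over subject-level
smooth variability of 0.5 mm RMS. Cross-validated accuracy is highest
when hippocampal and amygdalar features are combined, each structure set
alone is informative but weaker, and the permutation test (199 label
shuffles) finds the combined accuracy incompatible with chance — the
qualitative profile expected when a diffuse bilateral atrophy pattern
separates the groups.

A command-line interface covers the same ground
(`subshape simulate`, `subshape evaluate`, `subshape run-all`,
`subshape pib-label`); see `subshape --help`.

## Amyloid labels

`subshape.amyloid_labels` computes the global PiB retention ratio from a
regional uptake CSV (28 cortical VOIs + cerebellar reference) as the
VOI-volume-weighted mean SUVR, labelling a subject amyloid-positive iff
the ratio exceeds 1.5 (strictly).

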