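"""Synthetic cohorts: templates, deformity fields with planted group
effects, segmentation volumes, and regional uptake tables.

The generator emulates the statistical structure the shape pipeline
assumes in clinical data: per-structure surfaces corresponded to a
template, per-vertex deformity that is spatially coherent (nearby regions
deform together), a group-level mean difference concentrated in smooth
low-frequency patterns, and independent vertex-level measurement noise.
Each subject's field on a structure is

    x = group_pattern (amyloid-positives only)
      + smooth subject field   (harmonic coefficients with decaying variance)
      + white vertex noise.

Everything is a pure function of (spec, seed), so cohorts are exactly
reproducible and the whole pipeline is testable without clinical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .mesh_core import STRUCTURES, HarmonicBasis, TriangleMesh, compute_harmonics
from .surface_fitting import DeformityField

# hippocampus-like and amygdala-like semi-axes (mm); anisotropic ellipsoids
# standing in for the anatomical templates
DEFAULT_SEMI_AXES = {
    "hippocampus_L": (20.0, 10.0, 8.0),
    "hippocampus_R": (20.0, 10.0, 8.0),
    "amygdala_L": (12.0, 10.0, 9.0),
    "amygdala_R": (12.0, 10.0, 9.0),
}


@dataclass
class CohortSpec:
    """Study conditions of a simulated cohort.

    Defaults mirror the target study's composition: 45 amyloid-negative vs
    23 amyloid-positive subjects; effect amplitude 1.0 mm (= 2x the
    subject-level smooth field RMS of 0.5 mm) planted as a smooth
    low-frequency pattern, bilaterally symmetric across the structures in
    ``effect_structures``.
    """

    n_negative: int = 45
    n_positive: int = 23
    subdivision_level: int = 3
    effect_structures: tuple = STRUCTURES
    effect_pattern: str = "harmonic"  # or "patch"
    effect_amplitude_mm: float = 1.0
    effect_order: int = 12  # harmonics 1..effect_order carry the effect
    patch_center_vertex: int = 0
    patch_radius_mm: float = 6.0
    smooth_sd_mm: float = 0.5
    spectral_decay: float = 1.5  # rank-based variance decay exponent
    vertex_noise_sd_mm: float = 0.1
    n_harmonics: int = 70
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_negative < 2 or self.n_positive < 2:
            raise ValueError("need >= 2 subjects per group")
        if self.effect_amplitude_mm < 0:
            raise ValueError("amplitude must be >= 0")
        if self.smooth_sd_mm < 0 or self.vertex_noise_sd_mm < 0:
            raise ValueError("noise SDs must be >= 0")


def make_template(
    structure_tag: str, subdivision_level: int = 3, semi_axes=None
) -> TriangleMesh:
    """Icosphere-based anatomically proportioned template mesh.

    Subdivision level s gives 10·4^s + 2 vertices; the unit sphere is
    scaled anisotropically to structure-like proportions.
    """
    if subdivision_level < 2:
        raise ValueError("subdivision_level must be >= 2")
    import trimesh

    if semi_axes is None:
        semi_axes = DEFAULT_SEMI_AXES.get(structure_tag, (10.0, 10.0, 10.0))
    ico = trimesh.creation.icosphere(subdivisions=subdivision_level)
    verts = np.asarray(ico.vertices) * np.asarray(semi_axes, float)
    mesh = TriangleMesh(verts, np.asarray(ico.faces), structure_tag)
    mesh.validate()
    return mesh


def make_templates(spec: CohortSpec) -> dict:
    return {
        tag: make_template(tag, spec.subdivision_level) for tag in STRUCTURES
    }


def compute_bases(templates: dict, K: int) -> dict:
    return {tag: compute_harmonics(m, K) for tag, m in templates.items()}


def planted_patch_pattern(
    template: TriangleMesh,
    basis: HarmonicBasis,
    center_vertex: int,
    radius_mm: float,
    amplitude_mm: float,
    smoothing_n_c: int = 30,
) -> tuple:
    """Patch-indicator effect: inward deformity on a geodesic-ball patch,
    spectrally smoothed. Returns (coefficients, patch_vertex_mask)."""
    d = np.linalg.norm(template.vertices - template.vertices[center_vertex], axis=1)
    mask = d <= radius_mm
    indicator = mask.astype(float)
    n_c = min(smoothing_n_c, basis.K)
    beta = basis.eigenvectors[:, :n_c].T @ (basis.mass * indicator)
    coeffs = np.zeros(basis.K)
    coeffs[:n_c] = beta
    rms = np.linalg.norm(coeffs) / np.sqrt(basis.total_mass)
    if rms > 0:
        coeffs *= amplitude_mm / rms
    return coeffs, mask


@dataclass
class SyntheticCohort:
    """Fields, labels and ground truth of one simulated cohort."""

    spec: CohortSpec
    subject_ids: list
    labels: np.ndarray  # 1 = amyloid-positive
    fields: dict  # subject_id -> {structure_tag: DeformityField}
    effect_coefficients: dict  # structure_tag -> (K,) planted pattern
    effect_masks: dict = dc_field(default_factory=dict)  # patch mode only


def simulate_cohort(spec: CohortSpec, bases: dict,
                    templates: dict | None = None) -> SyntheticCohort:
    """Draw a cohort of per-structure deformity fields with planted effects.

    Negatives have zero group mean; positives additionally carry the
    planted pattern. Subject-level smooth fields have harmonic coefficients
    c_k ~ N(0, v_k) with rank-based decay v_k ∝ (k+1)^(-spectral_decay),
    scaled so the vertex RMS equals ``smooth_sd_mm``; white vertex noise is
    added on top. Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_negative + spec.n_positive
    labels = np.r_[np.zeros(spec.n_negative, int), np.ones(spec.n_positive, int)]
    subject_ids = [f"sub{j:03d}" for j in range(n)]

    # planted pattern per structure (bilaterally shared draw for the
    # harmonic mode so left/right effects are symmetric)
    effect, masks = {}, {}
    shared = None
    for tag in STRUCTURES:
        basis = bases[tag]
        if tag not in spec.effect_structures or spec.effect_amplitude_mm == 0:
            effect[tag] = np.zeros(basis.K)
            continue
        if spec.effect_pattern == "harmonic":
            lo = min(spec.effect_order, basis.K - 1)
            if shared is None:
                shared = rng.normal(size=lo)
            p = np.zeros(basis.K)
            p[1 : lo + 1] = shared
            p *= spec.effect_amplitude_mm / (
                np.linalg.norm(p) / np.sqrt(basis.total_mass)
            )
            # atrophy-dominant sign: net inward shift for positives
            if p[1] > 0:
                p = -p
            effect[tag] = p
        else:
            if templates is None:
                raise ValueError("patch pattern requires templates")
            coeffs, mask = planted_patch_pattern(
                templates[tag], basis, spec.patch_center_vertex,
                spec.patch_radius_mm, spec.effect_amplitude_mm,
            )
            effect[tag] = -coeffs  # inward (atrophy) patch
            masks[tag] = mask

    # subject-level smooth variance profile per structure
    var_profile = {}
    for tag in STRUCTURES:
        K = bases[tag].K
        v = (np.arange(K) + 1.0) ** (-spec.spectral_decay)
        v[0] *= 0.25  # damp pure-size mode relative to shape modes
        v *= spec.smooth_sd_mm**2 * bases[tag].total_mass / v.sum()
        var_profile[tag] = v

    fields: dict = {sid: {} for sid in subject_ids}
    for tag in STRUCTURES:
        basis = bases[tag]
        K, V = basis.K, basis.n_vertices
        coeff = rng.normal(size=(n, K)) * np.sqrt(var_profile[tag])
        coeff[labels == 1] += effect[tag]
        smooth = coeff @ basis.eigenvectors.T  # (n, V)
        noise = rng.normal(scale=spec.vertex_noise_sd_mm, size=(n, V)) \
            if spec.vertex_noise_sd_mm > 0 else np.zeros((n, V))
        x = smooth + noise
        for j, sid in enumerate(subject_ids):
            fields[sid][tag] = DeformityField(sid, tag, x[j])

    return SyntheticCohort(spec, subject_ids, labels, fields, effect, masks)


def simulate_segmentations(
    cohort: SyntheticCohort,
    templates: dict,
    spacing_mm: float = 0.5,
    structures=("hippocampus_L",),
    subjects=None,
) -> dict:
    """Voxelize subject surfaces (template + field·normals) into binary
    segmentations. Returns subject_id -> {structure_tag: VoxelGrid}."""
    from .mesh_core import grid_for_mesh, voxelize
    from .surface_fitting import displace_along_normals

    subjects = list(cohort.subject_ids if subjects is None else subjects)
    out: dict = {}
    for tag in structures:
        tmpl = templates[tag]
        margin = 4.0 + max(
            float(np.abs(cohort.fields[s][tag].values).max()) for s in subjects
        )
        spacing, origin, shape = grid_for_mesh(tmpl, [spacing_mm] * 3, margin)
        for sid in subjects:
            mesh = displace_along_normals(tmpl, cohort.fields[sid][tag].values)
            try:
                grid = voxelize(mesh, spacing, origin, shape)
            except ValueError as exc:
                import warnings

                warnings.warn(
                    f"skipping {sid}/{tag}: {exc}", RuntimeWarning, stacklevel=2
                )
                continue
            out.setdefault(sid, {})[tag] = grid
    return out


# 28 cortical volume-of-interest names (bilateral), matching the amyloid
# quantification protocol's regional layout
VOI_NAMES = [
    f"{region}_{side}"
    for region in (
        "frontal_sup", "frontal_mid", "frontal_med", "frontal_operc",
        "frontal_orb", "rectus_olfactory", "cingulum_post", "parietal_sup",
        "parietal_inf", "supramarginal", "angular", "precuneus",
        "temporal_lat", "occipital",
    )
    for side in ("L", "R")
]


def simulate_suvr_tables(
    n_subjects: int, positive_fraction: float, seed: int, threshold: float = 1.5
):
    """Regional uptake tables whose volume-weighted global ratio falls on
    the intended side of the positivity threshold by construction.

    Returns ``(tables, labels)``: a list of per-subject DataFrames with
    columns (voi_name, mean_suv, volume_ml) plus a cerebellar reference
    row, and the generation-truth binary labels.
    """
    import pandas as pd

    if not 0 <= positive_fraction <= 1:
        raise ValueError("positive_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_pos = int(round(n_subjects * positive_fraction))
    labels = np.r_[np.zeros(n_subjects - n_pos, int), np.ones(n_pos, int)]
    tables = []
    for lab in labels:
        volumes = rng.uniform(5.0, 40.0, size=28)
        # target global SUVR safely on the correct side of the threshold
        target = threshold + (rng.uniform(0.15, 0.8) if lab else -rng.uniform(0.15, 0.55))
        suvr = np.clip(target + rng.normal(scale=0.1, size=28), 0.4, None)
        # rescale to hit the target volume-weighted mean exactly
        suvr *= target / (np.sum(volumes * suvr) / volumes.sum())
        ref_uptake = rng.uniform(0.8, 1.4)
        df = pd.DataFrame(
            {
                "voi_name": VOI_NAMES + ["cerebellar_cortex"],
                "mean_suv": np.r_[suvr * ref_uptake, ref_uptake],
                "volume_ml": np.r_[volumes, rng.uniform(80.0, 140.0)],
            }
        )
        tables.append(df)
    return tables, labels
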