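"""Manifold-harmonic transform of deformity fields and feature assembly.

A deformity field x on a template with V vertices is expanded in the
template's Laplace–Beltrami eigenbasis,

    β_k = Σ_i m_i φ_k(i) x_i            (mass-weighted projection),

and truncated at a cut-off frequency N_c. Low-order coefficients capture
spatially coherent shape change; truncation removes high-frequency
segmentation/measurement noise. Per-subject features are the concatenated
coefficient blocks of the included structures in the fixed order
(hippocampus_L, hippocampus_R, amygdala_L, amygdala_R).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh_core import STRUCTURES, HarmonicBasis
from .surface_fitting import DeformityField

FEATURE_SETS = {
    "hippocampal": ("hippocampus_L", "hippocampus_R"),
    "amygdalar": ("amygdala_L", "amygdala_R"),
    "combined": STRUCTURES,
}


@dataclass
class SpectralCoefficients:
    structure_tag: str
    coefficients: np.ndarray  # (N_c,)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, float).ravel()
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("non-finite spectral coefficients")

    @property
    def n_c(self) -> int:
        return len(self.coefficients)


@dataclass
class FeatureVector:
    subject_id: str
    feature_set: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(f"unknown feature_set {self.feature_set!r}")
        self.values = np.asarray(self.values, float).ravel()


def mht_forward(
    field: DeformityField, basis: HarmonicBasis, n_c: int
) -> SpectralCoefficients:
    """Project a deformity field onto the first ``n_c`` harmonics."""
    if len(field.values) != basis.n_vertices:
        raise ValueError(
            f"field length {len(field.values)} != basis vertex count "
            f"{basis.n_vertices}"
        )
    if n_c > basis.K:
        raise ValueError(f"n_c={n_c} exceeds basis size K={basis.K}")
    beta = basis.eigenvectors[:, :n_c].T @ (basis.mass * field.values)
    return SpectralCoefficients(field.structure_tag, beta)


def mht_inverse(
    coeffs: SpectralCoefficients, basis: HarmonicBasis, subject_id: str = ""
) -> DeformityField:
    """Reconstruct the (low-pass filtered) field  x̂ = Σ_{k<N_c} β_k φ_k."""
    n_c = coeffs.n_c
    if n_c > basis.K:
        raise ValueError(f"coefficient length {n_c} exceeds basis size {basis.K}")
    x = basis.eigenvectors[:, :n_c] @ coeffs.coefficients
    return DeformityField(subject_id, coeffs.structure_tag, x)


def spectral_filter(
    field: DeformityField, basis: HarmonicBasis, n_c: int
) -> DeformityField:
    """Low-pass filter a field by forward/inverse MHT truncation."""
    return mht_inverse(mht_forward(field, basis, n_c), basis, field.subject_id)


def choose_cutoff(
    fields, basis: HarmonicBasis, energy_fraction: float = 0.9
) -> int:
    """Goodness-of-fit cut-off: the smallest N_c whose truncated
    reconstructions retain, on average over the supplied training fields,
    at least ``energy_fraction`` of each field's mass-weighted energy."""
    if not 0 < energy_fraction <= 1:
        raise ValueError("energy_fraction must be in (0, 1]")
    fields = list(fields)
    if not fields:
        raise ValueError("no fields supplied")
    X = np.stack([f.values for f in fields])  # (n, V)
    B = X @ (basis.mass[:, None] * basis.eigenvectors)  # (n, K)
    total = np.einsum("ij,j,ij->i", X, basis.mass, X)
    total = np.maximum(total, 1e-300)
    cum = np.cumsum(B**2, axis=1) / total[:, None]
    mean_cum = cum.mean(axis=0)
    hit = np.nonzero(mean_cum >= energy_fraction - 1e-12)[0]
    return int(hit[0]) + 1 if hit.size else basis.K


def assemble_feature(
    subject_fields: dict,
    feature_set: str,
    bases: dict,
    n_c,
    subject_id: str = "",
) -> FeatureVector:
    """Concatenate per-structure spectral coefficients for one subject.

    ``subject_fields`` and ``bases`` map structure_tag to DeformityField /
    HarmonicBasis; ``n_c`` is an int (shared) or a per-structure mapping.
    """
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature_set {feature_set!r}")
    blocks = []
    for tag in FEATURE_SETS[feature_set]:
        if tag not in subject_fields:
            raise ValueError(f"missing structure {tag!r} for feature set "
                             f"{feature_set!r}")
        nc = n_c[tag] if isinstance(n_c, dict) else int(n_c)
        blocks.append(mht_forward(subject_fields[tag], bases[tag], nc).coefficients)
    sid = subject_id or next(iter(subject_fields.values())).subject_id
    return FeatureVector(sid, feature_set, np.concatenate(blocks))


def feature_matrix(cohort_fields, feature_set: str, bases: dict, n_c):
    """Stack per-subject feature vectors into an (n_subjects, p) matrix.

    ``cohort_fields`` maps subject_id -> {structure_tag: DeformityField}.
    Returns ``(X, subject_ids, column_names)``.
    """
    ids = list(cohort_fields)
    rows, names = [], None
    for sid in ids:
        fv = assemble_feature(cohort_fields[sid], feature_set, bases, n_c, sid)
        rows.append(fv.values)
    names = feature_names(feature_set, n_c)
    return np.stack(rows), ids, names


_SHORT = {
    "hippocampus_L": "hippL",
    "hippocampus_R": "hippR",
    "amygdala_L": "amygL",
    "amygdala_R": "amygR",
}


def feature_names(feature_set: str, n_c) -> list:
    names = []
    for tag in FEATURE_SETS[feature_set]:
        nc = n_c[tag] if isinstance(n_c, dict) else int(n_c)
        names += [f"{_SHORT[tag]}_k{k:03d}" for k in range(nc)]
    return names
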