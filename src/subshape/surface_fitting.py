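"""Template-to-subject surface fitting and normal-direction deformity fields.

The geometric front-end of the pipeline: a structure template mesh is
deformed onto each subject's binary segmentation so that every subject
surface shares the template's connectivity and vertex ordering
(correspondence by construction). Per-subject shape is then summarized as
a scalar deformity field: the signed displacement of each corresponded
vertex along the template's outward normal, positive = outward
(local enlargement), negative = inward (atrophy).

Brain-size correction is realized as similarity Procrustes alignment of
the corresponded subject surface to the template before projection onto
the normals; it is applied per structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve
from scipy.spatial import cKDTree

from .mesh_core import TriangleMesh, VoxelGrid, vertex_normals


@dataclass
class CorrespondedSurface:
    """A subject surface sharing the template's connectivity.

    ``faces`` is the template's face array (shared reference, not copied);
    ``provenance`` records whether the surface came out of ``laplacian_deform``
    ("fitted") or was supplied pre-corresponded ("supplied").
    """

    subject_id: str
    structure_tag: str
    vertices: np.ndarray
    faces: np.ndarray
    provenance: str = "fitted"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        if self.provenance not in ("fitted", "supplied"):
            raise ValueError("provenance must be 'fitted' or 'supplied'")


@dataclass
class DeformityField:
    """Per-vertex signed normal displacement (mm) of a subject surface."""

    subject_id: str
    structure_tag: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("deformity field contains non-finite values")


def boundary_face_centers(target: VoxelGrid) -> np.ndarray:
    """World coordinates of voxel-face centers between occupied and empty
    voxels (the implicit segmentation boundary)."""
    occ = target.occupancy
    pts = []
    pad = np.pad(occ, 1, constant_values=False)
    for ax in range(3):
        a = pad
        b = np.roll(pad, -1, axis=ax)
        trans = a != b
        idx = np.argwhere(trans)
        # face between voxel idx-1 (padded) and its +ax neighbour
        centers = (idx - 1).astype(float)
        centers[:, ax] += 0.5
        pts.append(target.origin + centers * target.spacing)
    return np.concatenate(pts, axis=0)


def laplacian_deform(
    template: TriangleMesh,
    target: VoxelGrid,
    iterations: int = 10,
    stiffness_weight: float = 1.0,
    motion_tol: float = 1e-3,
) -> CorrespondedSurface:
    """Deform a template mesh onto a binary segmentation.

    Each iteration solves the least-squares system

        min_v  stiffness_weight * ||L v − δ||²  +  w_t Σ_i ||v_i − b_i||²

    where L is the template's uniform graph Laplacian, δ its differential
    coordinates (recomputed from the current iterate so the surface can
    bend globally while keeping local detail), b_i the closest boundary
    point of the target segmentation to vertex i, and w_t a soft-constraint
    weight ramped up over iterations. Connectivity is never modified.
    """
    template.validate()
    if not target.occupancy.any():
        raise ValueError("target segmentation is empty")
    V = template.n_vertices
    f = template.faces

    # uniform (combinatorial) graph Laplacian, scale-free
    edges = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    A = sp.coo_matrix(
        (np.ones(len(edges)), (edges[:, 0], edges[:, 1])), shape=(V, V)
    ).tocsr()
    A.data[:] = 1.0
    deg = np.asarray(A.sum(axis=1)).ravel()
    L = sp.diags(deg) - A

    bpoints = boundary_face_centers(target)
    tree = cKDTree(bpoints)

    v = template.vertices.copy()
    mean_spacing = float(np.mean(target.spacing))
    for it in range(iterations):
        delta = L @ v
        # ramp the data weight: gentle attraction first, tight fit last
        w = 0.5 * (2.0 ** min(it, 8))
        _, nearest = tree.query(v)
        b = bpoints[nearest]
        lhs = (stiffness_weight * (L.T @ L) + w * sp.identity(V)).tocsc()
        rhs = stiffness_weight * (L.T @ delta) + w * b
        v_new = np.column_stack([spsolve(lhs, rhs[:, k]) for k in range(3)])
        motion = np.linalg.norm(v_new - v, axis=1).mean()
        v = v_new
        if motion < motion_tol * mean_spacing:
            break
    else:
        if motion >= 0.5 * mean_spacing:
            warnings.warn(
                f"laplacian_deform: residual mean vertex motion "
                f"{motion:.3g} mm after {iterations} iterations; "
                "returning best iterate",
                RuntimeWarning,
                stacklevel=2,
            )
    return CorrespondedSurface(
        subject_id="", structure_tag=template.structure_tag,
        vertices=v, faces=template.faces, provenance="fitted",
    )


def similarity_align(moving_vertices: np.ndarray, fixed_vertices: np.ndarray):
    """Least-squares similarity (scale+rotation+translation) Procrustes.

    Closed-form Umeyama solution on corresponded vertex sets. Returns
    ``(s, R, t, aligned)`` with ``aligned = s * moving @ R.T + t``.
    """
    X = np.asarray(moving_vertices, float)
    Y = np.asarray(fixed_vertices, float)
    if X.shape != Y.shape:
        raise ValueError("vertex sets must be corresponded (equal shapes)")
    mx, my = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - mx, Y - my
    varx = np.einsum("ij,ij->", Xc, Xc)
    if varx < 1e-20 or np.einsum("ij,ij->", Yc, Yc) < 1e-20:
        raise ValueError("degenerate (zero-variance) point set")
    C = Yc.T @ Xc / len(X)
    U, D, Vt = np.linalg.svd(C)
    sflip = np.ones(3)
    if np.linalg.det(U @ Vt) < 0:
        sflip[-1] = -1.0
    R = U @ np.diag(sflip) @ Vt
    s = float(np.sum(D * sflip) * len(X) / varx)
    t = my - s * R @ mx
    aligned = s * X @ R.T + t
    return s, R, t, aligned


def compute_deformity(
    subject: CorrespondedSurface,
    template: TriangleMesh,
    normalize_size: bool = True,
) -> DeformityField:
    """Signed normal displacement of a corresponded subject surface.

    value_i = (subject_vertex_i − template_vertex_i) · template_normal_i,
    after optional similarity-Procrustes alignment of the subject to the
    template (per-structure brain-size correction).
    """
    if subject.vertices.shape != template.vertices.shape:
        raise ValueError(
            f"vertex count mismatch: subject {len(subject.vertices)} vs "
            f"template {template.n_vertices}"
        )
    sv = subject.vertices
    if normalize_size:
        _, _, _, sv = similarity_align(sv, template.vertices)
    n = vertex_normals(template)
    vals = np.einsum("ij,ij->i", sv - template.vertices, n)
    return DeformityField(subject.subject_id, subject.structure_tag, vals)


def displace_along_normals(template: TriangleMesh, field: np.ndarray) -> TriangleMesh:
    """Template vertices moved by a scalar field along outward normals."""
    field = np.asarray(field, float).ravel()
    if len(field) != template.n_vertices:
        raise ValueError("field length must equal template vertex count")
    n = vertex_normals(template)
    return TriangleMesh(
        template.vertices + field[:, None] * n,
        template.faces.copy(),
        template.structure_tag,
    )


def fields_to_frame(fields) -> "object":
    """Serialize deformity fields to a long-format DataFrame
    (subject_id, structure_tag, vertex_index, value_mm)."""
    import pandas as pd

    rows = []
    for fld in fields:
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": fld.subject_id,
                    "structure_tag": fld.structure_tag,
                    "vertex_index": np.arange(len(fld.values)),
                    "value_mm": fld.values,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def frame_to_fields(df) -> list:
    """Inverse of :func:`fields_to_frame`."""
    out = []
    for (sid, tag), grp in df.groupby(["subject_id", "structure_tag"], sort=False):
        grp = grp.sort_values("vertex_index")
        out.append(DeformityField(str(sid), str(tag), grp["value_mm"].to_numpy()))
    return out
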