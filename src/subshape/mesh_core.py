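"""Triangle-mesh data model, Laplace–Beltrami operators, spectral basis,
voxelization and overlap metrics.

The shape pipeline measures subcortical deformity as a scalar signal on a
template surface; everything downstream (manifold harmonics, spectral
filtering, discriminative maps) lives on the operators built here. The
discretization is the standard manifold-harmonics construction: cotangent
stiffness matrix with barycentric lumped mass, and the generalized
eigenproblem  S φ = λ M φ  whose eigenpairs form the spectral dictionary.

Coordinates are world millimeters throughout. Voxel indices are 0-based and
the grid origin is the world position of the *center* of voxel (0, 0, 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import eigsh

STRUCTURES = ("hippocampus_L", "hippocampus_R", "amygdala_L", "amygdala_R")
_VALID_TAGS = STRUCTURES + ("other",)


class MeshTopologyError(ValueError):
    """Raised when a mesh violates the closed-2-manifold contract."""


@dataclass
class TriangleMesh:
    """Closed, consistently oriented genus-0 triangle surface.

    Parameters
    ----------
    vertices : (V, 3) float array, mm
    faces : (F, 3) int array of vertex indices, counter-clockwise seen
        from outside (positive signed volume)
    structure_tag : which subcortical structure this surface represents
    """

    vertices: np.ndarray
    faces: np.ndarray
    structure_tag: str = "other"

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (V, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (F, 3)")
        if self.structure_tag not in _VALID_TAGS:
            raise ValueError(
                f"structure_tag {self.structure_tag!r} not in {_VALID_TAGS}"
            )

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def validate(self) -> None:
        """Check index bounds, degeneracy, closedness, orientation, genus."""
        V, F = self.n_vertices, self.n_faces
        if self.faces.min(initial=0) < 0 or self.faces.max(initial=-1) >= V:
            raise MeshTopologyError("face index out of range")
        f = self.faces
        if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
            raise MeshTopologyError("degenerate face repeats a vertex")
        # Directed edge multiset: closed orientable manifold iff every
        # directed edge appears exactly once and its reverse exactly once.
        di = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        key = di[:, 0] * V + di[:, 1]
        uniq, counts = np.unique(key, return_counts=True)
        if np.any(counts > 1):
            bad = uniq[counts > 1][0]
            raise MeshTopologyError(
                f"inconsistent orientation or non-manifold: directed edge "
                f"({bad // V}, {bad % V}) repeated"
            )
        rev = di[:, 1] * V + di[:, 0]
        missing = np.setdiff1d(key, rev, assume_unique=False)
        if missing.size:
            bad = missing[0]
            raise MeshTopologyError(
                f"open or non-manifold surface: edge ({bad // V}, {bad % V}) "
                f"has no opposite-orientation twin"
            )
        E = len(di) // 2
        if V - E + F != 2:
            raise MeshTopologyError(
                f"Euler characteristic {V - E + F} != 2 (not genus 0)"
            )
        if self.signed_volume() <= 0:
            raise MeshTopologyError("negative signed volume: inward orientation")

    def signed_volume(self) -> float:
        """Signed enclosed volume from the divergence theorem (mm^3)."""
        a, b, c = (self.vertices[self.faces[:, k]] for k in range(3))
        return float(np.einsum("ij,ij->", a, np.cross(b, c)) / 6.0)

    def face_areas(self) -> np.ndarray:
        a, b, c = (self.vertices[self.faces[:, k]] for k in range(3))
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def oriented_copy(self) -> "TriangleMesh":
        """Return a copy flipped, if necessary, to outward orientation."""
        if self.signed_volume() < 0:
            return TriangleMesh(
                self.vertices.copy(), self.faces[:, ::-1].copy(), self.structure_tag
            )
        return TriangleMesh(
            self.vertices.copy(), self.faces.copy(), self.structure_tag
        )


@dataclass
class VoxelGrid:
    """Binary occupancy on a regular axis-aligned grid.

    ``origin`` is the world coordinate (mm) of the center of voxel (0,0,0);
    ``spacing`` is per-axis voxel size in mm.
    """

    occupancy: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.occupancy = np.ascontiguousarray(self.occupancy, dtype=bool)
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        if self.occupancy.ndim != 3:
            raise ValueError("occupancy must be 3-D")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be > 0 on all axes")

    @property
    def shape(self) -> tuple:
        return self.occupancy.shape

    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def occupied_volume(self) -> float:
        return float(self.occupancy.sum()) * self.voxel_volume()

    def same_geometry(self, other: "VoxelGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class HarmonicBasis:
    """Mass-orthonormal Laplace–Beltrami eigenpairs of a template mesh.

    eigenvalues : (K,) ascending, mm^-2
    eigenvectors : (V, K), columns φ_k with Φᵀ M Φ = I
    mass : (V,) barycentric lumped vertex areas, mm^2
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    mass: np.ndarray
    structure_tag: str = "other"

    @property
    def K(self) -> int:
        return len(self.eigenvalues)

    @property
    def n_vertices(self) -> int:
        return len(self.mass)

    @property
    def total_mass(self) -> float:
        return float(self.mass.sum())


def build_laplacian(mesh: TriangleMesh) -> tuple:
    """Cotangent stiffness matrix and barycentric lumped mass weights.

    Returns ``(S, m)``: a symmetric positive-semidefinite sparse stiffness
    with zero row sums (off-diagonal ``-(cot a + cot b)/2`` over the two
    angles opposite each edge), and per-vertex mass = one third of incident
    face area, summing to total surface area.

    Obtuse triangles yield negative cotangents; they are kept as-is, but a
    warning is issued if more than 1% of off-diagonal entries are positive,
    since a badly conditioned template degrades the harmonic basis.
    """
    mesh.validate()
    V = mesh.n_vertices
    f = mesh.faces
    v = mesh.vertices

    ii, jj, ww = [], [], []
    # angle at corner k is opposite edge (k+1, k+2)
    for k in range(3):
        o = v[f[:, k]]
        p = v[f[:, (k + 1) % 3]]
        q = v[f[:, (k + 2) % 3]]
        u, w_ = p - o, q - o
        cross = np.linalg.norm(np.cross(u, w_), axis=1)
        cot = np.einsum("ij,ij->i", u, w_) / np.maximum(cross, 1e-300)
        ii.append(f[:, (k + 1) % 3])
        jj.append(f[:, (k + 2) % 3])
        ww.append(0.5 * cot)
    ii, jj, ww = (np.concatenate(x) for x in (ii, jj, ww))
    W = sp.coo_matrix((ww, (ii, jj)), shape=(V, V))
    W = (W + W.T).tocsr()  # symmetric edge weights
    S = sp.diags(np.asarray(W.sum(axis=1)).ravel()) - W

    off = W.data[W.data != 0]
    if off.size and np.mean(off < 0) > 0.01:
        warnings.warn(
            f"{np.mean(off < 0):.1%} of cotangent edge weights are negative "
            "(obtuse triangles); template mesh is poorly conditioned",
            RuntimeWarning,
            stacklevel=2,
        )

    areas = mesh.face_areas()
    m = np.zeros(V)
    for k in range(3):
        np.add.at(m, f[:, k], areas / 3.0)
    if np.any(m <= 0):
        raise ValueError("zero lumped mass: vertex with zero-area face fan")
    return S.tocsr(), m


def _fix_signs(phi: np.ndarray) -> np.ndarray:
    """Deterministic eigenvector signs: largest-|entry| positive, ties by
    lowest vertex index (argmax returns the first maximum)."""
    idx = np.argmax(np.abs(phi), axis=0)
    signs = np.sign(phi[idx, np.arange(phi.shape[1])])
    signs[signs == 0] = 1.0
    return phi * signs


def compute_harmonics(mesh: TriangleMesh, K: int) -> HarmonicBasis:
    """K lowest eigenpairs of  S φ = λ M φ  (manifold harmonic basis).

    Eigenvectors are mass-orthonormal (ΦᵀMΦ = I) with deterministic signs;
    eigenvalues ascend from λ_0 ≈ 0 (the constant mode).
    """
    if not 1 <= K <= mesh.n_vertices:
        raise ValueError(f"K={K} out of range [1, {mesh.n_vertices}]")
    S, m = build_laplacian(mesh)
    M = sp.diags(m)
    if K >= mesh.n_vertices - 1:
        # dense fallback: eigsh cannot return the full spectrum
        from scipy.linalg import eigh

        lam, phi = eigh(S.toarray(), M.toarray())
        lam, phi = lam[:K], phi[:, :K]
    else:
        try:
            lam, phi = eigsh(
                S, k=K, M=M, sigma=-1e-3, which="LM",
                v0=np.ones(mesh.n_vertices),
            )
        except Exception as exc:  # pragma: no cover - solver failure path
            raise RuntimeError(
                f"eigensolver failed to converge for K={K}: {exc}"
            ) from exc
    order = np.argsort(lam)
    lam, phi = lam[order], phi[:, order]
    lam[0] = max(lam[0], 0.0) if abs(lam[0]) < 1e-8 * max(lam[-1], 1.0) else lam[0]
    # enforce exact mass-orthonormality (eigsh already returns M-orthonormal
    # vectors; renormalize to kill rounding)
    nrm = np.sqrt(np.einsum("ik,i,ik->k", phi, m, phi))
    phi = phi / nrm
    phi = _fix_signs(phi)
    return HarmonicBasis(lam, phi, m, mesh.structure_tag)


def vertex_normals(mesh: TriangleMesh) -> np.ndarray:
    """Per-vertex unit outward normals (angle-weighted face-normal average)."""
    mesh.validate()
    v, f = mesh.vertices, mesh.faces
    fn = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    fl = np.linalg.norm(fn, axis=1)
    if np.any(fl < 1e-300):
        raise ValueError("zero-area face in normal computation")
    fn = fn / fl[:, None]
    out = np.zeros_like(v)
    for k in range(3):
        o = v[f[:, k]]
        u = v[f[:, (k + 1) % 3]] - o
        w = v[f[:, (k + 2) % 3]] - o
        cosang = np.einsum("ij,ij->i", u, w) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(w, axis=1)
        )
        ang = np.arccos(np.clip(cosang, -1.0, 1.0))
        np.add.at(out, f[:, k], fn * ang[:, None])
    nrm = np.linalg.norm(out, axis=1)
    if np.any(nrm < 1e-300):
        raise ValueError("degenerate vertex fan: zero aggregated normal")
    return out / nrm[:, None]


def voxelize(mesh: TriangleMesh, spacing, origin, shape) -> VoxelGrid:
    """Rasterize a closed mesh: voxel occupied iff its center is inside.

    Inside/outside is decided by parity of crossings of a +z axis-aligned
    ray through the voxel center; the ray grid is deterministically
    perturbed by a tiny irrational offset so rays never pass through mesh
    vertices or edges exactly.
    """
    mesh.validate()
    spacing = np.asarray(spacing, dtype=float).reshape(3)
    origin = np.asarray(origin, dtype=float).reshape(3)
    shape = tuple(int(s) for s in shape)
    lo = origin - 0.5 * spacing
    hi = origin + (np.array(shape) - 0.5) * spacing
    vmin, vmax = mesh.vertices.min(axis=0), mesh.vertices.max(axis=0)
    if np.any(vmin < lo) or np.any(vmax > hi):
        raise ValueError(
            f"mesh extent [{vmin}, {vmax}] exceeds grid box [{lo}, {hi}]"
        )

    eps = spacing[:2] * np.array([1.0e-6 * np.sqrt(2), 1.0e-6 * np.sqrt(3)])
    xs = origin[0] + spacing[0] * np.arange(shape[0]) + eps[0]
    ys = origin[1] + spacing[1] * np.arange(shape[1]) + eps[1]

    v, f = mesh.vertices, mesh.faces
    tri = v[f]  # (F, 3, 3)
    occ = np.zeros(shape, dtype=bool)
    # per-column z crossings, accumulated triangle by triangle
    crossings: dict = {}
    for t in range(len(tri)):
        a, b, c = tri[t]
        txmin, txmax = min(a[0], b[0], c[0]), max(a[0], b[0], c[0])
        tymin, tymax = min(a[1], b[1], c[1]), max(a[1], b[1], c[1])
        i0 = max(0, int(np.ceil((txmin - eps[0] - origin[0]) / spacing[0])))
        i1 = min(shape[0] - 1, int(np.floor((txmax - eps[0] - origin[0]) / spacing[0])))
        j0 = max(0, int(np.ceil((tymin - eps[1] - origin[1]) / spacing[1])))
        j1 = min(shape[1] - 1, int(np.floor((tymax - eps[1] - origin[1]) / spacing[1])))
        if i1 < i0 or j1 < j0:
            continue
        gx, gy = np.meshgrid(xs[i0 : i1 + 1], ys[j0 : j1 + 1], indexing="ij")
        p = np.stack([gx.ravel(), gy.ravel()], axis=1)
        # barycentric test in the xy-plane
        d = (b[1] - c[1]) * (a[0] - c[0]) + (c[0] - b[0]) * (a[1] - c[1])
        if abs(d) < 1e-300:
            continue  # triangle vertical in z: never crossed transversally
        w1 = ((b[1] - c[1]) * (p[:, 0] - c[0]) + (c[0] - b[0]) * (p[:, 1] - c[1])) / d
        w2 = ((c[1] - a[1]) * (p[:, 0] - c[0]) + (a[0] - c[0]) * (p[:, 1] - c[1])) / d
        w3 = 1.0 - w1 - w2
        inside = (w1 >= 0) & (w2 >= 0) & (w3 >= 0)
        if not inside.any():
            continue
        z = w1[inside] * a[2] + w2[inside] * b[2] + w3[inside] * c[2]
        idx = np.nonzero(inside)[0]
        ncols = j1 - j0 + 1
        for k, zi in zip(idx, z):
            col = (i0 + k // ncols, j0 + k % ncols)
            crossings.setdefault(col, []).append(zi)

    z0, dz = origin[2], spacing[2]
    for (i, j), zs in crossings.items():
        zs = sorted(zs)
        if len(zs) % 2:  # should not happen with perturbed rays
            warnings.warn(
                f"odd crossing count at column {(i, j)}; dropping last",
                RuntimeWarning,
                stacklevel=2,
            )
            zs = zs[:-1]
        for zlo, zhi in zip(zs[::2], zs[1::2]):
            k0 = max(0, int(np.ceil((zlo - z0) / dz)))
            k1 = min(shape[2] - 1, int(np.floor((zhi - z0) / dz)))
            if k1 >= k0:
                occ[i, j, k0 : k1 + 1] = True
    return VoxelGrid(occ, spacing, origin)


def grid_for_mesh(mesh: TriangleMesh, spacing, margin_mm: float = 2.0):
    """Convenience: (spacing, origin, shape) of a grid enclosing the mesh."""
    spacing = np.asarray(spacing, dtype=float).reshape(3)
    lo = mesh.vertices.min(axis=0) - margin_mm
    hi = mesh.vertices.max(axis=0) + margin_mm
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    return spacing, lo, tuple(shape)


def overlap_fraction(test: VoxelGrid, reference: VoxelGrid) -> tuple:
    """Fraction of the reference volume covered by the test volume.

    Returns ``(fraction, dice)`` where fraction = |test ∩ ref| / |ref| and
    Dice = 2|∩| / (|test| + |ref|).
    """
    if not test.same_geometry(reference):
        raise ValueError("voxel grids have mismatched geometry")
    nref = int(reference.occupancy.sum())
    if nref == 0:
        raise ValueError("reference volume is empty")
    inter = int((test.occupancy & reference.occupancy).sum())
    ntest = int(test.occupancy.sum())
    dice = 2.0 * inter / (ntest + nref) if (ntest + nref) else 0.0
    return inter / nref, dice


# ---------------------------------------------------------------------------
# I/O


def save_mesh(mesh: TriangleMesh, path) -> None:
    """Write PLY or OFF (ASCII), by extension."""
    import trimesh

    tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
    path = str(path)
    if path.endswith(".ply"):
        data = tm.export(file_type="ply", encoding="ascii")
    elif path.endswith(".off"):
        data = tm.export(file_type="off")
    else:
        raise ValueError(f"unsupported mesh format: {path}")
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)


def load_mesh(path, structure_tag: str = "other") -> TriangleMesh:
    import trimesh

    tm = trimesh.load(str(path), process=False)
    return TriangleMesh(
        np.asarray(tm.vertices), np.asarray(tm.faces), structure_tag
    ).oriented_copy()


def save_volume(grid: VoxelGrid, path) -> None:
    """Write a binary segmentation as NIfTI; grid geometry in the affine."""
    import nibabel as nib

    aff = np.eye(4)
    aff[:3, :3] = np.diag(grid.spacing)
    aff[:3, 3] = grid.origin
    img = nib.Nifti1Image(grid.occupancy.astype(np.uint8), aff)
    nib.save(img, str(path))


def load_volume(path) -> VoxelGrid:
    """Read a binary NIfTI segmentation (axis-aligned affine required)."""
    import nibabel as nib

    img = nib.load(str(path))
    aff = img.affine
    rot = aff[:3, :3]
    if np.any(np.abs(rot - np.diag(np.diag(rot))) > 1e-6 * np.abs(np.diag(rot)).max()):
        raise ValueError("oblique NIfTI affine: only axis-aligned volumes supported")
    data = np.asarray(img.dataobj)
    vals = np.unique(data)
    if not np.all(np.isin(vals, [0, 1])):
        raise ValueError("volume is not strictly binary")
    return VoxelGrid(data > 0, np.diag(rot), aff[:3, 3])
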