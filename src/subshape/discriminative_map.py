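"""Back-projection of the LDA axis to per-vertex discriminative maps.

The trained discriminant lives in PCA space; mapping it back through the
PCA component matrix gives a vector over spectral coefficients, whose
per-structure blocks are inverse-transformed to vertex space and
unit-normalized. The signed per-vertex value indicates how strongly (and
in which direction) outward deformity at that vertex votes for the
amyloid-positive class; large-|value| regions are the discriminative
regions. No vertex-wise significance is attached — the map describes the
classifier, not group-specific deformity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classifier import PCALDAClassifier
from .mesh_core import TriangleMesh
from .spectral_features import FEATURE_SETS, SpectralCoefficients, mht_inverse


@dataclass
class DiscriminativeMap:
    structure_tag: str
    values: np.ndarray  # per-vertex, unit Euclidean norm
    energy_share: float  # fraction of squared feature-space axis norm

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float).ravel()
        nrm = np.linalg.norm(self.values)
        if abs(nrm - 1.0) > 1e-10:
            raise ValueError(f"map norm {nrm} != 1")


def backproject_axis(
    state: PCALDAClassifier, bases: dict, feature_set: str, n_c
) -> dict:
    """Per-structure discriminative maps from a trained classifier.

    The PCA-space axis w is lifted to feature space (components @ w),
    split into per-structure coefficient blocks of length N_c, and each
    block is inverse-MHT'd to vertex space and normalized to unit length.
    ``energy_share`` reports each structure's fraction of the squared
    feature-space axis norm before normalization.
    """
    a = state.feature_axis_
    tags = FEATURE_SETS[feature_set]
    sizes = [n_c[t] if isinstance(n_c, dict) else int(n_c) for t in tags]
    if sum(sizes) != len(a):
        raise ValueError(
            f"feature layout mismatch: blocks sum to {sum(sizes)} but the "
            f"axis has {len(a)} components"
        )
    total_sq = float(a @ a)
    out = {}
    start = 0
    for tag, size in zip(tags, sizes):
        block = a[start : start + size]
        start += size
        if bases[tag].K < size:
            raise ValueError(f"basis for {tag} has K={bases[tag].K} < {size}")
        field = mht_inverse(SpectralCoefficients(tag, block), bases[tag])
        vals = field.values
        nrm = np.linalg.norm(vals)
        if nrm == 0:
            raise ValueError(f"zero discriminative map for {tag}")
        out[tag] = DiscriminativeMap(
            tag, vals / nrm, float(block @ block) / total_sq
        )
    return out


def export_map(dmap: DiscriminativeMap, template: TriangleMesh, path) -> None:
    """Write the template with the map as a per-vertex ``quality`` scalar
    in ASCII PLY (readable by standard mesh viewers)."""
    if len(dmap.values) != template.n_vertices:
        raise ValueError("map length does not match template vertex count")
    if np.linalg.norm(dmap.values) == 0:
        raise ValueError("refusing to export an all-zero map")
    v, f, q = template.vertices, template.faces, dmap.values
    try:
        with open(str(path), "w") as fh:
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"comment structure {dmap.structure_tag}\n")
            fh.write(f"element vertex {len(v)}\n")
            fh.write("property float x\nproperty float y\nproperty float z\n")
            fh.write("property float quality\n")
            fh.write(f"element face {len(f)}\n")
            fh.write("property list uchar int vertex_indices\nend_header\n")
            for (x, y, z), qi in zip(v, q):
                fh.write(f"{x:.7g} {y:.7g} {z:.7g} {qi:.7g}\n")
            for a, b, c in f:
                fh.write(f"3 {a} {b} {c}\n")
    except OSError as exc:
        raise OSError(f"failed writing discriminative map to {path}: {exc}") from exc


def load_map(path) -> tuple:
    """Read back a PLY written by :func:`export_map`.

    Returns ``(vertices, faces, values, structure_tag)``.
    """
    with open(str(path)) as fh:
        lines = fh.read().splitlines()
    if lines[0] != "ply":
        raise ValueError(f"{path}: not a PLY file")
    nv = nf = None
    tag = "other"
    i = 0
    for i, ln in enumerate(lines):
        if ln.startswith("comment structure"):
            tag = ln.split()[-1]
        elif ln.startswith("element vertex"):
            nv = int(ln.split()[-1])
        elif ln.startswith("element face"):
            nf = int(ln.split()[-1])
        elif ln == "end_header":
            break
    body = lines[i + 1 :]
    vdata = np.array([[float(t) for t in ln.split()] for ln in body[:nv]])
    fdata = np.array([[int(t) for t in ln.split()[1:]] for ln in body[nv : nv + nf]])
    return vdata[:, :3], fdata, vdata[:, 3], tag


def top_decile_vertices(dmap: DiscriminativeMap) -> np.ndarray:
    """Boolean mask of the top 10% of vertices by |value|."""
    k = max(1, len(dmap.values) // 10)
    thresh = np.partition(np.abs(dmap.values), -k)[-k]
    return np.abs(dmap.values) >= thresh
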