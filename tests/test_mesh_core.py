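import numpy as np
import pytest

from subshape.mesh_core import (
    MeshTopologyError,
    TriangleMesh,
    VoxelGrid,
    build_laplacian,
    compute_harmonics,
    grid_for_mesh,
    load_mesh,
    load_volume,
    overlap_fraction,
    save_mesh,
    save_volume,
    vertex_normals,
    voxelize,
)

from .conftest import icosphere_mesh


def regular_tetrahedron():
    # edge length sqrt(8)/sqrt(2) ... vertices of a cube diagonal; rescale
    v = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float)
    v /= np.linalg.norm(v[0] - v[1])  # unit edge
    f = np.array([[0, 1, 2], [0, 3, 1], [0, 2, 3], [1, 3, 2]])
    return TriangleMesh(v, f).oriented_copy()


class TestTopology:
    def test_valid_tetrahedron(self):
        regular_tetrahedron().validate()

    def test_open_mesh_rejected_naming_edge(self):
        m = regular_tetrahedron()
        open_mesh = TriangleMesh(m.vertices, m.faces[:3])
        with pytest.raises(MeshTopologyError, match="edge"):
            open_mesh.validate()

    def test_degenerate_face_rejected(self):
        m = regular_tetrahedron()
        bad = m.faces.copy()
        bad[0] = [0, 0, 1]
        with pytest.raises(MeshTopologyError, match="degenerate"):
            TriangleMesh(m.vertices, bad).validate()

    def test_inverted_orientation_detected_and_reorientable(self):
        m = regular_tetrahedron()
        flipped = TriangleMesh(m.vertices, m.faces[:, ::-1])
        with pytest.raises(MeshTopologyError, match="orientation|volume"):
            flipped.validate()
        fixed = flipped.oriented_copy()
        fixed.validate()
        assert fixed.signed_volume() > 0

    def test_euler_characteristic_genus0(self, unit_sphere):
        V, F = unit_sphere.n_vertices, unit_sphere.n_faces
        E = 3 * F // 2
        assert V - E + F == 2


class TestLaplacian:
    def test_tetrahedron_cotangent_entry(self):
        # every angle is 60 deg: off-diagonal -(cot60+cot60)/2 = -1/sqrt(3)
        S, m = build_laplacian(regular_tetrahedron())
        off = S[0, 1]
        assert off == pytest.approx(-1.0 / np.sqrt(3), abs=1e-12)

    def test_zero_row_sums_and_symmetry(self, unit_sphere):
        S, _ = build_laplacian(unit_sphere)
        assert np.abs(S @ np.ones(unit_sphere.n_vertices)).max() < 1e-10
        assert abs(S - S.T).max() < 1e-12

    def test_total_mass_is_sphere_area(self, unit_sphere_fine):
        _, m = build_laplacian(unit_sphere_fine)
        assert m.sum() == pytest.approx(4 * np.pi, rel=0.01)
        assert (m > 0).all()

    def test_obtuse_warning_on_skewed_mesh(self):
        squashed = icosphere_mesh(3, scale=(20.0, 10.0, 2.0))
        with pytest.warns(RuntimeWarning, match="obtuse"):
            build_laplacian(squashed)


class TestHarmonics:
    def test_constant_nullspace(self, unit_sphere):
        b = compute_harmonics(unit_sphere, 1)
        assert abs(b.eigenvalues[0]) < 1e-8
        phi0 = b.eigenvectors[:, 0]
        assert np.ptp(phi0) < 1e-8 * abs(phi0).max()

    def test_sphere_spectrum_l_l_plus_1(self, unit_sphere_fine):
        # analytic Laplace-Beltrami spectrum of the unit sphere: l(l+1)
        # with multiplicity 2l+1
        b = compute_harmonics(unit_sphere_fine, 16)
        lam = b.eigenvalues
        expected = np.array([0.0] + [2.0] * 3 + [6.0] * 5 + [12.0] * 7)
        assert abs(lam[0]) < 1e-8
        assert np.allclose(lam[1:], expected[1:], rtol=0.05)

    def test_mass_orthonormality(self, sphere_basis):
        b = sphere_basis
        G = b.eigenvectors.T * b.mass @ b.eigenvectors
        assert np.abs(G - np.eye(b.K)).max() < 1e-8

    def test_eigenvalues_nondecreasing(self, sphere_basis):
        assert (np.diff(sphere_basis.eigenvalues) >= -1e-12).all()

    def test_deterministic_signs(self, unit_sphere):
        b1 = compute_harmonics(unit_sphere, 10)
        b2 = compute_harmonics(unit_sphere, 10)
        assert np.array_equal(b1.eigenvectors, b2.eigenvectors)

    def test_K_out_of_range(self, unit_sphere):
        with pytest.raises(ValueError, match="out of range"):
            compute_harmonics(unit_sphere, 0)
        with pytest.raises(ValueError, match="out of range"):
            compute_harmonics(unit_sphere, unit_sphere.n_vertices + 1)


class TestNormals:
    def test_sphere_normals_radial(self, unit_sphere):
        n = vertex_normals(unit_sphere)
        radial = unit_sphere.vertices / np.linalg.norm(
            unit_sphere.vertices, axis=1, keepdims=True
        )
        cos = np.einsum("ij,ij->i", n, radial)
        assert (cos > np.cos(np.radians(2))).all()

    def test_unit_length(self, templates):
        for m in templates.values():
            n = vertex_normals(m)
            assert np.abs(np.linalg.norm(n, axis=1) - 1).max() < 1e-12

    def test_never_inward_on_convex_after_reorientation(self):
        m = icosphere_mesh(2)
        flipped = TriangleMesh(m.vertices, m.faces[:, ::-1]).oriented_copy()
        n = vertex_normals(flipped)
        assert np.einsum("ij,ij->i", n, flipped.vertices).mean() > 0


class TestVoxelize:
    def test_ellipsoid_volume(self):
        m = icosphere_mesh(4, scale=(10.0, 6.0, 4.0))
        spacing, origin, shape = grid_for_mesh(m, [0.5] * 3)
        grid = voxelize(m, spacing, origin, shape)
        assert grid.occupied_volume() == pytest.approx(
            4 / 3 * np.pi * 10 * 6 * 4, rel=0.02
        )

    def test_mesh_outside_grid_rejected(self):
        m = icosphere_mesh(2)
        with pytest.raises(ValueError, match="exceeds"):
            voxelize(m, [0.5] * 3, [0, 0, 0], (3, 3, 3))

    def test_far_voxels_unoccupied(self):
        m = icosphere_mesh(2)
        spacing, origin, shape = grid_for_mesh(m, [0.25] * 3, margin_mm=3.0)
        grid = voxelize(m, spacing, origin, shape)
        assert not grid.occupancy[0].any() and not grid.occupancy[-1].any()


class TestOverlap:
    @staticmethod
    def _box(shift=0):
        occ = np.zeros((10, 10, 10), bool)
        occ[:, :, :] = True
        g = VoxelGrid(occ, [1, 1, 1], [0, 0, 0])
        if shift:
            occ2 = np.zeros_like(occ)
            occ2[shift:] = occ[:-shift]
            return g, VoxelGrid(occ2, [1, 1, 1], [0, 0, 0])
        return g

    def test_identical_grids(self):
        g = self._box()
        fr, dice = overlap_fraction(g, g)
        assert fr == 1.0 and dice == 1.0

    def test_disjoint(self):
        occ = np.zeros((4, 4, 4), bool)
        occ[0, 0, 0] = True
        occ2 = np.zeros_like(occ)
        occ2[3, 3, 3] = True
        fr, dice = overlap_fraction(
            VoxelGrid(occ, [1] * 3, [0] * 3), VoxelGrid(occ2, [1] * 3, [0] * 3)
        )
        assert fr == 0.0 and dice == 0.0

    def test_half_shifted_box(self):
        g, gs = self._box(shift=5)
        fr, _ = overlap_fraction(gs, g)
        assert fr == 0.5

    def test_dice_symmetric(self):
        g, gs = self._box(shift=3)
        _, d1 = overlap_fraction(gs, g)
        _, d2 = overlap_fraction(g, gs)
        assert d1 == d2

    def test_errors(self):
        g = self._box()
        small = VoxelGrid(np.ones((2, 2, 2), bool), [1] * 3, [0] * 3)
        with pytest.raises(ValueError, match="mismatch"):
            overlap_fraction(g, small)
        empty = VoxelGrid(np.zeros((10, 10, 10), bool), [1] * 3, [0] * 3)
        with pytest.raises(ValueError, match="empty"):
            overlap_fraction(g, empty)


class TestIO:
    @pytest.mark.parametrize("ext", ["ply", "off"])
    def test_mesh_round_trip(self, tmp_path, ext):
        m = icosphere_mesh(2, scale=(3, 2, 1))
        path = tmp_path / f"m.{ext}"
        save_mesh(m, path)
        back = load_mesh(path)
        assert np.allclose(back.vertices, m.vertices, atol=1e-4)
        assert np.array_equal(back.faces, m.faces)

    def test_volume_round_trip(self, tmp_path):
        occ = np.zeros((5, 6, 7), bool)
        occ[1:4, 2:5, 3:6] = True
        g = VoxelGrid(occ, [0.5, 0.5, 1.0], [1.0, -2.0, 3.0])
        path = tmp_path / "seg.nii.gz"
        save_volume(g, path)
        back = load_volume(path)
        assert np.array_equal(back.occupancy, g.occupancy)
        assert np.allclose(back.spacing, g.spacing)
        assert np.allclose(back.origin, g.origin)
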