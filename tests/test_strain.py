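"""Green-Lagrange strain on triangulated meshes and AHA regional curves."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cctstrain import phantom, strain
from cctstrain.strain import (
    aha_label,
    area_change,
    deformation_gradient,
    element_bases,
    element_basis,
    green_lagrange,
    regional_curves,
    rotate_strain,
)


class TestElementBasis:
    def test_axis_aligned_case(self):
        # triangle in the y-z plane with +x normal, long axis +z
        tri = np.array([[0.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        e_r, e_th, e_z = element_basis(tri, apex=np.array([5.0, 0.0, -1.0]),
                                       base=np.array([5.0, 0.0, 1.0]))
        assert np.allclose(e_r, [1, 0, 0])
        assert np.allclose(e_z, [0, 0, 1])
        assert np.allclose(e_th, [0, 1, 0])

    def test_triad_is_orthonormal_and_right_handed(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            tri = rng.normal(size=(3, 3))
            apex, base = rng.normal(size=3), rng.normal(size=3)
            try:
                e_r, e_th, e_z = element_basis(tri, apex, base)
            except ValueError:
                continue
            Q = np.stack([e_r, e_th, e_z])
            assert np.allclose(Q @ Q.T, np.eye(3), atol=1e-12)
            assert np.linalg.det(Q) == pytest.approx(1.0, abs=1e-12)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(1)
        tri = rng.normal(size=(3, 3))
        apex, base = rng.normal(size=3), rng.normal(size=3)
        e_r, e_th, e_z = element_basis(tri, apex, base)
        e21, e31 = tri[1] - tri[0], tri[2] - tri[0]
        n = np.cross(e21, e31)
        assert np.allclose(e_r, n / np.linalg.norm(n))
        v = base - apex
        proj = v - (v @ e_r) * e_r
        assert np.allclose(e_z, proj / np.linalg.norm(proj))
        assert np.allclose(e_th, np.cross(e_z, e_r))

    def test_degenerate_inputs_rejected(self):
        tri = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        with pytest.raises(ValueError):
            element_basis(tri, np.zeros(3), np.ones(3))
        flat = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 1.0, 0]])
        with pytest.raises(ValueError):  # long axis parallel to the normal
            element_basis(flat, np.array([0, 0, 0.0]), np.array([0, 0, 2.0]))


class TestDeformationGradient:
    def test_identity_for_identical_triangles(self):
        tri = np.random.default_rng(0).normal(size=(3, 3))
        assert np.allclose(deformation_gradient(tri, tri), np.eye(3),
                           atol=1e-12)

    def test_in_plane_scaling_singular_values(self):
        tri = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 1, 0]])
        scaled = 1.2 * tri
        F = deformation_gradient(tri, scaled)
        sv = np.sort(np.linalg.svd(F, compute_uv=False))
        assert np.allclose(sv, [1.0, 1.2, 1.2], atol=1e-12)

    def test_maps_edges_exactly(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            a, b = rng.normal(size=(3, 3)), rng.normal(size=(3, 3))
            F = deformation_gradient(a, b)
            assert np.allclose(F @ (a[1] - a[0]), b[1] - b[0], atol=1e-10)
            assert np.allclose(F @ (a[2] - a[0]), b[2] - b[0], atol=1e-10)


class TestGreenLagrange:
    def test_identity_and_rotation_give_zero(self):
        assert np.allclose(green_lagrange(np.eye(3)), 0.0)
        R = Rotation.from_euler("xyz", [0.3, -1.0, 2.2]).as_matrix()
        assert np.allclose(green_lagrange(R), 0.0, atol=1e-15)

    def test_diagonal_stretch(self):
        E = green_lagrange(np.diag([1.2, 0.9, 1.0]))
        assert np.allclose(np.diag(E), [0.22, -0.095, 0.0], atol=1e-12)


class TestRotateStrain:
    def test_global_axis_basis_reorders_entries(self):
        E = np.diag([1.0, 2.0, 3.0])
        Q = np.eye(3)[[2, 0, 1]]  # e_r = z, e_theta = x, e_z = y
        E_e, e_tt, e_zz = rotate_strain(E, Q)
        assert e_tt == pytest.approx(1.0)
        assert e_zz == pytest.approx(2.0)

    def test_trace_invariant_under_rotation(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(3, 3))
        E = 0.5 * (A + A.T)
        Q = Rotation.random(random_state=0).as_matrix()
        E_e, _, _ = rotate_strain(E, Q)
        assert np.trace(E_e) == pytest.approx(np.trace(E), abs=1e-12)

    def test_non_orthonormal_basis_rejected(self):
        with pytest.raises(ValueError):
            rotate_strain(np.eye(3), np.eye(3) * 2.0)

    def test_pure_circumferential_stretch_recovers_analytic(self):
        # vertical wall facet under an in-plane horizontal stretch of 0.8
        tri = np.array([[1.0, 0.0, 0.0], [1.0, 0.1, 0.0], [1.0, 0.0, 0.1]])
        scale = np.diag([0.8, 0.8, 1.0])
        F = deformation_gradient(tri, tri @ scale.T)
        E = green_lagrange(F)
        Q = np.stack(element_basis(tri, np.array([0, 0, -1.0]),
                                   np.array([0, 0, 1.0])))
        _, e_tt, e_zz = rotate_strain(E, Q)
        assert e_tt == pytest.approx(-0.18, abs=1e-12)
        assert e_zz == pytest.approx(0.0, abs=1e-12)


class TestAreaChange:
    def test_identity(self):
        tri = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 1, 0]])
        assert area_change(tri, tri) == pytest.approx((1.0, 1.0))

    def test_uniform_scaling(self):
        tri = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 1, 0]])
        ratio, squeez = area_change(tri, 0.8 * tri)
        assert ratio == pytest.approx(0.64, abs=1e-12)
        assert squeez == pytest.approx(0.8, abs=1e-12)

    def test_matches_in_plane_determinant(self):
        rng = np.random.default_rng(4)
        tri = rng.normal(size=(3, 3))
        A = rng.normal(size=(3, 3))
        mapped = tri @ A.T
        ratio, _ = area_change(tri, mapped)
        F = deformation_gradient(tri, mapped)
        # in-plane determinant: product of the two non-unit singular
        # values times the (unit) normal stretch equals det F
        assert ratio == pytest.approx(abs(np.linalg.det(F)), rel=1e-9)

    def test_degenerate_reference_rejected(self):
        tri = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        with pytest.raises(ValueError):
            area_change(tri, tri)


class TestAhaLabel:
    def test_every_triangle_labelled_in_range(self, default_phantom,
                                              reference_segmentation):
        _, _, truth = default_phantom
        _, mesh = reference_segmentation
        labels = aha_label(mesh, truth.landmarks0)
        assert labels.shape == (mesh.n_triangles,)
        assert set(np.unique(labels)) <= set(range(1, 17))
        assert set(np.unique(labels)) == set(range(1, 17))

    def test_axisymmetric_mesh_has_balanced_basal_sectors(
            self, default_phantom):
        spec, _, truth = default_phantom
        mesh = phantom.ellipsoid_cavity_mesh(spec, subdivisions=4)
        labels = aha_label(mesh, truth.landmarks0)
        areas = mesh.triangle_areas()
        basal = [areas[labels == s].sum() for s in range(1, 7)]
        assert max(basal) <= 1.1 * min(basal)

    def test_rotating_septal_landmarks_permutes_ring_labels(
            self, default_phantom):
        spec, _, truth = default_phantom
        mesh = phantom.ellipsoid_cavity_mesh(spec, subdivisions=3)
        lm = dict(truth.landmarks0)
        labels = aha_label(mesh, lm)
        rot = Rotation.from_rotvec([0, 0, np.deg2rad(60.0)])
        lm2 = dict(lm)
        for k in ("septum_1", "septum_2"):
            lm2[k] = spec.centre + rot.apply(lm[k] - spec.centre)
        labels2 = aha_label(mesh, lm2)
        basal = labels <= 6
        expected = (labels[basal] - 1 - 1) % 6 + 1
        frac = (labels2[basal] == expected).mean()
        assert frac > 0.98  # boundary triangles may sit on sector edges

    def test_missing_landmarks_rejected(self, default_phantom):
        spec, _, truth = default_phantom
        mesh = phantom.ellipsoid_cavity_mesh(spec, subdivisions=2)
        lm = dict(truth.landmarks0)
        del lm["septum_1"]
        with pytest.raises(ValueError, match="septum_1"):
            aha_label(mesh, lm)


def _deformed_sequence(spec, truth, mesh, frames_idx):
    return [mesh] + [mesh.with_vertices(truth.deform(mesh.vertices, t))
                     for t in frames_idx[1:]]


class TestRegionalCurves:
    def test_identity_motion_gives_reference_values(self, default_phantom):
        spec, _, truth = default_phantom
        mesh = phantom.cylinder_shell_mesh(spec)
        lm = truth.landmarks0
        apex = lm["apex"]
        base = np.mean([lm[f"mv_{i}"] for i in (1, 2, 3)], axis=0)
        bases = element_bases(mesh, apex, base)
        labels = aha_label(mesh, lm)
        curves = regional_curves([mesh, mesh, mesh], labels, bases)
        assert np.allclose(curves.e_cc, 0.0)
        assert np.allclose(curves.e_ll, 0.0)
        assert np.allclose(curves.area_ratio, 1.0)

    def test_exact_analytic_deformation_recovers_closed_form(
            self, default_phantom):
        spec, _, truth = default_phantom
        mesh = phantom.cylinder_shell_mesh(spec)
        lm = truth.landmarks0
        apex = lm["apex"]
        base = np.mean([lm[f"mv_{i}"] for i in (1, 2, 3)], axis=0)
        bases = element_bases(mesh, apex, base)
        labels = aha_label(mesh, lm)
        meshes = _deformed_sequence(spec, truth, mesh, range(spec.n_frames))
        curves = regional_curves(meshes, labels, bases)
        for t in range(spec.n_frames):
            e_cc, e_ll, ratio = truth.strain(t)
            assert np.allclose(curves.e_cc[t], e_cc, atol=1e-6)
            assert np.allclose(curves.e_ll[t], e_ll, atol=1e-6)
            assert np.allclose(curves.area_ratio[t], ratio, atol=1e-6)

    def test_segment_means_consistent_with_total_area(self, default_phantom):
        spec, _, truth = default_phantom
        mesh = phantom.cylinder_shell_mesh(spec)
        lm = truth.landmarks0
        apex = lm["apex"]
        base = np.mean([lm[f"mv_{i}"] for i in (1, 2, 3)], axis=0)
        bases = element_bases(mesh, apex, base)
        labels = aha_label(mesh, lm)
        deformed = mesh.with_vertices(truth.deform(mesh.vertices, 5))
        curves = regional_curves([mesh, deformed], labels, bases)
        total_ratio = deformed.area() / mesh.area()
        assert np.nanmean(curves.area_ratio[1]) == pytest.approx(
            total_ratio, rel=0.01)

    def test_empty_segment_is_nan_not_zero(self, default_phantom):
        spec, _, truth = default_phantom
        # a short tube restricted to the apical third leaves basal segments
        # unpopulated
        mesh = phantom.cylinder_shell_mesh(spec, z_lo=-0.6, z_hi=-0.3)
        lm = truth.landmarks0
        apex = lm["apex"]
        base = np.mean([lm[f"mv_{i}"] for i in (1, 2, 3)], axis=0)
        bases = element_bases(mesh, apex, base)
        labels = aha_label(mesh, lm)
        curves = regional_curves([mesh, mesh], labels, bases)
        missing = [s for s in range(1, 17)
                   if not np.any(labels == s)]
        assert missing  # the construction leaves at least one segment empty
        for s in missing:
            assert np.isnan(curves.e_cc[:, s - 1]).all()

    def test_csv_round_trip(self, tmp_path, default_phantom):
        spec, _, truth = default_phantom
        mesh = phantom.cylinder_shell_mesh(spec, n_theta=24, n_z=8)
        lm = truth.landmarks0
        apex = lm["apex"]
        base = np.mean([lm[f"mv_{i}"] for i in (1, 2, 3)], axis=0)
        bases = element_bases(mesh, apex, base)
        labels = aha_label(mesh, lm)
        meshes = _deformed_sequence(spec, truth, mesh, range(4))
        curves = regional_curves(meshes, labels, bases)
        p = str(tmp_path / "curves.csv")
        curves.to_csv(p)
        back = strain.StrainCurveSet.from_csv(p)
        assert np.allclose(back.e_cc, curves.e_cc, equal_nan=True)
        assert np.allclose(back.area_ratio, curves.area_ratio, equal_nan=True)


class TestInvariants:
    def test_rigid_motion_produces_zero_strain(self, default_phantom):
        spec, _, truth = default_phantom
        mesh = phantom.ellipsoid_cavity_mesh(spec, subdivisions=2)
        lm = truth.landmarks0
        apex = lm["apex"]
        base = np.mean([lm[f"mv_{i}"] for i in (1, 2, 3)], axis=0)
        bases = element_bases(mesh, apex, base)
        for seed in range(20):
            R = Rotation.random(random_state=seed).as_matrix()
            t = np.random.default_rng(seed).uniform(-5, 5, 3)
            moved = mesh.with_vertices(mesh.vertices @ R.T + t)
            e_cc, e_ll, ratio = strain.frame_strains(mesh, moved, bases)
            assert np.abs(e_cc).max() < 1e-9
            assert np.abs(e_ll).max() < 1e-9
            assert np.abs(ratio - 1.0).max() < 1e-9

    def test_radial_strain_components_vanish(self, default_phantom):
        # the normal-preserving deformation gradient makes the radial row
        # and column of the rotated strain tensor identically zero
        spec, _, truth = default_phantom
        mesh = phantom.ellipsoid_cavity_mesh(spec, subdivisions=3)
        lm = truth.landmarks0
        apex = lm["apex"]
        base = np.mean([lm[f"mv_{i}"] for i in (1, 2, 3)], axis=0)
        bases = element_bases(mesh, apex, base)
        deformed = mesh.with_vertices(truth.deform(mesh.vertices, 5))
        a = strain._edge_normal_matrix(mesh.triangle_corners())
        b = strain._edge_normal_matrix(deformed.triangle_corners())
        F = b @ np.linalg.inv(a)
        E = 0.5 * (np.swapaxes(F, -1, -2) @ F - np.eye(3))
        E_e = bases @ E @ np.swapaxes(bases, -1, -2)
        assert np.abs(E_e[:, 0, :]).max() < 1e-10
        assert np.abs(E_e[:, :, 0]).max() < 1e-10

    def test_labels_and_connectivity_stable_across_frames(
            self, default_phantom):
        spec, _, truth = default_phantom
        mesh = phantom.cylinder_shell_mesh(spec, n_theta=24, n_z=8)
        lm = truth.landmarks0
        apex = lm["apex"]
        base = np.mean([lm[f"mv_{i}"] for i in (1, 2, 3)], axis=0)
        bases = element_bases(mesh, apex, base)
        labels = aha_label(mesh, lm)
        meshes = _deformed_sequence(spec, truth, mesh, range(spec.n_frames))
        curves = regional_curves(meshes, labels, bases)
        assert curves.e_cc.shape == (spec.n_frames, 16)
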