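"""Free-form deformation transform, objective terms and registration."""

import numpy as np
import pytest
from scipy import ndimage

from cctstrain import reg_ffd as rf
from cctstrain.imaging import ImageVolume
from cctstrain.motion import DisplacementField, interpolate_displacement


def _cubic_basis_scalar(t):
    return np.array([(1 - t)**3 / 6,
                     (3 * t**3 - 6 * t**2 + 4) / 6,
                     (-3 * t**3 + 3 * t**2 + 3 * t + 1) / 6,
                     t**3 / 6])


class TestBsplineDisplacement:
    def test_zero_grid_gives_zero(self):
        g = rf.ControlPointGrid.for_domain((0, 0, 0), (10, 10, 10), 2.5)
        d = rf.bspline_displacement(g, np.array([[1.0, 5.0, 9.0]]))
        assert np.allclose(d, 0.0)

    def test_partition_of_unity_reproduces_constants(self):
        g = rf.ControlPointGrid.for_domain((0, 0, 0), (10, 10, 10), 3.0)
        g.disp[:] = np.array([1.5, -2.0, 0.25])
        pts = np.random.default_rng(0).uniform(0, 10, (50, 3))
        d = rf.bspline_displacement(g, pts)
        assert np.allclose(d, [1.5, -2.0, 0.25], atol=1e-12)

    def test_matches_direct_basis_sum(self):
        # brute-force tensor-product sum over the 4^3 supporting controls
        rng = np.random.default_rng(2)
        g = rf.ControlPointGrid.for_domain((0, 0, 0), (12, 12, 12), 4.0)
        g.disp[:] = rng.normal(size=g.disp.shape)
        for pt in rng.uniform(1, 11, (10, 3)):
            u = (pt - g.origin) / g.spacing
            i = np.floor(u).astype(int)
            t = u - i
            w = [_cubic_basis_scalar(t[ax]) for ax in range(3)]
            expected = np.zeros(3)
            for a in range(4):
                for b in range(4):
                    for c in range(4):
                        expected += (w[0][a] * w[1][b] * w[2][c]
                                     * g.disp[i[0] - 1 + a, i[1] - 1 + b,
                                              i[2] - 1 + c])
            got = rf.bspline_displacement(g, pt)
            assert np.allclose(got, expected, atol=1e-12)

    def test_point_outside_domain_rejected(self):
        g = rf.ControlPointGrid.for_domain((0, 0, 0), (10, 10, 10), 2.0)
        with pytest.raises(ValueError):
            rf.bspline_displacement(g, np.array([[50.0, 5.0, 5.0]]))


class TestSsd:
    def _pair(self):
        rng = np.random.default_rng(0)
        a = ndimage.gaussian_filter(rng.normal(size=(16, 16, 16)), 2) * 100
        return ImageVolume(a, 1.0, (0, 0, 0))

    def test_identical_images_zero(self):
        a = self._pair()
        b = ImageVolume(a.data.copy(), 1.0, (0, 0, 0))
        assert rf.ssd(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_gives_k_squared(self):
        a = self._pair()
        b = ImageVolume(a.data + 7.0, 1.0, (0, 0, 0))
        assert rf.ssd(a, b) == pytest.approx(49.0, abs=1e-9)

    def test_transform_matching_shift_cancels_difference(self):
        a = self._pair()
        shifted = np.roll(a.data, 3, axis=0)
        b = ImageVolume(shifted, 1.0, (0, 0, 0))
        g = rf.ControlPointGrid.for_domain((0, 0, 0), (16, 16, 16), 4.0)
        g.disp[..., 0] = 3.0
        inner_a = ImageVolume(a.data[4:-4, 4:-4, 4:-4], 1.0, (4, 4, 4))
        assert rf.ssd(inner_a, b, g) < 1e-9


class TestBendingEnergy:
    def test_zero_displacements(self):
        g = rf.ControlPointGrid.for_domain((0, 0, 0), (10, 10, 10), 2.0)
        assert rf.bending_energy(g) == 0.0

    def test_affine_field_has_zero_bending(self):
        g = rf.ControlPointGrid.for_domain((0, 0, 0), (10, 10, 10), 2.0)
        i, j, k = np.meshgrid(*[np.arange(s) for s in g.shape], indexing="ij")
        g.disp[..., 0] = 0.5 * i - 0.2 * j + k
        g.disp[..., 1] = 1.0 + 2.0 * k
        assert rf.bending_energy(g) == pytest.approx(0.0, abs=1e-20)

    def test_unit_spike_matches_hand_computed_stencils(self):
        g = rf.ControlPointGrid.for_domain((0, 0, 0), (8, 8, 8), 2.0)
        c = tuple(s // 2 for s in g.shape)
        g.disp[c + (0,)] = 1.0
        # along each axis the spike contributes to three stencils:
        # (1)^2 + (-2)^2 + (1)^2 = 6, so 18 over the three axes
        expected = 18.0 / np.prod(g.shape)
        assert rf.bending_energy(g) == pytest.approx(expected, rel=1e-12)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(5)
        g = rf.ControlPointGrid.for_domain((0, 0, 0), (8, 8, 8), 3.0)
        g.disp[:] = rng.normal(size=g.disp.shape)
        grad = rf.bending_gradient(g)
        for _ in range(5):
            idx = tuple(rng.integers(0, s) for s in g.disp.shape)
            eps = 1e-6
            gp = g.copy(); gp.disp[idx] += eps
            gm = g.copy(); gm.disp[idx] -= eps
            fd = (rf.bending_energy(gp) - rf.bending_energy(gm)) / (2 * eps)
            assert grad[idx] == pytest.approx(fd, rel=1e-5, abs=1e-10)


class TestSparsity:
    def test_all_zero(self):
        g = rf.ControlPointGrid.for_domain((0, 0, 0), (8, 8, 8), 2.0)
        assert rf.sparsity_penalty([g]) == 0.0

    def test_single_component_approaches_l1(self):
        g = rf.ControlPointGrid.for_domain((0, 0, 0), (8, 8, 8), 2.0)
        g.disp[2, 2, 2, 0] = 5.0
        val = rf.sparsity_penalty([g], eps=1e-8)
        assert val == pytest.approx(5.0, abs=1e-6)

    def test_two_levels_match_direct_sum(self):
        rng = np.random.default_rng(9)
        gs = []
        for sp in (4.0, 2.0):
            g = rf.ControlPointGrid.for_domain((0, 0, 0), (8, 8, 8), sp)
            g.disp[:] = rng.normal(size=g.disp.shape)
            gs.append(g)
        eps = rf.SPARSITY_EPS
        direct = sum(float(np.sum(np.sqrt(g.disp**2 + eps**2) - eps))
                     for g in gs)
        assert rf.sparsity_penalty(gs) == pytest.approx(direct, rel=1e-12)


class TestObjectiveGradient:
    def test_analytic_gradient_matches_central_differences(self):
        rng = np.random.default_rng(0)
        shape = (12, 12, 12)
        a = ndimage.gaussian_filter(rng.normal(size=shape), 2) * 100
        b = np.roll(a, 1, axis=0)
        ia = ImageVolume(a, 1.0, (0, 0, 0))
        ib = ImageVolume(b, 1.0, (0, 0, 0))
        hyper = rf.FfdHyperparams(theta0=1e-3, theta1=0.1)
        grid = rf.ControlPointGrid.for_domain((0, 0, 0), shape, 4.0)
        grid.disp[:] = rng.normal(0, 0.3, grid.disp.shape)
        problem = rf._LevelProblem(ia, ib, grid, np.zeros((*shape, 3)), hyper,
                                   neighbours=[rng.normal(0, 0.2, grid.disp.shape)],
                                   temporal=True)
        _, g = problem.objective_and_gradient(grid.disp, exact=True)
        for _ in range(15):
            idx = tuple(rng.integers(0, s) for s in grid.disp.shape)
            eps = 1e-5
            xp = grid.disp.copy(); xp[idx] += eps
            xm = grid.disp.copy(); xm[idx] -= eps
            fd = (problem.objective(xp) - problem.objective(xm)) / (2 * eps)
            assert abs(fd - g[idx]) <= 1e-4 * max(abs(fd), 1e-8)


class TestRegisterTsffd:
    def test_identical_frames_give_zero_displacement(self, small_static_phantom):
        _, frames, _ = small_static_phantom
        ref = frames[0]
        same = ImageVolume(ref.data.copy(), ref.spacing, ref.origin, 1)
        stacks = rf.register_tsffd([ref, same], rf.FfdHyperparams())
        disp = rf.stack_displacement(stacks[1], ref.shape, ref.origin,
                                     ref.spacing)
        assert np.abs(disp).max() < 0.1 * float(ref.spacing.min())

    def test_objective_trace_is_monotone(self):
        rng = np.random.default_rng(1)
        shape = (16, 16, 16)
        a = ndimage.gaussian_filter(rng.normal(size=shape), 2) * 200
        b = np.roll(a, 2, axis=1)
        ia = ImageVolume(a, 1.0, (0, 0, 0))
        ib = ImageVolume(b, 1.0, (0, 0, 0))
        hyper = rf.FfdHyperparams(levels=1)
        grid = rf.ControlPointGrid.for_domain((0, 0, 0), shape, 4.0)
        problem = rf._LevelProblem(ia, ib, grid, np.zeros((*shape, 3)), hyper)
        _, trace = rf._optimise_level(problem, hyper)
        assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))

    def test_two_voxel_translation_landmark_error(self, small_static_phantom):
        spec, frames, truth = small_static_phantom
        ref = frames[0]
        shifted = np.roll(frames[1].data, (2, 2, 2), axis=(0, 1, 2))
        tgt = ImageVolume(shifted, ref.spacing, ref.origin, 1)
        stacks = rf.register_tsffd([ref, tgt], rf.FfdHyperparams())
        field = DisplacementField.from_ffd_stack(
            stacks[1], ref.shape, ref.origin, ref.spacing)
        lm = np.array(list(truth.landmarks0.values()))
        moved = lm + interpolate_displacement(field, lm)
        err = np.linalg.norm(moved - (lm + 2.0 * spec.voxel_size), axis=1)
        assert err.mean() < 0.5 * spec.voxel_size

    def test_mismatched_shapes_rejected(self):
        a = ImageVolume(np.zeros((16, 16, 16)), 1.0, (0, 0, 0))
        b = ImageVolume(np.zeros((16, 16, 8)), 1.0, (0, 0, 0))
        with pytest.raises(ValueError):
            rf.register_tsffd([a, b])

    def test_overstiff_bending_suppresses_recovered_motion(
            self, default_phantom):
        # the bending weight balances motion against noise tracking; a
        # weight of 1 freezes the transform and biases strain toward zero
        spec, frames, truth = default_phantom
        pair = [frames[0], frames[spec.n_frames // 2]]
        mags = {}
        for th0 in (5e-6, 1.0):
            stacks = rf.register_tsffd(
                pair, rf.FfdHyperparams(theta0=th0, temporal=False))
            disp = rf.stack_displacement(stacks[1], frames[0].shape,
                                         frames[0].origin, frames[0].spacing)
            mags[th0] = float(np.abs(disp).max())
        assert mags[1.0] < 0.2 * mags[5e-6]


class TestSerialisation:
    def test_stack_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        stack = []
        for level, sp in enumerate((8.0, 4.0)):
            g = rf.ControlPointGrid.for_domain((0, 0, 0), (16, 16, 16), sp,
                                               level)
            g.disp[:] = rng.normal(size=g.disp.shape)
            stack.append(g)
        p = str(tmp_path / "transform.npz")
        rf.save_stack(p, stack)
        back = rf.load_stack(p)
        for a, b in zip(stack, back):
            assert np.array_equal(a.disp, b.disp)
            assert np.allclose(a.origin, b.origin)
            assert a.level == b.level
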