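"""Temporal sparse free-form deformation (TSFFD) registration.

The transform is a stack of cubic B-spline control-point grids at
successively halved spacings (four levels by default, coarsest spacing of
about a quarter of the domain extent); the total displacement is the sum
over levels.  The similarity measure is the mean sum of squared intensity
differences (SSD); regularisation adds a bending-energy term (squared
second finite differences of control displacements, weight ``theta0``), an
epsilon-smoothed L1 sparsity term over all control displacements across
levels (weight ``theta1``), and, in temporal mode, a cyclic first-difference
penalty that couples each frame's control points to its temporal
neighbours.  The objective is minimised per level by a descent line-search
scheme whose direction comes from an inexact (conjugate-gradient) solve of
the damped Gauss-Newton normal equations; only decreasing steps are
accepted, so the objective trace is monotone non-increasing.

All frames of a sequence are registered directly to the reference frame
(frame 0); frame-to-frame accumulation is deliberately avoided because it
compounds tracking error over the cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imaging import ImageVolume

#: extra control points added on each side of the image domain so the
#: cubic support of every in-domain point is fully populated
SUPPORT_MARGIN = 3

SPARSITY_EPS = 1e-2  # mm; smoothing width of the L1 penalty


def bspline_basis(t: np.ndarray) -> np.ndarray:
    """The four cubic B-spline basis weights at fractional offset t in [0,1).

    Returns shape ``t.shape + (4,)``; the weights sum to one (partition of
    unity).
    """
    t = np.asarray(t, dtype=np.float64)
    w = np.empty(t.shape + (4,))
    w[..., 0] = (1 - t) ** 3 / 6.0
    w[..., 1] = (3 * t**3 - 6 * t**2 + 4) / 6.0
    w[..., 2] = (-3 * t**3 + 3 * t**2 + 3 * t + 1) / 6.0
    w[..., 3] = t**3 / 6.0
    return w


@dataclass
class ControlPointGrid:
    """One level of a free-form deformation.

    Control point ``(i, j, k)`` sits at ``origin + (i, j, k) * spacing`` and
    carries a 3-vector displacement in mm (``disp`` has shape
    ``(ni, nj, nk, 3)``).
    """

    origin: np.ndarray
    spacing: np.ndarray
    disp: np.ndarray
    level: int = 0

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        self.spacing = np.broadcast_to(
            np.asarray(self.spacing, dtype=np.float64), (3,)).copy()
        self.disp = np.asarray(self.disp, dtype=np.float64)
        if np.any(self.spacing <= 0):
            raise ValueError("control-point spacing must be positive")
        if self.disp.ndim != 4 or self.disp.shape[3] != 3:
            raise ValueError("disp must have shape (ni, nj, nk, 3)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.disp.shape[:3]

    def copy(self) -> "ControlPointGrid":
        return ControlPointGrid(self.origin, self.spacing, self.disp.copy(),
                                self.level)

    @classmethod
    def for_domain(cls, domain_origin, domain_extent, spacing,
                   level: int = 0) -> "ControlPointGrid":
        """Zero-displacement grid covering a domain plus B-spline support."""
        domain_origin = np.asarray(domain_origin, dtype=np.float64)
        domain_extent = np.asarray(domain_extent, dtype=np.float64)
        spacing = np.broadcast_to(np.asarray(spacing, dtype=np.float64), (3,))
        n = (np.floor(domain_extent / spacing).astype(int) + 1
             + 2 * SUPPORT_MARGIN)
        origin = domain_origin - SUPPORT_MARGIN * spacing
        return cls(origin, spacing, np.zeros((*n, 3)), level)


@dataclass
class FfdHyperparams:
    """Optimiser and regularisation settings for TSFFD.

    ``theta0`` (bending-energy weight) and ``theta1`` (sparsity weight)
    default to the values found optimal for gated cardiac CT by exhaustive
    grid search: 5e-6 and 0.43.  The temporal penalty shares ``theta0``.
    """

    theta0: float = 5e-6
    theta1: float = 0.43
    levels: int = 4
    step_size: float = 1.0  # initial line-search fraction of the GN step
    max_iter: int = 25  # outer (linearisation) steps per level
    tol: float = 1e-6
    temporal: bool = True
    temporal_sweeps: int = 2
    warm_start: bool = True

    def __post_init__(self) -> None:
        if self.theta0 < 0 or self.theta1 < 0:
            raise ValueError("penalty weights must be non-negative")
        if self.levels < 1:
            raise ValueError("at least one level is required")
        if self.step_size <= 0:
            raise ValueError("step size must be positive")


# ---------------------------------------------------------------------------
# B-spline evaluation
# ---------------------------------------------------------------------------


def _support_indices(grid: ControlPointGrid, points: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    u = (points - grid.origin) / grid.spacing
    i = np.floor(u).astype(np.int64)
    t = u - i
    lo = i - 1
    hi = i + 2
    n = np.array(grid.shape)
    if np.any(lo < 0) or np.any(hi > n - 1):
        bad = np.argwhere((lo < 0).any(axis=-1) | (hi > n - 1).any(axis=-1))
        raise ValueError(
            f"point outside the control-grid domain (first offending row "
            f"{bad.ravel()[0] if bad.size else '?'})")
    return i, t


def bspline_displacement(grid: ControlPointGrid, points: np.ndarray
                         ) -> np.ndarray:
    """Cubic tensor-product B-spline displacement at arbitrary mm points."""
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    i, t = _support_indices(grid, pts)
    w = [bspline_basis(t[:, ax]) for ax in range(3)]  # each (n, 4)
    out = np.zeros((pts.shape[0], 3))
    for a in range(4):
        for b in range(4):
            wab = w[0][:, a] * w[1][:, b]
            for c in range(4):
                coeff = wab * w[2][:, c]
                out += coeff[:, None] * grid.disp[
                    i[:, 0] - 1 + a, i[:, 1] - 1 + b, i[:, 2] - 1 + c]
    if np.ndim(points) == 1:
        return out[0]
    return out


def _axis_weight_matrix(grid: ControlPointGrid, axis: int, coords: np.ndarray
                        ) -> np.ndarray:
    """Dense (n_samples, n_ctrl) cubic-weight matrix along one axis."""
    u = (coords - grid.origin[axis]) / grid.spacing[axis]
    i = np.floor(u).astype(np.int64)
    t = u - i
    n = grid.shape[axis]
    if np.any(i - 1 < 0) or np.any(i + 2 > n - 1):
        raise ValueError("sample coordinates outside the control-grid domain")
    w = bspline_basis(t)
    W = np.zeros((coords.size, n))
    rows = np.arange(coords.size)
    for a in range(4):
        W[rows, i - 1 + a] += w[:, a]
    return W


def _lattice_weights(grid: ControlPointGrid, shape, origin, spacing
                     ) -> list[np.ndarray]:
    return [
        _axis_weight_matrix(
            grid, ax, np.asarray(origin)[ax] + np.arange(shape[ax]) * np.asarray(spacing)[ax])
        for ax in range(3)
    ]


def dense_displacement(grid: ControlPointGrid, shape, origin, spacing,
                       weights: list[np.ndarray] | None = None) -> np.ndarray:
    """Displacement of one level sampled on a regular voxel lattice."""
    W = weights if weights is not None else _lattice_weights(
        grid, shape, origin, spacing)
    return np.einsum("ai,bj,ck,ijkd->abcd", W[0], W[1], W[2], grid.disp,
                     optimize=True)


def _project_to_grid(weights: list[np.ndarray], voxel_field: np.ndarray
                     ) -> np.ndarray:
    """Adjoint of :func:`dense_displacement`: scatter a voxel vector field
    onto control points with the same cubic weights."""
    return np.einsum("ai,bj,ck,abcd->ijkd", weights[0], weights[1], weights[2],
                     voxel_field, optimize=True)


def stack_displacement(stack, shape, origin, spacing) -> np.ndarray:
    """Summed dense displacement of a multi-level stack on a voxel lattice."""
    total = np.zeros((*shape, 3))
    for g in stack:
        total += dense_displacement(g, shape, origin, spacing)
    return total


# ---------------------------------------------------------------------------
# objective terms
# ---------------------------------------------------------------------------


def _as_stack(transform) -> list[ControlPointGrid]:
    if transform is None:
        return []
    if isinstance(transform, ControlPointGrid):
        return [transform]
    return list(transform)


def _warp(target: ImageVolume, coords_world: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    idx = (coords_world - target.origin) / target.spacing
    sampled = ndimage.map_coordinates(
        target.data, np.moveaxis(idx, -1, 0), order=1,
        mode="constant", cval=np.nan)
    valid = ~np.isnan(sampled)
    return sampled, valid


def _lattice_world(image: ImageVolume) -> np.ndarray:
    axes = [image.origin[ax] + np.arange(image.shape[ax]) * image.spacing[ax]
            for ax in range(3)]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


def ssd(image_a: ImageVolume, image_b: ImageVolume, transform=None) -> float:
    """Mean squared intensity difference between a and the warped b.

    ``transform`` may be None (identity), a single :class:`ControlPointGrid`
    or a multi-level stack; b is sampled with trilinear interpolation at
    ``x + h(x)`` and out-of-bounds samples are excluded from the mean.
    """
    stack = _as_stack(transform)
    world = _lattice_world(image_a)
    disp = stack_displacement(stack, image_a.shape, image_a.origin,
                              image_a.spacing) if stack else 0.0
    sampled, valid = _warp(image_b, world + disp)
    if not valid.any():
        raise ValueError("no in-bounds samples: domains do not overlap")
    r = sampled[valid] - image_a.data[valid]
    return float(np.mean(r**2))


def bending_energy(grid: ControlPointGrid) -> float:
    """Discrete thin-plate proxy: mean squared second finite differences.

    Second differences of the control displacements are taken along each
    grid axis in index space and the squared values are summed, normalised
    by the number of control points.
    """
    if min(grid.shape) < 3:
        raise ValueError("bending energy needs at least 3 control points per axis")
    total = 0.0
    d = grid.disp
    for ax in range(3):
        dd = np.diff(d, n=2, axis=ax)
        total += float(np.sum(dd**2))
    return total / float(np.prod(grid.shape))


def bending_gradient(grid: ControlPointGrid) -> np.ndarray:
    """Gradient of :func:`bending_energy` w.r.t. the control displacements."""
    g = np.zeros_like(grid.disp)
    d = grid.disp
    n = float(np.prod(grid.shape))
    for ax in range(3):
        dd = np.diff(d, n=2, axis=ax)  # stencil [1, -2, 1]
        sl = [slice(None)] * 4

        def add(offset, coeff):
            sl_ = list(sl)
            sl_[ax] = slice(offset, offset + dd.shape[ax])
            g[tuple(sl_)] += coeff * dd

        add(0, 2.0)
        add(1, -4.0)
        add(2, 2.0)
    return g / n


def sparsity_penalty(grids, eps: float = SPARSITY_EPS) -> float:
    """Epsilon-smoothed L1 norm of all control displacements across levels."""
    total = 0.0
    for g in _as_stack(grids):
        x = g.disp
        total += float(np.sum(np.sqrt(x**2 + eps**2) - eps))
    return total


def sparsity_gradient(grid: ControlPointGrid, eps: float = SPARSITY_EPS
                      ) -> np.ndarray:
    x = grid.disp
    return x / np.sqrt(x**2 + eps**2)


# ---------------------------------------------------------------------------
# single-frame, single-level optimisation
# ---------------------------------------------------------------------------


#: calibrated HU span of CT data; fixes the relative scale of the
#: similarity (mean HU^2) and the dimensionless regularisation terms so the
#: published hyperparameter magnitudes sit in their meaningful regimes
HU_RANGE = 4095.0


class _LevelProblem:
    """Objective and gradient for one frame with one active level.

    The objective combines the mean SSD (HU^2), the bending energy of the
    active level scaled by ``HU_RANGE**2`` and by the inverse squared
    control spacing (so weights around 1e-6..1e-5 balance data fit against
    stiffness while a weight of 1 freezes curved motion), the per-component
    mean of the smoothed-L1 sparsity term, and, in temporal mode, a cyclic
    first-difference coupling to the neighbouring frames' control points
    that shares the bending scale.  Frozen levels contribute a fixed dense
    displacement.
    """

    def __init__(self, ref: ImageVolume, tgt: ImageVolume,
                 active: ControlPointGrid, frozen_disp: np.ndarray,
                 hyper: FfdHyperparams, n_levels_total: int = 1,
                 neighbours: list[np.ndarray] | None = None,
                 temporal: bool = False):
        self.ref = ref
        self.tgt = tgt
        self.active = active
        self.frozen = frozen_disp
        self.hyper = hyper
        self.neighbours = neighbours or []
        self.world = _lattice_world(ref)
        self.weights = _lattice_weights(active, ref.shape, ref.origin,
                                        ref.spacing)
        h2 = float(np.mean(active.spacing)) ** 2
        self.bend_scale = HU_RANGE**2 / h2 * float(np.prod(active.shape))
        self.sparse_scale = 1.0 / active.disp.size
        # temporal coupling shares theta0 and the bending scale, averaged
        # per control point so it stays gentle relative to the data term
        self.temporal_scale = (HU_RANGE**2 / h2 / active.disp.size
                               if temporal else 0.0)
        # first differences of the target per axis: the exact derivative of
        # its trilinear interpolant is their bilinear interpolation within
        # the enclosing cell, which makes the analytic objective gradient
        # match finite differences to rounding error
        self.diff_tgt = [np.diff(tgt.data, axis=ax) / tgt.spacing[ax]
                         for ax in range(3)]
        # smooth surrogate image gradient used only for the descent
        # direction: central differences of the Gaussian-regularised target
        self._surrogate = None

    def _sample_gradient(self, idx: np.ndarray) -> np.ndarray:
        """Exact gradient of the trilinear target interpolant at fractional
        voxel coordinates ``idx`` (..., 3)."""
        coords = np.moveaxis(idx, -1, 0)
        out = np.empty(idx.shape)
        for ax in range(3):
            c = [coords[d].copy() for d in range(3)]
            n = self.tgt.shape[ax]
            c[ax] = np.clip(np.floor(c[ax]), 0, n - 2)
            out[..., ax] = ndimage.map_coordinates(
                self.diff_tgt[ax], c, order=1, mode="constant", cval=0.0)
        return out

    def _sample_surrogate(self, idx: np.ndarray) -> np.ndarray:
        if self._surrogate is None:
            sm = ndimage.gaussian_filter(self.tgt.data, 1.0)
            self._surrogate = np.stack(
                np.gradient(sm, *self.tgt.spacing, edge_order=1), axis=-1)
        coords = np.moveaxis(idx, -1, 0)
        return np.stack([
            ndimage.map_coordinates(self._surrogate[..., d], coords,
                                    order=1, mode="constant", cval=0.0)
            for d in range(3)], axis=-1)

    def _terms(self, disp_ctrl: np.ndarray):
        grid = ControlPointGrid(self.active.origin, self.active.spacing,
                                disp_ctrl, self.active.level)
        disp = self.frozen + dense_displacement(
            grid, self.ref.shape, self.ref.origin, self.ref.spacing,
            self.weights)
        coords = self.world + disp
        sampled, valid = _warp(self.tgt, coords)
        n_valid = int(valid.sum())
        if n_valid == 0:
            raise ValueError("transform maps the whole image out of bounds")
        r = np.where(valid, sampled - self.ref.data, 0.0)
        return grid, coords, r, valid, n_valid

    def _penalties(self, grid: ControlPointGrid, disp_ctrl: np.ndarray
                   ) -> float:
        j = self.hyper.theta0 * self.bend_scale * bending_energy(grid)
        j += (self.hyper.theta1 * self.sparse_scale
              * sparsity_penalty([grid]))
        for nb in self.neighbours:
            j += (self.hyper.theta0 * self.temporal_scale
                  * float(np.sum((disp_ctrl - nb) ** 2)))
        return j

    def objective(self, disp_ctrl: np.ndarray) -> float:
        grid, _, r, valid, n_valid = self._terms(disp_ctrl)
        return (float(np.sum(r**2)) / n_valid
                + self._penalties(grid, disp_ctrl))

    def objective_and_gradient(self, disp_ctrl: np.ndarray, exact: bool = True
                               ) -> tuple[float, np.ndarray]:
        """Objective value and its gradient w.r.t. the active level.

        With ``exact=True`` the similarity gradient is the true derivative
        of the trilinear objective (matches finite differences); with
        ``exact=False`` it uses the smooth surrogate image gradient that
        the optimiser prefers on the piecewise-smooth objective.
        """
        grid, coords, r, valid, n_valid = self._terms(disp_ctrl)
        j = float(np.sum(r**2)) / n_valid
        idx = (coords - self.tgt.origin) / self.tgt.spacing
        gb = (self._sample_gradient(idx) if exact
              else self._sample_surrogate(idx))
        voxel_grad = (2.0 / n_valid) * r[..., None] * gb
        voxel_grad[~valid] = 0.0
        grad = _project_to_grid(self.weights, voxel_grad)
        j += self._penalties(grid, disp_ctrl)
        grad += (self.hyper.theta0 * self.bend_scale
                 * bending_gradient(grid))
        grad += (self.hyper.theta1 * self.sparse_scale
                 * sparsity_gradient(grid))
        for nb in self.neighbours:
            grad += (2.0 * self.hyper.theta0 * self.temporal_scale
                     * (disp_ctrl - nb))
        if not exact:
            gb[~valid] = 0.0
            self._last_gb = gb
            self._last_n_valid = n_valid
        return j, grad

    def gauss_newton_diag(self) -> np.ndarray:
        """Diagonal Gauss-Newton curvature of the data term, used as a
        preconditioner; call after ``objective_and_gradient(exact=False)``."""
        W2 = [w**2 for w in self.weights]
        return (2.0 / self._last_n_valid) * np.einsum(
            "ai,bj,ck,abcd->ijkd", W2[0], W2[1], W2[2], self._last_gb**2,
            optimize=True)


def _optimise_level(problem: _LevelProblem, hyper: FfdHyperparams,
                    max_cg: int = 30) -> tuple[np.ndarray, list[float]]:
    """Inexact Gauss-Newton descent with a backtracking line search.

    Each outer step linearises the warped-image residual around the
    current control displacements, solves the damped Gauss-Newton normal
    equations approximately with matrix-free conjugate gradients (the
    operator applies the B-spline interpolation, the image-gradient
    projection and the bending/temporal stencils, so no matrix is formed),
    and accepts the step through a backtracking line search on the true
    objective.  Only strictly decreasing steps are accepted, so the
    returned trace of objective values is monotone non-increasing.
    """
    x = problem.active.disp.copy()
    j = problem.objective(x)
    trace = [j]
    W = problem.weights
    th0s = hyper.theta0 * problem.bend_scale

    def apply_B(v):
        return np.einsum("ai,bj,ck,ijkd->abcd", W[0], W[1], W[2], v,
                         optimize=True)

    def apply_Bt(u):
        return np.einsum("ai,bj,ck,abcd->ijkd", W[0], W[1], W[2], u,
                         optimize=True)

    def bending_apply(v):
        g = ControlPointGrid(problem.active.origin, problem.active.spacing, v)
        return bending_gradient(g)

    s = min(1.0, hyper.step_size)
    for _ in range(hyper.max_iter):
        j, g = problem.objective_and_gradient(x, exact=False)
        gb = problem._last_gb
        scale = 2.0 / problem._last_n_valid

        def normal_op(v):
            u = apply_B(v)
            w = np.einsum("...i,...i->...", gb, u)[..., None] * gb
            out = scale * apply_Bt(w)
            out += th0s * bending_apply(v)
            if problem.neighbours:
                out += (2.0 * hyper.theta0 * problem.temporal_scale
                        * len(problem.neighbours) * v)
            return out

        diag_scale = scale * float(
            np.einsum("...i,...i->...", gb, gb).mean()) + 1e-30
        lam = 1e-3 * diag_scale
        rhs = -g
        d = np.zeros_like(x)
        r = rhs.copy()
        p = r.copy()
        rs = float(np.sum(r * r))
        rs0 = rs
        if rs0 <= 0:
            break
        for _cg in range(max_cg):
            np_ = normal_op(p) + lam * p
            alpha = rs / max(float(np.sum(p * np_)), 1e-300)
            d += alpha * p
            r -= alpha * np_
            rs_new = float(np.sum(r * r))
            if rs_new < 1e-4 * rs0:
                break
            p = r + (rs_new / rs) * p
            rs = rs_new
        accepted = False
        for _attempt in range(2):
            while s > 1e-6:
                x_try = x + s * d
                j_try = problem.objective(x_try)
                if j_try < j:
                    accepted = True
                    break
                s *= 0.5
            if accepted:
                break
            s = 1.0  # one fresh-step retry before giving up
        if not accepted:
            break
        rel = (j - j_try) / max(abs(j), 1e-300)
        x, j = x_try, j_try
        trace.append(j)
        s = min(2.0 * s, 1.0)
        if rel < hyper.tol:
            break
    return x, trace


def save_stack(path: str, stack: list[ControlPointGrid]) -> None:
    """Serialise a multi-level transform to a compressed npz container.

    The container stores, per level, the grid origin, spacing and
    displacement array; levels reload in order.
    """
    arrays = {}
    for g in stack:
        arrays[f"origin_{g.level}"] = g.origin
        arrays[f"spacing_{g.level}"] = g.spacing
        arrays[f"disp_{g.level}"] = g.disp
    np.savez_compressed(path, levels=np.array([g.level for g in stack]),
                        **arrays)


def load_stack(path: str) -> list[ControlPointGrid]:
    with np.load(path) as z:
        return [ControlPointGrid(z[f"origin_{l}"], z[f"spacing_{l}"],
                                 z[f"disp_{l}"], int(l))
                for l in z["levels"]]


def level_spacings(extent: np.ndarray, levels: int) -> list[float]:
    """Control spacings per level: coarsest about a quarter of the extent,
    halving at each finer level."""
    coarse = float(np.max(extent)) / 4.0
    return [coarse / (2**l) for l in range(levels)]


def _downsample(image: ImageVolume, factor: int) -> ImageVolume:
    """Gaussian-antialiased subsampling for the multi-resolution pyramid."""
    if factor <= 1:
        return image
    data = ndimage.gaussian_filter(image.data, 0.5 * factor)
    return ImageVolume(data[::factor, ::factor, ::factor],
                       image.spacing * factor, image.origin,
                       image.frame_index)


def register_tsffd(sequence: list[ImageVolume], hyper: FfdHyperparams | None = None,
                   verbose: bool = False):
    """Register every frame of a gated sequence to the reference (frame 0).

    Returns a list of multi-level stacks, one per frame (the frame-0 stack
    is identically zero).  Levels are processed coarse to fine; within each
    level, frames are optimised in temporal order with warm-started
    initialisation, and in temporal mode extra sweeps couple each frame to
    its cyclic neighbours through a first-difference penalty weighted by
    ``theta0``.
    """
    hyper = hyper or FfdHyperparams()
    if len(sequence) < 2:
        raise ValueError("at least two frames are required")
    ref = sequence[0]
    for img in sequence[1:]:
        if img.shape != ref.shape:
            raise ValueError("all frames must share the reference image shape")
    extent = np.array(ref.shape) * ref.spacing
    spacings = level_spacings(extent, hyper.levels)
    n_frames = len(sequence)
    stacks: list[list[ControlPointGrid]] = [[] for _ in range(n_frames)]

    for level, sp in enumerate(spacings):
        # multi-resolution pyramid: optimise each level at an image
        # resolution commensurate with its control spacing
        factor = int(np.clip(sp / (2.0 * float(ref.spacing.min())), 1, 4))
        ref_l = _downsample(ref, factor)
        tgts_l = [None] + [_downsample(img, factor) for img in sequence[1:]]
        for t in range(n_frames):
            stacks[t].append(ControlPointGrid.for_domain(
                ref.origin, extent, sp, level))
        sweeps = hyper.temporal_sweeps if (hyper.temporal and n_frames > 2) else 1
        for sweep in range(sweeps):
            for t in range(1, n_frames):
                active = stacks[t][level]
                if (hyper.warm_start and sweep == 0 and t > 1
                        and not active.disp.any()):
                    active.disp[:] = stacks[t - 1][level].disp
                frozen = stack_displacement(
                    stacks[t][:level], ref_l.shape, ref_l.origin,
                    ref_l.spacing
                ) if level else np.zeros((*ref_l.shape, 3))
                neighbours = []
                if hyper.temporal and sweep > 0:
                    neighbours = [stacks[(t - 1) % n_frames][level].disp,
                                  stacks[(t + 1) % n_frames][level].disp]
                problem = _LevelProblem(ref_l, tgts_l[t], active, frozen,
                                        hyper, hyper.levels, neighbours,
                                        temporal=bool(neighbours))
                active.disp, trace = _optimise_level(problem, hyper)
                if verbose:
                    print(f"level {level} frame {t} sweep {sweep}: "
                          f"J {trace[0]:.4g} -> {trace[-1]:.4g} "
                          f"({len(trace) - 1} steps)")
    return stacks
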