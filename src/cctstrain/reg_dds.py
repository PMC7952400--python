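"""Dense displacement sampling (DDS) registration.

A discrete, MRF-style deformable registration: control points on a uniform
voxel lattice each choose one displacement label from a quantised 3D search
region; the data term is the mean Hamming distance between binarised
self-similarity-context (SSC) descriptors over a patch, and smoothness is a
squared-difference penalty between neighbouring labels, weighted by a
single hyperparameter ``theta`` (default 0.5, the value found optimal for
gated cardiac CT).  Neighbourhood relations are approximated by a
minimum spanning tree of the control lattice, on which the labelling
problem is solved exactly by leaf-to-root min-sum message passing.

Registration runs as a sequence of passes over the full-resolution image
with decreasing control spacings (8, 7, 6, 5, 4 voxels by default), each
pass composing its incremental field with the running estimate.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .imaging import ImageVolume

SSC_BITS = 12  # pairwise comparisons between the six neighbourhood offsets


@dataclass
class DdsHyperparams:
    """Smoothness weight and level schedule for DDS registration.

    ``spacings`` are the control-point spacings (voxels) of the successive
    passes over the full-resolution image; ``steps`` are the matching
    displacement quantisations, decreasing to one voxel at the finest pass
    so any integer displacement is reachable; the search radius of each
    pass equals its control spacing.
    """

    theta: float = 0.5
    spacings: tuple[int, ...] = (8, 7, 6, 5, 4)
    steps: tuple[int, ...] = (4, 4, 2, 2, 1)
    patch_sigma: float = 0.8  # Gaussian weighting of descriptor patches, voxels
    zero_bias: float = 0.2  # tie-breaking prior toward zero labels, coarse levels

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise ValueError("theta must be non-negative")
        sp = tuple(int(s) for s in self.spacings)
        if any(s <= 0 for s in sp):
            raise ValueError("spacings must be positive")
        if any(a < b for a, b in zip(sp, sp[1:])):
            raise ValueError("spacings must be non-increasing")
        self.spacings = sp
        st = tuple(int(s) for s in self.steps)
        if len(st) != len(sp):
            raise ValueError("one quantisation step per level is required")
        if any(s <= 0 for s in st):
            raise ValueError("quantisation steps must be positive")
        self.steps = st


@dataclass
class DisplacementLabelSpace:
    """Quantised, zero-centred 3D displacement labels (voxel units)."""

    radius: int
    step: int
    offsets: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.radius < 0 or self.step <= 0:
            raise ValueError("radius must be >= 0 and step > 0")
        k = self.radius // self.step
        axis = np.arange(-k, k + 1) * self.step
        grid = np.stack(np.meshgrid(axis, axis, axis, indexing="ij"), axis=-1)
        self.offsets = grid.reshape(-1, 3).astype(np.int64)

    @property
    def n_labels(self) -> int:
        return self.offsets.shape[0]

    @property
    def zero_index(self) -> int:
        return int(np.argwhere((self.offsets == 0).all(axis=1))[0, 0])


# ---------------------------------------------------------------------------
# self-similarity context descriptors
# ---------------------------------------------------------------------------

_OFFSETS_6 = np.array([
    [1, 0, 0], [-1, 0, 0],
    [0, 1, 0], [0, -1, 0],
    [0, 0, 1], [0, 0, -1],
], dtype=np.int64)

# the 12 unordered pairs of non-opposite 6-neighbourhood offsets
_PAIRS_12 = [(i, j) for i in range(6) for j in range(i + 1, 6)
             if not np.array_equal(_OFFSETS_6[i], -_OFFSETS_6[j])]
assert len(_PAIRS_12) == SSC_BITS


def _shift(volume: np.ndarray, offset: np.ndarray) -> np.ndarray:
    """volume evaluated at x + offset, replicating the border."""
    out = volume
    for ax, o in enumerate(offset):
        if o:
            out = np.take(out, np.clip(np.arange(out.shape[ax]) + o, 0,
                                       out.shape[ax] - 1), axis=ax)
    return out


def ssc_descriptor(image: ImageVolume, sigma: float = 0.8,
                   noise_gate: float = 8.0) -> np.ndarray:
    """Binarised self-similarity-context descriptors, packed into uint16.

    For each voxel, the Gaussian-weighted patch SSD is computed between the
    12 non-opposite pairs of its 6-neighbourhood offsets; distances are
    turned into self-similarities ``exp(-D / mean_channel_D)`` and each
    channel is binarised against the voxel's mean channel value (ties give
    0, so a constant image yields all-zero descriptors).  Voxels whose mean
    channel distance falls below ``noise_gate`` times the volume median are
    treated as structureless and binarise to all-zero: without the gate,
    featureless regions (air, homogeneous blood pool) produce random bits
    from image noise that poison the matching cost.  The descriptor is
    invariant to positive affine intensity rescaling (the gate threshold is
    a ratio, so it is too).
    """
    if min(image.shape) < 5:
        raise ValueError("image too small for the descriptor patch support")
    data = image.data
    dists = np.empty((SSC_BITS,) + data.shape)
    for b, (i, j) in enumerate(_PAIRS_12):
        diff = _shift(data, _OFFSETS_6[i]) - _shift(data, _OFFSETS_6[j])
        dists[b] = ndimage.gaussian_filter(diff**2, sigma)
    mean_d = dists.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        sims = np.exp(-dists / np.maximum(mean_d, 1e-30))
    sims[:, mean_d <= 0] = 1.0  # flat region: all channels tie
    mean_s = sims.mean(axis=0)
    bits = sims > mean_s  # strict: ties binarise to 0
    if noise_gate > 0:
        bits[:, mean_d < noise_gate * np.median(mean_d)] = False
    packed = np.zeros(data.shape, dtype=np.uint16)
    for b in range(SSC_BITS):
        packed |= bits[b].astype(np.uint16) << b
    return packed


def hamming_volume(desc_a: np.ndarray, desc_b: np.ndarray) -> np.ndarray:
    """Per-voxel Hamming distance between packed descriptor volumes."""
    return np.bitwise_count(desc_a ^ desc_b).astype(np.float64)


# ---------------------------------------------------------------------------
# unary costs
# ---------------------------------------------------------------------------


def control_lattice(shape, spacing: int) -> np.ndarray:
    """Voxel indices of control points: a uniform lattice with the given
    spacing, inset by half a spacing; shape (n0, n1, n2, 3)."""
    axes = [np.arange(spacing // 2, s, spacing) for s in shape]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


def unary_costs(desc_ref: np.ndarray, desc_tgt: np.ndarray,
                grid_points: np.ndarray, labels: DisplacementLabelSpace,
                patch_halfwidth: int = 2) -> np.ndarray:
    """Data cost per (control point, label): mean Hamming distance between
    reference descriptors around p and target descriptors around p + f.

    Patches straddling the border are evaluated with border replication;
    a label whose displaced patch loses all overlap with the image (centre
    out of bounds by at least the patch halfwidth) costs +inf.  Returns
    shape ``(n_points, n_labels)``.
    """
    if labels.n_labels == 0:
        raise ValueError("empty label space")
    pts = grid_points.reshape(-1, 3)
    shape = np.array(desc_ref.shape)
    size = 2 * patch_halfwidth + 1
    costs = np.empty((pts.shape[0], labels.n_labels))
    for li, f in enumerate(labels.offsets):
        shifted = _shift(desc_tgt, f)
        ham = hamming_volume(desc_ref, shifted)
        mean_ham = ndimage.uniform_filter(ham, size=size, mode="nearest")
        vals = mean_ham[tuple(pts.T)]
        moved = pts + f
        oob = ((moved < -patch_halfwidth)
               | (moved > shape - 1 + patch_halfwidth)).any(axis=1)
        vals = np.where(oob, np.inf, vals)
        costs[:, li] = vals
    return costs


# ---------------------------------------------------------------------------
# minimum spanning tree
# ---------------------------------------------------------------------------


def lattice_edges(grid_shape) -> np.ndarray:
    """6-neighbour edges of a control lattice, as flat index pairs."""
    n = np.array(grid_shape, dtype=np.int64)
    idx = np.arange(int(np.prod(n))).reshape(tuple(n))
    edges = []
    for ax in range(3):
        a = np.take(idx, np.arange(n[ax] - 1), axis=ax).ravel()
        b = np.take(idx, np.arange(1, n[ax]), axis=ax).ravel()
        edges.append(np.stack([a, b], axis=1))
    return np.concatenate(edges, axis=0)


def build_mst(n_nodes: int, edges: np.ndarray, weights: np.ndarray
              ) -> tuple[np.ndarray, int]:
    """Prim's minimum spanning tree with deterministic tie-breaking.

    Ties on edge weight are broken by lexicographic (weight, parent, node)
    ordering; the root is node 0.  Returns ``(parent, root)`` where
    ``parent[root] = -1``.  Raises if the edge set does not connect all
    nodes.
    """
    adj: list[list[tuple[int, float]]] = [[] for _ in range(n_nodes)]
    for (a, b), w in zip(np.asarray(edges), np.asarray(weights, dtype=float)):
        adj[int(a)].append((int(b), w))
        adj[int(b)].append((int(a), w))
    parent = np.full(n_nodes, -2, dtype=np.int64)
    parent[0] = -1
    heap: list[tuple[float, int, int]] = []
    for nb, w in adj[0]:
        heapq.heappush(heap, (w, 0, nb))
    n_in = 1
    while heap and n_in < n_nodes:
        w, par, node = heapq.heappop(heap)
        if parent[node] != -2:
            continue
        parent[node] = par
        n_in += 1
        for nb, w2 in adj[node]:
            if parent[nb] == -2:
                heapq.heappush(heap, (w2, node, nb))
    if n_in < n_nodes:
        raise ValueError("edge set does not connect all control points")
    return parent, 0


def mst_edge_weights(image: ImageVolume, grid_points: np.ndarray,
                     patch_halfwidth: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Edges and weights for the control-lattice MST.

    The weight of an edge is the absolute difference of mean patch
    intensity between its two control points in the reference image, so
    the tree prefers not to cross tissue boundaries.
    """
    gshape = grid_points.shape[:3]
    pts = grid_points.reshape(-1, 3)
    size = 2 * patch_halfwidth + 1
    mean_int = ndimage.uniform_filter(image.data, size=size, mode="nearest")
    feat = mean_int[tuple(pts.T)]
    edges = lattice_edges(gshape)
    weights = np.abs(feat[edges[:, 0]] - feat[edges[:, 1]])
    return edges, weights


# ---------------------------------------------------------------------------
# exact inference on the tree
# ---------------------------------------------------------------------------


def _children_and_order(parent: np.ndarray, root: int
                        ) -> tuple[list[list[int]], list[int]]:
    n = parent.size
    children: list[list[int]] = [[] for _ in range(n)]
    for node in range(n):
        if node != root:
            children[parent[node]].append(node)
    order: list[int] = []
    stack = [root]
    while stack:
        node = stack.pop()
        order.append(node)
        stack.extend(children[node])
    return children, order


def mst_minsum(costs: np.ndarray, parent: np.ndarray, root: int,
               theta: float, labels: DisplacementLabelSpace) -> np.ndarray:
    """Exact MAP labelling on a tree by min-sum message passing.

    Minimises ``sum_p cost(p, f_p) + theta * sum_(p,q) ||f_p - f_q||^2``
    over the tree edges; ties in the backtracking argmin resolve to the
    lowest label index.  Returns the label index per node.
    """
    n_nodes, n_labels = costs.shape
    if np.any(np.all(~np.isfinite(costs), axis=1)):
        raise ValueError("a node has no finite-cost label")
    off = labels.offsets.astype(np.float64)
    d2 = np.sum((off[:, None, :] - off[None, :, :]) ** 2, axis=-1)
    pair = theta * d2  # (label_child, label_parent)
    children, order = _children_and_order(parent, root)
    acc = costs.copy()
    argmins = np.zeros((n_nodes, n_labels), dtype=np.int64)
    for node in reversed(order):
        if node == root:
            continue
        total = acc[node][:, None] + pair  # (own label, parent label)
        argmins[node] = np.argmin(total, axis=0)
        acc[parent[node]] += total[argmins[node], np.arange(n_labels)]
    labelling = np.zeros(n_nodes, dtype=np.int64)
    labelling[root] = int(np.argmin(acc[root]))
    for node in order:
        if node == root:
            continue
        labelling[node] = argmins[node][labelling[parent[node]]]
    return labelling


# ---------------------------------------------------------------------------
# full registration
# ---------------------------------------------------------------------------


def _interpolate_labels_dense(grid_points: np.ndarray, disp_vox: np.ndarray,
                              shape, order: int = 1) -> np.ndarray:
    """Interpolate control-point displacements to every voxel.

    Linear interpolation is the default: with discrete labels it is free of
    the ringing that higher-order splines introduce next to isolated label
    changes, which otherwise accumulates across composed levels.
    """
    gshape = grid_points.shape[:3]
    disp = disp_vox.reshape(*gshape, 3)
    out = np.empty((*shape, 3))
    # control lattice coordinates are affine in voxel index:
    # index = (voxel - first) / spacing per axis
    first = grid_points.reshape(-1, 3).min(axis=0)
    spacing = np.array([
        grid_points[1, 0, 0, 0] - grid_points[0, 0, 0, 0] if gshape[0] > 1 else 1,
        grid_points[0, 1, 0, 1] - grid_points[0, 0, 0, 1] if gshape[1] > 1 else 1,
        grid_points[0, 0, 1, 2] - grid_points[0, 0, 0, 2] if gshape[2] > 1 else 1,
    ], dtype=np.float64)
    axes = [(np.arange(shape[ax]) - first[ax]) / spacing[ax] for ax in range(3)]
    coords = np.stack(np.meshgrid(*axes, indexing="ij"), axis=0)
    coords = coords.reshape(3, -1)
    for d in range(3):
        out[..., d] = ndimage.map_coordinates(
            disp[..., d], coords, order=order, mode="nearest").reshape(shape)
    return out


def _compose(inc: np.ndarray, prev: np.ndarray) -> np.ndarray:
    """phi_new(x) = inc(x) + prev(x + inc(x)) on the voxel lattice."""
    shape = inc.shape[:3]
    base = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"),
                    axis=-1).astype(np.float64)
    coords = (base + inc).reshape(-1, 3).T
    warped_prev = np.stack([
        ndimage.map_coordinates(prev[..., d], coords, order=1, mode="nearest"
                                ).reshape(shape)
        for d in range(3)], axis=-1)
    return inc + warped_prev


def _warp_image(image: ImageVolume, disp_vox: np.ndarray) -> ImageVolume:
    shape = image.shape
    base = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"),
                    axis=-1).astype(np.float64)
    coords = (base + disp_vox).reshape(-1, 3).T
    data = ndimage.map_coordinates(image.data, coords, order=1, mode="nearest"
                                   ).reshape(shape)
    return ImageVolume(data, image.spacing, image.origin, image.frame_index)


def _warp_image_nn(image: ImageVolume, disp_vox: np.ndarray) -> ImageVolume:
    """Warp with the rounded field and nearest-neighbour gathers.

    Used for descriptor extraction during the pyramid: trilinear
    resampling blurs the warped image wherever the running field is
    fractional, which degrades the self-similarity descriptors; rounding
    keeps every gathered patch crisp at the cost of at most half a voxel
    of quantisation."""
    shape = np.array(image.shape)
    base = np.stack(np.meshgrid(*[np.arange(s) for s in image.shape],
                                indexing="ij"), axis=-1)
    co = np.clip(np.round(base + disp_vox).astype(np.int64), 0, shape - 1)
    data = image.data[co[..., 0], co[..., 1], co[..., 2]]
    return ImageVolume(data, image.spacing, image.origin, image.frame_index)


def register_dds(reference: ImageVolume, target: ImageVolume,
                 hyper: DdsHyperparams | None = None, verbose: bool = False
                 ) -> np.ndarray:
    """Dense displacement field (voxel units, reference -> target).

    Runs one discrete-labelling pass per control spacing on the
    full-resolution image; each pass searches displacements up to the
    spacing at its quantisation step, and composes its incremental field
    with the running estimate.  The returned array has shape
    ``(*reference.shape, 3)``.
    """
    hyper = hyper or DdsHyperparams()
    if reference.shape != target.shape:
        raise ValueError("reference and target must share the same domain")
    if min(reference.shape) < 4 * hyper.spacings[0] // 2:
        raise ValueError("image too small for the coarsest control spacing")
    field_total = np.zeros((*reference.shape, 3))
    desc_ref = ssc_descriptor(reference, hyper.patch_sigma)
    for level, spacing in enumerate(hyper.spacings):
        step = hyper.steps[level]
        warped = _warp_image_nn(target, field_total)
        desc_tgt = ssc_descriptor(warped, hyper.patch_sigma)
        pts = control_lattice(reference.shape, spacing)
        labels = DisplacementLabelSpace(radius=spacing, step=step)
        hw = max(1, spacing // 2)
        costs = unary_costs(desc_ref, desc_tgt, pts, labels,
                            patch_halfwidth=hw)
        if step > 1 and hyper.zero_bias > 0:
            # prefer keeping the running estimate while the quantisation is
            # still coarse: residuals below the step are data-ambiguous and
            # would otherwise dither between bracketing labels
            costs = costs + hyper.zero_bias * np.linalg.norm(
                labels.offsets / step, axis=1)[None, :]
        edges, weights = mst_edge_weights(reference, pts, patch_halfwidth=hw)
        parent, root = build_mst(pts.reshape(-1, 3).shape[0], edges, weights)
        labelling = mst_minsum(costs, parent, root, hyper.theta, labels)
        disp_vox = labels.offsets[labelling].astype(np.float64)
        inc = _interpolate_labels_dense(pts, disp_vox, reference.shape)
        field_total = _compose(inc, field_total)
        if verbose:
            mags = np.linalg.norm(disp_vox, axis=1)
            print(f"level {level} spacing {spacing}: "
                  f"mean |label| {mags.mean():.2f} vox")
    return field_total
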