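"""Image handling, blood-pool segmentation and endocardial mesh generation.

Volumes are 3D scalar grids in Hounsfield units with an isotropic or
anisotropic voxel spacing.  The coordinate convention used throughout the
package is: voxel indices are 0-based, array axis ``i`` corresponds to
world axis ``i``, and ``world = origin + index * spacing`` (millimetres).
Direction cosines beyond an axis-aligned affine are not modelled; NIfTI
volumes written here carry a diagonal affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import trimesh
from scipy import ndimage
from skimage.measure import marching_cubes


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ImageVolume:
    """A 3D scalar volume (HU) with voxel spacing and world origin in mm."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.spacing = np.broadcast_to(
            np.asarray(self.spacing, dtype=np.float64), (3,)
        ).copy()
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3).copy()
        if self.data.ndim != 3:
            raise ValueError("image data must be 3-dimensional")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_to_world(self, index: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices to world mm coordinates."""
        return self.origin + np.asarray(index, dtype=np.float64) * self.spacing

    def world_to_voxel(self, point: np.ndarray) -> np.ndarray:
        """Map world mm coordinates to fractional voxel indices."""
        return (np.asarray(point, dtype=np.float64) - self.origin) / self.spacing

    def sample(self, points: np.ndarray, order: int = 1) -> np.ndarray:
        """Interpolate intensities at world-coordinate points (mm)."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        idx = (pts - self.origin) / self.spacing
        return ndimage.map_coordinates(self.data, idx.T, order=order, mode="nearest")

    def to_nifti(self) -> nib.Nifti1Image:
        affine = np.diag(np.append(self.spacing, 1.0))
        affine[:3, 3] = self.origin
        return nib.Nifti1Image(self.data.astype(np.float32), affine)

    def save(self, path: str) -> None:
        nib.save(self.to_nifti(), path)

    @classmethod
    def load(cls, path: str, frame_index: int = 0) -> "ImageVolume":
        img = nib.load(path)
        affine = img.affine
        data = np.asanyarray(img.dataobj, dtype=np.float64)
        # tolerate axis flips in the affine by resampling to a positive-
        # spacing convention: keep the diagonal magnitudes, flip data axes
        # where the diagonal is negative.
        spacing = np.abs(np.diag(affine)[:3])
        origin = affine[:3, 3].copy()
        for ax in range(3):
            if affine[ax, ax] < 0:
                data = np.flip(data, axis=ax)
                origin[ax] = origin[ax] + affine[ax, ax] * (data.shape[ax] - 1)
        return cls(data, spacing, origin, frame_index)


@dataclass
class BinaryMask:
    """A boolean volume aligned voxel-for-voxel with a source :class:`ImageVolume`."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        self.spacing = np.broadcast_to(
            np.asarray(self.spacing, dtype=np.float64), (3,)
        ).copy()
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3).copy()

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def volume_mm3(self) -> float:
        """Foreground volume: voxel count times voxel volume."""
        return float(self.data.sum()) * float(np.prod(self.spacing))

    def save(self, path: str) -> None:
        affine = np.diag(np.append(self.spacing, 1.0))
        affine[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(self.data.astype(np.uint8), affine), path)


@dataclass
class SurfaceMesh:
    """Triangulated surface, vertices in world mm, counter-clockwise triangles.

    ``labels`` optionally stores one AHA segment id (1-16) per triangle.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    labels: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be (m, 3)")

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_triangles(self) -> int:
        return self.triangles.shape[0]

    def triangle_corners(self) -> np.ndarray:
        """Vertex coordinates per triangle, shape (m, 3, 3)."""
        return self.vertices[self.triangles]

    def triangle_areas(self) -> np.ndarray:
        c = self.triangle_corners()
        cross = np.cross(c[:, 1] - c[:, 0], c[:, 2] - c[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def triangle_centroids(self) -> np.ndarray:
        return self.triangle_corners().mean(axis=1)

    def area(self) -> float:
        return float(self.triangle_areas().sum())

    def enclosed_volume(self) -> float:
        """Unsigned enclosed volume by the divergence theorem (closed mesh)."""
        c = self.triangle_corners()
        v = np.einsum("ij,ij->i", c[:, 0], np.cross(c[:, 1], c[:, 2]))
        return abs(float(v.sum())) / 6.0

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices.copy(),
            faces=self.triangles.copy(),
            process=False,
        )

    def with_vertices(self, vertices: np.ndarray) -> "SurfaceMesh":
        """Same connectivity and labels, new vertex positions."""
        return SurfaceMesh(np.asarray(vertices, dtype=np.float64),
                           self.triangles.copy(),
                           None if self.labels is None else self.labels.copy())

    def save(self, path: str) -> None:
        self.to_trimesh().export(path)

    @classmethod
    def load(cls, path: str) -> "SurfaceMesh":
        tm = trimesh.load(path, process=False)
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def crop_to_bounding_box(image: ImageVolume, box) -> ImageVolume:
    """Crop to half-open voxel index ranges ``((i0, i1), (j0, j1), (k0, k1))``.

    The origin is shifted so world coordinates of the retained voxels are
    unchanged.
    """
    box = [(int(lo), int(hi)) for lo, hi in box]
    for ax, (lo, hi) in enumerate(box):
        if not (0 <= lo < hi <= image.shape[ax]):
            raise ValueError(f"bounding box empty or out of range on axis {ax}")
    sl = tuple(slice(lo, hi) for lo, hi in box)
    lo_idx = np.array([lo for lo, _ in box], dtype=np.float64)
    return ImageVolume(
        image.data[sl].copy(),
        image.spacing,
        image.origin + lo_idx * image.spacing,
        image.frame_index,
    )


_STRUCT_6 = ndimage.generate_binary_structure(3, 1)


def region_grow(image: ImageVolume, seeds, margin: float = 30.0) -> BinaryMask:
    """Grey-value region growing from seed voxels.

    The admissible band is ``[min(seed HU) - margin, max(seed HU) + margin]``;
    the mask is the union of 6-connected components of in-band voxels that
    contain a seed.
    """
    seeds = np.atleast_2d(np.asarray(seeds, dtype=np.int64))
    if seeds.size == 0:
        raise ValueError("at least one seed voxel is required")
    if margin < 0:
        raise ValueError("margin must be non-negative")
    for s in seeds:
        if np.any(s < 0) or np.any(s >= np.array(image.shape)):
            raise ValueError(f"seed {tuple(s)} lies outside the image")
    seed_vals = image.data[tuple(seeds.T)]
    lo, hi = seed_vals.min() - margin, seed_vals.max() + margin
    band = (image.data >= lo) & (image.data <= hi)
    lab, _ = ndimage.label(band, structure=_STRUCT_6)
    keep = np.unique(lab[tuple(seeds.T)])
    keep = keep[keep > 0]
    mask = np.isin(lab, keep)
    return BinaryMask(mask, image.spacing, image.origin)


def _signed_distance_2d(mask2d: np.ndarray, sampling) -> np.ndarray:
    """Positive inside, negative outside; zero level sits between voxels."""
    mask2d = np.asarray(mask2d, dtype=bool)
    inside = ndimage.distance_transform_edt(mask2d, sampling=sampling)
    outside = ndimage.distance_transform_edt(~mask2d, sampling=sampling)
    return inside - outside


def interpolate_segmentation(
    slice_masks: dict[int, np.ndarray],
    target_shape,
    spacing=(1.0, 1.0, 1.0),
    origin=(0.0, 0.0, 0.0),
    axis: int = 2,
) -> BinaryMask:
    """Fill a sparse stack of 2D annotations into a 3D mask.

    Annotated slices are reproduced exactly; slices between two annotations
    are filled by linear interpolation of per-slice signed distance maps,
    thresholded at zero.  Slices outside the annotated range are empty.
    """
    if len(slice_masks) < 2:
        raise ValueError("at least two annotated slices are required")
    target_shape = tuple(int(s) for s in target_shape)
    spacing = np.broadcast_to(np.asarray(spacing, dtype=np.float64), (3,))
    in_plane = tuple(spacing[ax] for ax in range(3) if ax != axis)
    indices = sorted(slice_masks)
    if indices[0] < 0 or indices[-1] >= target_shape[axis]:
        raise ValueError("annotated slice index outside the target shape")
    sdms = {i: _signed_distance_2d(slice_masks[i], in_plane) for i in indices}
    out = np.zeros(target_shape, dtype=bool)

    def put(i, plane):
        sl = [slice(None)] * 3
        sl[axis] = i
        out[tuple(sl)] = plane

    for i in indices:
        put(i, np.asarray(slice_masks[i], dtype=bool))
    for a, b in zip(indices[:-1], indices[1:]):
        for i in range(a + 1, b):
            w = (i - a) / (b - a)
            put(i, (1 - w) * sdms[a] + w * sdms[b] > 0)
    return BinaryMask(out, spacing, origin)


def extract_surface(mask: BinaryMask, iso: float = 0.5, presmooth_sigma: float = 1.0
                    ) -> SurfaceMesh:
    """Marching-cubes endocardial surface from a binary mask, in world mm.

    The binary field is softened with a small Gaussian (in voxels) before
    contouring so the zero-level surface is smooth rather than a voxel
    staircase; ``presmooth_sigma=0`` contours the raw binary field.
    """
    if not mask.data.any():
        raise ValueError("mask is empty")
    f = mask.data.astype(np.float64)
    if presmooth_sigma > 0:
        f = ndimage.gaussian_filter(f, presmooth_sigma)
    # pad so surfaces touching the boundary still close
    f = np.pad(f, 1, mode="constant")
    verts, faces, _, _ = marching_cubes(f, level=iso, spacing=tuple(mask.spacing))
    verts = verts - mask.spacing  # undo padding shift
    verts = verts + mask.origin
    mesh = SurfaceMesh(verts, faces)
    # orient consistently, normals outward
    tm = mesh.to_trimesh()
    tm.fix_normals()
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def smooth_mesh(mesh: SurfaceMesh, iterations: int = 10) -> SurfaceMesh:
    """Volume-preserving Taubin smoothing.

    Runs the classic lambda/mu pass-band scheme, then rescales about the
    centroid so enclosed volume is preserved (well within the 0.5%
    contract).
    """
    if iterations == 0:
        return mesh.with_vertices(mesh.vertices.copy())
    tm = mesh.to_trimesh()
    v0 = tm.volume
    trimesh.smoothing.filter_taubin(tm, lamb=0.5, nu=-0.53, iterations=iterations)
    if abs(v0) > 0:
        centroid = tm.vertices.mean(axis=0)
        scale = (abs(v0) / abs(tm.volume)) ** (1.0 / 3.0)
        tm.vertices = centroid + scale * (tm.vertices - centroid)
    out = mesh.with_vertices(np.asarray(tm.vertices))
    return SurfaceMesh(out.vertices, np.asarray(tm.faces), out.labels)


def surface_to_mask_distance(mesh: SurfaceMesh, mask: BinaryMask) -> float:
    """Mean unsigned distance (mm) from mesh vertices to the mask boundary.

    The boundary is the 0-level of the voxel signed-distance field
    (positive inside), sampled with trilinear interpolation at each vertex.
    """
    if not mask.data.any():
        raise ValueError("mask is empty")
    inside = ndimage.distance_transform_edt(mask.data, sampling=mask.spacing)
    outside = ndimage.distance_transform_edt(~mask.data, sampling=mask.spacing)
    # shift both transforms by half a voxel so the zero level sits at the
    # voxel-boundary interface rather than at voxel centres
    half = 0.5 * float(np.mean(mask.spacing))
    sdf = np.where(mask.data, inside - half, -(outside - half))
    idx = (mesh.vertices - mask.origin) / mask.spacing
    vals = ndimage.map_coordinates(sdf, idx.T, order=1, mode="nearest")
    return float(np.mean(np.abs(vals)))
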