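"""Turn registration output into deformed meshes and propagated landmarks.

A registration result — whether a B-spline control-point stack or a dense
voxel field — is first rasterised onto a regular sample lattice; mesh
vertices and landmarks are then moved by the trilinearly interpolated
displacement at their reference position.  Points outside the field domain
are an error rather than extrapolated, because silent extrapolation
corrupts strain.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imaging import ImageVolume, SurfaceMesh

REQUIRED_LANDMARKS = ("apex", "mv_1", "mv_2", "mv_3", "septum_1", "septum_2")


@dataclass
class DisplacementField:
    """Dense displacement vectors (mm) on a regular world-space lattice."""

    origin: np.ndarray
    spacing: np.ndarray
    field: np.ndarray  # (ni, nj, nk, 3), mm

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        self.spacing = np.broadcast_to(
            np.asarray(self.spacing, dtype=np.float64), (3,)).copy()
        self.field = np.asarray(self.field, dtype=np.float64)
        if self.field.ndim != 4 or self.field.shape[3] != 3:
            raise ValueError("field must have shape (ni, nj, nk, 3)")
        if not np.all(np.isfinite(self.field)):
            raise ValueError("displacement field contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.field.shape[:3]

    @classmethod
    def identity(cls, shape, origin=(0, 0, 0), spacing=1.0) -> "DisplacementField":
        return cls(np.asarray(origin, dtype=np.float64), spacing,
                   np.zeros((*shape, 3)))

    @classmethod
    def from_ffd_stack(cls, stack, shape, origin, spacing) -> "DisplacementField":
        """Rasterise a multi-level B-spline stack onto a voxel lattice."""
        from .reg_ffd import stack_displacement

        field = stack_displacement(stack, shape, origin, spacing)
        return cls(np.asarray(origin, dtype=np.float64), spacing, field)

    @classmethod
    def from_voxel_field(cls, disp_vox: np.ndarray, image: ImageVolume
                         ) -> "DisplacementField":
        """Wrap a voxel-unit dense field (e.g. DDS output) in world mm."""
        return cls(image.origin, image.spacing,
                   np.asarray(disp_vox, dtype=np.float64) * image.spacing)

    def save_npz(self, path: str) -> None:
        np.savez_compressed(path, origin=self.origin, spacing=self.spacing,
                            field=self.field)

    @classmethod
    def load_npz(cls, path: str) -> "DisplacementField":
        with np.load(path) as z:
            return cls(z["origin"], z["spacing"], z["field"])


def interpolate_displacement(field: DisplacementField, points: np.ndarray
                             ) -> np.ndarray:
    """Component-wise trilinear interpolation of the field at mm points."""
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    idx = (pts - field.origin) / field.spacing
    n = np.array(field.shape)
    eps = 1e-9
    bad = (idx < -eps).any(axis=1) | (idx > n - 1 + eps).any(axis=1)
    if bad.any():
        i = int(np.argmax(bad))
        raise ValueError(
            f"point {pts[i]} lies outside the displacement-field domain")
    idx = np.clip(idx, 0.0, (n - 1).astype(np.float64))
    out = np.stack([
        ndimage.map_coordinates(field.field[..., d], idx.T, order=1,
                                mode="nearest")
        for d in range(3)], axis=-1)
    if np.ndim(points) == 1:
        return out[0]
    return out


def deform_mesh(mesh: SurfaceMesh, field: DisplacementField,
                min_area: float = 1e-12) -> SurfaceMesh:
    """Move every vertex by the interpolated displacement (connectivity and
    labels preserved).  Triangles collapsing below ``min_area`` mm^2 raise,
    rather than being silently dropped."""
    disp = interpolate_displacement(field, mesh.vertices)
    out = mesh.with_vertices(mesh.vertices + disp)
    areas = out.triangle_areas()
    if np.any(areas < min_area):
        bad = int(np.argmin(areas))
        raise ValueError(
            f"deformation produced a degenerate triangle (index {bad}, "
            f"area {areas[bad]:.3g} mm^2)")
    return out


def propagate_landmarks(landmarks: dict[str, np.ndarray],
                        fields: list[DisplacementField]
                        ) -> list[dict[str, np.ndarray]]:
    """Per-frame landmark positions under each frame's reference->frame field."""
    names = list(landmarks)
    pts = np.array([landmarks[n] for n in names], dtype=np.float64)
    out = []
    for f in fields:
        moved = pts + interpolate_displacement(f, pts)
        out.append({n: moved[i] for i, n in enumerate(names)})
    return out


def save_landmarks_csv(path: str, per_frame: list[dict[str, np.ndarray]]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "frame", "x", "y", "z"])
        for t, lm in enumerate(per_frame):
            for name, p in lm.items():
                w.writerow([name, t, f"{p[0]:.6f}", f"{p[1]:.6f}", f"{p[2]:.6f}"])


def load_landmarks_csv(path: str) -> list[dict[str, np.ndarray]]:
    frames: dict[int, dict[str, np.ndarray]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            t = int(row.get("frame", 0))
            frames.setdefault(t, {})[row["name"]] = np.array(
                [float(row["x"]), float(row["y"]), float(row["z"])])
    return [frames[t] for t in sorted(frames)]
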