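"""Green-Lagrange strain on triangulated endocardial meshes.

Each reference triangle carries a fixed orthonormal element triad: the
radial direction is the (counter-clockwise) triangle normal, the
longitudinal direction is the left-ventricular long axis projected into
the triangle plane, and the circumferential direction completes the
right-handed frame.  The per-element deformation gradient ``F`` maps the
reference edge vectors onto the deformed edge vectors and the reference
unit normal onto the deformed unit normal — i.e. no through-wall stretch —
so that after rotation into the element frame the radial row and column of
the strain tensor vanish identically.  The Green-Lagrange tensor is
``E = (F^T F - I) / 2``; its circumferential and longitudinal diagonal
entries are the reported strains.  Local area change is the triangle area
ratio; its square root is the SQUEEZ index of Pourmorteza-style
endocardial analysis.

Regional values are unweighted means over the triangles of each AHA
segment (basal 1-6, mid 7-12, apical 13-16; the apex cap is not used).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imaging import SurfaceMesh

METRICS = ("e_cc", "e_ll", "area_ratio")
N_SEGMENTS = 16


# ---------------------------------------------------------------------------
# element frames
# ---------------------------------------------------------------------------


def element_basis(triangle: np.ndarray, apex: np.ndarray, base: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthonormal (e_r, e_theta, e_z) triad for one reference triangle.

    ``e_r`` is the unit normal of the counter-clockwise triangle,
    ``e_z`` the unit in-plane projection of the long axis ``base - apex``,
    and ``e_theta = e_z x e_r``.  Degenerate triangles, or a long axis
    parallel to the normal, are rejected.
    """
    tri = np.asarray(triangle, dtype=np.float64)
    e21 = tri[1] - tri[0]
    e31 = tri[2] - tri[0]
    n = np.cross(e21, e31)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise ValueError("degenerate triangle: zero area")
    e_r = n / nn
    v_ab = np.asarray(base, dtype=np.float64) - np.asarray(apex, dtype=np.float64)
    proj = v_ab - (v_ab @ e_r) * e_r
    pn = np.linalg.norm(proj)
    if pn < 1e-12:
        raise ValueError("long axis parallel to the element normal")
    e_z = proj / pn
    e_theta = np.cross(e_z, e_r)
    return e_r, e_theta, e_z


def element_bases(mesh: SurfaceMesh, apex: np.ndarray, base: np.ndarray
                  ) -> np.ndarray:
    """Per-triangle rotation matrices Q with rows (e_r, e_theta, e_z).

    Computed once on the reference mesh; the triads stay fixed for every
    frame of the cycle.
    """
    c = mesh.triangle_corners()
    e21 = c[:, 1] - c[:, 0]
    e31 = c[:, 2] - c[:, 0]
    n = np.cross(e21, e31)
    nn = np.linalg.norm(n, axis=1, keepdims=True)
    if np.any(nn < 1e-12):
        raise ValueError("mesh contains a degenerate triangle")
    e_r = n / nn
    v_ab = (np.asarray(base, dtype=np.float64)
            - np.asarray(apex, dtype=np.float64))
    proj = v_ab - (e_r @ v_ab)[:, None] * e_r
    pn = np.linalg.norm(proj, axis=1, keepdims=True)
    if np.any(pn < 1e-12):
        raise ValueError("long axis parallel to an element normal")
    e_z = proj / pn
    e_theta = np.cross(e_z, e_r)
    return np.stack([e_r, e_theta, e_z], axis=1)  # (m, 3 rows, 3)


# ---------------------------------------------------------------------------
# tensors
# ---------------------------------------------------------------------------


def _edge_normal_matrix(corners: np.ndarray) -> np.ndarray:
    """Columns [e21, e31, n_hat] per triangle; corners shape (..., 3, 3)."""
    e21 = corners[..., 1, :] - corners[..., 0, :]
    e31 = corners[..., 2, :] - corners[..., 0, :]
    n = np.cross(e21, e31)
    nn = np.linalg.norm(n, axis=-1, keepdims=True)
    if np.any(nn < 1e-12):
        raise ValueError("degenerate triangle: zero area")
    return np.stack([e21, e31, n / nn], axis=-1)


def deformation_gradient(ref_triangle: np.ndarray, def_triangle: np.ndarray
                         ) -> np.ndarray:
    """Per-element deformation gradient F (3x3).

    Maps reference edges onto deformed edges and the reference unit normal
    onto the deformed unit normal (no stretch along the normal):
    ``F = [e21' e31' n'] [e21 e31 n]^-1``.
    """
    a = _edge_normal_matrix(np.asarray(ref_triangle, dtype=np.float64))
    b = _edge_normal_matrix(np.asarray(def_triangle, dtype=np.float64))
    return b @ np.linalg.inv(a)


def green_lagrange(F: np.ndarray) -> np.ndarray:
    """E = (F^T F - I) / 2; zero for any rigid motion."""
    F = np.asarray(F, dtype=np.float64)
    return 0.5 * (np.swapaxes(F, -1, -2) @ F - np.eye(3))


def rotate_strain(E: np.ndarray, basis) -> tuple[np.ndarray, float, float]:
    """Rotate a strain tensor into the element frame: E_e = Q E Q^T.

    ``basis`` is either the (e_r, e_theta, e_z) tuple or the 3x3 matrix Q
    with those rows.  Returns ``(E_e, E_thetatheta, E_zz)``; rejects a
    non-orthonormal Q.
    """
    Q = np.asarray(basis, dtype=np.float64)
    if Q.shape != (3, 3):
        Q = np.stack(basis)
    if np.linalg.norm(Q @ Q.T - np.eye(3)) > 1e-8:
        raise ValueError("element basis is not orthonormal")
    E_e = Q @ np.asarray(E, dtype=np.float64) @ Q.T
    return E_e, float(E_e[1, 1]), float(E_e[2, 2])


def area_change(ref_triangle: np.ndarray, def_triangle: np.ndarray
                ) -> tuple[float, float]:
    """(area_ratio, squeez) of one triangle; squeez = sqrt(area ratio)."""
    def tri_area(t):
        t = np.asarray(t, dtype=np.float64)
        return 0.5 * np.linalg.norm(np.cross(t[1] - t[0], t[2] - t[0]))

    a_ref = tri_area(ref_triangle)
    if a_ref < 1e-12:
        raise ValueError("degenerate reference triangle")
    ratio = tri_area(def_triangle) / a_ref
    return float(ratio), float(np.sqrt(ratio))


# ---------------------------------------------------------------------------
# AHA 16-segment labelling
# ---------------------------------------------------------------------------


def aha_label(mesh: SurfaceMesh, landmarks: dict[str, np.ndarray]
              ) -> np.ndarray:
    """One AHA segment id (1-16) per triangle.

    The long axis runs from the apex landmark to the centroid of the three
    mitral-valve landmarks.  Triangle centroids get a normalised
    longitudinal coordinate s (0 apex, 1 base) split into thirds
    (apical/mid/basal) and a circumferential angle referenced to the mean
    septal direction, counted counter-clockwise viewed from the base.
    Basal and mid rings have six 60-degree sectors (labels 1-6 and 7-12),
    the apical ring four 90-degree sectors (13-16).
    """
    from .motion import REQUIRED_LANDMARKS

    missing = [n for n in REQUIRED_LANDMARKS if n not in landmarks]
    if missing:
        raise ValueError(f"missing required landmarks: {missing}")
    apex = np.asarray(landmarks["apex"], dtype=np.float64)
    base = np.mean([landmarks[f"mv_{i}"] for i in (1, 2, 3)], axis=0)
    axis = base - apex
    axis_len = np.linalg.norm(axis)
    if axis_len < 1e-9:
        raise ValueError("apex and mitral centroid coincide")
    axis = axis / axis_len
    septum = 0.5 * (np.asarray(landmarks["septum_1"], dtype=np.float64)
                    + np.asarray(landmarks["septum_2"], dtype=np.float64))
    ref_dir = septum - apex
    ref_dir = ref_dir - (ref_dir @ axis) * axis
    if np.linalg.norm(ref_dir) < 1e-9:
        raise ValueError("septal landmarks lie on the long axis")
    ref_dir = ref_dir / np.linalg.norm(ref_dir)
    ref_perp = np.cross(axis, ref_dir)

    cent = mesh.triangle_centroids()
    rel = cent - apex
    s = np.clip((rel @ axis) / axis_len, 0.0, 1.0)
    in_plane = rel - np.outer(rel @ axis, axis)
    theta = np.arctan2(in_plane @ ref_perp, in_plane @ ref_dir) % (2 * np.pi)

    labels = np.empty(mesh.n_triangles, dtype=np.int64)
    basal = s >= 2.0 / 3.0
    mid = (s >= 1.0 / 3.0) & ~basal
    apical = ~basal & ~mid
    labels[basal] = 1 + (theta[basal] // (np.pi / 3)).astype(np.int64)
    labels[mid] = 7 + (theta[mid] // (np.pi / 3)).astype(np.int64)
    labels[apical] = 13 + (theta[apical] // (np.pi / 2)).astype(np.int64)
    return labels


# ---------------------------------------------------------------------------
# regional time series
# ---------------------------------------------------------------------------


@dataclass
class StrainCurveSet:
    """Per-segment time series of circumferential strain, longitudinal
    strain and area ratio.

    Arrays have shape (n_frames, 16); missing (empty) segments hold NaN.
    ``times`` are cycle fractions in [0, 1).
    """

    times: np.ndarray
    e_cc: np.ndarray
    e_ll: np.ndarray
    area_ratio: np.ndarray
    squeez: np.ndarray | None = None

    def metric(self, name: str) -> np.ndarray:
        if name not in METRICS and name != "squeez":
            raise KeyError(f"unknown metric {name!r}; choose from {METRICS}")
        return getattr(self, name)

    @property
    def n_frames(self) -> int:
        return self.times.size

    def to_frame(self) -> pd.DataFrame:
        """Tidy table (frame, time, segment, metric, value)."""
        rows = []
        for name in METRICS:
            arr = self.metric(name)
            for t in range(self.n_frames):
                for s in range(N_SEGMENTS):
                    rows.append((t, self.times[t], s + 1, name, arr[t, s]))
        return pd.DataFrame(rows, columns=["frame", "time", "segment",
                                           "metric", "value"])

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str) -> "StrainCurveSet":
        df = pd.read_csv(path)
        frames = np.sort(df["frame"].unique())
        times = df.groupby("frame")["time"].first().loc[frames].to_numpy()
        arrs = {}
        for name in METRICS:
            sub = df[df["metric"] == name].pivot(index="frame",
                                                 columns="segment",
                                                 values="value")
            arrs[name] = sub.reindex(index=frames,
                                     columns=range(1, N_SEGMENTS + 1)).to_numpy()
        return cls(times, arrs["e_cc"], arrs["e_ll"], arrs["area_ratio"])

    def bullseye(self, metric: str, frame: int) -> np.ndarray:
        """The 16 segment values of one metric at one frame."""
        return self.metric(metric)[frame]


def frame_strains(reference: SurfaceMesh, deformed: SurfaceMesh,
                  bases: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-triangle (E_cc, E_ll, area_ratio) for one deformed configuration."""
    a = _edge_normal_matrix(reference.triangle_corners())
    b = _edge_normal_matrix(deformed.triangle_corners())
    F = b @ np.linalg.inv(a)
    E = 0.5 * (np.swapaxes(F, -1, -2) @ F - np.eye(3))
    E_e = bases @ E @ np.swapaxes(bases, -1, -2)
    ratio = deformed.triangle_areas() / reference.triangle_areas()
    return E_e[:, 1, 1], E_e[:, 2, 2], ratio


def regional_curves(mesh_sequence: list[SurfaceMesh], labels: np.ndarray,
                    bases: np.ndarray, area_weighted: bool = False
                    ) -> StrainCurveSet:
    """Segment-mean strain curves over a cycle of deformed meshes.

    ``mesh_sequence[0]`` is the reference; all frames must share its
    connectivity.  The regional value is the unweighted mean over member
    triangles (an area-weighted mean is available as an option).  The
    frame-0 row is exactly (0, 0, 1); empty segments are NaN.
    """
    ref = mesh_sequence[0]
    labels = np.asarray(labels, dtype=np.int64)
    if labels.size != ref.n_triangles:
        raise ValueError("one label per reference triangle is required")
    for m in mesh_sequence[1:]:
        if m.n_triangles != ref.n_triangles or not np.array_equal(
                m.triangles, ref.triangles):
            raise ValueError("frames must share the reference connectivity")
    n_frames = len(mesh_sequence)
    times = np.arange(n_frames) / n_frames
    out = {name: np.full((n_frames, N_SEGMENTS), np.nan) for name in METRICS}
    out["squeez"] = np.full((n_frames, N_SEGMENTS), np.nan)
    w = ref.triangle_areas() if area_weighted else np.ones(ref.n_triangles)
    seg_masks = [(labels == s + 1) for s in range(N_SEGMENTS)]
    for t, mesh in enumerate(mesh_sequence):
        if t == 0:
            vals = {"e_cc": np.zeros(ref.n_triangles),
                    "e_ll": np.zeros(ref.n_triangles),
                    "area_ratio": np.ones(ref.n_triangles)}
        else:
            e_cc, e_ll, ratio = frame_strains(ref, mesh, bases)
            vals = {"e_cc": e_cc, "e_ll": e_ll, "area_ratio": ratio}
        for s, m in enumerate(seg_masks):
            if not m.any():
                continue  # flagged missing as NaN
            ws = w[m]
            for name in METRICS:
                out[name][t, s] = float(np.average(vals[name][m], weights=ws))
            out["squeez"][t, s] = np.sqrt(out["area_ratio"][t, s])
    return StrainCurveSet(times, out["e_cc"], out["e_ll"], out["area_ratio"],
                          out["squeez"])
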