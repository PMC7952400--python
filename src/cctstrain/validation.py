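"""Anatomical-measurement validation of motion tracking.

Ten anatomical measurements — diameters, a perimeter, the mitral-annulus
area and distances from the automatically computed annulus midpoint — are
evaluated per frame from annotated landmark points.  Tracking quality is
the mean squared *relative* difference between measurements computed from
automatically propagated landmarks and from manual annotations, averaged
over measurement kinds and temporal frames; the companion summary is the
mean absolute relative error in percent.  An exhaustive grid search over
registration hyperparameters minimises that cost.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: canonical measurement names, in the conventional reporting order
MEASUREMENT_NAMES = (
    "trigone_to_trigone",
    "posterior_perimeter",
    "mitral_annulus_area",
    "intercommissural_diameter",
    "anterior_posterior_horn",
    "midpoint_to_anterolateral_pm",
    "midpoint_to_posteromedial_pm",
    "midpoint_to_endocardial_apex",
    "midpoint_to_epicardial_apex",
    "midpoint_to_la_posterior",
)

_DISTANCE_PAIRS = {
    "trigone_to_trigone": ("trigone_1", "trigone_2"),
    "intercommissural_diameter": ("commissure_1", "commissure_2"),
    "anterior_posterior_horn": ("horn_anterior", "horn_posterior"),
}
_MIDPOINT_TARGETS = {
    "midpoint_to_anterolateral_pm": "pm_anterolateral",
    "midpoint_to_posteromedial_pm": "pm_posteromedial",
    "midpoint_to_endocardial_apex": "apex_endocardial",
    "midpoint_to_epicardial_apex": "apex_epicardial",
    "midpoint_to_la_posterior": "la_posterior",
}


@dataclass
class MeasurementRecord:
    """The ten anatomical measurements at one frame (mm; area mm^2).

    Undefined measurements (missing annotation points) hold NaN.
    """

    values: dict[str, float]

    def __post_init__(self) -> None:
        full = {n: float(self.values.get(n, np.nan))
                for n in MEASUREMENT_NAMES}
        extra = set(self.values) - set(MEASUREMENT_NAMES)
        if extra:
            raise ValueError(f"unknown measurement names: {sorted(extra)}")
        self.values = full

    def as_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in MEASUREMENT_NAMES])

    def n_defined(self) -> int:
        return int(np.isfinite(self.as_array()).sum())


def annulus_midpoint(annulus_points: np.ndarray) -> np.ndarray:
    """Arithmetic centroid of the mitral-annulus landmark ring."""
    pts = np.atleast_2d(np.asarray(annulus_points, dtype=np.float64))
    if pts.shape[0] < 3:
        raise ValueError("at least three annulus points are required")
    return pts.mean(axis=0)


def _polygon_area_3d(points: np.ndarray) -> float:
    """Area of a closed 3D polygon projected onto its least-squares plane."""
    pts = np.asarray(points, dtype=np.float64)
    c = pts.mean(axis=0)
    q = pts - c
    # plane basis from the two leading principal directions
    _, _, vt = np.linalg.svd(q, full_matrices=False)
    xy = q @ vt[:2].T
    x, y = xy[:, 0], xy[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def _collect_series(landmarks: dict[str, np.ndarray], prefix: str
                    ) -> np.ndarray | None:
    pts = []
    for i in itertools.count(1):
        key = f"{prefix}_{i}"
        if key not in landmarks:
            break
        pts.append(np.asarray(landmarks[key], dtype=np.float64))
    return np.array(pts) if len(pts) >= 2 else None


def compute_measurements(landmarks: dict[str, np.ndarray]) -> MeasurementRecord:
    """Evaluate the ten measurements from one frame's annotation points.

    Distances are Euclidean; the posterior perimeter is the length of the
    ordered ``posterior_i`` polyline; the annulus area is the shoelace area
    of the ordered ``annulus_i`` ring projected onto its least-squares
    plane; midpoint-based distances use :func:`annulus_midpoint`.  A
    measurement whose annotation points are absent is flagged NaN rather
    than failing the whole record.
    """
    vals: dict[str, float] = {}
    for name, (a, b) in _DISTANCE_PAIRS.items():
        if a in landmarks and b in landmarks:
            vals[name] = float(np.linalg.norm(
                np.asarray(landmarks[a]) - np.asarray(landmarks[b])))
    post = _collect_series(landmarks, "posterior")
    if post is not None:
        vals["posterior_perimeter"] = float(
            np.sum(np.linalg.norm(np.diff(post, axis=0), axis=1)))
    ring = _collect_series(landmarks, "annulus")
    if ring is not None and ring.shape[0] >= 3:
        vals["mitral_annulus_area"] = _polygon_area_3d(ring)
        mid = annulus_midpoint(ring)
        for name, target in _MIDPOINT_TARGETS.items():
            if target in landmarks:
                vals[name] = float(np.linalg.norm(
                    np.asarray(landmarks[target]) - mid))
    return MeasurementRecord(vals)


def records_to_matrix(records: list[MeasurementRecord]) -> np.ndarray:
    """(n_measurements, n_frames) value matrix from per-frame records."""
    return np.stack([r.as_array() for r in records], axis=1)


def tracking_cost(estimated: list[MeasurementRecord],
                  observed: list[MeasurementRecord]
                  ) -> tuple[float, float, int]:
    """Mean squared relative tracking error and its reporting companion.

    ``J`` is the mean over measurement kinds and frames of the squared
    relative difference ``((h - y) / y)^2`` between estimated ``h`` and
    observed ``y``; the companion is the mean absolute relative error in
    percent.  Cells with an observed value of zero (or either side
    undefined) are excluded and counted.  Returns
    ``(J, mean_abs_pct, n_excluded)``.
    """
    h = records_to_matrix(estimated)
    y = records_to_matrix(observed)
    if h.shape != y.shape:
        raise ValueError("estimated and observed records differ in shape")
    valid = np.isfinite(h) & np.isfinite(y) & (y != 0)
    n_excluded = int(h.size - valid.sum())
    if not valid.any():
        raise ValueError("no valid measurement cells")
    rel = (h[valid] - y[valid]) / y[valid]
    return float(np.mean(rel**2)), float(np.mean(np.abs(rel)) * 100.0), n_excluded


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------


@dataclass
class GridSpec:
    """Inclusive per-hyperparameter grid: values from min to max by step."""

    lo: float
    hi: float
    step: float

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError("grid minimum exceeds maximum")
        if self.step <= 0:
            raise ValueError("grid step must be positive")

    @property
    def values(self) -> np.ndarray:
        n = int(round((self.hi - self.lo) / self.step)) + 1
        v = self.lo + self.step * np.arange(n)
        return v[v <= self.hi + 1e-12]

    @classmethod
    def explicit(cls, values) -> "ExplicitGrid":
        return ExplicitGrid(np.asarray(values, dtype=np.float64))


@dataclass
class ExplicitGrid:
    """A grid axis given as an explicit value list."""

    _values: np.ndarray

    @property
    def values(self) -> np.ndarray:
        return self._values


def grid_search(grids: dict[str, GridSpec | ExplicitGrid], evaluate,
                ) -> tuple[dict[str, float], pd.DataFrame]:
    """Exhaustive, deterministic hyperparameter search.

    ``evaluate(params) -> error`` is called for every permutation of the
    per-axis values, enumerated in lexicographic order of the axis names'
    insertion order; a failing evaluation records NaN rather than aborting.
    Returns the argmin parameter dict (first grid point on ties) and the
    full error surface, one row per permutation.
    """
    names = list(grids)
    axes = [np.asarray(grids[n].values, dtype=np.float64) for n in names]
    rows = []
    best, best_err = None, np.inf
    for combo in itertools.product(*axes):
        params = dict(zip(names, (float(v) for v in combo)))
        try:
            err = float(evaluate(params))
        except Exception:
            err = np.nan
        rows.append({**params, "error": err})
        if np.isfinite(err) and err < best_err:
            best, best_err = params, err
    surface = pd.DataFrame(rows)
    if best is None:
        raise ValueError("every grid evaluation failed")
    return best, surface


# ---------------------------------------------------------------------------
# agreement statistics
# ---------------------------------------------------------------------------


def agreement_stats(manual, auto) -> dict[str, float]:
    """Pearson r, R^2 of the simple regression of auto on manual, Welch
    two-sample t-test p-value, and the 95% CI of the mean difference."""
    manual = np.asarray(manual, dtype=np.float64)
    auto = np.asarray(auto, dtype=np.float64)
    if manual.size != auto.size or manual.size < 3:
        raise ValueError("need equal-length lists of at least 3 values")
    if np.std(manual) == 0 or np.std(auto) == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(stats.pearsonr(manual, auto).statistic)
    res = stats.linregress(manual, auto)
    t = stats.ttest_ind(auto, manual, equal_var=False)
    diff = auto - manual
    # Welch CI of the mean difference between the two samples
    se = np.sqrt(np.var(auto, ddof=1) / auto.size
                 + np.var(manual, ddof=1) / manual.size)
    dof = t.df
    halfwidth = stats.t.ppf(0.975, dof) * se
    mean_diff = float(auto.mean() - manual.mean())
    return {
        "pearson_r": r,
        "r_squared": float(res.rvalue**2),
        "t_test_p": float(t.pvalue),
        "ci_low": mean_diff - float(halfwidth),
        "ci_high": mean_diff + float(halfwidth),
    }


def split_train_validation(n_sets: int, n_train: int, seed: int
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Seeded random split of dataset indices into train/validation."""
    if not 0 < n_train < n_sets:
        raise ValueError("n_train must be between 1 and n_sets - 1")
    perm = np.random.default_rng(seed).permutation(n_sets)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])
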