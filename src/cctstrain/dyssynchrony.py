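"""Strain-curve timing metrics and dyssynchrony statistics.

From each regional strain curve three scalar measurements are taken: T2P,
the time (as cycle fraction) of the curve's peak, where the peak is the
sample of largest absolute deviation from the frame-0 value (so the
definition covers negative-going contraction strains and positive-going
area curves alike); TOS, the linearly interpolated first time the curve
departs from its onset value by at least half its amplitude, moving toward
the peak; and MAG, the peak-to-peak amplitude (max - min).  Onset is frame
0, the R-wave reference frame.

The systolic dyssynchrony index (SDI) is the sample standard deviation of
a per-segment timing value across the 16 AHA segments.  Group comparisons
between healthy and dyssynchronous (CRT) subjects run a Welch two-sample
t-test on per-subject SDI values of each of the nine strain/metric
combinations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .strain import METRICS, N_SEGMENTS, StrainCurveSet

CURVE_MEASUREMENTS = ("t2p", "tos", "mag")


@dataclass
class CurveMetrics:
    """T2P and TOS as cycle fractions in [0, 1]; MAG dimensionless >= 0.

    ``t2p`` and ``tos`` are NaN for a constant curve (undefined peak).
    """

    t2p: float
    tos: float
    mag: float


def curve_metrics(curve: np.ndarray, times: np.ndarray | None = None
                  ) -> CurveMetrics:
    """Timing and amplitude measurements of one strain curve over a cycle."""
    y = np.asarray(curve, dtype=np.float64)
    if y.size < 3:
        raise ValueError("a curve needs at least 3 samples")
    if times is None:
        t = np.arange(y.size) / (y.size - 1)
    else:
        t = np.asarray(times, dtype=np.float64)
        if t.size != y.size:
            raise ValueError("times and curve lengths differ")
    mag = float(y.max() - y.min())
    if mag == 0.0:
        return CurveMetrics(np.nan, np.nan, 0.0)
    dev = y - y[0]
    peak_idx = int(np.argmax(np.abs(dev)))
    t2p = float(t[peak_idx])
    # first crossing of 50% amplitude toward the peak, linearly interpolated
    target = 0.5 * mag
    sgn = np.sign(dev[peak_idx])
    d = sgn * dev  # positive toward the peak
    tos = np.nan
    for i in range(1, y.size):
        if d[i] >= target:
            if d[i] == d[i - 1]:
                tos = float(t[i])
            else:
                w = (target - d[i - 1]) / (d[i] - d[i - 1])
                tos = float(t[i - 1] + w * (t[i] - t[i - 1]))
            break
    return CurveMetrics(t2p, tos, mag)


def sdi(per_segment_values: np.ndarray) -> float:
    """Sample standard deviation (n-1 denominator) across the 16 segments."""
    v = np.asarray(per_segment_values, dtype=np.float64)
    if v.size != N_SEGMENTS:
        raise ValueError(f"exactly {N_SEGMENTS} segment values are required")
    if not np.all(np.isfinite(v)):
        raise ValueError("missing segment values")
    return float(np.std(v, ddof=1))


def curve_set_metrics(curves: StrainCurveSet) -> pd.DataFrame:
    """Per-segment T2P/TOS/MAG for all three strain metrics of one subject.

    Tidy table with columns (metric, segment, t2p, tos, mag); area curves
    are measured as deviation from their frame-0 value of 1.
    """
    rows = []
    for name in METRICS:
        arr = curves.metric(name)
        for s in range(N_SEGMENTS):
            y = arr[:, s]
            if not np.all(np.isfinite(y)):
                rows.append((name, s + 1, np.nan, np.nan, np.nan))
                continue
            m = curve_metrics(y, curves.times)
            rows.append((name, s + 1, m.t2p, m.tos, m.mag))
    return pd.DataFrame(rows, columns=["metric", "segment", "t2p", "tos", "mag"])


def subject_sdi_table(curves: StrainCurveSet) -> dict[tuple[str, str], float]:
    """SDI (std across 16 segments) of each metric/measurement combination."""
    table = curve_set_metrics(curves)
    out = {}
    for name in METRICS:
        sub = table[table["metric"] == name]
        for meas in CURVE_MEASUREMENTS:
            vals = sub[meas].to_numpy()
            out[(name, meas)] = sdi(vals) if np.all(np.isfinite(vals)) else np.nan
    return out


def group_comparison(healthy: list[StrainCurveSet],
                     crt: list[StrainCurveSet]) -> pd.DataFrame:
    """Welch t-test of per-subject SDI values between the two groups.

    One row per (strain metric, curve measurement) — nine rows — with the
    group means and the two-sided p-value; degenerate variance in both
    groups flags the p-value NaN.
    """
    if len(healthy) < 2 or len(crt) < 2:
        raise ValueError("at least two subjects per group are required")
    h_tabs = [subject_sdi_table(c) for c in healthy]
    c_tabs = [subject_sdi_table(c) for c in crt]
    rows = []
    for name in METRICS:
        for meas in CURVE_MEASUREMENTS:
            hv = np.array([t[(name, meas)] for t in h_tabs])
            cv = np.array([t[(name, meas)] for t in c_tabs])
            if np.ptp(hv) == 0 and np.ptp(cv) == 0:
                p = np.nan
            else:
                p = float(stats.ttest_ind(hv, cv, equal_var=False).pvalue)
            rows.append((name, meas, float(hv.mean()), float(cv.mean()), p))
    return pd.DataFrame(rows, columns=["metric", "measurement",
                                       "healthy_mean_sdi", "crt_mean_sdi",
                                       "p_value"])


def frame_subsample_compare(curves_hi: StrainCurveSet, stride: int = 2
                            ) -> pd.DataFrame:
    """Effect of halving the temporal frame count on the curve measurements.

    Recomputes T2P/TOS/MAG on the stride-subsampled curves and reports the
    per-segment relative difference in percent, plus the mean and standard
    deviation per metric/measurement.  The frame count must be divisible
    by the stride.
    """
    n = curves_hi.n_frames
    if n % stride:
        raise ValueError("stride must divide the frame count")
    lo = StrainCurveSet(
        curves_hi.times[::stride],
        curves_hi.e_cc[::stride],
        curves_hi.e_ll[::stride],
        curves_hi.area_ratio[::stride],
    )
    hi_tab = curve_set_metrics(curves_hi).set_index(["metric", "segment"])
    lo_tab = curve_set_metrics(lo).set_index(["metric", "segment"])
    rows = []
    for (name, seg), hi_row in hi_tab.iterrows():
        lo_row = lo_tab.loc[(name, seg)]
        for meas in CURVE_MEASUREMENTS:
            ref = hi_row[meas]
            if not np.isfinite(ref) or ref == 0:
                rel = np.nan
            else:
                rel = 100.0 * (lo_row[meas] - ref) / ref
            rows.append((name, seg, meas, rel))
    return pd.DataFrame(rows, columns=["metric", "segment", "measurement",
                                       "rel_diff_pct"])


def subsample_summary(diffs: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sd of |relative difference| per metric/measurement."""
    g = diffs.assign(abs_pct=diffs["rel_diff_pct"].abs()).groupby(
        ["metric", "measurement"])["abs_pct"]
    return g.agg(["mean", "std"]).reset_index()
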