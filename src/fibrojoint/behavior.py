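"""Freely-moving behavior metrics from trajectory and yaw data.

Quantifies mobility per session: cumulated revolutions and the
time-weighted distribution of their magnitude (D9 = 90% quantile, Q2 =
median), mean angular velocity, mean displacement speed, and paired
active-vs-inactive condition comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def filter_low_confidence(traj: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Drop frames whose tracking confidence falls below the threshold.

    Gaps are not interpolated; downstream rate metrics exclude sample pairs
    that span a removed gap.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    conf_cols = [c for c in traj.columns if c.startswith("conf")]
    if not conf_cols:
        raise ValueError("trajectory has no confidence column")
    keep = np.ones(len(traj), dtype=bool)
    for c in conf_cols:
        keep &= traj[c].to_numpy() >= threshold
    return traj.loc[keep].reset_index(drop=True)


def cumulative_revolutions(yaw_deg: np.ndarray) -> np.ndarray:
    """Signed cumulated revolutions relative to the session start.

    ``yaw_deg`` must be unwrapped; a full revolution is a complete 360-deg
    rotation in either direction.
    """
    yaw = np.asarray(yaw_deg, dtype=float)
    if yaw.size == 0:
        raise ValueError("empty yaw series")
    return (yaw - yaw[0]) / 360.0


def _time_below(level: float, lo: np.ndarray, hi: np.ndarray, dt: np.ndarray) -> float:
    """Total time the piecewise-linear |revolutions| trace spends <= level."""
    span = hi - lo
    frac = np.where(span > 0, np.clip((level - lo) / np.where(span > 0, span, 1.0), 0, 1),
                    (level >= lo).astype(float))
    return float(np.sum(dt * frac))


def time_weighted_quantile(
    values: np.ndarray, t_s: np.ndarray, q: float
) -> float:
    """Quantile of a piecewise-linear trace weighted by time spent at each level."""
    if not 0 < q < 1:
        raise ValueError("quantile must be in (0, 1)")
    v = np.asarray(values, dtype=float)
    t = np.asarray(t_s, dtype=float)
    if v.size < 2 or v.shape != t.shape:
        raise ValueError("need >= 2 samples with matching times")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("time must be strictly increasing")
    lo = np.minimum(v[:-1], v[1:])
    hi = np.maximum(v[:-1], v[1:])
    total = float(dt.sum())
    target = q * total
    # invert the piecewise-linear CDF by bisection over the level
    a, b = float(v.min()), float(v.max())
    if _time_below(a, lo, hi, dt) >= target:
        return a
    for _ in range(100):
        mid = 0.5 * (a + b)
        if _time_below(mid, lo, hi, dt) < target:
            a = mid
        else:
            b = mid
    return 0.5 * (a + b)


@dataclass
class RevolutionStats:
    """Time-weighted distribution of |cumulated revolutions|."""

    d9_revolutions: float
    q2_revolutions: float
    bin_edges: np.ndarray
    time_fractions: np.ndarray

    def __post_init__(self) -> None:
        assert self.d9_revolutions >= self.q2_revolutions >= 0


def revolution_time_stats(
    revolutions: np.ndarray, t_s: np.ndarray, bin_width: float = 0.25
) -> RevolutionStats:
    """Histogram + D9/Q2 of the time spent at each |revolutions| level.

    D9 (Q2) is the number of revolutions below which the animal spends 90%
    (50%) of the session time; both use the magnitude of the cumulated
    rotation so clockwise and counter-clockwise torsion count equally.
    """
    rev = np.abs(np.asarray(revolutions, dtype=float))
    t = np.asarray(t_s, dtype=float)
    if rev.size < 2 or rev.shape != t.shape:
        raise ValueError("need >= 2 samples with matching times")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("time must be monotone increasing")
    d9 = time_weighted_quantile(rev, t, 0.9)
    q2 = time_weighted_quantile(rev, t, 0.5)
    n_bins = max(1, int(np.ceil((rev.max() + 1e-12) / bin_width)))
    edges = np.arange(n_bins + 1) * bin_width
    lo = np.minimum(rev[:-1], rev[1:])
    hi = np.maximum(rev[:-1], rev[1:])
    time_in = np.empty(n_bins)
    for i in range(n_bins):
        time_in[i] = _time_below(edges[i + 1], lo, hi, dt) - _time_below(edges[i], lo, hi, dt)
    total = dt.sum()
    return RevolutionStats(
        d9_revolutions=d9,
        q2_revolutions=q2,
        bin_edges=edges,
        time_fractions=time_in / total,
    )


def _pair_mask(t: np.ndarray, max_dt_s: float | None) -> np.ndarray:
    """Consecutive-pair mask excluding pairs that span a removed gap."""
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("time must be strictly increasing")
    if max_dt_s is None:
        max_dt_s = 1.5 * float(np.median(dt))
    return dt <= max_dt_s


def mean_angular_velocity(
    yaw_deg: np.ndarray, t_s: np.ndarray, max_dt_s: float | None = None
) -> float:
    """Mean |dyaw/dt| (deg/s) over retained consecutive sample pairs.

    Pairs spanning a gap longer than ``max_dt_s`` (default 1.5x the median
    sampling interval) are excluded.
    """
    yaw = np.asarray(yaw_deg, dtype=float)
    t = np.asarray(t_s, dtype=float)
    if yaw.size < 2 or yaw.shape != t.shape:
        raise ValueError("need >= 2 samples")
    keep = _pair_mask(t, max_dt_s)
    if not keep.any():
        raise ValueError("no usable sample pairs")
    rate = np.abs(np.diff(yaw)[keep] / np.diff(t)[keep])
    return float(rate.mean())


def mean_displacement(traj: pd.DataFrame, max_dt_s: float | None = None) -> float:
    """Mean displacement speed (mm/s) over retained consecutive frame pairs."""
    if len(traj) < 2:
        raise ValueError("need >= 2 retained frames")
    t = traj["t_s"].to_numpy(dtype=float)
    x = traj["x_mm"].to_numpy(dtype=float)
    y = traj["y_mm"].to_numpy(dtype=float)
    keep = _pair_mask(t, max_dt_s)
    if not keep.any():
        raise ValueError("no usable frame pairs")
    step = np.hypot(np.diff(x), np.diff(y))[keep]
    speed = step / np.diff(t)[keep]
    return float(speed.mean())


@dataclass
class SessionMetrics:
    """Mobility summary for one behavioral session."""

    d9_revolutions: float
    q2_revolutions: float
    mean_ang_vel_deg_s: float
    mean_disp_mm_per_s: float
    revolution_histogram: RevolutionStats

    def to_dict(self) -> dict:
        return {
            "d9_revolutions": self.d9_revolutions,
            "q2_revolutions": self.q2_revolutions,
            "mean_ang_vel_deg_s": self.mean_ang_vel_deg_s,
            "mean_disp_mm_per_s": self.mean_disp_mm_per_s,
        }


def session_metrics(
    traj: pd.DataFrame,
    confidence_threshold: float = 0.6,
    bin_width: float = 0.25,
) -> SessionMetrics:
    """Full mobility summary of one session from a tracked trajectory.

    Yaw is taken from the trajectory's ``yaw_deg`` column (the IMU/filter
    yaw when available), assumed unwrapped.
    """
    traj = filter_low_confidence(traj, confidence_threshold)
    t = traj["t_s"].to_numpy(dtype=float)
    yaw = traj["yaw_deg"].to_numpy(dtype=float)
    rev = cumulative_revolutions(yaw)
    hist = revolution_time_stats(rev, t, bin_width=bin_width)
    return SessionMetrics(
        d9_revolutions=hist.d9_revolutions,
        q2_revolutions=hist.q2_revolutions,
        mean_ang_vel_deg_s=mean_angular_velocity(yaw, t),
        mean_disp_mm_per_s=mean_displacement(traj),
        revolution_histogram=hist,
    )


def compare_conditions(
    active: np.ndarray, inactive: np.ndarray, test: str = "wilcoxon"
) -> tuple[float, float]:
    """Two-sided paired comparison of per-animal session values.

    ``test`` is ``"wilcoxon"`` (signed-rank, used for the revolution
    distributions) or ``"paired_t"``.  With all differences zero the
    Wilcoxon test is degenerate and reported as ``(0.0, 1.0)``.
    """
    a = np.asarray(active, dtype=float)
    b = np.asarray(inactive, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired values must be equal-length 1-D arrays")
    diffs = a - b
    if test == "wilcoxon":
        if np.all(diffs == 0):
            return 0.0, 1.0
        res = stats.wilcoxon(a, b)
        return float(res.statistic), float(res.pvalue)
    if test == "paired_t":
        if a.size < 2:
            raise ValueError("paired t-test needs >= 2 pairs")
        if np.all(diffs == diffs[0]):
            # zero-variance differences: exact shift, p -> 0 unless the shift is 0
            return (np.inf if diffs[0] != 0 else 0.0), (0.0 if diffs[0] != 0 else 1.0)
        res = stats.ttest_rel(a, b)
        return float(res.statistic), float(res.pvalue)
    raise ValueError("test must be 'wilcoxon' or 'paired_t'")
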