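"""Head-orientation estimation from 9-DoF IMU data.

Implements the Madgwick gradient-descent fusion filter (MARG form): gyro
quaternion integration corrected by a gradient step on the joint
gravity + magnetic-field objective.  The magnetometer anchors absolute yaw
against gyro drift; a hard-iron offset can be estimated by sphere fitting.

Quaternions are ``(w, x, y, z)`` and describe the rotation taking
sensor-frame vectors into the world frame; yaw is the z-rotation (ZYX Euler
convention), in degrees, positive counter-clockwise seen from above.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import CalibrationError


@dataclass(frozen=True)
class ImuSample:
    """One IMU sample: gyro (rad/s), accel (g), magnetometer (uT)."""

    t_s: float
    gyro: np.ndarray
    accel: np.ndarray
    mag: np.ndarray


@dataclass(frozen=True)
class FilterParams:
    """Madgwick filter parameters.

    ``beta`` is the gradient-descent gain trading gyro trust against
    accel/mag correction speed; 0.1 is Madgwick's published recommendation
    for MARG operation.  ``init_mode`` selects the initial state: a
    TRIAD-style fix from the first accel+mag pair (absolute orientation from
    the start) or the identity quaternion.
    """

    beta: float = 0.1
    init_mode: str = "accel_mag"

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.init_mode not in ("accel_mag", "identity"):
            raise ValueError("init_mode must be 'accel_mag' or 'identity'")


@dataclass(frozen=True)
class OrientationEstimate:
    """Filter state: unit quaternion, derived yaw (deg), timestamp."""

    q: np.ndarray
    yaw_deg: float
    t_s: float

    @classmethod
    def from_quaternion(cls, q: np.ndarray, t_s: float = 0.0) -> "OrientationEstimate":
        q = np.asarray(q, dtype=float)
        q = q / np.linalg.norm(q)
        return cls(q=q, yaw_deg=yaw_of(q), t_s=t_s)

    @classmethod
    def identity(cls, t_s: float = 0.0) -> "OrientationEstimate":
        return cls(q=np.array([1.0, 0.0, 0.0, 0.0]), yaw_deg=0.0, t_s=t_s)


def yaw_of(q: np.ndarray) -> float:
    """Yaw (deg, in (-180, 180]) of a unit quaternion, ZYX Euler convention."""
    q = np.asarray(q, dtype=float)
    n = np.linalg.norm(q)
    if n < 1e-12:
        raise ValueError("zero-norm quaternion has no orientation")
    w, x, y, z = q / n
    return float(np.degrees(np.arctan2(2 * (w * z + x * y), 1 - 2 * (y * y + z * z))))


def unwrap_yaw(yaw_deg: np.ndarray) -> np.ndarray:
    """Unwrap a yaw series (deg) into a continuous trace (no +-180 jumps)."""
    yaw_deg = np.asarray(yaw_deg, dtype=float)
    if yaw_deg.size == 0:
        raise ValueError("empty yaw series")
    return np.unwrap(yaw_deg, period=360.0)


def calibrate_hard_iron(mag_samples: np.ndarray) -> np.ndarray:
    """Hard-iron offset: center of the least-squares sphere fit to the cloud.

    Requires at least 10 samples spanning multiple headings; a degenerate
    cloud (rank < 3 after centering) raises :class:`CalibrationError`.
    """
    pts = np.asarray(mag_samples, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise CalibrationError("mag_samples must be an N x 3 array")
    if pts.shape[0] < 10:
        raise CalibrationError(f"need >= 10 samples, got {pts.shape[0]}")
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[2] < 1e-9 * max(sv[0], 1.0):
        raise CalibrationError("degenerate magnetometer cloud (rank < 3)")
    # |p - c|^2 = r^2  <=>  2 p.c + (r^2 - |c|^2) = |p|^2, linear in (c, d)
    a = np.column_stack([2 * pts, np.ones(len(pts))])
    b = (pts**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    return sol[:3]


def _quat_mult(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    pw, px, py, pz = p
    qw, qx, qy, qz = q
    return np.array(
        [
            pw * qw - px * qx - py * qy - pz * qz,
            pw * qx + px * qw + py * qz - pz * qy,
            pw * qy - px * qz + py * qw + pz * qx,
            pw * qz + px * qy - py * qx + pz * qw,
        ]
    )


def _rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate a sensor-frame vector into the world frame by q."""
    qv = np.concatenate([[0.0], v])
    qc = q * np.array([1.0, -1.0, -1.0, -1.0])
    return _quat_mult(_quat_mult(q, qv), qc)[1:]


def madgwick_update(
    state: OrientationEstimate,
    sample: ImuSample,
    dt_s: float,
    params: FilterParams = FilterParams(),
) -> OrientationEstimate:
    """One Madgwick MARG update step.

    The state is first propagated by gyro quaternion integration, then
    corrected by the normalized gradient of the accel+mag alignment
    objective, scaled by ``beta * dt``.  Evaluating the gradient at the
    propagated state keeps the correction unbiased during steady rotation
    (the objective is already zero when gyro tracking is exact).  A
    zero-norm accel or mag sample skips the correction (gyro-only update);
    ``beta = 0`` is pure gyro integration.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be > 0")
    q = np.asarray(state.q, dtype=float)
    gyro = np.asarray(sample.gyro, dtype=float)
    qdot = 0.5 * _quat_mult(q, np.concatenate([[0.0], gyro]))
    q = q + qdot * dt_s
    q = q / np.linalg.norm(q)
    w, x, y, z = q

    a = np.asarray(sample.accel, dtype=float)
    m = np.asarray(sample.mag, dtype=float)
    an, mn = np.linalg.norm(a), np.linalg.norm(m)
    if params.beta > 0 and an > 0 and mn > 0:
        a = a / an
        m = m / mn
        # World-frame magnetic reference from the current estimate:
        # horizontal magnitude bx and vertical component bz.
        h = _rotate(q, m)
        bx = np.hypot(h[0], h[1])
        bz = h[2]

        f = np.array(
            [
                2 * (x * z - w * y) - a[0],
                2 * (w * x + y * z) - a[1],
                1 - 2 * (x * x + y * y) - a[2],
                2 * bx * (0.5 - y * y - z * z) + 2 * bz * (x * z - w * y) - m[0],
                2 * bx * (x * y - w * z) + 2 * bz * (w * x + y * z) - m[1],
                2 * bx * (w * y + x * z) + 2 * bz * (0.5 - x * x - y * y) - m[2],
            ]
        )
        jac = np.array(
            [
                [-2 * y, 2 * z, -2 * w, 2 * x],
                [2 * x, 2 * w, 2 * z, 2 * y],
                [0.0, -4 * x, -4 * y, 0.0],
                [
                    -2 * bz * y,
                    2 * bz * z,
                    -4 * bx * y - 2 * bz * w,
                    -4 * bx * z + 2 * bz * x,
                ],
                [
                    -2 * bx * z + 2 * bz * x,
                    2 * bx * y + 2 * bz * w,
                    2 * bx * x + 2 * bz * z,
                    -2 * bx * w + 2 * bz * y,
                ],
                [
                    2 * bx * y,
                    2 * bx * z - 4 * bz * x,
                    2 * bx * w - 4 * bz * y,
                    2 * bx * x,
                ],
            ]
        )
        grad = jac.T @ f
        gn = np.linalg.norm(grad)
        if gn > 0:
            q = q - params.beta * dt_s * grad / gn

    q_new = q / np.linalg.norm(q)
    return OrientationEstimate(q=q_new, yaw_deg=yaw_of(q_new), t_s=sample.t_s)


def triad_init(accel: np.ndarray, mag: np.ndarray, t_s: float = 0.0) -> OrientationEstimate:
    """Absolute orientation from one accel+mag pair (TRIAD-style fix).

    World axes: z up (from gravity), x along the horizontal component of the
    magnetic field; the quaternion maps sensor vectors into this frame.
    """
    up = np.asarray(accel, dtype=float)
    up = up / np.linalg.norm(up)
    m = np.asarray(mag, dtype=float)
    north = m - (m @ up) * up
    nn = np.linalg.norm(north)
    if nn < 1e-12:
        return OrientationEstimate.identity(t_s)
    north = north / nn
    east_neg = np.cross(up, north)  # world +y axis expressed in sensor frame
    c_world_to_sensor = np.column_stack([north, east_neg, up])
    xyzw = Rotation.from_matrix(c_world_to_sensor.T).as_quat()
    q = np.array([xyzw[3], xyzw[0], xyzw[1], xyzw[2]])
    return OrientationEstimate.from_quaternion(q, t_s)


def filter_stream(
    imu: pd.DataFrame,
    params: FilterParams = FilterParams(),
    mag_offset: np.ndarray | None = None,
) -> pd.DataFrame:
    """Run the Madgwick filter over an IMU stream.

    ``imu`` uses the standard columns ``t_s, gx..gz, ax..az, mx..mz``.  An
    optional hard-iron ``mag_offset`` is subtracted from the magnetometer
    readings.  Returns a DataFrame ``t_s, qw, qx, qy, qz, yaw_deg``.
    """
    t = imu["t_s"].to_numpy(dtype=float)
    if t.size == 0:
        raise ValueError("empty IMU stream")
    if np.any(np.diff(t) <= 0):
        raise ValueError("IMU timestamps must be strictly increasing")
    gyro = imu[["gx", "gy", "gz"]].to_numpy(dtype=float)
    accel = imu[["ax", "ay", "az"]].to_numpy(dtype=float)
    mag = imu[["mx", "my", "mz"]].to_numpy(dtype=float)
    if mag_offset is not None:
        mag = mag - np.asarray(mag_offset, dtype=float)

    if params.init_mode == "accel_mag":
        state = triad_init(accel[0], mag[0], t_s=t[0])
    else:
        state = OrientationEstimate.identity(t_s=t[0])

    out = np.empty((t.size, 6))
    out[0] = [t[0], *state.q, state.yaw_deg]
    for i in range(1, t.size):
        # trapezoidal gyro: the mean rate over the interval integrates more
        # accurately than the endpoint sample at a 50-Hz rate
        g_mid = 0.5 * (gyro[i - 1] + gyro[i])
        sample = ImuSample(t_s=t[i], gyro=g_mid, accel=accel[i], mag=mag[i])
        state = madgwick_update(state, sample, dt_s=t[i] - t[i - 1], params=params)
        out[i] = [t[i], *state.q, state.yaw_deg]
    return pd.DataFrame(out, columns=["t_s", "qw", "qx", "qy", "qz", "yaw_deg"])
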