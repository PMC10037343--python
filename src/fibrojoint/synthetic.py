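"""Synthetic data generators with known ground truth.

Every input the pipeline consumes can be generated here: fiber-bundle scenes,
sensor captures under joint rotation, VSD sequences with photobleaching and
depolarization waves, IMU sample streams, and open-field trajectories.  All
generators are bit-reproducible for a fixed seed.

Geometry conventions
--------------------
Images are indexed ``(row, col)``, origin top-left.  Physical positions are
expressed in micrometers relative to the sensor center, as ``(row, col)``
offsets.  Rotation angles are in degrees; a positive angle is
counter-clockwise when viewing the sensor (y axis pointing up, i.e. against
the row index).  The scene is oversampled relative to the sensor so that
sub-pixel rigid motion is well defined; sensor sampling is an area average
over each pixel footprint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigurationError, GeometryError
from .io import ImageSequence

U16_MAX = 65535

# Maximum eccentricity (um) the scene padding accommodates.
_ECC_MARGIN_UM = 250.0


def _require(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise ConfigurationError(f"{fieldname}: {msg}")


@dataclass(frozen=True)
class SceneConfig:
    """Fiber-bundle scene parameters.

    The default geometry is a 2.5 x 2.5 mm square bundle field of 600 x 600
    individual fibers patched in 6 x 6 subassemblies (100 patches per side),
    imaged on a 100 x 100 pixel 16-bit sensor (25 um per sensor pixel).
    """

    field_mm: float = 2.5
    sensor_px: int = 100
    patch_grid: int = 100
    n_broken_patches: int = 2
    vignette_strength: float = 0.3
    base_level: float = 10000.0
    rng_seed: int = 0
    oversample: int = 4
    #: contrast (fractional sd) of the smooth random fluorescence field
    blob_contrast: float = 0.25
    #: half-range of the per-patch random transmission gain
    patch_gain_range: float = 0.15
    #: fractional darkening of the cladding at patch borders
    border_darkening: float = 0.15
    #: optical point-spread sigma in *sensor* pixels; bandlimits the scene so
    #: sub-pixel resampling is well posed
    psf_sigma_px: float = 0.6

    def __post_init__(self) -> None:
        _require(self.sensor_px > 0, "sensor_px", "must be > 0")
        _require(self.field_mm > 0, "field_mm", "must be > 0")
        _require(self.patch_grid > 0, "patch_grid", "must be > 0")
        _require(
            0 <= self.n_broken_patches <= self.patch_grid**2,
            "n_broken_patches",
            "must be in [0, patch_grid**2]",
        )
        _require(0 <= self.base_level <= U16_MAX, "base_level", "must be in [0, 65535]")
        _require(0 <= self.vignette_strength <= 1, "vignette_strength", "must be in [0, 1]")
        _require(self.oversample >= 4, "oversample", "must be >= 4")
        _require(self.psf_sigma_px >= 0, "psf_sigma_px", "must be >= 0")


@dataclass(frozen=True)
class CaptureConfig:
    """Sensor capture parameters for rendering a frame under joint rotation.

    ``ecc_um`` is the offset of the rotation axis from the bundle/image
    center, as a ``(row, col)`` vector in micrometers: mechanical
    eccentricity makes the image center describe a circle of that radius as
    the joint rotates.  ``moire`` is a single global 2-D sinusoid
    ``(fx, fy, phase, amplitude)`` with spatial frequencies in cycles/px
    (fx along columns, fy along rows) and amplitude in counts, modelling the
    patterned noise from the fiber structure beating against the sensor grid.
    """

    ecc_um: tuple[float, float] = (0.0, 0.0)
    residual_rot_amp_deg: float = 0.0
    noise_sd_counts: float = 0.0
    moire: tuple[float, float, float, float] | None = None
    bit_depth: int = 16
    rng_seed: int = 0

    def __post_init__(self) -> None:
        _require(self.noise_sd_counts >= 0, "noise_sd_counts", "must be >= 0")
        if self.moire is not None:
            _require(len(self.moire) == 4, "moire", "must be (fx, fy, phase, amplitude)")
            _require(self.moire[3] >= 0, "moire", "amplitude must be >= 0")
        _require(self.bit_depth == 16, "bit_depth", "only 16-bit sensors are modelled")
        _require(
            float(np.hypot(*self.ecc_um)) <= _ECC_MARGIN_UM,
            "ecc_um",
            f"magnitude must be <= {_ECC_MARGIN_UM} um",
        )


@dataclass(frozen=True)
class VsdSimConfig:
    """VSD sequence parameters: photobleaching decay plus an embedded wave.

    ``bleach_coeffs`` are the quadratic coefficients ``(a, b, c)`` of the
    bleaching trend in dF/F units, evaluated on the absolute time axis
    (seconds since shutter opening, i.e. offset by ``preexposure_s``).
    ``wave`` is ``(onset_frame, origin_px, speed_px_per_frame, amplitude,
    width_px)`` describing a radially expanding Gaussian-profile
    depolarization front; amplitude is in dF/F units and may be signed.
    """

    n_frames: int = 512
    dt_ms: float = 2.0
    bleach_coeffs: tuple[float, float, float] = (0.005, -0.1, 0.0)
    preexposure_s: float = 2.0
    wave: tuple[int, tuple[float, float], float, float, float] | None = None
    noise_sd: float = 0.0
    moire: tuple[float, float, float, float] | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_frames >= 1, "n_frames", "must be >= 1")
        _require(self.dt_ms > 0, "dt_ms", "must be > 0")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        _require(self.preexposure_s >= 0, "preexposure_s", "must be >= 0")
        if self.wave is not None:
            _require(len(self.wave) == 5, "wave", "must be (onset, origin, speed, amp, width)")
            _require(self.wave[4] > 0, "wave", "width must be > 0")


@dataclass(frozen=True)
class ImuSimConfig:
    """9-DoF IMU stream parameters (gyro rad/s, accel g, magnetometer uT)."""

    rate_hz: float = 50.0
    gyro_noise_sd: float = 0.0
    accel_noise_sd: float = 0.0
    mag_noise_sd: float = 0.0
    gyro_bias: tuple[float, float, float] = (0.0, 0.0, 0.0)
    mag_field: tuple[float, float, float] = (22.0, 0.0, -42.0)
    mag_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        _require(self.rate_hz > 0, "rate_hz", "must be > 0")
        for name in ("gyro_noise_sd", "accel_noise_sd", "mag_noise_sd"):
            _require(getattr(self, name) >= 0, name, "must be >= 0")
        bx, by, _ = self.mag_field
        _require(math.hypot(bx, by) > 0, "mag_field", "horizontal component must be non-zero")


@dataclass(frozen=True)
class TrajectoryConfig:
    """Open-field trajectory parameters (30-cm circular arena, 500-Hz video)."""

    arena_radius_mm: float = 150.0
    duration_s: float = 60.0
    frame_rate_hz: float = 500.0
    speed_scale: float = 50.0
    turning_bias: float = 0.0
    #: stationary sd of the Ornstein-Uhlenbeck turn-rate process (deg/s)
    turn_rate_sd_deg_s: float = 45.0
    #: correlation time of the turn-rate process (s)
    turn_tau_s: float = 0.5
    dropout_rate: float = 0.01
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("arena_radius_mm", "duration_s", "frame_rate_hz", "speed_scale", "turn_tau_s"):
            _require(getattr(self, name) > 0, name, "must be > 0")
        _require(self.turn_rate_sd_deg_s >= 0, "turn_rate_sd_deg_s", "must be >= 0")
        _require(0 <= self.dropout_rate <= 1, "dropout_rate", "must be in [0, 1]")


@dataclass
class Scene:
    """Oversampled bundle scene: float image plus geometry metadata."""

    image: np.ndarray
    pixel_um: float
    field_mm: float
    sensor_px: int
    oversample: int
    pad_px: int
    config: SceneConfig = field(repr=False, default=None)
    #: per-patch transmission gains (patch_grid x patch_grid); broken
    #: subassemblies carry a near-zero gain
    patch_gains: np.ndarray = field(repr=False, default=None)

    @property
    def pitch_um(self) -> float:
        """Physical size of one *sensor* pixel in micrometers."""
        return self.field_mm * 1000.0 / self.sensor_px


def rotation_matrix(theta_deg: float) -> np.ndarray:
    """Rotation matrix acting on (row, col) vectors.

    A positive angle rotates the image content counter-clockwise as seen on
    screen (x = col to the right, y up).
    """
    th = math.radians(theta_deg)
    c, s = math.cos(th), math.sin(th)
    return np.array([[c, s], [-s, c]])


def patch_border_profile(n_px: int, patch_px: float, darkening: float) -> np.ndarray:
    """1-D multiplicative cladding profile, periodic at the patch pitch.

    Pixels within half a scene pixel of a patch boundary are darkened by
    ``darkening``; the profile has exact period ``patch_px``.
    """
    x = np.arange(n_px, dtype=float)
    frac = np.mod(x, patch_px)
    near_border = np.minimum(frac, patch_px - frac) < 0.75
    return np.where(near_border, 1.0 - darkening, 1.0)


def make_bundle_scene(cfg: SceneConfig) -> Scene:
    """Generate an oversampled fiber-bundle resting-fluorescence scene.

    The square bundle field (side ``field_mm``) carries a smooth random
    fluorescence field, per-patch transmission gains, darkened patch-border
    cladding (periodic at ``patch_grid``), a radial vignette and exactly
    ``n_broken_patches`` near-zero patch subassemblies.  Outside the field
    the scene is dark.  The optical point-spread function (``psf_sigma_px``)
    is applied last, bandlimiting the scene below the sensor Nyquist so that
    sub-pixel rigid motion and resampling are well defined.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    m = cfg.sensor_px * cfg.oversample  # fine pixels across the bundle field
    pixel_um = cfg.field_mm * 1000.0 / m
    pad = math.ceil(m * (math.sqrt(2) - 1) / 2) + math.ceil(_ECC_MARGIN_UM / pixel_um) + 2
    n = m + 2 * pad

    img = np.zeros((n, n))
    sl = slice(pad, pad + m)

    # Smooth random fluorescence field (correlation length ~ 4 sensor px).
    blob = rng.standard_normal((m, m))
    blob = ndimage.gaussian_filter(blob, sigma=4.0 * cfg.oversample, mode="reflect")
    std = blob.std()
    if std > 0:
        blob = blob / std
    fieldimg = np.clip(1.0 + cfg.blob_contrast * blob, 0.05, None)

    # Per-patch transmission gains and broken (near-zero) patches.
    gains = 1.0 + cfg.patch_gain_range * (2.0 * rng.random((cfg.patch_grid,) * 2) - 1.0)
    if cfg.n_broken_patches:
        idx = rng.choice(cfg.patch_grid**2, size=cfg.n_broken_patches, replace=False)
        gains.flat[idx] = 0.01
    patch_px = m / cfg.patch_grid
    pi = np.minimum((np.arange(m) / patch_px).astype(int), cfg.patch_grid - 1)
    fieldimg *= gains[np.ix_(pi, pi)]

    border = patch_border_profile(m, patch_px, cfg.border_darkening)
    fieldimg *= border[:, None] * border[None, :]

    # Radial vignette over the field.
    ax = (np.arange(m) - (m - 1) / 2) / (m / 2)
    r2 = ax[:, None] ** 2 + ax[None, :] ** 2
    fieldimg *= 1.0 - cfg.vignette_strength * r2 / 2.0

    img[sl, sl] = cfg.base_level * fieldimg
    if cfg.psf_sigma_px > 0:
        img = ndimage.gaussian_filter(img, sigma=cfg.psf_sigma_px * cfg.oversample)
    return Scene(
        image=img,
        pixel_um=pixel_um,
        field_mm=cfg.field_mm,
        sensor_px=cfg.sensor_px,
        oversample=cfg.oversample,
        pad_px=pad,
        config=cfg,
        patch_gains=gains,
    )


def total_rotation_deg(motor_angle_deg: float, cap: CaptureConfig) -> float:
    """Effective image rotation: motor angle plus the residual sinusoidal offset."""
    return motor_angle_deg + cap.residual_rot_amp_deg * math.sin(math.radians(motor_angle_deg))


def _capture_float(
    scene: Scene,
    motor_angle_deg: float,
    cap: CaptureConfig,
    shift_um: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Noise-free float capture (before moire, noise and quantization).

    ``shift_um`` is an extra (row, col) translation of the scene content,
    used to model residual mechanical repositioning offsets.
    """
    s = scene.oversample
    m = scene.sensor_px * s
    n = scene.image.shape[0]
    # Fine-grid sensor sample positions, um relative to the sensor center.
    pos = (np.arange(m) - (m - 1) / 2) * scene.pixel_um
    pr, pc = np.meshgrid(pos, pos, indexing="ij")
    e = np.asarray(cap.ecc_um, dtype=float)
    rot = rotation_matrix(total_rotation_deg(motor_angle_deg, cap))
    dr, dc = pr - e[0], pc - e[1]
    qr = e[0] + rot[0, 0] * dr + rot[0, 1] * dc - shift_um[0]
    qc = e[1] + rot[1, 0] * dr + rot[1, 1] * dc - shift_um[1]
    # Scene pixel index of a physical position.
    ir = qr / scene.pixel_um + (n - 1) / 2
    ic = qc / scene.pixel_um + (n - 1) / 2
    if ir.min() < 0 or ic.min() < 0 or ir.max() > n - 1 or ic.max() > n - 1:
        raise GeometryError(
            "sensor footprint exits the scene bounds at "
            f"motor angle {motor_angle_deg:.1f} deg (ecc {cap.ecc_um})"
        )
    fine = ndimage.map_coordinates(scene.image, [ir, ic], order=1, mode="nearest")
    return fine.reshape(scene.sensor_px, s, scene.sensor_px, s).mean(axis=(1, 3))


def render_capture(
    scene: Scene,
    motor_angle_deg: float,
    cap: CaptureConfig,
    rng: np.random.Generator | None = None,
    shift_um: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Render one 16-bit sensor frame at the given motor angle.

    The scene content is rotated by the motor angle about the rotation axis
    (offset ``ecc_um`` from the image center), area-averaged onto the sensor
    grid, then the static moire sinusoid and additive Gaussian noise are
    applied before clipping and quantization to 16 bits.

    A ``rng`` may be supplied to draw noise for a whole series; otherwise a
    fresh generator is seeded from ``cap.rng_seed``.
    """
    frame = _capture_float(scene, motor_angle_deg, cap, shift_um=shift_um)
    if cap.moire is not None:
        frame = frame + moire_pattern(scene.sensor_px, cap.moire)
    if cap.noise_sd_counts > 0:
        if rng is None:
            rng = np.random.default_rng(cap.rng_seed)
        frame = frame + rng.normal(0.0, cap.noise_sd_counts, frame.shape)
    return np.clip(np.rint(frame), 0, U16_MAX).astype(np.uint16)


def moire_pattern(
    n_px: int, moire: tuple[float, float, float, float], dtype=float
) -> np.ndarray:
    """Global 2-D sinusoid ``A*sin(2*pi*(fx*col + fy*row) + phase)`` on the sensor grid."""
    fx, fy, phase, amp = moire
    rows = np.arange(n_px)[:, None]
    cols = np.arange(n_px)[None, :]
    return (amp * np.sin(2 * np.pi * (fx * cols + fy * rows) + phase)).astype(dtype)


def true_transform_px(
    motor_angle_deg: float, cap: CaptureConfig, pitch_um: float, sensor_px: int
):
    """Ground-truth rigid transform mapping capture(angle) -> capture(0), in pixels.

    Returned as a :class:`~fibrojoint.registration.RigidTransform` with the
    rotation expressed about the sensor center, the eccentric motion absorbed
    into the translation (chord length ``2*|ecc|*sin(angle/2)``).
    """
    from .registration import RigidTransform

    alpha = total_rotation_deg(motor_angle_deg, cap)
    e_px = np.asarray(cap.ecc_um) / pitch_um
    rot = rotation_matrix(alpha)
    t = (np.eye(2) - rot) @ e_px
    c = (sensor_px - 1) / 2.0
    return RigidTransform(
        theta_deg=alpha, tr_px=float(t[0]), tc_px=float(t[1]), center_px=(c, c)
    )


def bleach_trace(
    coeffs: tuple[float, float, float], t_abs_s: np.ndarray
) -> np.ndarray:
    """Quadratic bleaching trend in dF/F units on the absolute time axis."""
    a, b, c = coeffs
    return a * t_abs_s**2 + b * t_abs_s + c


def make_vsd_sequence(
    scene: Scene, cfg: VsdSimConfig
) -> tuple[ImageSequence, dict]:
    """Generate a VSD image sequence with photobleaching and an embedded wave.

    Frame ``t`` is ``base * (1 + bleach(t) + wave(t) + moire + noise)`` where
    ``base`` is the angle-0 capture of the scene, ``bleach`` the quadratic
    trend evaluated at ``preexposure_s + t*dt``, and ``wave`` the radial
    depolarization front.  Returns the (16-bit) sequence together with a
    ground-truth dict holding the dF/F wave field and the bleach trace.
    """
    base = _capture_float(scene, 0.0, CaptureConfig())
    h = w = scene.sensor_px
    tt = np.arange(cfg.n_frames)
    t_abs = cfg.preexposure_s + tt * cfg.dt_ms / 1000.0
    bleach = bleach_trace(cfg.bleach_coeffs, t_abs)

    wave_field = np.zeros((cfg.n_frames, h, w))
    if cfg.wave is not None:
        onset, origin, speed, amp, width = cfg.wave
        rr = np.arange(h)[:, None] - origin[0]
        cc = np.arange(w)[None, :] - origin[1]
        dist = np.hypot(rr, cc)
        for k in range(int(onset), cfg.n_frames):
            radius = speed * (k - onset)
            wave_field[k] = amp * np.exp(-((dist - radius) ** 2) / (2 * width**2))

    rng = np.random.default_rng(cfg.rng_seed)
    rel = 1.0 + bleach[:, None, None] + wave_field
    if cfg.moire is not None:
        rel = rel + moire_pattern(h, cfg.moire)[None]
    if cfg.noise_sd > 0:
        rel = rel + rng.normal(0.0, cfg.noise_sd, rel.shape)
    frames = np.clip(np.rint(base[None] * rel), 0, U16_MAX).astype(np.uint16)

    seq = ImageSequence(
        frames=frames,
        dt_ms=cfg.dt_ms,
        preexposure_s=cfg.preexposure_s,
        motor_angle_deg=np.zeros(cfg.n_frames),
    )
    truth = {"wave": wave_field, "bleach": bleach, "base": base, "t_abs_s": t_abs}
    return seq, truth


def make_imu_stream(
    yaw_profile: Callable[[np.ndarray], np.ndarray],
    duration_s: float,
    cfg: ImuSimConfig,
) -> pd.DataFrame:
    """Synthesize a 9-DoF IMU stream consistent with a head-yaw profile.

    ``yaw_profile`` maps time (s, vectorized) to yaw in degrees.  The head is
    assumed level (gravity along -z in the sensor frame is measured as
    ``+1 g`` on the accelerometer z axis); the magnetometer reads the world
    field rotated into the sensor frame, plus the hard-iron ``mag_offset``.

    Returns a DataFrame with columns ``t_s, gx, gy, gz, ax, ay, az, mx, my, mz``.
    """
    if duration_s <= 0:
        raise ConfigurationError("duration_s: must be > 0")
    n = round(duration_s * cfg.rate_hz)
    t = np.arange(n) / cfg.rate_hz
    yaw = np.asarray(yaw_profile(t), dtype=float)
    psi = np.radians(yaw)
    rate = np.gradient(psi, t) if n > 1 else np.zeros(1)

    rng = np.random.default_rng(cfg.rng_seed)
    gyro = np.zeros((n, 3))
    gyro[:, 2] = rate
    gyro += np.asarray(cfg.gyro_bias)
    if cfg.gyro_noise_sd > 0:
        gyro += rng.normal(0.0, cfg.gyro_noise_sd, gyro.shape)

    accel = np.tile([0.0, 0.0, 1.0], (n, 1))
    if cfg.accel_noise_sd > 0:
        accel += rng.normal(0.0, cfg.accel_noise_sd, accel.shape)

    bx, by, bz = cfg.mag_field
    c, s = np.cos(psi), np.sin(psi)
    mag = np.empty((n, 3))
    mag[:, 0] = c * bx + s * by
    mag[:, 1] = -s * bx + c * by
    mag[:, 2] = bz
    mag += np.asarray(cfg.mag_offset)
    if cfg.mag_noise_sd > 0:
        mag += rng.normal(0.0, cfg.mag_noise_sd, mag.shape)

    return pd.DataFrame(
        np.column_stack([t, gyro, accel, mag]),
        columns=["t_s", "gx", "gy", "gz", "ax", "ay", "az", "mx", "my", "mz"],
    )


def make_arena_trajectory(cfg: TrajectoryConfig) -> pd.DataFrame:
    """Generate a tracked open-field trajectory with heading-consistent yaw.

    A correlated random walk: the turn rate is an Ornstein-Uhlenbeck process
    (stationary sd ``turn_rate_sd_deg_s``, correlation time ``turn_tau_s``)
    around a constant ``turning_bias`` (deg/s); speed is ``speed_scale``
    mm/s, softly steered away from the arena wall.  Confidence is near 1
    with occasional low-confidence dropouts.

    Returns a DataFrame with columns ``t_s, x_mm, y_mm, conf, yaw_deg``
    (yaw unwrapped, in degrees).
    """
    rng = np.random.default_rng(cfg.rng_seed)
    n = round(cfg.duration_s * cfg.frame_rate_hz)
    dt = 1.0 / cfg.frame_rate_hz
    x = np.empty(n)
    y = np.empty(n)
    yaw = np.empty(n)
    pos = np.array([0.0, 0.0])
    heading = rng.uniform(0, 2 * np.pi)
    bias = math.radians(cfg.turning_bias)
    sigma = math.radians(cfg.turn_rate_sd_deg_s)
    tau = cfg.turn_tau_s
    rate = sigma * rng.standard_normal()
    steer_zone = 0.85 * cfg.arena_radius_mm
    noise = rng.standard_normal(n)
    for i in range(n):
        x[i], y[i] = pos
        yaw[i] = heading
        heading += (bias + rate) * dt
        rate += (-rate / tau) * dt + sigma * math.sqrt(2 * dt / tau) * noise[i]
        r = math.hypot(*pos)
        if r > steer_zone:
            # steer toward the center, proportional to wall proximity
            to_center = math.atan2(-pos[1], -pos[0])
            diff = (to_center - heading + math.pi) % (2 * math.pi) - math.pi
            heading += 4.0 * (r / cfg.arena_radius_mm) * diff * dt
        step = cfg.speed_scale * dt
        pos = pos + step * np.array([math.cos(heading), math.sin(heading)])
        r = math.hypot(*pos)
        if r > cfg.arena_radius_mm:
            pos *= cfg.arena_radius_mm / r

    conf = np.clip(1.0 - np.abs(rng.normal(0.0, 0.02, n)), 0.0, 1.0)
    drop = rng.random(n) < cfg.dropout_rate
    conf[drop] = rng.uniform(0.0, 0.5, drop.sum())
    return pd.DataFrame(
        {
            "t_s": np.arange(n) * dt,
            "x_mm": x,
            "y_mm": y,
            "conf": conf,
            "yaw_deg": np.degrees(yaw),
        }
    )
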