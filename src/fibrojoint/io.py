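"""File I/O: 16-bit TIFF stacks with JSON sidecars, and time-series CSV.

Image sequences travel as multi-page 16-bit TIFF files; per-frame motor
angles and timing metadata live in a JSON sidecar next to the stack
(``<stem>.json``).  Round trips are lossless.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


@dataclass
class ImageSequence:
    """T x H x W stack of 16-bit frames with per-frame motor angle and timing."""

    frames: np.ndarray
    dt_ms: float = 2.0
    preexposure_s: float = 0.0
    motor_angle_deg: np.ndarray | None = None
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a T x H x W array")
        if self.motor_angle_deg is None:
            self.motor_angle_deg = np.zeros(self.frames.shape[0])
        self.motor_angle_deg = np.asarray(self.motor_angle_deg, dtype=float)
        if self.motor_angle_deg.shape[0] != self.frames.shape[0]:
            raise ValueError("motor_angle_deg length must equal the number of frames")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def t_s(self) -> np.ndarray:
        """Acquisition time of each frame, seconds."""
        return self.t0_s + np.arange(self.n_frames) * self.dt_ms / 1000.0


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_stack(path: str | Path, seq: ImageSequence) -> None:
    """Write a multi-page 16-bit TIFF stack plus its JSON metadata sidecar."""
    path = Path(path)
    frames = seq.frames
    if frames.dtype != np.uint16:
        raise ValueError(
            f"expected uint16 frames, got {frames.dtype}; convert explicitly first"
        )
    tifffile.imwrite(path, frames, photometric="minisblack")
    meta = {
        "dt_ms": seq.dt_ms,
        "preexposure_s": seq.preexposure_s,
        "t0_s": seq.t0_s,
        "motor_angle_deg": [float(a) for a in seq.motor_angle_deg],
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_stack(path: str | Path) -> ImageSequence:
    """Read a multi-page TIFF stack and its sidecar back into an ImageSequence.

    Raises on non-16-bit stacks (an explicit conversion is required) and on a
    sidecar whose angle list does not match the stack length; a missing
    sidecar falls back to metadata defaults with a warning.
    """
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.dtype != np.uint16:
        raise ValueError(
            f"{path.name}: stack is {frames.dtype}, not 16-bit; convert explicitly"
        )
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        warnings.warn(f"{sidecar.name} missing; using metadata defaults", stacklevel=2)
        return ImageSequence(frames=frames)
    meta = json.loads(sidecar.read_text())
    angles = meta.get("motor_angle_deg")
    if angles is not None and len(angles) != frames.shape[0]:
        raise ValueError(
            f"{sidecar.name}: motor_angle_deg has {len(angles)} entries "
            f"for {frames.shape[0]} frames"
        )
    return ImageSequence(
        frames=frames,
        dt_ms=meta.get("dt_ms", 2.0),
        preexposure_s=meta.get("preexposure_s", 0.0),
        motor_angle_deg=None if angles is None else np.asarray(angles, dtype=float),
        t0_s=meta.get("t0_s", 0.0),
    )


IMU_COLUMNS = ["t_s", "gx", "gy", "gz", "ax", "ay", "az", "mx", "my", "mz"]
TRAJECTORY_COLUMNS = ["t_s", "x_mm", "y_mm", "conf", "yaw_deg"]


def read_imu_csv(path: str | Path) -> pd.DataFrame:
    """Read an IMU stream CSV (t_s, gx..gz rad/s, ax..az g, mx..mz uT)."""
    df = pd.read_csv(path)
    missing = set(IMU_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"IMU CSV missing columns: {sorted(missing)}")
    return df[IMU_COLUMNS]


def read_trajectory_csv(path: str | Path) -> pd.DataFrame:
    """Read a tracked trajectory CSV (t_s, x_mm, y_mm, conf, yaw_deg)."""
    df = pd.read_csv(path)
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {sorted(missing)}")
    return df[TRAJECTORY_COLUMNS]
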