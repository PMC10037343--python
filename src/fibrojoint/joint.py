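"""Motorized rotary joint simulation: stepper geometry, backlash, operating modes.

The joint couples a stepper motor (400 physical steps/rev at x8
microstepping) to the fiber-bundle shaft through a 1:3 timing belt, so one
shaft revolution subdivides into 9600 microsteps.  Backlash is modelled as a
pure symmetric dead band: on a direction reversal the first
``backlash_usteps`` of commanded motion produce no output motion.

Three operating modes are simulated:

* **HR** (hardware registration): the shaft locks at the optimal reference
  orientation (OREF) for each acquisition sequence, using an anti-backlash
  approach (overshoot past OREF, then approach in a fixed direction) so the
  locked output angle is exactly repeatable; it follows the animal's yaw
  between sequences.
* **SR** (software registration): the motor follows continuously and is held
  still only during each frame's exposure; frames are registered offline
  from the recorded motor angle.
* **HYBRID**: locked at OREF with a fast one-revolution unwind each time the
  accumulated head rotation exceeds 360 deg.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SchedulingError

FOLLOW = "FOLLOW"
HR_LOCKED = "HR_LOCKED"
SR = "SR"
HYBRID = "HYBRID"


@dataclass(frozen=True)
class MotorConfig:
    """Stepper + transmission geometry and backlash model parameters."""

    physical_steps_per_rev: int = 400
    microstepping: int = 8
    gear_ratio: int = 3
    backlash_usteps: int = 0
    max_speed_usteps_s: float = 48000.0
    #: anti-backlash overshoot past OREF; None -> 2x backlash, in degrees
    approach_offset_deg: float | None = None

    def __post_init__(self) -> None:
        for name in ("physical_steps_per_rev", "microstepping", "gear_ratio"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name}: must be >= 1")
        if self.backlash_usteps < 0:
            raise ConfigurationError("backlash_usteps: must be >= 0")
        if self.max_speed_usteps_s <= 0:
            raise ConfigurationError("max_speed_usteps_s: must be > 0")

    @property
    def usteps_per_rev(self) -> int:
        return self.physical_steps_per_rev * self.microstepping * self.gear_ratio

    def deg_to_usteps(self, deg: float) -> float:
        return deg * self.usteps_per_rev / 360.0

    def usteps_to_deg(self, usteps: float) -> float:
        return usteps * 360.0 / self.usteps_per_rev

    @property
    def approach_offset_usteps(self) -> int:
        if self.approach_offset_deg is None:
            return max(2 * self.backlash_usteps, 1)
        return int(round(self.deg_to_usteps(self.approach_offset_deg)))


def steps_per_revolution(cfg: MotorConfig) -> int:
    """Microsteps per shaft revolution: physical steps x microstepping x gear ratio."""
    return cfg.usteps_per_rev


@dataclass(frozen=True)
class JointState:
    """Joint state in microsteps.

    ``commanded_usteps`` is the motor-side command mapped to the shaft;
    ``output_usteps`` is the actual shaft position.  Within the dead band
    ``|commanded - output| <= backlash_usteps`` and the output only moves
    while a tooth face is engaged (``engaged_dir`` +1/-1, 0 when floating).
    """

    commanded_usteps: int = 0
    output_usteps: int = 0
    engaged_dir: int = -1
    mode: str = FOLLOW
    oref_usteps: int = 0


def command_move(state: JointState, delta_usteps: int, cfg: MotorConfig) -> JointState:
    """Advance the commanded position by ``delta_usteps`` through the dead band.

    The output is dragged so that it stays within
    ``[commanded - backlash, commanded]``: moving in the engaged direction
    transfers 1:1, a reversal first traverses the (remaining) dead band.
    """
    b = cfg.backlash_usteps
    c = state.commanded_usteps + int(delta_usteps)
    o = min(max(state.output_usteps, c - b), c)
    if b == 0:
        engaged = state.engaged_dir if delta_usteps == 0 else (1 if delta_usteps > 0 else -1)
    elif o == c - b:
        engaged = 1
    elif o == c:
        engaged = -1
    else:
        engaged = 0
    return replace(state, commanded_usteps=c, output_usteps=o, engaged_dir=engaged)


def lock_at_oref(state: JointState, cfg: MotorConfig) -> JointState:
    """Lock the shaft at OREF with the anti-backlash approach.

    The motor first reaches a position shifted from OREF by the approach
    offset (which must exceed the backlash), then moves to OREF in the fixed
    +1 direction.  The locked output angle is therefore identical across
    locks regardless of prior motion history.
    """
    approach = cfg.approach_offset_usteps
    if approach <= cfg.backlash_usteps:
        raise ConfigurationError(
            "approach_offset_deg: anti-backlash approach offset "
            f"({approach} usteps) must exceed the backlash ({cfg.backlash_usteps})"
        )
    pre_target = state.oref_usteps - approach
    state = command_move(state, pre_target - state.commanded_usteps, cfg)
    state = command_move(state, approach, cfg)
    return replace(state, mode=HR_LOCKED)


def unlock(state: JointState) -> JointState:
    return replace(state, mode=FOLLOW)


def follow(
    state: JointState, target_yaw_unwrapped_deg: float, cfg: MotorConfig, dt_s: float
) -> JointState:
    """Track the unwrapped yaw target, rate-limited by ``max_speed_usteps_s``.

    The target is the *unwrapped* yaw: fiber torsion is what is being
    tracked, so +720 deg commands two full turns, not zero.
    """
    if state.mode == HR_LOCKED:
        raise ValueError("cannot follow while locked at OREF")
    if dt_s <= 0:
        raise ValueError("dt_s must be > 0")
    target = int(round(cfg.deg_to_usteps(target_yaw_unwrapped_deg)))
    delta = target - state.commanded_usteps
    limit = int(np.floor(cfg.max_speed_usteps_s * dt_s))
    delta = int(np.clip(delta, -limit, limit))
    return command_move(state, delta, cfg)


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Acquisition timing: sequence triggers and per-frame parameters."""

    trigger_times_s: tuple
    n_frames: int = 512
    frame_interval_ms: float = 2.0
    exposure_ms: float = 2.0
    #: motor settle time before an SR exposure may start
    settle_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ConfigurationError("n_frames: must be >= 1")
        if self.frame_interval_ms <= 0 or self.exposure_ms <= 0:
            raise ConfigurationError("frame_interval_ms/exposure_ms: must be > 0")
        if self.exposure_ms > self.frame_interval_ms:
            raise ConfigurationError("exposure_ms: cannot exceed frame_interval_ms")
        t = np.asarray(self.trigger_times_s, dtype=float)
        if t.size and np.any(np.diff(t) < self.duration_s):
            raise ConfigurationError("trigger_times_s: sequences overlap")

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval_ms / 1000.0

    def frame_times(self, trigger_s: float) -> np.ndarray:
        return trigger_s + np.arange(self.n_frames) * self.frame_interval_ms / 1000.0


def run_session(
    mode: str,
    t_s: np.ndarray,
    yaw_unwrapped_deg: np.ndarray,
    schedule: AcquisitionSchedule,
    cfg: MotorConfig,
) -> dict:
    """Simulate a full session of one operating mode.

    ``t_s``/``yaw_unwrapped_deg`` is the time-aligned orientation stream
    (e.g. Madgwick output).  Returns a dict with:

    * ``frames``: DataFrame (t_s, sequence, frame, motor_deg, torsion_deg)
      giving the shaft output angle during each frame's exposure;
    * ``events``: DataFrame (t_s, event) of lock / unlock / unwind events;
    * ``trace``: DataFrame (t_s, commanded_usteps, output_deg, mode,
      torsion_deg) sampled at the orientation stream rate.
    """
    t_s = np.asarray(t_s, dtype=float)
    yaw = np.asarray(yaw_unwrapped_deg, dtype=float)
    if t_s.shape != yaw.shape or t_s.size < 2:
        raise ValueError("t_s and yaw must be equal-length series (>= 2 samples)")
    if mode not in ("HR", "SR", "HYBRID"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "SR":
        min_cycle = schedule.exposure_ms + schedule.settle_ms
        if schedule.frame_interval_ms <= min_cycle:
            raise SchedulingError(
                f"SR frame interval {schedule.frame_interval_ms} ms leaves no time "
                f"to move (exposure {schedule.exposure_ms} + settle {schedule.settle_ms} ms)"
            )

    triggers = np.asarray(schedule.trigger_times_s, dtype=float)
    seq_windows = [(tr, tr + schedule.duration_s) for tr in triggers]

    state = JointState(mode=FOLLOW)
    events: list[tuple[float, str]] = []
    trace = np.empty((t_s.size, 3))  # commanded, output_deg, torsion
    modes: list[str] = []
    unwind_revs = 0  # net full revolutions removed by HYBRID unwinds
    spr = cfg.usteps_per_rev

    def in_sequence(t: float) -> bool:
        return any(a <= t < b for a, b in seq_windows)

    def in_exposure(t: float) -> bool:
        for a, b in seq_windows:
            if a <= t < b:
                phase = (t - a) % (schedule.frame_interval_ms / 1000.0)
                return phase < schedule.exposure_ms / 1000.0
        return False

    if mode == "HYBRID":
        state = lock_at_oref(state, cfg)
        events.append((t_s[0], "lock"))

    for i, (t, psi) in enumerate(zip(t_s, yaw)):
        dt = t_s[i] - t_s[i - 1] if i else t_s[1] - t_s[0]
        if mode == "HR":
            if in_sequence(t):
                if state.mode != HR_LOCKED:
                    state = lock_at_oref(state, cfg)
                    events.append((t, "lock"))
            else:
                if state.mode == HR_LOCKED:
                    state = unlock(state)
                    events.append((t, "unlock"))
                state = follow(state, psi, cfg, dt)
        elif mode == "SR":
            if not in_exposure(t):
                state = follow(state, psi, cfg, dt)
        else:  # HYBRID
            torsion_now = psi - (cfg.usteps_to_deg(state.output_usteps) + 360.0 * unwind_revs)
            if abs(torsion_now) >= 360.0:
                # fast unwind of exactly one revolution toward the yaw, then re-lock
                direction = 1 if torsion_now > 0 else -1
                unwind_revs += direction
                state = unlock(state)
                state = command_move(state, direction * spr, cfg)
                state = lock_at_oref(state, cfg)
                events.append((t, "unwind"))
        out_deg = cfg.usteps_to_deg(state.output_usteps) + 360.0 * unwind_revs
        trace[i] = [state.commanded_usteps, out_deg, psi - out_deg]
        modes.append(state.mode)

    trace_df = pd.DataFrame(
        {
            "t_s": t_s,
            "commanded_usteps": trace[:, 0].astype(int),
            "output_deg": trace[:, 1],
            "mode": modes,
            "torsion_deg": trace[:, 2],
        }
    )

    rows = []
    for si, tr in enumerate(triggers):
        ft = schedule.frame_times(tr)
        idx = np.searchsorted(t_s, ft, side="right") - 1
        idx = np.clip(idx, 0, t_s.size - 1)
        for fi, (tf, k) in enumerate(zip(ft, idx)):
            rows.append(
                (tf, si, fi, trace_df["output_deg"].iloc[k], trace_df["torsion_deg"].iloc[k])
            )
    frames_df = pd.DataFrame(
        rows, columns=["t_s", "sequence", "frame", "motor_deg", "torsion_deg"]
    )
    events_df = pd.DataFrame(events, columns=["t_s", "event"])
    return {"frames": frames_df, "events": events_df, "trace": trace_df}
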