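"""Angular-interpolation control of the distal joints.

The hybrid arm mirrors the user's two proximal joints and machine-controls
the five distal ones.  Directly applying the network's goal posture to the
distal joints jumps abruptly whenever the movement goal changes; the
angular-interpolation controller removes that discontinuity by spreading
the remaining angular gap over the estimated remainder of the reach.

Per control tick (nominally 90 Hz), for each distal joint i:

1. ``gap_i = goal_i - theta_i(t-1)`` — angular displacement still to do,
   where ``goal`` is the saturated network prediction.
2. The hand speed is estimated from the *locked* hand position — forward
   kinematics with the distal joints frozen at their previous values — so
   that only user-driven proximal motion contributes (no feedback of the
   controller's own output into its update rate):
   ``Sh = ||Phlock(t) - Phlock(t-1)|| / (T(t) - T(t-1))``.
3. The estimated remaining movement time is ``MT_hat = R / Sh`` with ``R``
   the remaining hand-target distance, and the joint advances by
   ``gap_i / (MT_hat * Freq)`` — equivalently (when the update rate equals
   the sampling rate) by ``gap_i * s / R`` with ``s`` the per-tick locked
   hand displacement.  The timestamp-robust displacement form is the
   canonical implementation here; the frequency form is provided for
   cross-checking.
4. Once ``|gap_i|`` falls below the latch threshold (1 degree), the joint
   is considered arrived and tracks the saturated prediction directly
   until the target changes.

When the user does not move (``Sh = 0``) the distal joints hold still: the
user stays in command.  The per-tick fraction ``s / R`` is clipped to
[0, 1] so a joint never overshoots its goal when the hand is already close
to (or past) the target.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .kinematics import (
    ArmGeometry,
    RangeOfMotion,
    TargetSpec,
    forward_kinematics,
    join_angles,
    locked_hand_position,
    split_angles,
)
from .network import saturate

__all__ = [
    "ControllerConfig",
    "ControllerState",
    "target_key",
    "initial_state",
    "compute_gap",
    "locked_hand_speed",
    "estimate_movement_time",
    "angular_update",
    "angular_update_by_frequency",
    "interpolation_step",
    "direct_step",
    "reset_on_target_change",
]


@dataclass(frozen=True)
class ControllerConfig:
    """Loop rate, latch threshold and overshoot handling."""

    freq: float = 90.0  # Hz
    latch_threshold: float = 1.0  # degrees
    clip_fraction: bool = True  # clip per-tick s/R ratio to [0, 1]

    def __post_init__(self) -> None:
        if self.freq <= 0 or self.latch_threshold <= 0:
            raise ValueError("freq and latch_threshold must be positive")


@dataclass(frozen=True)
class ControllerState:
    """The controller's memory between ticks."""

    distal_prev: np.ndarray  # (5,) degrees, theta_i(t-1)
    hand_prev: np.ndarray  # (3,) meters, Ph(t-1) (= Phlock(t-1))
    time_prev: float  # seconds, T(t-1)
    latched: np.ndarray  # (5,) bool, per-joint arrival flags
    target_id: tuple | None = None


def target_key(target: TargetSpec) -> tuple:
    """Stable identifier of a target (used to detect target changes).
    Uses the object's ``uid`` when set — the same object seen from a
    translated shoulder frame is not a new movement goal — otherwise the
    rounded context vector."""
    if target.uid is not None:
        return ("uid", target.uid)
    return tuple(np.round(target.context, 9))


def initial_state(
    geometry: ArmGeometry, angles: np.ndarray, time: float = 0.0, target: TargetSpec | None = None
) -> ControllerState:
    """State at trial start: the arm rests at ``angles`` (full 7-vector)."""
    _, distal = split_angles(angles)
    pose = forward_kinematics(geometry, np.asarray(angles, dtype=float))
    return ControllerState(
        distal_prev=np.array(distal, dtype=float),
        hand_prev=pose.position,
        time_prev=float(time),
        latched=np.zeros(5, dtype=bool),
        target_id=target_key(target) if target is not None else None,
    )


def compute_gap(goal: np.ndarray, state: ControllerState) -> np.ndarray:
    """Per-joint angular displacement still to achieve (degrees)."""
    return np.asarray(goal, dtype=float) - state.distal_prev


def locked_hand_speed(
    geometry: ArmGeometry, proximal_now: np.ndarray, state: ControllerState, time_now: float
) -> float:
    """Hand speed (m/s) attributable to the user's proximal motion alone."""
    if not time_now > state.time_prev:
        raise ValueError("time must strictly increase between controller updates")
    phlock = locked_hand_position(geometry, proximal_now, state.distal_prev)
    return float(np.linalg.norm(phlock - state.hand_prev) / (time_now - state.time_prev))


def estimate_movement_time(target: TargetSpec, hand_now: np.ndarray, speed: float) -> float:
    """Estimated time (s) to cover the remaining hand-target distance at
    the current locked-hand speed.  Caller guards ``speed > 0``."""
    if speed <= 0:
        raise ValueError("speed must be positive; the zero-speed branch holds the joints")
    return float(np.linalg.norm(target.position - np.asarray(hand_now, dtype=float)) / speed)


def angular_update(
    prev: np.ndarray,
    gap: np.ndarray,
    displacement: float,
    remaining: float,
    clip_fraction: bool = True,
) -> np.ndarray:
    """Displacement-form update: ``theta + gap * (s / R)``.

    ``s`` is the locked-hand displacement this tick and ``R`` the remaining
    hand-target distance.  With ``clip_fraction`` the ratio is clipped to
    [0, 1] so the joint never moves past its goal.
    """
    if displacement == 0.0:
        return np.array(prev, dtype=float)
    frac = 1.0 if remaining <= 1e-12 else displacement / remaining
    if clip_fraction:
        frac = min(max(frac, 0.0), 1.0)
    return np.asarray(prev, dtype=float) + np.asarray(gap, dtype=float) * frac


def angular_update_by_frequency(
    prev: np.ndarray, gap: np.ndarray, mt_hat: float, freq: float
) -> np.ndarray:
    """Frequency-form update: ``theta + gap / (MT_hat * Freq)``.

    Equivalent to :func:`angular_update` whenever the tick interval equals
    ``1 / freq`` (the displacement form is then ``s / R = 1 / (MT_hat *
    Freq)``).  Kept unclipped: it is the literal formula, used for
    cross-validation of the two forms.
    """
    return np.asarray(prev, dtype=float) + np.asarray(gap, dtype=float) / (mt_hat * freq)


def interpolation_step(
    geometry: ArmGeometry,
    predictor,
    rom: RangeOfMotion,
    target: TargetSpec,
    proximal_now: np.ndarray,
    state: ControllerState,
    time_now: float,
    config: ControllerConfig = ControllerConfig(),
) -> tuple[np.ndarray, ControllerState]:
    """One control tick of the angular-interpolation method.

    Returns the distal command (5,) and the advanced state.  The state's
    ``target_id`` must match ``target`` — call :func:`reset_on_target_change`
    when the movement goal changes (this clears the latches but preserves
    the joint values, which is what makes the transition continuous).
    """
    key = target_key(target)
    if state.target_id is not None and state.target_id != key:
        raise ValueError("target changed without reset_on_target_change")
    if not time_now > state.time_prev:
        raise ValueError("time must strictly increase between controller updates")
    proximal_now = np.asarray(proximal_now, dtype=float)

    goal = saturate(
        predictor.predict_goal(target, proximal_now if getattr(predictor, "requires_proximal", False) else None),
        rom,
    )
    gap = compute_gap(goal, state)

    # current hand position: distal joints still hold their previous values,
    # so the true hand position coincides with the locked one
    phlock = locked_hand_position(geometry, proximal_now, state.distal_prev)
    displacement = float(np.linalg.norm(phlock - state.hand_prev))
    remaining = float(np.linalg.norm(target.position - phlock))

    latched = state.latched | (np.abs(gap) < config.latch_threshold)
    out = angular_update(state.distal_prev, gap, displacement, remaining, config.clip_fraction)
    out[latched] = goal[latched]

    hand_new = forward_kinematics(geometry, join_angles(proximal_now, out)).position
    new_state = ControllerState(
        distal_prev=out.copy(),
        hand_prev=hand_new,
        time_prev=float(time_now),
        latched=latched,
        target_id=key if state.target_id is None else state.target_id,
    )
    return out, new_state


def direct_step(
    predictor, rom: RangeOfMotion, target: TargetSpec, proximal_now: np.ndarray
) -> np.ndarray:
    """Direct application of the (saturated) prediction to the distal
    joints — the historical control the interpolation method replaces.
    Stateless; a target change can move every joint by the full prediction
    gap within a single tick."""
    prox = (
        np.asarray(proximal_now, dtype=float)
        if getattr(predictor, "requires_proximal", False)
        else None
    )
    return saturate(predictor.predict_goal(target, prox), rom)


def reset_on_target_change(state: ControllerState, new_target: TargetSpec) -> ControllerState:
    """Acknowledge a movement-goal change: clear the per-joint latches and
    adopt the new target id while *preserving* joint values, hand position
    and time — continuity across target changes is the point of the method.
    No-op if the target is unchanged."""
    key = target_key(new_target)
    if key == state.target_id:
        return state
    return replace(state, latched=np.zeros(5, dtype=bool), target_id=key)
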