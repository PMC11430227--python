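"""Closed-loop pick-and-place trial execution.

A simulated user moves the two proximal joints toward the shoulder posture
from which the current target was generated while the chosen control
drives the five distal joints.  A trial succeeds at the first control tick
at which the hand pose sits inside the target validation zone (position
and grasp-axis tolerance) for at least the user's reaction delay; it fails
when the time limit expires.

Controls
--------
``interpolation``
    the angular-interpolation method (smooth transition to the predicted
    goal configuration)
``direct``
    saturated network predictions applied directly to the distal joints
``natural_replay``
    the virtual arm replays a full natural 7-joint movement — the
    gold-standard control the others are compared against

The same controls can be re-applied *offline* to the recorded proximal
angles of a natural trial (:func:`offline_reconstruct`), producing the
reconstructed trajectories scored by the offline metric suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .controller import (
    ControllerConfig,
    direct_step,
    initial_state,
    interpolation_step,
)
from .kinematics import (
    DISTAL,
    PROXIMAL,
    ArmGeometry,
    RangeOfMotion,
    TargetSpec,
    forward_kinematics,
    forward_kinematics_batch,
    join_angles,
)
from .metrics import MetricsReport, phase_metrics
from .network import saturate
from .synthetic import (
    Trajectory,
    generate_natural_movement,
    simulate_user_shoulder,
)

__all__ = [
    "TrialConfig",
    "SimulatedUser",
    "TrialRecord",
    "validate_pose",
    "run_trial",
    "run_phase",
    "offline_reconstruct",
    "default_trial_filter",
]

CONTROLS = ("interpolation", "direct", "natural_replay")
#: predictor variants each control may be paired with ("oracle" = lookup stub)
_PAIRING = {
    "interpolation": {"pc+", "c+", "oracle"},
    "direct": {"pc-", "oracle"},
}


@dataclass(frozen=True)
class TrialConfig:
    """Validation-zone tolerances and trial timing."""

    distance_tolerance: float  # meters
    angle_tolerance: float  # degrees
    time_limit: float  # seconds
    freq: float = 90.0  # Hz

    def __post_init__(self) -> None:
        if min(self.distance_tolerance, self.angle_tolerance, self.time_limit, self.freq) <= 0:
            raise ValueError("all trial-config values must be positive")

    # presets used in the experiments
    @classmethod
    def exp1_test(cls) -> "TrialConfig":
        return cls(0.04, 10.0, 10.0)

    @classmethod
    def exp2_test(cls) -> "TrialConfig":
        return cls(0.03, 10.0, 6.0)

    @classmethod
    def exp1_familiarization(cls) -> "TrialConfig":
        return cls(0.02, 5.0, 5.0)


@dataclass(frozen=True)
class SimulatedUser:
    """Parameters of the simulated user's shoulder behaviour.

    The user reaches the goal proximal posture with the given profile over
    ``duration`` seconds.  Afterwards, like a human correcting online under
    visual feedback, the user servos: every tick the proximal pair takes
    the greedy step (of at most ``servo_step`` degrees per joint) that most
    reduces the visible hand-target pose error, tolerances-weighted.
    ``reaction_delay`` models the time between noticing the hand inside the
    validation zone and pressing the validation button (0 = instantaneous
    validation)."""

    duration: float = 1.5  # seconds of shoulder movement
    profile: str = "minimum_jerk"
    noise_sd: float = 0.0  # degrees
    reaction_delay: float = 0.0  # seconds
    servo: bool = True  # corrective phase after the main reach
    servo_step: float = 0.25  # degrees per joint per tick (~22 deg/s at 90 Hz)
    trunk: bool = True  # allow compensatory trunk/shoulder translation
    trunk_step: float = 0.0015  # m per tick (~13 cm/s at 90 Hz)
    trunk_range: float = 0.15  # m, max shoulder excursion from rest


@dataclass
class TrialRecord:
    """Outcome of one pick-or-place trial."""

    target: TargetSpec
    trajectory: Trajectory  # full 7-joint trajectory actually executed
    success: bool
    movement_time: float  # s, target appearance -> validation (nan if failed)
    validation_time: float  # s, last zone entry -> validation (nan if failed)
    zone_entry_times: list[float] = field(default_factory=list)
    control: str = ""
    shoulder_positions: np.ndarray | None = None  # (N, 3) if the shoulder translates


def validate_pose(pose, target: TargetSpec, cfg: TrialConfig) -> bool:
    """True iff the hand is inside the target validation zone: position
    within the distance tolerance and grasp axis within the angle
    tolerance of the target's axis.  Spin about the axis is free."""
    if np.linalg.norm(pose.position - target.position) > cfg.distance_tolerance:
        return False
    cosang = float(np.clip(np.dot(pose.rotational_axis, target.grasp_axis()), -1.0, 1.0))
    return np.degrees(np.arccos(cosang)) <= cfg.angle_tolerance


def _pose_cost(pose, target: TargetSpec, cfg: TrialConfig) -> float:
    """Tolerance-weighted pose error the simulated user tries to reduce."""
    pos_err = float(np.linalg.norm(pose.position - target.position))
    cosang = float(np.clip(np.dot(pose.rotational_axis, target.grasp_axis()), -1.0, 1.0))
    ang_err = float(np.degrees(np.arccos(cosang)))
    return pos_err / cfg.distance_tolerance + ang_err / cfg.angle_tolerance


def _servo_step(
    prox: np.ndarray,
    offset: np.ndarray,
    distal_now: np.ndarray,
    target: TargetSpec,
    geometry: ArmGeometry,
    rom: RangeOfMotion,
    cfg: TrialConfig,
    user: "SimulatedUser",
    rng: np.random.Generator | None = None,
    predictor=None,
) -> tuple[np.ndarray, np.ndarray]:
    """One tick of greedy visual-feedback correction.

    Candidate moves are +-step adjustments of the two proximal joints and,
    when trunk compensation is enabled, small shoulder translations along
    each axis; the candidate minimising the anticipated tolerance-weighted
    pose error wins.  A user familiar with the device anticipates where the
    distal joints will settle for a candidate shoulder state (the goal
    prediction there); without such an internal model the current distal
    configuration is used.  When every move would make things worse the
    user explores with a small random wiggle rather than freezing.
    """
    anticipates = predictor is not None and getattr(predictor, "requires_proximal", False)
    step = user.servo_step
    cands: list[tuple[np.ndarray, np.ndarray]] = []
    for dsfe in (-step, 0.0, step):
        for dsaa in (-step, 0.0, step):
            p = np.clip(
                prox + np.array([dsfe, dsaa]),
                rom.min_deg[PROXIMAL], rom.max_deg[PROXIMAL],
            )
            cands.append((p, offset))
    if user.trunk:
        for ax in range(3):
            for sgn in (-1.0, 1.0):
                o = offset.copy()
                o[ax] = np.clip(o[ax] + sgn * user.trunk_step, -user.trunk_range, user.trunk_range)
                cands.append((prox, o))
    best, best_cost = (prox, offset), np.inf
    for p, o in cands:
        tgt_local = target.shifted(o)
        if anticipates:
            distal_c = saturate(predictor.predict_goal(tgt_local, p), rom)
        else:
            distal_c = distal_now
        pose = forward_kinematics(geometry, join_angles(p, distal_c))
        cost = _pose_cost(pose, tgt_local, cfg)
        if cost < best_cost:
            best, best_cost = (p, o), cost
    if rng is not None and np.array_equal(best[0], prox) and np.array_equal(best[1], offset):
        wiggled = np.clip(
            prox + rng.uniform(-step, step, 2),
            rom.min_deg[PROXIMAL], rom.max_deg[PROXIMAL],
        )
        return wiggled, offset
    return best


def _check_pairing(control: str, predictor) -> None:
    if control not in CONTROLS:
        raise ValueError(f"unknown control {control!r}; expected one of {CONTROLS}")
    if control == "natural_replay":
        return
    if predictor is None:
        raise ValueError(f"control {control!r} needs a predictor")
    variant = getattr(predictor, "variant", None)
    if variant not in _PAIRING[control]:
        raise ValueError(f"control {control!r} cannot be paired with predictor variant {variant!r}")


def run_trial(
    control: str,
    predictor,
    target: TargetSpec,
    goal_posture: np.ndarray,
    start_angles: np.ndarray,
    geometry: ArmGeometry,
    rom: RangeOfMotion,
    cfg: TrialConfig,
    user: SimulatedUser = SimulatedUser(),
    seed: int | None = None,
) -> TrialRecord:
    """Execute one closed-loop trial.

    ``goal_posture`` is the 7-joint configuration the target was generated
    from; the simulated user steers the proximal joints toward its
    proximal pair (and, under ``natural_replay``, the whole arm replays a
    natural movement toward it).
    """
    _check_pairing(control, predictor)
    start_angles = np.asarray(start_angles, dtype=float)
    goal_posture = np.asarray(goal_posture, dtype=float)
    ctrl_cfg = ControllerConfig(freq=cfg.freq)
    if target.uid is None:  # one movement goal per trial
        target = TargetSpec(target.position, target.alpha, target.beta, uid=0)

    rng = np.random.default_rng(seed)
    _, prox_traj = simulate_user_shoulder(
        start_angles[PROXIMAL], goal_posture[PROXIMAL], user.duration, cfg.freq,
        user.profile, user.noise_sd, seed,
    )
    if control == "natural_replay":
        nat = generate_natural_movement(start_angles, goal_posture, user.duration, cfg.freq)

    n_ticks = int(np.floor(cfg.time_limit * cfg.freq))
    state = initial_state(geometry, start_angles, time=0.0, target=target)
    times = [0.0]
    angles = [start_angles.copy()]
    entries: list[float] = []
    in_zone = validate_pose(forward_kinematics(geometry, start_angles), target, cfg)
    if in_zone:
        entries.append(0.0)
    success, mt, vt = False, np.nan, np.nan

    distal_cur = start_angles[DISTAL].copy()
    prox = start_angles[PROXIMAL].copy()
    offset = np.zeros(3)  # shoulder translation from trunk compensation
    offsets = [offset.copy()]
    for k in range(1, n_ticks + 1):
        t = k / cfg.freq
        if k < len(prox_traj):
            prox = prox_traj[k]
        elif user.servo and control != "natural_replay":
            prox, offset = _servo_step(
                prox, offset, distal_cur, target, geometry, rom, cfg, user, rng, predictor
            )
        else:
            prox = prox_traj[-1]
        tgt_local = target.shifted(offset)
        if control == "interpolation":
            distal, state = interpolation_step(
                geometry, predictor, rom, tgt_local, prox, state, t, ctrl_cfg
            )
        elif control == "direct":
            distal = direct_step(predictor, rom, tgt_local, prox)
        else:  # natural_replay
            nat_angles = nat.angles[k] if k < len(nat) else nat.angles[-1]
            prox, distal = nat_angles[PROXIMAL], nat_angles[DISTAL]
        distal_cur = distal
        full = join_angles(prox, distal)
        times.append(t)
        angles.append(full)
        offsets.append(offset.copy())

        pose = forward_kinematics(geometry, full)
        valid_now = validate_pose(pose, tgt_local, cfg)
        if valid_now and not in_zone:
            entries.append(t)
        in_zone = valid_now
        if in_zone and entries and (t - entries[-1]) >= user.reaction_delay:
            success, mt, vt = True, t, t - entries[-1]
            break

    traj = Trajectory(np.array(times), np.vstack(angles))
    return TrialRecord(
        target=target,
        trajectory=traj,
        success=success,
        movement_time=mt,
        validation_time=vt,
        zone_entry_times=entries,
        control=control,
        shoulder_positions=np.vstack(offsets),
    )


def default_trial_filter(record: TrialRecord, geometry: ArmGeometry) -> bool:
    """Keep a trial unless its hand path contains a non-physiological jump
    (> 0.5 m between consecutive ticks) — a stand-in for the motion-capture
    artifact screening applied to human recordings."""
    pos, _ = record.trajectory.hand_path(geometry)
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    return bool(np.all(steps <= 0.5))


def run_phase(
    targets: list[TargetSpec],
    goal_postures: np.ndarray,
    control: str,
    predictor,
    geometry: ArmGeometry,
    rom: RangeOfMotion,
    cfg: TrialConfig,
    user: SimulatedUser = SimulatedUser(),
    seed: int | None = None,
    trial_filter=default_trial_filter,
) -> tuple[list[TrialRecord], MetricsReport]:
    """Run every target in order as one experimental phase.

    Trials chain: each starts from the posture at which the previous trial
    ended (the pick-then-place alternation).  The first trial starts from
    the mid-range posture.  Metrics are aggregated over the trials kept by
    ``trial_filter``.
    """
    if not targets:
        raise ValueError("no targets")
    _check_pairing(control, predictor)
    goal_postures = np.atleast_2d(goal_postures)
    rng = np.random.default_rng(seed)
    start = 0.5 * (rom.min_deg + rom.max_deg)
    records: list[TrialRecord] = []
    for tg, posture in zip(targets, goal_postures):
        trial_seed = int(rng.integers(2**31))
        rec = run_trial(
            control, predictor, tg, posture, start, geometry, rom, cfg, user, trial_seed
        )
        records.append(rec)
        start = rec.trajectory.angles[-1]
    kept = [r for r in records if trial_filter is None or trial_filter(r, geometry)]
    report = phase_metrics(kept if kept else records, geometry)
    return records, report


def offline_reconstruct(
    control: str,
    natural_trial: TrialRecord,
    predictor,
    geometry: ArmGeometry,
    rom: RangeOfMotion,
    cfg: TrialConfig,
) -> Trajectory:
    """Re-apply a control to the proximal angles recorded in a successful
    natural trial, tick by tick, returning the reconstructed 7-joint
    trajectory (same length and timestamps as the input).

    ``natural_replay`` reconstructs the input identically; the others
    replace the distal joints with their own commands, which is what the
    offline metric suite (MMAE / MHPD / MHOD) scores.
    """
    if not natural_trial.success:
        raise ValueError("offline reconstruction applies to successful trials only")
    _check_pairing(control, predictor)
    src = natural_trial.trajectory
    target = natural_trial.target
    ctrl_cfg = ControllerConfig(freq=cfg.freq)
    out = src.angles.copy()
    if control == "natural_replay":
        return Trajectory(src.t.copy(), out)
    state = initial_state(geometry, src.angles[0], time=src.t[0], target=target)
    for k in range(1, len(src)):
        prox = src.angles[k, PROXIMAL]
        if control == "interpolation":
            distal, state = interpolation_step(
                geometry, predictor, rom, target, prox, state, src.t[k], ctrl_cfg
            )
        else:
            distal = direct_step(predictor, rom, target, prox)
        out[k, DISTAL] = distal
    return Trajectory(src.t.copy(), out)
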