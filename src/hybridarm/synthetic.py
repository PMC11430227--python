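"""Synthetic natural-movement generation.

Everything the control pipeline normally obtains from humans is generated
here: smooth 7-joint pick-and-place trajectories (a stand-in for a recorded
natural-movement database), training samples pairing arm postures with the
pose of a hypothetical object held in the hand, plausible/possible target
sets, and simulated shoulder motion to drive closed-loop trials.

Movements are joint-space minimum-jerk profiles between postures sampled
inside per-joint ranges of motion, sampled at the simulator's nominal 90 Hz.
Successive movements chain start-to-end, mimicking the alternating
pick-then-place structure of the task.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinematics import (
    DISTAL,
    JOINT_NAMES,
    PROXIMAL,
    ArmGeometry,
    RangeOfMotion,
    TargetSpec,
    forward_kinematics_batch,
    _axis_projection_angles,
)

__all__ = [
    "Trajectory",
    "TrainingSet",
    "minimum_jerk_profile",
    "generate_natural_movement",
    "generate_pick_and_place",
    "functional_rom",
    "jitter_rom",
    "synthetic_database",
    "sample_postures",
    "sample_plausible_targets",
    "sample_possible_targets",
    "rom_from_database",
    "build_training_set",
    "simulate_user_shoulder",
    "targets_to_frame",
    "targets_from_frame",
]

NOMINAL_FREQ = 90.0  # Hz, acquisition and control-loop rate

#: Functional distal ranges (degrees) used when sampling *natural-like*
#: movement waypoints.  Natural reaching does not exercise the anatomical
#: extremes of every joint at once: amplitudes here follow the upper-limb
#: functional range-of-motion literature (elbow 30-130, pronosupination
#: +-50, humeral rotation +-30, wrist deviation -10..15, wrist flexion
#: +-20).  The proximal joints span the user's full shoulder range.
FUNCTIONAL_DISTAL_RANGE: dict[str, tuple[float, float]] = {
    "hr": (-30.0, 30.0),
    "efe": (30.0, 130.0),
    "fps": (-50.0, 50.0),
    "wru": (-10.0, 15.0),
    "wfe": (-20.0, 20.0),
}


def functional_rom(rom: RangeOfMotion) -> RangeOfMotion:
    """The waypoint-sampling range for natural-like movements: the user's
    shoulder range with distal joints restricted to the intersection of
    their anatomical range and the functional amplitudes above."""
    lo, hi = rom.min_deg.copy(), rom.max_deg.copy()
    for name, (flo, fhi) in FUNCTIONAL_DISTAL_RANGE.items():
        i = JOINT_NAMES.index(name)
        lo[i], hi[i] = max(lo[i], flo), min(hi[i], fhi)
    return RangeOfMotion(lo, hi)


@dataclass
class Trajectory:
    """A time-stamped sequence of 7-joint configurations.

    ``t`` has shape (N,), strictly increasing seconds; ``angles`` has shape
    (N, 7), degrees, columns in canonical joint order.
    """

    t: np.ndarray
    angles: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.t.ndim != 1 or self.angles.shape != (self.t.size, 7):
            raise ValueError("need t of shape (N,) and angles of shape (N, 7)")
        if self.t.size < 2:
            raise ValueError("a trajectory needs at least two samples")
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def hand_path(self, geometry: ArmGeometry) -> tuple[np.ndarray, np.ndarray]:
        """Hand positions (N, 3) and grasp axes (N, 3) along the trajectory."""
        return forward_kinematics_batch(geometry, self.angles)

    def to_frame(self, geometry: ArmGeometry | None = None) -> pd.DataFrame:
        df = pd.DataFrame(self.angles, columns=list(JOINT_NAMES))
        df.insert(0, "t", self.t)
        if geometry is not None:
            pos, _ = self.hand_path(geometry)
            df[["x", "y", "z"]] = pos
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Trajectory":
        return cls(df["t"].to_numpy(), df[list(JOINT_NAMES)].to_numpy())

    def to_csv(self, path, geometry: ArmGeometry | None = None) -> None:
        self.to_frame(geometry).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class TrainingSet:
    """Posture/context pairs for goal-predictor training.

    ``contexts`` holds (x, y, z, alpha, beta) of the hypothetical object in
    the hand, recomputed with the *user's* arm geometry (morphology
    retargeting); ``angles`` holds the generating 7-joint configurations.
    """

    contexts: np.ndarray  # (N, 5)
    angles: np.ndarray  # (N, 7)

    def __post_init__(self) -> None:
        self.contexts = np.asarray(self.contexts, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.contexts.shape != (self.angles.shape[0], 5) or self.angles.shape[1] != 7:
            raise ValueError("contexts must be (N, 5) and angles (N, 7)")

    def __len__(self) -> int:
        return self.angles.shape[0]

    @property
    def proximal(self) -> np.ndarray:
        return self.angles[:, PROXIMAL]

    @property
    def distal(self) -> np.ndarray:
        return self.angles[:, DISTAL]

    def consistency_error(self, geometry: ArmGeometry) -> float:
        """Max deviation between stored contexts and contexts recomputed
        from the stored angles (should be ~0 by construction)."""
        pos, axes = forward_kinematics_batch(geometry, self.angles)
        alpha, beta = _axis_projection_angles(axes)
        recomputed = np.column_stack([pos, alpha, beta])
        return float(np.max(np.abs(recomputed - self.contexts)))


def minimum_jerk_profile(tau: np.ndarray) -> np.ndarray:
    """Normalised minimum-jerk position profile 10 tau^3 - 15 tau^4 + 6 tau^5."""
    tau = np.asarray(tau, dtype=float)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def generate_natural_movement(
    start: np.ndarray, end: np.ndarray, duration: float, freq: float = NOMINAL_FREQ
) -> Trajectory:
    """Joint-space minimum-jerk movement from ``start`` to ``end`` postures.

    Every joint follows the same normalised time profile, which gives zero
    velocity and acceleration at both endpoints and a single-peaked,
    bell-shaped speed profile — the standard smooth stand-in for natural
    point-to-point reaching.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    n = max(int(round(duration * freq)), 1) + 1
    t = np.arange(n) / freq
    tau = t / duration
    angles = start[None, :] + minimum_jerk_profile(tau)[:, None] * (end - start)[None, :]
    angles[-1] = end  # endpoints exact
    return Trajectory(t, angles)


def sample_postures(
    rom: RangeOfMotion, n: int, rng: np.random.Generator, elbow_scale: float | None = None
) -> np.ndarray:
    """Draw ``n`` postures uniformly within the range of motion; with
    ``elbow_scale`` the elbow interval is shrunk about its midpoint (the
    85% rule that keeps generated postures away from full arm extension)."""
    if n <= 0:
        raise ValueError("n must be positive")
    r = rom if elbow_scale is None else rom.scaled("efe", elbow_scale)
    return rng.uniform(r.min_deg, r.max_deg, size=(n, 7))


def _targets_from_postures(geometry: ArmGeometry, postures: np.ndarray) -> list[TargetSpec]:
    pos, axes = forward_kinematics_batch(geometry, postures)
    alpha, beta = _axis_projection_angles(axes)
    return [
        TargetSpec(position=pos[i], alpha=float(alpha[i]), beta=float(beta[i]))
        for i in range(postures.shape[0])
    ]


def sample_plausible_targets(
    geometry: ArmGeometry,
    rom: RangeOfMotion,
    n: int = 300,
    elbow_scale: float = 0.85,
    seed: int | np.random.Generator | None = None,
    return_postures: bool = False,
):
    """Generate a *plausible* target set: each target is the pose of the
    object a hand would hold at a posture drawn uniformly inside the range
    of motion (elbow shrunk to ``elbow_scale`` of its span).  Every target
    is reachable by construction.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    postures = sample_postures(rom, n, rng, elbow_scale=elbow_scale)
    targets = _targets_from_postures(geometry, postures)
    return (targets, postures) if return_postures else targets


def sample_possible_targets(
    trajectories: list[Trajectory],
    geometry: ArmGeometry,
    n: int = 200,
    seed: int | np.random.Generator | None = None,
    return_postures: bool = False,
):
    """Generate a *possible* target set from configurations actually
    visited by the supplied trajectories."""
    if not trajectories:
        raise ValueError("trajectory pool is empty")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pool = np.vstack([tr.angles for tr in trajectories])
    idx = rng.integers(0, pool.shape[0], size=n)
    postures = pool[idx]
    targets = _targets_from_postures(geometry, postures)
    return (targets, postures) if return_postures else targets


def generate_pick_and_place(
    rom: RangeOfMotion,
    n_movements: int,
    duration_range: tuple[float, float] = (0.9, 1.3),
    freq: float = NOMINAL_FREQ,
    natural_amplitudes: bool = True,
    seed: int | np.random.Generator | None = None,
) -> list[Trajectory]:
    """A chain of ``n_movements`` minimum-jerk movements between waypoint
    postures, each starting where the previous ended (pick-then-place
    alternation).  Durations are drawn uniformly from ``duration_range``
    seconds.  With ``natural_amplitudes`` (the default) waypoints are drawn
    from :func:`functional_rom` — natural reaching keeps the distal joints
    within their functional amplitudes — otherwise uniformly over ``rom``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    wrom = functional_rom(rom) if natural_amplitudes else rom
    waypoints = sample_postures(wrom, n_movements + 1, rng)
    durations = rng.uniform(*duration_range, size=n_movements)
    return [
        generate_natural_movement(waypoints[i], waypoints[i + 1], durations[i], freq)
        for i in range(n_movements)
    ]


def jitter_rom(
    rom: RangeOfMotion, rng: np.random.Generator, fraction: float = 0.05
) -> RangeOfMotion:
    """Perturb each joint limit by up to ``fraction`` of the joint span —
    one synthetic 'participant' differs from another by such a jitter."""
    span = rom.span
    lo = rom.min_deg + rng.uniform(-fraction, fraction, 7) * span
    hi = rom.max_deg + rng.uniform(-fraction, fraction, 7) * span
    return RangeOfMotion(lo, np.maximum(hi, lo + 1.0))


def synthetic_database(
    rom: RangeOfMotion,
    n_participants: int = 12,
    movements_per_participant: int = 42,
    duration_range: tuple[float, float] = (0.9, 1.3),
    freq: float = NOMINAL_FREQ,
    seed: int | None = None,
) -> list[Trajectory]:
    """Emulate a multi-participant natural pick-and-place database: each
    synthetic participant has an independently jittered range of motion and
    contributes a chain of minimum-jerk movements.  Defaults give ~500
    movements of ~100 frames each (~50k samples at 90 Hz)."""
    rng = np.random.default_rng(seed)
    movements: list[Trajectory] = []
    for _ in range(n_participants):
        prom = jitter_rom(rom, rng)
        movements.extend(
            generate_pick_and_place(prom, movements_per_participant, duration_range, freq, seed=rng)
        )
    return movements


def rom_from_database(
    trajectories: list[Trajectory],
    shoulder_rom: RangeOfMotion,
    lo_q: float = 0.05,
    hi_q: float = 0.95,
) -> RangeOfMotion:
    """Range of motion with proximal limits taken from the user's shoulder
    and distal limits from the (5-95%) quantiles of the distal excursions
    observed in a movement database — the rule used when the user's own
    distal joints cannot be measured."""
    pool = np.vstack([tr.angles for tr in trajectories])
    lo = shoulder_rom.min_deg.copy()
    hi = shoulder_rom.max_deg.copy()
    lo[DISTAL] = np.quantile(pool[:, DISTAL], lo_q, axis=0)
    hi[DISTAL] = np.quantile(pool[:, DISTAL], hi_q, axis=0)
    return RangeOfMotion(lo, hi)


def build_training_set(trajectories: list[Trajectory], geometry: ArmGeometry) -> TrainingSet:
    """One training sample per frame: the frame's 7 joint angles paired
    with the pose of a hypothetical object held in the hand, computed by
    applying those angles to an arm with the *user's* segment lengths
    (morphology retargeting)."""
    angles = np.vstack([tr.angles for tr in trajectories])
    pos, axes = forward_kinematics_batch(geometry, angles)
    alpha, beta = _axis_projection_angles(axes)
    contexts = np.column_stack([pos, alpha, beta])
    return TrainingSet(contexts=contexts, angles=angles)


def simulate_user_shoulder(
    start_proximal: np.ndarray,
    goal_proximal: np.ndarray,
    duration: float = 1.5,
    freq: float = NOMINAL_FREQ,
    profile: str = "minimum_jerk",
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulated user shoulder motion: a proximal-only (sfe, saa) movement
    from ``start_proximal`` to ``goal_proximal``.

    Profiles: ``minimum_jerk`` (smooth reach), ``constant_speed`` (linear
    ramp), ``noisy`` (minimum jerk plus seeded Gaussian angle noise of
    ``noise_sd`` degrees, endpoints exact).

    Returns (t (N,), proximal (N, 2) degrees).
    """
    start = np.asarray(start_proximal, dtype=float)
    goal = np.asarray(goal_proximal, dtype=float)
    n = max(int(round(duration * freq)), 1) + 1
    t = np.arange(n) / freq
    tau = t / duration
    if profile == "constant_speed":
        shape = tau
    elif profile in ("minimum_jerk", "noisy"):
        shape = minimum_jerk_profile(tau)
    else:
        raise ValueError(f"unknown profile {profile!r}")
    prox = start[None, :] + shape[:, None] * (goal - start)[None, :]
    if profile == "noisy" and noise_sd > 0:
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        noise = rng.normal(0.0, noise_sd, size=prox.shape)
        noise[0] = noise[-1] = 0.0
        prox = prox + noise
    prox[-1] = goal
    return t, prox


def targets_to_frame(targets: list[TargetSpec]) -> pd.DataFrame:
    return pd.DataFrame(
        [[*tg.position, tg.alpha, tg.beta] for tg in targets],
        columns=["x", "y", "z", "alpha", "beta"],
    )


def targets_from_frame(df: pd.DataFrame) -> list[TargetSpec]:
    return [
        TargetSpec(position=row[["x", "y", "z"]].to_numpy(dtype=float), alpha=float(row["alpha"]), beta=float(row["beta"]))
        for _, row in df.iterrows()
    ]
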