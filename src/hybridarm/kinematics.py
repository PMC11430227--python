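"""Seven-degree-of-freedom kinematic model of the human arm.

The arm is modelled as an open chain of seven revolute joints — three at the
shoulder (flexion/extension ``sfe``, adduction/abduction ``saa``, humeral
rotation ``hr``), one at the elbow (``efe``), one along the forearm
(pronation/supination ``fps``) and two at the wrist (radial/ulnar deviation
``wru``, flexion/extension ``wfe``) — connected by three rigid segments
(upper arm, forearm, hand).

Reference frame
---------------
Origin at the shoulder, axes trunk-aligned: ``+x`` rightward, ``+y`` upward,
``+z`` forward.  The reference posture (all angles zero) is the arm hanging
along the trunk, i.e. the chain fully extended along ``-y``.  All angles are
in degrees, all positions in meters.

Sign conventions (right arm):

====== ============ ======================================================
joint  local axis   positive direction
====== ============ ======================================================
sfe    -x           flexion: arm moves forward (+z)
saa    +z           abduction: arm moves laterally (+x)
hr     +y           humeral rotation about the upper-arm long axis
efe    -x           flexion: forearm moves forward
fps    +y           pronation/supination about the forearm long axis
wru    +z           radial/ulnar deviation
wfe    -x           wrist flexion
====== ============ ======================================================

The hand's *grasp axis* — the axis of a cylindrical object held in the
hand, the one degree of freedom left unconstrained by the task — is the
distal direction of the hand segment.  Its orientation is summarised by two
projection angles: ``alpha``, measured in the frontal (x-y) plane, and
``beta``, measured in the sagittal (y-z) plane, both zero for a vertical,
downward-pointing axis and signed in (-180, 180].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "JOINT_NAMES",
    "PROXIMAL",
    "DISTAL",
    "ArmGeometry",
    "HandPose",
    "TargetSpec",
    "RangeOfMotion",
    "joint_angles",
    "split_angles",
    "join_angles",
    "forward_kinematics",
    "forward_kinematics_batch",
    "locked_hand_position",
    "context_from_pose",
    "default_geometry",
    "default_rom",
]

JOINT_NAMES: tuple[str, ...] = ("sfe", "saa", "hr", "efe", "fps", "wru", "wfe")
#: index slices into a 7-vector of joint angles
PROXIMAL = slice(0, 2)  # sfe, saa — under direct user control
DISTAL = slice(2, 7)  # hr, efe, fps, wru, wfe — machine-controlled

#: revolute-joint table of the chain: (joint name, local rotation axis,
#: sign of a positive anatomical angle).  Together with the segment
#: translations in :meth:`ArmGeometry.joint_table` this fixes the chain in a
#: DH-equivalent way (successive axes twisted by +-90 degrees).
CHAIN: tuple[tuple[str, str, float], ...] = (
    ("sfe", "x", -1.0),
    ("saa", "z", +1.0),
    ("hr", "y", +1.0),
    ("efe", "x", -1.0),
    ("fps", "y", +1.0),
    ("wru", "z", +1.0),
    ("wfe", "x", -1.0),
)

#: index of the joint after which each segment translation is applied
_SEGMENT_AFTER = {2: "upper_arm_length", 4: "forearm_length", 6: "hand_length"}

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}
_DOWN = np.array([0.0, -1.0, 0.0])


@dataclass(frozen=True)
class ArmGeometry:
    """Segment lengths of the arm, in meters."""

    upper_arm_length: float = 0.31
    forearm_length: float = 0.27
    hand_length: float = 0.10

    def __post_init__(self) -> None:
        for name in ("upper_arm_length", "forearm_length", "hand_length"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def total_length(self) -> float:
        return self.upper_arm_length + self.forearm_length + self.hand_length

    def joint_table(self) -> list[dict]:
        """The 7-row joint table: rotation axis, sign and the segment
        translation (in the local frame) applied distally to each joint."""
        rows = []
        for i, (name, axis, sign) in enumerate(CHAIN):
            seg = _SEGMENT_AFTER.get(i)
            trans = _DOWN * getattr(self, seg) if seg else np.zeros(3)
            rows.append({"joint": name, "axis": axis, "sign": sign, "translation": trans})
        return rows

    def to_dict(self) -> dict:
        return {
            "upper_arm_length": self.upper_arm_length,
            "forearm_length": self.forearm_length,
            "hand_length": self.hand_length,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArmGeometry":
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass(frozen=True)
class HandPose:
    """Hand position and grasp-axis orientation in the shoulder frame."""

    position: np.ndarray  # (3,) meters
    rotational_axis: np.ndarray  # (3,) unit vector, cylinder-grasp axis
    alpha: float  # degrees, frontal-plane projection angle
    beta: float  # degrees, sagittal-plane projection angle


@dataclass(frozen=True)
class TargetSpec:
    """A movement goal: where the hand must go and how the grasp axis must
    be oriented (position of the object's mid point plus frontal and
    sagittal orientation angles).  Spin about the grasp axis is free."""

    position: np.ndarray  # (3,) meters, shoulder frame
    alpha: float  # degrees
    beta: float  # degrees
    uid: int | None = None  # object identity, stable under frame shifts

    def shifted(self, offset: np.ndarray) -> "TargetSpec":
        """The same physical target seen from a shoulder translated by
        ``offset`` (trunk compensation moves the target in the shoulder
        frame, not the hand)."""
        return TargetSpec(
            position=np.asarray(self.position, float) - np.asarray(offset, float),
            alpha=self.alpha, beta=self.beta, uid=self.uid,
        )

    @property
    def context(self) -> np.ndarray:
        """The (x, y, z, alpha, beta) vector fed to the goal predictor."""
        return np.array([*self.position, self.alpha, self.beta])

    def grasp_axis(self) -> np.ndarray:
        """Unit grasp axis reconstructed from the (alpha, beta) projections."""
        return _axis_from_projections(self.alpha, self.beta)


@dataclass(frozen=True)
class RangeOfMotion:
    """Per-joint angular limits in degrees, in canonical joint order."""

    min_deg: np.ndarray
    max_deg: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.min_deg, dtype=float)
        hi = np.asarray(self.max_deg, dtype=float)
        object.__setattr__(self, "min_deg", lo)
        object.__setattr__(self, "max_deg", hi)
        if lo.shape != (7,) or hi.shape != (7,):
            raise ValueError("RangeOfMotion needs exactly seven (min, max) pairs")
        if not np.all(lo < hi):
            raise ValueError("every joint must satisfy min_deg < max_deg")

    @property
    def span(self) -> np.ndarray:
        return self.max_deg - self.min_deg

    def distal(self) -> tuple[np.ndarray, np.ndarray]:
        return self.min_deg[DISTAL], self.max_deg[DISTAL]

    def contains(self, angles: np.ndarray) -> bool:
        a = np.asarray(angles, dtype=float)
        return bool(np.all(a >= self.min_deg - 1e-9) and np.all(a <= self.max_deg + 1e-9))

    def scaled(self, joint: str, fraction: float) -> "RangeOfMotion":
        """Return a copy with one joint's interval shrunk to ``fraction`` of
        its span about its midpoint (used for the 85% elbow rule)."""
        if not 0 < fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        i = JOINT_NAMES.index(joint)
        lo, hi = self.min_deg.copy(), self.max_deg.copy()
        mid, half = 0.5 * (lo[i] + hi[i]), 0.5 * (hi[i] - lo[i]) * fraction
        lo[i], hi[i] = mid - half, mid + half
        return RangeOfMotion(lo, hi)

    def to_dict(self) -> dict:
        return {n: [float(lo), float(hi)] for n, lo, hi in zip(JOINT_NAMES, self.min_deg, self.max_deg)}

    @classmethod
    def from_dict(cls, d: dict) -> "RangeOfMotion":
        lo = [float(d[n][0]) for n in JOINT_NAMES]
        hi = [float(d[n][1]) for n in JOINT_NAMES]
        return cls(np.array(lo), np.array(hi))


def default_geometry() -> ArmGeometry:
    return ArmGeometry()


def default_rom() -> RangeOfMotion:
    """Physiologically plausible default joint limits (degrees)."""
    lo = np.array([-40.0, -10.0, -60.0, 0.0, -80.0, -20.0, -60.0])
    hi = np.array([130.0, 120.0, 60.0, 145.0, 80.0, 30.0, 60.0])
    return RangeOfMotion(lo, hi)


def joint_angles(sfe=0.0, saa=0.0, hr=0.0, efe=0.0, fps=0.0, wru=0.0, wfe=0.0) -> np.ndarray:
    """Build a 7-vector of joint angles (degrees) in canonical order."""
    return np.array([sfe, saa, hr, efe, fps, wru, wfe], dtype=float)


def split_angles(angles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a 7-vector into (proximal (2,), distal (5,))."""
    a = np.asarray(angles, dtype=float)
    return a[..., PROXIMAL], a[..., DISTAL]


def join_angles(proximal: np.ndarray, distal: np.ndarray) -> np.ndarray:
    """Concatenate proximal (2,) and distal (5,) back into a 7-vector."""
    return np.concatenate([np.asarray(proximal, float), np.asarray(distal, float)], axis=-1)


def _rotation(axis: str, deg: np.ndarray) -> np.ndarray:
    """Batch rotation matrices about a coordinate axis; deg shape (N,) -> (N, 3, 3)."""
    t = np.deg2rad(np.asarray(deg, dtype=float))
    c, s = np.cos(t), np.sin(t)
    n = t.shape[0]
    R = np.zeros((n, 3, 3))
    i = _AXIS_INDEX[axis]
    j, k = (i + 1) % 3, (i + 2) % 3
    R[:, i, i] = 1.0
    R[:, j, j] = c
    R[:, k, k] = c
    R[:, j, k] = -s
    R[:, k, j] = s
    return R


def _axis_projection_angles(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(alpha, beta) in degrees from grasp axes, shape (..., 3)."""
    ax, ay, az = axis[..., 0], axis[..., 1], axis[..., 2]
    alpha = np.degrees(np.arctan2(ax, -ay))
    beta = np.degrees(np.arctan2(az, -ay))
    return alpha, beta


def _axis_from_projections(alpha: float, beta: float) -> np.ndarray:
    """Unit axis whose frontal/sagittal projection angles are (alpha, beta).

    Degenerate when both projections approach +-90 deg (horizontal axis); the
    task-geometry modules keep targets away from that singularity.
    """
    ta, tb = np.tan(np.radians(alpha)), np.tan(np.radians(beta))
    v = np.array([ta, -1.0, tb])
    v /= np.linalg.norm(v)
    if abs(alpha) > 90.0 or abs(beta) > 90.0:  # axis points upward
        v = -v
    return v


def forward_kinematics_batch(
    geometry: ArmGeometry, angles: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised forward kinematics.

    Parameters
    ----------
    geometry : ArmGeometry
    angles : array, shape (N, 7), degrees

    Returns
    -------
    positions : (N, 3) hand grasp-point positions, meters
    axes : (N, 3) unit grasp axes
    """
    a = np.atleast_2d(np.asarray(angles, dtype=float))
    if a.shape[1] != 7:
        raise ValueError("angles must have seven columns")
    n = a.shape[0]
    R = np.broadcast_to(np.eye(3), (n, 3, 3)).copy()
    p = np.zeros((n, 3))
    for i, (_, axis, sign) in enumerate(CHAIN):
        R = R @ _rotation(axis, sign * a[:, i])
        seg = _SEGMENT_AFTER.get(i)
        if seg:
            p = p + (R @ (_DOWN * getattr(geometry, seg)))
    grasp = R @ _DOWN
    return p, grasp


def forward_kinematics(geometry: ArmGeometry, angles: np.ndarray) -> HandPose:
    """Map one 7-vector of joint angles (degrees) to the hand pose.

    The position is the grasp point at the distal end of the hand segment;
    the rotational axis is the cylinder-grasp axis (see module docstring).
    """
    a = np.asarray(angles, dtype=float)
    if a.shape != (7,):
        raise ValueError("expected exactly seven joint angles")
    if not np.all(np.isfinite(a)):
        raise ValueError("joint angles must be finite")
    p, grasp = forward_kinematics_batch(geometry, a[None, :])
    alpha, beta = _axis_projection_angles(grasp[0])
    return HandPose(position=p[0], rotational_axis=grasp[0], alpha=float(alpha), beta=float(beta))


def locked_hand_position(
    geometry: ArmGeometry, proximal_now: np.ndarray, distal_prev: np.ndarray
) -> np.ndarray:
    """Hand position with the five distal joints frozen at their previous
    values while the proximal joints take their current values.

    This is the "locked" position used to estimate hand speed from user
    motion alone, so that machine-driven distal motion cannot feed back into
    its own update rate.
    """
    return forward_kinematics(geometry, join_angles(proximal_now, distal_prev)).position


def context_from_pose(pose: HandPose) -> TargetSpec:
    """The target a hand at ``pose`` would be grasping: a hypothetical
    object placed in the hand, described by position and (alpha, beta)."""
    return TargetSpec(position=np.array(pose.position, dtype=float), alpha=pose.alpha, beta=pose.beta)
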