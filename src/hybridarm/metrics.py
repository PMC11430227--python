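"""Online and offline trajectory metrics.

Online (computed from trials as they were executed):

* success rate (SR), movement time (MT), validation time (VT)
* shoulder spread volume (SV) — volume of the covariance ellipsoid
  covering 97% of the recorded shoulder positions, an index of
  compensatory trunk/shoulder movement
* spectral arc length (SAL) — frequency-domain smoothness of the hand
  speed profile (between -1 and -inf; more negative = less smooth)
* trajectory curvature (CT) — maximum deviation of the hand from the
  straight line joining the initial and final hand positions
* distance index (DI) — hand path length over straight-line distance

Offline (comparing a control-reconstructed trajectory with the natural
one it was derived from):

* MMAE — mean absolute joint-angle error, proximal pair and distal five
  separately
* MHPD — median hand position distance
* MHOD — median angle between the two hands' grasp axes (spin-free)

Per-trial values are aggregated across a phase by the median, and MT/VT
and the trajectory metrics are computed on successful trials only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .kinematics import DISTAL, PROXIMAL, ArmGeometry, forward_kinematics_batch
from .synthetic import Trajectory

__all__ = [
    "success_rate",
    "movement_time",
    "validation_time",
    "shoulder_spread_volume",
    "spectral_arc_length",
    "curvature_of_trajectory",
    "distance_index",
    "offline_distances",
    "phase_metrics",
    "MetricsReport",
]

#: Gaussian coverage fraction of the spread ellipsoid
SV_COVERAGE = 0.97
#: spectral-arc-length parameters: cutoff frequency (Hz) and zero-padding factor
SAL_CUTOFF_HZ = 20.0
SAL_PADDING = 4


def success_rate(records) -> float:
    """Percentage of successful trials."""
    records = list(records)
    if not records:
        raise ValueError("no trials")
    return 100.0 * sum(r.success for r in records) / len(records)


def movement_time(record) -> float:
    """Seconds from target appearance to validation (successful trials)."""
    if not record.success:
        raise ValueError("movement time is defined for successful trials only")
    return float(record.movement_time)


def validation_time(record) -> float:
    """Seconds from the *last* entry into the validation zone to the
    validation itself (successful trials)."""
    if not record.success:
        raise ValueError("validation time is defined for successful trials only")
    return float(record.validation_time)


def shoulder_spread_volume(positions: np.ndarray, coverage: float = SV_COVERAGE) -> float:
    """Volume (dm^3) of the covariance-aligned ellipsoid that covers
    ``coverage`` of a Gaussian with the sample covariance of ``positions``
    (meters, shape (N, 3)).

    The ellipsoid semi-axes are sqrt(q * eigvals(Sigma)) with q the
    ``coverage`` quantile of a chi-square with 3 degrees of freedom, giving
    volume (4/3) * pi * sqrt(det(Sigma)) * q^(3/2).
    """
    P = np.asarray(positions, dtype=float)
    if P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 4:
        raise ValueError("need at least four 3-D shoulder positions")
    if np.ptp(P, axis=0).max() == 0.0:
        return 0.0  # stationary shoulder: zero spread
    cov = np.cov(P.T)
    det = float(np.linalg.det(cov))
    if det <= 0.0:
        raise ValueError("degenerate (coplanar) shoulder position cloud")
    q = stats.chi2.ppf(coverage, df=3)
    volume_m3 = (4.0 / 3.0) * np.pi * np.sqrt(det) * q**1.5
    return volume_m3 * 1e3  # m^3 -> dm^3


def _speed_profile(positions: np.ndarray, timestamps: np.ndarray) -> tuple[np.ndarray, float]:
    P = np.asarray(positions, dtype=float)
    t = np.asarray(timestamps, dtype=float)
    if P.shape[0] != t.size:
        raise ValueError("positions and timestamps length mismatch")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("timestamps must be strictly increasing")
    mean_dt = float(dt.mean())
    if np.max(np.abs(dt - mean_dt)) > 0.05 * mean_dt:
        raise ValueError("spectral arc length requires uniform sampling")
    v = np.linalg.norm(np.diff(P, axis=0), axis=1) / dt
    return v, 1.0 / mean_dt


def spectral_arc_length(
    positions: np.ndarray,
    timestamps: np.ndarray,
    cutoff_hz: float = SAL_CUTOFF_HZ,
    padding: int = SAL_PADDING,
) -> float:
    """Spectral arc length of the hand speed profile.

    The speed profile's magnitude spectrum is computed on a zero-padded
    FFT (next power of two of ``padding`` times the signal length),
    normalised by its DC value and restricted to [0, cutoff_hz]; the
    metric is minus the arc length of that normalised curve over the
    frequency axis scaled to [0, 1].  Always <= -1; smoother movement
    (spectrum concentrated at low frequency) gives values closer to -1.
    """
    P = np.asarray(positions, dtype=float)
    if P.shape[0] < 8:
        raise ValueError("need at least eight samples")
    v, fs = _speed_profile(P, timestamps)
    if np.allclose(v, 0.0):
        raise ValueError("spectral arc length is undefined for a motionless trajectory")
    n_fft = int(2 ** np.ceil(np.log2(padding * v.size)))
    spectrum = np.abs(np.fft.rfft(v, n_fft))
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    sel = freqs <= cutoff_hz
    f, mag = freqs[sel], spectrum[sel] / spectrum[0]
    df = np.diff(f / cutoff_hz)
    dmag = np.diff(mag)
    return float(-np.sum(np.sqrt(df**2 + dmag**2)))


def curvature_of_trajectory(positions: np.ndarray) -> float:
    """Maximum distance (m) of the hand from the straight line joining the
    first and last hand positions."""
    P = np.asarray(positions, dtype=float)
    if P.shape[0] < 2:
        raise ValueError("need at least two positions")
    a, b = P[0], P[-1]
    chord = b - a
    L = np.linalg.norm(chord)
    if L == 0:
        raise ValueError("endpoints coincide; the straight line is undefined")
    u = chord / L
    rel = P - a
    perp = rel - np.outer(rel @ u, u)
    return float(np.max(np.linalg.norm(perp, axis=1)))


def distance_index(positions: np.ndarray) -> float:
    """Total hand path length over the straight-line start-to-end distance
    (>= 1, = 1 for a straight monotone path)."""
    P = np.asarray(positions, dtype=float)
    straight = np.linalg.norm(P[-1] - P[0])
    if straight == 0:
        raise ValueError("endpoints coincide; the distance index is undefined")
    path = np.sum(np.linalg.norm(np.diff(P, axis=0), axis=1))
    return float(path / straight)


def offline_distances(
    actual: Trajectory, reconstructed: Trajectory, geometry: ArmGeometry
) -> dict[str, float]:
    """Reconstruction errors of one trial.

    Returns the per-trial quantities whose across-trial medians form the
    offline metric suite: mean absolute joint error over frames (proximal
    pair and distal five separately, degrees), median per-frame hand
    position distance (m), and median per-frame grasp-axis angle (degrees,
    spin about the axis ignored).
    """
    if len(actual) != len(reconstructed):
        raise ValueError("trajectories must have equal length")
    if not np.allclose(actual.t, reconstructed.t):
        raise ValueError("trajectories must share timestamps")
    diff = np.abs(actual.angles - reconstructed.angles)
    pa, axa = forward_kinematics_batch(geometry, actual.angles)
    pr, axr = forward_kinematics_batch(geometry, reconstructed.angles)
    # atan2 form is exact for identical axes and accurate near 0 and 180
    cross = np.linalg.norm(np.cross(axa, axr), axis=1)
    dot = np.sum(axa * axr, axis=1)
    ang = np.degrees(np.arctan2(cross, dot))
    return {
        "mmae_proximal_deg": float(np.mean(diff[:, PROXIMAL])),
        "mmae_distal_deg": float(np.mean(diff[:, DISTAL])),
        "mhpd_m": float(np.median(np.linalg.norm(pa - pr, axis=1))),
        "mhod_deg": float(np.median(ang)),
    }


@dataclass
class MetricsReport:
    """Per-trial metric table plus phase-level aggregates."""

    trials: pd.DataFrame  # one row per trial
    success_rate: float  # percent
    shoulder_spread_volume_dm3: float
    medians: dict[str, float]  # medians of per-trial metrics, successful trials

    def to_dict(self) -> dict:
        return {
            "success_rate": self.success_rate,
            "shoulder_spread_volume_dm3": self.shoulder_spread_volume_dm3,
            "medians": self.medians,
            "n_trials": int(len(self.trials)),
        }


def phase_metrics(records, geometry: ArmGeometry) -> MetricsReport:
    """Aggregate a phase's trial records into the online metric suite.

    MT, VT, SAL, CT and DI are computed on successful trials only and
    summarised by their medians.  The shoulder spread volume is taken over
    the shoulder positions recorded across the phase (zero for a simulated
    user whose shoulder point does not translate).
    """
    records = list(records)
    rows = []
    for i, r in enumerate(records):
        row = {"trial": i, "success": r.success}
        if r.success:
            pos, _ = r.trajectory.hand_path(geometry)
            if r.shoulder_positions is not None and len(r.shoulder_positions) == len(pos):
                pos = pos + r.shoulder_positions  # hand path in the room frame
            row["movement_time_s"] = r.movement_time
            row["validation_time_s"] = r.validation_time
            row["sal"] = spectral_arc_length(pos, r.trajectory.t) if len(r.trajectory) >= 8 else np.nan
            if np.linalg.norm(pos[-1] - pos[0]) > 0:
                row["curvature_m"] = curvature_of_trajectory(pos)
                row["distance_index"] = distance_index(pos)
        rows.append(row)
    trials = pd.DataFrame(rows)
    shoulder = np.vstack([r.shoulder_positions for r in records if r.shoulder_positions is not None]) \
        if any(r.shoulder_positions is not None for r in records) else np.zeros((4, 3))
    try:
        sv = 0.0 if np.ptp(shoulder, axis=0).max() == 0.0 else shoulder_spread_volume(shoulder)
    except ValueError:  # rank-deficient cloud spans no volume
        sv = 0.0
    med_cols = ["movement_time_s", "validation_time_s", "sal", "curvature_m", "distance_index"]
    medians = {
        c: float(trials[c].median()) for c in med_cols if c in trials and trials[c].notna().any()
    }
    return MetricsReport(
        trials=trials,
        success_rate=success_rate(records),
        shoulder_spread_volume_dm3=sv,
        medians=medians,
    )
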