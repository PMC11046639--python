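"""Order parameters and experiment statistics.

Polarization and angular momentum are the standard collective-motion
order parameters; both are computed from unit headings (and, for the
angular momentum, unit relative-position vectors about the centroid),
so each lies in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GroupMetrics",
    "polarization",
    "angular_momentum",
    "time_averaged",
    "milling_probability",
    "fragmentation_check",
    "turning_response",
    "group_heading_angle",
]


def polarization(headings: np.ndarray) -> float:
    """Norm of the mean unit heading: 1 = perfectly aligned group."""
    h = np.asarray(headings, dtype=float)
    if h.ndim != 2 or h.shape[0] < 1:
        raise ValueError("need at least one heading row")
    return float(np.linalg.norm(h.mean(axis=0)))


def angular_momentum(positions: np.ndarray, headings: np.ndarray) -> float:
    """Norm of the mean 2D cross product of unit centroid-relative
    positions with headings; ~1 indicates milling.

    An agent exactly at the centroid contributes zero.
    """
    r = np.asarray(positions, dtype=float)
    v = np.asarray(headings, dtype=float)
    if r.shape[0] < 2:
        raise ValueError("need at least two agents")
    ric = r - r.mean(axis=0)
    nrm = np.linalg.norm(ric, axis=1)
    safe = np.where(nrm > 0, nrm, 1.0)
    rhat = np.where(nrm[:, None] > 0, ric / safe[:, None], 0.0)
    cross = rhat[:, 0] * v[:, 1] - rhat[:, 1] * v[:, 0]
    return float(abs(cross.mean()))


def time_averaged(series: np.ndarray, times: np.ndarray, t0: float) -> float:
    """Mean of a per-step series over [t0, end]."""
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    sel = times >= t0
    if not np.any(sel):
        raise ValueError("t0 is beyond the end of the series")
    return float(series[sel].mean())


def milling_probability(trial_m_hats, threshold: float = 0.5) -> float:
    """Fraction of trials whose time-averaged angular momentum strictly
    surpasses the threshold."""
    m = np.asarray(list(trial_m_hats), dtype=float)
    if m.size < 1:
        raise ValueError("need at least one trial")
    return float(np.mean(m > threshold))


def fragmentation_check(nn_dist: np.ndarray, times: np.ndarray,
                        window: float = 10.0, min_duration: float = 3.0,
                        distance: float = 2.0) -> bool:
    """True iff some agent's nearest-neighbor distance exceeds
    ``distance`` for at least ``min_duration`` seconds cumulative within
    the last ``window`` seconds of the trajectory.
    """
    nn = np.asarray(nn_dist, dtype=float)
    times = np.asarray(times, dtype=float)
    span = times[-1] - times[0]
    if window > span + 1e-9:
        raise ValueError("check window longer than trajectory")
    sel = times >= times[-1] - window
    if sel.sum() < 2:
        raise ValueError("not enough samples in window")
    dt = np.diff(times[sel]).mean()
    isolated_time = (nn[sel] > distance).sum(axis=0) * dt
    return bool(np.any(isolated_time >= min_duration))


def group_heading_angle(headings_series: np.ndarray) -> np.ndarray:
    """Unwrapped angle of the group's mean heading over time."""
    h = np.asarray(headings_series, dtype=float)
    mean = h.mean(axis=1)
    ang = np.arctan2(mean[:, 1], mean[:, 0])
    return np.unwrap(ang)


def turning_response(headings_series: np.ndarray, times: np.ndarray,
                     t_perturb: float, flag_window: float = 10.0,
                     flag_threshold: float = np.pi,
                     integrate_window: tuple[float, float] = (0.5, 1.0)):
    """Group turning after a perturbation.

    Returns ``(turn_angle, t_rel, response_flag, integrated_turn)``:
    the unwrapped group-heading angle relative to its value at the
    perturbation, the relative time axis, whether the net |turn|
    exceeded ``flag_threshold`` within ``flag_window`` seconds, and the
    net turning magnitude across ``integrate_window`` (seconds after
    the perturbation).  The unwrapped (continuously accumulated) angle
    is used throughout, so full rotations are not aliased away.
    """
    times = np.asarray(times, dtype=float)
    sel = times >= t_perturb - 1e-12
    t_rel = times[sel] - t_perturb
    ang = group_heading_angle(np.asarray(headings_series)[sel])
    turn = ang - ang[0]
    in_flag = t_rel <= flag_window + 1e-12
    response_flag = bool(np.any(np.abs(turn[in_flag]) > flag_threshold))
    lo, hi = integrate_window
    in_int = (t_rel >= lo) & (t_rel <= hi + 1e-12)
    if np.sum(in_int) >= 2:
        seg = turn[in_int]
        integrated = float(abs(seg[-1] - seg[0]))
    else:
        integrated = 0.0
    return turn, t_rel, response_flag, integrated


@dataclass
class GroupMetrics:
    """Per-trial order-parameter summaries."""

    times: np.ndarray
    polarization_series: np.ndarray
    angular_momentum_series: np.ndarray
    p_hat: float
    m_hat: float
    fragmented: bool
    turning_angle_series: np.ndarray | None = None

    @classmethod
    def from_record(cls, record, t0: float = 5.0, frag_window: float = 10.0) -> "GroupMetrics":
        p = record.polarization_series()
        m = record.angular_momentum_series()
        nn = record.nearest_neighbor_distances()
        return cls(
            times=record.times,
            polarization_series=p,
            angular_momentum_series=m,
            p_hat=time_averaged(p, record.times, t0),
            m_hat=time_averaged(m, record.times, t0),
            fragmented=fragmentation_check(nn, record.times, window=frag_window),
        )
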