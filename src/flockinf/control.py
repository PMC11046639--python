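"""Action as free-energy descent on the heading direction.

Only first-order (rate-of-change) precision-weighted sensory errors
drive steering: the distance itself does not instantaneously depend on
heading, but its flow does.  Each sector contributes its mean unit
direction-to-neighbors scaled by that sector's weighted error; informed
agents add a target direction scaled by the target error.  A positive
weighted error pulls the agent toward the corresponding direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .generative_model import ModelParams
from .inference import PredictionErrors

__all__ = ["SectorVectors", "sector_vectors", "heading_derivative", "apply_heading_update"]


@dataclass
class SectorVectors:
    """Unit-average directions to neighbors per sector (zero rows for
    empty sectors), plus the optional unit vector toward the target."""

    dR: np.ndarray                # (L, 2)
    dT: np.ndarray | None = None  # (2,)


def sector_vectors(state, focal: int, memberships: list[np.ndarray],
                   params: ModelParams) -> SectorVectors:
    """Mean unit direction to each sector's neighbors for one agent.

    Coincident neighbors (zero separation) are excluded from the sum.
    Informed agents get the unit vector toward the target.
    """
    r = state.positions[focal]
    dR = np.zeros((params.L, 2))
    for l, idx in enumerate(memberships):
        if len(idx) == 0:
            continue
        diff = state.positions[idx] - r
        dist = np.linalg.norm(diff, axis=1)
        keep = dist > 0
        if not np.any(keep):
            continue
        dR[l] = np.mean(diff[keep] / dist[keep, None], axis=0)
    dT = None
    if state.target is not None and state.informed_mask[focal]:
        d = state.target - r
        nd = np.linalg.norm(d)
        dT = d / nd if nd > 0 else np.zeros(2)
    return SectorVectors(dR=dR, dT=dT)


def heading_derivative(errors: PredictionErrors, vectors: SectorVectors) -> np.ndarray:
    """dv/dt = sum_l xi'_l dR_l (+ xi_target dT): a matrix-vector product
    of precision-weighted first-order errors with sector directions."""
    dvdt = vectors.dR.T @ errors.xi_z_prime
    if errors.xi_target is not None and vectors.dT is not None:
        dvdt = dvdt + errors.xi_target * vectors.dT
    return dvdt


def apply_heading_update(heading: np.ndarray, dvdt: np.ndarray,
                         kappa_a: float, dt: float) -> np.ndarray:
    """Euler step on the heading followed by renormalization to unit
    length; a vanishing update leaves the heading unchanged."""
    v = np.asarray(heading, dtype=float) + kappa_a * dt * np.asarray(dvdt, dtype=float)
    nrm = np.linalg.norm(v)
    if nrm == 0.0:
        return np.asarray(heading, dtype=float).copy()
    return v / nrm
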