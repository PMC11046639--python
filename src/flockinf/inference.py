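"""Generalized filtering: free energy, prediction errors, belief updates,
and slow online learning of the sensory smoothness parameter.

The batched functions (``grad_mu_batched`` etc.) operate on stacked
arrays of shape ``(N, M, orders)`` and are the single implementation
used by the simulation stepper; the per-agent operations wrap them.
Channel layout: rows ``0..L-1`` are the visual sectors, the optional
row ``L`` is the target-distance channel of informed agents.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .generative_model import (
    GeneralizedBelief,
    ModelParams,
    drift,
    drift_jacobian,
    shift,
    shift_matrix,
    temporal_precision,
)

__all__ = [
    "PredictionErrors",
    "prediction_errors",
    "free_energy",
    "belief_step",
    "plasticity_step",
]


@dataclass
class PredictionErrors:
    """Sensory and model errors for one agent, masked rows zeroed."""

    eps_z: np.ndarray        # (M, n_orders_y) sensory errors
    eps_w: np.ndarray        # (M, n_orders_x) model errors
    xi_z_prime: np.ndarray   # (L,) precision-weighted first-order sensory errors
    xi_target: float | None  # precision-weighted first-order target error
    mask: np.ndarray         # (M,) observed-channel mask


# ---------------------------------------------------------------------------
# shared pieces
# ---------------------------------------------------------------------------

def _sensory_weights(params: ModelParams, lambda_z, n_channels: int) -> np.ndarray:
    """Diagonal sensory precision, shape (..., M, n_orders_y).

    ``lambda_z`` may be a scalar or a per-agent array (broadcast against
    leading axes).  Order 0 weight is Gamma; order 1 is ``2 Gamma lam^2``.
    """
    lam = np.asarray(lambda_z, dtype=float)
    gam = params.gamma_z_arr
    if n_channels > params.L:
        gam = np.concatenate([gam, [params.Gamma_z_target]])
    w = np.zeros(lam.shape + (n_channels, params.n_orders_y))
    w[..., :, 0] = gam
    if params.n_orders_y >= 2:
        w[..., :, 1] = 2.0 * gam * (lam * lam)[..., None]
    return w


@lru_cache(maxsize=128)
def _process_mats(params: ModelParams):
    """Pi_w and the per-row matrices  Pi_w (D + rate I)  used in the gradient.

    Cached on the (frozen, hashable) parameter object.
    """
    K = params.n_orders_x
    Pi_w = params.Gamma_w * temporal_precision(params.lambda_w, K)
    D = shift_matrix(K)
    B_soc = D - drift_jacobian(params, target=False)
    B_tgt = D - drift_jacobian(params, target=True)
    return Pi_w, Pi_w @ B_soc, Pi_w @ B_tgt


def grad_mu_batched(mu: np.ndarray, y: np.ndarray, obs_mask: np.ndarray,
                    lambda_z, params: ModelParams):
    """Free-energy gradient w.r.t. beliefs for stacked agents.

    Parameters
    ----------
    mu : (..., M, n_orders_x) belief means
    y : (..., M, n_orders_y) generalized observations
    obs_mask : (..., M) boolean, observed channels
    lambda_z : scalar or (...,) learned smoothness per agent

    Returns ``(grad, eps_z, eps_w, xi1)`` where ``xi1`` is the
    precision-weighted first-order sensory error per channel (zero on
    masked channels) that also drives the heading update.
    """
    mu = np.asarray(mu, dtype=float)
    Ko = params.n_orders_y
    M = mu.shape[-2]
    m = np.asarray(obs_mask, dtype=bool)

    eps_z = (np.asarray(y, dtype=float) - mu[..., :Ko]) * m[..., None]
    w = _sensory_weights(params, lambda_z, M)
    wez = w * eps_z

    eps_w = shift(mu) - drift(mu, params)
    _, M_soc, M_tgt = _process_mats(params)
    grad_w = eps_w @ M_soc
    if M > params.L:
        grad_w[..., params.L:, :] = eps_w[..., params.L:, :] @ M_tgt

    grad = grad_w.copy()
    grad[..., :Ko] -= wez
    xi1 = wez[..., 1] if Ko >= 2 else np.zeros(eps_z.shape[:-1])
    return grad, eps_z, eps_w, xi1


def belief_update_batched(mu, y, obs_mask, lambda_z, params: ModelParams, dt: float):
    """One Euler step of  d(mu)/dt = D mu - kappa_mu grad_mu(F)."""
    grad, _, _, xi1 = grad_mu_batched(mu, y, obs_mask, lambda_z, params)
    return mu + dt * (shift(mu) - params.kappa_mu * grad), xi1


def plasticity_update_batched(eps_z, obs_mask, lambda_z, params: ModelParams, dt: float):
    """Slow free-energy descent on the sensory smoothness, clamped."""
    if params.n_orders_y < 2 or params.kappa_theta == 0:
        return lambda_z
    lam = np.asarray(lambda_z, dtype=float)
    M = eps_z.shape[-2]
    gam = params.gamma_z_arr
    if M > params.L:
        gam = np.concatenate([gam, [params.Gamma_z_target]])
    m = np.asarray(obs_mask, dtype=float)
    quad = np.sum(2.0 * gam * eps_z[..., 1] ** 2 * m, axis=-1) * lam
    n_obs = np.sum(m, axis=-1)
    dF = quad - n_obs / lam
    return np.clip(lam - params.kappa_theta * dt * dF, params.lambda_min, params.lambda_max)


# ---------------------------------------------------------------------------
# per-agent operations
# ---------------------------------------------------------------------------

def _stack_frame(belief: GeneralizedBelief, frame, params: ModelParams):
    """Align a sensory frame with the belief's channel layout."""
    M = belief.n_latents
    Ko = params.n_orders_y
    y = np.zeros((M, Ko))
    mask = np.zeros(M, dtype=bool)
    y_soc = np.asarray(frame.y, dtype=float)
    m_soc = np.asarray(frame.mask, dtype=bool)
    y[: params.L][m_soc] = y_soc[m_soc]
    mask[: params.L] = m_soc
    if M > params.L:
        if getattr(frame, "y_target", None) is not None:
            y[params.L] = np.asarray(frame.y_target, dtype=float)
            mask[params.L] = True
    return y, mask


def prediction_errors(belief: GeneralizedBelief, frame, params: ModelParams,
                      lambda_z: float | None = None) -> PredictionErrors:
    """Sensory errors ``y - mu``, model errors ``D mu - f(mu)``, and the
    precision-weighted first-order errors that steer the agent."""
    lam = params.lambda_z if lambda_z is None else float(lambda_z)
    y, mask = _stack_frame(belief, frame, params)
    _, eps_z, eps_w, xi1 = grad_mu_batched(belief.mu, y, mask, lam, params)
    xi_target = float(xi1[params.L]) if belief.n_latents > params.L and mask[params.L] else None
    return PredictionErrors(
        eps_z=eps_z,
        eps_w=eps_w,
        xi_z_prime=np.asarray(xi1[: params.L]),
        xi_target=xi_target,
        mask=mask,
    )


def free_energy(belief: GeneralizedBelief, frame, params: ModelParams,
                lambda_z: float | None = None) -> float:
    """Laplace free energy: precision-weighted squared prediction errors
    plus normalization (log-determinant) terms.

    Masked sectors contribute to neither the quadratic nor the log-det
    sensory terms (equivalent to infinite sensory variance there).
    """
    lam = params.lambda_z if lambda_z is None else float(lambda_z)
    if lam <= 0:
        raise ValueError("lambda_z must be > 0")
    y, mask = _stack_frame(belief, frame, params)
    _, eps_z, eps_w, _ = grad_mu_batched(belief.mu, y, mask, lam, params)

    M = belief.n_latents
    w = _sensory_weights(params, lam, M)
    quad_z = 0.5 * float(np.sum(w * eps_z**2 * mask[:, None]))
    logdet_z = 0.5 * float(np.sum(np.log(w[mask])))

    Pi_w, _, _ = _process_mats(params)
    sign, logdet_w_one = np.linalg.slogdet(Pi_w)
    if sign <= 0:
        raise ValueError("process precision is not positive definite")
    quad_w = 0.5 * float(np.einsum("mk,kj,mj->", eps_w, Pi_w, eps_w))
    logdet_w = 0.5 * M * float(logdet_w_one)
    return quad_z + quad_w - logdet_z - logdet_w


def belief_step(belief: GeneralizedBelief, frame, params: ModelParams, dt: float,
                lambda_z: float | None = None) -> GeneralizedBelief:
    """Euler step of generalized filtering:  mu += dt (D mu - kappa_mu grad F)."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    lam = params.lambda_z if lambda_z is None else float(lambda_z)
    y, mask = _stack_frame(belief, frame, params)
    mu_new, _ = belief_update_batched(belief.mu, y, mask, lam, params, dt)
    if not np.all(np.isfinite(mu_new)):
        raise FloatingPointError("belief update produced non-finite means")
    return GeneralizedBelief(mu_new, belief.informed)


def plasticity_step(belief: GeneralizedBelief, frame, params: ModelParams,
                    learned_lambda_z: float, dt: float) -> float:
    """One slow learning step on lambda_z (rate kappa_theta = kappa_mu / 10)."""
    y, mask = _stack_frame(belief, frame, params)
    _, eps_z, _, _ = grad_mu_batched(belief.mu, y, mask, learned_lambda_z, params)
    lam = plasticity_update_batched(eps_z, mask, learned_lambda_z, params, dt)
    return float(lam)
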