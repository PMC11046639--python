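"""Agent-side world model.

Each agent carries a linear stochastic model of the average neighbor
distance within each of its visual sectors (optionally plus the distance
to an external target).  The model lives in generalized coordinates of
motion: a latent is represented by a short vector of its instantaneous
derivatives ``(x, x', x'', ...)``.  This module holds the drift of that
model, the order-shift operator, and the construction of precision
(inverse covariance) matrices from an amplitude component and a temporal
smoothness component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "ModelParams",
    "GeneralizedBelief",
    "drift",
    "drift_jacobian",
    "shift",
    "shift_matrix",
    "temporal_precision",
    "temporal_covariance",
    "generalized_precision",
]

_DEFAULT_SECTORS = ((-120.0, -60.0), (-60.0, 0.0), (0.0, 60.0), (60.0, 120.0))


@dataclass(frozen=True)
class ModelParams:
    """All generative-model and update-rate parameters.

    Angular sectors are half-open ``[lower, upper)`` intervals in degrees,
    measured counterclockwise from the heading vector; bearings outside
    every sector are blind.

    Parameters without a principled default (marked "calibrated") were
    chosen so that the default configuration produces cohesive polarized
    motion; all are configurable.
    """

    L: int = 4
    sector_angles: tuple = _DEFAULT_SECTORS
    sensing_radius: float = 5.0
    n_orders_x: int = 3
    n_orders_y: int = 2
    alpha: float = 0.5
    eta: float = 1.0
    alpha_t: float = 0.5
    Gamma_z: tuple = (25.0, 25.0, 25.0, 25.0)  # calibrated
    lambda_z: float = 1.0
    Gamma_z_target: float = 25.0
    Gamma_w: float = 10.0      # calibrated
    lambda_w: float = 1.0
    kappa_mu: float = 0.5      # calibrated
    kappa_a: float = 0.9       # calibrated
    kappa_theta: float = 0.05  # kappa_mu / 10
    sigma2_z: float = 0.01     # calibrated (true order-0 observation noise)
    sigma2_zprime: float = 0.01
    sigma2_z_target: float = 0.01
    sigma2_a: float = 0.1      # calibrated heading (action) noise variance
    speed: float = 1.0
    lambda_min: float = 0.1
    lambda_max: float = 5.0
    dt: float = 0.01

    def __post_init__(self):
        if isinstance(self.Gamma_z, (int, float)):
            object.__setattr__(self, "Gamma_z", (float(self.Gamma_z),) * self.L)
        else:
            object.__setattr__(self, "Gamma_z", tuple(float(g) for g in self.Gamma_z))
        object.__setattr__(
            self, "sector_angles", tuple((float(a), float(b)) for a, b in self.sector_angles)
        )
        self.validate()

    def validate(self) -> None:
        errs = []
        if self.L < 1:
            errs.append("L: must be >= 1")
        if len(self.sector_angles) != self.L:
            errs.append("sector_angles: need exactly L intervals")
        for lo, hi in self.sector_angles:
            if not lo < hi:
                errs.append(f"sector_angles: degenerate interval [{lo}, {hi})")
        ivs = sorted(self.sector_angles)
        for (lo1, hi1), (lo2, hi2) in zip(ivs, ivs[1:]):
            if lo2 < hi1:
                errs.append(f"sector_angles: overlapping intervals [{lo1},{hi1}) and [{lo2},{hi2})")
        if self.eta <= 0:
            errs.append("eta: must be > 0")
        if not self.n_orders_y < self.n_orders_x:
            errs.append("n_orders_y: must be < n_orders_x")
        if self.n_orders_x not in (2, 3):
            errs.append("n_orders_x: only 2 or 3 supported")
        if len(self.Gamma_z) != self.L:
            errs.append("Gamma_z: need one amplitude per sector")
        for name in ("lambda_z", "lambda_w", "Gamma_z_target", "Gamma_w"):
            if getattr(self, name) <= 0:
                errs.append(f"{name}: must be > 0")
        if any(g <= 0 for g in self.Gamma_z):
            errs.append("Gamma_z: all entries must be > 0")
        for name in ("sigma2_z", "sigma2_zprime", "sigma2_z_target", "sigma2_a"):
            if getattr(self, name) < 0:
                errs.append(f"{name}: must be >= 0")
        for name in ("kappa_mu", "kappa_a", "kappa_theta", "alpha", "alpha_t"):
            if getattr(self, name) < 0:
                errs.append(f"{name}: must be >= 0")
        if self.sensing_radius <= 0:
            errs.append("sensing_radius: must be > 0")
        if not 0 < self.lambda_min <= self.lambda_max:
            errs.append("lambda_min/lambda_max: need 0 < lambda_min <= lambda_max")
        if self.dt <= 0:
            errs.append("dt: must be > 0")
        if self.speed <= 0:
            errs.append("speed: must be > 0")
        if errs:
            raise ValueError("invalid model parameters: " + "; ".join(errs))

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "sector_angles":
                v = [list(iv) for iv in v]
            elif f.name == "Gamma_z":
                v = list(v)
            d[f.name] = v
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown model parameter(s): {sorted(unknown)}")
        return cls(**d)

    def with_(self, **kw) -> "ModelParams":
        return replace(self, **kw)

    @property
    def gamma_z_arr(self) -> np.ndarray:
        return np.asarray(self.Gamma_z, dtype=float)


@dataclass
class GeneralizedBelief:
    """Posterior means over latents across derivative orders.

    ``mu`` has one row per latent -- the L sectors, plus a final target
    row when the agent is informed -- and one column per derivative
    order ``(mu, mu', mu'')``.
    """

    mu: np.ndarray
    informed: bool = False

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        if self.mu.ndim != 2:
            raise ValueError("belief means must be a (latents, orders) matrix")
        if not np.all(np.isfinite(self.mu)):
            raise ValueError("belief means must be finite")

    @property
    def n_latents(self) -> int:
        return self.mu.shape[0]

    @property
    def n_orders(self) -> int:
        return self.mu.shape[1]

    def copy(self) -> "GeneralizedBelief":
        return GeneralizedBelief(self.mu.copy(), self.informed)


# ---------------------------------------------------------------------------
# generalized-coordinate machinery
# ---------------------------------------------------------------------------

def shift(gen_vec: np.ndarray) -> np.ndarray:
    """Move a vector of generalized coordinates up one order.

    Order ``k`` of the output is order ``k + 1`` of the input; the top
    order is truncated to zero.  Operates on the last axis, so batched
    ``(..., n_orders)`` inputs work unchanged.
    """
    g = np.asarray(gen_vec, dtype=float)
    out = np.zeros_like(g)
    out[..., :-1] = g[..., 1:]
    return out


def shift_matrix(n_orders: int) -> np.ndarray:
    """Matrix form of :func:`shift` acting on column order-vectors."""
    return np.eye(n_orders, k=1)


def drift(belief: GeneralizedBelief, params: ModelParams) -> np.ndarray:
    """Generalized drift of the agent's dynamics model, one row per latent.

    Social rows relax the distance to the preferred spacing ``eta`` at
    rate ``alpha``; order ``k >= 1`` applies the linearized drift to the
    k-th derivative.  The optional target row relaxes to zero at rate
    ``alpha_t``.
    """
    mu = belief.mu if isinstance(belief, GeneralizedBelief) else np.asarray(belief, dtype=float)
    f = -params.alpha * mu
    f[..., : params.L, 0] += params.alpha * params.eta
    if mu.shape[-2] > params.L:
        f[..., params.L :, :] = -params.alpha_t * mu[..., params.L :, :]
    return f


def drift_jacobian(params: ModelParams, target: bool = False) -> np.ndarray:
    """d(drift)/d(mu) for one latent row: a diagonal rate matrix."""
    rate = params.alpha_t if target else params.alpha
    return -rate * np.eye(params.n_orders_x)


# ---------------------------------------------------------------------------
# precision construction
# ---------------------------------------------------------------------------

def temporal_covariance(lam: float, n_orders: int) -> np.ndarray:
    """Covariance between derivative orders of a smooth noise process.

    Derived from a Gaussian autocorrelation ``rho(h) = exp(-h^2/(4 lam^2))``:
    entry ``(j, k)`` is ``(-1)^j rho^(j+k)(0)``.
    """
    if lam <= 0:
        raise ValueError("smoothness must be > 0")
    a = 1.0 / (4.0 * lam * lam)
    if n_orders == 1:
        return np.array([[1.0]])
    if n_orders == 2:
        return np.array([[1.0, 0.0], [0.0, 2.0 * a]])
    if n_orders == 3:
        return np.array(
            [
                [1.0, 0.0, -2.0 * a],
                [0.0, 2.0 * a, 0.0],
                [-2.0 * a, 0.0, 12.0 * a * a],
            ]
        )
    raise ValueError("n_orders must be in {1, 2, 3}")


def temporal_precision(lam: float, n_orders: int) -> np.ndarray:
    """Inverse of :func:`temporal_covariance`.

    For ``n_orders == 2`` this is exactly ``diag(1, 2 lam^2)`` -- the
    first-derivative channel is up-weighted quadratically in the assumed
    noise smoothness.
    """
    if lam <= 0:
        raise ValueError("smoothness must be > 0")
    if n_orders == 2:
        return np.array([[1.0, 0.0], [0.0, 2.0 * lam * lam]])
    cov = temporal_covariance(lam, n_orders)
    return np.linalg.inv(cov)


def generalized_precision(Gamma: np.ndarray, lam: float, n_orders: int) -> np.ndarray:
    """Block precision over (latent, order): ``diag(Gamma) (x) temporal_precision``.

    The order-1 diagonal entry for latent l is ``2 Gamma_l lam^2``.
    """
    Gamma = np.atleast_1d(np.asarray(Gamma, dtype=float))
    if np.any(Gamma <= 0):
        raise ValueError("amplitude precisions must be > 0")
    return np.kron(np.diag(Gamma), temporal_precision(lam, n_orders))
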