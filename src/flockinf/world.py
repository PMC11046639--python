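"""True environment dynamics: positions, headings, sector geometry,
noisy observation generation, and the joint Euler-Maruyama integration
of inference, action, and (optionally) plasticity for all agents.

All agents update synchronously from the pre-step state; sensing,
belief updates, and heading updates are vectorized across the group.
"""

from __future__ import annotations

import json
from functools import lru_cache
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .generative_model import GeneralizedBelief, ModelParams, shift
from .inference import _process_mats, grad_mu_batched, plasticity_update_batched

try:
    from . import _fast
except ImportError:  # pragma: no cover
    _fast = None

__all__ = [
    "SensoryFrame",
    "SwarmState",
    "TrajectoryRecord",
    "assign_sectors",
    "true_hidden_state",
    "observe",
    "init_state",
    "step",
    "run",
    "run_simulation",
]


@dataclass
class SensoryFrame:
    """One agent's generalized observations per sector, with missing-data
    mask, plus optional target observations (informed agents only)."""

    y: np.ndarray                 # (L, n_orders_y)
    mask: np.ndarray              # (L,) sector non-empty
    y_target: np.ndarray | None = None   # (n_orders_y,)


@dataclass
class SwarmState:
    positions: np.ndarray          # (N, 2)
    headings: np.ndarray           # (N, 2), unit rows
    mu: np.ndarray                 # (N, M, n_orders_x) stacked belief means
    learned_lambda_z: np.ndarray   # (N,)
    informed_mask: np.ndarray      # (N,) bool
    time: float = 0.0
    target: np.ndarray | None = None   # (2,) target position, if any

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.headings = np.asarray(self.headings, dtype=float)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        norms = np.linalg.norm(self.headings, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("heading rows must be unit vectors")
        if self.time < 0:
            raise ValueError("time must be >= 0")

    @property
    def n_agents(self) -> int:
        return self.positions.shape[0]

    @property
    def _has_target_row(self) -> bool:
        return bool(np.any(self.informed_mask))

    @property
    def beliefs(self) -> list[GeneralizedBelief]:
        has_t = self._has_target_row
        out = []
        for i in range(self.n_agents):
            if has_t and not self.informed_mask[i]:
                out.append(GeneralizedBelief(self.mu[i, :-1].copy()))
            else:
                out.append(GeneralizedBelief(self.mu[i].copy(), informed=bool(self.informed_mask[i])))
        return out

    def copy(self) -> "SwarmState":
        return SwarmState(
            self.positions.copy(), self.headings.copy(), self.mu.copy(),
            self.learned_lambda_z.copy(), self.informed_mask.copy(),
            self.time, None if self.target is None else self.target.copy(),
        )


# ---------------------------------------------------------------------------
# sensing
# ---------------------------------------------------------------------------

def _sector_geometry(positions: np.ndarray, headings: np.ndarray, params: ModelParams):
    """Vectorized sector memberships and per-sector summaries for all agents.

    Returns (member (N, L, N) bool, dist (N, N), unit (N, N, 2)) where
    ``member[i, l, j]`` marks neighbor j in sector l of focal i.
    """
    N = positions.shape[0]
    diff = positions[None, :, :] - positions[:, None, :]        # diff[i, j] = r_j - r_i
    dist = np.linalg.norm(diff, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(dist[..., None] > 0, diff / np.where(dist[..., None] > 0, dist[..., None], 1.0), 0.0)
    within = (dist > 0) & (dist <= params.sensing_radius)
    np.fill_diagonal(within, False)

    head_ang = np.degrees(np.arctan2(headings[:, 1], headings[:, 0]))
    bear = np.degrees(np.arctan2(diff[..., 1], diff[..., 0])) - head_ang[:, None]
    bear = (bear + 180.0) % 360.0 - 180.0                       # wrap to [-180, 180)

    member = np.zeros((N, params.L, N), dtype=bool)
    for l, (lo, hi) in enumerate(params.sector_angles):
        member[:, l, :] = within & (bear >= lo) & (bear < hi)
    return member, dist, unit


def sense_all(positions: np.ndarray, headings: np.ndarray, params: ModelParams):
    """True hidden states for every agent at once.

    Returns ``(xh, xp, mask, dR)``: per-sector mean distance (N, L), its
    analytic time derivative with membership held fixed (N, L), the
    non-empty mask (N, L), and the mean unit direction to neighbors
    (N, L, 2).
    """
    member, dist, unit = _sector_geometry(positions, headings, params)
    vel = headings * params.speed
    relv = vel[None, :, :] - vel[:, None, :]                    # v_j - v_i
    approach = np.sum(unit * relv, axis=-1)                     # d dist_ij / dt

    K = member.sum(axis=2)
    mask = K > 0
    Ksafe = np.where(mask, K, 1)
    xh = np.einsum("ilj,ij->il", member, dist) / Ksafe
    xp = np.einsum("ilj,ij->il", member, approach) / Ksafe
    dR = np.einsum("ilj,ijc->ilc", member, unit) / Ksafe[..., None]
    xh = np.where(mask, xh, 0.0)
    xp = np.where(mask, xp, 0.0)
    dR = np.where(mask[..., None], dR, 0.0)
    return xh, xp, mask, dR


def target_hidden_state(positions: np.ndarray, headings: np.ndarray,
                        target: np.ndarray, speed: float):
    """Distance to the target and its rate of change for every agent."""
    d = target[None, :] - positions
    dist = np.linalg.norm(d, axis=1)
    dist = np.where(dist > 0, dist, 1e-12)
    dT = d / dist[:, None]
    rate = -np.sum(dT * headings, axis=1) * speed
    return dist, rate, dT


# -- per-focal-agent views (spec operations) --------------------------------

def assign_sectors(state: SwarmState, focal: int, params: ModelParams) -> list[np.ndarray]:
    """Neighbor index arrays per sector for one focal agent.

    Neighbor j belongs to sector l iff ``0 < ||r_j - r|| <= sensing_radius``
    and its bearing relative to the focal heading falls in sector l's
    half-open interval.  Self is excluded; so is everything outside the
    +/-120 degree (default) field of view.
    """
    member, _, _ = _sector_geometry(state.positions, state.headings, params)
    return [np.flatnonzero(member[focal, l]) for l in range(params.L)]


def true_hidden_state(state: SwarmState, focal: int, memberships: list[np.ndarray],
                      params: ModelParams):
    """Per-sector (x, x') for one agent given fixed memberships.

    x is the mean neighbor distance; x' its analytic time derivative
    (mean radial separation rate), holding membership fixed.  Empty
    sectors are marked missing.
    """
    r = state.positions[focal]
    v = state.headings[focal] * params.speed
    xh = np.zeros(params.L)
    xp = np.zeros(params.L)
    mask = np.zeros(params.L, dtype=bool)
    for l, idx in enumerate(memberships):
        if len(idx) == 0:
            continue
        diff = state.positions[idx] - r
        dist = np.linalg.norm(diff, axis=1)
        relv = state.headings[idx] * params.speed - v
        xh[l] = dist.mean()
        xp[l] = np.mean(np.sum(diff * relv, axis=1) / dist)
        mask[l] = True
    return xh, xp, mask


def observe(xh: np.ndarray, xp: np.ndarray, mask: np.ndarray, params: ModelParams,
            rng: np.random.Generator, target_x: tuple[float, float] | None = None) -> SensoryFrame:
    """Noisy generalized observations of one agent's hidden state."""
    y = np.zeros((params.L, params.n_orders_y))
    y[:, 0] = xh + rng.normal(0.0, np.sqrt(params.sigma2_z), params.L)
    if params.n_orders_y >= 2:
        y[:, 1] = xp + rng.normal(0.0, np.sqrt(params.sigma2_zprime), params.L)
    y_t = None
    if target_x is not None:
        y_t = np.array(target_x[: params.n_orders_y]) + rng.normal(
            0.0, np.sqrt(params.sigma2_z_target), params.n_orders_y
        )
    return SensoryFrame(y=y, mask=mask.copy(), y_target=y_t)


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def init_state(n_agents: int, params: ModelParams, rng: np.random.Generator,
               informed_mask: np.ndarray | None = None,
               target: np.ndarray | None = None,
               box_side: float | None = None) -> SwarmState:
    """Random initial conditions: positions uniform in a square of side
    ``sqrt(N) * eta`` centered at the origin, headings at uniform angles.

    Beliefs start at the noiseless sensed scene (preferred distance eta
    for empty sectors), with higher orders zero.
    """
    if informed_mask is None:
        informed_mask = np.zeros(n_agents, dtype=bool)
    informed_mask = np.asarray(informed_mask, dtype=bool)
    side = box_side if box_side is not None else np.sqrt(n_agents) * params.eta
    positions = rng.uniform(-side / 2, side / 2, size=(n_agents, 2))
    ang = rng.uniform(0.0, 2.0 * np.pi, size=n_agents)
    headings = np.column_stack([np.cos(ang), np.sin(ang)])

    has_target_row = bool(np.any(informed_mask))
    M = params.L + 1 if has_target_row else params.L
    mu = np.zeros((n_agents, M, params.n_orders_x))
    xh, _, mask, _ = sense_all(positions, headings, params)
    mu[:, : params.L, 0] = np.where(mask, xh, params.eta)
    if has_target_row:
        if target is None:
            raise ValueError("informed agents require a target position")
        dist, _, _ = target_hidden_state(positions, headings, np.asarray(target, float), params.speed)
        mu[:, params.L, 0] = np.where(informed_mask, dist, 0.0)
    lam = np.full(n_agents, params.lambda_z)
    return SwarmState(positions, headings, mu, lam, informed_mask, 0.0,
                      None if target is None else np.asarray(target, dtype=float))


def _check_finite(arr: np.ndarray, term: str):
    if not np.all(np.isfinite(arr)):
        bad = np.unique(np.argwhere(~np.isfinite(arr))[:, 0])
        raise FloatingPointError(
            f"integration failure: non-finite {term} for agent(s) {bad.tolist()}"
        )


def _draw_noise(n_agents: int, params: ModelParams, has_target: bool,
                rng: np.random.Generator):
    """Noise arrays for one step, drawn in a fixed order for determinism."""
    L = params.L
    n0 = rng.normal(0.0, np.sqrt(params.sigma2_z), (n_agents, L))
    if params.n_orders_y >= 2:
        n1 = rng.normal(0.0, np.sqrt(params.sigma2_zprime), (n_agents, L))
    else:
        n1 = np.zeros((n_agents, L))
    if has_target:
        nt = rng.normal(0.0, np.sqrt(params.sigma2_z_target), (n_agents, params.n_orders_y))
        if params.n_orders_y < 2:
            nt = np.column_stack([nt, np.zeros(n_agents)])
    else:
        nt = np.zeros((n_agents, 2))
    if params.sigma2_a > 0:
        na = rng.normal(0.0, np.sqrt(params.sigma2_a * params.dt), (n_agents, 2))
    else:
        na = np.zeros((n_agents, 2))
    return n0, n1, nt, na


def _advance_numpy(pos, head, mu, lam, informed, target, params: ModelParams,
                   n0, n1, nt, na, stim, plasticity: bool):
    """Reference (vectorized numpy) backend for one integration step."""
    N = pos.shape[0]
    L = params.L
    dt = params.dt
    has_target_row = mu.shape[1] > L

    xh, xp, mask, dR = sense_all(pos, head, params)
    y_soc = np.zeros((N, L, params.n_orders_y))
    y_soc[:, :, 0] = xh + n0
    if params.n_orders_y >= 2:
        y_soc[:, :, 1] = xp + n1
        if stim is not None:
            y_soc[:, :, 1] += stim

    if has_target_row:
        if target is None:
            raise ValueError("state has informed agents but no target")
        t_dist, t_rate, dT = target_hidden_state(pos, head, target, params.speed)
        y_t = np.zeros((N, params.n_orders_y))
        y_t[:, 0] = t_dist
        if params.n_orders_y >= 2:
            y_t[:, 1] = t_rate
        y_t = y_t + nt[:, : params.n_orders_y]
        y_all = np.concatenate([y_soc, y_t[:, None, :]], axis=1)
        obs_mask = np.concatenate([mask, informed[:, None]], axis=1)
    else:
        y_all, obs_mask = y_soc, mask

    # inference + action gradients from the pre-step beliefs
    grad, eps_z, _, xi1 = grad_mu_batched(mu, y_all, obs_mask, lam, params)
    mu_new = mu + dt * (shift(mu) - params.kappa_mu * grad)

    dvdt = np.einsum("il,ilc->ic", xi1[:, :L], dR)
    if has_target_row:
        dvdt = dvdt + xi1[:, L][:, None] * dT

    v = head + params.kappa_a * dt * dvdt + na
    nrm = np.linalg.norm(v, axis=1)
    head_new = np.where(nrm[:, None] > 0, v / np.where(nrm[:, None] > 0, nrm[:, None], 1.0), head)

    lam_new = lam
    if plasticity:
        lam_new = plasticity_update_batched(eps_z, obs_mask, lam, params, dt)

    pos_new = pos + head_new * params.speed * dt
    return pos_new, head_new, mu_new, np.asarray(lam_new, float)


def _fast_available(params: ModelParams) -> bool:
    return (_fast is not None and _fast.HAS_NUMBA
            and params.n_orders_x == 3 and params.n_orders_y == 2)


@lru_cache(maxsize=128)
def _kernel_consts(params: ModelParams):
    """Static per-parameter arrays for the numba kernel (cached)."""
    _, M_soc, M_tgt = _process_mats(params)
    sec = np.asarray(params.sector_angles, dtype=float)
    return (np.ascontiguousarray(sec[:, 0]), np.ascontiguousarray(sec[:, 1]),
            params.gamma_z_arr.copy(), M_soc, M_tgt)


def _advance(pos, head, mu, lam, informed, target, params: ModelParams,
             n0, n1, nt, na, stim, plasticity: bool, reference: bool = False):
    if reference or not _fast_available(params):
        return _advance_numpy(pos, head, mu, lam, informed, target, params,
                              n0, n1, nt, na, stim, plasticity)
    sec_lo, sec_hi, gamma_arr, M_soc, M_tgt = _kernel_consts(params)
    has_target = mu.shape[1] > params.L
    if has_target and target is None:
        raise ValueError("state has informed agents but no target")
    return _fast.step_kernel(
        pos, head, mu, lam, np.asarray(informed, np.bool_),
        has_target, target if target is not None else np.zeros(2),
        sec_lo, sec_hi,
        params.sensing_radius, params.speed,
        gamma_arr, params.Gamma_z_target, params.eta,
        params.alpha, params.alpha_t,
        M_soc, M_tgt, params.kappa_mu, params.kappa_a, params.dt,
        n0, n1, stim if stim is not None else np.zeros_like(n0), nt, na,
        plasticity, params.kappa_theta, params.lambda_min, params.lambda_max,
    )


def step(state: SwarmState, params: ModelParams, rng: np.random.Generator,
         stimuli: np.ndarray | None = None, plasticity: bool = False,
         reference: bool = False) -> SwarmState:
    """Advance the swarm by one Euler-Maruyama step of size ``params.dt``.

    Per agent, from the pre-step state: sense -> observe (stimulus
    offsets added to the rate channel y') -> belief update -> heading
    update (renormalized) -> optional plasticity update; positions then
    advance along the new heading at constant speed.

    ``reference=True`` forces the plain-numpy backend (the numba kernel
    is used otherwise when applicable; both consume identical noise).
    """
    has_target_row = state.mu.shape[1] > params.L
    noise = _draw_noise(state.n_agents, params, has_target_row, rng)
    pos_new, head_new, mu_new, lam_new = _advance(
        state.positions, state.headings, state.mu, state.learned_lambda_z,
        state.informed_mask, state.target, params, *noise,
        stim=stimuli, plasticity=plasticity, reference=reference)
    _check_finite(mu_new, "belief mean")
    _check_finite(head_new, "heading")
    _check_finite(pos_new, "position")
    return SwarmState(pos_new, head_new, mu_new, lam_new.copy(),
                      state.informed_mask, state.time + params.dt,
                      None if state.target is None else state.target)


# ---------------------------------------------------------------------------
# trajectory recording
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryRecord:
    """Time-indexed record of a run plus per-step order parameters."""

    times: np.ndarray              # (S,)
    positions: np.ndarray          # (S, N, 2)
    headings: np.ndarray           # (S, N, 2)
    lambda_z: np.ndarray | None = None   # (S, N)
    mu: np.ndarray | None = None         # (S, N, M, K)
    metadata: dict = field(default_factory=dict)

    @property
    def n_agents(self) -> int:
        return self.positions.shape[1]

    def polarization_series(self) -> np.ndarray:
        return np.array([_metrics.polarization(h) for h in self.headings])

    def angular_momentum_series(self) -> np.ndarray:
        return np.array([_metrics.angular_momentum(p, h)
                         for p, h in zip(self.positions, self.headings)])

    def nearest_neighbor_distances(self) -> np.ndarray:
        """(S, N) distance of every agent to its nearest neighbor."""
        if _fast is not None and _fast.HAS_NUMBA:
            return _fast.nearest_neighbor_kernel(np.ascontiguousarray(self.positions))
        S, N, _ = self.positions.shape
        out = np.zeros((S, N))
        for s in range(S):
            d = np.linalg.norm(self.positions[s, None, :, :] - self.positions[s, :, None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            out[s] = d.min(axis=1)
        return out

    def final_state(self) -> tuple[np.ndarray, np.ndarray]:
        return self.positions[-1], self.headings[-1]

    def to_dataframe(self) -> pd.DataFrame:
        S, N, _ = self.positions.shape
        rows = {
            "time": np.repeat(self.times, N),
            "agent_id": np.tile(np.arange(N), S),
            "x": self.positions[:, :, 0].ravel(),
            "y": self.positions[:, :, 1].ravel(),
            "vx": self.headings[:, :, 0].ravel(),
            "vy": self.headings[:, :, 1].ravel(),
        }
        if self.lambda_z is not None:
            rows["lambda_z"] = self.lambda_z.ravel()
        if self.mu is not None:
            M, K = self.mu.shape[2], self.mu.shape[3]
            for m in range(M):
                for k in range(K):
                    rows[f"mu_{m}_{k}"] = self.mu[:, :, m, k].ravel()
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrajectoryRecord":
        df = pd.read_csv(path)
        times = np.sort(df["time"].unique())
        N = df["agent_id"].nunique()
        S = len(times)
        df = df.sort_values(["time", "agent_id"])
        positions = df[["x", "y"]].to_numpy().reshape(S, N, 2)
        headings = df[["vx", "vy"]].to_numpy().reshape(S, N, 2)
        lam = df["lambda_z"].to_numpy().reshape(S, N) if "lambda_z" in df else None
        return cls(times=times, positions=positions, headings=headings, lambda_z=lam)

    def summary(self) -> dict:
        p = self.polarization_series()
        m = self.angular_momentum_series()
        return {
            "metadata": self.metadata,
            "polarization": p.tolist(),
            "angular_momentum": m.tolist(),
        }

    def write_summary(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh)


def run(state: SwarmState, params: ModelParams, duration: float,
        rng: np.random.Generator, stimuli_fn=None, plasticity: bool = False,
        record_lambda: bool = False, record_mu: bool = False,
        metadata: dict | None = None) -> TrajectoryRecord:
    """Integrate ``duration / dt`` steps from ``state`` and record each step.

    ``stimuli_fn(t)`` may return per-agent, per-sector offsets added to
    the rate observation channel at time t (or None).
    """
    n_steps = int(round(duration / params.dt))
    N = state.n_agents
    times = state.time + params.dt * np.arange(n_steps + 1)
    positions = np.zeros((n_steps + 1, N, 2))
    headings = np.zeros((n_steps + 1, N, 2))
    lam = np.zeros((n_steps + 1, N)) if record_lambda else None
    mu = np.zeros((n_steps + 1,) + state.mu.shape) if record_mu else None

    # tight array loop sharing the step backend; state validation and
    # finite checks run on the recorded arrays afterwards
    p, h = state.positions.copy(), state.headings.copy()
    m_arr, lz = state.mu.copy(), state.learned_lambda_z.copy()
    informed, target = state.informed_mask, state.target
    has_target = m_arr.shape[1] > params.L
    t = state.time
    for s_i in range(n_steps + 1):
        positions[s_i] = p
        headings[s_i] = h
        if lam is not None:
            lam[s_i] = lz
        if mu is not None:
            mu[s_i] = m_arr
        if s_i == n_steps:
            break
        stim = stimuli_fn(t) if stimuli_fn is not None else None
        noise = _draw_noise(N, params, has_target, rng)
        p, h, m_arr, lz = _advance(p, h, m_arr, lz, informed, target, params,
                                   *noise, stim=stim, plasticity=plasticity)
        t += params.dt
    _check_finite(np.column_stack([positions[-1], headings[-1]]), "state")
    if not np.all(np.isfinite(m_arr)):
        _check_finite(m_arr, "belief mean")
    cur = SwarmState(p, h, m_arr, lz.copy(), informed, t,
                     None if target is None else target.copy())

    meta = dict(metadata or {})
    meta.setdefault("duration_s", duration)
    meta.setdefault("dt_s", params.dt)
    rec = TrajectoryRecord(times=times, positions=positions, headings=headings,
                           lambda_z=lam, mu=mu, metadata=meta)
    rec._final = cur  # noqa: SLF001 -- kept for experiment forking
    return rec


def run_simulation(config, seed: int) -> TrajectoryRecord:
    """Run a free-schooling simulation from a validated config object.

    ``config`` needs attributes ``model`` (ModelParams), ``n_agents``,
    and ``duration_s``; metadata embeds the config mapping and seed.
    """
    params = config.model
    rng = np.random.default_rng(seed)
    state = init_state(config.n_agents, params, rng)
    meta = {"seed": seed, "n_agents": config.n_agents}
    if hasattr(config, "to_dict"):
        meta["config"] = config.to_dict()
    return run(state, params, config.duration_s, rng,
               plasticity=getattr(config, "plasticity", False),
               record_lambda=getattr(config, "plasticity", False),
               metadata=meta)
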