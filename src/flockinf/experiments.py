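"""Reproducible, seeded experiment drivers: free schooling sweeps over
sensory-precision components, informed-target navigation, and transient
sensory perturbations with and without online plasticity.

Trial counts and durations are configurable so that the full-scale
protocols (hundreds of trials) and desk-scale test runs share one code
path.  All randomness derives from a master seed via a deterministic
seed tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics as m
from . import world
from .cli_io import seed_tree
from .generative_model import ModelParams

__all__ = [
    "PerturbationStimulus",
    "ExperimentReport",
    "build_stimulus",
    "free_schooling_sweep",
    "target_navigation",
    "perturbation_experiment",
]


# ---------------------------------------------------------------------------
# perturbation stimulus
# ---------------------------------------------------------------------------

@dataclass
class PerturbationStimulus:
    """Transient "pseudomotion" wave of first-order prediction errors.

    Each repetition is a negative phase applied to the first sector pair
    followed by a positive phase on the second pair (mirrored sector
    order for the opposite apparent motion direction); offsets add to
    the rate observation channel y' only, and vanish outside the wave.
    """

    amplitude: float
    phase_duration: float = 0.5
    repetitions: int = 2
    direction: str = "forward"
    n_sectors: int = 4

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.direction not in ("forward", "mirrored"):
            raise ValueError("direction must be 'forward' or 'mirrored'")
        if self.phase_duration <= 0:
            raise ValueError("phase_duration must be > 0")

    @property
    def duration(self) -> float:
        return 2.0 * self.repetitions * self.phase_duration

    def phase_table(self) -> list[tuple[float, float, tuple, float]]:
        """List of (t_start, t_end, sectors, sign * amplitude)."""
        half = self.n_sectors // 2
        first = tuple(range(half))
        second = tuple(range(half, self.n_sectors))
        if self.direction == "mirrored":
            first, second = tuple(reversed(second)), tuple(reversed(first))
        out = []
        t = 0.0
        for _ in range(self.repetitions):
            out.append((t, t + self.phase_duration, first, -self.amplitude))
            t += self.phase_duration
            out.append((t, t + self.phase_duration, second, +self.amplitude))
            t += self.phase_duration
        return out

    def sector_offsets(self, t_rel: float) -> np.ndarray | None:
        """Per-sector y' offsets at time ``t_rel`` after stimulus onset."""
        if self.amplitude == 0 or t_rel < 0 or t_rel >= self.duration:
            return None
        off = np.zeros(self.n_sectors)
        for t0, t1, sectors, amp in self.phase_table():
            if t0 <= t_rel < t1:
                off[list(sectors)] = amp
                break
        return off


def build_stimulus(amplitude: float, phase_duration: float = 0.5,
                   repetitions: int = 2, direction: str = "forward",
                   n_sectors: int = 4) -> PerturbationStimulus:
    return PerturbationStimulus(amplitude=amplitude, phase_duration=phase_duration,
                                repetitions=repetitions, direction=direction,
                                n_sectors=n_sectors)


def stimulus_schedule(stim: PerturbationStimulus | None, subset, n_agents: int,
                      t_start: float):
    """Closure mapping absolute time to (N, L) y'-offsets (or None)."""
    if stim is None or stim.amplitude == 0:
        return None
    ind = np.zeros(n_agents)
    ind[np.asarray(subset, dtype=int)] = 1.0

    def fn(t: float):
        off = stim.sector_offsets(t - t_start)
        if off is None:
            return None
        return np.outer(ind, off)

    return fn


@dataclass
class ExperimentReport:
    """Per-condition tables plus a reproducibility summary.

    Fragmented trials are flagged in the tables, never silently dropped.
    """

    trials: pd.DataFrame
    summary: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# protocol 1: free schooling sweep
# ---------------------------------------------------------------------------

def free_schooling_sweep(gamma_values, lambda_values, n_trials: int, seed: int,
                         base_params: ModelParams | None = None,
                         n_agents: int = 50, duration: float = 15.0,
                         t0: float = 5.0) -> ExperimentReport:
    """Grid over (Gamma_z, lambda_z): per cell, ``n_trials`` seeded free
    schooling runs with per-trial polarization / angular-momentum
    averages, milling probability (threshold 0.5) over non-fragmented
    trials, and the fragmentation fraction."""
    base = base_params or ModelParams()
    gamma_values = list(gamma_values)
    lambda_values = list(lambda_values)
    labels = [f"sweep:g={g}:l={lam}:trial={t}"
              for g in gamma_values for lam in lambda_values for t in range(n_trials)]
    seeds = seed_tree(seed, labels)

    rows = []
    for g in gamma_values:
        for lam in lambda_values:
            params = base.with_(Gamma_z=(float(g),) * base.L, lambda_z=float(lam))
            for t in range(n_trials):
                child = seeds[f"sweep:g={g}:l={lam}:trial={t}"]
                rng = np.random.default_rng(child)
                state = world.init_state(n_agents, params, rng)
                rec = world.run(state, params, duration, rng)
                gm = m.GroupMetrics.from_record(rec, t0=t0, frag_window=min(10.0, duration))
                rows.append({"Gamma_z": g, "lambda_z": lam, "trial": t, "seed": child,
                             "p_hat": gm.p_hat, "m_hat": gm.m_hat,
                             "fragmented": gm.fragmented})
    trials = pd.DataFrame(rows)

    cells = []
    for (g, lam), sub in trials.groupby(["Gamma_z", "lambda_z"]):
        ok = sub[~sub["fragmented"]]
        cells.append({
            "Gamma_z": g, "lambda_z": lam, "n_trials": len(sub),
            "n_fragmented": int(sub["fragmented"].sum()),
            "frag_fraction": float(sub["fragmented"].mean()),
            "mean_p_hat": float(ok["p_hat"].mean()) if len(ok) else float("nan"),
            "mean_m_hat": float(ok["m_hat"].mean()) if len(ok) else float("nan"),
            "milling_prob": m.milling_probability(ok["m_hat"]) if len(ok) else 0.0,
        })
    return ExperimentReport(trials=trials,
                            summary={"protocol": "sweep", "seed": seed,
                                     "cells": cells, "t0": t0,
                                     "n_agents": n_agents, "duration_s": duration})


# ---------------------------------------------------------------------------
# protocol 2: informed-target navigation
# ---------------------------------------------------------------------------

def n_informed(p_inf: float, n_agents: int) -> int:
    """Round half away from zero, the documented convention."""
    return int(np.floor(p_inf * n_agents + 0.5))


def target_navigation(p_inf: float, Gamma_z_social: float, Gamma_z_target: float,
                      n_trials: int, seed: int,
                      base_params: ModelParams | None = None,
                      n_agents: int = 30, duration: float = 15.0,
                      target_distance: float = 10.0,
                      success_radius: float = 0.25) -> ExperimentReport:
    """Collective navigation accuracy for a given proportion of informed
    agents: a trial succeeds iff the group centroid reaches within
    ``success_radius`` of the target, without fragmenting, within
    ``duration`` seconds."""
    if not 0.0 <= p_inf <= 1.0:
        raise ValueError("p_inf must be in [0, 1]")
    base = base_params or ModelParams()
    params = base.with_(Gamma_z=(float(Gamma_z_social),) * base.L,
                        Gamma_z_target=float(Gamma_z_target))
    k = n_informed(p_inf, n_agents)
    seeds = seed_tree(seed, [f"nav:pinf={p_inf}:trial={t}" for t in range(n_trials)])

    rows = []
    for t in range(n_trials):
        child = seeds[f"nav:pinf={p_inf}:trial={t}"]
        rng = np.random.default_rng(child)
        ang = rng.uniform(0.0, 2.0 * np.pi)
        target = target_distance * np.array([np.cos(ang), np.sin(ang)])
        informed = np.zeros(n_agents, dtype=bool)
        if k > 0:
            informed[rng.choice(n_agents, size=min(k, n_agents), replace=False)] = True
        state = world.init_state(n_agents, params, rng,
                                 informed_mask=informed,
                                 target=target if k > 0 else None)
        rec = world.run(state, params, duration, rng)
        centroid = rec.positions.mean(axis=1)
        dist = np.linalg.norm(centroid - target, axis=1)
        reached = bool(np.any(dist <= success_radius))
        frag = m.fragmentation_check(rec.nearest_neighbor_distances(), rec.times,
                                     window=min(10.0, duration))
        rows.append({"trial": t, "seed": child, "n_informed": k, "reached": reached,
                     "fragmented": frag, "success": reached and not frag,
                     "min_centroid_dist": float(dist.min())})
    trials = pd.DataFrame(rows)
    accuracy = float(trials["success"].mean()) if len(trials) else 0.0
    return ExperimentReport(
        trials=trials,
        summary={"protocol": "navigate", "seed": seed, "p_inf": p_inf,
                 "n_informed": k, "accuracy": accuracy,
                 "Gamma_z_social": Gamma_z_social, "Gamma_z_target": Gamma_z_target,
                 "n_trials": n_trials, "n_fragmented": int(trials["fragmented"].sum())},
    )


# ---------------------------------------------------------------------------
# protocol 3: perturbation with/without plasticity
# ---------------------------------------------------------------------------

def perturbation_experiment(n_init: int, n_real: int, n_perturbed: int, seed: int,
                            base_params: ModelParams | None = None,
                            n_agents: int = 50, burn_in: float = 100.0,
                            post: float = 20.0, stim_delay: float = 1.0,
                            stimulus: PerturbationStimulus | None = None,
                            conditions: tuple = (True, False)) -> ExperimentReport:
    """Forked-realization perturbation protocol.

    Each initialization is burned in to (approximate) stationarity, then
    forked into ``n_real`` realizations per plasticity condition with
    fresh noise but identical history; the same random agent subset and
    noise stream are used for the paired on/off realizations.  The
    stimulus starts ``stim_delay`` seconds after the fork.
    """
    if not 1 <= n_perturbed <= n_agents - 1:
        raise ValueError("n_perturbed must be in [1, N - 1]")
    base = base_params or ModelParams()
    stim = stimulus if stimulus is not None else build_stimulus(amplitude=8.0)

    init_seeds = seed_tree(seed, [f"init={i}" for i in range(n_init)])
    rows = []
    for i in range(n_init):
        rng_i = np.random.default_rng(init_seeds[f"init={i}"])
        state0 = world.init_state(n_agents, base, rng_i)
        burn = world.run(state0, base, burn_in, rng_i)
        snapshot = burn._final

        real_seeds = seed_tree(init_seeds[f"init={i}"],
                               [f"real={r}" for r in range(n_real)])
        for r in range(n_real):
            child = real_seeds[f"real={r}"]
            subset = np.random.default_rng((child, 7)).choice(
                n_agents, size=n_perturbed, replace=False)
            t_perturb = snapshot.time + stim_delay
            for plast in conditions:
                rng_c = np.random.default_rng((child, 11))
                sched = stimulus_schedule(stim, subset, n_agents, t_perturb)
                rec = world.run(snapshot.copy(), base, post, rng_c,
                                stimuli_fn=sched, plasticity=plast,
                                record_lambda=plast)
                _, _, flag, integrated = m.turning_response(
                    rec.headings, rec.times, t_perturb)
                frag = m.fragmentation_check(rec.nearest_neighbor_distances(),
                                             rec.times, window=min(5.0, post))
                rows.append({"init": i, "real": r, "plasticity": plast,
                             "seed": child, "n_perturbed": n_perturbed,
                             "responded": flag, "integrated_turn": integrated,
                             "fragmented": frag})
    trials = pd.DataFrame(rows)

    per_init = []
    for (i, plast), sub in trials.groupby(["init", "plasticity"]):
        ok = sub[~sub["fragmented"]]
        per_init.append({
            "init": i, "plasticity": plast, "n_real": len(sub),
            "n_fragmented": int(sub["fragmented"].sum()),
            "mean_integrated_turn": float(ok["integrated_turn"].mean()) if len(ok) else float("nan"),
            "response_prob": float(ok["responded"].mean()) if len(ok) else float("nan"),
        })
    per_init_df = pd.DataFrame(per_init)

    cond_summary = {}
    for plast, sub in per_init_df.groupby("plasticity"):
        vals = sub["mean_integrated_turn"].dropna()
        prob = sub["response_prob"].dropna()
        cond_summary[bool(plast)] = {
            "mean_integrated_turn": float(vals.mean()) if len(vals) else float("nan"),
            "sem_integrated_turn": float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan"),
            "response_prob": float(prob.mean()) if len(prob) else float("nan"),
        }
    return ExperimentReport(
        trials=trials,
        summary={"protocol": "perturb", "seed": seed, "n_perturbed": n_perturbed,
                 "per_init": per_init, "conditions": cond_summary,
                 "stimulus": {"amplitude": stim.amplitude,
                              "phase_duration": stim.phase_duration,
                              "repetitions": stim.repetitions,
                              "direction": stim.direction},
                 "burn_in_s": burn_in, "post_s": post, "stim_delay_s": stim_delay},
    )
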