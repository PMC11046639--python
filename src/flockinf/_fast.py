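"""Numba-accelerated integration kernel.

Replicates the reference (vectorized numpy) step for the standard
3-belief-order / 2-observation-order model; the numpy path in
:mod:`flockinf.world` remains the behavioral reference and the test
oracle.  Noise is drawn by the caller so both backends consume
identical random streams.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    HAS_NUMBA = True
except ImportError:  # pragma: no cover - numba is expected in the environment
    HAS_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=True)
def step_kernel(pos, head, mu, lam, informed, has_target, target,
                sec_lo, sec_hi, radius, speed,
                gamma, gamma_t, eta, alpha, alpha_t,
                M_soc, M_tgt, kappa_mu, kappa_a, dt,
                noise0, noise1, stim, tnoise, anoise,
                plasticity, kappa_theta, lam_min, lam_max):
    N = pos.shape[0]
    L = sec_lo.shape[0]
    M = mu.shape[1]
    r2 = radius * radius

    pos2 = np.empty_like(pos)
    head2 = np.empty_like(head)
    mu2 = np.empty_like(mu)
    lam2 = lam.copy()

    Kc = np.zeros(L)
    sdist = np.zeros(L)
    sappr = np.zeros(L)
    sux = np.zeros(L)
    suy = np.zeros(L)

    for i in range(N):
        hx = head[i, 0]
        hy = head[i, 1]
        hang = math.degrees(math.atan2(hy, hx))

        for l in range(L):
            Kc[l] = 0.0
            sdist[l] = 0.0
            sappr[l] = 0.0
            sux[l] = 0.0
            suy[l] = 0.0
        for j in range(N):
            if j == i:
                continue
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            d2 = dx * dx + dy * dy
            if d2 == 0.0 or d2 > r2:
                continue
            d = math.sqrt(d2)
            b = math.degrees(math.atan2(dy, dx)) - hang
            b = (b + 180.0) % 360.0 - 180.0
            for l in range(L):
                if sec_lo[l] <= b < sec_hi[l]:
                    ux = dx / d
                    uy = dy / d
                    Kc[l] += 1.0
                    sdist[l] += d
                    sappr[l] += ux * (head[j, 0] - hx) * speed + uy * (head[j, 1] - hy) * speed
                    sux[l] += ux
                    suy[l] += uy
                    break

        dvdt_x = 0.0
        dvdt_y = 0.0
        lam_i = lam[i]
        quad = 0.0
        n_obs = 0.0

        for m in range(M):
            is_target = has_target and m == L
            # model (process) error: shift(mu) - drift
            e0 = mu[i, m, 1]
            e1 = mu[i, m, 2]
            e2 = 0.0
            if is_target:
                e0 += alpha_t * mu[i, m, 0]
                e1 += alpha_t * mu[i, m, 1]
                e2 += alpha_t * mu[i, m, 2]
                Mm = M_tgt
            else:
                e0 += alpha * (mu[i, m, 0] - eta)
                e1 += alpha * mu[i, m, 1]
                e2 += alpha * mu[i, m, 2]
                Mm = M_soc
            g0 = e0 * Mm[0, 0] + e1 * Mm[1, 0] + e2 * Mm[2, 0]
            g1 = e0 * Mm[0, 1] + e1 * Mm[1, 1] + e2 * Mm[2, 1]
            g2 = e0 * Mm[0, 2] + e1 * Mm[1, 2] + e2 * Mm[2, 2]

            if is_target:
                observed = informed[i]
                if observed:
                    tdx = target[0] - pos[i, 0]
                    tdy = target[1] - pos[i, 1]
                    tdist = math.sqrt(tdx * tdx + tdy * tdy)
                    if tdist <= 0.0:
                        tdist = 1e-12
                    dTx = tdx / tdist
                    dTy = tdy / tdist
                    rate = -(dTx * hx + dTy * hy) * speed
                    y0 = tdist + tnoise[i, 0]
                    y1 = rate + tnoise[i, 1]
                    w0 = gamma_t
                    w1 = 2.0 * gamma_t * lam_i * lam_i
                    ez0 = y0 - mu[i, m, 0]
                    ez1 = y1 - mu[i, m, 1]
                    g0 -= w0 * ez0
                    g1 -= w1 * ez1
                    xi = w1 * ez1
                    dvdt_x += xi * dTx
                    dvdt_y += xi * dTy
                    quad += 2.0 * gamma_t * ez1 * ez1
                    n_obs += 1.0
            else:
                observed = Kc[m] > 0.0
                if observed:
                    xh = sdist[m] / Kc[m]
                    xp = sappr[m] / Kc[m]
                    y0 = xh + noise0[i, m]
                    y1 = xp + noise1[i, m] + stim[i, m]
                    w0 = gamma[m]
                    w1 = 2.0 * gamma[m] * lam_i * lam_i
                    ez0 = y0 - mu[i, m, 0]
                    ez1 = y1 - mu[i, m, 1]
                    g0 -= w0 * ez0
                    g1 -= w1 * ez1
                    xi = w1 * ez1
                    dvdt_x += xi * sux[m] / Kc[m]
                    dvdt_y += xi * suy[m] / Kc[m]
                    quad += 2.0 * gamma[m] * ez1 * ez1
                    n_obs += 1.0

            mu2[i, m, 0] = mu[i, m, 0] + dt * (mu[i, m, 1] - kappa_mu * g0)
            mu2[i, m, 1] = mu[i, m, 1] + dt * (mu[i, m, 2] - kappa_mu * g1)
            mu2[i, m, 2] = mu[i, m, 2] + dt * (-kappa_mu * g2)

        vx = hx + kappa_a * dt * dvdt_x + anoise[i, 0]
        vy = hy + kappa_a * dt * dvdt_y + anoise[i, 1]
        nrm = math.sqrt(vx * vx + vy * vy)
        if nrm > 0.0:
            head2[i, 0] = vx / nrm
            head2[i, 1] = vy / nrm
        else:
            head2[i, 0] = hx
            head2[i, 1] = hy

        if plasticity and kappa_theta > 0.0:
            dF = quad * lam_i - n_obs / lam_i
            lnew = lam_i - kappa_theta * dt * dF
            if lnew < lam_min:
                lnew = lam_min
            elif lnew > lam_max:
                lnew = lam_max
            lam2[i] = lnew

        pos2[i, 0] = pos[i, 0] + head2[i, 0] * speed * dt
        pos2[i, 1] = pos[i, 1] + head2[i, 1] * speed * dt

    return pos2, head2, mu2, lam2


@njit(cache=True)
def nearest_neighbor_kernel(positions):
    """Per-frame nearest-neighbor distance, positions (S, N, 2) -> (S, N)."""
    S, N, _ = positions.shape
    out = np.empty((S, N))
    for s in range(S):
        for i in range(N):
            best = np.inf
            for j in range(N):
                if j == i:
                    continue
                dx = positions[s, j, 0] - positions[s, i, 0]
                dy = positions[s, j, 1] - positions[s, i, 1]
                d2 = dx * dx + dy * dy
                if d2 < best:
                    best = d2
            out[s, i] = math.sqrt(best)
    return out
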