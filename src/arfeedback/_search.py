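"""Compiled kernels for the Monte Carlo screen and Metropolis–Hastings
refinement.  Thin, unvalidated; the public surface is
:mod:`arfeedback.fitting`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from . import _ode

INF = np.inf


@njit(cache=True)
def _score_one(arch, p, y0, t_grid, t_obs, obs_c, obs_i,
               rtol, atol, max_steps):
    """Paired simulation + SSE of one parameter vector.

    Returns (sse_control, sse_inhibitor); either failure yields (inf, inf).
    The target readout is normalized to max 100 over the report grid and
    linearly interpolated to the observed times.
    """
    Yc, sc = _ode.integrate(arch, p, y0, t_grid, False, rtol, atol,
                            max_steps, False)
    if sc != _ode.OK:
        return INF, INF
    Yi, si = _ode.integrate(arch, p, y0, t_grid, True, rtol, atol,
                            max_steps, False)
    if si != _ode.OK:
        return INF, INF

    mc = 0.0
    mi = 0.0
    for j in range(t_grid.shape[0]):
        if Yc[j, 8] > mc:
            mc = Yc[j, 8]
        if Yi[j, 8] > mi:
            mi = Yi[j, 8]
    if mc <= 0.0 or mi <= 0.0:
        return INF, INF

    tc = 100.0 * np.maximum(Yc[:, 8], 0.0) / mc
    ti = 100.0 * np.maximum(Yi[:, 8], 0.0) / mi
    sim_c = np.interp(t_obs, t_grid, tc)
    sim_i = np.interp(t_obs, t_grid, ti)

    sse_c = 0.0
    sse_i = 0.0
    for j in range(t_obs.shape[0]):
        dc = sim_c[j] - obs_c[j]
        di = sim_i[j] - obs_i[j]
        sse_c += dc * dc
        sse_i += di * di
    if not (np.isfinite(sse_c) and np.isfinite(sse_i)):
        return INF, INF
    return sse_c, sse_i


@njit(cache=True)
def score_batch(arch, P, y0, t_grid, t_obs, obs_c, obs_i,
                rtol, atol, max_steps):
    """Score every row of the (n, 18) parameter matrix ``P``.

    Returns an (n, 2) array of (sse_control, sse_inhibitor).
    """
    n = P.shape[0]
    out = np.empty((n, 2))
    for i in range(n):
        sc, si = _score_one(arch, P[i], y0, t_grid, t_obs, obs_c, obs_i,
                            rtol, atol, max_steps)
        out[i, 0] = sc
        out[i, 1] = si
    return out


@njit(cache=True)
def mh_chain(arch, p0, active, y0, t_grid, t_obs, obs_c, obs_i,
             n_mh, proposal_cv, temperature, sse0_c, sse0_i, seed,
             rtol, atol, max_steps):
    """Metropolis–Hastings refinement of one parameter vector.

    Proposals perturb each active parameter with a Gaussian of standard
    deviation ``proposal_cv`` times its current value; negative draws are
    re-drawn.  The fast/slow PARP7 decay pair is re-ordered after each
    proposal so the fast rate stays the larger.  Acceptance uses
    ``min(1, exp((sse_cur - sse_prop) / temperature))``; ``temperature <= 0``
    accepts only strict improvements (greedy limit).

    Returns (chain_params, chain_sse, best_index) where chain arrays have
    ``n_mh + 1`` entries (the start state first) and ``chain_sse`` holds
    (sse_control, sse_inhibitor) rows.
    """
    np.random.seed(seed)
    n_par = p0.shape[0]
    chain_p = np.empty((n_mh + 1, n_par))
    chain_s = np.empty((n_mh + 1, 2))
    chain_p[0] = p0
    chain_s[0, 0] = sse0_c
    chain_s[0, 1] = sse0_i

    cur = p0.copy()
    cur_sse = sse0_c + sse0_i
    cur_c, cur_i = sse0_c, sse0_i
    best_idx = 0
    best_sse = cur_sse
    prop = np.empty(n_par)

    for step in range(1, n_mh + 1):
        for j in range(n_par):
            if not active[j]:
                prop[j] = cur[j]
                continue
            sd = proposal_cv * cur[j]
            v = cur[j] + sd * np.random.standard_normal()
            while v < 0.0:
                v = cur[j] + sd * np.random.standard_normal()
            prop[j] = v
        # keep the fast PARP7 decay rate the larger of the pair
        if prop[13] < prop[14]:
            tmp = prop[13]
            prop[13] = prop[14]
            prop[14] = tmp

        sc, si = _score_one(arch, prop, y0, t_grid, t_obs, obs_c, obs_i,
                            rtol, atol, max_steps)
        s = sc + si
        accept = False
        if np.isfinite(s):
            if s <= cur_sse:
                accept = True
            elif temperature > 0.0:
                if np.random.random() < np.exp((cur_sse - s) / temperature):
                    accept = True
        if accept:
            cur[:] = prop
            cur_sse = s
            cur_c, cur_i = sc, si
        chain_p[step] = cur
        chain_s[step, 0] = cur_c
        chain_s[step, 1] = cur_i
        if cur_sse < best_sse:
            best_sse = cur_sse
            best_idx = step

    return chain_p, chain_s, best_idx
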