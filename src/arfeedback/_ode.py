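"""Compiled ODE kernels for the AR–PARP7 feedback models.

The right-hand sides, analytic Jacobians and a Rosenbrock(2,3) stiff
integrator live here as numba-jitted functions operating on plain float64
arrays.  The public, documented surface is in :mod:`arfeedback.models`;
nothing in this module validates its inputs.

State layout (index -> species):

    0  mRNA_AR      AR transcript
    1  AR_free      free unmodified ligand-bound AR
    2  AR_adp_free  free ADP-ribosylated AR
    3  P_free       unoccupied promoters
    4  C_AR         unmodified AR-promoter complex
    5  C_ADP        modified AR-promoter complex
    6  mRNA_P7      PARP7 transcript
    7  P7           PARP7 protein
    8  T            target transcript (composite readout)

Parameter vector layout (index -> rate constant, all per hour):

    0  k_trl_ar   1  k_tx_ar    2  k_rep_ar   3  k_deg_arm
    4  k_on_AR    5  k_off_AR   6  k_on_ADP   7  k_off_ADP
    8  k_cat_adp  9  k_deg_adp  10 k_tx_p7    11 k_deg_p7m
    12 k_trl_p7   13 k_deg_p7_fast  14 k_deg_p7_slow  15 K_stab
    16 k_tx_target  17 k_deg_target

Architecture codes: 0 = simple, 1 = chromatin, 2 = nucleoplasm.
"""

from __future__ import annotations

import numpy as np
from numba import njit

N_STATE = 9

# integrator status codes
OK = 0
MAX_STEPS_EXCEEDED = 1
NONFINITE = 2
NEGATIVE_STATE = 3

# pre-clamp tolerance for negative states at report points
NEG_TOL = 1e-8


@njit(cache=True)
def rhs(arch: int, p: np.ndarray, y: np.ndarray, k_cat: float, dy: np.ndarray) -> None:
    M, A, Aa, P, Ca, Cd, Mp, S, T = (
        y[0], y[1], y[2], y[3], y[4], y[5], y[6], y[7], y[8])

    k_trl_ar, k_tx_ar, k_rep_ar, k_deg_arm = p[0], p[1], p[2], p[3]
    k_on_AR, k_off_AR, k_on_ADP, k_off_ADP = p[4], p[5], p[6], p[7]
    k_deg_adp = p[9]
    k_tx_p7, k_deg_p7m, k_trl_p7 = p[10], p[11], p[12]
    kf, ks, K_stab = p[13], p[14], p[15]
    k_tx_t, k_deg_t = p[16], p[17]

    # AR transcript: basal production, mass-action self-repression, decay
    dy[0] = k_tx_ar - k_rep_ar * A * M - k_deg_arm * M

    if arch == 0:  # simple: no promoter species, AR itself transcribes
        mod = k_cat * S * A
        dy[1] = k_trl_ar * M - mod
        dy[2] = mod - k_deg_adp * Aa
        dy[3] = 0.0
        dy[4] = 0.0
        dy[5] = 0.0
        u = A
        drive = A
    else:
        bindA = k_on_AR * A * P
        relA = k_off_AR * Ca
        bindD = k_on_ADP * Aa * P
        relD = k_off_ADP * Cd
        if arch == 1:  # chromatin: modification targets promoter-bound AR
            mod = k_cat * S * Ca
            dy[1] = k_trl_ar * M - bindA + relA
            dy[2] = -bindD + relD - k_deg_adp * Aa
            dy[4] = bindA - relA - mod
            dy[5] = bindD - relD + mod
        else:  # nucleoplasm: modification targets free AR
            mod = k_cat * S * A
            dy[1] = k_trl_ar * M - bindA + relA - mod
            dy[2] = -bindD + relD - k_deg_adp * Aa + mod
            dy[4] = bindA - relA
            dy[5] = bindD - relD
        dy[3] = -bindA + relA - bindD + relD
        u = A + Ca
        drive = Ca + Cd

    # PARP7: transcription driven by the transcribing unit, decay fast->slow
    # as unmodified AR accumulates (AR promotes the slow rate)
    delta = kf - (kf - ks) * u / (K_stab + u)
    dy[6] = k_tx_p7 * drive - k_deg_p7m * Mp
    dy[7] = k_trl_p7 * Mp - delta * S
    dy[8] = k_tx_t * drive - k_deg_t * T


@njit(cache=True)
def jacobian(arch: int, p: np.ndarray, y: np.ndarray, k_cat: float,
             J: np.ndarray) -> None:
    M, A, Aa, P, Ca, Cd, Mp, S, T = (
        y[0], y[1], y[2], y[3], y[4], y[5], y[6], y[7], y[8])

    k_trl_ar, k_tx_ar, k_rep_ar, k_deg_arm = p[0], p[1], p[2], p[3]
    k_on_AR, k_off_AR, k_on_ADP, k_off_ADP = p[4], p[5], p[6], p[7]
    k_deg_adp = p[9]
    k_tx_p7, k_deg_p7m, k_trl_p7 = p[10], p[11], p[12]
    kf, ks, K_stab = p[13], p[14], p[15]
    k_tx_t, k_deg_t = p[16], p[17]

    J[:, :] = 0.0

    # row 0: mRNA_AR
    J[0, 0] = -k_rep_ar * A - k_deg_arm
    J[0, 1] = -k_rep_ar * M

    if arch == 0:
        u = A
        J[1, 0] = k_trl_ar
        J[1, 1] = -k_cat * S
        J[1, 7] = -k_cat * A
        J[2, 1] = k_cat * S
        J[2, 2] = -k_deg_adp
        J[2, 7] = k_cat * A
        # rows 3-5 stay zero (species absent)
        J[6, 1] = k_tx_p7
        J[8, 1] = k_tx_t
    else:
        u = A + Ca
        # row 1: AR_free
        J[1, 0] = k_trl_ar
        J[1, 1] = -k_on_AR * P
        J[1, 3] = -k_on_AR * A
        J[1, 4] = k_off_AR
        # row 2: AR_adp_free
        J[2, 2] = -k_on_ADP * P - k_deg_adp
        J[2, 3] = -k_on_ADP * Aa
        J[2, 5] = k_off_ADP
        # row 3: P_free
        J[3, 1] = -k_on_AR * P
        J[3, 2] = -k_on_ADP * P
        J[3, 3] = -k_on_AR * A - k_on_ADP * Aa
        J[3, 4] = k_off_AR
        J[3, 5] = k_off_ADP
        # row 4: C_AR, row 5: C_ADP
        J[4, 1] = k_on_AR * P
        J[4, 3] = k_on_AR * A
        J[4, 4] = -k_off_AR
        J[5, 2] = k_on_ADP * P
        J[5, 3] = k_on_ADP * Aa
        J[5, 5] = -k_off_ADP
        if arch == 1:
            J[4, 4] -= k_cat * S
            J[4, 7] = -k_cat * Ca
            J[5, 4] = k_cat * S
            J[5, 7] = k_cat * Ca
        else:
            J[1, 1] -= k_cat * S
            J[1, 7] = -k_cat * A
            J[2, 1] = k_cat * S
            J[2, 7] = k_cat * A
        J[6, 4] = k_tx_p7
        J[6, 5] = k_tx_p7
        J[8, 4] = k_tx_t
        J[8, 5] = k_tx_t

    # row 6: mRNA_P7
    J[6, 6] = -k_deg_p7m
    # row 7: P7 with AR-dependent decay rate
    delta = kf - (kf - ks) * u / (K_stab + u)
    ddelta_du = -(kf - ks) * K_stab / ((K_stab + u) * (K_stab + u))
    J[7, 6] = k_trl_p7
    J[7, 7] = -delta
    J[7, 1] = -S * ddelta_du
    if arch != 0:
        J[7, 4] = -S * ddelta_du
    # row 8: T
    J[8, 8] = -k_deg_t


@njit(cache=True)
def _lu_factor(W: np.ndarray, piv: np.ndarray) -> bool:
    """In-place LU with partial pivoting; returns False on singularity."""
    n = W.shape[0]
    for k in range(n):
        pk = k
        amax = abs(W[k, k])
        for i in range(k + 1, n):
            a = abs(W[i, k])
            if a > amax:
                amax = a
                pk = i
        if amax == 0.0:
            return False
        piv[k] = pk
        if pk != k:
            for j in range(n):
                tmp = W[k, j]
                W[k, j] = W[pk, j]
                W[pk, j] = tmp
        inv = 1.0 / W[k, k]
        for i in range(k + 1, n):
            l = W[i, k] * inv
            W[i, k] = l
            for j in range(k + 1, n):
                W[i, j] -= l * W[k, j]
    return True


@njit(cache=True)
def _lu_solve(W: np.ndarray, piv: np.ndarray, b: np.ndarray,
              x: np.ndarray) -> None:
    n = W.shape[0]
    for i in range(n):
        x[i] = b[i]
    for k in range(n):
        pk = piv[k]
        if pk != k:
            tmp = x[k]
            x[k] = x[pk]
            x[pk] = tmp
        for i in range(k + 1, n):
            x[i] -= W[i, k] * x[k]
    for i in range(n - 1, -1, -1):
        s = x[i]
        for j in range(i + 1, n):
            s -= W[i, j] * x[j]
        x[i] = s / W[i, i]


@njit(cache=True)
def _solve_refined(W0: np.ndarray, LU: np.ndarray, piv: np.ndarray,
                   b: np.ndarray, x: np.ndarray, r: np.ndarray,
                   dx: np.ndarray) -> None:
    """LU solve plus one pass of iterative refinement.

    W can be severely ill-conditioned on large stiff steps; a single
    refinement pass keeps linear invariants of the system (e.g. promoter
    conservation) from drifting at the solver's forward-error level.
    """
    n = W0.shape[0]
    _lu_solve(LU, piv, b, x)
    for i in range(n):
        s = b[i]
        for j in range(n):
            s -= W0[i, j] * x[j]
        r[i] = s
    _lu_solve(LU, piv, r, dx)
    for i in range(n):
        x[i] += dx[i]


@njit(cache=True)
def integrate(arch: int, p: np.ndarray, y0: np.ndarray, t_out: np.ndarray,
              inhibitor: bool, rtol: float, atol: float,
              max_steps: int, refine: bool = True) -> tuple[np.ndarray, int]:
    """Adaptive Rosenbrock(2,3) integration reported at ``t_out``.

    Returns ``(Y, status)`` with ``Y`` of shape ``(len(t_out), 9)``.  The
    interpolant between accepted steps is the solver's own quadratic
    continuous extension.  States are reported as computed (no clamping);
    a state below ``-NEG_TOL`` at a report point yields status
    ``NEGATIVE_STATE``.
    """
    n_out = t_out.shape[0]
    Y = np.empty((n_out, N_STATE))
    k_cat = 0.0 if inhibitor else p[8]

    d = 1.0 / (2.0 + np.sqrt(2.0))
    e32 = 6.0 + np.sqrt(2.0)

    t = t_out[0]
    t_end = t_out[n_out - 1]
    y = y0.copy()

    iout = 0
    # report points that coincide with the start
    while iout < n_out and t_out[iout] <= t:
        for j in range(N_STATE):
            Y[iout, j] = y[j]
        iout += 1
    if iout >= n_out:
        return Y, OK

    f0 = np.empty(N_STATE)
    f1 = np.empty(N_STATE)
    f2 = np.empty(N_STATE)
    k1 = np.empty(N_STATE)
    k2 = np.empty(N_STATE)
    k3 = np.empty(N_STATE)
    b = np.empty(N_STATE)
    ytmp = np.empty(N_STATE)
    ynew = np.empty(N_STATE)
    J = np.empty((N_STATE, N_STATE))
    W = np.empty((N_STATE, N_STATE))
    W0 = np.empty((N_STATE, N_STATE))
    piv = np.empty(N_STATE, dtype=np.int64)
    res = np.empty(N_STATE)
    dx = np.empty(N_STATE)

    rhs(arch, p, y, k_cat, f0)
    for j in range(N_STATE):
        if not np.isfinite(f0[j]):
            return Y, NONFINITE

    # initial step: limited by the fastest apparent time scale
    fmax = 0.0
    for j in range(N_STATE):
        sc = atol + rtol * abs(y[j])
        r = abs(f0[j]) / sc
        if r > fmax:
            fmax = r
    h = 0.01 if fmax == 0.0 else min(0.01, 0.1 / fmax)
    hmax = (t_end - t) / 4.0
    if h > hmax:
        h = hmax
    hmin = 1e-14

    steps = 0
    while t < t_end:
        if steps >= max_steps:
            return Y, MAX_STEPS_EXCEEDED
        steps += 1
        if t + h > t_end:
            h = t_end - t

        jacobian(arch, p, y, k_cat, J)
        hd = h * d
        for i in range(N_STATE):
            for j in range(N_STATE):
                W[i, j] = -hd * J[i, j]
                W0[i, j] = W[i, j]
            W[i, i] += 1.0
            W0[i, i] += 1.0
        if not _lu_factor(W, piv):
            h *= 0.5
            if h < hmin:
                return Y, MAX_STEPS_EXCEEDED
            continue

        if refine:
            _solve_refined(W0, W, piv, f0, k1, res, dx)
        else:
            _lu_solve(W, piv, f0, k1)
        for j in range(N_STATE):
            ytmp[j] = y[j] + 0.5 * h * k1[j]
        rhs(arch, p, ytmp, k_cat, f1)
        for j in range(N_STATE):
            b[j] = f1[j] - k1[j]
        if refine:
            _solve_refined(W0, W, piv, b, k2, res, dx)
        else:
            _lu_solve(W, piv, b, k2)
        for j in range(N_STATE):
            k2[j] += k1[j]
        for j in range(N_STATE):
            ynew[j] = y[j] + h * k2[j]
        rhs(arch, p, ynew, k_cat, f2)
        for j in range(N_STATE):
            b[j] = f2[j] - e32 * (k2[j] - f1[j]) - 2.0 * (k1[j] - f0[j])
        _lu_solve(W, piv, b, k3)

        # error estimate and norm
        errnorm = 0.0
        finite = True
        for j in range(N_STATE):
            if not (np.isfinite(ynew[j]) and np.isfinite(f2[j])):
                finite = False
                break
            e = (h / 6.0) * (k1[j] - 2.0 * k2[j] + k3[j])
            ay = abs(y[j])
            an = abs(ynew[j])
            sc = atol + rtol * (ay if ay > an else an)
            r = abs(e) / sc
            if r > errnorm:
                errnorm = r

        if (not finite) or errnorm > 1.0:
            if not finite:
                h *= 0.1
            else:
                fac = 0.9 / errnorm ** (1.0 / 3.0)
                if fac < 0.1:
                    fac = 0.1
                h *= fac
            if h < hmin:
                return Y, NONFINITE if not finite else MAX_STEPS_EXCEEDED
            continue

        # accepted: emit report points inside (t, t+h] via the quadratic
        # continuous extension  y(t+s*h) = y + h*[s(1-s)k1 + s(s-2d)k2]/(1-2d)
        tnew = t + h
        while iout < n_out and t_out[iout] <= tnew + 1e-14:
            s = (t_out[iout] - t) / h
            if s > 1.0:
                s = 1.0
            c1 = s * (1.0 - s) / (1.0 - 2.0 * d)
            c2 = s * (s - 2.0 * d) / (1.0 - 2.0 * d)
            for j in range(N_STATE):
                v = y[j] + h * (c1 * k1[j] + c2 * k2[j])
                if v < -NEG_TOL:
                    return Y, NEGATIVE_STATE
                Y[iout, j] = v
            iout += 1

        t = tnew
        for j in range(N_STATE):
            y[j] = ynew[j]
            f0[j] = f2[j]

        fac = 0.9 / errnorm ** (1.0 / 3.0) if errnorm > 0.0 else 5.0
        if fac > 5.0:
            fac = 5.0
        h *= fac
        if t + h > t_end:
            pass  # trimmed at loop head

    return Y, OK
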