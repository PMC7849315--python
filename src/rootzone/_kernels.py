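"""Compiled inner loop for the ODE integration.

The explicit integrator takes thousands of sub-steps per time unit (the
membrane carrier pools make the auxin equations stiff), so the batched
RK4/Euler loop is JIT-compiled with numba.  The formulas mirror
``rootzone.simulator._rhs`` exactly; the pure-numpy path remains available
(``use_numba=False``) and the two are cross-checked in the test suite.

State layout: ``Y`` is a (16, n) array of per-file pools in the order
A, PINc, PINm_apical, PINm_basal, PINm_outer, PINm_inner, DIV, L for the
epidermis then the cortex; ``led`` holds the four cumulative auxin ledger
terms (source in, degraded, outer efflux, advected out).
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised through the simulator
    from numba import njit
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn
        return wrap if not (args and callable(args[0])) else args[0]

# parameter vector layout (see _param_vector in simulator.py)
K_A, D_A, M_P, D_P, Q_P, L_N, TR_N, TR_WN, TR_A, TR_I, \
    K_V0, K_V1, K_V2, K_V3, K_V4, T_V, H1, H2, \
    KL_M, KL_E, ML_M, ML_E, MAXL, K_D, LITERAL, MAXA_FIXED = range(26)


@njit(cache=True)
def _logistic(x):
    if x >= 0.0:
        return 1.0 / (1.0 + np.exp(-x))
    ex = np.exp(x)
    return ex / (1.0 + ex)


@njit(cache=True)
def _rhs_kernel(Y, elong_e, elong_c, src_e, N, pv, dY, dled):
    n = Y.shape[1]
    lat = pv[L_N] * N
    base = N * pv[TR_N] + (1.0 - N) * pv[TR_WN]
    literal = pv[LITERAL] > 0.5

    # dynamic maxA: meristem max over both files, global fallback
    if pv[MAXA_FIXED] > 0.0:
        maxA = pv[MAXA_FIXED]
    else:
        maxA = 0.0
        gmax = 0.0
        for k in range(n):
            if not elong_e[k] and Y[0, k] > maxA:
                maxA = Y[0, k]
            if not elong_c[k] and Y[8, k] > maxA:
                maxA = Y[8, k]
            if Y[0, k] > gmax:
                gmax = Y[0, k]
            if Y[8, k] > gmax:
                gmax = Y[8, k]
        if maxA <= 0.0:
            maxA = gmax
        if maxA < 1e-12:
            maxA = 1e-12

    for j in range(4):
        dled[j] = 0.0

    for f in range(2):
        o = 8 * f
        for k in range(n):
            idx = float(k + 1)
            A = Y[o + 0, k]
            PINc = Y[o + 1, k]
            Pa = Y[o + 2, k]
            Pb = Y[o + 3, k]
            Po = Y[o + 4, k]
            Pi = Y[o + 5, k]
            DIV = Y[o + 6, k]
            L = Y[o + 7, k]
            elong = elong_e[k] if f == 0 else elong_c[k]

            lg = _logistic(pv[TR_A] * A + pv[TR_I] * idx)
            T = PINc * base * lg
            turn = pv[D_P] * (1.0 + A / pv[Q_P])
            decay = 0.0 if literal else turn

            dY[o + 1, k] = pv[M_P] - pv[D_P] * PINc * (1.0 + A / pv[Q_P]) \
                - (0.0 if literal else T)
            dY[o + 2, k] = (1.0 - lat) * T - decay * Pa
            dY[o + 3, k] = -decay * Pb
            if f == 0:   # epidermis: outer face -> sink, inner -> cortex
                dY[o + 4, k] = -decay * Po
                dY[o + 5, k] = lat * T - decay * Pi
            else:        # cortex: outer face -> epidermis
                dY[o + 4, k] = lat * T - decay * Po
                dY[o + 5, k] = -decay * Pi

            # division factor
            gate = 1.0 / (1.0 + np.exp(idx * pv[T_V]))
            synth = pv[K_V0] * pv[K_V1] * (A / maxA + L / pv[MAXL]) * gate
            degr = DIV * pv[K_V2] * (1.0 + (A / pv[K_V3]) ** pv[H1]) \
                / (1.0 + (A / pv[K_V4]) ** pv[H2])
            dY[o + 6, k] = synth - degr

            # growth
            kl = pv[KL_E] if elong else pv[KL_M]
            ml = pv[ML_E] if elong else pv[ML_M]
            g = kl * A / (A + 1.0) * L * (1.0 - L / ml)
            dY[o + 7, k] = g if g > 0.0 else 0.0

    # auxin transport
    ka = pv[K_A]
    kd = pv[K_D]
    for k in range(n):
        dY[0, k] = 0.0
        dY[8, k] = 0.0
    for k in range(n):
        A_e = Y[0, k]
        A_c = Y[8, k]
        up_e = ka * A_e * Y[2, k]
        dn_e = ka * A_e * Y[3, k]
        up_c = ka * A_c * Y[10, k]
        dn_c = ka * A_c * Y[11, k]
        lat_ec = ka * A_e * Y[5, k] + kd * A_e
        lat_ce = ka * A_c * Y[12, k] + kd * A_c
        sink_e = ka * A_e * Y[4, k]

        dAe = src_e[k] - up_e - dn_e - lat_ec + lat_ce - sink_e \
            - pv[D_A] * A_e
        dAc = -up_c - dn_c - lat_ce + lat_ec - pv[D_A] * A_c
        dY[0, k] += dAe
        dY[8, k] += dAc
        if k + 1 < n:
            dY[0, k + 1] += up_e
            dY[8, k + 1] += up_c
        else:
            dled[3] += up_e + up_c
        if k > 0:
            dY[0, k - 1] += dn_e
            dY[8, k - 1] += dn_c

        dled[0] += src_e[k]
        dled[1] += pv[D_A] * (A_e + A_c)
        dled[2] += sink_e


@njit(cache=True)
def subsystem_gauss_seidel(A_e, A_c, src_e, N, pv, omega, tol, max_iter):
    """Damped Gauss-Seidel sweeps for the auxin fixed point of the static
    auxin/PIN2 subsystem (PIN pools closed-form in the local auxin).
    Mutates A_e, A_c in place; returns the iteration count (negative if
    not converged)."""
    n = A_e.size
    base = N * pv[TR_N] + (1.0 - N) * pv[TR_WN]
    lat = pv[L_N] * N
    ka = pv[K_A]
    kd = pv[K_D]
    for it in range(max_iter):
        worst = 0.0
        up_prev_e = 0.0
        up_prev_c = 0.0
        for k in range(n):
            idx = float(k + 1)
            # epidermis pools at current A
            Ae = A_e[k]
            lg = _logistic(pv[TR_A] * Ae + pv[TR_I] * idx)
            turn = pv[D_P] * (1.0 + Ae / pv[Q_P])
            PINc = pv[M_P] / (turn + base * lg)
            T = PINc * base * lg
            Pa_e = (1.0 - lat) * T / turn
            Pl_e = lat * T / turn
            # cortex pools at current A
            Ac = A_c[k]
            lg_c = _logistic(pv[TR_A] * Ac + pv[TR_I] * idx)
            turn_c = pv[D_P] * (1.0 + Ac / pv[Q_P])
            PINc_c = pv[M_P] / (turn_c + base * lg_c)
            T_c = PINc_c * base * lg_c
            Pa_c = (1.0 - lat) * T_c / turn_c
            Pl_c = lat * T_c / turn_c

            in_e = src_e[k] + up_prev_e + ka * Ac * Pl_c + kd * Ac
            out_e = ka * (Pa_e + Pl_e) + kd + pv[D_A]
            new_e = in_e / out_e
            de = abs(new_e - Ae) / (Ae if Ae > 1e-9 else 1e-9)
            if de > worst:
                worst = de
            A_e[k] = (1.0 - omega) * Ae + omega * new_e

            in_c = up_prev_c + ka * A_e[k] * Pl_e + kd * A_e[k]
            out_c = ka * (Pa_c + Pl_c) + kd + pv[D_A]
            new_c = in_c / out_c
            dc = abs(new_c - Ac) / (Ac if Ac > 1e-9 else 1e-9)
            if dc > worst:
                worst = dc
            A_c[k] = (1.0 - omega) * Ac + omega * new_c

            # shootward flux out of the updated cells feeds cell k+1
            lg = _logistic(pv[TR_A] * A_e[k] + pv[TR_I] * idx)
            turn = pv[D_P] * (1.0 + A_e[k] / pv[Q_P])
            PINc = pv[M_P] / (turn + base * lg)
            up_prev_e = ka * A_e[k] * (1.0 - lat) * PINc * base * lg / turn
            lg_c = _logistic(pv[TR_A] * A_c[k] + pv[TR_I] * idx)
            turn_c = pv[D_P] * (1.0 + A_c[k] / pv[Q_P])
            PINc_c = pv[M_P] / (turn_c + base * lg_c)
            up_prev_c = ka * A_c[k] * (1.0 - lat) * PINc_c * base * lg_c \
                / turn_c
        if worst < tol:
            return it + 1
    return -max_iter


@njit(cache=True)
def integrate_batch(Y, led, elong_e, elong_c, src_e, N, pv, dt, nsub,
                    use_rk4):
    """Advance ``nsub`` fixed steps of size ``dt``; mutates Y and led."""
    n = Y.shape[1]
    k1 = np.empty((16, n))
    l1 = np.empty(4)
    if use_rk4:
        k2 = np.empty((16, n))
        k3 = np.empty((16, n))
        k4 = np.empty((16, n))
        l2 = np.empty(4)
        l3 = np.empty(4)
        l4 = np.empty(4)
        Ytmp = np.empty((16, n))
    for _ in range(nsub):
        _rhs_kernel(Y, elong_e, elong_c, src_e, N, pv, k1, l1)
        if use_rk4:
            for r in range(16):
                for c in range(n):
                    Ytmp[r, c] = Y[r, c] + 0.5 * dt * k1[r, c]
            _rhs_kernel(Ytmp, elong_e, elong_c, src_e, N, pv, k2, l2)
            for r in range(16):
                for c in range(n):
                    Ytmp[r, c] = Y[r, c] + 0.5 * dt * k2[r, c]
            _rhs_kernel(Ytmp, elong_e, elong_c, src_e, N, pv, k3, l3)
            for r in range(16):
                for c in range(n):
                    Ytmp[r, c] = Y[r, c] + dt * k3[r, c]
            _rhs_kernel(Ytmp, elong_e, elong_c, src_e, N, pv, k4, l4)
            for r in range(16):
                for c in range(n):
                    v = Y[r, c] + (dt / 6.0) * (k1[r, c] + 2.0 * k2[r, c]
                                                + 2.0 * k3[r, c] + k4[r, c])
                    Y[r, c] = v if v > 0.0 else 0.0
            for j in range(4):
                led[j] += (dt / 6.0) * (l1[j] + 2.0 * l2[j]
                                        + 2.0 * l3[j] + l4[j])
        else:
            for r in range(16):
                for c in range(n):
                    v = Y[r, c] + dt * k1[r, c]
                    Y[r, c] = v if v > 0.0 else 0.0
            for j in range(4):
                led[j] += dt * l1[j]
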