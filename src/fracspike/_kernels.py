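"""Numba-compiled inner loops for the GL-LIF and L1-HH simulators.

The fractional memory sums are O(N*W) for a window of W steps, which is
the dominant cost; these loops are kept free of Python objects so numba
can vectorize the history dot products.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def flif_gl_kernel(drive, dt_eta, tau_m, theta, n_ref, w_rev, Cw, W, B):
    """Advance the GL fractional LIF on the deviation u = v - v_r.

    drive : r_m * I(t) in mV (one entry per grid point)
    dt_eta : (dt)^eta
    theta : v_Th - v_r in mV
    n_ref : refractory steps (samples clamped to rest after a spike)
    w_rev : GL weights w_1..w_{W+B} reversed (w_rev[W+B-k] = w_k)
    Cw : cumulative weight sums Cw[k] = sum_{i<=k} w_i, length n+1
    W : exact-memory window in steps
    B : tail compression block length (steps); B = 0 disables the tail

    History within the window enters the memory sum exactly; older
    history is compressed into per-block means weighted by the exact
    cumulative GL weights (the weight sequence's total variation beyond
    the window is tiny, so the block approximation is near-exact).
    Returns (u, spike_indices).  The clamped samples stay at u = 0 and
    participate in the memory sum at that value.
    """
    n = drive.shape[0]
    u = np.zeros(n)
    spikes = np.empty(n, dtype=np.int64)
    n_spk = 0
    ref_until = -1
    WB = w_rev.shape[0]          # = W + B
    n_blocks = 0 if B == 0 else n // B + 1
    block_sum = np.zeros(max(n_blocks, 1))
    for N in range(n - 1):
        idx = N + 1
        if B > 0 and idx % B == 0:
            b = idx // B - 1
            acc = 0.0
            for j in range(idx - B, idx):
                acc += u[j]
            block_sum[b] = acc
        if idx <= ref_until:
            u[idx] = 0.0
            continue
        nb = 0 if B == 0 else max(0, (idx - W) // B)
        j0 = nb * B                 # exact region covers u[j0:idx]
        Kex = idx - j0
        s = np.dot(w_rev[WB - Kex:WB], u[j0:idx])
        for b in range(nb):
            k_hi = idx - b * B      # weights w_{k_lo+1} .. w_{k_hi}
            k_lo = k_hi - B
            s += (block_sum[b] / B) * (Cw[k_hi] - Cw[k_lo])
        u[idx] = dt_eta * (-u[N] + drive[N]) / tau_m - s
        if u[idx] >= theta:
            spikes[n_spk] = idx
            n_spk += 1
            u[idx] = 0.0
            ref_until = idx + n_ref
    return u, spikes[:n_spk]


@njit(cache=True, inline="always")
def _xexprel(x):
    """x / (e^x - 1) with the removable singularity at x = 0."""
    if abs(x) < 1e-6:
        return 1.0 - x / 2.0 + x * x / 12.0
    return x / (np.expm1(x))


@njit(cache=True, inline="always")
def _alpha_n(u):
    # 0.01 (10 - u) / (e^{(10-u)/10} - 1) == 0.1 * xexprel((10-u)/10)
    return 0.1 * _xexprel((10.0 - u) / 10.0)


@njit(cache=True, inline="always")
def _beta_n(u):
    return 0.125 * np.exp(-u / 80.0)


@njit(cache=True, inline="always")
def _alpha_m(u):
    return 1.0 * _xexprel((25.0 - u) / 10.0)


@njit(cache=True, inline="always")
def _beta_m(u):
    return 4.0 * np.exp(-u / 18.0)


@njit(cache=True, inline="always")
def _alpha_h(u):
    return 0.07 * np.exp(-u / 20.0)


@njit(cache=True, inline="always")
def _beta_h(u):
    return 1.0 / (1.0 + np.exp(3.0 - 0.1 * u))


@njit(cache=True, inline="always")
def _vmh_rhs(v, m, h, n, I, cm, gna, gk, gm, ena, ek, vr, V0):
    u = v - V0
    dv = (-(gm * (v - vr) + gk * (n ** 4) * (v - ek)
            + gna * (m ** 3) * h * (v - ena)) + I) / cm
    dm = _alpha_m(u) * (1.0 - m) - _beta_m(u) * m
    dh = _alpha_h(u) * (1.0 - h) - _beta_h(u) * h
    return dv, dm, dh


@njit(cache=True)
def fhh_l1_kernel(I, dt, eta, gamma2me, cm, gna, gk, gm, ena, ek, vr, V0,
                  v0, m0, h0, n0, d_rev, W):
    """Fractional-n-gate Hodgkin–Huxley: RK4 on (v, m, h), L1 on n.

    Per global step, (v, m, h) advance one RK4 step holding n fixed,
    then n advances one L1 step using the start-of-step voltage.

    d_rev : L1 difference coefficients d_1..d_W reversed
            (d_j = (j+1)^(1-eta) - j^(1-eta)), all zero at eta = 1
    gamma2me : Gamma(2 - eta)

    Returns (v, m, h, n, max_gate_violation).
    """
    nsteps = I.shape[0]
    v = np.empty(nsteps)
    m = np.empty(nsteps)
    h = np.empty(nsteps)
    ngate = np.empty(nsteps)
    dn = np.zeros(nsteps)          # dn[k] = n_{k+1} - n_k
    v[0], m[0], h[0], ngate[0] = v0, m0, h0, n0
    dt_eta_g = dt ** eta * gamma2me
    viol = 0.0
    memoryless = eta >= 1.0
    for N in range(nsteps - 1):
        vv, mm, hh, nn = v[N], m[N], h[N], ngate[N]
        Ia = I[N]
        Ib = 0.5 * (I[N] + I[N + 1])
        Ic = I[N + 1]
        # RK4 on (v, m, h) with n held at its current value
        k1v, k1m, k1h = _vmh_rhs(vv, mm, hh, nn, Ia, cm, gna, gk, gm, ena, ek, vr, V0)
        k2v, k2m, k2h = _vmh_rhs(vv + 0.5 * dt * k1v, mm + 0.5 * dt * k1m,
                                 hh + 0.5 * dt * k1h, nn, Ib, cm, gna, gk, gm,
                                 ena, ek, vr, V0)
        k3v, k3m, k3h = _vmh_rhs(vv + 0.5 * dt * k2v, mm + 0.5 * dt * k2m,
                                 hh + 0.5 * dt * k2h, nn, Ib, cm, gna, gk, gm,
                                 ena, ek, vr, V0)
        k4v, k4m, k4h = _vmh_rhs(vv + dt * k3v, mm + dt * k3m, hh + dt * k3h,
                                 nn, Ic, cm, gna, gk, gm, ena, ek, vr, V0)
        v[N + 1] = vv + dt / 6.0 * (k1v + 2.0 * k2v + 2.0 * k3v + k4v)
        m[N + 1] = mm + dt / 6.0 * (k1m + 2.0 * k2m + 2.0 * k3m + k4m)
        h[N + 1] = hh + dt / 6.0 * (k1h + 2.0 * k2h + 2.0 * k3h + k4h)
        # L1 update of n from the start-of-step voltage
        u = vv - V0
        an = _alpha_n(u)
        bn = _beta_n(u)
        ninf = an / (an + bn)
        taun = 1.0 / (an + bn)
        s = 0.0
        if not memoryless:
            K = min(N, W)
            if K > 0:
                s = np.dot(d_rev[W - K:W], dn[N - K:N])
        ngate[N + 1] = nn + dt_eta_g * (ninf - nn) / taun - s
        # gates must stay in [0, 1]; record and clip small excursions
        for arrval in (m[N + 1], h[N + 1], ngate[N + 1]):
            if arrval < 0.0 and -arrval > viol:
                viol = -arrval
            if arrval > 1.0 and arrval - 1.0 > viol:
                viol = arrval - 1.0
        if m[N + 1] < 0.0:
            m[N + 1] = 0.0
        elif m[N + 1] > 1.0:
            m[N + 1] = 1.0
        if h[N + 1] < 0.0:
            h[N + 1] = 0.0
        elif h[N + 1] > 1.0:
            h[N + 1] = 1.0
        if ngate[N + 1] < 0.0:
            ngate[N + 1] = 0.0
        elif ngate[N + 1] > 1.0:
            ngate[N + 1] = 1.0
        dn[N] = ngate[N + 1] - ngate[N]
    return v, m, h, ngate, viol
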