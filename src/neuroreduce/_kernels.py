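"""Numba-compiled inner loops for batched single-neuron simulation.

Each kernel advances a batch of independent neurons with the Euler-Maruyama
scheme at constant per-neuron inputs, accumulating the temporal average of
the residual observable r over the averaging horizon, per-segment sums for
batch-means standard errors, and a subsampled r trace for period detection.
The voltage mean is accumulated alongside.

Kernels return ``blow_step`` >= 0 if a non-finite voltage was detected (the
caller raises); -1 otherwise.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["mckean_run", "fhn_run", "hh_run"]

_SIG_COMMON = """
X (B, dim) in-place; I (B,); g (dim,) noise amplitudes; seed for the
kernel-local RNG (used only if any amplitude is positive).
"""


@njit(cache=True)
def mckean_run(X, I, dt, n_tr, n_av, g, seed, stride, nb, n_trace,
               v_lo, v_hi, m, s_out, b, c, eps):
    B = X.shape[0]
    sqdt = np.sqrt(dt)
    noisy = g[0] > 0.0 or g[1] > 0.0
    if noisy:
        np.random.seed(seed)
    r_sum = np.zeros(B)
    v_sum = np.zeros(B)
    batch_sums = np.zeros((nb, B))
    traces = np.zeros((B, n_trace))
    batch_len = max(1, n_av // nb)
    ti = 0
    blow = -1
    for k in range(n_tr + n_av):
        averaging = k >= n_tr
        ka = k - n_tr
        for i in range(B):
            v = X[i, 0]
            w = X[i, 1]
            if v < v_lo:
                fv = m * v_lo + s_out * (v - v_lo)
            elif v > v_hi:
                fv = m * v_hi + s_out * (v - v_hi)
            else:
                fv = m * v
            dv = (fv - w) / eps + I[i]
            dw = c * (v - b * w)
            v_new = v + dt * dv
            w_new = w + dt * dw
            if noisy:
                if g[0] > 0.0:
                    v_new += sqdt * g[0] * np.random.normal()
                if g[1] > 0.0:
                    w_new += sqdt * g[1] * np.random.normal()
            X[i, 0] = v_new
            X[i, 1] = w_new
            if averaging:
                r = (fv - s_out * v) / eps
                r_sum[i] += r
                v_sum[i] += v
                bi = ka // batch_len
                if bi >= nb:
                    bi = nb - 1
                batch_sums[bi, i] += r
                if ka % stride == 0 and ti < n_trace:
                    traces[i, ti] = r
        if averaging and ka % stride == 0 and ti < n_trace:
            ti += 1
        if (k + 1) % 512 == 0:
            for i in range(B):
                if not np.isfinite(X[i, 0]):
                    blow = k
                    break
            if blow >= 0:
                break
    return r_sum, v_sum, batch_sums, traces, ti, blow


@njit(cache=True)
def fhn_run(X, I, dt, n_tr, n_av, g, seed, stride, nb, n_trace,
            c1, c3, a, b, tau_w, kred):
    B = X.shape[0]
    sqdt = np.sqrt(dt)
    noisy = g[0] > 0.0 or g[1] > 0.0
    if noisy:
        np.random.seed(seed)
    r_sum = np.zeros(B)
    v_sum = np.zeros(B)
    batch_sums = np.zeros((nb, B))
    traces = np.zeros((B, n_trace))
    batch_len = max(1, n_av // nb)
    ti = 0
    blow = -1
    for k in range(n_tr + n_av):
        averaging = k >= n_tr
        ka = k - n_tr
        for i in range(B):
            v = X[i, 0]
            w = X[i, 1]
            fv = c1 * v - c3 * v * v * v
            v_new = v + dt * (fv - w + I[i])
            w_new = w + dt * (v + a - b * w) / tau_w
            if noisy:
                if g[0] > 0.0:
                    v_new += sqdt * g[0] * np.random.normal()
                if g[1] > 0.0:
                    w_new += sqdt * g[1] * np.random.normal()
            X[i, 0] = v_new
            X[i, 1] = w_new
            if averaging:
                r = fv + kred * v
                r_sum[i] += r
                v_sum[i] += v
                bi = ka // batch_len
                if bi >= nb:
                    bi = nb - 1
                batch_sums[bi, i] += r
                if ka % stride == 0 and ti < n_trace:
                    traces[i, ti] = r
        if averaging and ka % stride == 0 and ti < n_trace:
            ti += 1
        if (k + 1) % 512 == 0:
            for i in range(B):
                if not np.isfinite(X[i, 0]):
                    blow = k
                    break
            if blow >= 0:
                break
    return r_sum, v_sum, batch_sums, traces, ti, blow


@njit(cache=True)
def _vtrap(x):
    if abs(x) < 1e-9:
        return 1.0
    return x / np.expm1(x)


@njit(cache=True)
def hh_run(X, I, dt, n_tr, n_av, g, seed, stride, nb, n_trace,
           C, gNa, gK, gL, ENa, EK, EL):
    B = X.shape[0]
    sqdt = np.sqrt(dt)
    noisy = False
    for d in range(4):
        if g[d] > 0.0:
            noisy = True
    if noisy:
        np.random.seed(seed)
    r_sum = np.zeros(B)
    v_sum = np.zeros(B)
    batch_sums = np.zeros((nb, B))
    traces = np.zeros((B, n_trace))
    batch_len = max(1, n_av // nb)
    ti = 0
    blow = -1
    for k in range(n_tr + n_av):
        averaging = k >= n_tr
        ka = k - n_tr
        for i in range(B):
            V = X[i, 0]
            m = X[i, 1]
            h = X[i, 2]
            n = X[i, 3]
            am = _vtrap((25.0 - V) / 10.0)
            bm = 4.0 * np.exp(-V / 18.0)
            ah = 0.07 * np.exp(-V / 20.0)
            bh = 1.0 / (np.exp((30.0 - V) / 10.0) + 1.0)
            an = 0.1 * _vtrap((10.0 - V) / 10.0)
            bn = 0.125 * np.exp(-V / 80.0)
            ina = gNa * m * m * m * h * (V - ENa)
            ik = gK * n * n * n * n * (V - EK)
            il = gL * (V - EL)
            V_new = V + dt * (I[i] - ina - ik - il) / C
            m_new = m + dt * (am * (1.0 - m) - bm * m)
            h_new = h + dt * (ah * (1.0 - h) - bh * h)
            n_new = n + dt * (an * (1.0 - n) - bn * n)
            if noisy:
                if g[0] > 0.0:
                    V_new += sqdt * g[0] * np.random.normal()
                if g[1] > 0.0:
                    m_new += sqdt * g[1] * np.random.normal()
                if g[2] > 0.0:
                    h_new += sqdt * g[2] * np.random.normal()
                if g[3] > 0.0:
                    n_new += sqdt * g[3] * np.random.normal()
            # gating variables stay in the physical range [0, 1]
            if m_new < 0.0:
                m_new = 0.0
            elif m_new > 1.0:
                m_new = 1.0
            if h_new < 0.0:
                h_new = 0.0
            elif h_new > 1.0:
                h_new = 1.0
            if n_new < 0.0:
                n_new = 0.0
            elif n_new > 1.0:
                n_new = 1.0
            X[i, 0] = V_new
            X[i, 1] = m_new
            X[i, 2] = h_new
            X[i, 3] = n_new
            if averaging:
                r = (-ina - ik + gL * EL) / C
                r_sum[i] += r
                v_sum[i] += V
                bi = ka // batch_len
                if bi >= nb:
                    bi = nb - 1
                batch_sums[bi, i] += r
                if ka % stride == 0 and ti < n_trace:
                    traces[i, ti] = r
        if averaging and ka % stride == 0 and ti < n_trace:
            ti += 1
        if (k + 1) % 512 == 0:
            for i in range(B):
                if not np.isfinite(X[i, 0]):
                    blow = k
                    break
            if blow >= 0:
                break
    return r_sum, v_sum, batch_sums, traces, ti, blow
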