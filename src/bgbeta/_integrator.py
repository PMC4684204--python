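"""Fixed-step method-of-steps integrator kernels (numba-compiled).

The delay system is advanced with classical RK4.  Delayed state lookups use
cubic Hermite interpolation of the stored solution (values + derivatives on
the step grid), so delays need not be commensurate with the step.  The only
structural requirement is ``step <= min(delay)``: then every stage time
``t + c*h`` looks back to ``t + c*h - T <= t``, which is already stored.

Grid layout: row ``i`` of the storage arrays holds the state at time
``(i - n_hist) * h``; rows ``0 .. n_hist`` contain the history segment
covering ``[-n_hist*h, 0]``.

Parameter-vector layout (see :meth:`bgbeta.params.ModelParameters.pack`)::

    0-5   w_SG w_GS w_CS w_SC w_GG w_CC
    6-11  T_SG T_GS T_GG T_CS T_SC T_CC
    12-15 tau_S tau_G tau_E tau_I
    16-17 C Str
    18-25 M_S B_S M_G B_G M_E B_E M_I B_I
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True)
def _sigmoid(x, M, B):
    # bounded (0, M), F(0) = B, max slope 1; exp overflow saturates to 0
    return M / (1.0 + ((M - B) / B) * math.exp(-4.0 * x / M))


@njit(cache=True)
def _hermite(tq, h, n_hist, last, Y, F, col):
    pos = tq / h + n_hist
    if pos < 0.0:
        pos = 0.0
    if pos >= last:
        return Y[last, col]
    k = int(math.floor(pos))
    th = pos - k
    h00 = (1.0 + 2.0 * th) * (1.0 - th) * (1.0 - th)
    h10 = th * (1.0 - th) * (1.0 - th)
    h01 = th * th * (3.0 - 2.0 * th)
    h11 = th * th * (th - 1.0)
    return (
        h00 * Y[k, col]
        + h10 * h * F[k, col]
        + h01 * Y[k + 1, col]
        + h11 * h * F[k + 1, col]
    )


@njit(cache=True)
def _network_rhs(t, y, p, h, n_hist, last, Y, F, linear, extra_stn, out):
    S_sg = _hermite(t - p[6], h, n_hist, last, Y, F, 0)   # S(t - T_SG)
    G_gs = _hermite(t - p[7], h, n_hist, last, Y, F, 1)   # G(t - T_GS)
    G_gg = _hermite(t - p[8], h, n_hist, last, Y, F, 1)   # G(t - T_GG)
    E_cs = _hermite(t - p[9], h, n_hist, last, Y, F, 2)   # E(t - T_CS)
    S_sc = _hermite(t - p[10], h, n_hist, last, Y, F, 0)  # S(t - T_SC)
    E_cc = _hermite(t - p[11], h, n_hist, last, Y, F, 2)  # E(t - T_CC)
    I_cc = _hermite(t - p[11], h, n_hist, last, Y, F, 3)  # I(t - T_CC)

    x_S = p[2] * E_cs - p[1] * G_gs + extra_stn
    x_G = p[0] * S_sg - p[4] * G_gg - p[17]
    x_E = -p[3] * S_sc - p[5] * I_cc + p[16]
    x_I = p[5] * E_cc

    if linear:
        f_S, f_G, f_E, f_I = x_S, x_G, x_E, x_I
    else:
        f_S = _sigmoid(x_S, p[18], p[19])
        f_G = _sigmoid(x_G, p[20], p[21])
        f_E = _sigmoid(x_E, p[22], p[23])
        f_I = _sigmoid(x_I, p[24], p[25])

    out[0] = (f_S - y[0]) / p[12]
    out[1] = (f_G - y[1]) / p[13]
    out[2] = (f_E - y[2]) / p[14]
    out[3] = (f_I - y[3]) / p[15]


@njit(cache=True)
def integrate_network(p, h, n_steps, n_hist, Y, F, linear, extra_stn, blow):
    """Advance the four-population model ``n_steps`` RK4 steps of size ``h``.

    ``Y``/``F`` must be pre-allocated ``(n_hist + n_steps + 1, 4)`` arrays
    whose first ``n_hist + 1`` rows hold the history values/derivatives.
    Returns the number of completed steps (< n_steps if the state left the
    ``|y| <= blow`` box or became non-finite, which only linear runs do).
    """
    k1 = np.empty(4)
    k2 = np.empty(4)
    k3 = np.empty(4)
    k4 = np.empty(4)
    yt = np.empty(4)
    for n in range(n_steps):
        cur = n_hist + n
        t = n * h
        y = Y[cur]
        _network_rhs(t, y, p, h, n_hist, cur, Y, F, linear, extra_stn, k1)
        for j in range(4):
            F[cur, j] = k1[j]
            yt[j] = y[j] + 0.5 * h * k1[j]
        _network_rhs(t + 0.5 * h, yt, p, h, n_hist, cur, Y, F, linear,
                     extra_stn, k2)
        for j in range(4):
            yt[j] = y[j] + 0.5 * h * k2[j]
        _network_rhs(t + 0.5 * h, yt, p, h, n_hist, cur, Y, F, linear,
                     extra_stn, k3)
        for j in range(4):
            yt[j] = y[j] + h * k3[j]
        _network_rhs(t + h, yt, p, h, n_hist, cur, Y, F, linear,
                     extra_stn, k4)
        ok = True
        for j in range(4):
            ynew = y[j] + h / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
            Y[cur + 1, j] = ynew
            if not math.isfinite(ynew) or abs(ynew) > blow:
                ok = False
        if not ok:
            return n + 1
    last = n_hist + n_steps
    _network_rhs(n_steps * h, Y[last], p, h, n_hist, last, Y, F, linear,
                 extra_stn, k1)
    for j in range(4):
        F[last, j] = k1[j]
    return n_steps


@njit(cache=True)
def _reduced_rhs(t, y, w_GS, w_SG, w_SS, T, h, n_hist, last, Y, F, out):
    s_d = _hermite(t - T, h, n_hist, last, Y, F, 0)
    out[0] = -w_GS * y[1] - w_SS * s_d - y[0]
    out[1] = w_SG * y[0] - y[1]


@njit(cache=True)
def integrate_reduced(w_GS, w_SG, w_SS, T, h, n_steps, n_hist, Y, F, blow):
    """Two-variable delayed STN-GPe oscillator in dimensionless time:
    ``s' = -w_GS g - w_SS s(t - T) - s``, ``g' = w_SG s - g``."""
    k1 = np.empty(2)
    k2 = np.empty(2)
    k3 = np.empty(2)
    k4 = np.empty(2)
    yt = np.empty(2)
    for n in range(n_steps):
        cur = n_hist + n
        t = n * h
        y = Y[cur]
        _reduced_rhs(t, y, w_GS, w_SG, w_SS, T, h, n_hist, cur, Y, F, k1)
        for j in range(2):
            F[cur, j] = k1[j]
            yt[j] = y[j] + 0.5 * h * k1[j]
        _reduced_rhs(t + 0.5 * h, yt, w_GS, w_SG, w_SS, T, h, n_hist, cur,
                     Y, F, k2)
        for j in range(2):
            yt[j] = y[j] + 0.5 * h * k2[j]
        _reduced_rhs(t + 0.5 * h, yt, w_GS, w_SG, w_SS, T, h, n_hist, cur,
                     Y, F, k3)
        for j in range(2):
            yt[j] = y[j] + h * k3[j]
        _reduced_rhs(t + h, yt, w_GS, w_SG, w_SS, T, h, n_hist, cur,
                     Y, F, k4)
        ok = True
        for j in range(2):
            ynew = y[j] + h / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
            Y[cur + 1, j] = ynew
            if not math.isfinite(ynew) or abs(ynew) > blow:
                ok = False
        if not ok:
            return n + 1
    last = n_hist + n_steps
    _reduced_rhs(n_steps * h, Y[last], w_GS, w_SG, w_SS, T, h, n_hist, last,
                 Y, F, k1)
    for j in range(2):
        F[last, j] = k1[j]
    return n_steps
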