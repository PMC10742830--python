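"""Numba-compiled inner loops for the clamped-network simulation.

The clamping protocol integrates every oscillator in the network for tens of
thousands of RK steps per data sample; these kernels carry that inner loop.
They implement exactly the same vector fields as :mod:`criticality.rcc_models`
and the same update cadences as the pure-Python reference path built on
:mod:`criticality.ode_engine` (which the test suite cross-checks against
them), with weight learning, dynamic input normalisation and state recording
applied once per recorded point.

Status convention: window kernels return -1 on success, or the index of the
control iteration at which the trajectory left the finite/bounded domain.
"""

import math

import numpy as np
from numba import njit

#: integrator flags
RK4 = 0
FEHLBERG = 1

_BLOWUP = 1e12
_NEG_LIMIT = -1e3  # Berry concentrations below this count as divergence


@njit(cache=True)
def _berry_rates(state, W, ext, out,
                 gamma, beta, KRn, KSl, KG, Kdeg, kg, kdeg, ka, hl, hn,
                 mu_f, f_p, f_g, xi_p, xi_g,
                 ro7, ro8, w7, w8, phi7, phi8, per_unit):
    n = state.shape[0]
    F = 0.0
    M = 0.0
    if ro7 >= 0:
        for k in range(n):
            if k != ro7 and k != ro8:
                M += state[k, 0]
                F += state[k, 1]
    for i in range(n):
        m = state[i, 0]
        f = state[i, 1]
        p = state[i, 2]
        g = state[i, 3]
        fq = f if f > 0.0 else 0.0
        qf = fq / (fq + mu_f)
        sp = f_p * math.exp(xi_p * qf)
        sg = f_g * math.exp(xi_g * qf)
        if i == ro7:
            s = 0.0
            if per_unit:
                for k in range(n):
                    if k != ro7 and k != ro8:
                        s += w7[k] * state[k, 1]
            else:
                for k in range(n):
                    s += w7[k]
                s *= F
            rim = phi7 * (s + state[ro8, 0])
        elif i == ro8:
            s = 0.0
            if per_unit:
                for k in range(n):
                    if k != ro7 and k != ro8:
                        s += w8[k] * state[k, 0]
            else:
                for k in range(n):
                    s += w8[k]
                s *= M
            rim = phi8 * (s + state[ro7, 0])
        else:
            s = 0.0
            for k in range(n):
                if k != i:
                    s += W[k, i] * state[k, 0]
            rim = s + ext[i]
        ex = kg * f * g / (KG + f)
        tr = m * p / (1.0 + m)
        fn = f ** hn
        fl = f ** hl
        out[i, 0] = ex - tr + rim
        out[i, 1] = -ex + tr - f * p / (1.0 + f)
        out[i, 2] = sp * gamma * fn / (KRn + fn) - ka * p * p
        out[i, 3] = sg * beta * fl / (KSl + fl) - kdeg * g * p / (Kdeg + g)


@njit(cache=True)
def _wu_rates(state, wvec, eps, out,
              a, b, c, d, e, f_param, kk,
              mu_x, mu_y, mu_z, mu_w, xi_x, xi_y, xi_z, xi_w,
              omega, rho_gain):
    n = state.shape[0]
    Dx = 0.0
    Dy = 0.0
    Dz = 0.0
    Dw = 0.0
    for k in range(n):
        Dx += wvec[k] * state[k, 0]
        Dy += wvec[k] * state[k, 1]
        Dz += wvec[k] * state[k, 2]
        Dw += wvec[k] * state[k, 3]
    for i in range(n):
        x = state[i, 0]
        y = state[i, 1]
        z = state[i, 2]
        w = state[i, 3]
        xq = x if x > 0.0 else 0.0
        yq = y if y > 0.0 else 0.0
        zq = z if z > 0.0 else 0.0
        qx = xq / (xq + mu_x)
        qy = yq / (yq + mu_y)
        qz = zq / (zq + mu_z)
        sx = math.exp(xi_x * qx * qz)
        sy = math.exp(xi_y * qx * qz)
        sz = math.exp(xi_z * qx * qy)
        sw = math.exp(xi_w * qy * qz) + omega
        rho = rho_gain * eps[i]
        out[i, 0] = a * (y - x) + e * sx * y * z + kk * w + Dx
        out[i, 1] = c * x - d * y - sy * x * z + Dy
        out[i, 2] = sz * x * y - b * z + Dz
        out[i, 3] = rho * y + f_param * sw * y * z + Dw


# Runge-Kutta-Fehlberg 4(5) coefficients (5th-order solution).
_A21 = 1.0 / 4.0
_A31 = 3.0 / 32.0
_A32 = 9.0 / 32.0
_A41 = 1932.0 / 2197.0
_A42 = -7200.0 / 2197.0
_A43 = 7296.0 / 2197.0
_A51 = 439.0 / 216.0
_A52 = -8.0
_A53 = 3680.0 / 513.0
_A54 = -845.0 / 4104.0
_A61 = -8.0 / 27.0
_A62 = 2.0
_A63 = -3544.0 / 2565.0
_A64 = 1859.0 / 4104.0
_A65 = -11.0 / 40.0
_B1 = 16.0 / 135.0
_B3 = 6656.0 / 12825.0
_B4 = 28561.0 / 56430.0
_B5 = -9.0 / 50.0
_B6 = 2.0 / 55.0


@njit(cache=True)
def berry_window(state, W, eps_raw, has_input, rim_base, h,
                 n_control, stride, integrator,
                 gamma, beta, KRn, KSl, KG, Kdeg, kg, kdeg, ka, hl, hn,
                 mu_f, f_p, f_g, xi_p, xi_g,
                 learn, alpha, theta,
                 ro7, ro8, w7, w8, phi7, phi8, per_unit, ro_alpha, ro_theta,
                 dyn, mu_eps, f_eps, th_eps,
                 rec):
    """Integrate one clamp window of a Berry network.

    ``eps_raw`` holds the (statically scaled) sample value routed to each
    oscillator (zero where none); weight learning and dynamic normalisation
    are re-evaluated once per control iteration, i.e. every ``stride``
    micro-steps; the state after each control iteration is written to
    ``rec`` (shape ``(n_control, n, 4)``).  Returns -1 or the failing
    iteration index.
    """
    n = state.shape[0]
    ext = np.empty(n)
    q = np.empty(n)
    k1 = np.empty((n, 4))
    k2 = np.empty((n, 4))
    k3 = np.empty((n, 4))
    k4 = np.empty((n, 4))
    k5 = np.empty((n, 4))
    k6 = np.empty((n, 4))
    yt = np.empty((n, 4))

    for c in range(n_control):
        # filament quotients of the current state
        for i in range(n):
            fi = state[i, 1]
            if fi < 0.0:
                fi = 0.0
            q[i] = fi / (fi + mu_f)
        if learn:
            for i in range(n):
                if i == ro7 or i == ro8:
                    continue
                for j in range(n):
                    if j == i or j == ro7 or j == ro8:
                        continue
                    dq = q[j] - q[i]
                    sgn = 1.0 if dq > 0.0 else (-1.0 if dq < 0.0 else 0.0)
                    W[i, j] = theta * math.exp(alpha * (q[i] * q[j])) * sgn
        if ro7 >= 0:
            q7 = q[ro7]
            q8 = q[ro8]
            for k in range(n):
                if k == ro7 or k == ro8:
                    w7[k] = 0.0
                    w8[k] = 0.0
                    continue
                dq = q7 - q[k]
                sgn = 1.0 if dq > 0.0 else (-1.0 if dq < 0.0 else 0.0)
                w7[k] = ro_theta * math.exp(ro_alpha * (q[k] * q7)) * sgn
                dq = q8 - q[k]
                sgn = 1.0 if dq > 0.0 else (-1.0 if dq < 0.0 else 0.0)
                w8[k] = ro_theta * math.exp(ro_alpha * (q[k] * q8)) * sgn
        for i in range(n):
            if has_input[i]:
                eps = eps_raw[i]
                if dyn:
                    qe = eps / (eps + mu_eps[i])
                    ext[i] = rim_base + f_eps[i] * math.exp(th_eps[i] * qe * q[i]) * eps
                else:
                    ext[i] = rim_base + eps
            else:
                ext[i] = rim_base

        for _ in range(stride):
            if integrator == RK4:
                _berry_rates(state, W, ext, k1, gamma, beta, KRn, KSl, KG,
                             Kdeg, kg, kdeg, ka, hl, hn, mu_f, f_p, f_g,
                             xi_p, xi_g, ro7, ro8, w7, w8, phi7, phi8, per_unit)
                for i in range(n):
                    for j in range(4):
                        yt[i, j] = state[i, j] + 0.5 * h * k1[i, j]
                _berry_rates(yt, W, ext, k2, gamma, beta, KRn, KSl, KG,
                             Kdeg, kg, kdeg, ka, hl, hn, mu_f, f_p, f_g,
                             xi_p, xi_g, ro7, ro8, w7, w8, phi7, phi8, per_unit)
                for i in range(n):
                    for j in range(4):
                        yt[i, j] = state[i, j] + 0.5 * h * k2[i, j]
                _berry_rates(yt, W, ext, k3, gamma, beta, KRn, KSl, KG,
                             Kdeg, kg, kdeg, ka, hl, hn, mu_f, f_p, f_g,
                             xi_p, xi_g, ro7, ro8, w7, w8, phi7, phi8, per_unit)
                for i in range(n):
                    for j in range(4):
                        yt[i, j] = state[i, j] + h * k3[i, j]
                _berry_rates(yt, W, ext, k4, gamma, beta, KRn, KSl, KG,
                             Kdeg, kg, kdeg, ka, hl, hn, mu_f, f_p, f_g,
                             xi_p, xi_g, ro7, ro8, w7, w8, phi7, phi8, per_unit)
                for i in range(n):
                    for j in range(4):
                        state[i, j] += (h / 6.0) * (k1[i, j] + 2.0 * k2[i, j]
                                                    + 2.0 * k3[i, j] + k4[i, j])
            else:
                _berry_rates(state, W, ext, k1, gamma, beta, KRn, KSl, KG,
                             Kdeg, kg, kdeg, ka, hl, hn, mu_f, f_p, f_g,
                             xi_p, xi_g, ro7, ro8, w7, w8, phi7, phi8, per_unit)
                for i in range(n):
                    for j in range(4):
                        yt[i, j] = state[i, j] + h * _A21 * k1[i, j]
                _berry_rates(yt, W, ext, k2, gamma, beta, KRn, KSl, KG,
                             Kdeg, kg, kdeg, ka, hl, hn, mu_f, f_p, f_g,
                             xi_p, xi_g, ro7, ro8, w7, w8, phi7, phi8, per_unit)
                for i in range(n):
                    for j in range(4):
                        yt[i, j] = state[i, j] + h * (_A31 * k1[i, j] + _A32 * k2[i, j])
                _berry_rates(yt, W, ext, k3, gamma, beta, KRn, KSl, KG,
                             Kdeg, kg, kdeg, ka, hl, hn, mu_f, f_p, f_g,
                             xi_p, xi_g, ro7, ro8, w7, w8, phi7, phi8, per_unit)
                for i in range(n):
                    for j in range(4):
                        yt[i, j] = state[i, j] + h * (_A41 * k1[i, j]
                                                      + _A42 * k2[i, j]
                                                      + _A43 * k3[i, j])
                _berry_rates(yt, W, ext, k4, gamma, beta, KRn, KSl, KG,
                             Kdeg, kg, kdeg, ka, hl, hn, mu_f, f_p, f_g,
                             xi_p, xi_g, ro7, ro8, w7, w8, phi7, phi8, per_unit)
                for i in range(n):
                    for j in range(4):
                        yt[i, j] = state[i, j] + h * (_A51 * k1[i, j]
                                                      + _A52 * k2[i, j]
                                                      + _A53 * k3[i, j]
                                                      + _A54 * k4[i, j])
                _berry_rates(yt, W, ext, k5, gamma, beta, KRn, KSl, KG,
                             Kdeg, kg, kdeg, ka, hl, hn, mu_f, f_p, f_g,
                             xi_p, xi_g, ro7, ro8, w7, w8, phi7, phi8, per_unit)
                for i in range(n):
                    for j in range(4):
                        yt[i, j] = state[i, j] + h * (_A61 * k1[i, j]
                                                      + _A62 * k2[i, j]
                                                      + _A63 * k3[i, j]
                                                      + _A64 * k4[i, j]
                                                      + _A65 * k5[i, j])
                _berry_rates(yt, W, ext, k6, gamma, beta, KRn, KSl, KG,
                             Kdeg, kg, kdeg, ka, hl, hn, mu_f, f_p, f_g,
                             xi_p, xi_g, ro7, ro8, w7, w8, phi7, phi8, per_unit)
                for i in range(n):
                    for j in range(4):
                        state[i, j] += h * (_B1 * k1[i, j] + _B3 * k3[i, j]
                                            + _B4 * k4[i, j] + _B5 * k5[i, j]
                                            + _B6 * k6[i, j])

        for i in range(n):
            for j in range(4):
                v = state[i, j]
                if not math.isfinite(v) or abs(v) > _BLOWUP or v < _NEG_LIMIT:
                    return c
        for i in range(n):
            for j in range(4):
                rec[c, i, j] = state[i, j]
    return -1


@njit(cache=True)
def wu_window(state, wvec, eps_raw, h, n_control, stride, integrator,
              a, b, c, d, e, f_param, kk,
              mu_x, mu_y, mu_z, mu_w, xi_x, xi_y, xi_z, xi_w,
              omega, rho_gain, rec):
    """Integrate one clamp window of a Wu network (no learning, no
    normalisation; diffusive coupling by a shared weight vector).  Returns -1
    or the failing control-iteration index."""
    n = state.shape[0]
    k1 = np.empty((n, 4))
    k2 = np.empty((n, 4))
    k3 = np.empty((n, 4))
    k4 = np.empty((n, 4))
    k5 = np.empty((n, 4))
    k6 = np.empty((n, 4))
    yt = np.empty((n, 4))
    for ci in range(n_control):
        for _ in range(stride):
            if integrator == RK4:
                _wu_rates(state, wvec, eps_raw, k1, a, b, c, d, e, f_param,
                          kk, mu_x, mu_y, mu_z, mu_w, xi_x, xi_y, xi_z, xi_w,
                          omega, rho_gain)
                for i in range(n):
                    for j in range(4):
                        yt[i, j] = state[i, j] + 0.5 * h * k1[i, j]
                _wu_rates(yt, wvec, eps_raw, k2, a, b, c, d, e, f_param,
                          kk, mu_x, mu_y, mu_z, mu_w, xi_x, xi_y, xi_z, xi_w,
                          omega, rho_gain)
                for i in range(n):
                    for j in range(4):
                        yt[i, j] = state[i, j] + 0.5 * h * k2[i, j]
                _wu_rates(yt, wvec, eps_raw, k3, a, b, c, d, e, f_param,
                          kk, mu_x, mu_y, mu_z, mu_w, xi_x, xi_y, xi_z, xi_w,
                          omega, rho_gain)
                for i in range(n):
                    for j in range(4):
                        yt[i, j] = state[i, j] + h * k3[i, j]
                _wu_rates(yt, wvec, eps_raw, k4, a, b, c, d, e, f_param,
                          kk, mu_x, mu_y, mu_z, mu_w, xi_x, xi_y, xi_z, xi_w,
                          omega, rho_gain)
                for i in range(n):
                    for j in range(4):
                        state[i, j] += (h / 6.0) * (k1[i, j] + 2.0 * k2[i, j]
                                                    + 2.0 * k3[i, j] + k4[i, j])
            else:
                _wu_rates(state, wvec, eps_raw, k1, a, b, c, d, e, f_param,
                          kk, mu_x, mu_y, mu_z, mu_w, xi_x, xi_y, xi_z, xi_w,
                          omega, rho_gain)
                for i in range(n):
                    for j in range(4):
                        yt[i, j] = state[i, j] + h * _A21 * k1[i, j]
                _wu_rates(yt, wvec, eps_raw, k2, a, b, c, d, e, f_param,
                          kk, mu_x, mu_y, mu_z, mu_w, xi_x, xi_y, xi_z, xi_w,
                          omega, rho_gain)
                for i in range(n):
                    for j in range(4):
                        yt[i, j] = state[i, j] + h * (_A31 * k1[i, j] + _A32 * k2[i, j])
                _wu_rates(yt, wvec, eps_raw, k3, a, b, c, d, e, f_param,
                          kk, mu_x, mu_y, mu_z, mu_w, xi_x, xi_y, xi_z, xi_w,
                          omega, rho_gain)
                for i in range(n):
                    for j in range(4):
                        yt[i, j] = state[i, j] + h * (_A41 * k1[i, j]
                                                      + _A42 * k2[i, j]
                                                      + _A43 * k3[i, j])
                _wu_rates(yt, wvec, eps_raw, k4, a, b, c, d, e, f_param,
                          kk, mu_x, mu_y, mu_z, mu_w, xi_x, xi_y, xi_z, xi_w,
                          omega, rho_gain)
                for i in range(n):
                    for j in range(4):
                        yt[i, j] = state[i, j] + h * (_A51 * k1[i, j]
                                                      + _A52 * k2[i, j]
                                                      + _A53 * k3[i, j]
                                                      + _A54 * k4[i, j])
                _wu_rates(yt, wvec, eps_raw, k5, a, b, c, d, e, f_param,
                          kk, mu_x, mu_y, mu_z, mu_w, xi_x, xi_y, xi_z, xi_w,
                          omega, rho_gain)
                for i in range(n):
                    for j in range(4):
                        yt[i, j] = state[i, j] + h * (_A61 * k1[i, j]
                                                      + _A62 * k2[i, j]
                                                      + _A63 * k3[i, j]
                                                      + _A64 * k4[i, j]
                                                      + _A65 * k5[i, j])
                _wu_rates(yt, wvec, eps_raw, k6, a, b, c, d, e, f_param,
                          kk, mu_x, mu_y, mu_z, mu_w, xi_x, xi_y, xi_z, xi_w,
                          omega, rho_gain)
                for i in range(n):
                    for j in range(4):
                        state[i, j] += h * (_B1 * k1[i, j] + _B3 * k3[i, j]
                                            + _B4 * k4[i, j] + _B5 * k5[i, j]
                                            + _B6 * k6[i, j])
        for i in range(n):
            for j in range(4):
                v = state[i, j]
                if not math.isfinite(v) or abs(v) > _BLOWUP:
                    return ci
        for i in range(n):
            for j in range(4):
                rec[ci, i, j] = state[i, j]
    return -1


@njit(cache=True)
def berry_lyapunov(rim, h, n_steps, discard, renorm, d0,
                   gamma, beta, KRn, KSl, KG, Kdeg, kg, kdeg, ka, hl, hn,
                   mu_f, f_p, f_g, xi_p, xi_g):
    """Benettin two-trajectory estimate of the largest Lyapunov exponent of a
    single Berry oscillator at constant drive ``rim``.

    The reference trajectory starts at (1, 1, 1, 1), runs ``discard``
    settling steps, is then shadowed by a companion displaced by ``d0`` along
    m, renormalised back to distance ``d0`` every ``renorm`` steps; the
    exponent is the mean log stretch per unit time.
    """
    W = np.zeros((1, 1))
    ext = np.empty(1)
    ext[0] = rim
    dummy = np.zeros(1)
    y = np.ones((1, 4))
    k1 = np.empty((1, 4))
    k2 = np.empty((1, 4))
    k3 = np.empty((1, 4))
    k4 = np.empty((1, 4))
    yt = np.empty((1, 4))

    def _step(state):
        _berry_rates(state, W, ext, k1, gamma, beta, KRn, KSl, KG, Kdeg,
                     kg, kdeg, ka, hl, hn, mu_f, f_p, f_g, xi_p, xi_g,
                     -1, -1, dummy, dummy, 0.0, 0.0, False)
        for j in range(4):
            yt[0, j] = state[0, j] + 0.5 * h * k1[0, j]
        _berry_rates(yt, W, ext, k2, gamma, beta, KRn, KSl, KG, Kdeg,
                     kg, kdeg, ka, hl, hn, mu_f, f_p, f_g, xi_p, xi_g,
                     -1, -1, dummy, dummy, 0.0, 0.0, False)
        for j in range(4):
            yt[0, j] = state[0, j] + 0.5 * h * k2[0, j]
        _berry_rates(yt, W, ext, k3, gamma, beta, KRn, KSl, KG, Kdeg,
                     kg, kdeg, ka, hl, hn, mu_f, f_p, f_g, xi_p, xi_g,
                     -1, -1, dummy, dummy, 0.0, 0.0, False)
        for j in range(4):
            yt[0, j] = state[0, j] + h * k3[0, j]
        _berry_rates(yt, W, ext, k4, gamma, beta, KRn, KSl, KG, Kdeg,
                     kg, kdeg, ka, hl, hn, mu_f, f_p, f_g, xi_p, xi_g,
                     -1, -1, dummy, dummy, 0.0, 0.0, False)
        for j in range(4):
            state[0, j] += (h / 6.0) * (k1[0, j] + 2.0 * k2[0, j]
                                        + 2.0 * k3[0, j] + k4[0, j])

    for _ in range(discard):
        _step(y)
    y2 = y.copy()
    y2[0, 0] += d0
    acc = 0.0
    cnt = 0
    for _ in range(n_steps // renorm):
        for _ in range(renorm):
            _step(y)
            _step(y2)
        dist = 0.0
        for j in range(4):
            dist += (y2[0, j] - y[0, j]) ** 2
        dist = math.sqrt(dist)
        if dist > 0.0:
            acc += math.log(dist / d0)
            cnt += renorm
            for j in range(4):
                y2[0, j] = y[0, j] + (y2[0, j] - y[0, j]) * (d0 / dist)
    if cnt == 0:
        return 0.0
    return acc / (cnt * h)
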