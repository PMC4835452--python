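"""Compiled inner loop for the fixed-step RK4 integration.

Scalar re-statements of the rate functions and drive waveforms live here so
the 10^7-step inner loop (a 500 ms run resolving a 500 kHz carrier) stays in
machine code.  ``hh_core`` and ``forcing`` keep independent vectorised
implementations of the same formulas; the test suite cross-checks the two.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# Drive waveform codes shared with the integrator front-end.
DRIVE_CONSTANT = 0
DRIVE_OFFSET_SINE = 1
DRIVE_SINE = 2
DRIVE_COSINE = 3

_GUARD = 1e-7  # singularity guard, mirrors hh_core.SINGULARITY_GUARD


@njit(cache=True)
def hh_rates(v):
    x = 25.0 - v
    if abs(x) < _GUARD:
        alpha_m = 1.0
    else:
        alpha_m = 0.1 * x / math.expm1(x / 10.0)
    beta_m = 4.0 * math.exp(-v / 18.0)
    alpha_h = 0.07 * math.exp(-v / 20.0)
    beta_h = 1.0 / (math.exp((30.0 - v) / 10.0) + 1.0)
    y = 10.0 - v
    if abs(y) < _GUARD:
        alpha_n = 0.1
    else:
        alpha_n = 0.01 * y / math.expm1(y / 10.0)
    beta_n = 0.125 * math.exp(-v / 80.0)
    return alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n


@njit(cache=True)
def drive_value(t_ms, code, gated, j0, freq_hz, rep_freq_hz, duty_cycle):
    if code == DRIVE_CONSTANT:
        j = j0
    else:
        phase = 2.0 * math.pi * freq_hz * (t_ms * 1e-3)
        if code == DRIVE_OFFSET_SINE:
            j = j0 * (math.sin(phase) + 1.0)
        elif code == DRIVE_SINE:
            j = j0 * math.sin(phase)
        else:
            j = j0 * math.cos(phase)
    if gated:
        t_s = t_ms * 1e-3
        if t_s <= 0.0:
            return 0.0
        u = t_s * rep_freq_hz
        frac = u - math.floor(u)
        if frac == 0.0:
            frac = 1.0
        if frac > duty_cycle:
            return 0.0
    return j


@njit(cache=True)
def hh_deriv(v, m, h, n, i_ext, cm, g_na, g_k, g_l, v_na, v_k, v_l, phi):
    am, bm, ah, bh, an, bn = hh_rates(v)
    i_na = g_na * m * m * m * h * (v - v_na)
    i_k = g_k * n * n * n * n * (v - v_k)
    i_l = g_l * (v - v_l)
    dv = (i_ext - (i_na + i_k + i_l)) / cm
    dm = phi * (am * (1.0 - m) - bm * m)
    dh = phi * (ah * (1.0 - h) - bh * h)
    dn = phi * (an * (1.0 - n) - bn * n)
    return dv, dm, dh, dn


@njit(cache=True)
def rk4_integrate(
    v0, m0, h0, n0,
    dt, n_steps, stride,
    code, gated, j0, freq_hz, rep_freq_hz, duty_cycle,
    cm, g_na, g_k, g_l, v_na, v_k, v_l, phi,
):
    """Classical RK4 over ``n_steps`` steps of size ``dt`` (ms), recording
    every ``stride``-th sample (including the initial state).

    The drive is evaluated analytically at the RK4 sub-step times
    (t, t+dt/2, t+dt) rather than sampled-and-held, so the sub-millisecond
    carrier is not aliased.  Gating variables are clamped to [0, 1] after
    each step (a no-op analytically; guards round-off overshoot).

    Returns (t, v, m, h, n, i_ext, bad_step); bad_step is -1 on success or
    the 1-based index of the first step producing a non-finite state.
    """
    n_rec = n_steps // stride + 1
    t_out = np.empty(n_rec)
    v_out = np.empty(n_rec)
    m_out = np.empty(n_rec)
    h_out = np.empty(n_rec)
    n_out = np.empty(n_rec)
    i_out = np.empty(n_rec)

    v, m, h, n = v0, m0, h0, n0
    t_out[0] = 0.0
    v_out[0] = v
    m_out[0] = m
    h_out[0] = h
    n_out[0] = n
    i_out[0] = drive_value(0.0, code, gated, j0, freq_hz, rep_freq_hz, duty_cycle)

    for i in range(1, n_steps + 1):
        t0 = (i - 1) * dt
        j_a = drive_value(t0, code, gated, j0, freq_hz, rep_freq_hz, duty_cycle)
        j_b = drive_value(t0 + 0.5 * dt, code, gated, j0, freq_hz, rep_freq_hz, duty_cycle)
        j_c = drive_value(t0 + dt, code, gated, j0, freq_hz, rep_freq_hz, duty_cycle)

        k1v, k1m, k1h, k1n = hh_deriv(
            v, m, h, n, j_a, cm, g_na, g_k, g_l, v_na, v_k, v_l, phi)
        k2v, k2m, k2h, k2n = hh_deriv(
            v + 0.5 * dt * k1v, m + 0.5 * dt * k1m,
            h + 0.5 * dt * k1h, n + 0.5 * dt * k1n,
            j_b, cm, g_na, g_k, g_l, v_na, v_k, v_l, phi)
        k3v, k3m, k3h, k3n = hh_deriv(
            v + 0.5 * dt * k2v, m + 0.5 * dt * k2m,
            h + 0.5 * dt * k2h, n + 0.5 * dt * k2n,
            j_b, cm, g_na, g_k, g_l, v_na, v_k, v_l, phi)
        k4v, k4m, k4h, k4n = hh_deriv(
            v + dt * k3v, m + dt * k3m, h + dt * k3h, n + dt * k3n,
            j_c, cm, g_na, g_k, g_l, v_na, v_k, v_l, phi)

        v += dt / 6.0 * (k1v + 2.0 * k2v + 2.0 * k3v + k4v)
        m += dt / 6.0 * (k1m + 2.0 * k2m + 2.0 * k3m + k4m)
        h += dt / 6.0 * (k1h + 2.0 * k2h + 2.0 * k3h + k4h)
        n += dt / 6.0 * (k1n + 2.0 * k2n + 2.0 * k3n + k4n)

        if m < 0.0:
            m = 0.0
        elif m > 1.0:
            m = 1.0
        if h < 0.0:
            h = 0.0
        elif h > 1.0:
            h = 1.0
        if n < 0.0:
            n = 0.0
        elif n > 1.0:
            n = 1.0

        if not (math.isfinite(v) and math.isfinite(m)
                and math.isfinite(h) and math.isfinite(n)):
            return t_out, v_out, m_out, h_out, n_out, i_out, i

        if i % stride == 0:
            k = i // stride
            t_rec = i * dt
            t_out[k] = t_rec
            v_out[k] = v
            m_out[k] = m
            h_out[k] = h
            n_out[k] = n
            # re-evaluate at the recorded timestamp: t0+dt can differ from
            # i*dt by one ulp, enough to flip the pulse gate on a period edge
            i_out[k] = drive_value(
                t_rec, code, gated, j0, freq_hz, rep_freq_hz, duty_cycle
            )

    return t_out, v_out, m_out, h_out, n_out, i_out, -1
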