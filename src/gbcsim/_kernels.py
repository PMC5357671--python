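"""Numba-compiled inner loops: synapse recursion and membrane integration.

The membrane kernel integrates the single-compartment bushy-cell equation

    I_ext = C dV/dt + I_leak + I_Na + I_Kht + I_Klt + I_h + I_syn

with exponential-Euler updates for the gating variables and an implicit
(backward) Euler update for V, which keeps the stiff system stable at a
fixed 10 us step.  All kernel-internal units: mV, ms, nS, pF, pA.

Channel complement (Rothman-Manis ventral-cochlear-nucleus Type II):

* Na: m^3 h with the fast kinetics used for globular bushy cells
  (Rothman-Young-Manis rate functions);
* Kht (high-threshold K+): phi n^2 + (1-phi) p, phi = 0.85;
* Klt (low-threshold K+): w^4 z with partial inactivation (z floor 0.5);
* Ih: single activation gate r;
* leak: ohmic.

Rate functions are published at 22 degC; time constants are divided by
q10^((T-22)/10) to transpose to body temperature.
"""

import math

import numpy as np
from numba import njit

# gating-state vector layout
M, H, N, P, W, Z, R = 0, 1, 2, 3, 4, 5, 6
NGATES = 7

# soma parameter vector layout (see soma.SomaParams.as_array)
IC, IGNA, IGKHT, IGKLT, IGH, IGLEAK = 0, 1, 2, 3, 4, 5
IENA, IEK, IEH, IELEAK = 6, 7, 8, 9
IPHI, IQNA, IQK, IESYN = 10, 11, 12, 13
NPARAMS = 14

PHI_KHT = 0.85
ZSS_KLT = 0.5


@njit(cache=True)
def tm_conductances(times, w, u, k, tau_f, tau_s, g0):
    """Delivered conductance per event of the depression recursion.

    ``times`` in seconds (sorted), time constants in ms.  The interval for
    the first event is measured from t = 0.
    """
    n = times.size
    out = np.empty(n)
    g = g0
    t_last = 0.0
    one_u = 1.0 - u
    for i in range(n):
        dt = (times[i] - t_last) * 1e3
        ef = math.exp(-dt / tau_f)
        es = math.exp(-dt / tau_s)
        g = (k * (g * one_u * ef + w * (1.0 - ef))
             + (1.0 - k) * (g * one_u * es + w * (1.0 - es)))
        out[i] = g
        t_last = times[i]
    return out


# ----------------------------------------------------------------------
@njit(cache=True, inline="always")
def _na_rates(v):
    """Fast sodium alpha/beta rates (1/ms at 22 degC)."""
    x = v + 49.0
    if abs(x) < 1e-7:
        am = 0.36 * 3.0
    else:
        am = 0.36 * x / (1.0 - math.exp(-x / 3.0))
    y = v + 58.0
    if abs(y) < 1e-7:
        bm = 0.4 * 20.0
    else:
        bm = -0.4 * y / (1.0 - math.exp(y / 20.0))
    ah = 2.4 / (1.0 + math.exp((v + 68.0) / 3.0)) \
        + 0.8 / (1.0 + math.exp(v + 61.3))
    bh = 3.6 / (1.0 + math.exp(-(v + 21.0) / 10.0))
    return am, bm, ah, bh


@njit(cache=True, inline="always")
def gate_targets(v, qna, qk):
    """Steady states and q10-corrected time constants (ms) of all gates."""
    am, bm, ah, bh = _na_rates(v)
    minf = am / (am + bm)
    taum = 1.0 / (am + bm) / qna
    hinf = ah / (ah + bh)
    tauh = 1.0 / (ah + bh) / qna

    ninf = math.pow(1.0 + math.exp(-(v + 15.0) / 5.0), -0.5)
    taun = (100.0 / (11.0 * math.exp((v + 60.0) / 24.0)
                     + 21.0 * math.exp(-(v + 60.0) / 23.0)) + 0.7) / qk
    pinf = 1.0 / (1.0 + math.exp(-(v + 23.0) / 6.0))
    taup = (100.0 / (4.0 * math.exp((v + 60.0) / 32.0)
                     + 5.0 * math.exp(-(v + 60.0) / 22.0)) + 5.0) / qk

    winf = math.pow(1.0 + math.exp(-(v + 48.0) / 6.0), -0.25)
    tauw = (100.0 / (6.0 * math.exp((v + 60.0) / 6.0)
                     + 16.0 * math.exp(-(v + 60.0) / 45.0)) + 1.5) / qk
    zinf = ZSS_KLT + (1.0 - ZSS_KLT) / (1.0 + math.exp((v + 71.0) / 10.0))
    tauz = (1000.0 / (math.exp((v + 60.0) / 20.0)
                      + math.exp(-(v + 60.0) / 8.0)) + 50.0) / qk

    rinf = 1.0 / (1.0 + math.exp((v + 76.0) / 7.0))
    taur = (100000.0 / (237.0 * math.exp((v + 60.0) / 12.0)
                        + 17.0 * math.exp(-(v + 60.0) / 14.0)) + 25.0) / qk
    return (minf, taum, hinf, tauh, ninf, taun, pinf, taup,
            winf, tauw, zinf, tauz, rinf, taur)


@njit(cache=True)
def gate_steady_state(v, qna, qk):
    tg = gate_targets(v, qna, qk)
    g = np.empty(NGATES)
    for i in range(NGATES):
        g[i] = tg[2 * i]
    return g


@njit(cache=True, inline="always")
def _channel_conductances(gates, par):
    g_na = par[IGNA] * gates[M] ** 3 * gates[H]
    g_kht = par[IGKHT] * (PHI_KHT * gates[N] ** 2 + (1.0 - PHI_KHT) * gates[P])
    g_klt = par[IGKLT] * gates[W] ** 4 * gates[Z]
    g_h = par[IGH] * gates[R]
    return g_na, g_kht, g_klt, g_h


@njit(cache=True)
def membrane_current(v, gates, par):
    """Total ionic current (pA, outward positive) at a fixed state."""
    g_na, g_kht, g_klt, g_h = _channel_conductances(gates, par)
    return (g_na * (v - par[IENA]) + g_kht * (v - par[IEK])
            + g_klt * (v - par[IEK]) + g_h * (v - par[IEH])
            + par[IGLEAK] * (v - par[IELEAK]))


@njit(cache=True)
def integrate(v0, gates0, par, dt_ms, n_steps, syn_inc, syn_decay, i_ext):
    """Integrate the membrane for ``n_steps`` of ``dt_ms``.

    ``syn_inc[i]`` is the synaptic conductance (nS) arriving within step i,
    pre-decayed to the step's end point; ``syn_decay`` the per-step decay
    factor of the summed synaptic conductance; ``i_ext[i]`` an injected
    current (pA).  Returns (V trace incl. the initial point, final gates,
    final synaptic conductance).
    """
    v_out = np.empty(n_steps + 1)
    v = v0
    v_out[0] = v
    gates = gates0.copy()
    g_syn = 0.0
    qna = par[IQNA]
    qk = par[IQK]
    for i in range(n_steps):
        tg = gate_targets(v, qna, qk)
        for j in range(NGATES):
            inf = tg[2 * j]
            tau = tg[2 * j + 1]
            gates[j] = inf + (gates[j] - inf) * math.exp(-dt_ms / tau)
        g_syn = g_syn * syn_decay + syn_inc[i]
        g_na, g_kht, g_klt, g_h = _channel_conductances(gates, par)
        g_sum = g_na + g_kht + g_klt + g_h + par[IGLEAK] + g_syn
        drive = (g_na * par[IENA] + (g_kht + g_klt) * par[IEK]
                 + g_h * par[IEH] + par[IGLEAK] * par[IELEAK]
                 + g_syn * par[IESYN] + i_ext[i])
        c_dt = par[IC] / dt_ms
        v = (c_dt * v + drive) / (c_dt + g_sum)
        v_out[i + 1] = v
    return v_out, gates, g_syn


@njit(cache=True)
def bin_events(times_s, g_events, dt_ms, n_steps, decay_tau_ms):
    """Accumulate per-event conductances into per-step increments.

    An event inside step i (ending at t_i = (i+1)*dt) contributes
    ``g * exp(-(t_i - t_event)/tau)`` to ``inc[i]``, i.e. the increment is
    pre-decayed to the grid point, making the summed trace exact there.
    """
    inc = np.zeros(n_steps)
    dt_s = dt_ms * 1e-3
    for j in range(times_s.size):
        t = times_s[j]
        i = int(math.ceil(t / dt_s)) - 1
        if t <= 0.0:
            i = 0
        if i >= n_steps:
            continue
        if i < 0:
            i = 0
        t_grid = (i + 1) * dt_s
        inc[i] += g_events[j] * math.exp(-(t_grid - t) * 1e3 / decay_tau_ms)
    return inc
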