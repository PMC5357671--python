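"""Endbulb-of-Held synapse models with short-term depression.

Three phenomenological variants of the large axosomatic synapse between an
auditory nerve fiber and a globular bushy cell:

``tonic``
    constant peak conductance ``w`` at every presynaptic event;
``single_exp``
    depressing synapse with a single exponential recovery (Tsodyks-Markram
    recursion); the depression level X% is defined from the steady-state
    strengths at two reference rates (50 and 300 Hz by default) and can be
    dialed in through the utilization parameter ``u``;
``double_exp``
    depressing synapse with fast and slow recovery components, with default
    parameters matching mean in vitro endbulb measurements
    (u = 0.6, tau_f = 10.9 ms, tau_s = 1990 ms, k = 0.3), referred to as the
    ``yang2009mean`` synapse.

The recursion is event-driven: given the conductance state ``g_n`` after the
n-th event and the interval ``dt`` to the next one,

    g_{n+1} = k  [g_n (1-u) e^{-dt/tau_f} + w (1 - e^{-dt/tau_f})]
            + (1-k)[g_n (1-u) e^{-dt/tau_s} + w (1 - e^{-dt/tau_s})]

which reduces to the single-exponential form for k = 1.  The state is
initialized to ``g_0 = w/(1-u)`` so the first event delivers exactly ``w``.
Delivered conductances decay with a fixed 0.2 ms time constant and sum
linearly across events and synapses.

Units: conductances in nS, time constants in ms, event times in seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace, asdict

import numpy as np

__all__ = [
    "SynapseParams",
    "SynapseState",
    "DepressionSpec",
    "update_on_spike",
    "delivered_conductances",
    "steady_state_strength",
    "depression_level",
    "u_for_depression",
    "conductance_trace",
]

KINDS = ("tonic", "single_exp", "double_exp")


@dataclass(frozen=True)
class SynapseParams:
    """Parameters of one endbulb synapse (see module docstring for units)."""

    kind: str = "single_exp"
    w: float = 10.0          # peak conductance of a fully recovered synapse (nS)
    u: float = 0.0           # utilization per event, in [0, 1)
    tau: float = 90.0        # single-exp recovery constant (ms)
    tau_f: float = 10.9      # fast recovery constant (ms), double_exp
    tau_s: float = 1990.0    # slow recovery constant (ms), double_exp
    k: float = 0.3           # fraction of fast recovery, double_exp
    g_decay_tau: float = 0.2  # conductance decay constant (ms)
    e_rev: float = 0.0       # synaptic reversal potential (mV)

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if not 0.0 <= self.u <= 1.0:
            raise ValueError("u must be in [0, 1]")
        if self.kind != "tonic" and self.u >= 1.0:
            raise ValueError("u = 1 fully depletes a depressing synapse; "
                             "use the tonic kind instead")
        if not 0.0 <= self.k <= 1.0:
            raise ValueError("k must be in [0, 1]")
        if min(self.tau, self.tau_f, self.tau_s, self.g_decay_tau) <= 0:
            raise ValueError("time constants must be > 0")
        if self.w < 0:
            raise ValueError("w must be >= 0")

    # effective recovery mixture used by the recursion
    def _mixture(self) -> tuple[float, float, float]:
        """(k, tau_fast, tau_slow) in ms; single_exp maps to k=1."""
        if self.kind == "single_exp":
            return 1.0, self.tau, self.tau
        return self.k, self.tau_f, self.tau_s

    def with_weight(self, w: float) -> "SynapseParams":
        return replace(self, w=w)

    # -- constructors ---------------------------------------------------
    @classmethod
    def tonic(cls, w: float = 10.0, **kw) -> "SynapseParams":
        return cls(kind="tonic", w=w, u=0.0, **kw)

    @classmethod
    def depressing(cls, x_percent: float, w: float = 10.0, tau: float = 90.0,
                   **kw) -> "SynapseParams":
        """X%-depressing synapse: single-exponential recovery with ``u`` chosen
        so the 300 Hz steady state is ``x_percent`` below the 50 Hz one."""
        if x_percent == 0:
            return cls(kind="single_exp", w=w, u=0.0, tau=tau, **kw)
        u = u_for_depression(x_percent, kind="single_exp", tau=tau)
        return cls(kind="single_exp", w=w, u=u, tau=tau, **kw)

    @classmethod
    def yang2009mean(cls, w: float = 10.0, **kw) -> "SynapseParams":
        """Double-exponential-recovery synapse with mean in vitro parameters."""
        return cls(kind="double_exp", w=w, u=0.6, tau_f=10.9, tau_s=1990.0,
                   k=0.3, **kw)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SynapseParams":
        return cls(**d)


@dataclass
class SynapseState:
    """Recursion state: available peak conductance and last event time."""

    g_n: float
    t_last: float | None = None

    @classmethod
    def initial(cls, params: SynapseParams) -> "SynapseState":
        if params.kind == "tonic" or params.u >= 1.0:
            return cls(g_n=params.w, t_last=None)
        return cls(g_n=params.w / (1.0 - params.u), t_last=None)


@dataclass(frozen=True)
class DepressionSpec:
    """Reference rates defining the depression level X%."""

    f_low: float = 50.0
    f_high: float = 300.0


# ----------------------------------------------------------------------
def _advance(g_n: float, dt_ms: float, p: SynapseParams) -> float:
    k, tf, ts = p._mixture()
    ef = math.exp(-dt_ms / tf)
    es = math.exp(-dt_ms / ts)
    one_u = 1.0 - p.u
    return (k * (g_n * one_u * ef + p.w * (1.0 - ef))
            + (1.0 - k) * (g_n * one_u * es + p.w * (1.0 - es)))


def update_on_spike(state: SynapseState, params: SynapseParams,
                    t: float) -> tuple[SynapseState, float]:
    """Advance the recursion to a presynaptic event at time ``t`` (s).

    Returns the new state and the conductance delivered at this event.
    Event times must be strictly increasing; the interval for the first
    event is measured from the simulation origin (t = 0), which by the
    ``g_0 = w/(1-u)`` convention makes the first delivery exactly ``w``.
    """
    t_ref = 0.0 if state.t_last is None else state.t_last
    if t <= t_ref and state.t_last is not None:
        raise ValueError(f"non-increasing event time {t} after {state.t_last}")
    if t < 0:
        raise ValueError("event times must be >= 0")
    if params.kind == "tonic":
        return SynapseState(g_n=params.w, t_last=t), params.w
    dt_ms = (t - t_ref) * 1e3
    g_new = _advance(state.g_n, dt_ms, params)
    return SynapseState(g_n=g_new, t_last=t), g_new


def delivered_conductances(params: SynapseParams, times) -> np.ndarray:
    """Conductance delivered at each event of a sorted spike train (nS)."""
    times = np.asarray(times, dtype=float)
    if params.kind == "tonic" or params.u == 0.0:
        return np.full(times.shape, params.w)
    from ._kernels import tm_conductances
    k, tf, ts = params._mixture()
    g0 = params.w / (1.0 - params.u)
    return tm_conductances(times, params.w, params.u, k, tf, ts, g0)


# ----------------------------------------------------------------------
def steady_state_strength(params: SynapseParams, f: float,
                          tol: float = 1e-10, max_iter: int = 10**6) -> float:
    """Steady-state delivered conductance under periodic stimulation at ``f`` Hz.

    For the single-exponential synapse the fixed point has the closed form
    ``w (1-E) / (1 - (1-u) E)`` with ``E = exp(-1/(f tau))``.  The
    double-exponential fixed point is found by damped fixed-point iteration
    to a relative tolerance of 1e-10.
    """
    if f <= 0:
        raise ValueError("stimulation rate must be > 0")
    if params.kind == "tonic":
        return params.w
    dt_ms = 1e3 / f
    if params.kind == "single_exp":
        e = math.exp(-dt_ms / params.tau)
        return params.w * (1.0 - e) / (1.0 - (1.0 - params.u) * e)
    g = params.w
    for _ in range(max_iter):
        g_new = 0.5 * (g + _advance(g, dt_ms, params))
        if abs(g_new - g) <= tol * max(abs(g_new), 1e-300):
            return g_new
        g = g_new
    raise RuntimeError("steady-state iteration did not converge")


def depression_level(params: SynapseParams,
                     spec: DepressionSpec = DepressionSpec()) -> float:
    """Depression level X% = (1 - s_fhigh / s_flow) * 100."""
    if params.kind == "tonic":
        return 0.0
    s_lo = steady_state_strength(params, spec.f_low)
    s_hi = steady_state_strength(params, spec.f_high)
    if s_lo == 0.0:
        return 0.0
    return (1.0 - s_hi / s_lo) * 100.0


def u_for_depression(x_percent: float, kind: str = "single_exp",
                     tau: float = 90.0, tau_f: float = 10.9,
                     tau_s: float = 1990.0, k: float = 0.3,
                     spec: DepressionSpec = DepressionSpec(),
                     tol_pp: float = 1e-4) -> float:
    """Utilization ``u`` producing a given depression level.

    Bisection on ``u`` in [0, 1); the depression level is strictly increasing
    in ``u``.  Raises if ``x_percent`` cannot be reached for the given
    kind/time constants.
    """
    if not 0.0 <= x_percent < 100.0:
        raise ValueError("x_percent must be in [0, 100)")
    if x_percent == 0.0:
        return 0.0

    def level(u: float) -> float:
        p = SynapseParams(kind=kind, w=1.0, u=u, tau=tau, tau_f=tau_f,
                          tau_s=tau_s, k=k)
        return depression_level(p, spec)

    lo, hi = 0.0, 1.0 - 1e-9
    if level(hi) < x_percent:
        raise ValueError(
            f"depression of {x_percent}% unattainable for kind={kind!r} "
            f"(max {level(hi):.2f}%)")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if level(mid) < x_percent:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-14:
            break
    u = 0.5 * (lo + hi)
    assert abs(level(u) - x_percent) < max(tol_pp, 0.01), "bisection failed"
    return u


# ----------------------------------------------------------------------
def conductance_trace(event_times, event_g, t_grid,
                      g_decay_tau: float = 0.2) -> np.ndarray:
    """Summed conductance waveform on a time grid (nS).

    Each event contributes an instantaneous rise by its delivered conductance
    followed by exponential decay with ``g_decay_tau`` (ms); contributions sum
    linearly.  Exact at the grid points (the decay is propagated analytically
    between them).
    """
    event_times = np.asarray(event_times, dtype=float)
    event_g = np.asarray(event_g, dtype=float)
    t_grid = np.asarray(t_grid, dtype=float)
    if event_times.shape != event_g.shape:
        raise ValueError("event_times and event_g must have the same shape")
    order = np.argsort(event_times, kind="stable")
    event_times = event_times[order]
    event_g = event_g[order]
    tau_s = g_decay_tau * 1e-3

    out = np.zeros_like(t_grid)
    state = 0.0
    j = 0
    t_prev = -math.inf
    for i, t in enumerate(t_grid):
        if math.isfinite(t_prev):
            state *= math.exp(-(t - t_prev) / tau_s)
        while j < event_times.size and event_times[j] <= t:
            state += event_g[j] * math.exp(-(t - event_times[j]) / tau_s)
            j += 1
        out[i] = state
        t_prev = t
    return out
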