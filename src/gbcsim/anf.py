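"""Surrogate auditory-nerve-fiber (ANF) spike trains.

High-spontaneous-rate ANFs drive the bushy cell model.  Instead of a full
inner-ear model, this module generates spike trains as an inhomogeneous
Poisson process shaped by the three statistics the downstream results depend
on:

* **rate**: ~50 spikes/s spontaneous, a saturating driven rate during tones
  (~300 spikes/s at 60 dB SPL) with onset adaptation;
* **phase locking**: a von-Mises-shaped periodic modulation of the intensity
  at the tone frequency, whose concentration is chosen so the fiber's vector
  strength matches a CF-dependent target;
* **refractoriness**: an absolute dead time plus an exponential relative
  refractory period, with the proposal intensity compensated so realized
  stationary rates match the requested ones.

All spike times are in seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import optimize, special

from .protocols import ToneProtocol

__all__ = [
    "SpikeTrain",
    "ANFParams",
    "RateEnvelope",
    "rate_envelope",
    "vs_to_concentration",
    "generate_anf_train",
    "generate_population",
]


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class SpikeTrain:
    """A sorted set of spike times with its observation duration.

    ``times`` are seconds in ``[0, duration]``, strictly increasing.
    ``meta`` carries provenance (seed, fiber index, protocol id, ...).
    """

    times: np.ndarray
    duration: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1:
            raise ValueError("spike times must be a 1-d array")
        if t.size and (np.any(np.diff(t) <= 0)):
            raise ValueError("spike times must be strictly increasing")
        if t.size and (t[0] < 0 or t[-1] > self.duration + 1e-12):
            raise ValueError("spike times outside [0, duration]")

    def __len__(self) -> int:
        return self.times.size

    @property
    def rate(self) -> float:
        """Mean firing rate over the whole duration (spikes/s)."""
        return len(self) / self.duration if self.duration > 0 else math.nan


def default_vs_curve(cf: float) -> float:
    """Target fiber vector strength as a function of CF (Hz).

    Low-frequency plateau near 0.85 with a rolloff above a few kHz,
    mimicking the loss of phase locking of mammalian ANFs.
    """
    return 0.85 / math.sqrt(1.0 + (cf / 2500.0) ** 4)


@dataclass(frozen=True)
class ANFParams:
    """Statistical parameters of a surrogate high-spontaneous-rate fiber.

    Parameters
    ----------
    spont_rate : float
        Spontaneous rate (spikes/s).
    driven_rate_at_level : dict
        Mapping dB SPL -> steady-state driven rate (spikes/s); linearly
        interpolated between entries, clamped outside.
    onset_peak_rate : float
        Instantaneous rate at tone onset before adaptation (spikes/s).
    adapt_tau_rapid, adapt_tau_short : float
        Rapid and short-term adaptation time constants (s).
    adapt_rapid_fraction : float
        Share of the onset overshoot carried by the rapid component.
    offset_suppression : float
        Fractional suppression of spontaneous rate right after tone offset.
    offset_tau : float
        Recovery time constant of the post-offset suppression (s).
    vs_curve : dict or None
        Optional table CF (Hz) -> target fiber vector strength, linearly
        interpolated; ``None`` selects :func:`default_vs_curve`.
    abs_refractory, rel_refractory_tau : float
        Absolute dead time and relative-refractory recovery constant (s).
    """

    spont_rate: float = 50.0
    driven_rate_at_level: dict = field(
        default_factory=lambda: {50.0: 250.0, 60.0: 300.0})
    onset_peak_rate: float = 700.0
    adapt_tau_rapid: float = 0.002
    adapt_tau_short: float = 0.060
    adapt_rapid_fraction: float = 0.6
    offset_suppression: float = 0.4
    offset_tau: float = 0.100
    vs_curve: dict | None = None
    abs_refractory: float = 0.00075
    rel_refractory_tau: float = 0.0006

    def __post_init__(self):
        vals = [self.spont_rate, self.onset_peak_rate, self.adapt_tau_rapid,
                self.adapt_tau_short, self.offset_tau, self.abs_refractory,
                self.rel_refractory_tau]
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("non-finite ANF parameter")
        if self.spont_rate < 0 or self.onset_peak_rate < 0:
            raise ValueError("rates must be >= 0")
        if any(r < 0 for r in self.driven_rate_at_level.values()):
            raise ValueError("driven rates must be >= 0")
        if not 0.0 <= self.adapt_rapid_fraction <= 1.0:
            raise ValueError("adapt_rapid_fraction must be in [0, 1]")
        if not 0.0 <= self.offset_suppression <= 1.0:
            raise ValueError("offset_suppression must be in [0, 1]")

    def driven_rate(self, level_db: float) -> float:
        """Steady-state driven rate at a sound level (linear interpolation)."""
        levels = np.array(sorted(self.driven_rate_at_level))
        rates = np.array([self.driven_rate_at_level[l] for l in levels])
        return float(np.interp(level_db, levels, rates))

    def target_vs(self, cf: float) -> float:
        if self.vs_curve is None:
            return default_vs_curve(cf)
        cfs = np.array(sorted(self.vs_curve))
        vs = np.array([self.vs_curve[c] for c in cfs])
        return float(np.clip(np.interp(cf, cfs, vs), 0.0, 0.999))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ANFParams":
        d = dict(d)
        if "driven_rate_at_level" in d:
            d["driven_rate_at_level"] = {
                float(k): float(v) for k, v in d["driven_rate_at_level"].items()}
        if d.get("vs_curve"):
            d["vs_curve"] = {float(k): float(v) for k, v in d["vs_curve"].items()}
        return cls(**d)


# ----------------------------------------------------------------------
class RateEnvelope:
    """Piecewise firing-rate envelope r(t) of a fiber under a tone train.

    Within each tone the rate rises over the cosine-squared ramp, peaks near
    the onset peak rate, and decays with two adaptation time constants toward
    the level-dependent steady driven rate.  After tone offset the rate is
    transiently suppressed below spontaneous and recovers exponentially.
    Adaptation state is reset at each tone onset (the inter-tone gaps used
    here are long relative to the rapid components).
    """

    def __init__(self, protocol: ToneProtocol, params: ANFParams):
        self.protocol = protocol
        self.params = params
        self.r_spont = params.spont_rate
        self.r_driven = max(params.driven_rate(protocol.level_db), self.r_spont)
        self.r_peak = max(params.onset_peak_rate, self.r_driven)

    # -- pieces --------------------------------------------------------
    def _ramp(self, s: np.ndarray) -> np.ndarray:
        """Cosine-squared on/off gate of one tone; s is time from onset (s)."""
        p, d = self.protocol, self.protocol.tone_duration
        rd = p.ramp_duration
        env = np.ones_like(s)
        if rd > 0:
            up = s < rd
            env[up] = np.sin(0.5 * np.pi * s[up] / rd) ** 2
            down = s > d - rd
            env[down] = np.sin(0.5 * np.pi * (d - s[down]) / rd) ** 2
        env[(s < 0) | (s > d)] = 0.0
        return env

    def _adapted(self, s: np.ndarray) -> np.ndarray:
        """Onset-adapted driven rate, time from tone onset (s)."""
        pr = self.params
        over = self.r_peak - self.r_driven
        a = pr.adapt_rapid_fraction
        return self.r_driven + over * (
            a * np.exp(-s / pr.adapt_tau_rapid)
            + (1.0 - a) * np.exp(-s / pr.adapt_tau_short))

    # ------------------------------------------------------------------
    def __call__(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        p, pr = self.protocol, self.params
        if p.n_repetitions == 0:
            return np.full_like(t, self.r_spont)
        per = p.repetition_period
        cyc = np.clip(np.floor(t / per), 0, p.n_repetitions - 1)
        s = t - cyc * per  # time within the (clamped) cycle
        r = np.empty_like(t)
        in_tone = (s >= 0) & (s <= p.tone_duration) & (t >= 0)
        # tone: spontaneous floor + gated, adapted drive above it
        st = s[in_tone]
        r[in_tone] = self.r_spont + self._ramp(st) * (self._adapted(st) - self.r_spont)
        # gap: suppressed spontaneous recovering toward r_spont
        gap = ~in_tone
        sg = s[gap] - p.tone_duration
        sg = np.maximum(sg, 0.0)
        r[gap] = self.r_spont * (
            1.0 - pr.offset_suppression * np.exp(-sg / pr.offset_tau))
        r[t < 0] = self.r_spont
        return np.maximum(r, 0.0)

    @property
    def max_rate(self) -> float:
        return max(self.r_spont, self.r_peak)


def rate_envelope(protocol: ToneProtocol, params: ANFParams) -> RateEnvelope:
    """Build the piecewise rate envelope r(t) for a protocol/fiber pair."""
    return RateEnvelope(protocol, params)


# ----------------------------------------------------------------------
def vs_to_concentration(target_vs: float) -> float:
    """Von Mises concentration kappa whose mean resultant length is ``target_vs``.

    The stationary phase distribution of a modulated fiber is von Mises;
    its vector strength equals I1(kappa)/I0(kappa).  Inverted numerically.
    """
    if not 0.0 <= target_vs < 1.0:
        raise ValueError(f"target VS must be in [0, 1), got {target_vs}")
    if target_vs == 0.0:
        return 0.0

    def f(k):
        return special.i1e(k) / special.i0e(k) - target_vs

    hi = 2.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e6:  # pragma: no cover - VS < 1 always brackets
            raise RuntimeError("failed to bracket concentration")
    return float(optimize.brentq(f, 0.0, hi, xtol=1e-12, rtol=1e-12))


# ----------------------------------------------------------------------
#: cap on r*d_eff in the dead-time compensation: beyond this the requested
#: rate approaches the refractory ceiling and exact compensation diverges
_MAX_DEADTIME_LOAD = 0.65


def _dead_time_corrected(r: np.ndarray, d_eff: float) -> np.ndarray:
    """Proposal rate whose dead-time-thinned output approximates ``r``."""
    load = np.minimum(r * d_eff, _MAX_DEADTIME_LOAD)
    return r / (1.0 - load)


def generate_anf_train(
    protocol: ToneProtocol,
    params: ANFParams,
    seed,
    duration: float | None = None,
) -> SpikeTrain:
    """Generate one surrogate ANF spike train.

    The train is an inhomogeneous point process with intensity
    ``r_c(t) * m(t) * ref(t - t_last)`` where ``r_c`` is the dead-time
    compensated rate envelope, ``m`` a von Mises phase modulation at the tone
    frequency (active during tone bursts, unit mean over a cycle) and ``ref``
    the refractory hazard.  Sampled by thinning from a homogeneous proposal
    process at the intensity's upper bound; reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    if duration is None:
        duration = protocol.duration
    if duration <= 0:
        raise ValueError("duration must be positive (silence needs an explicit one)")

    env = rate_envelope(protocol, params)
    kappa = vs_to_concentration(params.target_vs(protocol.cf))
    # modulation m(theta) = exp(kappa cos theta)/I0(kappa): unit mean, max at 0
    log_i0 = math.log(special.i0e(kappa)) + kappa
    m_max = math.exp(kappa - log_i0)

    d_eff = params.abs_refractory + params.rel_refractory_tau
    lam_max = _dead_time_corrected(np.array([env.max_rate]), d_eff)[0] * m_max
    if lam_max <= 0:
        return SpikeTrain(np.empty(0), duration, {"seed": repr(seed)})

    n_prop = rng.poisson(lam_max * duration)
    t_prop = np.sort(rng.uniform(0.0, duration, n_prop))
    u_prop = rng.uniform(0.0, 1.0, n_prop)

    # stage 1: thin to the (refractory-free) target intensity, vectorized
    lam = _dead_time_corrected(env(t_prop), d_eff)
    if kappa > 0 and protocol.n_repetitions > 0:
        per = protocol.repetition_period
        cyc = np.clip(np.floor(t_prop / per), 0, protocol.n_repetitions - 1)
        s = t_prop - cyc * per
        in_tone = (s >= 0) & (s <= protocol.tone_duration)
        phase = 2.0 * np.pi * protocol.cf * t_prop[in_tone]
        mod = np.ones_like(t_prop)
        mod[in_tone] = np.exp(kappa * np.cos(phase) - log_i0)
        lam = lam * mod
    cand = t_prop[u_prop < lam / lam_max]
    u2 = rng.uniform(0.0, 1.0, cand.size)

    # stage 2: sequential refractory thinning
    t_abs = params.abs_refractory
    tau_rel = params.rel_refractory_tau
    times = []
    t_last = -np.inf
    for tc, u in zip(cand, u2):
        dt = tc - t_last
        if dt <= t_abs:
            continue
        if tau_rel > 0:
            p_ok = 1.0 - math.exp(-(dt - t_abs) / tau_rel)
        else:
            p_ok = 1.0
        if u < p_ok:
            times.append(tc)
            t_last = tc
    return SpikeTrain(np.asarray(times), duration,
                      {"seed": repr(seed), "cf": protocol.cf})


def generate_population(
    protocol: ToneProtocol,
    params: ANFParams,
    n_fibers: int,
    seed,
    duration: float | None = None,
) -> list[SpikeTrain]:
    """Generate ``n_fibers`` statistically independent fibers (spawned seeds)."""
    if n_fibers < 1:
        raise ValueError("n_fibers must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_fibers)
    trains = []
    for i, child in enumerate(children):
        st = generate_anf_train(protocol, params, child, duration=duration)
        st.meta["fiber_id"] = i
        trains.append(st)
    return trains
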