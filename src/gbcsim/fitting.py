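"""Synaptic-weight fitting against a target spontaneous rate.

For a given synapse type and number of converging fibers, the only free
parameter of the cell model is the shared peak synaptic conductance ``w``
(all endbulbs of one cell carry the same weight).  Spontaneous rate, vector
strength, entrainment and driven rate all grow with ``w``; the spontaneous
rate is the limiting factor, so the optimal weight is

    w_o = argmin_w | SR(w) - SR_t |

with SR measured in the silent gaps of the tone protocol and SR_t the target
spontaneous rate (7.5 spikes/s by default, the mean of low-CF globular bushy
cells).  A coarse logarithmic grid scan is refined by bisection between the
bracketing grid points; ties break toward the smaller weight.

The per-point experiment (:func:`fit_num_inputs`) inverts the other axis:
given a reference entrainment value at a CF, it finds the smallest number of
converging fibers whose fitted cell reaches that entrainment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anf import ANFParams, generate_population
from .metrics import pooled_metrics, summarize_response
from .protocols import ToneProtocol
from .soma import DEFAULT_DT, SomaParams, simulate
from .synapse import SynapseParams

__all__ = [
    "FitTarget",
    "FitProfile",
    "FULL_PROFILE",
    "DESK_PROFILE",
    "simulate_cell",
    "scan_weights",
    "optimal_weight",
    "fit_num_inputs",
    "NotBracketedError",
]


class NotBracketedError(ValueError):
    """The scanned weights do not bracket the target spontaneous rate."""


@dataclass(frozen=True)
class FitTarget:
    """Fit targets: spontaneous rate and, optionally, a reference entrainment."""

    sr_t: float = 7.5       # target spontaneous rate (spikes/s)
    cf: float | None = None
    ei_ref: float | None = None

    def __post_init__(self):
        if not self.sr_t > 0:
            raise ValueError("sr_t must be > 0")


@dataclass(frozen=True)
class FitProfile:
    """Problem sizes of a fit: seeds, repetitions and weight grid."""

    n_scan_seeds: int = 5
    n_validate_seeds: int = 10
    scan_repetitions: int | None = None      # None: use the protocol's
    validate_repetitions: int | None = None
    w_min: float = 0.5
    w_max: float = 60.0
    n_w: int = 16
    refine_tol: float = 0.5   # spikes/s
    max_refine: int = 8

    def w_grid(self) -> np.ndarray:
        return np.geomspace(self.w_min, self.w_max, self.n_w)


FULL_PROFILE = FitProfile()
DESK_PROFILE = FitProfile(n_scan_seeds=3, n_validate_seeds=3,
                          scan_repetitions=30, validate_repetitions=30,
                          n_w=10)

PROFILES = {"full": FULL_PROFILE, "desk": DESK_PROFILE}


def get_profile(profile) -> FitProfile:
    if isinstance(profile, FitProfile):
        return profile
    return PROFILES[profile]


# ----------------------------------------------------------------------
def _seed_for(master: int, *key: int) -> np.random.SeedSequence:
    """Deterministic sub-seed for a namespaced key."""
    return np.random.SeedSequence([int(master)] + [int(k) for k in key])


def simulate_cell(
    protocol: ToneProtocol,
    synapse: SynapseParams,
    n_inputs: int,
    anf: ANFParams,
    soma: SomaParams,
    seed,
    dt: float = DEFAULT_DT,
):
    """Generate a fiber population, run the soma, summarize the response.

    Returns ``(spike_times, ResponseSummary)``.
    """
    fibers = generate_population(protocol, anf, n_inputs, seed)
    res = simulate(soma, [synapse] * n_inputs, fibers,
                   t_end=protocol.duration, dt=dt)
    return res.spikes, summarize_response(res.spikes, protocol)


def _evaluate_weight(protocol, synapse_template, n_inputs, anf, soma, w,
                     seeds, dt):
    """Average response metrics over seeds at one weight (common seeds)."""
    syn = synapse_template.with_weight(float(w))
    spikes_all, srs, drs = [], [], []
    for ss in seeds:
        spikes, summ = simulate_cell(protocol, syn, n_inputs, anf, soma,
                                     ss, dt=dt)
        spikes_all.append(spikes)
        srs.append(summ.sr)
        drs.append(summ.driven_rate)
    vs, ei, n = pooled_metrics(spikes_all, protocol)
    srs = np.asarray(srs)
    return {
        "w": float(w),
        "sr": float(np.mean(srs)),
        "sr_se": float(np.std(srs, ddof=1) / math.sqrt(len(srs)))
        if len(srs) > 1 else math.nan,
        "vs": vs,
        "ei": ei,
        "driven_rate": float(np.mean(drs)),
        "n_spikes": int(n),
        "n_seeds": len(seeds),
    }


def scan_weights(
    synapse_template: SynapseParams,
    n_inputs: int,
    protocol: ToneProtocol,
    w_grid,
    seed: int = 0,
    n_seeds: int = 5,
    anf: ANFParams | None = None,
    soma: SomaParams | None = None,
    dt: float = DEFAULT_DT,
) -> pd.DataFrame:
    """Map weight -> (SR, VS, EI, driven rate), averaged over seeds.

    The same fiber realizations (derived sub-seeds) are reused for every
    weight, so monotone trends in ``w`` are not masked by sampling noise.
    """
    w_grid = np.sort(np.asarray(w_grid, dtype=float))
    if w_grid.size < 3:
        raise ValueError("w_grid needs at least 3 points")
    if n_seeds < 1:
        raise ValueError("need at least one seed")
    anf = anf or ANFParams()
    soma = soma or SomaParams()
    seeds = [_seed_for(seed, 101, i) for i in range(n_seeds)]
    rows = []
    for w in w_grid:
        try:
            rows.append(_evaluate_weight(protocol, synapse_template, n_inputs,
                                         anf, soma, w, seeds, dt))
        except Exception as exc:
            raise RuntimeError(
                f"simulation failed at w = {w} nS (seed block {seed})") from exc
    return pd.DataFrame(rows)


def optimal_weight(
    scan: pd.DataFrame,
    target: FitTarget,
    sr_fn=None,
    refine_tol: float = 0.5,
    max_refine: int = 8,
):
    """Select the weight whose spontaneous rate is closest to the target.

    ``scan`` must bracket the target SR.  If ``sr_fn`` (weight -> mean SR,
    same seeds as the scan) is given, one bisection pass refines between the
    bracketing grid points until ``|SR - sr_t| < refine_tol`` or
    ``max_refine`` evaluations.  Ties break toward the smaller weight.

    Returns ``(w_o, info)`` where ``info`` holds the SR at ``w_o`` and the
    refinement path.
    """
    scan = scan.sort_values("w", kind="stable").reset_index(drop=True)
    w = scan["w"].to_numpy()
    sr = scan["sr"].to_numpy()
    sr_t = target.sr_t
    if np.nanmin(sr) > sr_t or np.nanmax(sr) < sr_t:
        raise NotBracketedError(
            f"target SR {sr_t} spikes/s not bracketed by scanned SRs "
            f"[{np.nanmin(sr):.2f}, {np.nanmax(sr):.2f}]; extend the weight grid")

    cand = [(float(wi), float(si)) for wi, si in zip(w, sr)]
    best = min(cand, key=lambda c: (abs(c[1] - sr_t), c[0]))
    path = []

    if sr_fn is not None and abs(best[1] - sr_t) >= refine_tol:
        # interval across which SR crosses the target (first crossing; SR is
        # monotone in w up to sampling noise)
        lo = hi = None
        for a in range(len(w) - 1):
            if (sr[a] - sr_t) * (sr[a + 1] - sr_t) <= 0:
                lo, hi = a, a + 1
                break
        if lo is not None:
            w_lo, w_hi = w[lo], w[hi]
            s_lo, s_hi = sr[lo], sr[hi]
            for _ in range(max_refine):
                w_mid = math.sqrt(w_lo * w_hi) if w_lo > 0 else 0.5 * (w_lo + w_hi)
                s_mid = float(sr_fn(w_mid))
                path.append((w_mid, s_mid))
                cand.append((w_mid, s_mid))
                if abs(s_mid - sr_t) < refine_tol:
                    break
                if (s_lo - sr_t) * (s_mid - sr_t) <= 0:
                    w_hi, s_hi = w_mid, s_mid
                else:
                    w_lo, s_lo = w_mid, s_mid
        best = min(cand, key=lambda c: (abs(c[1] - sr_t), c[0]))

    info = {"sr_at_w": best[1], "refine_path": path,
            "n_evaluations": len(cand)}
    return best[0], info


# ----------------------------------------------------------------------
EI_FIT_TOLERANCE = 0.01

N_INPUTS_MIN, N_INPUTS_MAX = 10, 70


def fit_num_inputs(
    synapse_template: SynapseParams,
    cf: float,
    ei_ref: float,
    n_range,
    target: FitTarget | None = None,
    protocol: ToneProtocol | None = None,
    anf: ANFParams | None = None,
    soma: SomaParams | None = None,
    profile="desk",
    seed: int = 0,
    dt: float = DEFAULT_DT,
) -> int | None:
    """Smallest number of converging fibers reaching a reference entrainment.

    For each candidate N (ascending) the synaptic weight is first fitted to
    the target spontaneous rate, then the entrainment of the fitted cell is
    measured on fresh seeds; the first N whose EI reaches
    ``ei_ref - EI_FIT_TOLERANCE`` is returned.  ``None`` means not fittable
    within the anatomical range.
    """
    from .model import BushyCell  # local import: model builds on this module

    n_range = sorted(int(n) for n in n_range)
    if not n_range:
        raise ValueError("empty n_range")
    if n_range[0] < N_INPUTS_MIN or n_range[-1] > N_INPUTS_MAX:
        raise ValueError(
            f"n_range must lie within [{N_INPUTS_MIN}, {N_INPUTS_MAX}]")
    target = target or FitTarget(cf=cf)
    if ei_ref > 1.0:
        return None  # EI is bounded by 1; no cell can reach it
    protocol = protocol or ToneProtocol.sweep_train(cf)
    prof = get_profile(profile)
    for n in n_range:
        cell = BushyCell(protocol, synapse_template, n_inputs=n, anf=anf,
                         soma=soma, target_sr=target.sr_t, dt=dt)
        try:
            fit = cell.fit(seed=seed, profile=prof)
        except NotBracketedError:
            continue
        check = fit.validate(seed=seed)
        ei = check["ei"]
        if not math.isnan(ei) and ei >= ei_ref - EI_FIT_TOLERANCE:
            return n
    return None
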