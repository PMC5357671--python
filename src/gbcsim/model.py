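"""Model/results interface for a single globular bushy cell.

:class:`BushyCell` bundles the pieces of one simulated cell — a tone
protocol, a synapse type, the number of converging auditory-nerve fibers,
fiber statistics and soma parameters — and exposes ``fit()`` in the style of
statistical modelling packages: the free parameter (the shared synaptic
weight ``w``) is estimated against the target spontaneous rate, and a
results object carries the estimate, the weight scan it came from,
validation diagnostics and a ``summary()`` table.

Example
-------
>>> from gbcsim import BushyCell, SynapseParams, ToneProtocol
>>> cell = BushyCell(ToneProtocol.fitting_train(500.0, n_repetitions=30),
...                  SynapseParams.depressing(10.0), n_inputs=40)
>>> fit = cell.fit(seed=1, profile="desk")
>>> print(fit.summary())                        # doctest: +SKIP
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anf import ANFParams, generate_population
from .fitting import (FitProfile, FitTarget, get_profile, optimal_weight,
                      scan_weights, simulate_cell, _evaluate_weight,
                      _seed_for)
from .metrics import ResponseSummary, summarize_response
from .protocols import ToneProtocol
from .soma import DEFAULT_DT, SimResult, SomaParams, simulate
from .synapse import SynapseParams, depression_level

__all__ = ["BushyCell", "BushyCellFitResult"]


class BushyCell:
    """A globular bushy cell model with N identical endbulb synapses.

    Parameters
    ----------
    protocol : ToneProtocol
        Stimulation protocol used for fitting and simulation.
    synapse : SynapseParams
        Synapse template; its weight ``w`` is the parameter being fitted
        (all synapses of the cell share one weight).
    n_inputs : int
        Number of converging auditory-nerve fibers.
    anf : ANFParams, optional
        Statistics of the surrogate fibers (high-spontaneous-rate defaults).
    soma : SomaParams, optional
        Membrane parameters.
    target_sr : float
        Target spontaneous rate in spikes/s.
    dt : float
        Integration step in seconds.
    """

    def __init__(self, protocol: ToneProtocol, synapse: SynapseParams,
                 n_inputs: int = 40, anf: ANFParams | None = None,
                 soma: SomaParams | None = None, target_sr: float = 7.5,
                 dt: float = DEFAULT_DT,
                 fit_protocol: ToneProtocol | None = None):
        if n_inputs < 1:
            raise ValueError("n_inputs must be >= 1")
        if fit_protocol is not None and fit_protocol.cf != protocol.cf:
            raise ValueError("fit_protocol must share the protocol's CF")
        self.protocol = protocol
        self.fit_protocol = fit_protocol
        self.synapse = synapse
        self.n_inputs = int(n_inputs)
        self.anf = anf or ANFParams()
        self.soma = soma or SomaParams()
        self.target_sr = float(target_sr)
        self.dt = float(dt)

    # ------------------------------------------------------------------
    def _protocol_with(self, n_repetitions: int | None) -> ToneProtocol:
        if n_repetitions is None:
            return self.protocol
        return self.protocol.with_repetitions(n_repetitions)

    def simulate(self, w: float, seed=0,
                 n_repetitions: int | None = None) -> SimResult:
        """Full membrane simulation at weight ``w`` (voltage trace included)."""
        proto = self._protocol_with(n_repetitions)
        fibers = generate_population(proto, self.anf, self.n_inputs, seed)
        syn = self.synapse.with_weight(float(w))
        return simulate(self.soma, [syn] * self.n_inputs, fibers,
                        t_end=proto.duration, dt=self.dt)

    def response(self, w: float, seed=0,
                 n_repetitions: int | None = None) -> ResponseSummary:
        """Response metrics at weight ``w`` for one seed."""
        proto = self._protocol_with(n_repetitions)
        _, summ = simulate_cell(proto, self.synapse.with_weight(float(w)),
                                self.n_inputs, self.anf, self.soma, seed,
                                dt=self.dt)
        return summ

    # ------------------------------------------------------------------
    def fit(self, seed: int = 0, profile="full",
            w_grid=None) -> "BushyCellFitResult":
        """Fit the shared synaptic weight to the target spontaneous rate.

        Scans a logarithmic weight grid (metrics averaged over the
        profile's scan seeds, identical fiber realizations across weights),
        then refines by bisection between the bracketing grid points.
        """
        prof = get_profile(profile)
        base = self.fit_protocol if self.fit_protocol is not None else self.protocol
        proto = base if prof.scan_repetitions is None \
            else base.with_repetitions(prof.scan_repetitions)
        if w_grid is None:
            w_grid = prof.w_grid()
        scan = scan_weights(self.synapse, self.n_inputs, proto, w_grid,
                            seed=seed, n_seeds=prof.n_scan_seeds,
                            anf=self.anf, soma=self.soma, dt=self.dt)
        seeds = [_seed_for(seed, 101, i) for i in range(prof.n_scan_seeds)]

        def sr_fn(w):
            return _evaluate_weight(proto, self.synapse, self.n_inputs,
                                    self.anf, self.soma, w, seeds,
                                    self.dt)["sr"]

        w_o, info = optimal_weight(scan, FitTarget(sr_t=self.target_sr,
                                                   cf=self.protocol.cf),
                                   sr_fn=sr_fn, refine_tol=prof.refine_tol,
                                   max_refine=prof.max_refine)
        return BushyCellFitResult(model=self, w_opt=float(w_o), scan=scan,
                                  seed=int(seed), profile=prof,
                                  sr_at_fit=float(info["sr_at_w"]),
                                  refine_path=list(info["refine_path"]))


@dataclass
class BushyCellFitResult:
    """Result of a synaptic-weight fit.

    Attributes
    ----------
    w_opt : float
        Fitted shared peak synaptic conductance (nS).
    scan : pandas.DataFrame
        Weight scan: one row per scanned weight with SR, VS, EI, driven rate.
    sr_at_fit : float
        Mean spontaneous rate at ``w_opt`` during fitting (spikes/s).
    """

    model: BushyCell
    w_opt: float
    scan: pd.DataFrame
    seed: int
    profile: FitProfile
    sr_at_fit: float
    refine_path: list = field(default_factory=list)
    _validation: dict | None = None

    # ------------------------------------------------------------------
    def validate(self, seed: int | None = None,
                 n_seeds: int | None = None,
                 n_repetitions: int | None = None) -> dict:
        """Re-simulate at the fitted weight with seeds unseen during fitting.

        Returns pooled metrics: ``{"sr", "vs", "ei", "driven_rate",
        "n_seeds", "n_spikes"}``.
        """
        from .metrics import pooled_metrics
        prof = self.profile
        seed = self.seed if seed is None else seed
        n_seeds = prof.n_validate_seeds if n_seeds is None else n_seeds
        reps = prof.validate_repetitions if n_repetitions is None else n_repetitions
        proto = self.model._protocol_with(reps)
        syn = self.model.synapse.with_weight(self.w_opt)
        spikes_all, srs, drs = [], [], []
        for i in range(n_seeds):
            ss = _seed_for(seed, 977, i)  # disjoint namespace from scan seeds
            spikes, summ = simulate_cell(proto, syn, self.model.n_inputs,
                                         self.model.anf, self.model.soma,
                                         ss, dt=self.model.dt)
            spikes_all.append(spikes)
            srs.append(summ.sr)
            drs.append(summ.driven_rate)
        vs, ei, n = pooled_metrics(spikes_all, proto)
        out = {"sr": float(np.mean(srs)), "vs": vs, "ei": ei,
               "driven_rate": float(np.mean(drs)), "n_seeds": n_seeds,
               "n_spikes": int(n)}
        self._validation = out
        return out

    # ------------------------------------------------------------------
    def summary(self) -> str:
        """Human-readable summary table of the fit."""
        m = self.model
        syn = m.synapse
        try:
            x_pct = depression_level(syn)
        except Exception:
            x_pct = math.nan
        lines = [
            "Bushy cell synaptic-weight fit",
            "=" * 46,
            f"{'Synapse kind':<28}{syn.kind}",
            f"{'Depression level':<28}{x_pct:.1f} %",
            f"{'ANF inputs (N)':<28}{m.n_inputs}",
            f"{'CF':<28}{m.protocol.cf:.0f} Hz",
            f"{'Target SR':<28}{m.target_sr:.1f} spikes/s",
            "-" * 46,
            f"{'Fitted weight w_o':<28}{self.w_opt:.3f} nS",
            f"{'SR at fit':<28}{self.sr_at_fit:.2f} spikes/s",
            f"{'Scan points':<28}{len(self.scan)}"
            f" (+{len(self.refine_path)} refinements)",
        ]
        if self._validation:
            v = self._validation
            lines += [
                "-" * 46,
                f"{'Validation SR':<28}{v['sr']:.2f} spikes/s"
                f"  ({v['n_seeds']} fresh seeds)",
                f"{'Vector strength':<28}{v['vs']:.3f}",
                f"{'Entrainment index':<28}{v['ei']:.3f}",
                f"{'Driven rate':<28}{v['driven_rate']:.1f} spikes/s",
            ]
        lines.append("=" * 46)
        return "\n".join(lines)

    def plot_scan(self, ax=None):
        """Plot SR, EI and VS against the scanned weight (convenience)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        s = self.scan
        ax.plot(s["w"], s["sr"], "o-", label="SR (spikes/s)")
        ax2 = ax.twinx()
        ax2.plot(s["w"], s["vs"], "s--", color="C1", label="VS")
        ax2.plot(s["w"], s["ei"], "^--", color="C2", label="EI")
        ax.axhline(self.model.target_sr, color="k", ls=":", lw=0.8)
        ax.axvline(self.w_opt, color="r", ls=":", lw=0.8)
        ax.set_xscale("log")
        ax.set_xlabel("synaptic weight w (nS)")
        ax.set_ylabel("SR (spikes/s)")
        ax2.set_ylabel("VS / EI")
        h1, l1 = ax.get_legend_handles_labels()
        h2, l2 = ax2.get_legend_handles_labels()
        ax.legend(h1 + h2, l1 + l2, loc="upper left", fontsize=8)
        return ax
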