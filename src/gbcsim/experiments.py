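"""Orchestration of the result sweeps.

Three experiments map the parameter space of the bushy-cell model onto tidy
result tables:

* **depression sweep** — fixed fiber count, depression level x CF grid
  (plus the tonic and the in-vitro-fitted double-exponential synapse):
  how does short-term depression shape phase locking and entrainment?
* **convergence sweep** — fixed synapse type, fiber count x CF grid:
  how does the number of converging fibers shape them?
* **EI point fitting** — for user-supplied (CF, entrainment) reference
  points, the smallest fiber count that lets each synapse type reach the
  reference entrainment, or "not fittable".

Every grid cell re-fits the synaptic weight to the target spontaneous rate
before measuring.  Failed cells appear as flagged rows, never silently
dropped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anf import ANFParams, generate_population
from .fitting import (EI_FIT_TOLERANCE, FitTarget, NotBracketedError,
                      fit_num_inputs, get_profile, _seed_for)
from .metrics import pooled_metrics
from .model import BushyCell
from .protocols import ToneProtocol
from .soma import SomaParams, measure_refractory_period
from .synapse import SynapseParams

__all__ = [
    "SweepConfig",
    "synapse_variants",
    "anf_reference_vs",
    "run_depression_sweep",
    "run_convergence_sweep",
    "run_ei_point_fitting",
    "TRANSITION_REGION_CF",
]

log = logging.getLogger("gbcsim")

#: CF above which entrainment degrades and the synapse models diverge (Hz)
TRANSITION_REGION_CF = 500.0

DEFAULT_CF_GRID = (125.0, 200.0, 300.0, 450.0, 650.0, 1000.0, 1500.0, 3000.0)


@dataclass(frozen=True)
class SweepConfig:
    """Grids and conditions of the result sweeps."""

    cf_list: tuple = DEFAULT_CF_GRID
    depression_list: tuple = (0.0, 10.0, 20.0, 30.0, 50.0, 70.0)
    n_inputs_list: tuple = (20, 30, 40, 50)
    n_inputs: int = 40                  # fixed N of the depression sweep
    depression_x: float = 10.0          # fixed synapse of the convergence sweep
    include_tonic: bool = True
    include_yang: bool = True
    target_sr: float = 7.5
    tone_duration: float = 0.050
    level_db: float = 60.0
    repetition_period: float = 0.100
    profile: str = "desk"
    anf: ANFParams | None = None
    soma: SomaParams | None = None

    def __post_init__(self):
        if any(not (0.0 <= x < 100.0) for x in self.depression_list):
            raise ValueError("depression levels must be in [0, 100)")
        if any(not (10 <= n <= 70) for n in self.n_inputs_list):
            raise ValueError("n_inputs must be within [10, 70]")

    def protocol(self, cf: float) -> ToneProtocol:
        prof = get_profile(self.profile)
        n_rep = prof.scan_repetitions or 100
        return ToneProtocol(cf=cf, level_db=self.level_db,
                            tone_duration=self.tone_duration,
                            repetition_period=self.repetition_period,
                            n_repetitions=n_rep)


def synapse_variants(config: SweepConfig) -> list[tuple[str, float, SynapseParams]]:
    """(label, depression %, synapse template) for every configured type."""
    out = []
    if config.include_tonic:
        out.append(("tonic", 0.0, SynapseParams.tonic()))
    for x in config.depression_list:
        out.append((f"{x:g}%-depressing", float(x), SynapseParams.depressing(x)))
    if config.include_yang:
        from .synapse import depression_level
        yang = SynapseParams.yang2009mean()
        out.append(("yang2009mean", depression_level(yang), yang))
    return out


def anf_reference_vs(cf: float, config: SweepConfig, seed: int,
                     n_fibers: int = 10) -> float:
    """Pooled vector strength of the surrogate fibers themselves at a CF."""
    proto = config.protocol(cf)
    anf = config.anf or ANFParams()
    fibers = generate_population(proto, anf, n_fibers, _seed_for(seed, 555))
    vs, _, _ = pooled_metrics([f.times for f in fibers], proto)
    return vs


# ----------------------------------------------------------------------
def _fit_cell(config: SweepConfig, synapse: SynapseParams, n_inputs: int,
              cf: float, seed: int):
    cell = BushyCell(config.protocol(cf), synapse, n_inputs=n_inputs,
                     anf=config.anf, soma=config.soma,
                     target_sr=config.target_sr,
                     fit_protocol=ToneProtocol.fitting_train(cf))
    fit = cell.fit(seed=seed, profile=config.profile)
    check = fit.validate(seed=seed)
    return fit, check


def _sweep(config: SweepConfig, cells, seed: int) -> pd.DataFrame:
    """Run (label, x_percent, synapse, n_inputs, cf) cells into a tidy table."""
    rows = []
    for label, x_pct, syn, n_inputs, cf in cells:
        row = {"synapse": label, "x_percent": x_pct, "n_inputs": n_inputs,
               "cf": cf, "seed": seed, "status": "ok",
               "w_opt": math.nan, "sr": math.nan, "vs": math.nan,
               "ei": math.nan, "driven_rate": math.nan}
        try:
            fit, check = _fit_cell(config, syn, n_inputs, cf, seed)
            row.update(w_opt=fit.w_opt, sr=check["sr"], vs=check["vs"],
                       ei=check["ei"], driven_rate=check["driven_rate"])
        except NotBracketedError as exc:
            row["status"] = f"not-bracketed: {exc}"
        except Exception as exc:  # flagged, not silently skipped
            row["status"] = f"failed: {exc}"
        log.info("cell %s N=%d cf=%g: status=%s w=%.3g sr=%.3g vs=%.3g ei=%.3g",
                 label, n_inputs, cf, row["status"], row["w_opt"],
                 row["sr"], row["vs"], row["ei"])
        rows.append(row)
    return pd.DataFrame(rows)


def run_depression_sweep(config: SweepConfig, seed: int = 0) -> pd.DataFrame:
    """Depression level x CF sweep at a fixed number of fiber inputs."""
    cells = [(label, x, syn, config.n_inputs, cf)
             for label, x, syn in synapse_variants(config)
             for cf in config.cf_list]
    return _sweep(config, cells, seed)


def run_convergence_sweep(config: SweepConfig, seed: int = 0) -> pd.DataFrame:
    """Fiber count x CF sweep at a fixed synapse type.

    The output includes the fibers' own pooled vector strength (``anf_vs``)
    for comparison with the cell's.
    """
    syn = SynapseParams.depressing(config.depression_x)
    label = f"{config.depression_x:g}%-depressing"
    cells = [(label, config.depression_x, syn, n, cf)
             for n in config.n_inputs_list for cf in config.cf_list]
    df = _sweep(config, cells, seed)
    ref = {cf: anf_reference_vs(cf, config, seed) for cf in config.cf_list}
    df["anf_vs"] = df["cf"].map(ref)
    return df


def run_ei_point_fitting(points: pd.DataFrame, config: SweepConfig,
                         seed: int = 0,
                         n_grid=(10, 20, 30, 40, 50, 60, 70)) -> pd.DataFrame:
    """Fit the fiber count to each (CF, EI) reference point, per synapse type.

    Returns one row per (point, synapse type) with the smallest sufficient
    fiber count in ``n_fit`` (NaN where no fit is possible) and a boolean
    ``fittable`` column.
    """
    rows = []
    for _, pt in points.iterrows():
        cf, ei_ref = float(pt["cf_hz"]), float(pt["ei"])
        for label, x_pct, syn in synapse_variants(config):
            if ei_ref > 1.0 + EI_FIT_TOLERANCE:
                n_fit = None
            else:
                n_fit = fit_num_inputs(
                    syn, cf, ei_ref, n_grid,
                    target=FitTarget(sr_t=config.target_sr, cf=cf,
                                     ei_ref=ei_ref),
                    protocol=config.protocol(cf), anf=config.anf,
                    soma=config.soma, profile=config.profile, seed=seed)
            rows.append({"cf": cf, "ei_ref": ei_ref, "synapse": label,
                         "x_percent": x_pct,
                         "n_fit": math.nan if n_fit is None else n_fit,
                         "fittable": n_fit is not None, "seed": seed})
            log.info("point cf=%g ei=%.3f %s: %s", cf, ei_ref, label,
                     n_fit if n_fit is not None else "not fittable")
    return pd.DataFrame(rows)
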