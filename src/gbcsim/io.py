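"""File formats: spike-time CSV, response tables, and YAML configs.

Spike trains travel as CSV with columns ``fiber_id, spike_time_s`` (one
header line, times printed with microsecond precision).  Configurations are
YAML mappings with ``protocol``, ``anf``, ``synapse``, ``soma`` and ``fit``
sections that round-trip through the parameter dataclasses.
"""

from __future__ import annotations

import pathlib

import numpy as np
import pandas as pd
import yaml

from .anf import ANFParams, SpikeTrain
from .protocols import ToneProtocol
from .soma import SomaParams
from .synapse import SynapseParams

__all__ = [
    "write_spike_csv",
    "read_spike_csv",
    "write_event_log_csv",
    "load_config",
    "save_config",
    "read_ei_reference_csv",
]


def write_spike_csv(path, trains: list[SpikeTrain]) -> None:
    """Write spike trains as ``fiber_id, spike_time_s`` rows."""
    rows = []
    for i, tr in enumerate(trains):
        fid = tr.meta.get("fiber_id", i)
        for t in tr.times:
            rows.append((fid, t))
    df = pd.DataFrame(rows, columns=["fiber_id", "spike_time_s"])
    df.to_csv(path, index=False, float_format="%.6f")


def read_spike_csv(path, duration: float | None = None) -> list[SpikeTrain]:
    """Read spike trains; one :class:`SpikeTrain` per distinct fiber_id."""
    df = pd.read_csv(path)
    required = {"fiber_id", "spike_time_s"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}, "
                         f"found {list(df.columns)}")
    if duration is None:
        duration = float(df["spike_time_s"].max()) if len(df) else 0.0
    trains = []
    for fid, grp in df.groupby("fiber_id", sort=True):
        times = np.sort(grp["spike_time_s"].to_numpy(dtype=float))
        trains.append(SpikeTrain(times, duration,
                                 {"fiber_id": fid, "source": str(path)}))
    return trains


def read_ei_reference_csv(path) -> pd.DataFrame:
    """Read (cf_hz, ei) reference points for the per-point input-count fit."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["cf_hz", "ei"])
    required = {"cf_hz", "ei"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    for line_no, (_, row) in enumerate(df.iterrows(), start=2):
        if not (row["cf_hz"] > 0) or not (0.0 <= row["ei"] <= 1.0):
            raise ValueError(f"{path}, line {line_no}: invalid reference "
                             f"point (cf={row['cf_hz']}, ei={row['ei']})")
    return df[["cf_hz", "ei"]].astype(float)


def write_event_log_csv(path, event_logs) -> None:
    """Dump per-synapse delivered-conductance events for debugging.

    ``event_logs`` is the ``g_syn_events`` attribute of a simulation run
    with ``record_syn_events=True``: one ``(times, conductances)`` pair per
    synapse.  Columns: ``synapse_id, event_time_s, g_nS``.
    """
    rows = []
    for sid, (times, gs) in enumerate(event_logs):
        for t, g in zip(times, gs):
            rows.append((sid, t, g))
    df = pd.DataFrame(rows, columns=["synapse_id", "event_time_s", "g_nS"])
    df.to_csv(path, index=False, float_format="%.6f")


# ----------------------------------------------------------------------
_SECTIONS = {
    "protocol": ToneProtocol,
    "anf": ANFParams,
    "synapse": SynapseParams,
    "soma": SomaParams,
}


def load_config(path) -> dict:
    """Load a YAML config into parameter objects.

    Known sections are instantiated as their dataclasses; unknown sections
    (e.g. ``fit``, ``sweep``) pass through as plain dicts.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out = {}
    for key, val in raw.items():
        cls = _SECTIONS.get(key)
        if cls is not None and isinstance(val, dict):
            if key == "synapse":
                val = dict(val)
                x = val.pop("x_percent", None)
                if x is not None and val.get("kind", "single_exp") == "single_exp":
                    out[key] = SynapseParams.depressing(
                        float(x), **{k: v for k, v in val.items() if k != "kind"})
                    continue
            out[key] = cls.from_dict(val)
        else:
            out[key] = val
    return out


def save_config(path, config: dict) -> None:
    """Write parameter objects / dicts back to YAML (round-trippable)."""
    raw = {}
    for key, val in config.items():
        raw[key] = val.to_dict() if hasattr(val, "to_dict") else val
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
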