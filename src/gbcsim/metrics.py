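"""Response metrics: vector strength, entrainment index, firing rates.

Vector strength (VS) treats every spike as a unit vector at the stimulus
phase at which it occurred; VS is the length of the mean resultant,

    VS = | sum_j exp(i 2 pi f t_j) | / n,

1 for perfect phase locking, 0 for uniformly distributed phases.

The entrainment index (EI) asks whether the cell fired at least once per
stimulus cycle: inter-spike intervals are collected within each analysis
window (never across windows) and EI is the fraction falling within the
first-maximum band [0.5 T, 1.5 T] of the stimulus period T.

Metrics that cannot be computed (no spikes, fewer than two spikes) are
reported as NaN, never as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .protocols import ToneProtocol

__all__ = [
    "ResponseSummary",
    "vector_strength",
    "entrainment_index",
    "firing_rates",
    "summarize_response",
    "pooled_metrics",
]

DRIVEN_ONSET_GUARD = 0.010   # s excluded from driven-rate windows
SR_POST_OFFSET_GUARD = 0.020  # s excluded after each tone offset


@dataclass(frozen=True)
class ResponseSummary:
    """Summary of one simulated cell's response to a tone train."""

    vs: float            # vector strength, [0, 1] or NaN
    ei: float            # entrainment index, [0, 1] or NaN
    sr: float            # spontaneous rate in the silent gaps (spikes/s)
    driven_rate: float   # rate within tones, onset excluded (spikes/s)
    n_spikes_analyzed: int


def _in_windows(times: np.ndarray, windows) -> np.ndarray:
    mask = np.zeros(times.shape, dtype=bool)
    for a, b in windows:
        mask |= (times >= a) & (times <= b)
    return mask


def vector_strength(spikes, stimulus_frequency: float, windows=None) -> float:
    """Vector strength of spikes relative to a stimulus frequency (Hz)."""
    if stimulus_frequency <= 0:
        raise ValueError("stimulus_frequency must be > 0")
    t = np.asarray(spikes, dtype=float)
    if windows is not None:
        t = t[_in_windows(t, windows)]
    if t.size == 0:
        return math.nan
    phase = 2.0 * np.pi * stimulus_frequency * t
    return float(np.hypot(np.cos(phase).sum(), np.sin(phase).sum()) / t.size)


def entrainment_index(spikes, stimulus_frequency: float, windows=None) -> float:
    """Fraction of inter-spike intervals within [0.5 T, 1.5 T].

    Intervals are formed within each window separately; NaN if fewer than
    two spikes fall in any single window.
    """
    if stimulus_frequency <= 0:
        raise ValueError("stimulus_frequency must be > 0")
    t = np.asarray(spikes, dtype=float)
    period = 1.0 / stimulus_frequency
    if windows is None:
        windows = [(-np.inf, np.inf)]
    intervals = []
    for a, b in windows:
        w = t[(t >= a) & (t <= b)]
        if w.size >= 2:
            intervals.append(np.diff(w))
    if not intervals:
        return math.nan
    isi = np.concatenate(intervals)
    k = np.count_nonzero((isi >= 0.5 * period) & (isi <= 1.5 * period))
    return k / isi.size


def firing_rates(
    spikes,
    protocol: ToneProtocol,
    onset_guard: float = DRIVEN_ONSET_GUARD,
    post_offset_guard: float = SR_POST_OFFSET_GUARD,
) -> tuple[float, float]:
    """(spontaneous rate, driven rate) of a response to a tone train.

    The spontaneous rate is measured in the silent gaps, excluding a
    post-offset guard during which adaptation recovery contaminates the gap;
    the driven rate within tones, excluding an onset guard.
    """
    t = np.asarray(spikes, dtype=float)
    silence = protocol.silence_windows(post_offset_guard)
    tones = protocol.tone_windows(onset_guard)
    t_sil = sum(b - a for a, b in silence)
    t_tone = sum(b - a for a, b in tones)
    if t_sil <= 0 and t_tone <= 0:
        raise ValueError("protocol has no analyzable time")
    sr = np.count_nonzero(_in_windows(t, silence)) / t_sil if t_sil > 0 else math.nan
    dr = np.count_nonzero(_in_windows(t, tones)) / t_tone if t_tone > 0 else math.nan
    return sr, dr


def summarize_response(
    spikes,
    protocol: ToneProtocol,
    vs_ei_onset_exclusion: float = 0.0,
) -> ResponseSummary:
    """Compute VS, EI and rates of one response under a tone protocol.

    VS and EI use the full tone windows by default (``vs_ei_onset_exclusion``
    trims them); the driven-rate estimate always excludes its onset guard.
    """
    t = np.asarray(spikes, dtype=float)
    wins = protocol.tone_windows(vs_ei_onset_exclusion)
    vs = vector_strength(t, protocol.cf, wins)
    ei = entrainment_index(t, protocol.cf, wins)
    sr, dr = firing_rates(t, protocol)
    n = int(np.count_nonzero(_in_windows(t, wins)))
    return ResponseSummary(vs=vs, ei=ei, sr=sr, driven_rate=dr,
                           n_spikes_analyzed=n)


def pooled_metrics(
    spike_arrays,
    protocol: ToneProtocol,
    vs_ei_onset_exclusion: float = 0.0,
) -> tuple[float, float, int]:
    """(VS, EI, n spikes) pooled across repeated runs of the same protocol.

    VS pools the resultant vectors of all runs; EI pools interval counts.
    Intervals are still formed within a single run and window only.
    """
    wins = protocol.tone_windows(vs_ei_onset_exclusion)
    period = 1.0 / protocol.cf
    cx = sx = 0.0
    n_vs = 0
    k_ei = n_ei = 0
    for spikes in spike_arrays:
        t = np.asarray(spikes, dtype=float)
        t = t[_in_windows(t, wins)]
        phase = 2.0 * np.pi * protocol.cf * t
        cx += np.cos(phase).sum()
        sx += np.sin(phase).sum()
        n_vs += t.size
        for a, b in wins:
            w = t[(t >= a) & (t <= b)]
            if w.size >= 2:
                isi = np.diff(w)
                k_ei += int(np.count_nonzero(
                    (isi >= 0.5 * period) & (isi <= 1.5 * period)))
                n_ei += isi.size
    vs = math.hypot(cx, sx) / n_vs if n_vs else math.nan
    ei = k_ei / n_ei if n_ei else math.nan
    return vs, ei, n_vs
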