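"""Tone-train stimulation protocols.

A globular bushy cell is characterized *in vivo* with trains of short pure
tones at the unit's characteristic frequency (CF), repeated at a fixed period
so that spontaneous activity can be measured in the silent gaps between tones.
:class:`ToneProtocol` describes such a train; all times are in seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace, asdict


@dataclass(frozen=True)
class ToneProtocol:
    """A train of gated pure tones at a cell's characteristic frequency.

    Parameters
    ----------
    cf : float
        Tone (= characteristic) frequency in Hz.
    level_db : float
        Sound level in dB SPL.  The surrogate fiber model maps level to a
        steady-state driven rate (see :class:`gbcsim.anf.ANFParams`).
    tone_duration : float
        Duration of each tone burst in seconds, ramps included.
    repetition_period : float
        Onset-to-onset period of the train in seconds.
    n_repetitions : int
        Number of tone bursts.  Zero means silence (spontaneous activity
        only); callers must then supply an explicit duration where needed.
    ramp_duration : float
        Duration of the cosine-squared on/off ramps in seconds.
    """

    cf: float
    level_db: float = 50.0
    tone_duration: float = 0.025
    repetition_period: float = 0.100
    n_repetitions: int = 100
    ramp_duration: float = 0.0025

    #: post-offset guard used when carving silence windows (s); adaptation
    #: recovery contaminates the early part of each gap
    POST_OFFSET_GUARD = 0.020

    def __post_init__(self) -> None:
        if not (self.cf > 0) or not math.isfinite(self.cf):
            raise ValueError(f"cf must be a positive frequency, got {self.cf}")
        if self.n_repetitions < 0:
            raise ValueError("n_repetitions must be >= 0")
        if self.n_repetitions > 0:
            if self.tone_duration <= 0 or self.repetition_period <= 0:
                raise ValueError("tone_duration and repetition_period must be > 0")
            if self.tone_duration + 2 * self.POST_OFFSET_GUARD >= self.repetition_period:
                raise ValueError(
                    "tone_duration plus guards must fit inside repetition_period "
                    f"({self.tone_duration} + 2*{self.POST_OFFSET_GUARD} >= "
                    f"{self.repetition_period})"
                )
            if 2 * self.ramp_duration > self.tone_duration:
                raise ValueError("ramps longer than the tone itself")

    # ------------------------------------------------------------------
    @property
    def duration(self) -> float:
        """Total duration of the train (s)."""
        return self.n_repetitions * self.repetition_period

    @property
    def tone_onsets(self):
        """Onset time of each tone (s)."""
        return [i * self.repetition_period for i in range(self.n_repetitions)]

    def tone_windows(self, onset_guard: float = 0.0):
        """``(start, stop)`` windows covering each tone burst.

        ``onset_guard`` trims the start of every window, e.g. to exclude the
        onset transient from driven-rate estimates.
        """
        return [
            (t0 + onset_guard, t0 + self.tone_duration)
            for t0 in self.tone_onsets
            if t0 + onset_guard < t0 + self.tone_duration
        ]

    def silence_windows(self, post_offset_guard: float | None = None):
        """``(start, stop)`` windows covering the silent gaps between tones."""
        if post_offset_guard is None:
            post_offset_guard = self.POST_OFFSET_GUARD
        wins = []
        for t0 in self.tone_onsets:
            a = t0 + self.tone_duration + post_offset_guard
            b = t0 + self.repetition_period
            if a < b:
                wins.append((a, b))
        return wins

    # ------------------------------------------------------------------
    # presets
    @classmethod
    def fitting_train(cls, cf: float, n_repetitions: int = 100) -> "ToneProtocol":
        """Weight-fitting protocol: 25 ms gated tones every 100 ms at 50 dB SPL."""
        return cls(cf=cf, level_db=50.0, tone_duration=0.025,
                   repetition_period=0.100, n_repetitions=n_repetitions)

    @classmethod
    def sweep_train(cls, cf: float, n_repetitions: int = 100) -> "ToneProtocol":
        """Result-sweep protocol: 50 ms ramped tones every 100 ms at 60 dB SPL."""
        return cls(cf=cf, level_db=60.0, tone_duration=0.050,
                   repetition_period=0.100, n_repetitions=n_repetitions)

    def with_repetitions(self, n: int) -> "ToneProtocol":
        return replace(self, n_repetitions=n)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ToneProtocol":
        return cls(**d)
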