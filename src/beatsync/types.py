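"""Core domain types for beat-keeping analysis.

The vocabulary follows the sensorimotor-synchronization literature: a
*beat grid* is the isochronous stimulus (a metronome at some tempo), a
*movement trial* is one subject's sequence of movement low points
("bobs" for a head-bobbing animal, "chops" for a human arm movement), and a
*phase series* is the per-event relative phase of each movement with respect
to its nearest beat onset, in degrees of the beat cycle.

Angles are degrees everywhere in the public API, normalized to the
half-open interval (-180, +180]; negative phase means the movement precedes
the beat (negative mean asynchrony).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .exceptions import DomainError

__all__ = [
    "GROUPS",
    "BeatGrid",
    "MovementTrial",
    "PhaseSeries",
    "TrialSummary",
    "SubjectTempoSummary",
    "AnalysisConfig",
    "make_beat_grid",
    "wrap_degrees",
]

#: Recognized subject groups.
GROUPS = ("sea_lion", "human", "simulated", "synthetic")

_GRID_TOL = 1e-9  # onsets must be isochronous to within a nanosecond


def wrap_degrees(angle):
    """Normalize angles (degrees) to the interval (-180, +180].

    Accepts scalars or arrays; +180 maps to +180, -180 maps to +180.
    """
    a = np.asarray(angle, dtype=float)
    w = np.mod(a, 360.0)
    w = np.where(w > 180.0, w - 360.0, w)
    # np.mod returns values in [0, 360); 180 stays 180 which is in range.
    if np.ndim(angle) == 0:
        return float(w)
    return w


@dataclass(frozen=True)
class BeatGrid:
    """An isochronous stimulus: equally spaced beat onsets at a fixed tempo.

    Parameters
    ----------
    tempo_bpm
        Stimulus rate in beats per minute (> 0).
    onsets_s
        Strictly increasing onset times in seconds; successive differences
        must equal ``60 / tempo_bpm`` to within 1e-9 s.
    """

    tempo_bpm: float
    onsets_s: tuple

    def __post_init__(self):
        if self.tempo_bpm <= 0:
            raise DomainError(f"tempo_bpm must be > 0, got {self.tempo_bpm}")
        onsets = tuple(float(t) for t in self.onsets_s)
        if len(onsets) < 1:
            raise DomainError("a beat grid needs at least one onset")
        object.__setattr__(self, "onsets_s", onsets)
        period = 60.0 / self.tempo_bpm
        diffs = np.diff(onsets)
        if len(diffs) and (np.any(diffs <= 0) or np.max(np.abs(diffs - period)) > _GRID_TOL):
            raise DomainError(
                "beat onsets must be strictly increasing and equally spaced "
                f"at {period:.6f} s"
            )

    @property
    def period_s(self) -> float:
        """Seconds per beat (60 / tempo)."""
        return 60.0 / self.tempo_bpm

    @property
    def n_beats(self) -> int:
        return len(self.onsets_s)

    @property
    def t0(self) -> float:
        return self.onsets_s[0]


def make_beat_grid(tempo_bpm: float, n_beats: int, t0: float = 0.0) -> BeatGrid:
    """Construct a grid of ``n_beats`` onsets at ``tempo_bpm`` starting at ``t0``.

    Onsets are ``t0 + k * (60 / tempo_bpm)`` for ``k = 0 .. n_beats - 1``.
    """
    if tempo_bpm <= 0:
        raise DomainError(f"tempo_bpm must be > 0, got {tempo_bpm}")
    if int(n_beats) != n_beats or n_beats < 1:
        raise DomainError(f"n_beats must be a positive integer, got {n_beats}")
    period = 60.0 / tempo_bpm
    onsets = tuple(t0 + k * period for k in range(int(n_beats)))
    return BeatGrid(tempo_bpm=tempo_bpm, onsets_s=onsets)


@dataclass(frozen=True)
class MovementTrial:
    """One subject's movement low-point times for one stimulus exposure."""

    subject_id: str
    group: str
    tempo_bpm: float
    trial_index: int
    event_times_s: tuple

    def __post_init__(self):
        if self.group not in GROUPS:
            raise DomainError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.tempo_bpm <= 0:
            raise DomainError("tempo_bpm must be > 0")
        if int(self.trial_index) != self.trial_index or self.trial_index < 1:
            raise DomainError("trial_index must be a positive integer")
        times = tuple(float(t) for t in self.event_times_s)
        if np.any(np.diff(times) <= 0):
            raise DomainError(
                f"event times must be strictly increasing "
                f"(subject {self.subject_id}, trial {self.trial_index})"
            )
        object.__setattr__(self, "event_times_s", times)

    @property
    def n_events(self) -> int:
        return len(self.event_times_s)


@dataclass(frozen=True)
class PhaseSeries:
    """Per-event relative phases and inter-event intervals for one trial.

    ``phases_deg[i]`` is the phase of event *i* relative to its nearest beat,
    in (-180, +180]; ``beat_index[i]`` is the (1-based) index of that beat.
    ``intervals_s`` holds successive event-time differences (length
    ``n_events - 1``). ``n_unmatched`` counts events that fell outside the
    grid (more than half a period beyond either end) and were excluded.
    """

    phases_deg: np.ndarray
    beat_index: np.ndarray
    intervals_s: np.ndarray
    n_unmatched: int = 0

    def __post_init__(self):
        phases = np.asarray(self.phases_deg, dtype=float)
        beats = np.asarray(self.beat_index, dtype=int)
        intervals = np.asarray(self.intervals_s, dtype=float)
        if phases.size and (np.any(phases <= -180.0) or np.any(phases > 180.0)):
            raise DomainError("phases must lie in (-180, +180]")
        if beats.size and np.any(np.diff(beats) < 0):
            raise DomainError("beat_index must be non-decreasing")
        object.__setattr__(self, "phases_deg", phases)
        object.__setattr__(self, "beat_index", beats)
        object.__setattr__(self, "intervals_s", intervals)

    @property
    def n_events(self) -> int:
        return int(self.phases_deg.size)


@dataclass(frozen=True)
class TrialSummary:
    """Per-trial descriptive statistics.

    ``vector_length`` is the mean resultant length R-bar of the trial's
    phases (1 = all phases identical, 0 = balanced dispersion);
    ``circ_sd_deg`` is the circular standard deviation
    ``sqrt(-2 ln R)`` expressed in degrees.
    """

    subject_id: str
    group: str
    tempo_bpm: float
    trial_index: int
    n_events: int
    mean_interval_s: float
    sd_interval_s: float
    performed_tempo_bpm: float
    sd_tempo_bpm: float
    mean_phase_deg: float
    vector_length: float
    circ_sd_deg: float

    def __post_init__(self):
        if not (0.0 <= self.vector_length <= 1.0 + 1e-12):
            raise DomainError(f"vector_length must be in [0, 1], got {self.vector_length}")


@dataclass(frozen=True)
class SubjectTempoSummary:
    """One subject's aggregate over all trials at one stimulus tempo.

    Tempo and vector length are linear averages of the trial means; the
    tempo SD pools instantaneous tempos (60/interval) over every interval
    the subject produced at that tempo; the mean phase is the circular
    average of the trial mean phases.
    """

    subject_id: str
    group: str
    tempo_bpm: float
    n_trials: int
    mean_tempo_bpm: float
    sd_tempo_bpm: float
    mean_phase_deg: float
    mean_vector_length: float


_PHASE_SIGNS = ("movement_minus_beat", "beat_minus_movement")
_TIE_RULES = ("earlier", "later")
_TEMPO_METHODS = ("mean_of_instantaneous_bpm", "reciprocal_of_mean_interval")


@dataclass
class AnalysisConfig:
    """Analysis conventions.

    phase_sign
        ``movement_minus_beat`` (default): an early movement gets a negative
        phase, matching the negative-mean-asynchrony convention.
        ``beat_minus_movement`` flips the sign.
    nearest_beat_tie
        Which beat wins when an event lies exactly half a period between
        two onsets.
    tempo_method
        ``mean_of_instantaneous_bpm`` (default): performed tempo is the
        mean of 60/interval over a trial's intervals; the alternative uses
        60 / mean(interval).
    """

    phase_sign: str = "movement_minus_beat"
    nearest_beat_tie: str = "earlier"
    tempo_method: str = "mean_of_instantaneous_bpm"
    alpha: float = 0.05
    rng_seed: int = 0

    def __post_init__(self):
        if self.phase_sign not in _PHASE_SIGNS:
            raise DomainError(f"phase_sign must be one of {_PHASE_SIGNS}")
        if self.nearest_beat_tie not in _TIE_RULES:
            raise DomainError(f"nearest_beat_tie must be one of {_TIE_RULES}")
        if self.tempo_method not in _TEMPO_METHODS:
            raise DomainError(f"tempo_method must be one of {_TEMPO_METHODS}")
        if not (0.0 < self.alpha < 1.0):
            raise DomainError("alpha must lie in (0, 1)")

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
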