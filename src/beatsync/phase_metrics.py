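"""Relative phase, interval and circular descriptive statistics.

The phase of a movement event is its angular position within the beat
cycle: with stimulus period ``dt`` and the event matched to its nearest
beat onset,

    theta = 360 * (t_event - t_beat) / dt    (degrees, wrapped to (-180, 180])

so a movement that lands just *before* the beat has a small negative phase
(negative mean asynchrony). The circular mean and mean resultant length
R-bar = |mean(exp(i * theta))| summarize a set of phases; R-bar plays the
role of an inverse dispersion (1 = perfectly repeatable phase).
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np

from .exceptions import DegenerateDirectionError, DomainError
from .types import (
    AnalysisConfig,
    BeatGrid,
    MovementTrial,
    PhaseSeries,
    SubjectTempoSummary,
    TrialSummary,
    wrap_degrees,
)

__all__ = [
    "compute_phase_series",
    "circular_mean",
    "vector_length",
    "mean_resultant",
    "circ_sd_deg",
    "summarize_trial",
    "summarize_subject",
    "grid_for_trial",
]

logger = logging.getLogger(__name__)

_RESULTANT_EPS = 1e-12


def mean_resultant(phases_deg) -> complex:
    """Mean resultant vector ``mean(exp(i*theta))`` of phases in degrees."""
    phases = np.asarray(phases_deg, dtype=float)
    if phases.size == 0:
        raise DomainError("need at least one phase")
    rad = np.deg2rad(phases)
    return complex(np.mean(np.cos(rad)), np.mean(np.sin(rad)))


def circular_mean(phases_deg) -> float:
    """Circular mean direction in degrees, in (-180, +180].

    Raises :class:`DegenerateDirectionError` when the resultant length is
    numerically zero (no defined direction, e.g. antipodal pairs).
    """
    r = mean_resultant(phases_deg)
    if abs(r) < _RESULTANT_EPS:
        raise DegenerateDirectionError(
            "mean direction undefined: resultant length is numerically zero"
        )
    return wrap_degrees(math.degrees(math.atan2(r.imag, r.real)))


def vector_length(phases_deg) -> float:
    """Mean resultant length R-bar in [0, 1]."""
    return min(abs(mean_resultant(phases_deg)), 1.0)


def circ_sd_deg(r_bar: float) -> float:
    """Circular standard deviation sqrt(-2 ln R), in degrees."""
    if not (0.0 < r_bar <= 1.0):
        raise DomainError(f"vector length must be in (0, 1], got {r_bar}")
    return math.degrees(math.sqrt(max(-2.0 * math.log(r_bar), 0.0)))


def _nearest_beat_indices(rel: np.ndarray, tie: str) -> np.ndarray:
    """Nearest integer to each value in ``rel``, ties per ``tie`` rule."""
    k = np.floor(rel + 0.5)
    frac = rel - np.floor(rel)
    ties = frac == 0.5
    if tie == "earlier":
        k = np.where(ties, np.floor(rel), k)
    return k.astype(int)


def compute_phase_series(
    trial: MovementTrial, grid: BeatGrid, cfg: AnalysisConfig | None = None
) -> PhaseSeries:
    """Match each event to its nearest beat and compute relative phases.

    Events farther than half a period outside the grid are excluded (and
    counted in ``n_unmatched``); intervals are successive differences of
    *all* the trial's event times.
    """
    cfg = cfg or AnalysisConfig()
    if trial.n_events < 1:
        raise DomainError("trial has no events")
    t = np.asarray(trial.event_times_s, dtype=float)
    period = grid.period_s
    rel = (t - grid.t0) / period
    k = _nearest_beat_indices(rel, cfg.nearest_beat_tie)
    matched = (k >= 0) & (k <= grid.n_beats - 1)
    n_unmatched = int((~matched).sum())
    if n_unmatched:
        logger.warning(
            "%d event(s) outside the beat grid excluded (subject %s, trial %d)",
            n_unmatched,
            trial.subject_id,
            trial.trial_index,
        )
    k = k[matched]
    phases = wrap_degrees(360.0 * (rel[matched] - k))
    if cfg.phase_sign == "beat_minus_movement":
        phases = wrap_degrees(-phases)
    intervals = np.diff(t)
    return PhaseSeries(
        phases_deg=np.atleast_1d(phases),
        beat_index=k + 1,
        intervals_s=intervals,
        n_unmatched=n_unmatched,
    )


def grid_for_trial(trial: MovementTrial, t0: float = 0.0) -> BeatGrid:
    """Beat grid at the trial's stimulus tempo covering all its events.

    The stimulus is assumed to start at ``t0`` (default 0); enough beats
    are generated to reach half a period past the last event.
    """
    from .types import make_beat_grid

    period = 60.0 / trial.tempo_bpm
    last = trial.event_times_s[-1]
    n = max(1, int(math.floor((last - t0) / period + 0.5)) + 1)
    return make_beat_grid(trial.tempo_bpm, n, t0)


def _instantaneous_bpm(intervals: np.ndarray) -> np.ndarray:
    return 60.0 / intervals


def _sd(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1)) if values.size >= 2 else 0.0


def summarize_trial(
    trial: MovementTrial, grid: BeatGrid, cfg: AnalysisConfig | None = None
) -> TrialSummary:
    """Per-trial mean/SD interval, performed tempo, circular phase summary."""
    cfg = cfg or AnalysisConfig()
    if trial.n_events < 2:
        raise DomainError("summarize_trial needs at least 2 events (1 interval)")
    series = compute_phase_series(trial, grid, cfg)
    intervals = series.intervals_s
    bpm = _instantaneous_bpm(intervals)
    if cfg.tempo_method == "mean_of_instantaneous_bpm":
        performed = float(np.mean(bpm))
    else:
        performed = 60.0 / float(np.mean(intervals))
    r_bar = vector_length(series.phases_deg)
    mean_phase = circular_mean(series.phases_deg)
    return TrialSummary(
        subject_id=trial.subject_id,
        group=trial.group,
        tempo_bpm=trial.tempo_bpm,
        trial_index=trial.trial_index,
        n_events=series.n_events,
        mean_interval_s=float(np.mean(intervals)),
        sd_interval_s=_sd(intervals),
        performed_tempo_bpm=performed,
        sd_tempo_bpm=_sd(bpm),
        mean_phase_deg=mean_phase,
        vector_length=r_bar,
        circ_sd_deg=circ_sd_deg(r_bar) if r_bar > 0 else float("inf"),
    )


def summarize_subject(
    trials: Sequence[MovementTrial],
    grids: Sequence[BeatGrid] | BeatGrid,
    cfg: AnalysisConfig | None = None,
) -> SubjectTempoSummary:
    """Aggregate one subject's trials at one tempo.

    Mean tempo and vector length are linear averages of the trial means;
    the tempo SD pools instantaneous bpm over every interval across the
    trials; the mean phase is the circular mean of the trial mean phases.
    """
    cfg = cfg or AnalysisConfig()
    if not trials:
        raise DomainError("need at least one trial")
    subjects = {t.subject_id for t in trials}
    tempos = {t.tempo_bpm for t in trials}
    if len(subjects) != 1 or len(tempos) != 1:
        raise DomainError("summarize_subject requires one subject at one tempo")
    if isinstance(grids, BeatGrid):
        grids = [grids] * len(trials)
    if len(grids) != len(trials):
        raise DomainError("need one grid per trial")
    summaries = [summarize_trial(t, g, cfg) for t, g in zip(trials, grids)]
    pooled_bpm = np.concatenate(
        [_instantaneous_bpm(np.diff(np.asarray(t.event_times_s))) for t in trials]
    )
    return SubjectTempoSummary(
        subject_id=trials[0].subject_id,
        group=trials[0].group,
        tempo_bpm=trials[0].tempo_bpm,
        n_trials=len(trials),
        mean_tempo_bpm=float(np.mean([s.performed_tempo_bpm for s in summaries])),
        sd_tempo_bpm=_sd(pooled_bpm),
        mean_phase_deg=circular_mean([s.mean_phase_deg for s in summaries]),
        mean_vector_length=float(np.mean([s.vector_length for s in summaries])),
    )
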