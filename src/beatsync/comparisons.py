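"""Comparison procedures: rank tables, learning checks, half-trial drift.

These mirror the descriptive comparisons a beat-keeping study makes
between a focal subject (e.g. a trained animal) and a group of humans:
rank ordering on each performance metric, first-versus-last-trial
Watson-Williams tests for a learning effect, pooled first-half versus
second-half phase comparisons for within-trial drift, and direct
subject-versus-group phase tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .circ_tests import CircTestResult, watson_williams
from .exceptions import DomainError
from .phase_metrics import circular_mean
from .types import SubjectTempoSummary, wrap_degrees

__all__ = [
    "RANK_METRICS",
    "RankEntry",
    "rank_against_humans",
    "rank_table",
    "first_vs_last_trial",
    "within_trial_halves",
    "HalvesResult",
    "subject_vs_group_phase",
]

logger = logging.getLogger(__name__)

#: Metric name -> distance-from-perfect function on a SubjectTempoSummary.
#: Perfect performance is tempo error 0, interval SD 0, |phase| 0, vector
#: length 1; smaller distance is better on every metric.
RANK_METRICS = {
    "tempo_error_bpm": lambda s: abs(s.mean_tempo_bpm - s.tempo_bpm),
    "interval_sd_bpm": lambda s: abs(s.sd_tempo_bpm),
    "abs_phase_deg": lambda s: abs(wrap_degrees(s.mean_phase_deg)),
    "vector_length": lambda s: abs(1.0 - s.mean_vector_length),
}


@dataclass(frozen=True)
class RankEntry:
    """One metric's rank comparison at one tempo."""

    metric: str
    tempo_bpm: float
    focal_value: float
    focal_distance: float
    comparator_distances: tuple
    n_beaten: int  # comparators strictly farther from perfect (ties not counted)

    @property
    def n_comparators(self) -> int:
        return len(self.comparator_distances)


def rank_against_humans(
    focal: SubjectTempoSummary,
    comparators: Sequence[SubjectTempoSummary],
    tempo_bpm: float | None = None,
) -> dict[str, RankEntry]:
    """Count, per metric, how many comparators the focal subject beats.

    A comparator is beaten only when it is *strictly* farther from perfect
    performance; ties are conservatively not counted as wins.
    """
    tempo = focal.tempo_bpm if tempo_bpm is None else tempo_bpm
    if focal.tempo_bpm != tempo or any(c.tempo_bpm != tempo for c in comparators):
        raise DomainError("all summaries must be at the same stimulus tempo")
    raw_value = {
        "tempo_error_bpm": focal.mean_tempo_bpm,
        "interval_sd_bpm": focal.sd_tempo_bpm,
        "abs_phase_deg": focal.mean_phase_deg,
        "vector_length": focal.mean_vector_length,
    }
    table = {}
    for metric, dist in RANK_METRICS.items():
        focal_d = dist(focal)
        comp_d = tuple(dist(c) for c in comparators)
        table[metric] = RankEntry(
            metric=metric,
            tempo_bpm=tempo,
            focal_value=raw_value[metric],
            focal_distance=focal_d,
            comparator_distances=comp_d,
            n_beaten=sum(1 for d in comp_d if d > focal_d),
        )
    return table


def rank_table(
    focal_summaries: Sequence[SubjectTempoSummary],
    comparator_summaries: Sequence[SubjectTempoSummary],
) -> pd.DataFrame:
    """Rank the focal subject against comparators at every shared tempo."""
    rows = []
    for focal in sorted(focal_summaries, key=lambda s: s.tempo_bpm):
        comps = [c for c in comparator_summaries if c.tempo_bpm == focal.tempo_bpm]
        for metric, entry in rank_against_humans(focal, comps).items():
            rows.append(
                dict(
                    tempo_bpm=entry.tempo_bpm,
                    metric=metric,
                    focal_value=entry.focal_value,
                    n_beaten=entry.n_beaten,
                    n_comparators=entry.n_comparators,
                )
            )
    return pd.DataFrame(rows)


def first_vs_last_trial(trial_phase_lists: Sequence) -> CircTestResult:
    """Watson-Williams of the first trial's phases vs the last trial's.

    ``trial_phase_lists`` holds one phase array per trial, in trial order;
    a learning effect shows as a significant mean-direction difference.
    """
    if len(trial_phase_lists) < 2:
        raise DomainError("need at least 2 trials to compare first vs last")
    return watson_williams([trial_phase_lists[0], trial_phase_lists[-1]])


@dataclass(frozen=True)
class HalvesResult:
    """Pooled first-half vs second-half phase comparison."""

    test: CircTestResult
    mean_difference_deg: float  # circular mean(second) - mean(first), wrapped
    n_trials_used: int
    n_trials_excluded: int


def within_trial_halves(
    trial_phase_lists: Sequence, n_lead: int = 12, n_trail: int = 12
) -> HalvesResult:
    """Compare the first ``n_lead`` phases to the last ``n_trail`` across trials.

    Phases are pooled across trials (first movements of every trial in one
    group, last movements in the other) and compared with Watson-Williams;
    the signed circular-mean difference (second half minus first half)
    expresses the direction of any within-trial drift. For a 25-movement
    trial with the default 12/12 split, the halves are movements 1-12 and
    14-25 (the middle movement belongs to neither). Trials shorter than
    ``n_lead + 1`` movements are excluded with a warning.
    """
    lead, trail = [], []
    used = excluded = 0
    for phases in trial_phase_lists:
        phases = np.asarray(phases, dtype=float)
        if phases.size < n_lead + 1:
            excluded += 1
            logger.warning("excluding a %d-movement trial from halves analysis",
                           phases.size)
            continue
        lead.append(phases[:n_lead])
        trail.append(phases[-n_trail:])
        used += 1
    if used == 0:
        raise DomainError("every trial was too short for the halves analysis")
    first = np.concatenate(lead)
    second = np.concatenate(trail)
    result = watson_williams([first, second])
    diff = wrap_degrees(circular_mean(second) - circular_mean(first))
    return HalvesResult(
        test=result,
        mean_difference_deg=diff,
        n_trials_used=used,
        n_trials_excluded=excluded,
    )


def subject_vs_group_phase(subject_phases, group_phases) -> CircTestResult:
    """Watson-Williams of one subject's phases against a group's phases."""
    subject = np.asarray(subject_phases, dtype=float)
    group = np.asarray(group_phases, dtype=float)
    if subject.size == 0 or group.size == 0:
        raise DomainError("both phase samples must be nonempty")
    return watson_williams([subject, group])
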