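"""High-level pipeline helpers tying trials to summaries, tests and cohorts.

These are thin orchestration functions used by the command-line interface
and the reproduction script; all the science lives in the per-topic
modules.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Sequence

import numpy as np
import pandas as pd

from .circ_tests import rayleigh_test, v_test
from .exceptions import DomainError
from .human_simulator import SimConfig, fit_window_models, screen_trials, simulate_cohort
from .phase_metrics import (
    compute_phase_series,
    grid_for_trial,
    summarize_subject,
    summarize_trial,
)
from .types import AnalysisConfig, MovementTrial

__all__ = [
    "trial_summaries",
    "subject_summaries",
    "phase_series_by_trial",
    "run_trial_tests",
    "fit_and_simulate",
]


def trial_summaries(trials: Sequence[MovementTrial], cfg: AnalysisConfig | None = None):
    """Summarize every trial against a tempo-derived beat grid at t0 = 0."""
    cfg = cfg or AnalysisConfig()
    return [summarize_trial(t, grid_for_trial(t), cfg) for t in trials]


def subject_summaries(trials: Sequence[MovementTrial], cfg: AnalysisConfig | None = None):
    """Aggregate trials per (subject, tempo)."""
    cfg = cfg or AnalysisConfig()
    grouped = defaultdict(list)
    for t in trials:
        grouped[(t.subject_id, t.tempo_bpm)].append(t)
    out = []
    for (_, _), ts in sorted(grouped.items()):
        grids = [grid_for_trial(t) for t in ts]
        out.append(summarize_subject(ts, grids, cfg))
    return out


def phase_series_by_trial(trials: Sequence[MovementTrial], cfg: AnalysisConfig | None = None):
    """Phase series for each trial, keyed by (subject_id, tempo, trial_index)."""
    cfg = cfg or AnalysisConfig()
    return {
        (t.subject_id, t.tempo_bpm, t.trial_index): compute_phase_series(
            t, grid_for_trial(t), cfg
        )
        for t in trials
    }


def run_trial_tests(
    trials: Sequence[MovementTrial],
    cfg: AnalysisConfig | None = None,
    mu0_deg: float = 0.0,
) -> pd.DataFrame:
    """Per-trial Rayleigh (entrainment) and V-tests (synchronization to mu0)."""
    cfg = cfg or AnalysisConfig()
    rows = []
    for trial in trials:
        series = compute_phase_series(trial, grid_for_trial(trial), cfg)
        ray = rayleigh_test(series.phases_deg)
        vt = v_test(series.phases_deg, mu0_deg)
        rows.append(
            dict(
                subject_id=trial.subject_id,
                group=trial.group,
                tempo_bpm=trial.tempo_bpm,
                trial_index=trial.trial_index,
                n=ray.n,
                rayleigh_z=ray.statistic,
                rayleigh_p=ray.p_value,
                v_u=vt.statistic,
                v_p=vt.p_value,
                mean_phase_deg=ray.mean_angle_deg,
            )
        )
    return pd.DataFrame(rows)


def fit_and_simulate(
    trials: Sequence[MovementTrial],
    tempo_bpm: float,
    sim_cfg: SimConfig | None = None,
    cfg: AnalysisConfig | None = None,
):
    """Screen -> fit window models -> simulate a cohort at one tempo.

    Returns ``(cohort, models, n_screened_out)``. Only human-group trials
    at the requested tempo enter the fit.
    """
    cfg = cfg or AnalysisConfig()
    sim_cfg = sim_cfg or SimConfig()
    at_tempo = [t for t in trials if t.tempo_bpm == tempo_bpm and t.group == "human"]
    if not at_tempo:
        raise DomainError(f"no human trials at {tempo_bpm} bpm")
    pairs = [(t, summarize_trial(t, grid_for_trial(t), cfg)) for t in at_tempo]
    retained, removed = screen_trials(pairs, sim_cfg.screen_threshold)
    series = [
        compute_phase_series(t, grid_for_trial(t), cfg) for t, _ in retained
    ]
    models = fit_window_models(series, sim_cfg)
    cohort = simulate_cohort(models, tempo_bpm, sim_cfg)
    return cohort, models, len(removed)
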