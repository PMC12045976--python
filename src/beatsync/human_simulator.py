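"""Sliding-window Monte Carlo simulator of human beat keeping.

The simulator builds an empirical model of how people keep a beat with a
gross (high-amplitude) movement, without assuming any parametric trend
across a trial. Real trials are first screened (trials whose mean vector
length falls below a threshold are dropped), then pooled by tempo and
summarized in overlapping sliding windows of four consecutive movements:
within each window, inter-movement intervals are fit with a normal
distribution and phases with a von Mises distribution. A simulated trial
is then grown sequentially - draw the first movement's phase from window
1's von Mises, then repeatedly draw the next interval from the current
window's normal, derive the implied phase against a pre-computed beat
grid, and accept or reject that phase against the window's von Mises
density (mode-normalized rejection sampling) - until the trial reaches its
target number of movements. A cohort of such trials provides the null
distribution against which an individual's per-trial mean interval and
phase are z-tested.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .circ_tests import CircTestResult, fit_kappa
from .exceptions import DomainError, FitError, SimulationError
from .phase_metrics import circular_mean, mean_resultant, vector_length
from .types import BeatGrid, PhaseSeries, TrialSummary, make_beat_grid, wrap_degrees

__all__ = [
    "WindowModel",
    "SimConfig",
    "TrialStats",
    "SimulatedCohort",
    "ExceedanceResult",
    "screen_trials",
    "fit_window_models",
    "simulate_trial",
    "simulate_trial_events",
    "simulate_cohort",
    "z_test_vs_cohort",
    "exceedance_fraction",
    "acceptance_probability",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowModel:
    """Normal (interval) + von Mises (phase) fit for one sliding window."""

    window_index: int
    interval_mu_s: float
    interval_sigma_s: float
    phase_mu_deg: float
    phase_kappa: float
    n_obs: int

    def __post_init__(self):
        if self.interval_sigma_s < 0 or self.phase_kappa < 0:
            raise DomainError("interval_sigma_s and phase_kappa must be >= 0")


@dataclass
class SimConfig:
    """Simulation design parameters.

    Defaults reproduce the study design this simulator models: 10,000
    trials per tempo, 24 movements per simulated trial on a 29-beat grid
    (extra beats absorb skipped beats), sliding windows of width 4, and a
    screening threshold of 0.4 on the trial mean vector length.
    """

    n_trials: int = 10_000
    chops_per_trial: int = 24
    n_beats: int = 29
    window_width: int = 4
    screen_threshold: float = 0.4
    max_rejections_per_chop: int = 10_000
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("n_trials", "chops_per_trial", "n_beats", "window_width",
                     "max_rejections_per_chop"):
            if getattr(self, name) < 1:
                raise DomainError(f"{name} must be positive")
        if not (0.0 <= self.screen_threshold <= 1.0):
            raise DomainError("screen_threshold must be in [0, 1]")


@dataclass(frozen=True)
class TrialStats:
    """Summary of one simulated trial."""

    mean_phase_deg: float
    vector_length: float
    mean_interval_s: float
    mean_tempo_bpm: float
    n_chops: int


@dataclass(frozen=True)
class SimulatedCohort:
    """A seeded cohort of simulated trials at one tempo."""

    tempo_bpm: float
    rng_seed: int
    mean_phase_deg: np.ndarray
    vector_length: np.ndarray
    mean_interval_s: np.ndarray
    mean_tempo_bpm: np.ndarray

    @property
    def n_trials(self) -> int:
        return int(self.mean_phase_deg.size)

    def summary(self) -> dict:
        """Aggregate cohort statistics (tempo in bpm, phases circular)."""
        return {
            "tempo_bpm": self.tempo_bpm,
            "n_trials": self.n_trials,
            "mean_tempo_bpm": float(np.mean(self.mean_tempo_bpm)),
            "sd_tempo_bpm": float(np.std(self.mean_tempo_bpm, ddof=1)),
            "mean_interval_s": float(np.mean(self.mean_interval_s)),
            "mean_phase_deg": circular_mean(self.mean_phase_deg),
            "mean_vector_length": float(np.mean(self.vector_length)),
        }


def screen_trials(items: Sequence[tuple], threshold: float = 0.4):
    """Retain (trial, summary) pairs whose vector length is >= threshold.

    Only trials strictly *below* the threshold are removed. Returns
    ``(retained, removed)``; an empty retained list is allowed but logged
    loudly.
    """
    retained, removed = [], []
    for trial, summary in items:
        if summary.vector_length >= threshold:
            retained.append((trial, summary))
        else:
            removed.append((trial, summary))
            logger.info(
                "screened out subject %s trial %d (vector length %.3f < %.2f)",
                summary.subject_id, summary.trial_index,
                summary.vector_length, threshold,
            )
    if not retained:
        logger.warning("screening removed every trial (threshold %.2f)", threshold)
    return retained, removed


def fit_window_models(
    series_list: Sequence[PhaseSeries], cfg: SimConfig | None = None
) -> list[WindowModel]:
    """Fit per-window interval and phase distributions, pooling across trials.

    Window ``k`` (1-based) covers movements ``k .. k + width - 1``. Its
    phase pool holds those movements' phases from every trial; its interval
    pool holds the intervals *ending* at those movements (movement 1 has no
    interval, so window 1 pools the intervals of movements 2..width). With
    25-movement trials and width 4 this yields 22 windows.
    """
    cfg = cfg or SimConfig()
    if not series_list:
        raise DomainError("need at least one screened trial to fit windows")
    width = cfg.window_width
    max_len = max(s.n_events for s in series_list)
    n_windows = max_len - width + 1
    if n_windows < 1:
        raise DomainError("trials shorter than the window width")
    models = []
    for k in range(1, n_windows + 1):
        phases, intervals = [], []
        for s in series_list:
            lo, hi = k, min(k + width - 1, s.n_events)  # movement indices, 1-based
            phases.extend(s.phases_deg[lo - 1 : hi])
            # interval of movement m (m >= 2) is intervals_s[m - 2]
            ilo = max(lo, 2)
            intervals.extend(s.intervals_s[ilo - 2 : hi - 1])
        phases = np.asarray(phases)
        intervals = np.asarray(intervals)
        if phases.size < 2 or intervals.size < 2:
            raise FitError(f"window {k}: too few observations to fit")
        r = mean_resultant(phases)
        r_bar = min(abs(r), 1.0 - 1e-10)
        if abs(r) < 1e-12:
            phase_mu, kappa = 0.0, 0.0
            logger.warning("window %d: degenerate phase direction, kappa set to 0", k)
        else:
            phase_mu = wrap_degrees(math.degrees(math.atan2(r.imag, r.real)))
            kappa = fit_kappa(r_bar)
        models.append(
            WindowModel(
                window_index=k,
                interval_mu_s=float(np.mean(intervals)),
                interval_sigma_s=float(np.std(intervals, ddof=1)),
                phase_mu_deg=float(phase_mu),
                phase_kappa=float(kappa),
                n_obs=int(phases.size),
            )
        )
    return models


def window_for_chop(n: int, n_windows: int, width: int) -> int:
    """1-based window index generating movement ``n``.

    The window whose last member is movement ``n`` (i.e. the most recent
    history), clamped to the available range.
    """
    return min(max(n - width + 1, 1), n_windows)


def acceptance_probability(phase_deg: float, mu_deg: float, kappa: float) -> float:
    """Mode-normalized von Mises density ratio f(phase)/f(mu), in (0, 1]."""
    return math.exp(kappa * (math.cos(math.radians(phase_deg - mu_deg)) - 1.0))


def simulate_trial_events(
    models: Sequence[WindowModel],
    grid: BeatGrid,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate one simulated trial; returns (movement times, phases).

    Movement 1's phase is drawn directly from window 1's von Mises. Each
    later movement's interval is drawn from its window's normal
    distribution (negative draws rejected outright); the implied phase
    against the nearest beat is accepted with probability
    ``f_VM(phase) / f_VM(mu)``, otherwise the interval is redrawn.
    """
    if not models:
        raise DomainError("no window models supplied")
    n_windows = len(models)
    width = cfg.window_width
    period = grid.period_s
    t0 = grid.t0
    n_beats = grid.n_beats

    m1 = models[0]
    phase1 = wrap_degrees(math.degrees(rng.vonmises(math.radians(m1.phase_mu_deg),
                                                    m1.phase_kappa)))
    times = [t0 + phase1 / 360.0 * period]
    phases = [phase1]
    for n in range(2, cfg.chops_per_trial + 1):
        m = models[window_for_chop(n, n_windows, width) - 1]
        prev = times[-1]
        for _ in range(cfg.max_rejections_per_chop):
            interval = rng.normal(m.interval_mu_s, m.interval_sigma_s)
            if interval <= 0.0:
                continue
            t = prev + interval
            rel = (t - t0) / period
            k = math.floor(rel + 0.5)
            k = 0 if k < 0 else (n_beats - 1 if k > n_beats - 1 else k)
            phase = wrap_degrees(360.0 * (rel - k))
            if rng.random() < acceptance_probability(phase, m.phase_mu_deg,
                                                     m.phase_kappa):
                times.append(t)
                phases.append(phase)
                break
        else:
            raise SimulationError(
                f"rejection sampling exhausted at movement {n} "
                f"(window {m.window_index}): model is internally inconsistent"
            )
    return np.asarray(times), np.asarray(phases)


def simulate_trial(
    models: Sequence[WindowModel],
    grid: BeatGrid,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> TrialStats:
    """Generate one simulated trial and summarize it (see
    :func:`simulate_trial_events` for the generation procedure)."""
    times, phases = simulate_trial_events(models, grid, cfg, rng)
    intervals = np.diff(times)
    return TrialStats(
        mean_phase_deg=circular_mean(phases),
        vector_length=vector_length(phases),
        mean_interval_s=float(np.mean(intervals)),
        mean_tempo_bpm=float(np.mean(60.0 / intervals)),
        n_chops=len(phases),
    )


def simulate_cohort(
    models: Sequence[WindowModel], tempo_bpm: float, cfg: SimConfig
) -> SimulatedCohort:
    """Simulate ``cfg.n_trials`` independent trials at one tempo (seeded)."""
    rng = np.random.default_rng(cfg.rng_seed)
    grid = make_beat_grid(tempo_bpm, cfg.n_beats, 0.0)
    phase = np.empty(cfg.n_trials)
    vlen = np.empty(cfg.n_trials)
    ivl = np.empty(cfg.n_trials)
    bpm = np.empty(cfg.n_trials)
    for i in range(cfg.n_trials):
        s = simulate_trial(models, grid, cfg, rng)
        phase[i], vlen[i], ivl[i], bpm[i] = (
            s.mean_phase_deg, s.vector_length, s.mean_interval_s, s.mean_tempo_bpm,
        )
    return SimulatedCohort(
        tempo_bpm=tempo_bpm,
        rng_seed=cfg.rng_seed,
        mean_phase_deg=phase,
        vector_length=vlen,
        mean_interval_s=ivl,
        mean_tempo_bpm=bpm,
    )


def z_test_vs_cohort(
    observed: float, cohort_values, circular: bool = False
) -> CircTestResult:
    """Two-tailed z-test of one observation against a simulated cohort.

    With a large cohort the per-trial means are treated as approximately
    normal; circular quantities are compared on the linear degree scale
    after wrapping to (-180, +180].
    """
    values = np.asarray(cohort_values, dtype=float)
    if values.size < 100:
        raise DomainError("cohort must have at least 100 values for a z-test")
    if circular:
        values = wrap_degrees(values)
        observed = wrap_degrees(observed)
    mu = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    if sd == 0.0:
        raise DomainError("cohort SD is zero: z-test degenerate")
    z = (observed - mu) / sd
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return CircTestResult("z_test", float(z), min(p, 1.0), int(values.size))


@dataclass(frozen=True)
class ExceedanceResult:
    """How an observed mean phase sits within a simulated cohort.

    ``abs_exceedance``: fraction of cohort trials whose |mean phase| is
    larger than |observed| (i.e. observed is closer to perfect synchrony).
    ``frac_more_negative``: fraction of cohort trials with mean phase more
    negative than the observed one (observed is "more positive" than that
    fraction of the cohort).
    """

    abs_exceedance: float
    frac_more_negative: float
    n: int


def exceedance_fraction(observed_phase_deg: float, cohort_phases) -> ExceedanceResult:
    """Fractions of a cohort the observed phase beats (absolute and signed)."""
    phases = wrap_degrees(np.asarray(cohort_phases, dtype=float))
    if phases.size == 0:
        raise DomainError("cohort is empty")
    obs = wrap_degrees(observed_phase_deg)
    return ExceedanceResult(
        abs_exceedance=float(np.mean(np.abs(phases) > abs(obs))),
        frac_more_negative=float(np.mean(phases < obs)),
        n=int(phases.size),
    )
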