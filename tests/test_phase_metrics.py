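import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import beatsync as bs
from beatsync.exceptions import DegenerateDirectionError, DomainError
from beatsync.phase_metrics import grid_for_trial

phases_strategy = st.lists(
    st.floats(-179.9, 180.0, allow_nan=False), min_size=1, max_size=50
)


def brute_force_resultant(phases_deg):
    """Independent oracle: explicit complex sum."""
    z = sum(complex(math.cos(math.radians(p)), math.sin(math.radians(p)))
            for p in phases_deg) / len(phases_deg)
    return z


def _trial(times, tempo=120.0, subject="s", group="human", idx=1):
    return bs.MovementTrial(subject, group, tempo, idx, tuple(times))


class TestCircularMean:
    @pytest.mark.parametrize(
        "phases,expected",
        [
            ([30.0, -30.0], 0.0),
            ([170.0, -170.0], 180.0),
            ([10.0, 20.0, 30.0], 20.0),  # frozen from the complex-sum oracle
        ],
    )
    def test_known_values(self, phases, expected):
        assert bs.circular_mean(phases) == pytest.approx(expected, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            bs.circular_mean([])

    def test_antipodal_is_degenerate(self):
        with pytest.raises(DegenerateDirectionError):
            bs.circular_mean([90.0, -90.0])

    @given(phases_strategy)
    def test_matches_brute_force_oracle(self, phases):
        z = brute_force_resultant(phases)
        if abs(z) < 1e-6:
            return
        expected = bs.wrap_degrees(math.degrees(math.atan2(z.imag, z.real)))
        got = bs.circular_mean(phases)
        # compare on the circle
        assert abs(bs.wrap_degrees(got - expected)) < 1e-9

    @given(phases_strategy, st.floats(-360, 360))
    def test_rotation_covariance(self, phases, rot):
        z = brute_force_resultant(phases)
        if abs(z) < 1e-6:
            return
        rotated = bs.circular_mean([p + rot for p in phases])
        assert abs(bs.wrap_degrees(rotated - bs.circular_mean(phases) - rot)) < 1e-6


class TestVectorLength:
    @pytest.mark.parametrize(
        "phases,expected",
        [
            ([42.0] * 7, 1.0),
            ([0.0, 90.0, 180.0, 270.0], 0.0),
            ([30.0, -30.0], math.cos(math.radians(30.0))),
        ],
    )
    def test_known_values(self, phases, expected):
        assert bs.vector_length(phases) == pytest.approx(expected, abs=1e-9)

    @given(phases_strategy, st.floats(-360, 360))
    def test_rotation_invariance(self, phases, rot):
        assert bs.vector_length([p + rot for p in phases]) == pytest.approx(
            bs.vector_length(phases), abs=1e-9
        )

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        phases = rng.uniform(-180, 180, size=37)
        rad = np.deg2rad(phases)
        assert bs.vector_length(phases) == pytest.approx(
            float(pingouin.circ_r(rad)), abs=1e-12
        )
        assert bs.circular_mean(phases) == pytest.approx(
            bs.wrap_degrees(math.degrees(float(pingouin.circ_mean(rad)))), abs=1e-9
        )


class TestComputePhaseSeries:
    def test_event_before_beat_has_negative_phase(self):
        # event at 9.9 s, nearest beat 10.0 s, period 0.5 s -> -72 degrees
        grid = bs.make_beat_grid(120.0, 25, 0.0)
        series = bs.compute_phase_series(_trial([9.9]), grid)
        assert series.phases_deg[0] == pytest.approx(-72.0)

    def test_event_on_beat_is_zero(self):
        grid = bs.make_beat_grid(120.0, 5, 0.0)
        series = bs.compute_phase_series(_trial([1.5]), grid)
        assert series.phases_deg[0] == pytest.approx(0.0)

    def test_perfect_synchrony(self):
        grid = bs.make_beat_grid(120.0, 3, 0.0)
        series = bs.compute_phase_series(_trial([0.0, 0.5, 1.0]), grid)
        assert series.phases_deg == pytest.approx([0.0, 0.0, 0.0])
        assert series.intervals_s == pytest.approx([0.5, 0.5])
        assert list(series.beat_index) == [1, 2, 3]

    def test_halfway_tie_goes_to_earlier_beat_by_default(self):
        grid = bs.make_beat_grid(120.0, 4, 0.0)
        series = bs.compute_phase_series(_trial([0.75]), grid)
        assert list(series.beat_index) == [2]
        assert series.phases_deg[0] == pytest.approx(180.0)

    def test_halfway_tie_later_rule(self):
        grid = bs.make_beat_grid(120.0, 4, 0.0)
        cfg = bs.AnalysisConfig(nearest_beat_tie="later")
        series = bs.compute_phase_series(_trial([0.75]), grid, cfg)
        assert list(series.beat_index) == [3]
        assert series.phases_deg[0] == pytest.approx(-180.0, abs=1e-9) or \
            series.phases_deg[0] == pytest.approx(180.0)

    def test_event_beyond_grid_excluded(self):
        grid = bs.make_beat_grid(120.0, 2, 0.0)
        series = bs.compute_phase_series(_trial([0.0, 0.5, 5.0]), grid)
        assert series.n_unmatched == 1
        assert series.n_events == 2
        assert series.intervals_s.size == 2  # intervals use all events

    def test_empty_trial_rejected(self):
        grid = bs.make_beat_grid(120.0, 2, 0.0)
        with pytest.raises(DomainError):
            bs.compute_phase_series(
                bs.MovementTrial("s", "human", 120.0, 1, ()), grid
            )

    @given(shift=st.floats(-20, 20))
    def test_time_origin_invariance(self, shift):
        times = [0.02, 0.53, 0.98, 1.51]
        grid0 = bs.make_beat_grid(120.0, 4, 0.0)
        grid1 = bs.make_beat_grid(120.0, 4, shift)
        s0 = bs.compute_phase_series(_trial(times), grid0)
        s1 = bs.compute_phase_series(_trial([t + shift for t in times]), grid1)
        assert np.allclose(s0.phases_deg, s1.phases_deg, atol=1e-6)
        assert np.allclose(s0.intervals_s, s1.intervals_s, atol=1e-9)

    def test_sign_convention_duality(self):
        times = [0.02, 0.48, 1.03, 1.47]
        grid = bs.make_beat_grid(120.0, 4, 0.0)
        fwd = bs.compute_phase_series(_trial(times), grid)
        rev = bs.compute_phase_series(
            _trial(times), grid, bs.AnalysisConfig(phase_sign="beat_minus_movement")
        )
        assert np.allclose(rev.phases_deg, bs.wrap_degrees(-fwd.phases_deg))


class TestSummarizeTrial:
    def test_constant_half_second_intervals(self):
        grid = bs.make_beat_grid(120.0, 5, 0.0)
        s = bs.summarize_trial(_trial([0.0, 0.5, 1.0, 1.5, 2.0]), grid)
        assert s.performed_tempo_bpm == pytest.approx(120.0)
        assert s.sd_tempo_bpm == pytest.approx(0.0)
        assert s.mean_phase_deg == pytest.approx(0.0)
        assert s.vector_length == pytest.approx(1.0)
        assert s.circ_sd_deg == pytest.approx(0.0)

    def test_constant_offset_trial(self):
        # 25 events at t_i = i * 0.5 - 0.04 on a 120 bpm grid:
        # constant phase -0.04 / 0.5 * 360 = -28.8 degrees
        grid = bs.make_beat_grid(120.0, 25, 0.0)
        times = [i * 0.5 - 0.04 for i in range(25)]
        s = bs.summarize_trial(_trial(times), grid)
        assert s.mean_phase_deg == pytest.approx(-28.8)
        assert s.vector_length == pytest.approx(1.0)
        assert s.n_events == 25

    def test_single_event_rejected(self):
        grid = bs.make_beat_grid(120.0, 2, 0.0)
        with pytest.raises(DomainError):
            bs.summarize_trial(_trial([0.0]), grid)

    def test_tempo_method_switch(self):
        grid = bs.make_beat_grid(120.0, 4, 0.0)
        times = [0.0, 0.4, 1.0, 1.5]  # intervals 0.4, 0.6, 0.5
        s1 = bs.summarize_trial(_trial(times), grid)
        s2 = bs.summarize_trial(
            _trial(times), grid,
            bs.AnalysisConfig(tempo_method="reciprocal_of_mean_interval"),
        )
        assert s1.performed_tempo_bpm == pytest.approx(np.mean([150.0, 100.0, 120.0]))
        assert s2.performed_tempo_bpm == pytest.approx(120.0)

    def test_circ_sd_matches_vector_length_identity(self, study_summaries):
        for s in study_summaries:
            if s.vector_length > 0:
                assert s.circ_sd_deg == pytest.approx(
                    math.degrees(math.sqrt(-2 * math.log(s.vector_length))), rel=1e-9
                )


class TestSummarizeSubject:
    def test_identical_trials_idempotent(self):
        grid = bs.make_beat_grid(120.0, 25, 0.0)
        times = [i * 0.5 - 0.04 for i in range(25)]
        trials = [_trial(times, idx=i + 1) for i in range(4)]
        agg = bs.summarize_subject(trials, grid)
        single = bs.summarize_trial(trials[0], grid)
        assert agg.mean_tempo_bpm == pytest.approx(single.performed_tempo_bpm)
        assert agg.mean_phase_deg == pytest.approx(single.mean_phase_deg)
        assert agg.mean_vector_length == pytest.approx(single.vector_length)
        assert agg.n_trials == 4

    def test_antipodal_trial_means_degenerate(self):
        grid = bs.make_beat_grid(120.0, 25, 0.0)
        up = [i * 0.5 + 0.125 for i in range(25)]    # +90 degrees
        down = [i * 0.5 - 0.125 for i in range(25)]  # -90 degrees
        with pytest.raises(DegenerateDirectionError):
            bs.summarize_subject([_trial(up, idx=1), _trial(down, idx=2)], grid)

    def test_mean_of_trial_phases(self):
        grid = bs.make_beat_grid(120.0, 25, 0.0)
        t10 = [i * 0.5 + 10 / 360 * 0.5 for i in range(25)]
        t30 = [i * 0.5 + 30 / 360 * 0.5 for i in range(25)]
        agg = bs.summarize_subject([_trial(t10, idx=1), _trial(t30, idx=2)], grid)
        assert agg.mean_phase_deg == pytest.approx(20.0, abs=1e-6)

    def test_mixed_subjects_rejected(self):
        grid = bs.make_beat_grid(120.0, 3, 0.0)
        a = _trial([0.0, 0.5, 1.0], subject="a")
        b = _trial([0.0, 0.5, 1.0], subject="b")
        with pytest.raises(DomainError):
            bs.summarize_subject([a, b], grid)


class TestParameterRecovery:
    def test_von_mises_mean_and_concentration_recovered(self, rng):
        """(circular_mean, vector_length) estimate (mu, A(kappa)) at N = 1e4."""
        mu, kappa = -15.0, 5.0
        phases = np.degrees(rng.vonmises(math.radians(mu), kappa, size=10_000))
        assert bs.circular_mean(phases) == pytest.approx(mu, abs=1.5)
        assert bs.vector_length(phases) == pytest.approx(
            bs.vonmises_mean_resultant(kappa), abs=0.01
        )


class TestGridForTrial:
    def test_grid_covers_all_events(self, study):
        _, _, trials = study
        for t in trials[:20]:
            grid = grid_for_trial(t)
            assert grid.onsets_s[-1] >= t.event_times_s[-1] - grid.period_s / 2
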