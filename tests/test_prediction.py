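"""The amplitude/time prediction rules and the full-prediction loop."""

import numpy as np
import pytest

from myotet import (
    MotorUnit,
    PredictionConfig,
    StimulationPattern,
    ValidationError,
    build_twitch,
    compute_alpha,
    cot_degrees,
    full_predict,
    predict_with_observed_minima,
    reconstruct,
    sum_equal_twitches,
)
from myotet.prediction import predict_contraction


class TestAlphaModels:
    def test_strictly_decreasing_in_ratio(self):
        ratios = np.linspace(1.0, 20.0, 200)
        for model in ("base", "refined"):
            alphas = [compute_alpha(r, model) for r in ratios]
            assert np.all(np.diff(alphas) < 0)

    def test_refined_model_range_over_physiological_ratios(self):
        """Over p in [0.05, 1] the refined law spans ~[45.70, 117.2] degrees."""
        assert compute_alpha(1.0, "refined") == pytest.approx(117.2)
        assert compute_alpha(1 / 0.05, "refined") == pytest.approx(45.6966, abs=1e-4)

    def test_ratio_below_one_rejected(self):
        with pytest.raises(ValidationError):
            compute_alpha(0.9, "base")

    def test_cot_is_exactly_zero_at_right_angle(self):
        assert cot_degrees(90.0) == 0.0
        assert cot_degrees(45.0) == pytest.approx(1.0)


class TestPredictContraction:
    def test_rest_start_reproduces_first_twitch(self, slow_unit, cfg):
        assert predict_contraction(slow_unit, 0.0, 55.0, cfg) == slow_unit.first_twitch

    def test_right_angle_keeps_amplitude(self, slow_unit, cfg):
        for f in (1.0, 5.0, 20.0):
            p = predict_contraction(slow_unit, f, 90.0, cfg)
            assert p.f_max == slow_unit.first_twitch.f_max

    def test_45_degrees_doubles_amplitude_at_own_level(self, slow_unit, cfg):
        f1 = slow_unit.first_twitch.f_max
        assert predict_contraction(slow_unit, f1, 45.0, cfg).f_max == pytest.approx(2 * f1)

    def test_amplitude_vanishes_at_border_level(self, slow_unit, cfg):
        """At the maximal angle 117.2 deg the amplitude reaches zero near
        a starting force of 1.9458 twitch amplitudes (printed as 1.94)."""
        x_zero = -1.0 / cot_degrees(117.2)
        assert x_zero == pytest.approx(1.9458, abs=1e-4)
        f1 = slow_unit.first_twitch.f_max
        p = predict_contraction(slow_unit, x_zero * f1, 117.2, cfg)
        assert p.f_max == pytest.approx(0.0, abs=1e-9 * f1)

    @pytest.mark.parametrize(
        ("alpha", "sign"), [(45.0, 1), (70.0, 1), (90.0, 0), (110.0, -1), (117.2, -1)]
    )
    def test_amplitude_monotone_by_angle_regime(self, slow_unit, cfg, alpha, sign):
        """Amplitude grows with the starting force below 90 deg, is constant
        at 90 deg and shrinks above."""
        f1 = slow_unit.first_twitch.f_max
        levels = np.linspace(0.05, 1.5, 12) * f1
        amps = [predict_contraction(slow_unit, f, alpha, cfg).f_max for f in levels]
        diffs = np.diff(amps)
        if sign == 0:
            assert np.all(diffs == 0)
        else:
            assert np.all(sign * diffs > 0)

    def test_times_prolong_with_starting_force(self, slow_unit, cfg):
        levels = np.linspace(0.0, 2.0, 9) * slow_unit.first_twitch.f_max
        out = [predict_contraction(slow_unit, f, 80.0, cfg) for f in levels]
        for attr in ("t_hc", "t_c", "t_hr", "t_tw"):
            assert np.all(np.diff([getattr(p, attr) for p in out]) > 0)
        assert all(p.t_lead == slow_unit.first_twitch.t_lead for p in out)

    def test_negative_amplitudes_clamped_to_zero(self, slow_unit, cfg):
        f1 = slow_unit.first_twitch.f_max
        p = predict_contraction(slow_unit, 3.0 * f1, 117.2, cfg)
        assert p.f_max == 0.0


class TestFullPredict:
    def test_single_pulse_is_the_first_twitch(self, slow_unit, cfg):
        pattern = StimulationPattern(np.array([0.0]))
        trace, train = full_predict(slow_unit, pattern, cfg)
        assert len(train) == 1 and train.contractions[0] == slow_unit.first_twitch
        expected = build_twitch(slow_unit.first_twitch)(trace.times)
        np.testing.assert_array_equal(trace.force, expected)

    def test_fully_relaxed_pulses_give_identical_twitches(self, slow_unit, cfg):
        gap = slow_unit.first_twitch.t_lead + slow_unit.first_twitch.t_tw + 5.0
        _, train = full_predict(slow_unit, StimulationPattern(np.array([0.0, gap])), cfg)
        assert train.contractions[0] == train.contractions[1] == slow_unit.first_twitch
        assert np.all(train.f_tetmin == 0.0)

    def test_right_angle_unit_has_constant_amplitudes_longer_times(
        self, slow_unit, jittered_pattern
    ):
        cfg = PredictionConfig(alpha=90.0)
        _, train = full_predict(slow_unit, jittered_pattern, cfg)
        amps = [p.f_max for p in train.contractions]
        assert np.allclose(amps, slow_unit.first_twitch.f_max)
        assert max(p.t_c for p in train.contractions) > slow_unit.first_twitch.t_c

    def test_trace_is_sum_of_train_curves(self, slow_unit, jittered_pattern, cfg):
        """Reconstruction identity: the emitted trace equals the pointwise
        superposition of the train's own twitch models."""
        trace, train = full_predict(slow_unit, jittered_pattern, cfg)
        rebuilt = reconstruct(train, grid=trace)
        assert np.max(np.abs(rebuilt.force - trace.force)) < 1e-9 * slow_unit.f_mftf
        assert np.all(trace.force >= 0)

    def test_starting_levels_are_prior_sums_at_pulse_times(self, slow_unit, jittered_pattern, cfg):
        trace, train = full_predict(slow_unit, jittered_pattern, cfg)
        curves = train.curves()
        for n in range(1, len(train)):
            t_n = jittered_pattern.pulse_times[n]
            expected = sum(
                float(c(t_n - s)) for s, c in zip(jittered_pattern.pulse_times[:n], curves[:n])
            )
            assert train.f_tetmin[n] == pytest.approx(expected, rel=1e-12)


class TestObservedMinimaVariant:
    def test_all_zero_levels_collapse_to_equal_twitch_sum(self, slow_unit, jittered_pattern, cfg):
        baseline = sum_equal_twitches(slow_unit, jittered_pattern, cfg)
        predicted, _ = predict_with_observed_minima(
            slow_unit, jittered_pattern, np.zeros(jittered_pattern.n_pulses), cfg, grid=baseline
        )
        np.testing.assert_array_equal(predicted.force, baseline.force)

    def test_feeding_back_own_levels_reproduces_full_prediction(
        self, slow_unit, jittered_pattern, cfg
    ):
        trace, train = full_predict(slow_unit, jittered_pattern, cfg)
        again, _ = predict_with_observed_minima(
            slow_unit, jittered_pattern, train.f_tetmin, cfg, grid=trace
        )
        np.testing.assert_array_equal(again.force, trace.force)

    def test_level_list_validation(self, slow_unit, jittered_pattern, cfg):
        n = jittered_pattern.n_pulses
        with pytest.raises(ValidationError):
            predict_with_observed_minima(slow_unit, jittered_pattern, np.zeros(n - 1), cfg)
        bad_first = np.zeros(n)
        bad_first[0] = 1.0
        with pytest.raises(ValidationError):
            predict_with_observed_minima(slow_unit, jittered_pattern, bad_first, cfg)


class TestEqualTwitchBaseline:
    def test_single_pulse_is_the_twitch(self, slow_unit, cfg):
        trace = sum_equal_twitches(slow_unit, StimulationPattern(np.array([0.0])), cfg)
        np.testing.assert_array_equal(trace.force, build_twitch(slow_unit.first_twitch)(trace.times))

    def test_coincident_pulses_superpose_linearly(self, slow_unit, cfg):
        pattern = StimulationPattern.unchecked([0.0, 0.0, 0.0])
        trace = sum_equal_twitches(slow_unit, pattern, cfg)
        single = build_twitch(slow_unit.first_twitch)(trace.times)
        np.testing.assert_allclose(trace.force, 3.0 * single, rtol=1e-12)

    def test_sparse_pulses_peak_at_single_twitch_force(self, slow_unit, cfg):
        gap = slow_unit.first_twitch.t_lead + slow_unit.first_twitch.t_tw + 10.0
        trace = sum_equal_twitches(slow_unit, StimulationPattern(np.arange(4) * gap), cfg)
        assert trace.force.max() == pytest.approx(slow_unit.first_twitch.f_max, rel=1e-4)


def test_motor_unit_invariants(slow_twitch):
    with pytest.raises(ValidationError):
        MotorUnit("x", "S", slow_twitch, f_mftf=slow_twitch.f_max * 0.5)
    with pytest.raises(ValidationError):
        MotorUnit("x", "slow", slow_twitch, f_mftf=90.0)


def test_pattern_invariants():
    with pytest.raises(ValidationError):
        StimulationPattern.from_ipis([80.0, -1.0])
    with pytest.raises(ValidationError):
        StimulationPattern(np.array([]))
    assert StimulationPattern.from_ipis(np.full(40, 80.0)).n_pulses == 41
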