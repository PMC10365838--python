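"""Spike detection, adaptation index, f-points, hysteresis, trace cleaning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ca1ramp.analysis import (
    SpikeTrain,
    adaptation_index,
    analyze_ramp_response,
    classify_hysteresis,
    clean_interspike_trace,
    detect_spikes,
    instantaneous_frequency,
    peak_instantaneous_frequency,
    synaptic_adaptation_index,
)
from ca1ramp.synthetic import gen_synaptic_stim_times


class TestDetectSpikes:
    def test_subthreshold_trace_has_no_spikes(self):
        t = np.arange(0, 100, 0.1)
        assert detect_spikes(t, np.full_like(t, -60.0)).n_spikes == 0

    def test_sinusoid_two_upward_crossings(self):
        t = np.arange(0, 200, 0.1)
        v = -50 + 15 * np.sin(2 * np.pi * t / 100.0)  # crosses -40 upward twice
        assert detect_spikes(t, v).n_spikes == 2

    def test_level_above_threshold_counts_once(self):
        """A plateau above threshold is one crossing, not many."""
        t = np.arange(0, 30, 0.1)
        v = np.where((t >= 10) & (t <= 20), -35.0, -60.0)
        train = detect_spikes(t, v)
        assert train.n_spikes == 1
        assert train.spike_times[0] == pytest.approx(10.0)

    def test_spike_time_is_first_suprathreshold_sample(self):
        t = np.arange(0, 10, 1.0)
        v = np.array([-60, -50, -39.9, -10, -60, -60, -41, -40.0, -60, -60.0])
        train = detect_spikes(t, v)
        assert list(train.spike_times) == [2.0, 7.0]


class TestAdaptationIndex:
    def test_six_up_four_down(self):
        train = SpikeTrain(np.concatenate([np.linspace(100, 900, 6),
                                           np.linspace(1100, 1900, 4)]))
        assert adaptation_index(train, 1000.0) == pytest.approx(0.2)

    def test_all_spikes_on_up_ramp(self):
        train = SpikeTrain(np.linspace(100, 900, 7))
        assert adaptation_index(train, 1000.0) == 1.0

    def test_spike_exactly_at_peak_counts_as_up(self):
        train = SpikeTrain(np.array([500.0, 1000.0]))
        assert adaptation_index(train, 1000.0) == 1.0

    def test_empty_train_undefined(self):
        with pytest.raises(ValueError):
            adaptation_index(SpikeTrain(np.empty(0)), 1000.0)

    @given(st.lists(st.floats(1.0, 1999.0), min_size=1, max_size=40, unique=True))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetric_under_time_reversal(self, times):
        """Mirroring the train about the ramp peak flips the index sign
        (holds when no spike lands exactly on the boundary)."""
        peak = 1000.0
        times = sorted(t for t in times if abs(t - peak) > 1e-6)
        if not times:
            return
        train = SpikeTrain(np.array(times))
        mirrored = SpikeTrain(np.sort(2 * peak - np.array(times)))
        assert adaptation_index(train, peak) == pytest.approx(
            -adaptation_index(mirrored, peak)
        )

    def test_synaptic_variant_uses_first_15_stimuli(self):
        stim = gen_synaptic_stim_times()  # 30 pulses
        boundary = stim.pulse_times[15]
        train = SpikeTrain(np.array([boundary - 1.0, boundary + 1.0]))
        assert synaptic_adaptation_index(train, stim.pulse_times) == pytest.approx(0.0)


class TestInstantaneousFrequency:
    def test_two_spikes_give_one_midpoint_value(self):
        train = SpikeTrain(np.array([0.0, 100.0]))
        pts = instantaneous_frequency(train)
        assert len(pts) == 1
        assert pts["f_hz"].iloc[0] == pytest.approx(10.0)
        assert pts["t_mid_ms"].iloc[0] == pytest.approx(50.0)

    def test_uniform_isis_give_flat_frequency(self):
        train = SpikeTrain(np.arange(0.0, 500.0, 50.0))
        pts = instantaneous_frequency(train)
        assert np.allclose(pts["f_hz"], 20.0)

    def test_point_count_is_spikes_minus_one(self):
        for n in (2, 5, 17):
            train = SpikeTrain(np.cumsum(np.random.default_rng(n).uniform(20, 80, n)))
            assert len(instantaneous_frequency(train)) == n - 1

    def test_fewer_than_two_spikes_give_empty_frame(self):
        assert len(instantaneous_frequency(SpikeTrain(np.array([10.0])))) == 0
        assert peak_instantaneous_frequency(SpikeTrain(np.array([10.0]))) == 0.0

    def test_current_sampled_at_midpoint_relative_to_baseline(self):
        train = SpikeTrain(np.array([0.0, 100.0]))
        t = np.arange(0.0, 200.0, 1.0)
        current = 0.5 + 0.01 * t  # nA
        pts = instantaneous_frequency(train, time=t, current=current, tonic_baseline=0.5)
        assert pts["I_nA"].iloc[0] == pytest.approx(0.5)

    def test_up_down_labels_about_peak(self):
        train = SpikeTrain(np.array([800.0, 900.0, 1100.0, 1300.0]))
        pts = instantaneous_frequency(train, peak_time=1000.0)
        assert list(pts["phase"]) == ["up", "up", "down"]


class TestClassifyHysteresis:
    @staticmethod
    def _loop(direction):
        # rectangle traversed in temporal order: up limb low f, down limb high f
        x_up = np.linspace(0.0, 1.0, 6)
        x_down = x_up[::-1]
        if direction == "ccw":
            return np.concatenate([x_up, x_down]), np.concatenate(
                [np.full(6, 5.0), np.full(6, 15.0)]
            )
        return np.concatenate([x_up, x_down]), np.concatenate(
            [np.full(6, 15.0), np.full(6, 5.0)]
        )

    def test_constructed_clockwise_loop(self):
        x, y = self._loop("cw")
        assert classify_hysteresis(x, y) == "clockwise"

    def test_constructed_counterclockwise_loop(self):
        x, y = self._loop("ccw")
        assert classify_hysteresis(x, y) == "counterclockwise"

    def test_collinear_points_are_linear(self):
        x = np.concatenate([np.linspace(0, 1, 5), np.linspace(1, 0, 5)])
        assert classify_hysteresis(x, 5.0 + 10.0 * x) == "linear"

    def test_invariant_to_axis_rescaling(self):
        x, y = self._loop("cw")
        assert classify_hysteresis(1e-3 * x, y) == "clockwise"
        assert classify_hysteresis(1e3 * x, 1e-2 * y) == "clockwise"

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            classify_hysteresis(np.array([0.0, 1.0]), np.array([1.0, 2.0]))


class TestCleanInterspikeTrace:
    def test_constant_trace_untouched(self):
        t = np.arange(0, 100, 0.1)
        kept_t, kept = clean_interspike_trace(t, np.full_like(t, 0.05), preset="net")
        assert kept.size == t.size

    def test_net_preset_derivative_threshold(self):
        """Samples with |dI/dt| above 0.005 uA/(ms cm2) are removed."""
        t = np.arange(0, 100, 1.0)
        trace = 0.006 * t  # slope 0.006 everywhere
        _, kept = clean_interspike_trace(t, trace, preset="net")
        assert kept.size == 0
        trace_ok = 0.004 * t
        _, kept_ok = clean_interspike_trace(t, trace_ok, value_range=(-np.inf, np.inf),
                                            derivative_threshold=0.005)
        assert kept_ok.size == t.size

    def test_net_preset_value_range(self):
        t = np.arange(0, 10, 1.0)
        trace = np.full_like(t, 0.5)  # outside -0.3..0.09
        _, kept = clean_interspike_trace(t, trace, preset="net")
        assert kept.size == 0

    def test_trpm4_preset_removes_positive_values(self):
        t = np.arange(0, 10, 1.0)
        trace = np.array([-0.1, -0.05, 0.01, -0.2, 0.0, -0.1, -0.1, -0.1, -0.1, -0.1])
        _, kept = clean_interspike_trace(t, trace, preset="trpm4")
        assert kept.max() <= 0.0
        assert 0.01 not in kept

    def test_o_state_preset_occupancy_ceiling(self):
        t = np.arange(0, 10, 1.0)
        trace = np.full_like(t, 3e-4)  # above the 2e-4 occupancy bound
        _, kept = clean_interspike_trace(t, trace, preset="o_state")
        assert kept.size == 0

    def test_unknown_preset_rejected(self):
        with pytest.raises(KeyError):
            clean_interspike_trace(np.arange(5.0), np.arange(5.0), preset="bogus")


class TestAnalyzeRampResponse:
    def test_summary_fields_consistent(self):
        t = np.arange(0.0, 2000.0, 0.1)
        v = np.full_like(t, -65.0)
        spikes = [400.0, 550.0, 700.0, 850.0, 990.0, 1200.0]
        for ts in spikes:
            v[np.abs(t - ts) <= 1.0] = 10.0
        summary = analyze_ramp_response(t, v, peak_time=1000.0)
        assert summary.n_spikes == 6
        assert summary.adaptation_index == pytest.approx((5 - 1) / 6)
        assert len(summary.f_points) == 5
        assert summary.hysteresis_class is None
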