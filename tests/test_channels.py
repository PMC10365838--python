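"""Markov NaV kinetics and HH-style channel behavior."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ca1ramp.channels import (
    GATES,
    HHGatingState,
    NavMarkovState,
    NavParams,
    hh_channel_step_and_current,
    nav_current,
    nav_markov_step,
    nav_propagator,
    nav_propagator_table,
    nav_rate_matrix,
    nav_steady_state,
)


class TestNavMarkov:
    @given(
        v=st.floats(-100, 60),
        dt=st.floats(0.001, 5.0),
        w=st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4),
    )
    @settings(max_examples=50, deadline=None)
    def test_occupancy_conserved_and_positive(self, v, dt, w):
        p = np.array(w) / np.sum(w)
        state = NavMarkovState(p)
        new = nav_markov_step(state, v, dt)
        assert new.p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(new.p >= 0)

    def test_hyperpolarized_steady_state_is_closed(self):
        """Long hold far below threshold leaves channels closed, not open."""
        p = nav_steady_state(-90.0)
        assert p[0] > 0.95      # C dominant
        assert p[1] < 1e-4      # O empty

    @pytest.mark.parametrize("v", [-90.0, -70.0, -50.0, -30.0, 0.0])
    def test_time_stepping_converges_to_null_space(self, v):
        """Repeated propagator steps reach the rate-matrix null-space solution."""
        state = NavMarkovState()
        for _ in range(60):  # 60 s total; the I2 pool equilibrates in seconds
            state = nav_markov_step(state, v, 1000.0)
        assert np.abs(state.p - nav_steady_state(v)).max() < 1e-6

    def test_repeated_depolarizing_pulses_accumulate_i2(self):
        """Long-term inactivation builds monotonically over a pulse train."""
        params = NavParams()
        state = NavMarkovState(nav_steady_state(-60.0, params))
        i2 = []
        for _ in range(15):
            state = nav_markov_step(state, 0.0, 2.0, params)    # spike-like pulse
            state = nav_markov_step(state, -55.0, 48.0, params)  # interspike
            i2.append(state.I2)
        assert np.all(np.diff(i2) >= 0)
        assert i2[-1] > i2[0]

    def test_i2_recovery_is_slow_and_i1_recovery_fast(self):
        params = NavParams()
        # from pure I1 at rest: half-life of I1 should be milliseconds
        st_i1 = NavMarkovState(np.array([0.0, 0.0, 1.0, 0.0]))
        st_i1 = nav_markov_step(st_i1, -65.0, 20.0, params)
        assert st_i1.I1 < 0.05
        # from pure I2 at rest: recovery takes hundreds of ms
        st_i2 = NavMarkovState(np.array([0.0, 0.0, 0.0, 1.0]))
        st_i2 = nav_markov_step(st_i2, -65.0, 20.0, params)
        assert st_i2.I2 > 0.9
        st_i2 = nav_markov_step(st_i2, -65.0, 2000.0, params)
        assert st_i2.I2 < 0.1

    def test_generator_columns_sum_to_zero(self):
        Q = nav_rate_matrix(-40.0)
        assert np.allclose(Q.sum(axis=0), 0.0, atol=1e-14)

    def test_propagator_is_stochastic(self):
        M = nav_propagator(-30.0, 0.025)
        assert np.allclose(M.sum(axis=0), 1.0, atol=1e-12)
        assert np.all(M >= 0)

    def test_propagator_table_interpolation_error_small(self):
        table, v_min, dv = nav_propagator_table(0.025, dv=0.2)
        v = -42.13
        k = int((v - v_min) / dv)
        f = (v - v_min) / dv - k
        approx = (1 - f) * table[k] + f * table[k + 1]
        assert np.abs(approx - nav_propagator(v, 0.025)).max() < 1e-6

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            nav_markov_step(NavMarkovState(), -60.0, dt=0.0)
        with pytest.raises(ValueError):
            NavMarkovState(np.array([0.5, 0.5, 0.5, 0.5]))


class TestNavCurrent:
    def test_zero_open_zero_current(self):
        assert nav_current(NavMarkovState(), V=-60.0, g_na=0.03) == 0.0

    def test_reversal_potential(self):
        state = NavMarkovState(np.array([0.9, 0.1, 0.0, 0.0]))
        assert nav_current(state, V=55.0, g_na=0.03, E_na=55.0) == 0.0

    def test_subthreshold_persistent_current_value(self):
        state = NavMarkovState(np.array([0.99, 0.01, 0.0, 0.0]))
        i = nav_current(state, V=-60.0, g_na=0.03, E_na=55.0)
        assert i == pytest.approx(-0.0345, rel=1e-12)

    def test_negative_conductance_rejected(self):
        with pytest.raises(ValueError):
            nav_current(NavMarkovState(), V=0.0, g_na=-1.0)


class TestHHChannels:
    def test_long_clamp_reaches_steady_state(self):
        state = HHGatingState.at_rest(-65.0)
        v = -35.0
        for _ in range(200):
            state, _ = hh_channel_step_and_current(state, v, dt=10.0, densities={})
        for i, (_, _, kin) in enumerate(GATES):
            assert state.x[i] == pytest.approx(float(kin.inf(v)), abs=1e-6)

    def test_leak_current_ohmic(self):
        state = HHGatingState.at_rest(-60.0)
        _, currents = hh_channel_step_and_current(
            state, V=-60.0, dt=0.025, densities={"leak": 1e-4},
            reversals={"leak": -66.0},
        )
        assert currents["leak"] == pytest.approx(1e-4 * 6.0)

    def test_h_current_activates_on_hyperpolarization(self):
        """Stepping from -60 to -90 mV increases h-channel activation."""
        state = HHGatingState.at_rest(-60.0)
        q0 = state.value("h", "q")
        for _ in range(100):
            state, _ = hh_channel_step_and_current(state, -90.0, dt=10.0, densities={})
        assert state.value("h", "q") > q0

    def test_gates_stay_in_unit_interval(self):
        state = HHGatingState.at_rest(-70.0)
        for v in (-90.0, 40.0, -120.0, 0.0):
            state, _ = hh_channel_step_and_current(state, v, dt=5.0, densities={})
            assert np.all(state.x >= 0) and np.all(state.x <= 1)

    def test_kv1_silent_subthreshold(self):
        """The fast delayed rectifier stays off below spike threshold."""
        from ca1ramp.channels import gate_inf

        assert gate_inf(-50.0, ("kv1", "n")) < 0.01
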