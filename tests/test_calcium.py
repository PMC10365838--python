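"""Four-shell Ca2+ balance and the privileged nanodomain ODE."""

import math

import numpy as np
import pytest
from scipy.optimize import curve_fit

from ca1ramp.calcium import (
    CalciumParams,
    CalciumState,
    ShellGeometry,
    step_nanodomain,
    step_shell_calcium,
    vgcc_influx_rate,
)


@pytest.fixture
def geom():
    return ShellGeometry.cylinder(diameter=2.0, length=20.0)


@pytest.fixture
def params():
    return CalciumParams()


class TestShellGeometry:
    def test_outer_shell_capped_at_100nm(self):
        g = ShellGeometry.sphere(20.0)
        # outer shell volume equals a 0.1-um spherical shell at r=10
        expected = 4.0 / 3.0 * math.pi * (10.0**3 - 9.9**3)
        assert g.volumes[0] == pytest.approx(expected)

    def test_volumes_fill_compartment(self, geom):
        assert geom.volumes.sum() == pytest.approx(math.pi * 1.0**2 * 20.0)

    def test_thin_process_uses_equal_shells(self):
        g = ShellGeometry.cylinder(diameter=0.4, length=10.0)
        # r/4 = 0.05 um < 0.1 um cap
        assert g.volumes.sum() == pytest.approx(math.pi * 0.2**2 * 10.0)


class TestShellCalcium:
    def test_uniform_state_without_fluxes_is_stationary(self, geom, params):
        state = CalciumState.at_rest(params)
        new = step_shell_calcium(
            state, V=-60.0, I_ca_total=0.0, dt=0.025, params=params, geom=geom,
            er_enabled=False, pump_enabled=False,
        )
        assert np.allclose(new.shell_conc, state.shell_conc, atol=1e-12)
        assert np.allclose(new.buf_s, state.buf_s, atol=1e-12)

    def test_influx_creates_outward_to_inward_gradient(self, geom, params):
        """A brief Ca2+ pulse transiently orders shells outermost-highest."""
        state = CalciumState.at_rest(params)
        for _ in range(40):  # 1 ms of strong inward current
            state = step_shell_calcium(
                state, V=0.0, I_ca_total=-0.1, dt=0.025, params=params, geom=geom
            )
        c = state.shell_conc
        assert c[0] > c[1] > c[2] > c[3]

    def test_total_calcium_conserved_without_sources(self, geom, params):
        """Diffusion + buffering alone conserve volume-weighted total Ca."""
        state = CalciumState.at_rest(params)
        state.shell_conc = np.array([5.0, 0.5, 0.1, 0.05])  # non-equilibrium
        total0 = state.total_ca(geom)
        for _ in range(2000):  # 100 ms at dt=0.05
            state = step_shell_calcium(
                state, V=-60.0, I_ca_total=0.0, dt=0.05, params=params, geom=geom,
                er_enabled=False, pump_enabled=False,
            )
        assert state.total_ca(geom) == pytest.approx(total0, rel=1e-9)

    def test_pump_extrudes_calcium(self, geom, params):
        state = CalciumState.at_rest(params)
        state.shell_conc = np.full(4, 2.0)
        new = step_shell_calcium(
            state, V=-60.0, I_ca_total=0.0, dt=0.025, params=params, geom=geom,
            er_enabled=False, pump_enabled=True,
        )
        assert new.shell_conc[0] < state.shell_conc[0]

    def test_invalid_dt_rejected(self, geom, params):
        with pytest.raises(ValueError):
            step_shell_calcium(
                CalciumState.at_rest(params), -60.0, 0.0, dt=0.0, params=params, geom=geom
            )

    def test_influx_rate_unit_conversion(self):
        """0.1 mA/cm2 inward over a 20-um soma raises the 100-nm outer shell
        at the closed-form rate I*A/(2*F*V_shell) (two charges per ion)."""
        g = ShellGeometry.sphere(20.0)
        rate = vgcc_influx_rate(-0.1, g)
        amps = 0.1e-3 * (4 * math.pi * 10.0**2 * 1e-8)          # A
        mol_per_s = amps / (2 * 96485.332)
        vol_l = 4.0 / 3.0 * math.pi * (10.0**3 - 9.9**3) * 1e-15  # L
        expected = mol_per_s / vol_l * 1e6 / 1e3                 # uM/ms
        assert rate == pytest.approx(expected, rel=1e-9)


class TestNanodomain:
    def test_fixed_point_when_matching_outer_shell(self):
        out = step_nanodomain(ca_nd=0.1, I_ca_total=0.0, ca_outer=0.1, X=0.0, dt=1.0)
        assert out == pytest.approx(0.1, abs=1e-15)

    def test_decay_matches_closed_form_exponential(self):
        """From 10 uM toward a 0.1 uM outer shell: value at 400 ms is
        0.1 + 9.9/e (single-exponential relaxation, tau = 400 ms)."""
        ca = 10.0
        dt = 0.1
        for _ in range(4000):
            ca = step_nanodomain(ca, I_ca_total=0.0, ca_outer=0.1, X=0.0, dt=dt)
        assert ca == pytest.approx(0.1 + 9.9 * math.exp(-1.0), rel=1e-6)

    def test_fitted_efold_time_is_400ms(self):
        """Exponential fit to the simulated decay recovers tau within 1%."""
        dt = 0.1
        t = np.arange(0, 2000.0, dt)
        trace = np.empty_like(t)
        ca = 10.0
        for i in range(t.size):
            trace[i] = ca
            ca = step_nanodomain(ca, 0.0, ca_outer=0.1, X=0.0, dt=dt)

        def expdec(t, a, tau, c):
            return a * np.exp(-t / tau) + c

        (a, tau, c), _ = curve_fit(expdec, t, trace, p0=(9.0, 300.0, 0.0))
        assert tau == pytest.approx(400.0, rel=0.01)

    def test_steady_state_with_constant_influx(self):
        """With X=500 and constant inward current the fixed point is
        outer + tau * X * influx."""
        params = CalciumParams(nd_influx_scale=1.0)
        influx_per_ms = 500 * 0.001  # X * |I_ca| * scale
        expected = 0.1 + 400.0 * influx_per_ms
        ca = 0.1
        for _ in range(80000):  # 8 s: 20 relaxation times
            ca = step_nanodomain(ca, I_ca_total=-0.001, ca_outer=0.1, X=500.0,
                                 dt=0.1, params=params)
        assert ca == pytest.approx(expected, rel=1e-6)

    def test_outward_current_does_not_drain_nanodomain(self):
        """The influx term clips at zero for outward Ca2+ current."""
        with_outward = step_nanodomain(1.0, I_ca_total=+0.05, ca_outer=1.0, X=500.0, dt=1.0)
        assert with_outward == pytest.approx(1.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            step_nanodomain(1.0, 0.0, 0.1, X=-1.0, dt=1.0)
        with pytest.raises(RuntimeError):
            step_nanodomain(-1.0, 0.0, 0.1, X=0.0, dt=1.0)
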