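"""Three-state TRPM4 channel: instantaneous Ca2+ binding, voltage-gated opening.

TRPM4 is a Ca2+-activated, Ca2+-impermeable nonselective cation channel
(carrier of I_CAN).  The model has an unbound state, a Ca2+-bound closed
state, and an open state.  Ca2+ binding is much faster than voltage gating
and is treated as instantaneous with dissociation constant K_d = 87 uM
evaluated against the nanodomain concentration.  The open fraction m then
relaxes with first-order kinetics:

    alpha(V)  = 0.0057 exp(0.0060 V)        (opening, ms^-1)
    beta(V)   = 0.033  exp(-0.019 V)        (closing, ms^-1)
    alpha'    = alpha / (1 + K_d/[Ca]_ND)   (opening scaled by bound fraction)
    m_inf     = alpha' / (alpha' + beta)
    tau       = 1 / (alpha' + beta)

Removing the channel's voltage dependence means evaluating alpha and beta at
a frozen voltage (-60 mV, the holding potential) while the Ca2+ dependence
stays live.  The current is Ohmic, I = g m (V - E_CAN) with E_CAN = 0 mV by
default (nonselective cation channel convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "KD_CA",
    "Trpm4State",
    "trpm4_rates",
    "trpm4_bound_fraction",
    "trpm4_steady_state",
    "trpm4_step",
    "trpm4_current",
]

#: Ca2+ dissociation constant, uM.
KD_CA = 87.0

ALPHA_0 = 0.0057   # ms^-1 at 0 mV
ALPHA_SLOPE = 0.0060  # 1/mV
BETA_0 = 0.033     # ms^-1 at 0 mV
BETA_SLOPE = -0.019  # 1/mV


def trpm4_rates(V: float) -> tuple[float, float]:
    """Voltage-dependent opening and closing rates (alpha, beta), ms^-1."""
    return ALPHA_0 * math.exp(ALPHA_SLOPE * V), BETA_0 * math.exp(BETA_SLOPE * V)


def trpm4_bound_fraction(ca_nd: float) -> float:
    """Fraction of channels with Ca2+ bound: 1 / (1 + K_d/[Ca]_ND)."""
    if ca_nd <= 0:
        raise ValueError("nanodomain Ca2+ must be positive")
    return 1.0 / (1.0 + KD_CA / ca_nd)


def trpm4_steady_state(V: float, ca_nd: float) -> tuple[float, float]:
    """Steady-state activation and time constant (m_inf, tau_ms).

    ``m_inf`` is strictly increasing in both V and [Ca]_ND: depolarization
    raises alpha and lowers beta, and Ca2+ raises the bound fraction scaling
    alpha'.
    """
    alpha, beta = trpm4_rates(V)
    alpha_p = alpha * trpm4_bound_fraction(ca_nd)
    m_inf = alpha_p / (alpha_p + beta)
    tau = 1.0 / (alpha_p + beta)
    return m_inf, tau


@dataclass
class Trpm4State:
    """Open fraction of the TRPM4 conductance in one compartment."""

    m: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.m <= 1.0:
            raise ValueError("open fraction m must lie in [0, 1]")

    def bound_fraction(self, ca_nd: float) -> float:
        return trpm4_bound_fraction(ca_nd)


def trpm4_step(
    state: Trpm4State,
    V: float,
    ca_nd: float,
    dt: float,
    freeze_voltage: bool = False,
    V_freeze: float = -60.0,
) -> Trpm4State:
    """Relax m toward m_inf by an exact exponential update over ``dt``.

    With ``freeze_voltage`` the gating rates are evaluated at ``V_freeze``
    (default -60 mV) regardless of the actual membrane potential; the
    dependence on nanodomain Ca2+ remains live.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    v_eff = V_freeze if freeze_voltage else V
    m_inf, tau = trpm4_steady_state(v_eff, ca_nd)
    m = m_inf + (state.m - m_inf) * math.exp(-dt / tau)
    return Trpm4State(min(max(m, 0.0), 1.0))


def trpm4_current(m: float, V: float, g_trpm4: float, E_can: float = 0.0) -> float:
    """TRPM4 (I_CAN) current density, mA/cm2; inward (negative) below E_CAN."""
    if g_trpm4 < 0:
        raise ValueError("g_trpm4 must be non-negative")
    return g_trpm4 * m * (V - E_can)
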