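"""Membrane conductances: a 4-state Markov NaV channel and HH-style channels.

The Na+ conductance uses a Markov scheme with a closed state (C), an open
state (O), a fast-recovering short-term inactivated state (I1), and a
slowly-recovering long-term inactivated state (I2).  Entry into I2 during
repetitive firing, with recovery on a ~1 s time scale, cumulatively reduces
Na+ channel availability and produces spike-rate adaptation; sub-threshold
occupancy of O between spikes carries the persistent Na+ current.

Rate constants for this scheme are not uniquely constrained by any single
printed source; the defaults here were tuned so that (a) recovery from I1 is
fast (milliseconds) while recovery from I2 takes hundreds of milliseconds to
seconds, and (b) firing at place-cell-like rates (10-25 Hz) accumulates
enough I2 over a 1-s up-ramp to produce clear adaptation.

All other channels (CaL, CaR, CaT, two delayed rectifiers Kv1/Kv2, A-type
KA, inward rectifier KIR, h-current) are Hodgkin-Huxley style with Boltzmann
steady states and bell-shaped time constants stored as data tables, so that
alternative published CA1 parameterizations can be swapped in.  Currents are
Ohmic; units are mV, ms, uM, S/cm2, mA/cm2 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm, null_space

__all__ = [
    "NavParams",
    "NavMarkovState",
    "nav_rate_matrix",
    "nav_steady_state",
    "nav_markov_step",
    "nav_current",
    "GateKinetics",
    "GATES",
    "CHANNEL_GATE_POWERS",
    "HHGatingState",
    "gate_inf",
    "gate_tau",
    "kir_open_fraction",
    "hh_channel_step_and_current",
]

# ---------------------------------------------------------------------------
# Markov NaV channel
# ---------------------------------------------------------------------------

#: State ordering used everywhere: C, O, I1, I2.
NAV_STATES = ("C", "O", "I1", "I2")


@dataclass(frozen=True)
class NavParams:
    """Rate parameters (ms^-1, mV) of the 4-state NaV scheme.

    Transitions: C<->O (voltage dependent activation/deactivation), O->I1
    (fast inactivation), C->I1 (voltage-dependent closed-state inactivation,
    which keeps sub-threshold availability -- and hence the persistent
    current -- low between spikes), I1->C (fast recovery,
    hyperpolarization-favoured), I1->I2 (slow entry into long-term
    inactivation), I2->C (very slow recovery, hyperpolarization-favoured).
    """

    act_max: float = 6.0      # C->O maximal rate
    act_vhalf: float = -21.0
    act_k: float = 5.0
    deact_max: float = 6.0    # O->C maximal rate
    deact_vhalf: float = -51.0
    deact_k: float = 8.0
    inact: float = 1.3        # O->I1, voltage independent
    cs_inact_max: float = 0.0  # C->I1, depolarization-favoured
    cs_vhalf: float = -45.0
    cs_k: float = 6.0
    rec_i1_max: float = 0.35  # I1->C
    rec_i1_vhalf: float = -60.0
    rec_i1_k: float = 6.0
    slow_entry: float = 0.0015  # I1->I2, voltage independent
    rec_i2_max: float = 0.003  # I2->C
    rec_i2_vhalf: float = -60.0
    rec_i2_k: float = 6.0

    def rates(self, V: float):
        """Return the six transition rates at membrane potential ``V``."""
        a_co = self.act_max / (1.0 + np.exp(-(V - self.act_vhalf) / self.act_k))
        a_oc = self.deact_max / (1.0 + np.exp((V - self.deact_vhalf) / self.deact_k))
        a_oi1 = self.inact
        a_ci1 = self.cs_inact_max / (1.0 + np.exp(-(V - self.cs_vhalf) / self.cs_k))
        a_i1c = self.rec_i1_max / (1.0 + np.exp((V - self.rec_i1_vhalf) / self.rec_i1_k))
        a_i1i2 = self.slow_entry
        a_i2c = self.rec_i2_max / (1.0 + np.exp((V - self.rec_i2_vhalf) / self.rec_i2_k))
        return a_co, a_oc, a_oi1, a_ci1, a_i1c, a_i1i2, a_i2c


@dataclass
class NavMarkovState:
    """Occupancy probabilities of C, O, I1, I2 (sum to 1)."""

    p: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0, 0.0]))

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape[-1] != 4:
            raise ValueError("NaV state needs 4 occupancies (C, O, I1, I2)")
        if np.any(self.p < -1e-12) or np.any(self.p > 1 + 1e-12):
            raise ValueError("occupancies must lie in [0, 1]")
        if np.any(np.abs(self.p.sum(axis=-1) - 1.0) > 1e-9):
            raise ValueError("occupancies must sum to 1")

    @property
    def C(self) -> float:
        return float(self.p[..., 0])

    @property
    def O(self) -> float:
        return float(self.p[..., 1])

    @property
    def I1(self) -> float:
        return float(self.p[..., 2])

    @property
    def I2(self) -> float:
        return float(self.p[..., 3])


def nav_rate_matrix(V: float, params: NavParams | None = None) -> np.ndarray:
    """Generator matrix Q (column convention, dp/dt = Q p) at voltage ``V``."""
    params = params or NavParams()
    a_co, a_oc, a_oi1, a_ci1, a_i1c, a_i1i2, a_i2c = params.rates(V)
    Q = np.zeros((4, 4))
    Q[1, 0] = a_co    # C -> O
    Q[2, 0] = a_ci1   # C -> I1
    Q[0, 1] = a_oc    # O -> C
    Q[2, 1] = a_oi1   # O -> I1
    Q[0, 2] = a_i1c   # I1 -> C
    Q[3, 2] = a_i1i2  # I1 -> I2
    Q[0, 3] = a_i2c   # I2 -> C
    np.fill_diagonal(Q, 0.0)
    Q[np.diag_indices(4)] = -Q.sum(axis=0)
    return Q


def nav_steady_state(V: float, params: NavParams | None = None) -> np.ndarray:
    """Steady occupancies at fixed ``V``: normalized null space of Q."""
    Q = nav_rate_matrix(V, params)
    ns = null_space(Q)
    if ns.shape[1] != 1:  # pragma: no cover - scheme is irreducible
        raise RuntimeError("rate matrix null space is not one-dimensional")
    p = ns[:, 0]
    p = np.abs(p) / np.abs(p).sum()
    return p


def nav_propagator(V: float, dt: float, params: NavParams | None = None) -> np.ndarray:
    """Transition matrix expm(Q dt) with columns renormalized to sum to 1."""
    M = expm(nav_rate_matrix(V, params) * dt)
    return M / M.sum(axis=0, keepdims=True)


def nav_propagator_table(
    dt: float,
    params: NavParams | None = None,
    v_min: float = -120.0,
    v_max: float = 80.0,
    dv: float = 0.2,
) -> tuple[np.ndarray, float, float]:
    """Tabulate propagators on a voltage grid for the simulation kernel.

    Returns ``(table, v_min, dv)`` where ``table[k]`` is the 4x4 propagator
    at ``V = v_min + k*dv``.  Linear interpolation between adjacent grid
    matrices is a convex combination of stochastic matrices, so occupancy
    positivity and conservation survive interpolation.
    """
    volts = np.arange(v_min, v_max + dv / 2, dv)
    table = np.empty((volts.size, 4, 4))
    for k, v in enumerate(volts):
        table[k] = nav_propagator(float(v), dt, params)
    return table, v_min, dv


def nav_markov_step(
    state: NavMarkovState, V: float, dt: float, params: NavParams | None = None
) -> NavMarkovState:
    """Advance occupancies by ``dt`` at fixed ``V`` via the matrix exponential.

    Exact for constant voltage; preserves positivity and total occupancy.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    p_new = nav_propagator(V, dt, params) @ state.p
    if abs(p_new.sum() - 1.0) > 1e-6:  # pragma: no cover - guarded update
        raise RuntimeError("NaV occupancy drift exceeds 1e-6")
    return NavMarkovState(p_new)


def nav_current(state: NavMarkovState | float, V: float, g_na: float, E_na: float = 55.0) -> float:
    """Na+ current density, mA/cm2: ``g_na * O * (V - E_na)``.

    Sampled between spikes (sub-threshold V) this is the persistent Na+
    current.
    """
    if g_na < 0:
        raise ValueError("g_na must be non-negative")
    O = state.O if isinstance(state, NavMarkovState) else float(state)
    return g_na * O * (V - E_na)


# ---------------------------------------------------------------------------
# HH-style channels
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GateKinetics:
    """Boltzmann steady state and bell-shaped time constant for one gate.

    ``x_inf(V) = 1/(1+exp(-(V-vhalf)/k))`` — negative ``k`` makes the gate an
    inactivation gate.  ``tau(V) = tau_min + tau_amp / (exp((V-vtau)/ktau) +
    exp(-(V-vtau)/ktau))`` (mV, ms).
    """

    vhalf: float
    k: float
    tau_min: float
    tau_amp: float
    vtau: float
    ktau: float

    def inf(self, V):
        return 1.0 / (1.0 + np.exp(-(np.asarray(V, dtype=float) - self.vhalf) / self.k))

    def tau(self, V):
        v = np.asarray(V, dtype=float)
        return self.tau_min + self.tau_amp / (
            np.exp((v - self.vtau) / self.ktau) + np.exp(-(v - self.vtau) / self.ktau)
        )


#: Gate table: (channel, gate label, kinetics).  Order fixed; the engine
#: kernel indexes gates by position in this tuple.
GATES: tuple[tuple[str, str, GateKinetics], ...] = (
    ("cal", "m", GateKinetics(-15.0, 6.0, 0.5, 2.0, -15.0, 10.0)),
    ("car", "m", GateKinetics(-14.0, 7.0, 0.5, 1.5, -14.0, 12.0)),
    ("car", "h", GateKinetics(-65.0, -7.0, 20.0, 30.0, -65.0, 15.0)),
    ("cat", "m", GateKinetics(-45.0, 6.0, 1.0, 4.0, -45.0, 15.0)),
    ("cat", "h", GateKinetics(-70.0, -6.0, 10.0, 20.0, -70.0, 15.0)),
    ("kv1", "n", GateKinetics(-5.0, 8.0, 0.4, 2.5, -20.0, 12.0)),
    ("kv2", "n", GateKinetics(-30.0, 9.0, 20.0, 80.0, -40.0, 20.0)),
    ("ka", "a", GateKinetics(-25.0, 13.0, 0.3, 1.0, -25.0, 15.0)),
    ("ka", "b", GateKinetics(-56.0, -8.0, 4.0, 20.0, -60.0, 15.0)),
    ("h", "q", GateKinetics(-82.0, -7.0, 30.0, 70.0, -75.0, 20.0)),
)

#: Gate powers per channel in the conductance product, keyed by (channel, gate).
CHANNEL_GATE_POWERS: dict[tuple[str, str], int] = {
    ("cal", "m"): 2,
    ("car", "m"): 1,
    ("car", "h"): 1,
    ("cat", "m"): 2,
    ("cat", "h"): 1,
    ("kv1", "n"): 1,
    ("kv2", "n"): 1,
    ("ka", "a"): 1,
    ("ka", "b"): 1,
    ("h", "q"): 1,
}

#: Instantaneous inward-rectifier open fraction.
KIR_VHALF = -95.0
KIR_K = -8.0


def kir_open_fraction(V):
    """KIR conducts below E_K; open fraction falls steeply with depolarization."""
    return 1.0 / (1.0 + np.exp(-(np.asarray(V, dtype=float) - KIR_VHALF) / KIR_K))


def gate_index(channel: str, gate: str) -> int:
    for i, (c, g, _) in enumerate(GATES):
        if c == channel and g == gate:
            return i
    raise KeyError((channel, gate))


def gate_inf(V, index_or_name) -> np.ndarray:
    idx = index_or_name if isinstance(index_or_name, int) else gate_index(*index_or_name)
    return GATES[idx][2].inf(V)


def gate_tau(V, index_or_name) -> np.ndarray:
    idx = index_or_name if isinstance(index_or_name, int) else gate_index(*index_or_name)
    return GATES[idx][2].tau(V)


@dataclass
class HHGatingState:
    """Values of the ten HH gating variables, in ``GATES`` order."""

    x: np.ndarray = field(default_factory=lambda: np.zeros(len(GATES)))

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.shape[-1] != len(GATES):
            raise ValueError(f"expected {len(GATES)} gating variables")
        if np.any(self.x < -1e-12) or np.any(self.x > 1 + 1e-12):
            raise ValueError("gating variables must lie in [0, 1]")

    @classmethod
    def at_rest(cls, V: float) -> "HHGatingState":
        return cls(np.array([k.inf(V) for _, _, k in GATES]))

    def value(self, channel: str, gate: str) -> float:
        return float(self.x[gate_index(channel, gate)])


def hh_channel_step_and_current(
    state: HHGatingState,
    V: float,
    dt: float,
    densities: dict[str, float],
    reversals: dict[str, float] | None = None,
) -> tuple[HHGatingState, dict[str, float]]:
    """Advance all gates one exponential-relaxation step and return currents.

    Each gate relaxes toward its voltage-dependent steady state:
    ``x += (x_inf - x)(1 - exp(-dt/tau))`` — exact for the linear relaxation
    at frozen ``V``.  Currents (mA/cm2) are Ohmic products of the gate powers;
    ``leak`` and the instantaneous ``kir`` are included when their densities
    are given.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    from .morphology import DEFAULT_REVERSALS

    rev = dict(DEFAULT_REVERSALS)
    if reversals:
        rev.update(reversals)

    x_new = np.empty_like(state.x)
    for i, (_, _, kin) in enumerate(GATES):
        x_inf, tau = kin.inf(V), kin.tau(V)
        x_new[i] = x_inf + (state.x[i] - x_inf) * np.exp(-dt / tau)
    new_state = HHGatingState(np.clip(x_new, 0.0, 1.0))

    currents: dict[str, float] = {}
    for channel in ("cal", "car", "cat", "kv1", "kv2", "ka", "h"):
        if channel not in densities:
            continue
        open_frac = 1.0
        for (c, g), power in CHANNEL_GATE_POWERS.items():
            if c == channel:
                open_frac *= new_state.value(c, g) ** power
        currents[channel] = densities[channel] * open_frac * (V - rev[channel])
    if "kir" in densities:
        currents["kir"] = densities["kir"] * float(kir_open_fraction(V)) * (V - rev["kir"])
    if "leak" in densities:
        currents["leak"] = densities["leak"] * (V - rev["leak"])
    return new_state, currents
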