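"""Intracellular Ca2+ handling: four concentric shells plus a nanodomain.

Each compartment performs a Ca2+ material balance on four concentric shells
(shell 1 outermost, under the membrane).  The balance includes radial
diffusion between shells, first-order stationary and mobile buffers (the
mobile buffer's bound form diffuses radially), uptake into a fixed-
concentration endoplasmic-reticulum pool by SERCA, ER leak and a small
constant-IP3 release flux, a plasma-membrane extrusion pump, and influx
through voltage-gated Ca2+ channels.  Pump and channel fluxes act on the
outer shell only.  Longitudinal diffusion between like-numbered shells of
adjacent compartments is handled by the simulation engine.

A separate, privileged nanodomain concentration is what the TRPM4 channel
senses.  It obeys

    d[Ca]_ND/dt = X * max(0, -I_Ca) + ([Ca]_outer - [Ca]_ND) / 400 ms

where X is a scale factor standing in for the small effective volume of the
restricted domain: X = 0 outside cholinergic activation (the nanodomain then
simply tracks the bulk outer shell with a 400 ms time constant) and X = 500
during simulated carbachol, which lets the nanodomain reach micromolar
concentrations while bulk cytosolic Ca2+ stays in the hundreds of nM.  The
influx term is clipped at zero so an outward Ca2+ flux can never drain the
nanodomain below the bulk-tracking dynamics.

Units: uM, ms, mV, mA/cm2, um (geometry).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FARADAY",
    "ShellGeometry",
    "CalciumParams",
    "CalciumState",
    "step_shell_calcium",
    "step_nanodomain",
    "vgcc_influx_rate",
]

#: Faraday constant, C/mol.
FARADAY = 96485.332

N_SHELLS = 4


@dataclass(frozen=True)
class ShellGeometry:
    """Precomputed shell volumes and radial-interface areas for a compartment.

    The outermost shell is ``min(0.1 um, r/4)`` thick (a thin submembrane
    shell when the radius permits); the remaining radius is split into three
    equal shells.
    """

    volumes: np.ndarray          # um3, shell 1 first
    interface_areas: np.ndarray  # um2, between shells (1|2, 2|3, 3|4)
    interface_dx: np.ndarray     # um, center-to-center spacing at interfaces
    membrane_area: float         # um2

    @classmethod
    def cylinder(cls, diameter: float, length: float) -> "ShellGeometry":
        r = diameter / 2.0
        edges = _shell_edges(r)
        vols = np.array(
            [math.pi * (edges[i] ** 2 - edges[i + 1] ** 2) * length for i in range(N_SHELLS)]
        )
        areas = np.array([2.0 * math.pi * edges[i + 1] * length for i in range(N_SHELLS - 1)])
        return cls(vols, areas, _center_spacing(edges), 2.0 * math.pi * r * length)

    @classmethod
    def sphere(cls, diameter: float) -> "ShellGeometry":
        r = diameter / 2.0
        edges = _shell_edges(r)
        vols = np.array(
            [4.0 / 3.0 * math.pi * (edges[i] ** 3 - edges[i + 1] ** 3) for i in range(N_SHELLS)]
        )
        areas = np.array([4.0 * math.pi * edges[i + 1] ** 2 for i in range(N_SHELLS - 1)])
        return cls(vols, areas, _center_spacing(edges), 4.0 * math.pi * r**2)


def _shell_edges(r: float) -> np.ndarray:
    """Outer-to-inner shell boundary radii for a compartment of radius ``r``."""
    t_outer = min(0.1, r / N_SHELLS)
    inner = (r - t_outer) / (N_SHELLS - 1)
    edges = [r, r - t_outer]
    for _ in range(N_SHELLS - 1):
        edges.append(max(edges[-1] - inner, 0.0))
    return np.asarray(edges)


def _center_spacing(edges: np.ndarray) -> np.ndarray:
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers[:-1] - centers[1:]


@dataclass(frozen=True)
class CalciumParams:
    """Ca2+ handling parameters (defaults documented in docs/methods.md)."""

    D_ca: float = 0.22          # um2/ms, free Ca2+ diffusion
    D_buf: float = 0.05         # um2/ms, mobile buffer (bound form)
    buf_s_total: float = 150.0  # uM, stationary buffer
    buf_s_kon: float = 0.1      # 1/(uM ms)
    buf_s_kd: float = 2.0       # uM
    buf_m_total: float = 30.0   # uM, mobile buffer
    buf_m_kon: float = 0.1      # 1/(uM ms)
    buf_m_kd: float = 0.5       # uM
    pump_vmax: float = 0.02     # uM um/ms, membrane extrusion (per area)
    pump_km: float = 0.5        # uM
    serca_vmax: float = 5e-4    # uM/ms
    serca_km: float = 0.4       # uM
    ca_er: float = 400.0        # uM, fixed ER pool
    ip3_flux: float = 1e-7      # 1/ms, constant baseline-IP3 release coefficient
    A_ip3: float = 1.0          # scale on J_IP3R
    B_er: float = 1.0           # scale on (J_leak - J_SERCA)
    ca_rest: float = 0.1        # uM, nominal resting concentration
    nd_tau: float = 400.0       # ms, nanodomain <-> outer shell coupling
    nd_influx_scale: float = 3.0  # uM cm2 / (mA ms), folded into X's calibration

    @property
    def er_leak(self) -> float:
        """ER leak coefficient balancing SERCA and baseline IP3R at rest."""
        serca = self.serca_vmax * self.ca_rest**2 / (self.ca_rest**2 + self.serca_km**2)
        gradient = self.ca_er - self.ca_rest
        k = serca / gradient - (self.A_ip3 / max(self.B_er, 1e-12)) * self.ip3_flux
        return max(k, 0.0)


@dataclass
class CalciumState:
    """Shell/buffer/nanodomain state of one compartment."""

    shell_conc: np.ndarray
    buf_s: np.ndarray
    buf_m: np.ndarray
    ca_nd: float

    @classmethod
    def at_rest(cls, params: CalciumParams) -> "CalciumState":
        c = params.ca_rest
        bs = params.buf_s_total * c / (c + params.buf_s_kd)
        bm = params.buf_m_total * c / (c + params.buf_m_kd)
        return cls(
            shell_conc=np.full(N_SHELLS, c),
            buf_s=np.full(N_SHELLS, bs),
            buf_m=np.full(N_SHELLS, bm),
            ca_nd=c,
        )

    def total_ca(self, geom: ShellGeometry) -> float:
        """Volume-weighted total Ca2+ (free + buffered), uM * um3."""
        return float(np.sum((self.shell_conc + self.buf_s + self.buf_m) * geom.volumes))


def vgcc_influx_rate(I_ca_total: float, geom: ShellGeometry) -> float:
    """Outer-shell Ca2+ influx (uM/ms) from a membrane Ca2+ current density.

    ``I_ca_total`` is in mA/cm2 (inward negative).  The current is converted
    by the membrane area, divided by 2F, and distributed over the outer-shell
    volume.  Outward Ca2+ current removes Ca2+ (no clipping here; clipping is
    specific to the nanodomain term).
    """
    area_cm2 = geom.membrane_area * 1e-8
    mol_per_ms = -I_ca_total * 1e-3 * area_cm2 / (2.0 * FARADAY) * 1e-3
    vol_litres = geom.volumes[0] * 1e-15
    return mol_per_ms / vol_litres * 1e6


def _radial_diffusion_implicit(
    conc: np.ndarray, geom: ShellGeometry, D: float, dt: float
) -> np.ndarray:
    """Backward-Euler radial diffusion across the four shells.

    Flux-form discretization: V_i dC_i/dt = sum_j g_ij (C_j - C_i) with
    ``g = D A / dx`` at each interface; the implicit solve is unconditionally
    stable and conserves the volume-weighted total exactly.
    """
    g = D * geom.interface_areas / geom.interface_dx
    V = geom.volumes
    M = np.zeros((N_SHELLS, N_SHELLS))
    for i in range(N_SHELLS - 1):
        M[i, i] += g[i] / V[i]
        M[i, i + 1] -= g[i] / V[i]
        M[i + 1, i + 1] += g[i] / V[i + 1]
        M[i + 1, i] -= g[i] / V[i + 1]
    return np.linalg.solve(np.eye(N_SHELLS) + dt * M, conc)


def _buffer_step_implicit(
    ca: np.ndarray, bound: np.ndarray, total: float, kon: float, kd: float, dt: float
) -> tuple[np.ndarray, np.ndarray]:
    """Semi-implicit first-order buffer binding, one shell at a time.

    The bimolecular rate is linearized by freezing the free-buffer
    concentration at its start-of-step value; the resulting 2x2 linear system
    is solved exactly, conserving ``ca + bound`` to machine precision.
    """
    koff = kon * kd
    free = np.maximum(total - bound, 0.0)
    a = kon * free
    # (1 + dt a) ca' - dt koff bound' = ca ; -dt a ca' + (1 + dt koff) bound' = bound
    det = (1.0 + dt * a) * (1.0 + dt * koff) - dt * a * dt * koff
    ca_new = ((1.0 + dt * koff) * ca + dt * koff * bound) / det
    bound_new = (dt * a * ca + (1.0 + dt * a) * bound) / det
    return ca_new, bound_new


def step_shell_calcium(
    state: CalciumState,
    V: float,
    I_ca_total: float,
    dt: float,
    params: CalciumParams,
    geom: ShellGeometry,
    er_enabled: bool = True,
    pump_enabled: bool = True,
) -> CalciumState:
    """Advance one compartment's shell/buffer Ca2+ state by ``dt``.

    Operator split per step: explicit membrane/ER source terms, implicit
    radial diffusion (free Ca2+ and the mobile buffer's bound form), then
    semi-implicit buffer binding.  ``er_enabled``/``pump_enabled`` exist so
    conservation can be checked with all sources and sinks off.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    ca = state.shell_conc.copy()

    if pump_enabled:
        influx = vgcc_influx_rate(I_ca_total, geom)
        pump = (
            params.pump_vmax
            * ca[0]
            / (ca[0] + params.pump_km)
            * geom.membrane_area
            / geom.volumes[0]
        )
        ca[0] += dt * (influx - pump)
    if er_enabled:
        serca = params.serca_vmax * ca**2 / (ca**2 + params.serca_km**2)
        leak = params.er_leak * (params.ca_er - ca)
        ip3 = params.ip3_flux * (params.ca_er - ca)
        ca += dt * (params.A_ip3 * ip3 + params.B_er * (leak - serca))

    ca = _radial_diffusion_implicit(ca, geom, params.D_ca, dt)
    buf_m = _radial_diffusion_implicit(state.buf_m, geom, params.D_buf, dt)

    ca, buf_s = _buffer_step_implicit(
        ca, state.buf_s, params.buf_s_total, params.buf_s_kon, params.buf_s_kd, dt
    )
    ca, buf_m = _buffer_step_implicit(
        ca, buf_m, params.buf_m_total, params.buf_m_kon, params.buf_m_kd, dt
    )

    if np.any(ca < 0):
        raise RuntimeError("negative shell Ca2+ concentration; reduce dt")
    return CalciumState(shell_conc=ca, buf_s=buf_s, buf_m=buf_m, ca_nd=state.ca_nd)


def step_nanodomain(
    ca_nd: float,
    I_ca_total: float,
    ca_outer: float,
    X: float,
    dt: float,
    params: CalciumParams | None = None,
) -> float:
    """Advance the nanodomain concentration by ``dt`` (exact exponential update).

    Implements ``d[Ca]_ND/dt = X * max(0, -I_Ca) * k + ([Ca]_outer -
    [Ca]_ND)/tau`` with tau = 400 ms.  Both the source and the outer-shell
    concentration are frozen over the step, for which the linear ODE has the
    closed-form update used here.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if X < 0:
        raise ValueError("X must be non-negative")
    if ca_nd < 0:
        raise RuntimeError("negative nanodomain Ca2+ concentration")
    params = params or CalciumParams()
    influx = X * max(0.0, -I_ca_total) * params.nd_influx_scale
    target = ca_outer + params.nd_tau * influx
    return target + (ca_nd - target) * math.exp(-dt / params.nd_tau)
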