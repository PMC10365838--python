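"""Fixed-step integration kernel (numba) for the compartmental model.

One step advances, in order: HH gating variables (exact exponential
relaxation against tabulated steady states/time constants), the Markov NaV
occupancies (interpolated tabulated propagator matrices -- a convex
combination of stochastic matrices, so positivity and conservation are
preserved), the calcium shells (explicit membrane/ER sources, precomputed
implicit radial-diffusion solves, semi-implicit buffer binding, explicit
longitudinal diffusion), the nanodomain (exact exponential update), the
TRPM4 open fraction (exact exponential update), and finally the voltage via
an implicit (theta-method) tree solve with channel conductances frozen over
the step.

Units inside the kernel: mV, ms, uM, S/cm2, mA/cm2 (densities), uF
(absolute capacitance), uS (axial conductance), nA (injection), um3
(volumes).

Channel index order matches ``morphology.CHANNEL_NAMES``:
na, cal, car, cat, kv1, kv2, ka, kir, h, leak, trpm4.
Gate index order matches ``channels.GATES``.
"""

import numpy as np
from numba import njit

# Soma-trace record layout (see engine.SimulationResult)
REC_I_NA = 0
REC_I_CAL = 1
REC_I_CAR = 2
REC_I_CAT = 3
REC_I_KV1 = 4
REC_I_KV2 = 5
REC_I_KA = 6
REC_I_KIR = 7
REC_I_H = 8
REC_I_LEAK = 9
REC_I_TRPM4 = 10
REC_I_NET = 11
REC_NAV_C = 12
REC_NAV_O = 13
REC_NAV_I1 = 14
REC_NAV_I2 = 15
REC_CA_SH1 = 16
REC_CA_SH4 = 19
REC_CA_ND = 20
REC_TRPM4_M = 21
REC_I_CA = 22
N_REC = 23

TRPM4_ALPHA0 = 0.0057
TRPM4_ASLOPE = 0.0060
TRPM4_BETA0 = 0.033
TRPM4_BSLOPE = -0.019
TRPM4_KD = 87.0


@njit(cache=False)
def step_model(
    n_steps,
    dt,
    theta,
    # state (modified in place)
    V,            # (n,)
    nav,          # (n, 4)
    gates,        # (n, 10)
    m_trpm4,      # (n,)
    ca,           # (n, 4)
    bufs,         # (n, 4)
    bufm,         # (n, 4)
    cand,         # (n,)
    # voltage tables
    v_min,
    dv_tab,
    gate_inf_tab,   # (nv, 10)
    gate_efac_tab,  # (nv, 10)  exp(-dt/tau)
    kir_tab,        # (nv,)
    nav_tab,        # (nv, 4, 4)
    # per-compartment parameters
    g_dens,       # (11, n) S/cm2
    rev,          # (11,) mV
    area_cm2,     # (n,)
    c_abs,        # (n,) uF
    parent,       # (n,) int64, -1 for root
    g_ax,         # (n,) uS to parent
    # calcium
    diff_ca_inv,  # (n, 4, 4)
    diff_buf_inv, # (n, 4, 4)
    vols,         # (n, 4) um3
    long_g_ca,    # (n, 4) um3/ms to parent
    long_g_buf,   # (n, 4)
    influx_fac,   # (n,) uM/ms per mA/cm2 (outer shell)
    pump_fac,     # (n,) uM/ms at saturation
    bs_tot, bs_kon, bs_kd,
    bm_tot, bm_kon, bm_kd,
    serca_vmax, serca_km, ca_er, er_leak_k, ip3_k, a_ip3, b_er,
    pump_km,
    er_on, pump_on,
    # nanodomain / TRPM4
    X, nd_tau, nd_scale,
    freeze_v, v_freeze,
    playback, cand_play,  # flag, (n_steps, n)
    # stimulus
    stim,        # (n_steps,) nA
    inj_comp,
    # outputs
    v_rec,       # (n_steps, n)
    cand_rec,    # (n_steps, n)
    soma_rec,    # (n_steps, N_REC)
):
    n = V.shape[0]
    nv = gate_inf_tab.shape[0]
    nd_efac = np.exp(-dt / nd_tau)
    dca = np.empty((n, 4))
    dbm = np.empty((n, 4))
    g_tot = np.empty(n)
    b_tot = np.empty(n)
    i_ca_dens = np.empty(n)
    diag = np.empty(n)
    rhs = np.empty(n)
    tmp4 = np.empty(4)

    for step in range(n_steps):
        # ------------------------------------------------ gating and currents
        for i in range(n):
            v = V[i]
            x = (v - v_min) / dv_tab
            if x < 0.0:
                x = 0.0
            elif x > nv - 1.001:
                x = nv - 1.001
            k = int(x)
            f = x - k

            # HH gates: exact relaxation with tabulated inf and exp factor
            for g in range(10):
                xinf = gate_inf_tab[k, g] + f * (gate_inf_tab[k + 1, g] - gate_inf_tab[k, g])
                ef = gate_efac_tab[k, g] + f * (gate_efac_tab[k + 1, g] - gate_efac_tab[k, g])
                gates[i, g] = xinf + (gates[i, g] - xinf) * ef

            # Markov NaV: interpolated propagator
            for r in range(4):
                acc = 0.0
                for c in range(4):
                    m_rc = nav_tab[k, r, c] + f * (nav_tab[k + 1, r, c] - nav_tab[k, r, c])
                    acc += m_rc * nav[i, c]
                tmp4[r] = acc
            for r in range(4):
                nav[i, r] = tmp4[r]

            kir_o = kir_tab[k] + f * (kir_tab[k + 1] - kir_tab[k])

            # effective conductances, S/cm2
            g_na = g_dens[0, i] * nav[i, 1]
            g_cal = g_dens[1, i] * gates[i, 0] * gates[i, 0]
            g_car = g_dens[2, i] * gates[i, 1] * gates[i, 2]
            g_cat = g_dens[3, i] * gates[i, 3] * gates[i, 3] * gates[i, 4]
            g_kv1 = g_dens[4, i] * gates[i, 5]
            g_kv2 = g_dens[5, i] * gates[i, 6]
            g_ka = g_dens[6, i] * gates[i, 7] * gates[i, 8]
            g_kir = g_dens[7, i] * kir_o
            g_h = g_dens[8, i] * gates[i, 9]
            g_leak = g_dens[9, i]

            i_ca_dens[i] = (g_cal + g_car + g_cat) * (v - rev[1])

            # TRPM4 handled after the Ca/nanodomain update; accumulate the
            # voltage-independent part of the membrane conductance here.
            g_sum = g_na + g_cal + g_car + g_cat + g_kv1 + g_kv2 + g_ka + g_kir + g_h + g_leak
            b_sum = (
                g_na * rev[0]
                + (g_cal + g_car + g_cat) * rev[1]
                + (g_kv1 + g_kv2 + g_ka + g_kir) * rev[4]
                + g_h * rev[8]
                + g_leak * rev[9]
            )
            g_tot[i] = g_sum
            b_tot[i] = b_sum

        # ------------------------------------------------ calcium shells
        # longitudinal fluxes (explicit, symmetric -> conservative)
        for i in range(n):
            for s in range(4):
                dca[i, s] = 0.0
                dbm[i, s] = 0.0
        for i in range(n):
            p = parent[i]
            if p >= 0:
                for s in range(4):
                    fl = long_g_ca[i, s] * (ca[p, s] - ca[i, s])
                    dca[i, s] += fl / vols[i, s]
                    dca[p, s] -= fl / vols[p, s]
                    fb = long_g_buf[i, s] * (bufm[p, s] - bufm[i, s])
                    dbm[i, s] += fb / vols[i, s]
                    dbm[p, s] -= fb / vols[p, s]

        for i in range(n):
            # explicit sources
            if pump_on:
                ca[i, 0] += dt * (
                    influx_fac[i] * (-i_ca_dens[i])
                    - pump_fac[i] * ca[i, 0] / (ca[i, 0] + pump_km)
                )
            if er_on:
                for s in range(4):
                    c = ca[i, s]
                    serca = serca_vmax * c * c / (c * c + serca_km * serca_km)
                    leak = er_leak_k * (ca_er - c)
                    ip3 = ip3_k * (ca_er - c)
                    ca[i, s] += dt * (a_ip3 * ip3 + b_er * (leak - serca))
            for s in range(4):
                ca[i, s] += dt * dca[i, s]
                bufm[i, s] += dt * dbm[i, s]

            # implicit radial diffusion (precomputed inverse matrices)
            for r in range(4):
                acc = 0.0
                for c in range(4):
                    acc += diff_ca_inv[i, r, c] * ca[i, c]
                tmp4[r] = acc
            for r in range(4):
                ca[i, r] = tmp4[r]
            for r in range(4):
                acc = 0.0
                for c in range(4):
                    acc += diff_buf_inv[i, r, c] * bufm[i, c]
                tmp4[r] = acc
            for r in range(4):
                bufm[i, r] = tmp4[r]

            # semi-implicit buffer binding (stationary then mobile)
            for s in range(4):
                free = bs_tot - bufs[i, s]
                if free < 0.0:
                    free = 0.0
                a = bs_kon * free
                koff = bs_kon * bs_kd
                det = 1.0 + dt * a + dt * koff
                c_new = ((1.0 + dt * koff) * ca[i, s] + dt * koff * bufs[i, s]) / det
                b_new = (dt * a * ca[i, s] + (1.0 + dt * a) * bufs[i, s]) / det
                ca[i, s] = c_new
                bufs[i, s] = b_new

                free = bm_tot - bufm[i, s]
                if free < 0.0:
                    free = 0.0
                a = bm_kon * free
                koff = bm_kon * bm_kd
                det = 1.0 + dt * a + dt * koff
                c_new = ((1.0 + dt * koff) * ca[i, s] + dt * koff * bufm[i, s]) / det
                b_new = (dt * a * ca[i, s] + (1.0 + dt * a) * bufm[i, s]) / det
                ca[i, s] = c_new
                bufm[i, s] = b_new

            # ------------------------------------------ nanodomain and TRPM4
            if playback:
                cand[i] = cand_play[step, i]
            else:
                influx = X * nd_scale * (-i_ca_dens[i]) if i_ca_dens[i] < 0.0 else 0.0
                target = ca[i, 0] + nd_tau * influx
                cand[i] = target + (cand[i] - target) * nd_efac

            v_eff = v_freeze if freeze_v else V[i]
            alpha = TRPM4_ALPHA0 * np.exp(TRPM4_ASLOPE * v_eff)
            beta = TRPM4_BETA0 * np.exp(TRPM4_BSLOPE * v_eff)
            alpha_p = alpha / (1.0 + TRPM4_KD / cand[i])
            m_inf = alpha_p / (alpha_p + beta)
            tau_m = 1.0 / (alpha_p + beta)
            m_trpm4[i] = m_inf + (m_trpm4[i] - m_inf) * np.exp(-dt / tau_m)

            g_t = g_dens[10, i] * m_trpm4[i]
            g_tot[i] += g_t
            b_tot[i] += g_t * rev[10]

        # ------------------------------------------------ voltage (theta method)
        # c/dt (Vn - Vo) = -theta*(G Vn - b - ax(Vn)) - (1-theta)*(G Vo - b - ax(Vo)) + inj
        for i in range(n):
            mem_scale = 1e3 * area_cm2[i]  # mA/cm2 * cm2 -> uA
            diag[i] = c_abs[i] / dt + theta * mem_scale * g_tot[i]
            r = (
                c_abs[i] / dt * V[i]
                + mem_scale * (b_tot[i] - (1.0 - theta) * g_tot[i] * V[i])
            )
            if i == inj_comp:
                r += 1e-3 * stim[step]  # nA -> uA
            rhs[i] = r
        if theta < 1.0:
            for i in range(n):
                p = parent[i]
                if p >= 0:
                    ax = 1e-3 * g_ax[i] * (V[p] - V[i])  # uS*mV -> nA -> uA
                    rhs[i] += (1.0 - theta) * ax
                    rhs[p] -= (1.0 - theta) * ax
        for i in range(n):
            p = parent[i]
            if p >= 0:
                diag[i] += theta * 1e-3 * g_ax[i]
                diag[p] += theta * 1e-3 * g_ax[i]
        # Hines elimination (parent index < child index)
        for i in range(n - 1, 0, -1):
            p = parent[i]
            off = -theta * 1e-3 * g_ax[i]
            fac = off / diag[i]
            diag[p] -= fac * off
            rhs[p] -= fac * rhs[i]
        V[0] = rhs[0] / diag[0]
        for i in range(1, n):
            p = parent[i]
            off = -theta * 1e-3 * g_ax[i]
            V[i] = (rhs[i] - off * V[p]) / diag[i]

        # ------------------------------------------------ record
        for i in range(n):
            v_rec[step, i] = V[i]
            cand_rec[step, i] = cand[i]
        v0 = V[0]
        g_na = g_dens[0, 0] * nav[0, 1]
        g_cal = g_dens[1, 0] * gates[0, 0] * gates[0, 0]
        g_car = g_dens[2, 0] * gates[0, 1] * gates[0, 2]
        g_cat = g_dens[3, 0] * gates[0, 3] * gates[0, 3] * gates[0, 4]
        g_kv1 = g_dens[4, 0] * gates[0, 5]
        g_kv2 = g_dens[5, 0] * gates[0, 6]
        g_ka = g_dens[6, 0] * gates[0, 7] * gates[0, 8]
        x = (v0 - v_min) / dv_tab
        if x < 0.0:
            x = 0.0
        elif x > nv - 1.001:
            x = nv - 1.001
        k = int(x)
        f = x - k
        kir_o = kir_tab[k] + f * (kir_tab[k + 1] - kir_tab[k])
        g_kir = g_dens[7, 0] * kir_o
        g_h = g_dens[8, 0] * gates[0, 9]
        g_leak = g_dens[9, 0]
        g_t = g_dens[10, 0] * m_trpm4[0]
        soma_rec[step, REC_I_NA] = g_na * (v0 - rev[0])
        soma_rec[step, REC_I_CAL] = g_cal * (v0 - rev[1])
        soma_rec[step, REC_I_CAR] = g_car * (v0 - rev[1])
        soma_rec[step, REC_I_CAT] = g_cat * (v0 - rev[1])
        soma_rec[step, REC_I_KV1] = g_kv1 * (v0 - rev[4])
        soma_rec[step, REC_I_KV2] = g_kv2 * (v0 - rev[4])
        soma_rec[step, REC_I_KA] = g_ka * (v0 - rev[4])
        soma_rec[step, REC_I_KIR] = g_kir * (v0 - rev[4])
        soma_rec[step, REC_I_H] = g_h * (v0 - rev[8])
        soma_rec[step, REC_I_LEAK] = g_leak * (v0 - rev[9])
        soma_rec[step, REC_I_TRPM4] = g_t * (v0 - rev[10])
        net = 0.0
        for j in range(11):
            net += soma_rec[step, j]
        soma_rec[step, REC_I_NET] = net
        for r in range(4):
            soma_rec[step, REC_NAV_C + r] = nav[0, r]
            soma_rec[step, REC_CA_SH1 + r] = ca[0, r]
        soma_rec[step, REC_CA_ND] = cand[0]
        soma_rec[step, REC_TRPM4_M] = m_trpm4[0]
        soma_rec[step, REC_I_CA] = i_ca_dens[0]

        if not (-200.0 < V[0] < 200.0) or V[0] != V[0]:
            return step + 1  # diverged
    return 0
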