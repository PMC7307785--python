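"""Fused simulation kernel.

A single numba-compiled loop advances the coupled system: implicit
(backward-Euler) tridiagonal cable solve for voltage on the unbranched
axon–soma–proximal–distal chain, exponential-Euler gating updates
staggered at the previous-step voltage, event-driven and OU synaptic
conductances, and the explicit chloride (and optionally potassium) mass
balance with longitudinal diffusion.

All quantities entering the kernel are pre-converted to the package unit
system (mV, ms, µS, nA, nF, litres); densities have been multiplied by
compartment areas beforehand.
"""

import numpy as np
from numba import njit

from .mechanisms import hh_rates, m_current_gate

STATUS_OK = 0
STATUS_V_DIVERGED = 1
STATUS_CL_UNDERFLOW = 2


@njit(cache=True)
def _thomas(lower, diag, upper, rhs, x):
    """In-place Thomas solve of a tridiagonal system (overwrites inputs)."""
    n = diag.shape[0]
    for i in range(1, n):
        w = lower[i - 1] / diag[i - 1]
        diag[i] -= w * upper[i - 1]
        rhs[i] -= w * rhs[i - 1]
    x[n - 1] = rhs[n - 1] / diag[n - 1]
    for i in range(n - 2, -1, -1):
        x[i] = (rhs[i] - upper[i] * x[i + 1]) / diag[i]


@njit(cache=True)
def run_kernel(
    # sizes / time
    n_steps, dt,
    # geometry (per compartment unless noted)
    cap_nF, area_cm2, vol_L, g_ax_uS,          # g_ax: n-1 couplings
    dif_w,                                      # n-1: D*A_x/dx * 1e-15  (L/ms)
    # passive leaks, absolute µS
    glk_uS, glna_uS, glcl_uS,
    # HH channels, absolute µS
    gna_uS, gk_uS, gm_uS, vt, tau_max_m, n_exp,
    # KCC2
    pk_mAmM2cm2, kcc2_electrogenic,
    # fixed ion quantities
    rtf_mV, F, clo, ki_fixed, ko, ehco3, ek_fixed, ena,
    # modes
    dyn_cl, dyn_k,
    # dynamic-K extras (ignored unless dyn_k)
    gpas_uS, e_pas, tonic_cl, tonic_k, k0,
    # event-driven excitation (aggregated per compartment)
    eev_step, eev_comp, eev_wa, eev_wn,         # sorted by step
    fra, fda, frn, fdn,                         # per-step decay factors
    mg_over, mg_slope, e_exc,
    # event-driven inhibition (per synapse)
    isyn_comp, isyn_gmax_uS, iev_step, iev_syn,
    gaba_decay_bound, gaba_sinf, gaba_decay_free, pulse_steps,
    # gclamp sites
    gc_comp, gc_mean_uS, gc_sd_uS, gc_decay, gc_is_inh, gc_dyn_egaba,
    gc_noise,                                   # (n_steps, n_sites)
    e_inh_fixed,
    # current injection
    inj_comp, inj_nA, inj_start, inj_end,
    # initial state
    v0, cl0,
    # recording
    rec_every,
):
    n = v0.shape[0]
    v = v0.copy()
    cl = cl0.copy()
    k_conc = k0.copy()

    # gating state initialised at steady state of the initial voltage
    m = np.empty(n); h = np.empty(n); ng = np.empty(n); mM = np.empty(n)
    for i in range(n):
        am, bm, ah, bh, an, bn = hh_rates(v[i], vt)
        m[i] = am / (am + bm)
        h[i] = ah / (ah + bh)
        ng[i] = an / (an + bn)
        mi, _ = m_current_gate(v[i], tau_max_m)
        mM[i] = mi

    ecl = rtf_mV * np.log(cl / clo)
    ek = np.full(n, ek_fixed)
    if dyn_k:
        for i in range(n):
            ek[i] = rtf_mV * np.log(ko / k_conc[i])

    # synaptic state
    a_ampa = np.zeros(n); b_ampa = np.zeros(n)
    a_nmda = np.zeros(n); b_nmda = np.zeros(n)
    n_isyn = isyn_comp.shape[0]
    s_gaba = np.zeros(n_isyn)
    t_rem = np.zeros(n_isyn, dtype=np.int64)
    n_gc = gc_comp.shape[0]
    gc_state = gc_mean_uS.copy()

    # records
    n_snap = n_steps // rec_every + 1
    v_tip = np.empty(n_steps)
    v_soma_tr = np.empty(n_steps)
    soma_idx = inj_comp  # caller passes soma midpoint even when inj_nA == 0
    v_snap = np.empty((n_snap, n))
    cl_snap = np.empty((n_snap, n))
    snap_i = 0
    v_snap[0] = v
    cl_snap[0] = cl
    snap_i = 1

    # scratch for the tridiagonal solve
    lo = np.empty(n - 1); di = np.empty(n); up = np.empty(n - 1)
    rhs = np.empty(n); v_new = np.empty(n)
    g_gaba_comp = np.zeros(n)
    g_gc_exc = np.zeros(n)
    g_gc_inh = np.zeros(n)
    dcl = np.zeros(n)

    pe = 0
    pi = 0
    n_eev = eev_step.shape[0]
    n_iev = iev_step.shape[0]
    fail_step = -1
    status = STATUS_OK

    for step in range(n_steps):
        # -------- events --------------------------------------------------
        while pe < n_eev and eev_step[pe] == step:
            c = eev_comp[pe]
            a_ampa[c] += eev_wa[pe]; b_ampa[c] += eev_wa[pe]
            a_nmda[c] += eev_wn[pe]; b_nmda[c] += eev_wn[pe]
            pe += 1
        while pi < n_iev and iev_step[pi] == step:
            t_rem[iev_syn[pi]] = pulse_steps
            pi += 1

        # -------- synaptic state updates ---------------------------------
        for i in range(n):
            a_ampa[i] *= fra; b_ampa[i] *= fda
            a_nmda[i] *= frn; b_nmda[i] *= fdn
            g_gaba_comp[i] = 0.0
            g_gc_exc[i] = 0.0
            g_gc_inh[i] = 0.0
        for sidx in range(n_isyn):
            if t_rem[sidx] > 0:
                s_gaba[sidx] = gaba_sinf + (s_gaba[sidx] - gaba_sinf) * gaba_decay_bound
                t_rem[sidx] -= 1
            else:
                s_gaba[sidx] *= gaba_decay_free
            g_gaba_comp[isyn_comp[sidx]] += isyn_gmax_uS[sidx] * s_gaba[sidx]
        for gi in range(n_gc):
            mean = gc_mean_uS[gi]
            gc_state[gi] = (mean + (gc_state[gi] - mean) * gc_decay
                            + gc_sd_uS[gi] * gc_noise[step, gi])
            gval = gc_state[gi] if gc_state[gi] > 0.0 else 0.0
            if gc_is_inh[gi]:
                g_gc_inh[gc_comp[gi]] += gval
            else:
                g_gc_exc[gc_comp[gi]] += gval

        # -------- gating (at previous-step voltage) -----------------------
        for i in range(n):
            if gna_uS[i] > 0.0 or gk_uS[i] > 0.0 or gm_uS[i] > 0.0:
                am, bm, ah, bh, an, bn = hh_rates(v[i], vt)
                tm = 1.0 / (am + bm); minf = am * tm
                th = 1.0 / (ah + bh); hinf = ah * th
                tn = 1.0 / (an + bn); ninf = an * tn
                m[i] = minf + (m[i] - minf) * np.exp(-dt / tm)
                h[i] = hinf + (h[i] - hinf) * np.exp(-dt / th)
                ng[i] = ninf + (ng[i] - ninf) * np.exp(-dt / tn)
                mi, tM = m_current_gate(v[i], tau_max_m)
                mM[i] = mi + (mM[i] - mi) * np.exp(-dt / tM)

        # -------- assemble and solve the cable system ---------------------
        for i in range(n):
            egaba_i = 0.8 * ecl[i] + 0.2 * ehco3
            G = 0.0
            B = 0.0
            if dyn_k:
                G += gpas_uS[i]; B += gpas_uS[i] * e_pas
            else:
                G += glk_uS[i] + glna_uS[i] + glcl_uS[i]
                B += glk_uS[i] * ek[i] + glna_uS[i] * ena + glcl_uS[i] * ecl[i]
            if gna_uS[i] > 0.0:
                gna_eff = m[i] ** 3 * h[i] * gna_uS[i]
                G += gna_eff; B += gna_eff * ena
            if gk_uS[i] > 0.0:
                gk_eff = gk_uS[i] * ng[i] ** n_exp
                G += gk_eff; B += gk_eff * ek[i]
            if gm_uS[i] > 0.0:
                gm_eff = gm_uS[i] * mM[i]
                G += gm_eff; B += gm_eff * ek[i]
            # excitatory event-driven
            g_a = b_ampa[i] - a_ampa[i]
            mg = 1.0 / (1.0 + mg_over * np.exp(mg_slope * v[i]))
            g_n = (b_nmda[i] - a_nmda[i]) * mg
            if g_a < 0.0:
                g_a = 0.0
            if g_n < 0.0:
                g_n = 0.0
            G += g_a + g_n; B += (g_a + g_n) * e_exc
            # GABA_A event-driven: anionic split
            if g_gaba_comp[i] > 0.0:
                gcl_s = 0.8 * g_gaba_comp[i]
                gh_s = 0.2 * g_gaba_comp[i]
                G += gcl_s + gh_s
                B += gcl_s * ecl[i] + gh_s * ehco3
            # gclamp
            if g_gc_exc[i] > 0.0:
                G += g_gc_exc[i]; B += g_gc_exc[i] * e_exc
            if g_gc_inh[i] > 0.0:
                if gc_dyn_egaba:
                    gcl_s = 0.8 * g_gc_inh[i]
                    gh_s = 0.2 * g_gc_inh[i]
                    G += gcl_s + gh_s
                    B += gcl_s * ecl[i] + gh_s * ehco3
                else:
                    G += g_gc_inh[i]; B += g_gc_inh[i] * e_inh_fixed
            # KCC2 as a charge-carrying Cl⁻ current (optional mode):
            # extrusion = Cl⁻ efflux = inward charge = negative outward current
            if kcc2_electrogenic:
                j = pk_mAmM2cm2[i] * (ki_fixed * cl[i] - ko * clo)
                B += -(j * area_cm2[i] * 1e6)
            # injected step current (positive = depolarising)
            if inj_nA != 0.0 and i == inj_comp and inj_start <= step < inj_end:
                B += inj_nA

            cdt = cap_nF[i] / dt
            di[i] = cdt + G
            rhs[i] = cdt * v[i] + B

        for j2 in range(n - 1):
            lo[j2] = -g_ax_uS[j2]
            up[j2] = -g_ax_uS[j2]
            di[j2] += g_ax_uS[j2]
            di[j2 + 1] += g_ax_uS[j2]
        _thomas(lo, di, up, rhs, v_new)
        for i in range(n):
            v[i] = v_new[i]

        # -------- chloride / potassium update -----------------------------
        if dyn_cl:
            for i in range(n):
                icl = 0.0                         # nA, positive outward = influx
                if not dyn_k:
                    icl += glcl_uS[i] * (v[i] - ecl[i])
                if g_gaba_comp[i] > 0.0:
                    icl += 0.8 * g_gaba_comp[i] * (v[i] - ecl[i])
                if g_gc_inh[i] > 0.0 and gc_dyn_egaba:
                    icl += 0.8 * g_gc_inh[i] * (v[i] - ecl[i])
                d = 1e-9 * icl / (F * vol_L[i])
                rate = (1e-3 * pk_mAmM2cm2[i]
                        * (ki_fixed if not dyn_k else k_conc[i]) * cl[i]
                        * area_cm2[i] / (F * vol_L[i]))
                rate -= (1e-3 * pk_mAmM2cm2[i] * ko * clo
                         * area_cm2[i] / (F * vol_L[i]))
                d -= rate
                if dyn_k:
                    d += tonic_cl[i]
                dcl[i] = d
            for j2 in range(n - 1):
                flux = dif_w[j2] * (cl[j2 + 1] - cl[j2])   # L·mM/ms
                dcl[j2] += flux / vol_L[j2]
                dcl[j2 + 1] -= flux / vol_L[j2 + 1]
            for i in range(n):
                cl[i] += dt * dcl[i]
                if cl[i] < 1e-3:
                    status = STATUS_CL_UNDERFLOW
                    fail_step = step
                    break
                ecl[i] = rtf_mV * np.log(cl[i] / clo)
            if status != STATUS_OK:
                break
            if dyn_k:
                for i in range(n):
                    rate = (1e-3 * pk_mAmM2cm2[i]
                            * (k_conc[i] * cl[i] - ko * clo)
                            * area_cm2[i] / (F * vol_L[i]))
                    k_conc[i] += dt * (-rate + tonic_k[i])
                    ek[i] = rtf_mV * np.log(ko / k_conc[i])

        # -------- records / divergence guard ------------------------------
        v_tip[step] = v[0]
        v_soma_tr[step] = v[soma_idx]
        if (step + 1) % rec_every == 0 and snap_i < n_snap:
            v_snap[snap_i] = v
            cl_snap[snap_i] = cl
            snap_i += 1
        if step % 200 == 0:
            bad = False
            for i in range(n):
                if not np.isfinite(v[i]) or abs(v[i]) > 200.0:
                    bad = True
            if bad:
                status = STATUS_V_DIVERGED
                fail_step = step
                break

    return (status, fail_step, v_tip, v_soma_tr,
            v_snap[:snap_i], cl_snap[:snap_i], v, cl, k_conc)
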