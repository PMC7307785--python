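"""Simulation driver: couples the cable solver with mechanisms, synapses,
and the chloride mass balance; records traces and detects spikes."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _kernel
from .chloride import D_CL_DEFAULT, DynamicPotassium, egaba_combine
from .constants import DEFAULT_CONSTANTS
from .mechanisms import DEFAULT_TAU_MAX_M, DEFAULT_VT, NumericalFailure
from .morphology import NeuronModel
from .synapses import (
    E_EXC, E_INH_FIXED, GCLAMP_TAU_MS, MG_MM, TRANSMITTER_MM, TRANSMITTER_MS,
    StimulusProgram, dual_exp_norm, spike_trains_for,
)


@dataclass
class SimulationConfig:
    """Run-level settings.

    ``chloride_mode`` is ``"dynamic"`` (mass balance active) or
    ``"static"`` (every [Cl⁻]i frozen at its initial value, EGABA computed
    once).  ``potassium_mode`` is ``"fixed"`` or ``"dynamic"``.
    """

    dt_ms: float = 0.025
    duration_ms: float = 1000.0
    chloride_mode: str = "dynamic"
    potassium_mode: str = "fixed"
    seed: int = 0
    record_every_ms: float = 1.0
    spike_threshold_mV: float = -20.0
    spike_lockout_ms: float = 2.0
    vt: float = DEFAULT_VT
    tau_max_m: float = DEFAULT_TAU_MAX_M
    n_exponent: int = 1
    kcc2_electrogenic: bool = False
    d_cl: float = D_CL_DEFAULT
    inj_nA: float = 0.0             # somatic step current
    inj_start_ms: float = 0.0
    inj_end_ms: float = 0.0

    def __post_init__(self):
        if self.dt_ms <= 0:
            raise ValueError("dt must be > 0")
        if self.duration_ms < self.dt_ms:
            raise ValueError("duration must be >= dt")
        if self.chloride_mode not in ("dynamic", "static"):
            raise ValueError("chloride_mode must be 'dynamic' or 'static'")
        if self.potassium_mode not in ("fixed", "dynamic"):
            raise ValueError("potassium_mode must be 'fixed' or 'dynamic'")


@dataclass
class SimulationResult:
    """Traces, spike times, and end-of-run state of one simulation."""

    dt_ms: float
    v_tip: np.ndarray                # axon-tip Vm each step
    v_soma: np.ndarray               # somatic Vm each step
    t_snap_ms: np.ndarray            # snapshot times
    v_snap: np.ndarray               # (n_snap, n_comp)
    cl_snap: np.ndarray              # (n_snap, n_comp)
    egaba_snap: np.ndarray           # (n_snap, n_comp)
    spike_times_ms: np.ndarray
    final_v: np.ndarray
    final_cl: np.ndarray
    final_k: np.ndarray
    config: dict
    model: NeuronModel

    @property
    def t_ms(self) -> np.ndarray:
        return (np.arange(len(self.v_tip)) + 1) * self.dt_ms

    def section_mean(self, arr_snap: np.ndarray, section: str) -> np.ndarray:
        """Spatial mean of a snapshot series over one section's compartments."""
        mask = self.model.section_mask(section)
        return arr_snap[:, mask].mean(axis=1)

    def distal_delta_egaba(self) -> float:
        """Change in distal-dendrite spatial-mean EGABA from start to end (mV)."""
        tr = self.section_mean(self.egaba_snap, "distal")
        return float(tr[-1] - tr[0])


def detect_spikes(v: np.ndarray, dt_ms: float, threshold_mV: float = -20.0,
                  lockout_ms: float = 2.0) -> np.ndarray:
    """Upward threshold crossings with a refractory lockout (times in ms)."""
    above = v >= threshold_mV
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if len(crossings) == 0:
        return np.empty(0)
    lockout = max(int(round(lockout_ms / dt_ms)), 1)
    kept = [crossings[0]]
    for c in crossings[1:]:
        if c - kept[-1] >= lockout:
            kept.append(c)
    return (np.asarray(kept) + 1) * dt_ms


def _build_exc_events(stim: StimulusProgram, duration_ms, dt_ms, seed_seq):
    syns = stim.excitatory
    if not syns or stim.exc_rate_hz <= 0:
        z = np.empty(0, dtype=np.int64)
        return z, z.copy(), np.empty(0), np.empty(0)
    trains = spike_trains_for(len(syns), stim.exc_rate_hz, duration_ms, seed_seq)
    steps, comps, wa, wn = [], [], [], []
    for syn, tr in zip(syns, trains):
        norm_a = dual_exp_norm(syn.tau_rise_ampa, syn.tau_decay_ampa)
        norm_n = dual_exp_norm(syn.tau_rise_nmda, syn.tau_decay_nmda)
        w_ampa = syn.g_max_uS * (1.0 - syn.nmda_fraction) / norm_a
        w_nmda = syn.g_max_uS * syn.nmda_fraction / norm_n
        st = (tr / dt_ms).astype(np.int64)
        steps.append(st)
        comps.append(np.full(len(st), syn.compartment, dtype=np.int64))
        wa.append(np.full(len(st), w_ampa))
        wn.append(np.full(len(st), w_nmda))
    steps = np.concatenate(steps)
    order = np.argsort(steps, kind="stable")
    return (steps[order], np.concatenate(comps)[order],
            np.concatenate(wa)[order], np.concatenate(wn)[order])


def _build_inh_events(stim: StimulusProgram, duration_ms, dt_ms, seed_seq):
    syns = stim.inhibitory
    comp = np.array([s.compartment for s in syns], dtype=np.int64)
    gmax = np.array([s.g_max_uS for s in syns], dtype=float)
    if not syns or stim.inh_rate_hz <= 0:
        z = np.empty(0, dtype=np.int64)
        return comp, gmax, z, z.copy()
    trains = spike_trains_for(len(syns), stim.inh_rate_hz, duration_ms, seed_seq)
    steps, sidx = [], []
    for i, tr in enumerate(trains):
        st = (tr / dt_ms).astype(np.int64)
        steps.append(st)
        sidx.append(np.full(len(st), i, dtype=np.int64))
    steps = np.concatenate(steps)
    order = np.argsort(steps, kind="stable")
    return comp, gmax, steps[order], np.concatenate(sidx)[order]


def simulate(model: NeuronModel, stim: StimulusProgram | None,
             config: SimulationConfig,
             dynamic_k: DynamicPotassium | None = None) -> SimulationResult:
    """Integrate the full coupled system and return traces and spikes.

    Reproducible bit-for-bit for a fixed (model, stimulus, config): all
    randomness derives from ``stim.seed`` via a spawning seed sequence
    (excitatory trains, inhibitory trains, then gclamp noise).
    """
    stim = stim or StimulusProgram()
    cfg = config
    dt = cfg.dt_ms
    n_steps = int(round(cfg.duration_ms / dt))
    n = model.n
    cons = model.constants
    ions = model.ions

    root = np.random.SeedSequence(stim.seed)
    ss_exc, ss_inh, ss_gc = root.spawn(3)

    for kind, syns in (("excitatory", stim.excitatory),
                       ("inhibitory", stim.inhibitory),
                       ("gclamp", stim.gclamps)):
        for s in syns:
            if not (0 <= s.compartment < n):
                raise ValueError(
                    f"{kind} synapse compartment {s.compartment} out of range")

    eev_step, eev_comp, eev_wa, eev_wn = _build_exc_events(
        stim, cfg.duration_ms, dt, ss_exc)
    isyn_comp, isyn_gmax, iev_step, iev_syn = _build_inh_events(
        stim, cfg.duration_ms, dt, ss_inh)

    # gclamp arrays
    n_gc = len(stim.gclamps)
    gc_comp = np.array([g.compartment for g in stim.gclamps], dtype=np.int64)
    gc_mean = np.array([g.mean_uS for g in stim.gclamps], dtype=float)
    gc_sd = np.array([g.cv * g.mean_uS for g in stim.gclamps], dtype=float)
    gc_is_inh = np.array([g.inhibitory for g in stim.gclamps], dtype=np.bool_)
    gc_dyn_egaba = bool(all(g.dynamic_egaba for g in stim.gclamps)) if n_gc else True
    gc_tau = stim.gclamps[0].tau_ms if n_gc else GCLAMP_TAU_MS
    gc_decay = math.exp(-dt / gc_tau)
    rng_gc = np.random.default_rng(ss_gc)
    # kernel multiplies by sd; fold the exact-OU noise gain in here
    gc_noise = (rng_gc.standard_normal((n_steps, n_gc))
                * math.sqrt(1.0 - gc_decay ** 2) if n_gc
                else np.zeros((n_steps, 0)))

    # GABA kinetic constants
    alpha = stim.inhibitory[0].alpha if stim.inhibitory else 5.0
    beta = stim.inhibitory[0].beta if stim.inhibitory else 0.18
    kb = alpha * TRANSMITTER_MM + beta
    gaba_decay_bound = math.exp(-kb * dt)
    gaba_sinf = alpha * TRANSMITTER_MM / kb
    gaba_decay_free = math.exp(-beta * dt)
    pulse_steps = max(int(round(TRANSMITTER_MS / dt)), 1)

    # fixed reversals
    rtf = cons.rtf_mV
    ek_fixed = rtf * math.log(ions.K_o / ions.K_i)
    ena = rtf * math.log(ions.Na_o / ions.Na_i)
    ehco3 = -rtf * math.log(ions.HCO3_o / ions.HCO3_i)

    # absolute conductances
    a6 = model.area_cm2 * 1e6
    glk = model.g_leak_K * a6
    glna = model.g_leak_Na * a6
    glcl = model.g_leak_Cl * a6
    gna = model.g_na * a6
    gk = model.g_k * a6
    gm = model.g_m * a6
    cap_nF = model.cm * model.area_cm2 * 1e3

    dif_w = cfg.d_cl * model.diff_axs_um2 / model.dx_um * 1e-15

    dyn_k = dynamic_k is not None and dynamic_k.enabled
    if cfg.potassium_mode == "dynamic" and not dyn_k:
        raise ValueError("potassium_mode='dynamic' requires a DynamicPotassium "
                         "configuration from enable_dynamic_potassium()")
    if dyn_k:
        gpas = (model.g_leak_K + model.g_leak_Na + model.g_leak_Cl) * a6
        e_pas = dynamic_k.e_pas_mV
        tonic_cl = dynamic_k.tonic_cl_mM_per_ms
        tonic_k = dynamic_k.tonic_k_mM_per_ms
    else:
        gpas = np.zeros(n)
        e_pas = 0.0
        tonic_cl = np.zeros(n)
        tonic_k = np.zeros(n)
    k0 = np.full(n, ions.K_i)

    # dual-exp per-step decay factors (shared taus across synapses)
    ex0 = stim.excitatory[0] if stim.excitatory else None
    fra = math.exp(-dt / (ex0.tau_rise_ampa if ex0 else 0.2))
    fda = math.exp(-dt / (ex0.tau_decay_ampa if ex0 else 1.7))
    frn = math.exp(-dt / (ex0.tau_rise_nmda if ex0 else 2.04))
    fdn = math.exp(-dt / (ex0.tau_decay_nmda if ex0 else 75.2))

    rec_every = max(int(round(cfg.record_every_ms / dt)), 1)
    inj_start = int(round(cfg.inj_start_ms / dt))
    inj_end = int(round(cfg.inj_end_ms / dt))

    out = _kernel.run_kernel(
        n_steps, dt,
        cap_nF, model.area_cm2, model.vol_L, model.g_axial_uS, dif_w,
        glk, glna, glcl,
        gna, gk, gm, cfg.vt, cfg.tau_max_m, cfg.n_exponent,
        model.p_kcc2, cfg.kcc2_electrogenic,
        rtf, cons.F, ions.Cl_o, ions.K_i, ions.K_o, ehco3, ek_fixed, ena,
        cfg.chloride_mode == "dynamic", dyn_k,
        gpas, e_pas, tonic_cl, tonic_k, k0,
        eev_step, eev_comp, eev_wa, eev_wn,
        fra, fda, frn, fdn,
        MG_MM / 3.57, -0.062, E_EXC,
        isyn_comp, isyn_gmax, iev_step, iev_syn,
        gaba_decay_bound, gaba_sinf, gaba_decay_free, pulse_steps,
        gc_comp, gc_mean, gc_sd, gc_decay, gc_is_inh, gc_dyn_egaba,
        np.ascontiguousarray(gc_noise),
        E_INH_FIXED,
        model.soma_index, cfg.inj_nA, inj_start, inj_end,
        model.v0_mV.astype(float), model.cl0_mM.astype(float),
        rec_every,
    )
    (status, fail_step, v_tip, v_soma, v_snap, cl_snap,
     final_v, final_cl, final_k) = out
    if status == _kernel.STATUS_V_DIVERGED:
        raise NumericalFailure(f"voltage diverged at step {fail_step}")
    if status == _kernel.STATUS_CL_UNDERFLOW:
        raise NumericalFailure(f"[Cl-]i underflow at step {fail_step}")

    ecl_snap = rtf * np.log(cl_snap / ions.Cl_o)
    egaba_snap = egaba_combine(ecl_snap, ehco3)
    t_snap = np.arange(v_snap.shape[0]) * rec_every * dt

    spikes = detect_spikes(v_tip, dt, cfg.spike_threshold_mV,
                           cfg.spike_lockout_ms)
    return SimulationResult(
        dt_ms=dt, v_tip=v_tip, v_soma=v_soma,
        t_snap_ms=t_snap, v_snap=v_snap, cl_snap=cl_snap,
        egaba_snap=egaba_snap, spike_times_ms=spikes,
        final_v=final_v, final_cl=final_cl, final_k=final_k,
        config=asdict(cfg), model=model,
    )
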