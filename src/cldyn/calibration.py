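"""Calibration: analysis of chloride-recovery recordings (EGABA from puff
currents, single-exponential recovery fitting, pump-strength estimation)
and model tuning (leak fitting to input resistance, resting-state
computation, balanced excitation/inhibition search).

The recovery pipeline mirrors the perforated-patch experiment: a 15 s
optogenetic Cl⁻ load is followed by recovery toward baseline; sparse
[Cl⁻]i samples are fitted with ``baseline + A·exp(−t/τ)``, differentiated
analytically to an extrusion rate, and regressed against the KCC2 mass-
action bracket [K⁺]i[Cl⁻]i − [K⁺]o[Cl⁻]o to estimate the pump strength P.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .constants import DEFAULT_CONSTANTS, DEFAULT_IONS, IonTable, PhysicalConstants
from .chloride import egaba_combine, nernst
from .engine import SimulationConfig, StimulusProgram, simulate
from .mechanisms import REFERENCE_CELL, convert_pump_strength
from .morphology import NeuronModel
from .synapses import ExcitatorySynapse, InhibitorySynapse, place_evenly


class FitError(RuntimeError):
    """Recovery fit failed or is unidentifiable."""


# ----------------------------------------------------------------------
# EGABA / [Cl-]i algebra
# ----------------------------------------------------------------------

def egaba_from_current(i_pA: float, g_nS: float, vhold_mV: float) -> float:
    """Invert I = g·(Vhold − EGABA): EGABA = Vhold − I/g (pA / nS = mV)."""
    if g_nS <= 0:
        raise ValueError("conductance must be > 0")
    return vhold_mV - i_pA / g_nS


def fit_gaba_conductance(i_pA: np.ndarray, vhold_mV: np.ndarray):
    """Estimate (g_nS, EGABA) from puff currents at ≥ 2 holding potentials.

    Least-squares line I = g·Vhold − g·EGABA.
    """
    vhold = np.asarray(vhold_mV, float)
    if len(np.unique(vhold)) < 2:
        raise ValueError("need >= 2 distinct holding potentials")
    slope, intercept = np.polyfit(vhold, np.asarray(i_pA, float), 1)
    if slope <= 0:
        raise FitError("non-positive fitted conductance")
    return float(slope), float(-intercept / slope)


def cl_from_egaba(egaba_mV: float, hco3_i: float = DEFAULT_IONS.HCO3_i,
                  hco3_o: float = DEFAULT_IONS.HCO3_o,
                  cl_o: float = DEFAULT_IONS.Cl_o,
                  constants: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
    """Invert the 4:1-weighted GABA_A reversal for [Cl⁻]i (mM).

    EGABA = (4/5)ECl + (1/5)EHCO3 with both anion reversals Nernstian.
    """
    if min(hco3_i, hco3_o, cl_o) <= 0:
        raise ValueError("concentrations must be > 0")
    ehco3 = nernst(-1, hco3_i, hco3_o, constants)
    ecl = (egaba_mV - 0.2 * ehco3) / 0.8
    cl_i = cl_o * math.exp(ecl / constants.rtf_mV)
    if not (1e-4 < cl_i < 1e3):
        raise ValueError(
            f"EGABA {egaba_mV} mV maps to non-physical [Cl-]i = {cl_i:.3g} mM")
    return cl_i


# ----------------------------------------------------------------------
# Recovery fitting
# ----------------------------------------------------------------------

@dataclass
class RecoveryTrace:
    """Sparse [Cl⁻]i samples during recovery from a chloride load.

    ``t_s`` are seconds after load offset (strictly increasing, ≥ 4
    samples); ``cl_mM`` the corresponding concentrations; ``baseline_mM``
    the known resting concentration if available (fixed during fitting).
    """

    t_s: np.ndarray
    cl_mM: np.ndarray
    baseline_mM: float | None = None
    noise_sd_mM: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t_s = np.asarray(self.t_s, float)
        self.cl_mM = np.asarray(self.cl_mM, float)
        if len(self.t_s) < 4:
            raise ValueError("need >= 4 samples to fit a recovery")
        if np.any(np.diff(self.t_s) <= 0):
            raise ValueError("sample times must be strictly increasing")

    @classmethod
    def from_table(cls, path) -> "RecoveryTrace":
        df = pd.read_csv(path, sep=r"\s+", comment="#")
        return cls(df.iloc[:, 0].values, df.iloc[:, 1].values)

    def to_table(self, path) -> None:
        pd.DataFrame({"time_s": self.t_s, "cl_mM": self.cl_mM}).to_csv(
            path, sep="\t", index=False)


@dataclass
class PumpEstimate:
    """Result of a recovery fit: time constant and pump strength."""

    tau_s: float
    baseline_mM: float
    amplitude_mM: float
    P_conc: float                 # mM⁻¹·s⁻¹
    P_current: float              # mA·mM⁻²·cm⁻² via the reference geometry
    r_squared: float
    residual_sd_mM: float


def fit_recovery(trace: RecoveryTrace, Ki: float = DEFAULT_IONS.K_i,
                 Ko: float = DEFAULT_IONS.K_o,
                 Clo: float = DEFAULT_IONS.Cl_o) -> PumpEstimate:
    """Fit the single-exponential recovery and estimate the pump strength.

    The extrusion-rate regression is performed on the analytic derivative
    of the fitted exponential evaluated at the sample times: with
    V(t) = −d[Cl⁻]i/dt and the bracket B(t) = Ki·Cl(t) − Ko·Clo, the
    regression V = P·B + c has slope exactly P (a constant tonic influx is
    absorbed by the free intercept).
    """
    t, y = trace.t_s, trace.cl_mM
    amp0 = y[0] - (trace.baseline_mM if trace.baseline_mM is not None else y[-1])
    if abs(amp0) < 1e-9:
        raise FitError("trace already at baseline: pump strength unidentifiable")
    tau0 = max((t[-1] - t[0]) / 3.0, 1e-3)

    try:
        if trace.baseline_mM is not None:
            base = trace.baseline_mM

            def f(tt, A, tau):
                return base + A * np.exp(-tt / tau)

            popt, _ = optimize.curve_fit(f, t, y, p0=(amp0, tau0),
                                         maxfev=10000)
            A, tau = popt
        else:
            def f(tt, base, A, tau):
                return base + A * np.exp(-tt / tau)

            popt, _ = optimize.curve_fit(f, t, y, p0=(y[-1], amp0, tau0),
                                         maxfev=10000)
            base, A, tau = popt
    except RuntimeError as exc:
        raise FitError(f"exponential fit did not converge: {exc}") from exc
    if tau <= 0 or A <= 0:
        raise FitError(
            f"non-decaying fit (A={A:.3g}, tau={tau:.3g}): trace is not a "
            "recovery from an elevated load")

    fitted = base + A * np.exp(-t / tau)
    resid = y - fitted
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 0.0
    if trace.noise_sd_mM == 0 and r2 < 0.9:
        raise FitError(f"poor single-exponential fit (R² = {r2:.3f})")

    # analytic derivative → extrusion rate vs bracket, slope = P
    v_rate = (A / tau) * np.exp(-t / tau)          # mM/s, extrusion positive
    bracket = Ki * fitted - Ko * Clo               # mM²
    slope, intercept = np.polyfit(bracket, v_rate, 1)
    p_conc = float(slope)
    return PumpEstimate(
        tau_s=float(tau), baseline_mM=float(base), amplitude_mM=float(A),
        P_conc=p_conc,
        P_current=convert_pump_strength(p_conc, **REFERENCE_CELL),
        r_squared=r2, residual_sd_mM=float(resid.std()),
    )


# ----------------------------------------------------------------------
# Model tuning
# ----------------------------------------------------------------------

@dataclass
class TunedLeaks:
    """Outcome of leak fitting: densities, achieved Rin, emergent rest."""

    leak_scale: float             # summed S/cm² over the three ions
    rin_MOhm: float
    v_rest_mV: float
    cl_rest_mM: float


def _passive_rin(model: NeuronModel, scale: float) -> float:
    """Input resistance (MΩ) of the passive chain at the soma, analytic.

    Steady-state tridiagonal solve of (G_leak + G_axial)·ΔV = I with a
    unit current at the soma midpoint; MΩ = mV/nA.
    """
    from scipy.linalg import solve_banded
    n = model.n
    g_leak = np.full(n, scale) * model.area_cm2 * 1e6       # µS
    ab = np.zeros((3, n))
    ab[1] = g_leak
    ab[1, :-1] += model.g_axial_uS
    ab[1, 1:] += model.g_axial_uS
    ab[0, 1:] = -model.g_axial_uS
    ab[2, :-1] = -model.g_axial_uS
    rhs = np.zeros(n)
    rhs[model.soma_index] = 1.0                             # 1 nA
    dv = solve_banded((1, 1), ab, rhs)
    return float(dv[model.soma_index])


def resting_state(model: NeuronModel, electrogenic_kcc2: bool = False):
    """Uniform algebraic rest fixed point (V*, [Cl⁻]i*) of the leak+KCC2
    membrane (axonal channels neglected; they perturb rest only weakly).

    Solves simultaneously ΣI_leak = 0 and KCC2 extrusion = leak Cl⁻ influx.
    """
    ions = model.ions
    cons = model.constants
    rtf = cons.rtf_mV
    ek = rtf * math.log(ions.K_o / ions.K_i)
    ena = rtf * math.log(ions.Na_o / ions.Na_i)
    gk, gna, gcl = (float(model.g_leak_K[0]), float(model.g_leak_Na[0]),
                    float(model.g_leak_Cl[0]))
    p = float(model.p_kcc2[model.soma_index])

    def v_of_cl(cl):
        ecl = rtf * math.log(cl / ions.Cl_o)
        j = p * (ions.K_i * cl - ions.K_o * ions.Cl_o)      # mA/cm²
        return ecl + j / gcl                                 # from flux balance

    def f(cl):
        v = v_of_cl(cl)
        ecl = rtf * math.log(cl / ions.Cl_o)
        total = gk * (v - ek) + gna * (v - ena) + gcl * (v - ecl)
        if electrogenic_kcc2:
            total -= p * (ions.K_i * cl - ions.K_o * ions.Cl_o)
        return total

    cl_star = optimize.brentq(f, 1.0, 30.0, xtol=1e-12)
    return v_of_cl(cl_star), cl_star


def measure_input_resistance(model: NeuronModel, inj_nA: float = -0.01,
                             settle_ms: float = 500.0,
                             step_ms: float = 500.0) -> float:
    """Measure Rin with a small hyperpolarising somatic step (simulated).

    ΔV is taken from the pre-step baseline to the step-end plateau.
    """
    cfg = SimulationConfig(duration_ms=settle_ms + step_ms,
                           chloride_mode="static",
                           inj_nA=inj_nA, inj_start_ms=settle_ms,
                           inj_end_ms=settle_ms + step_ms)
    res = simulate(model, None, cfg)
    i0 = int(round(settle_ms / cfg.dt_ms)) - 1
    v_base = res.v_soma[i0]
    v_plateau = res.v_soma[-1]
    return float((v_plateau - v_base) / inj_nA)


def tune_leaks(model: NeuronModel, target_rin_MOhm: float = 365.0,
               refine: bool = True, tol: float = 0.01) -> TunedLeaks:
    """Fit the common leak magnitude (K:Na:Cl ratio fixed) to a target Rin.

    A bracketing search on the analytic passive input resistance is
    followed (optionally) by secant refinement against the simulated
    −10 pA step protocol, which includes the axonal channels' resting
    conductance.  The model is modified in place: leak densities, initial
    V and [Cl⁻]i are set to the tuned, emergent values.
    """
    if target_rin_MOhm <= 0:
        raise ValueError("target Rin must be > 0")

    def err(log_scale):
        return _passive_rin(model, math.exp(log_scale)) - target_rin_MOhm

    lo, hi = math.log(1e-6), math.log(1e-2)
    if err(lo) < 0 or err(hi) > 0:
        raise FitError("target input resistance not bracketed by leak scales")
    log_scale = optimize.brentq(err, lo, hi, xtol=1e-10)
    scale = math.exp(log_scale)
    model.set_leak_scale(scale)
    v, cl = resting_state(model)
    model.v0_mV[:] = v
    model.cl0_mM[:] = cl

    rin = measure_input_resistance(model) if refine else _passive_rin(model, scale)
    if refine:
        # secant iterations on log-scale against the simulated measurement
        for _ in range(4):
            if abs(rin - target_rin_MOhm) / target_rin_MOhm <= tol:
                break
            scale = scale * rin / target_rin_MOhm
            model.set_leak_scale(scale)
            v, cl = resting_state(model)
            model.v0_mV[:] = v
            model.cl0_mM[:] = cl
            rin = measure_input_resistance(model)
        else:
            raise FitError(
                f"input-resistance refinement did not converge (Rin={rin:.1f})")
    return TunedLeaks(leak_scale=scale, rin_MOhm=float(rin),
                      v_rest_mV=float(v), cl_rest_mM=float(cl))


# ----------------------------------------------------------------------
# Balanced-pair search
# ----------------------------------------------------------------------

def distal_fin_program(model: NeuronModel, n_exc: int, n_inh: int,
                       rate_hz: float, seed: int,
                       inh_section: str = "distal") -> StimulusProgram:
    """Evenly distributed f-in synapses: excitation distal, inhibition on
    ``inh_section``; every synapse driven at ``rate_hz``."""
    distal = model.section_compartments("distal")
    inh_comps = model.section_compartments(inh_section)
    return StimulusProgram(
        excitatory=[ExcitatorySynapse(int(c))
                    for c in place_evenly(n_exc, distal)],
        inhibitory=[InhibitorySynapse(int(c))
                    for c in place_evenly(n_inh, inh_comps)],
        exc_rate_hz=rate_hz, inh_rate_hz=rate_hz, seed=seed,
    )


def balanced_pair_search(model: NeuronModel, e_counts, i_counts,
                         input_rate_hz: float = 5.0,
                         target_rate_hz: float = 5.0,
                         trials: int = 3, tol_hz: float = 1.0,
                         chloride_mode: str = "dynamic",
                         inh_section: str = "distal",
                         duration_ms: float = 1000.0,
                         seed: int = 0):
    """Mean output rate over a grid of (E, I) synapse counts.

    Returns ``(rates_df, balanced_pairs)`` where ``rates_df`` is a tidy
    DataFrame (n_exc, n_inh, rate_hz) and ``balanced_pairs`` the list of
    (E, I) whose trial-mean output is within ``tol_hz`` of the target.
    """
    rows = []
    root = np.random.SeedSequence(seed)
    for ne in e_counts:
        for ni in i_counts:
            seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                     for s in root.spawn(trials)]
            rates = []
            for s in seeds:
                stim = distal_fin_program(model, ne, ni, input_rate_hz, s,
                                          inh_section)
                cfg = SimulationConfig(duration_ms=duration_ms,
                                       chloride_mode=chloride_mode)
                res = simulate(model, stim, cfg)
                rates.append(len(res.spike_times_ms) / (duration_ms / 1000.0))
            rows.append((ne, ni, float(np.mean(rates))))
    df = pd.DataFrame(rows, columns=["n_exc", "n_inh", "rate_hz"])
    balanced = [(int(r.n_exc), int(r.n_inh)) for r in df.itertuples()
                if abs(r.rate_hz - target_rate_hz) <= tol_hz]
    return df, balanced
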