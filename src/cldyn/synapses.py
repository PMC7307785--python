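"""Conductance-based synapses and stimulus generators.

Two families of drive are provided, interchangeable at the engine level:

* event-driven ("f-in") synapses receiving Poisson spike trains — mixed
  AMPA+NMDA excitation with dual-exponential kinetics and voltage-dependent
  Mg²⁺ unblock, and kinetic-scheme GABA_A receptors permeable to Cl⁻ and
  HCO₃⁻ in a 4:1 ratio;
* continuous fluctuating-conductance ("gclamp") drives — Ornstein-Uhlenbeck
  conductances with mean = baseline × relative conductance and CV 0.1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

# --- defaults -----------------------------------------------------------
TAU_RISE_AMPA = 0.2      # ms
TAU_DECAY_AMPA = 1.7     # ms
TAU_RISE_NMDA = 2.04     # ms
TAU_DECAY_NMDA = 75.2    # ms
ALPHA_GABA = 5.0         # mM⁻¹·ms⁻¹ transmitter binding rate
BETA_GABA = 0.18         # ms⁻¹ unbinding rate
GMAX_EXC_uS = 1e-3       # 1 nS mixed AMPA+NMDA synapse
GMAX_INH_uS = 350e-6     # 350 pS GABA_A synapse
E_EXC = 0.0              # mV
E_INH_FIXED = -74.0      # mV, legacy fixed-reversal inhibition
CL_FRACTION = 0.8        # Cl⁻ share of the GABA_A conductance (4:1 split)
MG_MM = 1.0              # external Mg²⁺, mM
TRANSMITTER_MM = 1.0     # transmitter pulse concentration
TRANSMITTER_MS = 1.0     # transmitter pulse duration
NMDA_FRACTION = 0.15     # share of g_max assigned to the NMDA component
GCLAMP_BASE_uS = 1e-4    # baseline passive conductance of a gclamp drive
GCLAMP_CV = 0.1          # coefficient of variation of the OU conductance
GCLAMP_TAU_MS = 10.0     # OU correlation time


@dataclass
class ExcitatorySynapse:
    """Mixed AMPA+NMDA synapse at one compartment."""

    compartment: int
    g_max_uS: float = GMAX_EXC_uS
    nmda_fraction: float = NMDA_FRACTION
    tau_rise_ampa: float = TAU_RISE_AMPA
    tau_decay_ampa: float = TAU_DECAY_AMPA
    tau_rise_nmda: float = TAU_RISE_NMDA
    tau_decay_nmda: float = TAU_DECAY_NMDA
    e_rev: float = E_EXC

    def __post_init__(self):
        if self.g_max_uS < 0:
            raise ValueError("g_max must be >= 0")
        if not (self.tau_rise_ampa < self.tau_decay_ampa
                and self.tau_rise_nmda < self.tau_decay_nmda):
            raise ValueError("tau_rise must be < tau_decay")


@dataclass
class InhibitorySynapse:
    """Kinetic GABA_A synapse (closed⇌open scheme, Cl⁻:HCO₃⁻ = 4:1)."""

    compartment: int
    g_max_uS: float = GMAX_INH_uS
    alpha: float = ALPHA_GABA
    beta: float = BETA_GABA

    def __post_init__(self):
        if self.g_max_uS < 0:
            raise ValueError("g_max must be >= 0")


@dataclass
class SpikeTrainStimulus:
    """Poisson drive for a set of synapses (one independent train each)."""

    rate_hz: float
    duration_ms: float
    seed: int

    def __post_init__(self):
        if self.rate_hz < 0:
            raise ValueError("rate must be >= 0")


@dataclass
class FluctuatingConductance:
    """One OU conductance site (gclamp)."""

    compartment: int
    relative: float          # multiplier on the baseline conductance
    inhibitory: bool
    baseline_uS: float = GCLAMP_BASE_uS
    cv: float = GCLAMP_CV
    tau_ms: float = GCLAMP_TAU_MS
    dynamic_egaba: bool = True   # inhibitory site follows local EGABA

    def __post_init__(self):
        if self.relative < 0:
            raise ValueError("relative conductance must be >= 0")

    @property
    def mean_uS(self) -> float:
        return self.baseline_uS * self.relative


@dataclass
class StimulusProgram:
    """Everything the engine needs to drive a simulation."""

    excitatory: list[ExcitatorySynapse] = field(default_factory=list)
    inhibitory: list[InhibitorySynapse] = field(default_factory=list)
    gclamps: list[FluctuatingConductance] = field(default_factory=list)
    exc_rate_hz: float = 0.0
    inh_rate_hz: float = 0.0
    seed: int = 0


# ----------------------------------------------------------------------
# Stimulus generation primitives
# ----------------------------------------------------------------------

def poisson_train(rate_hz: float, duration_ms: float, seed) -> np.ndarray:
    """Sorted Poisson event times (ms) in [0, duration).

    Inter-event intervals are sampled from the exponential distribution
    with mean 1000/rate ms; the train is reproducible for a fixed seed
    (``seed`` may be an int or a :class:`numpy.random.SeedSequence`).
    """
    if rate_hz < 0:
        raise ValueError("rate must be >= 0")
    if rate_hz == 0 or duration_ms <= 0:
        return np.empty(0)
    rng = np.random.default_rng(seed)
    mean_isi = 1000.0 / rate_hz
    # draw in blocks until past the duration
    times = []
    t = rng.exponential(mean_isi)
    while t < duration_ms:
        times.append(t)
        t += rng.exponential(mean_isi)
    return np.asarray(times)


def dual_exp_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Argmax of exp(−t/τd) − exp(−t/τr)."""
    return (tau_rise * tau_decay / (tau_decay - tau_rise)
            * math.log(tau_decay / tau_rise))


def dual_exp_norm(tau_rise: float, tau_decay: float) -> float:
    """Peak value of the un-normalised dual exponential."""
    tp = dual_exp_peak_time(tau_rise, tau_decay)
    return math.exp(-tp / tau_decay) - math.exp(-tp / tau_rise)


def dual_exp_conductance(t_ms, tau_rise: float, tau_decay: float):
    """Unit-peak dual-exponential conductance waveform; 0 for t < 0."""
    if tau_rise >= tau_decay:
        raise ValueError("tau_rise must be < tau_decay")
    t = np.asarray(t_ms, dtype=float)
    g = (np.exp(-t / tau_decay) - np.exp(-t / tau_rise)) / dual_exp_norm(
        tau_rise, tau_decay)
    return np.where(t < 0, 0.0, g)


def nmda_mg_factor(vm_mV, mg_mM: float = MG_MM):
    """Voltage-dependent Mg²⁺ unblock of the NMDA conductance, in (0, 1).

    ``1 / (1 + ([Mg]/3.57)·exp(−0.062·V))`` — a sigmoid rising with
    depolarisation.
    """
    return 1.0 / (1.0 + (mg_mM / 3.57) * np.exp(-0.062 * np.asarray(vm_mV)))


def gabaa_open_fraction(s: float, transmitter_mM: float, dt_ms: float,
                        alpha: float = ALPHA_GABA,
                        beta: float = BETA_GABA) -> float:
    """Advance ds/dt = α[T](1−s) − βs by ``dt`` (exact exponential update)."""
    k = alpha * transmitter_mM + beta
    s_inf = alpha * transmitter_mM / k if k > 0 else 0.0
    s_new = s_inf + (s - s_inf) * math.exp(-k * dt_ms)
    return min(max(s_new, 0.0), 1.0)


def gabaa_current(g_nS: float, vm: float, ecl: float, ehco3: float):
    """GABA_A current split into its anionic components (pA).

    ``ICl = (4/5)·g·(V−ECl)``, ``IHCO3 = (1/5)·g·(V−EHCO3)``;
    nS × mV = pA.  The total crosses zero exactly at the 4:1-weighted
    reversal EGABA.
    """
    if g_nS < 0:
        raise ValueError("conductance must be >= 0")
    icl = CL_FRACTION * g_nS * (vm - ecl)
    ihco3 = (1.0 - CL_FRACTION) * g_nS * (vm - ehco3)
    return icl, ihco3


def ou_step(x: float, mean: float, sd: float, tau_ms: float, dt_ms: float,
            normal: float) -> float:
    """Exact one-step update of an Ornstein-Uhlenbeck process."""
    decay = math.exp(-dt_ms / tau_ms)
    return mean + (x - mean) * decay + sd * math.sqrt(1.0 - decay * decay) * normal


def fluctuating_conductance_samples(spec: FluctuatingConductance,
                                    n_steps: int, dt_ms: float,
                                    seed) -> np.ndarray:
    """Generate an OU conductance path (µS), clipped at zero on output.

    The underlying OU state is kept linear (so long-run mean and CV match
    the specification); only the emitted conductance is clipped.
    """
    rng = np.random.default_rng(seed)
    mean = spec.mean_uS
    sd = spec.cv * mean
    decay = math.exp(-dt_ms / spec.tau_ms)
    noise_gain = sd * math.sqrt(1.0 - decay * decay)
    normals = rng.standard_normal(n_steps)
    out = np.empty(n_steps)
    x = mean
    for i in range(n_steps):
        x = mean + (x - mean) * decay + noise_gain * normals[i]
        out[i] = x if x > 0 else 0.0
    return out


# ----------------------------------------------------------------------
# Placement helpers
# ----------------------------------------------------------------------

def place_evenly(n_syn: int, compartments: np.ndarray) -> np.ndarray:
    """Assign ``n_syn`` synapses evenly spaced across ``compartments``.

    Positions are the midpoints of ``n_syn`` equal subdivisions of the
    section, mapped to the containing compartment.
    """
    if n_syn == 0:
        return np.empty(0, dtype=np.int64)
    frac = (np.arange(n_syn) + 0.5) / n_syn
    idx = np.minimum((frac * len(compartments)).astype(int),
                     len(compartments) - 1)
    return np.asarray(compartments)[idx]


def spike_trains_for(n_syn: int, rate_hz: float, duration_ms: float,
                     seed_seq: np.random.SeedSequence) -> list[np.ndarray]:
    """One independent Poisson train per synapse, deterministically seeded."""
    children = seed_seq.spawn(n_syn)
    return [poisson_train(rate_hz, duration_ms, s) for s in children]
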