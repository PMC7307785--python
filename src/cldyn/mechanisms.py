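"""Transmembrane mechanisms: ionic leaks, axonal spike channels, KCC2.

Sign conventions used throughout the package:

* positive membrane current = outward (cation leaving / anion entering);
* chloride influx raises [Cl⁻]i — for the Cl⁻ anion a *positive* (outward)
  current corresponds to Cl⁻ entry;
* the KCC2 term lowers [Cl⁻]i whenever [K⁺]i[Cl⁻]i > [K⁺]o[Cl⁻]o.

The axonal Na⁺/K⁺ channels use Traub-style rate functions (the standard
squid-derived kinetics with a threshold shift ``VT``); the delayed
rectifier current uses a single-exponent gate, ``IK = n·gK·(V−EK)``, with
the classical ``n⁴`` form available behind a flag.  The M-current is a
first-order voltage-dependent gate responsible for spike-frequency
adaptation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .constants import DEFAULT_CONSTANTS


class NumericalFailure(RuntimeError):
    """Simulation state became non-finite."""


@dataclass
class LeakParams:
    """Leak conductance densities (S/cm²) with a fixed K:Na:Cl ratio."""

    g_K: float
    g_Na: float
    g_Cl: float

    def __post_init__(self):
        if min(self.g_K, self.g_Na, self.g_Cl) < 0:
            raise ValueError("leak densities must be >= 0")


@dataclass
class KCC2Params:
    """KCC2 pump strength in both unit systems.

    ``P_conc`` (mM⁻¹·s⁻¹) is the whole-cell concentration form measured in
    recovery experiments; ``P_current`` (mA·mM⁻²·cm⁻²) is the surface-based
    form used per compartment.  They are linked by
    :func:`convert_pump_strength` through a reference geometry.
    """

    P_conc: float
    P_current: float
    scale_percent: float = 100.0

    def __post_init__(self):
        if self.scale_percent < 0:
            raise ValueError("KCC2 scale must be >= 0")


def leak_currents(vm_mV, reversals_mV: dict, leak: LeakParams) -> dict:
    """Ohmic per-ion leak current densities (mA/cm²), positive outward.

    ``reversals_mV`` maps ion name ("K", "Na", "Cl") to its reversal
    potential.  ``S/cm² × mV = mA/cm²``.
    """
    return {
        "K": leak.g_K * (vm_mV - reversals_mV["K"]),
        "Na": leak.g_Na * (vm_mV - reversals_mV["Na"]),
        "Cl": leak.g_Cl * (vm_mV - reversals_mV["Cl"]),
    }


# ----------------------------------------------------------------------
# Hodgkin-Huxley style axonal kinetics (Traub rate functions, VT shift)
# ----------------------------------------------------------------------

#: Threshold shift of the rate functions (mV).  Calibrated once so the
#: tuned cell converts the reference 5 Hz balanced drive into ~5 Hz output.
DEFAULT_VT = -63.0

#: M-current maximal time constant (ms); first-order gate per Pospischil-
#: style formulation.
DEFAULT_TAU_MAX_M = 500.0


@njit(cache=True)
def _vtrap(x, y):
    # x / (1 - exp(-x/y)) with the removable singularity handled
    if abs(x / y) < 1e-6:
        return y * (1.0 + x / (2.0 * y))
    return x / (1.0 - np.exp(-x / y))


@njit(cache=True)
def hh_rates(v, vt):
    """Traub α/β rates for m, h, n at potential ``v`` given shift ``vt``.

    Returns (am, bm, ah, bh, an, bn) in ms⁻¹.
    """
    u = v - vt
    am = 0.32 * _vtrap(u - 13.0, 4.0)
    bm = 0.28 * _vtrap(-(u - 40.0), 5.0)
    ah = 0.128 * np.exp(-(u - 17.0) / 18.0)
    bh = 4.0 / (1.0 + np.exp(-(u - 40.0) / 5.0))
    an = 0.032 * _vtrap(u - 15.0, 5.0)
    bn = 0.5 * np.exp(-(u - 10.0) / 40.0)
    return am, bm, ah, bh, an, bn


@njit(cache=True)
def m_current_gate(v, tau_max):
    """Steady state and time constant of the M-current gate at ``v``."""
    m_inf = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    tau = tau_max / (3.3 * np.exp((v + 35.0) / 20.0)
                     + np.exp(-(v + 35.0) / 20.0))
    return m_inf, tau


def gating_steady_state(v: float, vt: float = DEFAULT_VT,
                        tau_max_m: float = DEFAULT_TAU_MAX_M):
    """Fixed point of all gating variables at a clamped potential."""
    am, bm, ah, bh, an, bn = hh_rates(v, vt)
    m_inf_M, _ = m_current_gate(v, tau_max_m)
    return {
        "m": am / (am + bm),
        "h": ah / (ah + bh),
        "n": an / (an + bn),
        "m_M": m_inf_M,
    }


@dataclass
class ChannelState:
    """Axonal gating variables and maximal conductance densities."""

    m: float
    h: float
    n: float
    m_M: float
    g_na: float
    g_k: float
    g_m: float
    vt: float = DEFAULT_VT
    tau_max_m: float = DEFAULT_TAU_MAX_M
    n_exponent: int = 1      # as printed; 4 restores the classical form


def hh_currents(vm: float, state: ChannelState, ek: float, ena: float,
                dt: float):
    """One gating step + the three HH-style current densities (mA/cm²).

    ``INa = m³h·gNa·(V−ENa)``; ``IK = nˣ·gK·(V−EK)`` with x the configured
    exponent (1 as printed); ``IM = m_M·gM·(V−EK)``.  Gating is advanced by
    one exponential-Euler step evaluated at ``vm``.
    """
    for name in ("m", "h", "n", "m_M"):
        if not np.isfinite(getattr(state, name)):
            raise NumericalFailure(f"gating variable {name} is not finite")
    am, bm, ah, bh, an, bn = hh_rates(vm, state.vt)
    for name, a, b in (("m", am, bm), ("h", ah, bh), ("n", an, bn)):
        x = getattr(state, name)
        tau = 1.0 / (a + b)
        x_inf = a * tau
        setattr(state, name, x_inf + (x - x_inf) * np.exp(-dt / tau))
    m_inf, tau_m = m_current_gate(vm, state.tau_max_m)
    state.m_M = m_inf + (state.m_M - m_inf) * np.exp(-dt / tau_m)

    i_na = state.m ** 3 * state.h * state.g_na * (vm - ena)
    i_k = state.n ** state.n_exponent * state.g_k * (vm - ek)
    i_m = state.m_M * state.g_m * (vm - ek)
    return i_na, i_k, i_m, state


# ----------------------------------------------------------------------
# KCC2
# ----------------------------------------------------------------------

def kcc2_rate(P: float, Ki: float, Cli: float, Ko: float, Clo: float) -> float:
    """Cl⁻ extrusion rate V = P·([K⁺]i[Cl⁻]i − [K⁺]o[Cl⁻]o).

    With ``P`` in mM⁻¹·s⁻¹ the result is mM·s⁻¹; positive = net extrusion.
    """
    if min(Ki, Cli, Ko, Clo) <= 0:
        raise ValueError("concentrations must be > 0")
    return P * (Ki * Cli - Ko * Clo)


def convert_pump_strength(P_conc: float, volume_L: float, area_cm2: float,
                          F: float = DEFAULT_CONSTANTS.F) -> float:
    """Convert pump strength from mM⁻¹·s⁻¹ to mA·mM⁻²·cm⁻².

    The concentration form describes d[Cl⁻]/dt per unit bracket for a cell
    of volume ``volume_L``; multiplying by F·Vol/Area re-expresses it as a
    membrane current density per unit bracket:

    ``P_current = P_conc · F · Vol / Area`` with mM → mol conversions
    cancelling (1 mM·L·s⁻¹ · F = 1e-3 C·s⁻¹ → mA directly).
    """
    if volume_L <= 0 or area_cm2 <= 0:
        raise ValueError("volume and area must be > 0")
    return P_conc * F * volume_L / area_cm2


def invert_pump_strength(P_current: float, volume_L: float, area_cm2: float,
                         F: float = DEFAULT_CONSTANTS.F) -> float:
    """Inverse of :func:`convert_pump_strength`."""
    if volume_L <= 0 or area_cm2 <= 0:
        raise ValueError("volume and area must be > 0")
    return P_current * area_cm2 / (F * volume_L)


#: Reference whole-cell geometry of the recorded pyramidal cells used for
#: the standard unit conversion.
REFERENCE_CELL = {"volume_L": 1.058e-12, "area_cm2": 529e-8}
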