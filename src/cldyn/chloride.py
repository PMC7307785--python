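"""Chloride mass balance: reversal potentials, the per-compartment
three-term d[Cl⁻]i/dt update, and the dynamic-potassium configuration.

The mass balance combines (i) transmembrane Cl⁻ currents (leak and
GABA_A), (ii) KCC2 extrusion, and (iii) longitudinal diffusion between
compartment midpoints with sealed ends:

    d[Cl⁻]i/dt = ICl·Area/(F·Vol) − P·([K⁺]i[Cl⁻]i − [K⁺]o[Cl⁻]o)·Area·c/(F·Vol)
                 + diffusive exchange

with signs normalised so that synaptic/leak Cl⁻ influx raises [Cl⁻]i and a
positive KCC2 bracket lowers it.  Diffusion is a conservative second-order
finite difference on midpoints; fluxes at section junctions use the mean
cross-sectional area of the adjoining compartments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .mechanisms import NumericalFailure

#: Free-solution chloride diffusion coefficient, µm²/ms.
D_CL_DEFAULT = 2.03

#: Concentration floor below which the integrator flags failure (mM).
CL_FLOOR = 1e-3


@dataclass
class DiffusionParams:
    """Longitudinal diffusion settings (sealed-end boundary)."""

    d_cl: float = D_CL_DEFAULT

    def __post_init__(self):
        if self.d_cl <= 0:
            raise ValueError("D_Cl must be > 0")


def nernst(z: int, Ci: float, Co: float,
           constants: PhysicalConstants = DEFAULT_CONSTANTS):
    """Nernst reversal potential E = (RT/zF)·ln(Co/Ci), in mV."""
    Ci = np.asarray(Ci, dtype=float)
    if np.any(Ci <= 0) or Co <= 0:
        raise ValueError("concentrations must be > 0")
    E = constants.rtf_mV / z * np.log(Co / Ci)
    return float(E) if E.ndim == 0 else E


def egaba_combine(ecl, ehco3):
    """EGABA = (4/5)·ECl + (1/5)·EHCO3 (the 4:1 permeability weighting)."""
    return 0.8 * np.asarray(ecl) + 0.2 * ehco3


@dataclass
class ReversalState:
    """Per-compartment reversal potentials derived from the ion state."""

    ecl_mV: np.ndarray
    ehco3_mV: float
    @property
    def egaba_mV(self) -> np.ndarray:
        return egaba_combine(self.ecl_mV, self.ehco3_mV)


def diffusion_exchange(cl_mM: np.ndarray, d_cl: float,
                       axs_um2: np.ndarray, dx_um: np.ndarray,
                       vol_L: np.ndarray) -> np.ndarray:
    """d[Cl⁻]/dt (mM/ms) from midpoint diffusion; conservative by symmetry."""
    flux = d_cl * axs_um2 * (cl_mM[1:] - cl_mM[:-1]) / dx_um  # µm³·mM/ms
    dcl = np.zeros_like(cl_mM)
    dcl[:-1] += flux * 1e-15 / vol_L[:-1]
    dcl[1:] -= flux * 1e-15 / vol_L[1:]
    return dcl


def chloride_step(cl_mM: np.ndarray, icl_nA: np.ndarray,
                  p_kcc2_current: np.ndarray, diff: DiffusionParams,
                  area_cm2: np.ndarray, vol_L: np.ndarray,
                  axs_um2: np.ndarray, dx_um: np.ndarray,
                  dt_ms: float, Ki: float = 140.0, Ko: float = 4.0,
                  Clo: float = 135.0,
                  F: float = DEFAULT_CONSTANTS.F) -> np.ndarray:
    """Advance the chloride mass balance one explicit step.

    Parameters
    ----------
    cl_mM : per-compartment [Cl⁻]i (mM), modified copy returned.
    icl_nA : total transmembrane Cl⁻ current per compartment (nA),
        positive outward = Cl⁻ influx.
    p_kcc2_current : per-compartment pump strength (mA·mM⁻²·cm⁻²).
    axs_um2, dx_um : diffusion stencil (interface areas, midpoint gaps).

    Returns the updated concentrations; raises
    :class:`~cldyn.mechanisms.NumericalFailure` on underflow below 1e-3 mM.
    """
    if dt_ms <= 0:
        raise ValueError("dt must be > 0")
    if np.any(cl_mM <= 0):
        raise ValueError("concentrations must be > 0")
    cl = np.array(cl_mM, dtype=float)
    # membrane flux: nA → mM/ms conversion factor 1e-9 (A per nA) × 1e3
    # (M→mM) × 1e-3 (s→ms)
    dcl = 1e-9 * icl_nA / (F * vol_L)
    # KCC2: current-equivalent density × area, electroneutral mass term
    j_kcc2 = p_kcc2_current * (Ki * cl - Ko * Clo)          # mA/cm²
    dcl -= 1e-3 * j_kcc2 * area_cm2 / (F * vol_L)
    dcl += diffusion_exchange(cl, diff.d_cl, axs_um2, dx_um, vol_L)
    cl += dt_ms * dcl
    if np.any(cl < CL_FLOOR):
        loc = int(np.argmin(cl))
        raise NumericalFailure(
            f"[Cl-]i underflow ({cl[loc]:.2e} mM) in compartment {loc}")
    return cl


def kcc2_equilibrium_cl(Ki: float = 140.0, Ko: float = 4.0,
                        Clo: float = 135.0) -> float:
    """[Cl⁻]i at which the KCC2 bracket vanishes, Ko·Clo/Ki."""
    return Ko * Clo / Ki


@dataclass
class DynamicPotassium:
    """Configuration of the dynamic-K⁺ mode.

    In this mode [K⁺]i becomes a per-compartment state driven by the KCC2
    K⁺ efflux (equal to the Cl⁻ efflux, so net KCC2 charge flux is zero),
    the ionic leaks are replaced by a single passive conductance with
    reversal at the tuned resting potential, and constant tonic fluxes
    hold the initial [Cl⁻]i and [K⁺]i at rest.
    """

    enabled: bool = False
    e_pas_mV: float = float("nan")       # filled when enabled
    tonic_cl_mM_per_ms: np.ndarray | None = None
    tonic_k_mM_per_ms: np.ndarray | None = None


def enable_dynamic_potassium(model) -> DynamicPotassium:
    """Configure the dynamic-potassium variant for ``model``.

    The tonic fluxes are constructed so the model's initial ion state is a
    fixed point at rest: each equals the initial KCC2 extrusion rate of its
    compartment.  EK is subsequently recomputed by Nernst from the evolving
    [K⁺]i inside the engine.
    """
    ions = model.ions
    rate_cl = (1e-3 * model.p_kcc2
               * (ions.K_i * model.cl0_mM - ions.K_o * ions.Cl_o)
               * model.area_cm2 / (model.constants.F * model.vol_L))
    return DynamicPotassium(
        enabled=True,
        e_pas_mV=float(model.v0_mV[model.soma_index]),
        tonic_cl_mM_per_ms=rate_cl.copy(),   # influx balancing extrusion
        tonic_k_mM_per_ms=rate_cl.copy(),    # K⁺ re-entry balancing efflux
    )
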