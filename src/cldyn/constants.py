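"""Physical constants and ionic concentration tables.

All concentrations are millimolar (mM), temperatures Kelvin.  The package
works in the unit system conventional for compartmental neural modelling:
membrane potential in mV, time in ms, conductance densities in S/cm²,
membrane current densities in mA/cm², point-process conductances in µS and
point currents in nA, compartment capacitance in nF, and volume in litres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass(frozen=True)
class PhysicalConstants:
    """Fundamental constants at physiological temperature.

    Attributes
    ----------
    F : float
        Faraday constant, C·mol⁻¹.
    R : float
        Universal gas constant, J·K⁻¹·mol⁻¹.
    T : float
        Absolute temperature, K (default 310.15 K = 37 °C).
    """

    F: float = 96485.33
    R: float = 8.31446
    T: float = 310.15

    @property
    def rtf_mV(self) -> float:
        """R·T/F expressed in millivolts."""
        return 1e3 * self.R * self.T / self.F


@dataclass(frozen=True)
class IonTable:
    """Intra-/extracellular concentrations (mM) of the four modelled ions.

    Only [Cl⁻]i is a dynamic state by default; everything else is held
    fixed (intracellular K⁺ becomes dynamic in the dynamic-potassium mode).
    Valences: K⁺ +1, Na⁺ +1, Cl⁻ −1, HCO₃⁻ −1.
    """

    K_i: float = 140.0
    K_o: float = 4.0
    Na_i: float = 10.0
    Na_o: float = 140.0
    Cl_i: float = 4.25
    Cl_o: float = 135.0
    HCO3_i: float = 12.0
    HCO3_o: float = 23.0

    def __post_init__(self) -> None:
        for name in ("K_i", "K_o", "Na_i", "Na_o", "Cl_i", "Cl_o",
                     "HCO3_i", "HCO3_o"):
            if getattr(self, name) <= 0:
                raise ValueError(f"concentration {name} must be > 0")

    def replace(self, **kw) -> "IonTable":
        return replace(self, **kw)


#: The alternative bicarbonate set used when analysing perforated-patch
#: recordings (the experimental pipeline), as opposed to the model defaults.
EXPERIMENTAL_HCO3 = {"HCO3_i": 10.0, "HCO3_o": 25.0}

VALENCE = {"K": 1, "Na": 1, "Cl": -1, "HCO3": -1}

DEFAULT_CONSTANTS = PhysicalConstants()
DEFAULT_IONS = IonTable()
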