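"""Synthetic data generators: perforated-patch-style chloride-recovery
traces with known ground truth, GABA-puff current sets, and the canned
stimulus fixtures used by the figure-level protocols.

Every generator embeds its ground truth in the output metadata so that
estimation tests read truth only from there, never from the estimator.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .calibration import RecoveryTrace, distal_fin_program
from .constants import DEFAULT_IONS
from .morphology import NeuronModel
from .synapses import StimulusProgram


@dataclass
class RecoveryGeneratorSpec:
    """Ground-truth specification of a synthetic chloride-recovery trace.

    The cell is loaded to ``baseline + load`` mM at t = 0 (end of the 15 s
    photocurrent) and recovers by KCC2 extrusion against a constant tonic
    Cl⁻ influx that holds the stated baseline; recovery is therefore a
    single exponential with rate P·[K⁺]i.  ``schedule_s`` must span at
    least three recovery time constants.
    """

    true_P: float = 0.001            # mM⁻¹·s⁻¹
    load_mM: float = 10.0            # amplitude above baseline
    baseline_mM: float = 4.25
    schedule_s: np.ndarray = field(
        default_factory=lambda: np.arange(2.0, 92.0, 5.0))
    noise_sd_mM: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.schedule_s = np.asarray(self.schedule_s, float)
        if self.load_mM <= 0:
            raise ValueError("load amplitude must be > 0")
        tau = 1.0 / (self.true_P * DEFAULT_IONS.K_i)
        if self.schedule_s[-1] < 3 * tau:
            raise ValueError("sample schedule must cover >= 3 time constants")


def generate_recovery(spec: RecoveryGeneratorSpec,
                      Ki: float = DEFAULT_IONS.K_i,
                      Ko: float = DEFAULT_IONS.K_o,
                      Clo: float = DEFAULT_IONS.Cl_o) -> RecoveryTrace:
    """Integrate the single-compartment recovery ODE and sample it.

    d[Cl⁻]i/dt = L − P·(Ki·[Cl⁻]i − Ko·Clo), with L chosen so the baseline
    is a fixed point.  Gaussian measurement noise is added per sample.
    """
    P = spec.true_P
    L = P * (Ki * spec.baseline_mM - Ko * Clo)

    def rhs(t, y):
        return L - P * (Ki * y[0] - Ko * Clo)

    sol = solve_ivp(rhs, (0.0, spec.schedule_s[-1]),
                    [spec.baseline_mM + spec.load_mM],
                    t_eval=spec.schedule_s, rtol=1e-10, atol=1e-12,
                    dense_output=True)
    samples = sol.y[0]
    if spec.noise_sd_mM > 0:
        rng = np.random.default_rng(spec.seed)
        samples = samples + rng.normal(0.0, spec.noise_sd_mM, len(samples))
    return RecoveryTrace(
        t_s=spec.schedule_s, cl_mM=samples,
        baseline_mM=spec.baseline_mM, noise_sd_mM=spec.noise_sd_mM,
        meta={"true_P": P, "load_mM": spec.load_mM,
              "tau_true_s": 1.0 / (P * Ki), "tonic_influx_mM_s": L,
              "seed": spec.seed},
    )


def generate_puff_currents(egaba_true_mV: float, g_nS: float,
                           vhold_mV, noise_pA: float = 0.0,
                           n_per_hold: int = 1, seed: int = 0):
    """Synthetic GABA-puff currents I = g·(Vhold − EGABA) + noise (pA).

    Returns a record array with fields ``vhold_mV`` and ``i_pA``.  The
    resting (g, EGABA) line fit needs ≥ 2 distinct holding potentials
    (enforced by :func:`cldyn.calibration.fit_gaba_conductance`); repeated
    single-potential puffs support the single-current estimation path.
    """
    vhold = np.repeat(np.atleast_1d(np.asarray(vhold_mV, float)), n_per_hold)
    rng = np.random.default_rng(seed)
    i = g_nS * (vhold - egaba_true_mV)
    if noise_pA > 0:
        i = i + rng.normal(0.0, noise_pA, len(i))
    return np.rec.fromarrays([vhold, i], names=["vhold_mV", "i_pA"])


# ----------------------------------------------------------------------
# Protocol fixtures
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class Fixture:
    """A named, seeded stimulus protocol plus its model overrides."""

    name: str
    kind: str                    # "fin" | "gclamp" | "recovery"
    params: tuple                # sorted (key, value) pairs
    overrides: tuple             # sorted (key, value) pairs

    @property
    def param_dict(self) -> dict:
        return dict(self.params)

    @property
    def override_dict(self) -> dict:
        return dict(self.overrides)

    @property
    def seed(self) -> int:
        # stable across runs and platforms: derived from the name
        return zlib.crc32(self.name.encode())

    def program(self, model: NeuronModel) -> StimulusProgram:
        p = self.param_dict
        if self.kind != "fin":
            raise ValueError(f"fixture {self.name} is not an f-in protocol")
        return distal_fin_program(model, p["n_exc"], p["n_inh"],
                                  p["rate_hz"], self.seed,
                                  inh_section=p.get("inh_section", "distal"))


def _fx(name, kind, params, overrides=()):
    return Fixture(name, kind, tuple(sorted(params.items())),
                   tuple(sorted(dict(overrides).items())))


_FIXTURES = {
    f.name: f for f in [
        # balanced-pair reference configurations (distal inhibition)
        _fx("fig2_distal_balanced_5hz", "fin",
            dict(n_exc=250, n_inh=300, rate_hz=5.0, duration_ms=1000.0)),
        _fx("fig2_weak_inhibition", "fin",
            dict(n_exc=200, n_inh=30, rate_hz=5.0, duration_ms=1000.0)),
        _fx("fig2_strong_inhibition", "fin",
            dict(n_exc=300, n_inh=800, rate_hz=5.0, duration_ms=1000.0)),
        _fx("fig2_proximal_balanced_5hz", "fin",
            dict(n_exc=780, n_inh=330, rate_hz=5.0, duration_ms=1000.0,
                 inh_section="proximal")),
        # rate-series protocol: balanced input frequency sweep
        _fx("fig3_rate_series", "fin",
            dict(n_exc=250, n_inh=300, rate_hz=5.0, duration_ms=1000.0,
                 rate_grid_hz=(5.0, 10.0, 25.0, 50.0))),
        # I/O over synapse counts
        _fx("fig4_io_grid", "fin",
            dict(rate_hz=5.0, duration_ms=1000.0,
                 n_exc_grid=(50, 100, 150, 200, 250, 300, 400, 500),
                 n_inh_levels=(0, 100, 300))),
        # gclamp protocols (wider distal dendrite, 5 repeats)
        _fx("fig5_heatmap", "gclamp",
            dict(trials=5, duration_ms=10000.0, delta_ms=20.0,
                 times_ms=(20.0, 100.0, 500.0, 1000.0, 10000.0)),
            dict(distal_diam_um=1.0)),
        _fx("fig6_index_sweep", "gclamp",
            dict(duration_ms=1000.0,
                 pkcc2_percent=(25.0, 50.0, 100.0, 200.0),
                 distal_diam_um=(0.5, 1.0, 2.0),
                 inhibition=(4.0, 8.0))),
    ]
}


def fixture(name: str) -> Fixture:
    """Look up a named protocol fixture; unknown names list what exists."""
    try:
        return _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        ) from None


def list_fixtures() -> list[str]:
    return sorted(_FIXTURES)
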