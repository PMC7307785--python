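"""Spike-train statistics and input-output analysis: firing rates, IFR,
I/O curves, half-max offsets (x₅₀), the chloride index, and the
index-vs-ΔEGABA sweep.

The chloride index quantifies how much of inhibition's subtractive offset
is lost to chloride accumulation:

    index = 1 − a/b,  a = x₅₀(dynamic, i) − x₅₀(i=0),
                      b = x₅₀(static, i) − x₅₀(i=0)

0 means chloride dynamics are irrelevant (dynamic ≡ static); 1 means the
offset produced by inhibition vanishes entirely once chloride is dynamic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .chloride import DynamicPotassium, enable_dynamic_potassium
from .engine import SimulationConfig, simulate
from .morphology import NeuronModel, build_default_model
from .synapses import FluctuatingConductance, StimulusProgram, place_evenly


class UndefinedMeasure(RuntimeError):
    """A curve statistic (x₅₀, chloride index, correlation) is undefined."""


# ----------------------------------------------------------------------
# Rates
# ----------------------------------------------------------------------

def mean_rate(spike_times_ms: np.ndarray, window_ms: float) -> float:
    """Spike count over the window divided by its duration, in Hz."""
    if window_ms <= 0:
        raise ValueError("window must be > 0")
    return len(spike_times_ms) / (window_ms / 1000.0)


def ifr(trains_ms: list[np.ndarray], t_ms, delta_ms: float = 20.0):
    """Instantaneous firing rate pooled over trials (Hz).

    IFR(t) = Σ_k n_k([t−Δt, t]) / (K·Δt) with a backward window.  Scalar
    or array ``t_ms``; times earlier than Δt raise (truncated window).
    """
    if delta_ms <= 0:
        raise ValueError("time bin must be > 0")
    K = len(trains_ms)
    if K < 1:
        raise ValueError("need >= 1 trial")
    t = np.atleast_1d(np.asarray(t_ms, float))
    if np.any(t < delta_ms):
        raise ValueError("window truncated: t < delta")
    out = np.zeros(len(t))
    for tr in trains_ms:
        tr = np.asarray(tr)
        for j, tj in enumerate(t):
            out[j] += np.count_nonzero((tr > tj - delta_ms) & (tr <= tj))
    out /= K * delta_ms / 1000.0
    res = out if np.ndim(t_ms) else float(out[0])
    return res


# ----------------------------------------------------------------------
# I/O curves
# ----------------------------------------------------------------------

@dataclass
class IOCurve:
    """Mean output rate vs excitatory drive at a fixed inhibition level."""

    abscissa_kind: str            # "relative_conductance" | "synapse_count"
    x: np.ndarray
    rate_hz: np.ndarray
    trials: int
    chloride_mode: str
    inhibition: float

    def __post_init__(self):
        self.x = np.asarray(self.x, float)
        self.rate_hz = np.asarray(self.rate_hz, float)
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("abscissa grid must be sorted ascending")
        if np.any(self.rate_hz < 0):
            raise ValueError("rates must be >= 0")


#: Number of OU conductance sites per population placed evenly on a section.
GCLAMP_SITES = 10


def gclamp_program(model: NeuronModel, rel_exc: float, rel_inh: float,
                   seed: int, n_sites: int = GCLAMP_SITES,
                   inh_section: str = "distal") -> StimulusProgram:
    """Fluctuating-conductance drive: ``n_sites`` excitatory sites on the
    distal dendrite and ``n_sites`` inhibitory sites on ``inh_section``,
    each with mean = baseline × relative conductance."""
    distal = model.section_compartments("distal")
    inh_comps = model.section_compartments(inh_section)
    gcl = [FluctuatingConductance(int(c), rel_exc, inhibitory=False)
           for c in place_evenly(n_sites, distal)]
    if rel_inh > 0:
        gcl += [FluctuatingConductance(int(c), rel_inh, inhibitory=True)
                for c in place_evenly(n_sites, inh_comps)]
    return StimulusProgram(gclamps=gcl, seed=seed)


def io_curve(model: NeuronModel, inhibition: float, chloride_mode: str,
             grid, trials: int = 1, seed: int = 0,
             duration_ms: float = 1000.0,
             dynamic_k: DynamicPotassium | None = None,
             collect_delta_egaba: bool = False,
             inh_section: str = "distal"):
    """I/O curve over a relative-excitatory-conductance grid (gclamp drive).

    One simulation per (grid point, trial); trial seeds are derived from
    ``seed`` and shared across chloride modes so dynamic/static
    comparisons are paired.  If ``collect_delta_egaba``, also returns the
    trial-mean distal ΔEGABA per grid point.
    """
    grid = np.asarray(grid, float)
    rates = np.zeros(len(grid))
    degaba = np.zeros(len(grid))
    cfg = SimulationConfig(
        duration_ms=duration_ms, chloride_mode=chloride_mode,
        potassium_mode="dynamic" if dynamic_k else "fixed")
    for gi, x in enumerate(grid):
        r_trials, d_trials = [], []
        for tr in range(trials):
            stim_seed = (seed * 1000003 + gi * 1009 + tr) % (2 ** 31)
            stim = gclamp_program(model, x, inhibition, stim_seed,
                                  inh_section=inh_section)
            res = simulate(model, stim, cfg, dynamic_k=dynamic_k)
            r_trials.append(mean_rate(res.spike_times_ms, duration_ms))
            d_trials.append(res.distal_delta_egaba())
        rates[gi] = np.mean(r_trials)
        degaba[gi] = np.mean(d_trials)
    curve = IOCurve("relative_conductance", grid, rates, trials,
                    chloride_mode, inhibition)
    if collect_delta_egaba:
        return curve, degaba
    return curve


@dataclass
class HalfMax:
    """x₅₀: abscissa at half-maximal rate, from the rising limb."""

    x50: float
    max_rate_hz: float
    method: str = "linear-interpolation"


def half_max(curve: IOCurve, max_rate_hz: float | None = None) -> HalfMax:
    """Extract x₅₀ by piecewise-linear interpolation of the rising limb.

    ``max_rate_hz`` overrides the curve's own maximum (used when the
    no-inhibition plateau defines the reference maximum for a family of
    offset curves).  Undefined if the curve never exceeds half the max.
    """
    ref_max = float(curve.rate_hz.max()) if max_rate_hz is None else max_rate_hz
    if ref_max <= 0:
        raise UndefinedMeasure("flat curve: half-max undefined")
    half = ref_max / 2.0
    r = curve.rate_hz
    above = np.flatnonzero(r > half)
    if len(above) == 0:
        raise UndefinedMeasure("curve never exceeds half the maximal rate")
    j = above[0]
    if j == 0:
        return HalfMax(float(curve.x[0]), ref_max)
    x0, x1 = curve.x[j - 1], curve.x[j]
    r0, r1 = r[j - 1], r[j]
    x50 = x0 + (half - r0) * (x1 - x0) / (r1 - r0)
    return HalfMax(float(x50), ref_max)


# ----------------------------------------------------------------------
# Chloride index
# ----------------------------------------------------------------------

@dataclass
class ChlorideIndexResult:
    """x₅₀ triple, offsets, index, and the distal ΔEGABA of the dynamic run."""

    x50_dynamic: float
    x50_static: float
    x50_no_inhibition: float
    a: float
    b: float
    index: float
    delta_egaba_mV: float = float("nan")


def chloride_index(curve_dynamic: IOCurve, curve_static: IOCurve,
                   curve_no_inh: IOCurve,
                   delta_egaba_mV: float = float("nan")) -> ChlorideIndexResult:
    """Compute the chloride index from the three I/O curves.

    The reference maximum for all three x₅₀ extractions is the
    no-inhibition plateau (distal inhibition offsets the curve without
    changing its maximum).
    """
    ref = float(curve_no_inh.rate_hz.max())
    x0 = half_max(curve_no_inh, ref).x50
    xd = half_max(curve_dynamic, ref).x50
    xs = half_max(curve_static, ref).x50
    a = xd - x0
    b = xs - x0
    if b == 0:
        raise UndefinedMeasure("static offset b = 0: index undefined")
    return ChlorideIndexResult(xd, xs, x0, a, b, 1.0 - a / b, delta_egaba_mV)


# ----------------------------------------------------------------------
# Sweeps
# ----------------------------------------------------------------------

def _index_at(model: NeuronModel, inhibition: float, grid, trials, seed,
              duration_ms, dynamic_k=None) -> ChlorideIndexResult:
    no_inh = io_curve(model, 0.0, "dynamic", grid, trials, seed, duration_ms,
                      dynamic_k)
    dyn, deg = io_curve(model, inhibition, "dynamic", grid, trials, seed,
                        duration_ms, dynamic_k, collect_delta_egaba=True)
    stat = io_curve(model, inhibition, "static", grid, trials, seed,
                    duration_ms, dynamic_k)
    return chloride_index(dyn, stat, no_inh, float(np.mean(deg)))


def index_egaba_sweep(sweep: pd.DataFrame | list[dict], grid,
                      trials: int = 1, seed: int = 0,
                      duration_default_ms: float = 1000.0,
                      model_builder=build_default_model):
    """Run the chloride-index protocol over a sweep of model variants.

    Each sweep point is a dict with optional keys ``pkcc2_percent``,
    ``distal_diam_um``, ``rin_scale``, ``pkcc2_percent_distal``,
    ``duration_ms``, ``dynamic_k`` and a required ``inhibition`` (relative
    inhibitory conductance).  Returns ``(table, pearson_r)`` where
    ``table`` has one row per point with a, b, index, ΔEGABA; points with
    an undefined index are excluded from the correlation (count reported
    in ``table.attrs['n_undefined']``).
    """
    points = sweep.to_dict("records") if isinstance(sweep, pd.DataFrame) else list(sweep)
    rows = []
    n_undef = 0
    from .calibration import tune_leaks
    for k, pt in enumerate(points):
        overrides = {}
        if "distal_diam_um" in pt:
            overrides["distal_diam_um"] = pt["distal_diam_um"]
        model = model_builder(overrides)
        tune_leaks(model, 365.0 * float(pt.get("rin_scale", 1.0)), refine=False)
        if "pkcc2_percent" in pt:
            model.scale_kcc2(pt["pkcc2_percent"])
        if "pkcc2_percent_distal" in pt:
            model.scale_kcc2(pt["pkcc2_percent_distal"], section="distal")
        dk = enable_dynamic_potassium(model) if pt.get("dynamic_k") else None
        duration = float(pt.get("duration_ms", duration_default_ms))
        try:
            res = _index_at(model, float(pt["inhibition"]), grid, trials,
                            seed + k, duration, dk)
            rows.append({**pt, "a": res.a, "b": res.b, "index": res.index,
                         "delta_egaba_mV": res.delta_egaba_mV})
        except UndefinedMeasure:
            n_undef += 1
    table = pd.DataFrame(rows)
    table.attrs["n_undefined"] = n_undef
    if len(table) < 2 or table["index"].std() == 0 or \
            table["delta_egaba_mV"].std() == 0:
        raise UndefinedMeasure("sweep has no variance: correlation undefined")
    r, p = stats.pearsonr(table["delta_egaba_mV"], table["index"])
    return table, float(r)
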