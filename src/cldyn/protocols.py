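"""Figure-level protocols orchestrated end-to-end with provenance.

``run_protocol`` executes a named pipeline (chloride profiles, rate
series, I/O curves, IFR heatmaps, the index sweep, or the calibration
demo), writing a manifest sufficient to re-run the protocol bit-
identically, tidy tabular outputs, and — where applicable — HDF5 traces.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analysis import gclamp_program, ifr, index_egaba_sweep, io_curve, mean_rate
from .calibration import distal_fin_program, fit_recovery, tune_leaks
from .config import write_resolved_config
from .engine import SimulationConfig, simulate
from .morphology import build_default_model
from .store import write_run, chloride_profile
from .synthetic import RecoveryGeneratorSpec, fixture, generate_recovery

PROTOCOLS = ("fig2_profiles", "fig3_rates", "fig4_io", "fig5_heatmaps",
             "fig6_index_sweep", "calibration_demo")

#: Default relative-excitatory-conductance grid for gclamp I/O curves.
IO_GRID_DEFAULT = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 40.0, 50.0)


@dataclass
class RunManifest:
    protocol: str
    seed: int
    overrides: dict
    version: str
    outputs: list = field(default_factory=list)
    timing_s: dict = field(default_factory=dict)

    def write(self, out_dir: Path) -> Path:
        path = Path(out_dir) / "manifest.json"
        tmp = path.with_suffix(".json.tmp")
        tmp.write_text(json.dumps(self.__dict__, indent=2, default=str))
        tmp.rename(path)           # atomic: manifest appears only complete
        return path


def _tuned_model(overrides=None):
    model = build_default_model(overrides)
    tune_leaks(model, refine=False)
    return model


def run_protocol(name: str, overrides: dict | None = None,
                 out: str | Path = "results", seed: int = 0) -> RunManifest:
    """Execute a named protocol; returns the manifest (also written)."""
    if name not in PROTOCOLS:
        raise ValueError(f"unknown protocol {name!r}; available: {PROTOCOLS}")
    ov = dict(overrides or {})
    out_dir = Path(out) / name
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(name, seed, ov, __version__)
    t0 = time.perf_counter()

    if name == "calibration_demo":
        spec = RecoveryGeneratorSpec(noise_sd_mM=float(ov.get("noise_sd", 0.3)),
                                     seed=seed)
        trace = generate_recovery(spec)
        trace.to_table(out_dir / "recovery_trace.tsv")
        est = fit_recovery(trace)
        report = {"true_P": spec.true_P, "P_hat_conc": est.P_conc,
                  "P_hat_current": est.P_current, "tau_s": est.tau_s,
                  "r_squared": est.r_squared}
        (out_dir / "pump_estimate.json").write_text(json.dumps(report, indent=2))
        manifest.outputs = ["recovery_trace.tsv", "pump_estimate.json"]

    elif name == "fig2_profiles":
        model = _tuned_model()
        fx = fixture("fig2_distal_balanced_5hz")
        cfg = SimulationConfig(duration_ms=fx.param_dict["duration_ms"])
        rows = []
        for mode in ("excitatory", "inhibitory", "balanced"):
            p = fx.param_dict
            ne = p["n_exc"] if mode != "inhibitory" else 0
            ni = p["n_inh"] if mode != "excitatory" else 0
            stim = distal_fin_program(model, ne, ni, p["rate_hz"],
                                      fx.seed + seed)
            res = simulate(model, stim, cfg)
            prof = chloride_profile(res)
            prof["drive"] = mode
            rows.append(prof)
        pd.concat(rows).to_csv(out_dir / "cl_profiles.tsv", sep="\t",
                               index=False)
        write_resolved_config(out_dir / "config.yaml", model, cfg)
        manifest.outputs = ["cl_profiles.tsv", "config.yaml"]

    elif name == "fig3_rates":
        model = _tuned_model()
        fx = fixture("fig3_rate_series")
        p = fx.param_dict
        rates = ov.get("rate_grid_hz", p["rate_grid_hz"])
        rows = []
        for mode in ("dynamic", "static"):
            for rate in rates:
                stim = distal_fin_program(model, p["n_exc"], p["n_inh"],
                                          float(rate), fx.seed + seed)
                cfg = SimulationConfig(duration_ms=p["duration_ms"],
                                       chloride_mode=mode)
                res = simulate(model, stim, cfg)
                rows.append({"input_hz": rate, "chloride": mode,
                             "output_hz": mean_rate(res.spike_times_ms,
                                                    p["duration_ms"])})
        pd.DataFrame(rows).to_csv(out_dir / "rates.tsv", sep="\t", index=False)
        manifest.outputs = ["rates.tsv"]

    elif name == "fig4_io":
        model = _tuned_model()
        grid = ov.get("grid", IO_GRID_DEFAULT)
        levels = ov.get("inhibition_levels", (0.0, 4.0, 8.0))
        rows = []
        for mode in ("dynamic", "static"):
            for i_level in levels:
                curve = io_curve(model, float(i_level), mode, grid,
                                 trials=int(ov.get("trials", 3)), seed=seed)
                for x, r in zip(curve.x, curve.rate_hz):
                    rows.append({"chloride": mode, "inhibition": i_level,
                                 "rel_exc": x, "rate_hz": r})
        pd.DataFrame(rows).to_csv(out_dir / "io_curves.tsv", sep="\t",
                                  index=False)
        manifest.outputs = ["io_curves.tsv"]

    elif name == "fig5_heatmaps":
        fx = fixture("fig5_heatmap")
        p = fx.param_dict
        model = _tuned_model(fx.override_dict)
        exc_grid = ov.get("exc_grid", (1.0, 3.0, 5.0, 7.0))
        inh_grid = ov.get("inh_grid", (0.0, 4.0, 8.0))
        duration = float(ov.get("duration_ms", 1000.0))
        times = [t for t in p["times_ms"] if t <= duration]
        trials = int(ov.get("trials", p["trials"]))
        rows = []
        for mode in ("dynamic", "static"):
            for ge in exc_grid:
                for gi in inh_grid:
                    trains = []
                    cl_end = []
                    for k in range(trials):
                        stim = gclamp_program(model, float(ge), float(gi),
                                              fx.seed + seed + k)
                        cfg = SimulationConfig(duration_ms=duration,
                                               chloride_mode=mode)
                        res = simulate(model, stim, cfg)
                        trains.append(res.spike_times_ms)
                        cl_end.append(res.section_mean(res.cl_snap,
                                                       "distal")[-1])
                    for t in times:
                        rows.append({
                            "chloride": mode, "rel_exc": ge, "rel_inh": gi,
                            "t_ms": t,
                            "ifr_hz": ifr(trains, t, p["delta_ms"]),
                            "distal_cl_end_mM": float(np.mean(cl_end))})
        pd.DataFrame(rows).to_csv(out_dir / "ifr_heatmaps.tsv", sep="\t",
                                  index=False)
        manifest.outputs = ["ifr_heatmaps.tsv"]

    elif name == "fig6_index_sweep":
        fx = fixture("fig6_index_sweep")
        p = fx.param_dict
        points = []
        for pk in ov.get("pkcc2_percent", p["pkcc2_percent"]):
            for i_level in ov.get("inhibition", p["inhibition"]):
                points.append({"pkcc2_percent": pk, "inhibition": i_level})
        for dd in ov.get("distal_diam_um", p["distal_diam_um"]):
            for i_level in ov.get("inhibition", p["inhibition"]):
                points.append({"distal_diam_um": dd, "inhibition": i_level})
        if "points" in ov:
            points = points[: int(ov["points"])]
        table, r = index_egaba_sweep(points, ov.get("grid", IO_GRID_DEFAULT),
                                     trials=int(ov.get("trials", 1)),
                                     seed=seed)
        table.to_csv(out_dir / "index_sweep.tsv", sep="\t", index=False)
        (out_dir / "correlation.json").write_text(
            json.dumps({"pearson_r": r, "n_points": len(table),
                        "n_undefined": table.attrs["n_undefined"]}))
        manifest.outputs = ["index_sweep.tsv", "correlation.json"]

    manifest.timing_s["total"] = round(time.perf_counter() - t0, 3)
    manifest.write(out_dir)
    return manifest
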