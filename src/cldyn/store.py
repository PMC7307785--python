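"""Result persistence: one HDF5 container per run plus tabular text
summaries (spike times, per-section chloride profiles)."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .engine import SimulationResult


def save_result(path, result: SimulationResult) -> None:
    """Write traces, snapshots, spikes, and the config snapshot to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["config_json"] = json.dumps(result.config)
        f.attrs["dt_ms"] = result.dt_ms
        for name in ("v_tip", "v_soma", "t_snap_ms", "v_snap", "cl_snap",
                     "egaba_snap", "spike_times_ms", "final_v", "final_cl",
                     "final_k"):
            f.create_dataset(name, data=getattr(result, name))


def spike_table(result: SimulationResult) -> pd.DataFrame:
    return pd.DataFrame({"spike_time_ms": result.spike_times_ms})


def chloride_profile(result: SimulationResult) -> pd.DataFrame:
    """End-of-run [Cl⁻]i and EGABA vs path distance from the soma."""
    m = result.model
    return pd.DataFrame({
        "x_um": m.x_um,
        "section": [("axon", "soma", "proximal", "distal")[s]
                    for s in m.sec_id],
        "cl_mM": result.cl_snap[-1],
        "egaba_mV": result.egaba_snap[-1],
    })


def write_run(out_dir, result: SimulationResult, name: str = "run") -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_result(out / f"{name}.h5", result)
    spike_table(result).to_csv(out / f"{name}_spikes.tsv", sep="\t",
                               index=False)
    chloride_profile(result).to_csv(out / f"{name}_cl_profile.tsv", sep="\t",
                                    index=False)
    return out / f"{name}.h5"
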