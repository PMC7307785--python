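"""Hierarchical run configuration: YAML schema, resolution to full
defaults, and the provenance writer that emits the resolved config next to
every result."""

from __future__ import annotations

from pathlib import Path

import yaml

from .engine import SimulationConfig
from .morphology import NeuronModel, build_default_model

_TOP_KEYS = {"sections", "channels", "kcc2", "synapses", "stimuli", "sim"}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    return cfg


def build_from_config(cfg: dict) -> tuple[NeuronModel, SimulationConfig, dict]:
    """Materialise model and simulation settings from a config mapping."""
    overrides = {}
    for sec, vals in (cfg.get("sections") or {}).items():
        for attr, v in (vals or {}).items():
            overrides[f"{sec}_{attr}"] = v
    for key, v in (cfg.get("channels") or {}).items():
        overrides[key] = v
    kcc2 = cfg.get("kcc2") or {}
    if "percent" in kcc2:
        overrides["pkcc2_percent"] = kcc2["percent"]
    if "percent_distal" in kcc2:
        overrides["pkcc2_percent_distal"] = kcc2["percent_distal"]
    model = build_default_model(overrides)
    sim = SimulationConfig(**(cfg.get("sim") or {}))
    return model, sim, cfg.get("stimuli") or {}


def resolved_config(model: NeuronModel, sim: SimulationConfig,
                    stimuli: dict | None = None) -> dict:
    """Fully-defaulted snapshot sufficient to re-run the simulation."""
    return {
        "sections": {
            name: {"length_um": spec.length_um, "diam_um": spec.diam_um,
                   "n_comp": spec.n_comp}
            for name, spec in model.sections.items()},
        "channels": {
            "leak_scale": model.leak_scale,
            "g_na": float(model.g_na.max()),
            "g_k": float(model.g_k.max()),
            "g_m": float(model.g_m.max()),
            "cm": model.cm, "ra": model.ra,
        },
        "kcc2": {"p_current_default": float(model.p_kcc2[model.soma_index])},
        "stimuli": stimuli or {},
        "sim": {k: (v if not hasattr(v, "item") else v.item())
                for k, v in vars(sim).items()},
    }


def write_resolved_config(path, model: NeuronModel, sim: SimulationConfig,
                          stimuli: dict | None = None) -> None:
    Path(path).write_text(
        yaml.safe_dump(resolved_config(model, sim, stimuli),
                       sort_keys=True))
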