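"""End-to-end orchestration: simulate -> analyze -> results bundle.

A single structured config (YAML file or plain dict) drives the whole
chain the package implements for one synthetic chronic session:
category-space construction, behavioral simulation, neural simulation,
optional fluorescence conditioning, psychometric/boundary analysis,
responsiveness quantification, encoding-GLM fits with significance and
unique contributions, and category-tuning indices. Every stage's
randomness derives from one base seed; a manifest recording the full
config, seeds, package version and per-stage timings is written next
to the outputs so any number in the bundle can be regenerated.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import (boundary_angle_diff, choice_fraction_by_distance,
                       fit_choice_sigmoid, fit_expressed_boundary, fraction_correct)
from .glm import GlmEngine, max_vif, significance_by_shuffle, subgroup_delta_r2
from .responsiveness import responsive_probability
from .session import SessionRecording, save_session
from .signals import neuropil_correct, ratio_dff
from .simulate import (AgentParams, TimingConfig, random_planted_kernels,
                       simulate_behavior_session, simulate_fluorescence,
                       simulate_neural_session)
from .spaces import CategorySpace, build_category_space, reduce_to_category_stimuli
from .tuning import cti_result

__all__ = ["DEFAULT_CONFIG", "load_config", "validate_config",
           "space_from_config", "run_full_pipeline"]

#: demo-scale defaults: one in-task session of the reduced category space
DEFAULT_CONFIG: dict = {
    "seed": 1,
    "space": {
        "n_orientations": 6,
        "orientation_spacing_deg": 18.0,
        "spatial_frequencies": [0.04, 0.06, 0.08, 0.12, 0.16],
        "boundary_angle_deg": 23.0,
        "boundary_offset": 0.1,
        "directions": 1,
        "n_category_stimuli_per_side": 5,
    },
    "agent": {
        "planted_boundary_angle_deg": 23.0,
        "lapse_rate": 0.1,
        "side_bias": 0.0,
        "steepness": 3.0,
        "miss_probability": 0.1,
    },
    "session": {
        "n_trials": 120,
        "n_neurons": 8,
        "frame_rate_hz": 15.0,
        "noise_sd": 0.5,
        "trial_gain_cv": 0.2,
    },
    "signals": {"enabled": False, "contamination": 0.3, "drift_amplitude": 0.1},
    "behavior": {"boundary_method": "max_margin", "trained_angle_deg": 23.0},
    "responsiveness": {"enabled": True, "n_subsample": 8, "n_repeats": 25},
    "glm": {"n_repeats": 20, "train_fraction": 0.7, "l1_scale": 0.01,
            "delta_r2_subgroups": ["category", "choice"], "vif": True},
    "cti": {"enabled": True},
}

_SCHEMA: dict[str, dict[str, type | tuple]] = {
    "space": {"n_orientations": int, "orientation_spacing_deg": (int, float),
              "spatial_frequencies": list, "boundary_angle_deg": (int, float),
              "boundary_offset": (int, float), "directions": int,
              "n_category_stimuli_per_side": (int, type(None))},
    "agent": {"planted_boundary_angle_deg": (int, float),
              "lapse_rate": (int, float), "side_bias": (int, float),
              "steepness": (int, float), "miss_probability": (int, float)},
    "session": {"n_trials": int, "n_neurons": int, "frame_rate_hz": (int, float),
                "noise_sd": (int, float), "trial_gain_cv": (int, float)},
    "signals": {"enabled": bool, "contamination": (int, float),
                "drift_amplitude": (int, float)},
    "behavior": {"boundary_method": str, "trained_angle_deg": (int, float)},
    "responsiveness": {"enabled": bool, "n_subsample": int, "n_repeats": int},
    "glm": {"n_repeats": int, "train_fraction": (int, float),
            "l1_scale": (int, float), "delta_r2_subgroups": list, "vif": bool},
    "cti": {"enabled": bool},
}


def load_config(path_or_dict) -> dict:
    """Read and validate a YAML config (or validate a dict in place)."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as f:
            cfg = yaml.safe_load(f)
    else:
        cfg = dict(path_or_dict)
    return validate_config(cfg)


def validate_config(cfg: dict) -> dict:
    """Merge over defaults and type-check every field; fail before any work."""
    merged = {k: (dict(v) if isinstance(v, dict) else v)
              for k, v in DEFAULT_CONFIG.items()}
    for section, value in cfg.items():
        if section == "seed":
            merged["seed"] = int(value)
            continue
        if section not in _SCHEMA:
            raise ValueError(f"unknown config section: {section!r}")
        if not isinstance(value, dict):
            raise ValueError(f"config section {section!r} must be a mapping")
        for key, v in value.items():
            if key not in _SCHEMA[section]:
                raise ValueError(f"unknown config field: {section}.{key}")
            merged[section][key] = v
    for section, fields in _SCHEMA.items():
        for key, typ in fields.items():
            if key not in merged[section]:
                raise ValueError(f"missing config field: {section}.{key}")
            if not isinstance(merged[section][key], typ):
                raise ValueError(
                    f"config field {section}.{key} has type "
                    f"{type(merged[section][key]).__name__}, expected {typ}")
    return merged


def space_from_config(cfg: dict) -> CategorySpace:
    sc = cfg["space"]
    space = build_category_space(
        sc["n_orientations"], sc["orientation_spacing_deg"],
        sc["spatial_frequencies"], sc["boundary_angle_deg"],
        sc["boundary_offset"], sc["directions"],
    )
    if sc["n_category_stimuli_per_side"]:
        space = reduce_to_category_stimuli(space, sc["n_category_stimuli_per_side"])
    return space


def run_full_pipeline(config=None, seed: int | None = None,
                      output_dir=None) -> dict:
    """Run simulate -> (signals) -> behavior -> responsiveness -> glm -> cti.

    Returns the results bundle as a dict; with ``output_dir`` also
    writes the session container, per-stage CSV/JSON outputs and a
    manifest that makes the bundle reproducible.
    """
    cfg = load_config(config) if config is not None else validate_config({})
    if seed is not None:
        cfg["seed"] = int(seed)
    root = np.random.SeedSequence(cfg["seed"])
    seeds = {name: int(s.generate_state(1)[0] % 2**31) for name, s in
             zip(["behavior", "neural", "signals", "responsiveness", "glm", "cti"],
                 root.spawn(6))}
    bundle: dict = {"config": cfg, "seeds": seeds, "version": __version__}
    timings: dict[str, float] = {}

    # --- simulate -------------------------------------------------------
    t0 = time.time()
    space = space_from_config(cfg)
    agent = AgentParams(
        planted_boundary_angle_deg=cfg["agent"]["planted_boundary_angle_deg"],
        lapse_rate=cfg["agent"]["lapse_rate"],
        side_bias=cfg["agent"]["side_bias"],
        steepness=cfg["agent"]["steepness"],
        miss_probability=cfg["agent"]["miss_probability"],
    )
    trials = simulate_behavior_session(
        space, agent, cfg["session"]["n_trials"], TimingConfig(),
        seed=seeds["behavior"],
    )
    kernels = random_planted_kernels(space, cfg["session"]["n_neurons"],
                                     seed=seeds["neural"])
    session = simulate_neural_session(
        trials, kernels, cfg["session"]["frame_rate_hz"],
        noise_sd=cfg["session"]["noise_sd"],
        trial_gain_cv=cfg["session"]["trial_gain_cv"], seed=seeds["neural"],
    )
    timings["simulate"] = time.time() - t0

    # --- signals (optional round trip through raw fluorescence) ---------
    if cfg["signals"]["enabled"]:
        t0 = time.time()
        fluo = simulate_fluorescence(
            session, contamination=cfg["signals"]["contamination"],
            drift_amplitude=cfg["signals"]["drift_amplitude"],
            seed=seeds["signals"],
        )
        corrected = np.vstack([
            neuropil_correct(fluo.signal[n], fluo.neuropil[n])
            for n in range(session.n_neurons)
        ])
        dff = np.vstack([
            ratio_dff(corrected[n], fluo.structural[n], session.frame_rate_hz)
            for n in range(session.n_neurons)
        ])
        bundle["signals"] = {"dff_mean": float(dff.mean()),
                             "dff_sd": float(dff.std())}
        timings["signals"] = time.time() - t0

    # --- behavior --------------------------------------------------------
    t0 = time.time()
    bcfg = cfg["behavior"]
    boundary = fit_expressed_boundary(trials, space, bcfg["boundary_method"])
    dist_table = choice_fraction_by_distance(trials)
    sigmoid = fit_choice_sigmoid(dist_table)
    bundle["behavior"] = {
        "fraction_correct": fraction_correct(trials),
        "boundary_angle_deg": boundary.angle_deg,
        "boundary_offset": boundary.offset,
        "boundary_method": boundary.method,
        "boundary_goodness": boundary.goodness,
        "angle_diff_to_trained_deg": boundary_angle_diff(
            boundary, bcfg["trained_angle_deg"]),
        "sigmoid_steepness": sigmoid.steepness,
        "sigmoid_floor": sigmoid.floor,
        "sigmoid_span": sigmoid.span,
    }
    timings["behavior"] = time.time() - t0

    # --- responsiveness --------------------------------------------------
    if cfg["responsiveness"]["enabled"]:
        t0 = time.time()
        rcfg = cfg["responsiveness"]
        # clamp the subsample to what the session's stimuli allow; stimuli
        # with fewer than 2 trials cannot be tested and are left out
        counts = trials.groupby(["ori_index", "sf_index", "direction"]).size()
        eligible = counts[counts >= 2]
        n_sub = int(min(rcfg["n_subsample"], eligible.min()))
        stimuli = [tuple(map(int, s)) for s in eligible.index]
        probs = [
            responsive_probability(session, n, stimuli=stimuli,
                                   n_subsample=n_sub,
                                   n_repeats=rcfg["n_repeats"],
                                   seed=seeds["responsiveness"] + n)
            for n in range(session.n_neurons)
        ]
        bundle["responsiveness"] = {
            "per_neuron_probability": probs,
            "n_subsample": n_sub,
            "fraction_responsive": float(np.mean(probs)),
        }
        timings["responsiveness"] = time.time() - t0

    # --- encoding GLM ----------------------------------------------------
    t0 = time.time()
    gcfg = cfg["glm"]
    engine = GlmEngine(session, l1_scale=gcfg["l1_scale"])
    glm_rows = []
    fits = {}
    for n in range(session.n_neurons):
        fit = engine.cross_validated_fit(
            n, n_repeats=gcfg["n_repeats"],
            train_fraction=gcfg["train_fraction"], seed=seeds["glm"] + n)
        shuf = engine.cross_validated_fit(
            n, n_repeats=gcfg["n_repeats"],
            train_fraction=gcfg["train_fraction"],
            seed=seeds["glm"] + 10_000 + n, shuffle_trials=True)
        sig = significance_by_shuffle(fit, shuf, seed=seeds["glm"] + n)
        row = {"neuron": n, "test_r2": fit.mean_test_r2,
               "shuffled_r2": shuf.mean_test_r2, "significant": sig}
        for sg in gcfg["delta_r2_subgroups"]:
            row[f"delta_r2_{sg}"] = subgroup_delta_r2(
                engine, n, fit, sg, n_repeats=max(5, gcfg["n_repeats"] // 2),
                seed=seeds["glm"] + 20_000 + n)
        glm_rows.append(row)
        fits[n] = fit
    glm_table = pd.DataFrame(glm_rows)
    bundle["glm"] = {"table": glm_table,
                     "n_significant": int(glm_table["significant"].sum())}
    if gcfg["vif"]:
        mv, _ = max_vif(engine.design)
        bundle["glm"]["max_vif"] = float(mv)
    timings["glm"] = time.time() - t0

    # --- category tuning -------------------------------------------------
    if cfg["cti"]["enabled"]:
        t0 = time.time()
        cti_rows = []
        for n, fit in fits.items():
            r = cti_result(fit, space, neuron=n)
            cti_rows.append({"neuron": n, "semantic_cti": r.semantic,
                             "feature_cti": r.feature, "delta_cti": r.delta,
                             "choice_selectivity": r.choice,
                             "valid": r.semantic_valid and r.feature_valid})
        bundle["cti"] = {"table": pd.DataFrame(cti_rows)}
        timings["cti"] = time.time() - t0

    bundle["timings_s"] = timings

    if output_dir is not None:
        _write_bundle(bundle, session, trials, dist_table, Path(output_dir))
    return bundle


def _write_bundle(bundle: dict, session: SessionRecording, trials: pd.DataFrame,
                  dist_table: pd.DataFrame, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    save_session(session, out / "session.h5")
    trials.to_csv(out / "trials.csv", index=False)
    dist_table.to_csv(out / "choice_by_distance.csv", index=False)
    with open(out / "behavior.json", "w") as f:
        json.dump(bundle["behavior"], f, indent=2)
    if "responsiveness" in bundle:
        with open(out / "responsiveness.json", "w") as f:
            json.dump(bundle["responsiveness"], f, indent=2)
    bundle["glm"]["table"].to_csv(out / "glm_fits.csv", index=False)
    if "cti" in bundle:
        bundle["cti"]["table"].to_csv(out / "cti.csv", index=False)
    manifest = {
        "version": bundle["version"],
        "config": bundle["config"],
        "seeds": bundle["seeds"],
        "timings_s": bundle["timings_s"],
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, default=str)
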