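"""End-to-end orchestration: config, seeding, validation, manifests.

A run is described by a YAML/dict config; each stochastic stage derives
its own seed deterministically from the global seed and the stage name,
so a whole run is reproducible from one integer.  Every stage writes its
outputs under the run directory and is recorded in ``manifest.json``.
"""

from __future__ import annotations

import json
import logging
import zlib

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, design, psycho, sequential, synth, ddm, eeg

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "stages": ["design", "simulate", "psychometrics", "sequential"],
    "design": {"t_min": 0.3, "t_max": 0.9, "n_levels": 7,
               "reps_per_transition": 8, "include_null": True},
    "simulate": {"carryover_gain": 0.0, "n_subjects": 1},
    "filter": {"lo": 0.1, "hi": 1.0},
    "psychometrics": {"min_per_level": 8, "n_boot": 1999},
    "sequential": {"window": 131, "step": 1, "smooth": 10, "min_per_level": 8},
    "ddm": {"n_chains": 3, "n_samples": 600, "n_burn": 250, "varies_by": {}},
    "eeg": {"n_trials": 70, "n_channels": 4, "snr": 0.5,
            "slope_per_second": 1.0, "regressor": "prior_duration",
            "n_freqs": 40, "n_perm": 500,
            "baseline": "none"},
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(global_seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def load_config(path_or_dict) -> dict:
    """Load a config (YAML path or dict), merged over the defaults."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as f:
            user = yaml.safe_load(f) or {}
    else:
        user = dict(path_or_dict or {})
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


TABLE_SCHEMA = {
    "required": design.TABLE_COLUMNS,
    "choices": {"short", "long"},
}


def validate_table(path, schema: dict | None = None) -> list[dict]:
    """Validate a trial-table CSV; returns a machine-readable error list."""
    schema = schema or TABLE_SCHEMA
    try:
        table = pd.read_csv(path)
    except OSError as exc:
        raise IOError(f"cannot read {path}: {exc}") from exc
    errors = []
    for col in schema["required"]:
        if col not in table.columns:
            errors.append({"kind": "missing_column", "column": col})
    if errors:
        return errors
    bad_rt = table.index[table["rt_s"].notna() & (table["rt_s"] < 0)]
    errors.extend({"kind": "range", "column": "rt_s", "row": int(r)}
                  for r in bad_rt)
    bad_d = table.index[table["duration_s"] <= 0]
    errors.extend({"kind": "range", "column": "duration_s", "row": int(r)}
                  for r in bad_d)
    known = schema["choices"]
    bad_choice = table.index[table["choice"].notna()
                             & ~table["choice"].isin(known)]
    errors.extend({"kind": "enumeration", "column": "choice", "row": int(r)}
                  for r in bad_choice)
    return errors


def run_pipeline(config, out_dir) -> dict:
    """Execute the configured stages and write a manifest.

    Stage order: design -> simulate -> filter -> psychometrics ->
    sequential -> ddm -> eeg; any subset can be selected via
    ``config["stages"]`` (upstream stages a selected stage needs are run
    implicitly).  Returns the manifest dict (also written to
    ``manifest.json``); on a stage failure the manifest of completed
    stages is still written before the exception propagates.
    """
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": cfg,
        "stages": {},
        "outputs": {},
    }
    stages = cfg["stages"]
    try:
        _run_stages(cfg, out, seed, manifest, stages)
    finally:
        with open(out / "manifest.json", "w") as f:
            json.dump(manifest, f, indent=2, sort_keys=True, default=_jsonable)
    return manifest


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def _run_stages(cfg, out, seed, manifest, stages):
    need_behavior = any(s in stages for s in
                        ("design", "simulate", "psychometrics", "sequential", "ddm"))
    trials = None
    stimuli = None
    if need_behavior:
        dcfg = cfg["design"]
        stimuli = design.make_stimulus_set(
            dcfg["t_min"], dcfg["t_max"], dcfg["n_levels"])
        seq = design.generate_sequence(
            dcfg["n_levels"], dcfg["reps_per_transition"],
            include_null=dcfg["include_null"],
            seed=stage_seed(seed, "design"),
        )
        table = design.annotate_transitions(seq, stimuli)
        design.write_table(table, out / "design.csv")
        manifest["stages"]["design"] = {
            "seed": stage_seed(seed, "design"),
            "n_trials": int(seq.n_stimulus_trials),
            "n_null": int(seq.n_null),
            "length": len(seq),
            "geometric_mean_s": stimuli.geometric_mean,
        }
        manifest["outputs"]["design"] = "design.csv"
        trials = table

    if "simulate" in stages or any(
            s in stages for s in ("psychometrics", "sequential", "ddm")):
        scfg = cfg["simulate"]
        gspec = synth.default_generative_spec(
            seed=stage_seed(seed, "simulate"),
            carryover_gain=scfg["carryover_gain"],
        )
        if scfg.get("n_subjects", 1) > 1:
            trials = synth.simulate_subjects(scfg["n_subjects"], trials, gspec)
        else:
            trials = synth.simulate_bisection_dataset(trials, gspec)
            trials.insert(0, "subject", "s00")
        trials.to_csv(out / "trials.csv", index=False)
        manifest["stages"]["simulate"] = {
            "seed": stage_seed(seed, "simulate"),
            "n_rows": len(trials),
            "carryover_gain": scfg["carryover_gain"],
        }
        manifest["outputs"]["simulate"] = "trials.csv"

        fcfg = cfg["filter"]
        n0 = len(trials)
        trials = trials.groupby("subject", group_keys=False).apply(
            lambda df: psycho.filter_rt(df, fcfg["lo"], fcfg["hi"]))
        manifest["stages"]["filter"] = {
            "removed": n0 - len(trials), "kept": len(trials),
            "lo": fcfg["lo"], "hi": fcfg["hi"],
        }

    if "psychometrics" in stages:
        pcfg = cfg["psychometrics"]
        rows = []
        for sid, df in trials.groupby("subject"):
            fit = psycho.fit_gumbel_trials(df, min_per_level=pcfg["min_per_level"],
                                           enforce_min=False)
            rec = {"subject": sid, "bp": fit.bp, "dl": fit.dl, "cv": fit.cv,
                   "theta25": fit.theta25, "theta75": fit.theta75,
                   "converged": fit.converged}
            if fit.converged:
                ci = psycho.thresholds_bootstrap(
                    fit, n_boot=pcfg["n_boot"],
                    seed=stage_seed(seed, f"boot:{sid}"))
                rec["bp_ci_lo"], rec["bp_ci_hi"] = ci["bp"]
            chron = psycho.chronometric(df)
            rec["mean_rt"] = float(np.nanmean(chron.mean_rt))
            rows.append(rec)
        fits = pd.DataFrame(rows)
        fits.to_csv(out / "psychometrics.csv", index=False)
        manifest["stages"]["psychometrics"] = {
            "n_subjects": len(rows),
            "mean_bp": float(fits["bp"].mean()),
            "n_boot": pcfg["n_boot"],
        }
        manifest["outputs"]["psychometrics"] = "psychometrics.csv"

    if "sequential" in stages:
        qcfg = cfg["sequential"]
        rows = []
        slid_frames = []
        for sid, df in trials.groupby("subject"):
            co = sequential.carryover_bp(
                df, min_per_level=min(4, qcfg["min_per_level"]))
            rows.append({"subject": sid, "slope": co.slope,
                         "slope_se": co.slope_se,
                         "decisional_delta": co.decisional_delta})
            w = min(qcfg["window"], len(df))
            ser = sequential.sliding_bp(
                df, window=w, step=qcfg["step"], smooth=qcfg["smooth"],
                min_per_level=qcfg["min_per_level"])
            slid_frames.append(pd.DataFrame({
                "subject": sid, "center": ser.centers, "bp": ser.bp,
                "smoothed_bp": ser.smoothed_bp, "flagged": ser.insufficient,
            }))
        pd.DataFrame(rows).to_csv(out / "carryover.csv", index=False)
        pd.concat(slid_frames).to_csv(out / "sliding_bp.csv", index=False)
        slopes = [r["slope"] for r in rows if np.isfinite(r["slope"])]
        manifest["stages"]["sequential"] = {
            "mean_slope": float(np.mean(slopes)) if slopes else None,
        }
        manifest["outputs"]["sequential"] = ["carryover.csv", "sliding_bp.csv"]

    if "ddm" in stages:
        mcfg = cfg["ddm"]
        spec = ddm.ModelSpec(
            varies_by={k: tuple(v) for k, v in mcfg["varies_by"].items()},
            n_chains=mcfg["n_chains"], n_samples=mcfg["n_samples"],
            n_burn=mcfg["n_burn"], seed=stage_seed(seed, "ddm"),
        )
        fit = ddm.fit_hierarchical(trials, spec)
        fit.group.to_csv(out / "ddm_group.csv")
        fit.subject.to_csv(out / "ddm_subject.csv")
        manifest["stages"]["ddm"] = {
            "seed": spec.seed, "dic": fit.dic,
            "max_rhat": max(fit.rhat.values()) if fit.rhat else None,
            "converged": fit.converged,
        }
        manifest["outputs"]["ddm"] = ["ddm_group.csv", "ddm_subject.csv"]

    if "eeg" in stages:
        ecfg = cfg["eeg"]
        espec = synth.EEGEffectSpec(
            n_trials=ecfg["n_trials"], n_channels=ecfg["n_channels"],
            snr=ecfg["snr"], slope_per_second=ecfg["slope_per_second"],
        )
        rng = np.random.default_rng(stage_seed(seed, "eeg"))
        durs = np.geomspace(0.3, 0.9, 7)
        present = rng.choice(durs, espec.n_trials)
        prior = rng.choice(durs, espec.n_trials)
        epochs = synth.simulate_eeg_epochs(
            espec, present, rng, prior_durations=prior,
            regressor=ecfg["regressor"])
        epochs.save(out / "epochs.h5")
        freqs = eeg.log_freqs(n=ecfg["n_freqs"])
        tf = eeg.morlet_tf(epochs, freqs)
        if ecfg["baseline"] == "single_trial_division":
            tf = eeg.baseline_divide(tf)
        slope_map = eeg.duration_regression(tf, regressor=ecfg["regressor"])
        np.savetxt(out / "slope_map.csv", slope_map, delimiter=",")
        manifest["stages"]["eeg"] = {
            "seed": stage_seed(seed, "eeg"),
            "n_freqs": ecfg["n_freqs"],
            "max_abs_slope": float(np.abs(slope_map).max()),
        }
        manifest["outputs"]["eeg"] = ["epochs.h5", "slope_map.csv"]
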