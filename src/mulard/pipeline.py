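"""End-to-end orchestration: simulate -> preprocess -> calibrate -> predict
-> genetic parameters -> selection index, driven by one YAML config.

Every stage writes plain CSV (plus one JSON manifest per run) so any stage
can be rerun independently; the seed propagates to every stochastic stage.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chemometrics as chem
from . import genetic_model as gm
from . import pedigree as pg
from . import selection_index as si
from . import simdata
from . import spectra as sp

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulation": {},
    "recipe": {
        "derivative_order": 1,
        "derivative_gap": 10,
        "smooth_window": 5,
        "normalization": "snv",
    },
    "calibration": {"n_select": 198, "n_groups": 5, "n_latent_max": 12, "trait": "MR"},
    "model": {"traits": ["mMR"], "chain_length": 20000, "burn_in": 4000, "thinning": 1},
    "index": {"use": "phenotypic"},
}


def load_config(path=None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def recipe_from_config(block: dict) -> sp.PreprocessRecipe:
    known = {
        k: v
        for k, v in block.items()
        if k in (
            "derivative_order", "derivative_gap", "smooth_window",
            "normalization", "wavelength_window", "savitzky_golay",
        )
    }
    if "wavelength_window" in known:
        known["wavelength_window"] = tuple(known["wavelength_window"])
    return sp.PreprocessRecipe(**known)


def _manifest_entry(manifest: dict, stage: str, inputs, outputs, seed=None) -> None:
    manifest["stages"].append(
        {
            "stage": stage,
            "inputs": [str(p) for p in inputs],
            "outputs": [str(p) for p in outputs],
            "seed": seed,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
    )


def run_all(config: dict, outdir) -> Path:
    """Execute every stage in order; returns the run directory.

    Stages: simulate the study (phenotypes, pedigrees, composition, raw
    ground-mode spectra); preprocess; PLS calibration of the melting rate
    with cross-validation and external validation; prediction of all
    samples; Gibbs estimation of partial genetic parameters for the
    measured and the predicted melting rate; selection-index accuracy from
    the posterior-mean component matrices.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config, "stages": []}
    seed = int(config.get("seed", 0))

    # --- simulate
    sim_kwargs = dict(config.get("simulation") or {})
    sim_kwargs.setdefault("seed", seed)
    sim_cfg = simdata.SimulationConfig(**sim_kwargs)
    study = simdata.simulate_study(sim_cfg, spectra=True)
    study.write(out)
    _manifest_entry(
        manifest, "simulate", [],
        ["pedigree_common.csv", "pedigree_muscovy.csv", "phenotypes.csv",
         "truth.csv", "composition.csv", "spectra_ground.csv", "spectra_surface.csv"],
        seed=sim_cfg.seed,
    )

    # --- preprocess
    recipe = recipe_from_config(config["recipe"])
    avg = sp.average_replicates(study.spectra_ground)
    proc = sp.apply_recipe(avg, recipe)
    proc.write_csv(out / "spectra_processed.csv")
    _manifest_entry(manifest, "preprocess", ["spectra_ground.csv"], ["spectra_processed.csv"])

    # --- calibrate
    cal = config["calibration"]
    trait = cal.get("trait", "MR")
    y_map = dict(zip(study.composition["animal"], study.composition[trait]))
    y_all = np.array([y_map[s] for s in proc.sample_ids])
    cal_ids = chem.select_calibration_set(
        proc.values, proc.sample_ids, int(cal["n_select"]), seed=seed
    )
    mask = np.isin(proc.sample_ids, cal_ids)
    n_latent, secv, cv_table = chem.cross_validate(
        proc.values[mask], y_all[mask], range(1, int(cal["n_latent_max"]) + 1),
        n_groups=int(cal["n_groups"]), seed=seed,
    )
    model = chem.pls_fit(
        proc.values[mask], y_all[mask], n_latent,
        recipe=recipe, sample_ids=proc.sample_ids[mask],
    )
    ext = chem.validate_external(
        model, proc.values[~mask], y_all[~mask], proc.sample_ids[~mask]
    )
    cal_stats = model.stats.to_series()
    cal_stats["SECV"] = secv
    table1 = pd.DataFrame(
        {
            "set": ["calibration", "validation"],
            "n": [model.stats.n, ext.n],
            "mean": [model.stats.mean, ext.mean],
            "sd": [model.stats.sd, ext.sd],
            "SEC": [model.stats.sec, np.nan],
            "R2": [model.stats.r2, np.nan],
            "SECV": [secv, np.nan],
            "SEP": [np.nan, ext.sep],
            "bias": [np.nan, ext.bias],
        }
    )
    table1.to_csv(out / "calibration_stats.csv", index=False)
    with open(out / "calibration_model.json", "w") as fh:
        json.dump(model.to_dict(), fh)
    _manifest_entry(
        manifest, "calibrate", ["spectra_processed.csv", "composition.csv"],
        ["calibration_stats.csv", "calibration_model.json"], seed=seed,
    )

    # --- predict all samples, append as a new trait
    pred = pd.DataFrame(
        {"animal": proc.sample_ids, "pMR": model.predict(proc.values)}
    )
    pred.to_csv(out / "predictions.csv", index=False)
    phen = study.dataset.merge(pred, on="animal")
    phen.to_csv(out / "phenotypes_with_predictions.csv", index=False)
    _manifest_entry(
        manifest, "predict", ["calibration_model.json", "spectra_processed.csv"],
        ["predictions.csv", "phenotypes_with_predictions.csv"],
    )

    # --- genetic parameters (measured + predicted trait, bivariate)
    mdl = config["model"]
    traits = [sim_cfg.trait_names[0], "pMR"]
    gibbs_cfg = gm.GibbsConfig(
        chain_length=int(mdl["chain_length"]), burn_in=int(mdl["burn_in"]),
        thinning=int(mdl.get("thinning", 1)), seed=seed,
    )
    norm_report = gm.check_normality(phen, traits)
    norm_report.to_csv(out / "normality.csv", index=False)
    summary = gm.gibbs_fit(
        phen, study.pedigrees.common, study.pedigrees.muscovy, traits, gibbs_cfg
    )
    summary.to_table().to_csv(out / "genetic_parameters.csv", index=False)
    summary.ebv("dam").to_csv(out / "ebv_dam.csv", index=False)
    summary.ebv("sire").to_csv(out / "ebv_sire.csv", index=False)
    _manifest_entry(
        manifest, "genpar",
        ["phenotypes_with_predictions.csv", "pedigree_common.csv", "pedigree_muscovy.csv"],
        ["genetic_parameters.csv", "ebv_dam.csv", "ebv_sire.csv", "normality.csv"],
        seed=seed,
    )

    # --- selection index: predict trait 0's dam-line effect from trait 1
    G_dam = summary.component_mean("G_dam")
    G_sire = summary.component_mean("G_sire")
    R = summary.component_mean("R")
    problem = si.problem_from_components(
        G_dam, R, G_sire, target=0, predictors=[1],
        use=config["index"].get("use", "phenotypic"),
    )
    result = si.index_accuracy(problem)
    result.to_frame().to_csv(out / "index_accuracy.csv", index=False)
    _manifest_entry(manifest, "index", ["genetic_parameters.csv"], ["index_accuracy.csv"])

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out


def report(run_dir) -> str:
    """Human-readable summary of a completed (or partial) run."""
    run = Path(run_dir)
    lines = [f"Run report: {run}", "=" * 40]
    warn = []

    def section(title, fname, fmt=None):
        path = run / fname
        if not path.exists():
            warn.append(f"missing stage output: {fname}")
            return
        df = pd.read_csv(path)
        lines.append("")
        lines.append(title)
        lines.append("-" * len(title))
        lines.append(df.to_string(index=False, float_format=fmt))

    section("Calibration statistics (SEC / SECV / SEP)", "calibration_stats.csv",
            lambda v: f"{v:.2f}")
    section("Trait normality screen", "normality.csv", lambda v: f"{v:.3f}")
    section("Partial heritabilities and genetic correlations",
            "genetic_parameters.csv", lambda v: f"{v:.3f}")
    section("Selection-index accuracy", "index_accuracy.csv", lambda v: f"{v:.3f}")
    if warn:
        lines.append("")
        lines.append("WARNINGS")
        lines.extend(f"  - {w}" for w in warn)
    return "\n".join(lines)
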