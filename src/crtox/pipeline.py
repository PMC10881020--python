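"""End-to-end reproducible pipeline over synthetic (or supplied) data.

Stages: generate/ingest data -> cell-free ROS pre-fit (model 2) -> species
mono-culture fits -> co-culture prediction and goodness scores -> serial
transfer phase sweep.  Every artifact lands in the configured output
directory together with a run log recording seeds, versions and stage
status; identical configs give identical numeric outputs.
"""

from __future__ import annotations

import json
import logging
import platform
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .fit import (FitProblem, fit_cellfree_ros, fit_monoculture, goodness_scores,
                  predict_coculture)
from .io import (RunConfig, save_params, write_growth_csv, write_ros_csv)
from .model_core import CultureState, ModelSpec
from .reference import INOCULUM, reference_params
from .simulate import sweep_phase
from .synthetic_data import ExperimentDesign, NoiseModel, generate_growth_curves, \
    generate_ros_curves

log = logging.getLogger("crtox")

#: Default parameter boxes searched by the pipeline fits.
DEFAULT_BOUNDS = {
    "r": (1e-3, 10.0), "K": (1e-3, 10.0), "Y": (1e5, 1e10),
    "beta": (1e-6, 100.0), "gamma": (1e-6, 10.0), "alpha": (0.0, 1e-6),
    "d": (0.0, 10.0), "e": (0.0, 10.0), "m": (1e-3, 1e3), "l": (0.0, 10.0),
}

_FREE = {
    "model1": {"At": ["r", "K", "Y", "beta", "gamma"], "Ct": ["r", "K", "Y"]},
    "model2": {"At": ["r", "K", "Y", "beta"], "Ct": ["r", "K", "Y", "alpha"]},
}


def _fit_problem(config: RunConfig, spec: ModelSpec, species: str) -> FitProblem:
    free = _FREE[spec.family][species]
    fixed = {}
    if spec.family == "model1":
        fixed = {"beta": 0.0, "gamma": 0.0} if species == "Ct" else {}
    else:
        fixed = {"alpha": 0.0} if species == "At" else {"beta": 0.0}
    return FitProblem(spec=spec, free=free,
                      bounds={k: DEFAULT_BOUNDS[k] for k in free},
                      fixed=fixed, n_starts=config.n_starts,
                      n_polish=config.n_polish, seed=1789 + config.seed)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns a dict of results and artifact paths.

    Any stage failure raises, naming the stage; artifacts written by the
    stages already completed remain on disk.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    runlog: dict = {
        "crtox_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config": {**config.__dict__,
                   "fit_concentrations": list(config.fit_concentrations),
                   "sweep_C0": list(config.sweep_C0),
                   "sweep_D": list(config.sweep_D)},
        "seeds": {"noise": config.seed, "fit_multistart": 1789 + config.seed},
        "stages": [],
    }
    results: dict = {"runlog": runlog}
    stage = "setup"
    try:
        species_true, abiotic_true, spec = reference_params(config.family)
        noise = NoiseModel(cfu_cv=config.cfu_cv, ros_sd=config.ros_sd, seed=config.seed)
        design = ExperimentDesign()

        stage = "synthesize"
        params = {**species_true, "abiotic": abiotic_true} if abiotic_true \
            else dict(species_true)
        growth = generate_growth_curves(params, spec, design, noise)
        write_growth_csv(growth, outdir / "growth_curves.csv")
        ros = None
        if spec.family == "model2":
            ros = generate_ros_curves(params, design, noise)
            write_ros_csv(ros, outdir / "ros_curves.csv")
        runlog["stages"].append("synthesize")

        stage = "fit_cellfree_ros"
        abiotic_fit = None
        if spec.family == "model2":
            cellfree = ros[ros["culture_type"] == "cell_free"]
            res = fit_cellfree_ros(cellfree)
            abiotic_fit = res.abiotic_params()
            results["abiotic_fit"] = res
            runlog["abiotic_estimates"] = res.params
        runlog["stages"].append(stage)

        stage = "fit_monocultures"
        fit_conc = [c for c in config.fit_concentrations] if spec.family == "model2" \
            else sorted(growth["concentration_au"].unique())
        fits: dict[str, dict] = {}
        for sp_name in ("At", "Ct"):
            sub = growth[(growth["species"] == sp_name)
                         & (growth["culture_type"] == "mono")
                         & (growth["concentration_au"].isin(fit_conc))]
            ros_sub = None
            if ros is not None:
                ros_sub = ros[(ros["culture_type"] == f"mono_{sp_name}")
                              & (ros["concentration_au"].isin(fit_conc))]
            problem = _fit_problem(config, spec, sp_name)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = fit_monoculture(problem, sub, ros_df=ros_sub,
                                      abiotic=abiotic_fit, inoculum=INOCULUM,
                                      rtol=1e-6, cfu_floor=noise.detection_limit)
            fits[sp_name] = res
            runlog[f"estimates_{sp_name}"] = res.params
            log.info("fitted %s: objective %.4g", sp_name, res.objective)
        results["fits"] = fits
        fitted = {name: fits[name].species_params() for name in ("At", "Ct")}
        save_params(outdir / "fitted_params.yaml", fitted, abiotic_fit, spec)
        runlog["stages"].append(stage)

        stage = "predict_coculture"
        times = np.asarray(design.times, dtype=float)
        mono_pairs, co_pairs, co_trajs = [], [], {}
        for c0 in fit_conc:
            state0 = CultureState(B_At=INOCULUM, B_Ct=INOCULUM, C=float(c0))
            traj = predict_coculture(fitted["At"], fitted["Ct"], spec, state0,
                                     times, ab=abiotic_fit)
            co_trajs[c0] = traj
            for sp_name, col in (("At", "B_At"), ("Ct", "B_Ct")):
                obs = growth[(growth["species"] == sp_name)
                             & (growth["culture_type"] == "co")
                             & (growth["concentration_au"] == c0)]
                if len(obs):
                    co_pairs.append((traj, obs, col))
                mono_obs = growth[(growth["species"] == sp_name)
                                  & (growth["culture_type"] == "mono")
                                  & (growth["concentration_au"] == c0)]
                mono_state = CultureState(B_At=INOCULUM if sp_name == "At" else 0.0,
                                          B_Ct=INOCULUM if sp_name == "Ct" else 0.0,
                                          C=float(c0))
                mono_traj = predict_coculture(fitted["At"], fitted["Ct"], spec,
                                              mono_state, times, ab=abiotic_fit)
                if len(mono_obs):
                    mono_pairs.append((mono_traj, mono_obs, col))
        scores = goodness_scores(mono_pairs, co_pairs)
        results["scores"] = scores
        runlog["goodness_of_fit"] = scores["goodness_of_fit"]
        runlog["goodness_of_prediction"] = scores["goodness_of_prediction"]
        pred_rows = []
        for c0, traj in co_trajs.items():
            df = traj.to_dataframe()
            df.insert(0, "concentration_au", c0)
            pred_rows.append(df)
        pd.concat(pred_rows, ignore_index=True).to_csv(
            outdir / "coculture_prediction.csv", index=False)
        runlog["stages"].append(stage)

        stage = "sweep_phase"
        protocol = config.transfer_protocol()
        diagram = sweep_phase(np.asarray(config.sweep_C0), np.asarray(config.sweep_D),
                              fitted["At"], fitted["Ct"], spec, protocol,
                              horizon=config.horizon, ab=abiotic_fit,
                              inoculum=INOCULUM)
        diagram.to_dataframe().to_csv(outdir / "phase_diagram.csv", index=False)
        results["phase_diagram"] = diagram
        runlog["coexistence_cells"] = diagram.count("coexistence")
        runlog["stages"].append(stage)
    except Exception as e:
        runlog["failed_stage"] = stage
        runlog["error"] = repr(e)
        with open(outdir / "run_log.json", "w", encoding="utf-8") as fh:
            json.dump(runlog, fh, indent=2, default=str)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    runlog["elapsed_s"] = round(time.time() - t_start, 2)
    with open(outdir / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(runlog, fh, indent=2, default=str)
    results["outdir"] = str(outdir)
    return results
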