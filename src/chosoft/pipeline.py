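"""End-to-end orchestration: generate -> fit the three soft sensors ->
predict the validation condition -> compare against the (synthetic)
experiment.

Each stage is a function writing serialized artifacts into an output
directory, so a run is resumable: when ``resume`` is set, stages whose
artifacts already exist are skipped and the artifacts reloaded.  A single
global seed fans out to per-stage seeds by fixed offsets, and all randomness
flows from it; a manifest JSON records the seeds and stage artifact names.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import estimation, neuralnet, opls, stats, synthetic
from .core import (CSV_COLUMNS, Channel, CultureTable, FACTOR_CHANNELS,
                   RESPONSE_CHANNELS, load_config, logger, pool_replicates,
                   read_culture_table)
from .kinetics import DEFAULT_PARAMS, ModelState, simulate_fedbatch

__all__ = ["PipelineConfig", "run_pipeline", "mmk_initial_state"]

# fixed per-stage seed offsets (all derived from the one config seed)
SEED_OFFSETS = {"generate": 11, "fit_mmk": 23, "fit_opls": 37, "fit_nn": 41}

TRAIN_CONDITIONS = ("Control", "A", "B")
VALIDATION_CONDITION = "Validation"


@dataclass
class PipelineConfig:
    out_dir: Path
    seed: int = 1
    stages: tuple = ("generate", "fit_mmk", "fit_opls", "fit_nn",
                     "predict", "compare")
    resume: bool = False
    # generator
    noise_cv: float = 0.05
    use_missingness: bool = True
    # MMK fit
    mmk_mode: str = "teacher_forcing"
    mmk_fit_params: tuple = ("mu_max", "K_glc", "Y_xglc", "alpha_mab", "beta_mab")
    mmk_n_starts: int = 2
    # OPLS: 5 components, all predictive. With six correlated metabolite
    # factors plus time against nine responses the cross-product X'Y is full
    # rank, so no strictly Y-orthogonal X-variation exists to extract, and
    # orthogonal deflation on heavily missing data only erodes the signal.
    opls_pred: int = 5
    opls_orth: int = 0
    # NN
    nn_starts: int = 4
    nn_lambda_evals: int = 4
    exclude_responses: tuple = ("UDP_GLCNAC",)

    @classmethod
    def from_yaml(cls, path, out_dir) -> "PipelineConfig":
        cfg = load_config(path)
        kw = {"out_dir": Path(out_dir), "seed": int(cfg.get("seed", 1))}
        if "noise" in cfg and "cv" in cfg["noise"]:
            kw["noise_cv"] = float(cfg["noise"]["cv"])
        if "opls" in cfg:
            kw["opls_pred"] = int(cfg["opls"].get("predictive", 5))
            kw["opls_orth"] = int(cfg["opls"].get("orthogonal", 0))
        if "nn" in cfg:
            kw["nn_starts"] = int(cfg["nn"].get("n_starts", 4))
        return cls(**kw)


def mmk_initial_state(data: CultureTable, condition: str) -> ModelState:
    """Initial state for a forward simulation of one condition.

    Extracellular channels and VCD start from the t = 0 observations
    (replicate mean); NSD and glycan-linked pools, which are first sampled
    two-three days into culture, are initialized from the earliest measured
    values of the same condition.
    """
    init = ModelState()
    sub = data.df[(data.df["condition"] == condition) & data.df["value"].notna()]
    attr = {Channel.VCD: "Xv", Channel.GLC: "Glc", Channel.GLN: "Gln",
            Channel.GLU: "Glu", Channel.LAC: "Lac", Channel.NH4: "NH4",
            Channel.GAL: "Gal", Channel.TITER: "mAb",
            Channel.UDP_GLC: "UDP_Glc", Channel.UDP_GAL: "UDP_Gal",
            Channel.UDP_GLCNAC: "UDP_GlcNAc", Channel.UDP_GALNAC: "UDP_GalNAc"}
    updates = {}
    for ch, name in attr.items():
        rows = sub[sub["channel"] == ch.name]
        if rows.empty:
            continue
        if ch.is_nsd:
            t_first = rows["time_h"].min()
            updates[name] = float(rows[rows["time_h"] == t_first]["value"].mean())
        else:
            at0 = rows[rows["time_h"] == 0.0]
            if len(at0):
                updates[name] = float(at0["value"].mean())
    return ModelState(**{**init.__dict__, **updates})


def _write_table(table: CultureTable, path: Path):
    table.df.to_csv(path, index=False, na_rep="", float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed,
                "stage_seeds": {k: config.seed + v for k, v in SEED_OFFSETS.items()},
                "stages": {}}
    artifacts = {}

    def stage_done(name, *files):
        return config.resume and all((out / f).exists() for f in files)

    # ---- generate ----------------------------------------------------
    if "generate" in config.stages:
        files = ("observed.csv", "truth.csv")
        if not stage_done("generate", *files):
            noise = synthetic.NoiseSpec(default_cv=config.noise_cv)
            missing = (synthetic.MissingnessSpec() if config.use_missingness
                       else synthetic.MissingnessSpec(fraction={}))
            observed, truth = synthetic.generate_dataset(
                DEFAULT_PARAMS, noise=noise, missing=missing,
                seed=config.seed + SEED_OFFSETS["generate"])
            _write_table(observed, out / "observed.csv")
            _write_table(truth, out / "truth.csv")
        manifest["stages"]["generate"] = list(files)
    observed = read_culture_table(out / "observed.csv", validate=False)
    truth_path = out / "truth.csv"
    truth = read_culture_table(truth_path, validate=False) if truth_path.exists() else None
    train = CultureTable(
        observed.df[observed.df["condition"].isin(TRAIN_CONDITIONS)],
        validate=False)
    valid = observed.subset(condition=VALIDATION_CONDITION)

    # ---- fit MMK ------------------------------------------------------
    if "fit_mmk" in config.stages:
        f = "mmk_fit.json"
        if not stage_done("fit_mmk", f):
            cond = "A"  # representative fed condition for parameter fitting
            data_c = observed.subset(condition=cond)
            sched = synthetic.build_feed_schedule(
                next(c for c in synthetic.default_design() if c.name == cond))
            bounds = {n: (getattr(DEFAULT_PARAMS, n) / 5.0,
                          getattr(DEFAULT_PARAMS, n) * 5.0)
                      for n in config.mmk_fit_params}
            init = mmk_initial_state(observed, cond)
            result = estimation.fit(
                DEFAULT_PARAMS, bounds, data_c, sched, init=init,
                mode=config.mmk_mode, n_starts=config.mmk_n_starts,
                seed=config.seed + SEED_OFFSETS["fit_mmk"], tolerance=1e-6)
            result.to_json(out / f)
        manifest["stages"]["fit_mmk"] = [f]
        artifacts["mmk"] = estimation.FitResult.from_json(out / f)

    # ---- fit OPLS -----------------------------------------------------
    responses = [c for c in RESPONSE_CHANNELS
                 if c.name not in config.exclude_responses]
    if "fit_opls" in config.stages:
        f = "opls_model.json"
        if not stage_done("fit_opls", f):
            X, Y, xc, yc = opls.design_matrices(train, responses=RESPONSE_CHANNELS)
            model = opls.fit_opls(X, Y, A_pred=config.opls_pred,
                                  A_orth=config.opls_orth, x_cols=xc, y_cols=yc)
            model.q2_cum = opls.q2_crossval(
                X, Y, A_pred=config.opls_pred, A_orth=config.opls_orth,
                folds=7, seed=config.seed + SEED_OFFSETS["fit_opls"])
            model.to_json(out / f)
        manifest["stages"]["fit_opls"] = [f]
        artifacts["opls"] = opls.OPLSModel.from_json(out / f)

    # ---- fit NN -------------------------------------------------------
    if "fit_nn" in config.stages:
        f = "nn_model.json"
        if not stage_done("fit_nn", f):
            Xt, Yt, xc, yc = opls.design_matrices(train, responses=responses,
                                                  include_time=False)
            Xv, Yv, _, _ = opls.design_matrices(valid, responses=responses,
                                                include_time=False)
            model = neuralnet.fit_nn(
                Xt, Yt, Xv, Yv, n_starts=config.nn_starts,
                seed=config.seed + SEED_OFFSETS["fit_nn"],
                n_lambda=config.nn_lambda_evals, x_cols=xc, y_cols=yc)
            model.to_json(out / f)
        manifest["stages"]["fit_nn"] = [f]
        artifacts["nn"] = neuralnet.NNModel.from_json(out / f)

    # ---- predict validation condition ----------------------------------
    if "predict" in config.stages:
        files = []
        vcond = next(c for c in synthetic.default_design()
                     if c.name == VALIDATION_CONDITION)
        if "mmk" in artifacts:
            fn = "pred_mmk.csv"
            if not stage_done("predict", fn):
                sched = synthetic.build_feed_schedule(vcond)
                init = mmk_initial_state(observed, VALIDATION_CONDITION)
                grid = synthetic._simulation_grid(vcond)
                traj = simulate_fedbatch(artifacts["mmk"].params, init, sched, grid)
                rows = []
                for ch in RESPONSE_CHANNELS + FACTOR_CHANNELS:
                    series = traj.channel_series(ch)
                    for t, v in zip(grid, series):
                        if np.isfinite(v):
                            rows.append(("MMK", VALIDATION_CONDITION, 1, t,
                                         ch.name, v))
                CultureTable(pd.DataFrame(rows, columns=CSV_COLUMNS),
                             validate=False).write_csv(out / fn)
            files.append(fn)
        # data-driven sensors predict from the validation factor measurements
        Xv_t, _, _, _ = opls.design_matrices(valid, responses=RESPONSE_CHANNELS)
        wide_v = valid.wide().sort_values("time_h")
        for key, fn in (("opls", "pred_opls.csv"), ("nn", "pred_nn.csv")):
            if key not in artifacts:
                continue
            if not stage_done("predict", fn):
                model = artifacts[key]
                xcols = model.x_cols
                Xn = np.column_stack([
                    wide_v[c].to_numpy(dtype=float) if c in wide_v else
                    (wide_v["time_h"].to_numpy(dtype=float) if c == "time_h"
                     else np.full(len(wide_v), np.nan))
                    for c in xcols])
                if key == "opls":
                    Yh = opls.predict(model, Xn)
                else:
                    Yh = neuralnet.forward(model, Xn)
                rows = []
                tcol = wide_v["time_h"].to_numpy(dtype=float)
                for j, yname in enumerate(model.y_cols):
                    for t, v in zip(tcol, Yh[:, j]):
                        if np.isfinite(v):
                            rows.append((key.upper(), VALIDATION_CONDITION,
                                         1, t, yname, v))
                CultureTable(pd.DataFrame(rows, columns=CSV_COLUMNS),
                             validate=False).write_csv(out / fn)
            files.append(fn)
        manifest["stages"]["predict"] = files

    # ---- compare -------------------------------------------------------
    if "compare" in config.stages:
        preds = {}
        for name, fn in (("MMK", "pred_mmk.csv"), ("OPLS", "pred_opls.csv"),
                         ("NN", "pred_nn.csv")):
            if (out / fn).exists():
                preds[name] = read_culture_table(out / fn, validate=False)
        exp = pool_replicates(observed, VALIDATION_CONDITION)
        report_vars = [Channel.VCD, Channel.TITER, Channel.UDP_GAL,
                       Channel.UDP_GLC, Channel.UDP_GALNAC]
        # restrict sources to the experimental timepoints
        report = stats.compare_models(exp, preds, report_vars)
        files = []
        for name, entry in report.items():
            fn = f"tukey_{name}.csv"
            entry["tukey"].to_csv(out / fn, index=False, float_format="%.8g")
            files.append(fn)
        summary = {name: {"anova_F": entry["anova"][0],
                          "anova_p": entry["anova"][3]}
                   for name, entry in report.items()}
        (out / "compare_summary.json").write_text(json.dumps(summary, indent=1,
                                                             sort_keys=True))
        files.append("compare_summary.json")
        manifest["stages"]["compare"] = files

    from . import __version__
    manifest["version"] = __version__
    import hashlib
    manifest["artifact_sha256"] = {
        f: hashlib.sha256((out / f).read_bytes()).hexdigest()
        for files in manifest["stages"].values() for f in files
        if (out / f).exists()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return manifest
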