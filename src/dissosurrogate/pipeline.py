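"""End-to-end orchestration of the synthetic dissolution-surrogate study.

generate -> preprocess -> PLS composition calibration -> ANN profile models
(plus a linear PLS-direct baseline) -> f2/RMSEP evaluation and the
ANN-vs-PLS comparison table, for each of the three input sources: Raman
(both analytes from Raman transmission), NIR (both from NIR transmission)
and NIR-Raman (drug from Raman, polymer from NIR).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as dio
from .composition import (PLSCompositionModel, contiguous_block_cv, ga_select,
                          GAConfig, metrics, pls_fit, predict_composition,
                          select_n_lv)
from .evaluation import (F2Report, build_f2_report, compare_models,
                         effects_from_profiles)
from .preprocess import DEFAULT_RECIPES, apply_recipe
from .profiles import SweepResult, neuron_sweep, pls_direct_fit
from .synthetic import MODALITIES, SimulatorConfig, TabletDataset, generate_dataset

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "SOURCES"]

# Which preprocessed modality feeds each analyte, per input source.
SOURCES: dict[str, dict[str, str]] = {
    "raman": {"dr": "raman_trans", "hpmc": "raman_trans"},
    "nir": {"dr": "nir_trans", "hpmc": "nir_trans"},
    "nir_raman": {"dr": "raman_trans", "hpmc": "nir_trans"},
}


@dataclass
class PipelineConfig:
    """Run settings.  ``profile="quick"`` is a desk-scale configuration
    (BR trainer, 5 replicate runs, H in {1,3,5}); ``"full"`` mirrors the
    study protocol (both trainers, 100 runs, H 1..10)."""

    seed: int = 0
    out_dir: str | Path = "runs/run0"
    profile: str = "quick"
    trainers: tuple[str, ...] | None = None
    runs: int | None = None
    h_values: tuple[int, ...] | None = None
    max_epochs: int | None = None
    use_ga: bool = False
    ga: GAConfig = field(default_factory=GAConfig)
    max_lv: int = 6
    simulator: SimulatorConfig | None = None

    def resolved(self) -> dict:
        presets = {
            "quick": dict(trainers=("br",), runs=5, h_values=(1, 3, 5), max_epochs=80),
            "full": dict(trainers=("lm", "br"), runs=100,
                         h_values=tuple(range(1, 11)), max_epochs=300),
        }
        if self.profile not in presets:
            raise ValueError(f"unknown profile {self.profile!r}")
        r = presets[self.profile]
        return dict(
            trainers=self.trainers or r["trainers"],
            runs=self.runs or r["runs"],
            h_values=self.h_values or r["h_values"],
            max_epochs=self.max_epochs or r["max_epochs"],
        )


@dataclass
class PipelineResult:
    dataset: TabletDataset
    composition_models: dict[tuple[str, str], PLSCompositionModel]
    composition_metrics: pd.DataFrame
    test_inputs: dict[str, np.ndarray]
    sweeps: dict[tuple[str, str], SweepResult]
    ann_reports_true: dict[str, F2Report]
    ann_reports_measured: dict[str, F2Report]
    pls_reports_true: dict[str, F2Report]
    pls_reports_measured: dict[str, F2Report]
    comparison: pd.DataFrame
    manifest: dict
    run_dir: Path


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if isinstance(o, (np.ndarray,)):
            return o.tolist()
        if isinstance(o, Mapping):
            return dict(o)
        return str(o)
    blob = json.dumps(asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full cascade and write all artifacts to ``config.out_dir``."""
    r = config.resolved()
    run_dir = Path(config.out_dir)
    for sub in ("data", "preprocessed", "models", "reports"):
        (run_dir / sub).mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    master = np.random.SeedSequence(config.seed)
    stage_seeds = {name: int(s.generate_state(1)[0] % (2 ** 31))
                   for name, s in zip(("simulate", "ga", "sweep"), master.spawn(3))}

    # -- Stage 1: synthetic dataset -------------------------------------
    t0 = time.perf_counter()
    sim = config.simulator or SimulatorConfig(seed=stage_seeds["simulate"])
    ds = generate_dataset(sim)
    ids = ds.tablet_ids()
    train = ds.train_mask
    test = ds.test_mask
    dio.write_tablets_csv(run_dir / "data" / "tablets.csv", ds.tablets)
    dio.write_profiles_csv(run_dir / "data" / "profiles_measured.csv",
                           ds.times, ds.profiles_measured, ids)
    dio.write_profiles_csv(run_dir / "data" / "profiles_true.csv",
                           ds.times, ds.profiles_true, ids)
    for m in MODALITIES:
        dio.write_spectra_csv(run_dir / "data" / f"spectra_{m}.csv", ds.spectra[m])
    timings["generate"] = time.perf_counter() - t0

    # -- Stage 2: preprocessing (fit on training tablets, replay on test) -
    t0 = time.perf_counter()
    pre: dict[str, dict] = {}
    for m in MODALITIES:
        s = ds.spectra[m]
        s_train = s.subset(train)
        s_test = s.subset(test)
        fitted_train, state = apply_recipe(s_train, DEFAULT_RECIPES[m])
        fitted_test, _ = apply_recipe(s_test, DEFAULT_RECIPES[m], state)
        pre[m] = {"train": fitted_train, "test": fitted_test, "state": state}
        dio.write_spectra_csv(run_dir / "preprocessed" / f"{m}_train.csv", fitted_train)
        dio.write_spectra_csv(run_dir / "preprocessed" / f"{m}_test.csv", fitted_test)
    timings["preprocess"] = time.perf_counter() - t0

    # -- Stage 3: PLS composition calibration ---------------------------
    t0 = time.perf_counter()
    y_all = {
        "dr": np.array([tb.dr_true for tb in ds.tablets]),
        "hpmc": np.array([tb.hpmc_true for tb in ds.tablets]),
    }
    comp_models: dict[tuple[str, str], PLSCompositionModel] = {}
    rows = []
    for m in MODALITIES:
        for analyte in ("dr", "hpmc"):
            Xtr = pre[m]["train"].intensities
            ytr = y_all[analyte][train]
            cv = contiguous_block_cv(Xtr, ytr, config.max_lv, n_splits=30)
            n_lv = select_n_lv(cv[0])
            if config.use_ga:
                ga = ga_select(Xtr, ytr, config.ga, seed=stage_seeds["ga"])
                model = ga.model
                model.analyte = analyte
                model.wavenumbers = pre[m]["train"].wavenumbers
                cv_used = (np.array([ga.rmsecv]), np.array([np.nan]))
            else:
                model = pls_fit(Xtr, ytr, n_lv, analyte=analyte,
                                wavenumbers=pre[m]["train"].wavenumbers)
                cv_used = cv
            comp_models[(m, analyte)] = model
            mt = metrics(model,
                         Xtr if model.channel_mask is None else Xtr[:, model.channel_mask],
                         ytr,
                         pre[m]["test"].intensities if model.channel_mask is None
                         else pre[m]["test"].intensities[:, model.channel_mask],
                         y_all[analyte][test], cv_used)
            rows.append({"modality": m, "analyte": analyte, "n_lv": model.n_lv,
                         "r2c": mt.r2c, "r2cv": mt.r2cv, "r2p": mt.r2p,
                         "rmsec": mt.rmsec, "rmsecv": mt.rmsecv, "rmsep": mt.rmsep})
    comp_metrics = pd.DataFrame(rows)
    comp_metrics.to_csv(run_dir / "models" / "composition_metrics.csv", index=False)
    timings["calibrate"] = time.perf_counter() - t0

    # -- Stage 4: network inputs ----------------------------------------
    force = np.array([tb.force_measured for tb in ds.tablets])
    X_train_net = np.column_stack([
        np.array([tb.setting.dr_nominal for tb in ds.tablets])[train],
        np.array([tb.setting.hpmc_nominal for tb in ds.tablets])[train],
        force[train],
    ])
    Y_train_net = ds.profiles_measured[train]
    test_inputs: dict[str, np.ndarray] = {}
    for src, spec_map in SOURCES.items():
        dr_pred = predict_composition(comp_models[(spec_map["dr"], "dr")],
                                      pre[spec_map["dr"]]["test"])
        hp_pred = predict_composition(comp_models[(spec_map["hpmc"], "hpmc")],
                                      pre[spec_map["hpmc"]]["test"])
        test_inputs[src] = np.column_stack([dr_pred, hp_pred, force[test]])

    # -- Stage 5: ANN sweeps + PLS-direct baseline ----------------------
    t0 = time.perf_counter()
    Y_test_measured = ds.profiles_measured[test]
    Y_test_true = ds.profiles_true[test]
    test_ids = tuple(np.array(ids)[test])
    sweeps: dict[tuple[str, str], SweepResult] = {}
    ann_true: dict[str, F2Report] = {}
    ann_meas: dict[str, F2Report] = {}
    pls_true: dict[str, F2Report] = {}
    pls_meas: dict[str, F2Report] = {}
    sweep_ss = np.random.SeedSequence(stage_seeds["sweep"])
    sub_seeds = iter(sweep_ss.spawn(len(SOURCES) * len(r["trainers"]) + 1))
    best_trainer = r["trainers"][-1]  # BR is listed last and is the headline trainer
    pls_model = pls_direct_fit(X_train_net, Y_train_net, n_lv=3)
    for src in SOURCES:
        for trainer in r["trainers"]:
            seed_i = int(next(sub_seeds).generate_state(1)[0] % (2 ** 31))
            sweep = neuron_sweep(X_train_net, Y_train_net, test_inputs[src],
                                 Y_test_measured, trainer=trainer,
                                 runs=r["runs"], h_values=r["h_values"],
                                 seed=seed_i, max_epochs=r["max_epochs"])
            sweeps[(src, trainer)] = sweep
            pd.DataFrame({"H": sweep.h_values,
                          "mean_summed_rmsep": sweep.mean_summed_rmsep}
                         ).to_csv(run_dir / "models" / f"sweep_{src}_{trainer}.csv",
                                  index=False)
        best = sweeps[(src, best_trainer)].best_run.net
        pred_ann = best.forward(test_inputs[src])
        pred_pls = pls_model.predict(test_inputs[src])
        ann_true[src] = build_f2_report(f"ANN({src})", test_ids, Y_test_true, pred_ann)
        ann_meas[src] = build_f2_report(f"ANN({src})", test_ids, Y_test_measured, pred_ann)
        pls_true[src] = build_f2_report(f"PLS({src})", test_ids, Y_test_true, pred_pls)
        pls_meas[src] = build_f2_report(f"PLS({src})", test_ids, Y_test_measured, pred_pls)
        for tag, rep in (("ann", ann_meas[src]), ("pls", pls_meas[src]),
                         ("ann_vs_true", ann_true[src]), ("pls_vs_true", pls_true[src])):
            rep.table.to_csv(run_dir / "reports" / f"f2_{src}_{tag}.csv", index=False)
        dio.write_profiles_csv(run_dir / "reports" / f"predicted_{src}_ann.csv",
                               ds.times, pred_ann, test_ids)
    timings["profile_models"] = time.perf_counter() - t0

    # -- Stage 6: comparison table + factorial effects ------------------
    comparison = compare_models(ann_meas, pls_meas)
    comparison.to_csv(run_dir / "reports" / "comparison.csv")
    for t_resp in (15.0, 960.0):
        eff = effects_from_profiles(ds.tablets, ds.profiles_measured, ds.times, t_resp)
        eff.table.to_csv(run_dir / "reports" / f"effects_{int(t_resp)}min.csv",
                         index=False)

    manifest = {
        "config_hash": _config_hash(config),
        "master_seed": config.seed,
        "stage_seeds": stage_seeds,
        "profile": config.profile,
        "resolved": {k: list(v) if isinstance(v, tuple) else v for k, v in r.items()},
        "n_tablets": len(ds.tablets),
        "stage_timings_s": {k: round(v, 3) for k, v in timings.items()},
        "files": sorted(str(p.relative_to(run_dir))
                        for p in run_dir.rglob("*") if p.is_file()),
    }
    dio.write_json(run_dir / "manifest.json", manifest)

    return PipelineResult(
        dataset=ds, composition_models=comp_models,
        composition_metrics=comp_metrics, test_inputs=test_inputs,
        sweeps=sweeps, ann_reports_true=ann_true, ann_reports_measured=ann_meas,
        pls_reports_true=pls_true, pls_reports_measured=pls_meas,
        comparison=comparison, manifest=manifest, run_dir=run_dir)
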