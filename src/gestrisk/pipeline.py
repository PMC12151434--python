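"""End-to-end orchestration: simulate -> phenotype -> build -> train -> evaluate -> explain.

Each stage reads its inputs from, and writes its outputs to, plain files
under a run directory, so stages can be re-run or resumed independently
(and the CLI exposes them as subcommands).  Every stage seed is derived
from the master seed by a stable stage-name hash offset, so a fixed master
seed reproduces the whole run for the deterministic model families.

The truth sidecar written by the simulate stage is never read by any other
stage; it exists only so oracle checks outside the pipeline can grade the
run against the planted risk.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import evaluation as eval_mod
from . import features as feat_mod
from . import interpret as interp_mod
from . import modeling as model_mod
from . import phenotyping as pheno_mod
from . import synthetic as synth_mod

__all__ = [
    "DEFAULT_CONFIG",
    "ValidationError",
    "StageError",
    "stage_seed",
    "load_config",
    "validate_config",
    "run_pipeline",
    "simulate_stage",
    "phenotype_stage",
    "build_stage",
    "train_stage",
    "evaluate_stage",
    "explain_stage",
]

DEFAULT_CONFIG: dict = {
    "n_pregnancies": 2000,
    "master_seed": 0,
    "timepoints": [14, 20, 24, 28, 32, 34, 36, 38],
    "families": ["logistic", "gradient_boosting"],
    "resampler": "random_over",
    "test_fraction": 0.2,
    "cv_folds": 5,
    "search_iterations": 10,
    "cutoff": 0.5,
    "eod_bootstrap": 1000,
    "auc_bootstrap": 1000,
    "generator": {},
    "phenotype": {},
}


class ValidationError(ValueError):
    """Configuration rejected before any compute."""


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: master plus a stage-name CRC offset."""
    return int((int(master_seed) + zlib.crc32(stage.encode())) % (2**31))


def load_config(path=None, overrides: dict | None = None) -> dict:
    import yaml

    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg.update(user)
    if overrides:
        cfg.update({k: v for k, v in overrides.items() if v is not None})
    return cfg


def validate_config(cfg: dict) -> dict:
    unknown = set(cfg) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    cfg = {**DEFAULT_CONFIG, **cfg}
    for fam in cfg["families"]:
        if fam not in model_mod.FAMILIES:
            raise ValidationError(f"unknown model family {fam!r}")
    if cfg["resampler"] not in model_mod.RESAMPLERS:
        raise ValidationError(f"unknown resampler {cfg['resampler']!r}")
    if not cfg["timepoints"]:
        raise ValidationError("at least one timepoint required")
    if not 0 < cfg["test_fraction"] < 1:
        raise ValidationError("test_fraction must lie in (0, 1)")
    try:
        synth_mod.GeneratorConfig(**{**cfg["generator"],
                                     "n_pregnancies": cfg["n_pregnancies"],
                                     "seed": 0})
        pheno_mod.PhenotypeConfig(**cfg["phenotype"])
    except (TypeError, ValueError) as exc:
        raise ValidationError(str(exc)) from exc
    return cfg


def _digest(paths) -> str:
    h = hashlib.sha256()
    for p in sorted(Path(p) for p in paths):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# stages


def simulate_stage(cfg: dict, run_dir: Path) -> list[Path]:
    gen = synth_mod.GeneratorConfig(
        **{**cfg["generator"],
           "n_pregnancies": cfg["n_pregnancies"],
           "seed": stage_seed(cfg["master_seed"], "simulate")}
    )
    cohort = synth_mod.generate_cohort(gen)
    out = run_dir / "cohort"
    synth_mod.write_cohort(cohort, out, fmt="csv")
    return [out / "pregnancies.csv", out / "events.csv", out / "truth.csv"]


def phenotype_stage(cfg: dict, run_dir: Path) -> list[Path]:
    events = pd.read_csv(run_dir / "cohort" / "events.csv")
    pcfg = pheno_mod.PhenotypeConfig(**cfg["phenotype"])
    labels = pheno_mod.phenotype_cohort(events, pcfg)
    out = run_dir / "phenotype"
    out.mkdir(parents=True, exist_ok=True)
    labels.to_csv(out / "labels.csv", index=False)
    audit = {
        "n": int(len(labels)),
        "cases": int(labels["is_case"].sum()),
        "icd_only_positive": int(labels["icd_only"].sum()),
        "by_criterion": {
            str(int(k)): int(v)
            for k, v in labels["criterion_id"].value_counts().items()
        },
    }
    (out / "audit.json").write_text(json.dumps(audit, indent=2))
    return [out / "labels.csv", out / "audit.json"]


def _read_inputs(run_dir: Path):
    preg = pd.read_csv(run_dir / "cohort" / "pregnancies.csv")
    events = pd.read_csv(run_dir / "cohort" / "events.csv")
    labels = pd.read_csv(run_dir / "phenotype" / "labels.csv")
    return preg, events, labels


def build_stage(cfg: dict, run_dir: Path) -> list[Path]:
    preg, events, labels = _read_inputs(run_dir)
    pipeline = feat_mod.FeaturePipeline(visit_weeks=tuple(
        cfg["generator"].get("visit_weeks", synth_mod.GeneratorConfig().visit_weeks)
    ))
    dev_ids, test_ids = cohort_mod.split_by_patient(
        preg, cfg["test_fraction"], seed=stage_seed(cfg["master_seed"], "split")
    )
    out = run_dir / "datasets"
    out.mkdir(parents=True, exist_ok=True)
    written = []
    manifest = {"timepoints": list(cfg["timepoints"]),
                "dev_ids": list(map(str, dev_ids)),
                "test_ids": list(map(str, test_ids)),
                "rows": {}, "excluded": {}}
    for tp in cfg["timepoints"]:
        ds = cohort_mod.build_timepoint_dataset(preg, events, labels, tp, pipeline)
        frame = ds.X.copy()
        frame.insert(0, "__label__", ds.y.astype(int))
        for col in ds.groups.columns:
            frame.insert(1, f"__group_{col}__", ds.groups[col])
        path = out / f"dataset_{tp}.csv"
        frame.to_csv(path)
        written.append(path)
        manifest["rows"][str(tp)] = int(len(frame))
        manifest["excluded"][str(tp)] = int(len(preg) - len(frame))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    written.append(out / "manifest.json")
    return written


def _load_datasets(cfg: dict, run_dir: Path):
    out = run_dir / "datasets"
    manifest = json.loads((out / "manifest.json").read_text())
    pipeline = feat_mod.FeaturePipeline(visit_weeks=tuple(
        cfg["generator"].get("visit_weeks", synth_mod.GeneratorConfig().visit_weeks)
    ))
    datasets = {}
    for tp in manifest["timepoints"]:
        frame = pd.read_csv(out / f"dataset_{tp}.csv", index_col=0)
        group_cols = [c for c in frame.columns if c.startswith("__group_")]
        groups = frame[group_cols].rename(
            columns=lambda c: c[len("__group_"):-2])
        y = frame["__label__"].astype(bool)
        X = frame.drop(columns=["__label__", *group_cols])
        datasets[tp] = cohort_mod.CensoredDataset(
            timepoint_weeks=tp, X=X, y=y, groups=groups,
            censor_ga_minutes=int(tp * 7 * 1440),
            provenance=pipeline.provenance(tp), pipeline=pipeline,
        )
    dev = pd.Index(manifest["dev_ids"])
    test = pd.Index(manifest["test_ids"])
    return datasets, dev, test


def train_stage(cfg: dict, run_dir: Path) -> list[Path]:
    import joblib

    datasets, dev, _ = _load_datasets(cfg, run_dir)
    seed = stage_seed(cfg["master_seed"], "train")
    configs = [
        model_mod.ModelConfig(
            family=fam, resampler=cfg["resampler"], cv_folds=cfg["cv_folds"],
            search_iterations=cfg["search_iterations"], seed=seed,
        )
        for fam in cfg["families"]
    ]
    registry = model_mod.train_all(datasets, configs, dev_index=dev)
    out = run_dir / "models"
    out.mkdir(parents=True, exist_ok=True)
    index = []
    for (tp, fam), model in registry["models"].items():
        name = f"model_{tp}_{fam}.joblib"
        joblib.dump(model, out / name)
        index.append({
            "timepoint": tp, "family": fam, "file": name,
            "hyperparameters": {k: repr(v) for k, v in model.hyperparameters.items()},
            "mean_cv_auc": model.metadata.get("mean_cv_auc"),
        })
    joblib.dump(registry["selectors"], out / "selectors.joblib")
    (out / "index.json").write_text(json.dumps(index, indent=2))
    return [out / "index.json"]


def _load_registry(run_dir: Path):
    import joblib

    out = run_dir / "models"
    index = json.loads((out / "index.json").read_text())
    models = {}
    for entry in index:
        models[(entry["timepoint"], entry["family"])] = joblib.load(out / entry["file"])
    selectors = joblib.load(out / "selectors.joblib")
    return models, selectors


def evaluate_stage(cfg: dict, run_dir: Path) -> list[Path]:
    datasets, dev, test = _load_datasets(cfg, run_dir)
    models, selectors = _load_registry(run_dir)
    preg, _, labels = _read_inputs(run_dir)
    seed = stage_seed(cfg["master_seed"], "evaluate")

    report: dict = {"auc": [], "fairness": {}, "comparator": {}, "cutoffs": {}}
    for (tp, fam), model in sorted(models.items(), key=lambda kv: (kv[0][0], kv[0][1])):
        ds = datasets[tp]
        rows = ds.X.index.intersection(test)
        if ds.y.loc[rows].nunique() < 2:
            continue
        Xt = selectors[tp].transform(ds.X.loc[rows],
                                     for_linear=model.metadata.get("for_linear", False))
        scores = model_mod.predict_risk(model, Xt)
        auc, lo, hi = eval_mod.auc_ci(ds.y.loc[rows], scores,
                                      n_boot=cfg["auc_bootstrap"], seed=seed)
        report["auc"].append({"timepoint": tp, "family": fam,
                              "auc": auc, "ci_low": lo, "ci_high": hi})
        if fam == cfg["families"][-1]:
            flags = scores > cfg["cutoff"]
            report["cutoffs"][str(tp)] = eval_mod.cutoff_metrics(
                ds.y.loc[rows], scores).to_dict(orient="records")
            groups = ds.groups.loc[rows, "self_reported_race"].to_numpy()
            try:
                eod = eval_mod.equality_of_opportunity(
                    ds.y.loc[rows].to_numpy(), flags, groups,
                    n_boot=cfg["eod_bootstrap"], seed=seed)
                report["fairness"][str(tp)] = {
                    f"{a}|{b}": {"eod": v["eod"], "p_value": v["p_value"]}
                    for (a, b), v in eod.items()
                }
            except ValueError:
                report["fairness"][str(tp)] = None
            factors = eval_mod.acog_factors_from_pregnancies(
                preg[preg["pregnancy_id"].isin(rows)])
            acog = pd.Series(eval_mod.acog_flag(factors), index=factors.index).loc[rows]
            report["comparator"][str(tp)] = eval_mod.comparator_venn(
                ds.y.loc[rows], flags, acog.to_numpy())

    summary = eval_mod.cohort_summary(preg, labels)
    out = run_dir / "evaluation"
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    summary.to_csv(out / "cohort_summary.csv", index=False)
    pd.DataFrame(report["auc"]).to_csv(out / "auc_table.csv", index=False)
    return [out / "report.json", out / "cohort_summary.csv", out / "auc_table.csv"]


def explain_stage(cfg: dict, run_dir: Path) -> list[Path]:
    datasets, dev, _ = _load_datasets(cfg, run_dir)
    models, selectors = _load_registry(run_dir)
    seed = stage_seed(cfg["master_seed"], "explain")
    fam = ("gradient_boosting" if "gradient_boosting" in cfg["families"]
           else cfg["families"][0])
    out = run_dir / "explanations"
    out.mkdir(parents=True, exist_ok=True)
    per_tp = {}
    written = []
    for tp, ds in sorted(datasets.items()):
        model = models.get((tp, fam))
        if model is None:
            continue
        rows = ds.X.index.intersection(dev)
        Xd = selectors[tp].transform(ds.X.loc[rows],
                                     for_linear=model.metadata.get("for_linear", False))
        categories = {name: spec.category for name, spec in ds.provenance.items()}
        att = interp_mod.attribute(model, Xd, Xd, categories=categories, seed=seed)
        per_tp[tp] = att
        imp = interp_mod.global_importance(att)
        path = out / f"importance_{tp}.csv"
        imp.rename("mean_abs_attribution").to_csv(path)
        written.append(path)
        try:
            interp_mod.beeswarm(att, Xd, out / f"beeswarm_{tp}.png", seed=seed)
        except ImportError:
            pass
    shares = interp_mod.category_contributions(per_tp)
    shares.to_csv(out / "category_shares.csv")
    written.append(out / "category_shares.csv")
    return written


_STAGES = [
    ("simulate", simulate_stage),
    ("phenotype", phenotype_stage),
    ("build", build_stage),
    ("train", train_stage),
    ("evaluate", evaluate_stage),
    ("explain", explain_stage),
]


def run_pipeline(cfg: dict, run_dir, resume: bool = False) -> dict:
    """Execute all stages in order; returns the run report (also on disk).

    With ``resume=True`` a stage whose marker file already exists is
    skipped, so a failed run can pick up where it stopped.
    """
    cfg = validate_config({**DEFAULT_CONFIG, **cfg})
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    report = {"config": cfg, "stages": []}
    for name, func in _STAGES:
        marker = run_dir / f".done_{name}"
        if resume and marker.exists():
            report["stages"].append({"stage": name, "skipped": True})
            continue
        t0 = time.perf_counter()
        try:
            outputs = func(cfg, run_dir)
        except Exception as exc:  # prior outputs are preserved on disk
            raise StageError(name, exc) from exc
        report["stages"].append({
            "stage": name,
            "seed": stage_seed(cfg["master_seed"], name),
            "wall_seconds": round(time.perf_counter() - t0, 3),
            "outputs_digest": _digest(outputs),
            "outputs": [str(p) for p in outputs],
        })
        marker.write_text("ok")
    (run_dir / "run_report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
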