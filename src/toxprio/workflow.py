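"""End-to-end pipeline orchestration from a single run configuration.

A run walks through curate -> categorize -> train -> predict -> ad ->
evaluate, writing each stage's outputs plus a manifest (config hash,
input checksums, seeds, output checksums) so that a rerun with an
identical configuration reproduces the outputs bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .applicability_domain import ad_assess, ad_compare, build_leverage_model, compare_to_json
from .categorization import (KMeansCategorizer, assign_ghs, fit_kmeans_categorizer,
                             ghs_schema, kmeans_schema)
from .curation import (CurationParams, DescriptorTable, curate, load_descriptor_table,
                       load_metadata, pca_scores)
from .errors import ValidationError
from .evaluation import comparison_report
from .modeling import (HyperparameterGrid, fit_final, grid_search, load_model,
                       predict_category_direct, predict_lc50, save_model,
                       select_by_relative_importance, split_train_test,
                       two_step_categorize)

log = logging.getLogger("toxprio")

ALL_STAGES = ("curate", "categorize", "train", "predict", "ad", "evaluate")

_FLOAT_FORMAT = "%.12g"


@dataclass
class RunConfig:
    """Everything a pipeline run needs, with explicit seeds throughout."""

    outdir: str = "toxprio_run"
    seed: int = 0
    training_replicates: list[str] = field(default_factory=list)
    application: str | None = None
    metadata: str | None = None
    application_metadata: str | None = None
    id_column: str = "id"
    curation: dict = field(default_factory=dict)
    schema: str = "ghs"  # "ghs" or "kmeans"
    kmeans: dict = field(default_factory=dict)  # k, n_boot, train_frac, rounding
    train_frac: float = 0.9
    folds: int = 3
    importance: str = "oob_permutation"
    importance_threshold: float = 0.01
    regression_grid: dict | None = None
    classification_grid: dict | None = None
    ad_threshold: float | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError([f"unknown config key: {k}" for k in sorted(unknown)])
        return cls(**data)

    def to_canonical_yaml(self) -> str:
        payload = {k: getattr(self, k) for k in sorted(self.__dataclass_fields__)}
        return yaml.safe_dump(payload, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_canonical_yaml().encode()).hexdigest()[:16]

    def validate(self, stages: Sequence[str]) -> list[str]:
        problems = []
        for s in stages:
            if s not in ALL_STAGES:
                problems.append(f"unknown stage: {s}")
        if "curate" in stages:
            if len(self.training_replicates) != 3:
                problems.append("curate needs exactly 3 training_replicates paths")
            for p in self.training_replicates:
                if not Path(p).exists():
                    problems.append(f"missing training replicate: {p}")
            if self.application is None:
                problems.append("curate needs an application table path")
            elif not Path(self.application).exists():
                problems.append(f"missing application table: {self.application}")
        if {"categorize", "train", "evaluate"} & set(stages):
            if self.metadata is None:
                problems.append("categorize/train/evaluate need a metadata path")
            elif not Path(self.metadata).exists():
                problems.append(f"missing metadata table: {self.metadata}")
        if {"predict", "ad"} & set(stages) and "curate" not in stages:
            if self.application is None:
                problems.append("predict/ad need an application table (directly or via curate)")
        if self.schema not in {"ghs", "kmeans"}:
            problems.append(f"schema must be 'ghs' or 'kmeans', got {self.schema!r}")
        return problems


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _grid(spec: dict | None) -> HyperparameterGrid | None:
    if spec is None:
        return None
    return HyperparameterGrid(n_trees=tuple(spec["n_trees"]),
                              min_leaf=tuple(spec["min_leaf"]))


def _write_df(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, float_format=_FLOAT_FORMAT)


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


class _RunState:
    """In-memory hand-off between stages, with disk fallback."""

    def __init__(self, config: RunConfig, outdir: Path):
        self.config = config
        self.outdir = outdir
        self.curated_train: DescriptorTable | None = None
        self.curated_app: DescriptorTable | None = None
        self.records = None
        self.labels: pd.DataFrame | None = None
        self.categorizer: KMeansCategorizer | None = None
        self.models: dict = {}

    # --- lazy loaders -----------------------------------------------------
    def get_records(self):
        if self.records is None:
            self.records = load_metadata(self.config.metadata)
        return self.records

    def get_curated(self, which: str) -> DescriptorTable:
        attr = "curated_train" if which == "training" else "curated_app"
        if getattr(self, attr) is None:
            path = self.outdir / "curate" / f"curated_{which}.csv"
            if not path.exists():
                raise FileNotFoundError(f"stage output not found: {path}; run 'curate' first")
            setattr(self, attr, load_descriptor_table(path, id_column=self.config.id_column))
        return getattr(self, attr)

    def get_labels(self) -> pd.DataFrame:
        if self.labels is None:
            path = self.outdir / "categorize" / "labels.csv"
            if not path.exists():
                raise FileNotFoundError(f"stage output not found: {path}; run 'categorize' first")
            self.labels = pd.read_csv(path, index_col=0)
        return self.labels

    def get_categorizer(self) -> KMeansCategorizer:
        if self.categorizer is None:
            path = self.outdir / "categorize" / "kmeans_categorizer.json"
            if not path.exists():
                raise FileNotFoundError(f"stage output not found: {path}; run 'categorize' first")
            self.categorizer = KMeansCategorizer.from_json(path)
        return self.categorizer

    def get_model(self, task: str):
        if task not in self.models:
            path = self.outdir / "train" / f"{task}_model.joblib"
            if not path.exists():
                raise FileNotFoundError(f"stage output not found: {path}; run 'train' first")
            self.models[task] = load_model(path)
        return self.models[task]

    def get_schema(self):
        if self.config.schema == "ghs":
            return ghs_schema()
        return kmeans_schema(self.get_categorizer())


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def _stage_curate(state: _RunState, stage_dir: Path) -> None:
    cfg = state.config
    reps = [load_descriptor_table(p, id_column=cfg.id_column, replicate_id=i + 1)
            for i, p in enumerate(cfg.training_replicates)]
    app = load_descriptor_table(cfg.application, id_column=cfg.id_column)
    params = CurationParams(**cfg.curation)
    train, appc, report = curate(reps, app, params)
    state.curated_train, state.curated_app = train, appc
    _write_df(train.data, stage_dir / "curated_training.csv")
    _write_df(appc.data, stage_dir / "curated_application.csv")
    report.to_json(stage_dir / "curation_report.json")
    scores, evr = pca_scores(train.data.to_numpy(), n_components=min(2, *train.data.shape))
    pcs = pd.DataFrame(scores, index=train.data.index,
                       columns=[f"PC{i + 1}" for i in range(scores.shape[1])])
    _write_df(pcs, stage_dir / "pca_scores.csv")
    _write_json({"explained_variance_ratio": [float(v) for v in evr]},
                stage_dir / "pca_summary.json")
    log.info("curation kept %d of %d descriptors", len(report.kept), report.n_original())


def _stage_categorize(state: _RunState, stage_dir: Path) -> None:
    cfg = state.config
    records = [r for r in state.get_records() if r.lc50 is not None
               and r.monoisotopic_mass is not None]
    if not records:
        raise ValueError("metadata has no chemicals with both LC50 and mass")
    pts = np.array([[np.log10(r.lc50), r.monoisotopic_mass] for r in records])
    km = fit_kmeans_categorizer(pts, seed=cfg.seed, **cfg.kmeans)
    state.categorizer = km
    km.to_json(stage_dir / "kmeans_categorizer.json")
    from .categorization import assign_kmeans
    labels = pd.DataFrame({
        "log_lc50": pts[:, 0], "mass": pts[:, 1],
        "kmeans_label": [assign_kmeans(km, p) for p in pts],
    }, index=pd.Index([r.id for r in records], name="id"))
    labels["ghs_label"] = [assign_ghs(r.lc50) for r in records]
    state.labels = labels
    _write_df(labels, stage_dir / "labels.csv")
    log.info("k-means categorizer fitted (holdout agreement %.3f)",
             km.holdout_agreement if km.holdout_agreement is not None else float("nan"))


def _stage_train(state: _RunState, stage_dir: Path) -> None:
    cfg = state.config
    train_tbl = state.get_curated("training")
    labels = state.get_labels().reindex(train_tbl.ids).dropna(subset=["log_lc50"])
    X = train_tbl.data.loc[labels.index]
    y_reg = labels["log_lc50"].to_numpy()
    label_col = "ghs_label" if cfg.schema == "ghs" else "kmeans_label"
    y_clf = labels[label_col].to_numpy()

    tr_idx, te_idx = split_train_test(len(X), frac=cfg.train_frac, seed=cfg.seed)
    metrics = {"n_train": int(len(tr_idx)), "n_test": int(len(te_idx)),
               "schema": cfg.schema}
    for task, y in (("regression", y_reg), ("classification", y_clf)):
        grid = _grid(cfg.regression_grid if task == "regression" else cfg.classification_grid)
        gs = grid_search(X.iloc[tr_idx], y[tr_idx], task=task, grid=grid,
                        folds=cfg.folds, seed=cfg.seed, importance=cfg.importance)
        selected = select_by_relative_importance(gs.importances, cfg.importance_threshold)
        model = fit_final(X, y, selected, gs.best_n_trees, gs.best_min_leaf,
                          task=task, seed=cfg.seed, cv_scores=gs.best_cv_scores)
        model.importances = {k: float(v) for k, v in gs.importances.items()}
        state.models[task] = model
        save_model(model, stage_dir / f"{task}_model.joblib")
        _write_df(gs.cv_table, stage_dir / f"{task}_cv_table.csv")
        test_score = (float(np.mean(predict_category_direct(model, X.iloc[te_idx]) == y[te_idx]))
                      if task == "classification"
                      else None)
        if task == "regression":
            from .evaluation import r_squared
            test_score = float(r_squared(y[te_idx], predict_lc50(model, X.iloc[te_idx])))
        metrics[task] = {
            "best_n_trees": gs.best_n_trees, "best_min_leaf": gs.best_min_leaf,
            "cv_scores": gs.best_cv_scores,
            "cv_median": float(np.median(gs.best_cv_scores)),
            "cv_mean": float(np.mean(gs.best_cv_scores)),
            "n_selected_variables": len(selected),
            "train_score": model.train_score, "oob_score": model.oob_score,
            "test_score": test_score,
        }
        log.info("%s: trees=%d leaf=%d selected=%d cv_mean=%.3f", task,
                 gs.best_n_trees, gs.best_min_leaf, len(selected),
                 float(np.mean(gs.best_cv_scores)))
    _write_json(metrics, stage_dir / "training_metrics.json")


def _app_masses(state: _RunState, ids: Sequence[str]) -> np.ndarray | None:
    path = state.config.application_metadata
    if path is None:
        return None
    recs = {r.id: r.monoisotopic_mass for r in load_metadata(path)}
    return np.asarray([recs.get(i, np.nan) for i in ids], dtype=float)


def _stage_predict(state: _RunState, stage_dir: Path) -> None:
    app = state.get_curated("application")
    reg = state.get_model("regression")
    clf = state.get_model("classification")
    schema = state.get_schema()
    preds = pd.DataFrame(index=pd.Index(app.ids, name="id"))
    preds["pred_log_lc50"] = predict_lc50(reg, app.data)
    masses = _app_masses(state, app.ids) if schema.needs_mass else None
    preds["two_step_label"] = two_step_categorize(reg, schema, app.data, masses)
    preds["direct_label"] = predict_category_direct(clf, app.data)
    _write_df(preds, stage_dir / "predictions.csv")
    log.info("predicted %d application chemicals", len(preds))


def _stage_ad(state: _RunState, stage_dir: Path) -> None:
    cfg = state.config
    train_tbl = state.get_curated("training")
    app = state.get_curated("application")
    subsets = {"full": train_tbl.descriptor_names}
    for task in ("regression", "classification"):
        try:
            subsets[task] = state.get_model(task).selected_variables
        except FileNotFoundError:
            log.warning("no %s model found; skipping its AD subset", task)
    reports = []
    merged = pd.DataFrame(index=pd.Index(app.ids, name="id"))
    for name, cols in subsets.items():
        model = build_leverage_model(train_tbl.data[cols], subset_name=name,
                                     threshold=cfg.ad_threshold)
        rep = ad_assess(model, app.data[cols])
        reports.append(rep)
        merged[f"leverage_{name}"] = rep.table["leverage"]
        merged[f"in_domain_{name}"] = rep.table["in_domain"]
    _write_df(merged, stage_dir / "ad_report.csv")
    if len(reports) >= 2:
        compare_to_json(ad_compare(reports), stage_dir / "ad_summary.json")
    else:
        _write_json(reports[0].summary(), stage_dir / "ad_summary.json")
    for rep in reports:
        log.info("AD subset %s: %d in / %d out", rep.subset_name, rep.n_in, rep.n_out)


def _stage_evaluate(state: _RunState, stage_dir: Path) -> None:
    cfg = state.config
    train_tbl = state.get_curated("training")
    labels = state.get_labels().reindex(train_tbl.ids).dropna(subset=["log_lc50"])
    X = train_tbl.data.loc[labels.index]
    label_col = "ghs_label" if cfg.schema == "ghs" else "kmeans_label"
    true = labels[label_col].to_numpy()
    schema = state.get_schema()
    reg, clf = state.get_model("regression"), state.get_model("classification")
    masses = labels["mass"].to_numpy() if schema.needs_mass else None
    two_step = two_step_categorize(reg, schema, X, masses)
    direct = predict_category_direct(clf, X)
    rep_direct = comparison_report(true, direct, schema, {"two_step": two_step})
    rep_two = comparison_report(true, two_step, schema, {"direct": direct})
    ratio = (rep_two.misclassified / rep_direct.misclassified
             if rep_direct.misclassified else float("inf"))
    _write_json({
        "schema": cfg.schema,
        "direct_classification": rep_direct.to_dict(),
        "two_step_regression": rep_two.to_dict(),
        "misclassification_ratio_two_step_over_direct": ratio,
    }, stage_dir / "evaluation.json")
    log.info("misclassified: direct=%d two-step=%d (ratio %.2f)",
             rep_direct.misclassified, rep_two.misclassified, ratio)


_STAGE_FUNCS = {
    "curate": _stage_curate,
    "categorize": _stage_categorize,
    "train": _stage_train,
    "predict": _stage_predict,
    "ad": _stage_ad,
    "evaluate": _stage_evaluate,
}


def run(config: RunConfig, stages: Sequence[str] | None = None) -> dict:
    """Execute the requested stages and return the run manifest."""
    stages = list(stages) if stages is not None else list(ALL_STAGES)
    problems = config.validate(stages)
    if problems:
        raise ValidationError(problems)
    stages = sorted(set(stages), key=ALL_STAGES.index)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = {}
    for p in [*config.training_replicates, config.application, config.metadata,
              config.application_metadata]:
        if p and Path(p).exists():
            inputs[str(p)] = _sha256(Path(p))

    manifest = {
        "software": {"package": "toxprio", "version": __version__},
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "inputs": inputs,
        "stages": {},
    }
    (outdir / "config.yaml").write_text(config.to_canonical_yaml())
    state = _RunState(config, outdir)
    for stage in stages:
        stage_dir = outdir / stage
        stage_dir.mkdir(parents=True, exist_ok=True)
        log.info("=== stage %s ===", stage)
        try:
            _STAGE_FUNCS[stage](state, stage_dir)
        except Exception as exc:
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            _write_json(manifest, outdir / "manifest.json")
            raise
        manifest["stages"][stage] = {
            "status": "ok",
            "outputs": {f.name: _sha256(f) for f in sorted(stage_dir.iterdir())
                        if f.is_file()},
        }
    _write_json(manifest, outdir / "manifest.json")
    return manifest
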