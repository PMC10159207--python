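"""End-to-end interpretable-classification pipeline.

Stages: split -> train-only volcano selection -> log + autoscale (fit on
train) -> hyperparameter search under stratified cross-validation ->
final fit -> held-out evaluation (ROC AUC, percent-of-total confusion
rates) -> explanation (Tree SHAP for tree models, VIP for PLS-DA) ->
plot-data artifacts + a machine-readable manifest. Everything after the
split sees only the training partition until the evaluation step, and
the whole run is deterministic given the config.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import analytics, plsda, preprocess, shapley, synth, trees
from .feature_table import FeatureTable, read_feature_table, train_test_split

logger = logging.getLogger("metashap")

__all__ = ["PipelineConfig", "cv_search", "roc_auc", "run_pipeline", "recovery_replicate"]


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run."""

    input_path: str | None = None
    preset: str | None = None
    label_column: str = "label"
    positive_class: str | None = None
    test_fraction: float = 1.0 / 6.0
    seed: int = 0
    fc_threshold: float = 0.5
    p_threshold: float = 0.05
    model: str = "reference_forest"  # plsda | reference_forest | ingested_ensemble
    model_path: str | None = None  # for ingested_ensemble
    fixed_params: dict = field(default_factory=dict)
    grid: dict = field(default_factory=dict)
    cv_folds: int = 10
    top_k: int = 9
    outdir: str = "metashap_run"

    def __post_init__(self):
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.fc_threshold <= 0 or self.p_threshold <= 0:
            raise ValueError("selection thresholds must be positive")
        if self.model not in ("plsda", "reference_forest", "ingested_ensemble"):
            raise ValueError(f"unknown model {self.model!r}")
        if (self.input_path is None) == (self.preset is None):
            raise ValueError("exactly one of input_path or preset must be given")
        if not self.grid:
            self.grid = default_grid(self.model)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def default_grid(model: str) -> dict:
    """Small documented default grids over the standard knobs."""
    if model == "plsda":
        return {"n_components": [1, 2, 3, 4, 5]}
    if model == "reference_forest":
        return {"n_estimators": [100], "max_depth": [3, 5, None]}
    return {"_": [None]}  # ingested ensembles are not tuned


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) ROC AUC with midrank tie handling."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels, dtype=int).ravel()
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _stratified_folds(y: np.ndarray, folds: int, seed: int) -> np.ndarray:
    """Deterministic stratified fold assignment (round-robin per class)."""
    rng = np.random.default_rng(seed)
    assign = np.empty(y.size, dtype=int)
    for c in np.unique(y):
        members = np.flatnonzero(y == c)
        members = members[rng.permutation(members.size)]
        assign[members] = np.arange(members.size) % folds
    return assign


def _fit_and_score(model_spec: str, X, y, params: dict, seed: int):
    """Fit one model and return a callable scoring new samples continuously."""
    if model_spec == "plsda":
        m = plsda.fit_plsda(X, y, **params)
        return m, m.predict
    if model_spec == "reference_forest":
        m = trees.fit_reference_forest(X, y, seed=seed, **params)
        return m, m.predict
    raise ValueError(f"cv_search cannot fit model {model_spec!r}")


_COMPLEXITY_KEYS = ("n_components", "n_estimators", "max_depth")


def _complexity(params: dict) -> tuple:
    # None (unbounded depth) counts as larger than any numeric value
    return tuple(
        float("inf") if params.get(k) is None else float(params.get(k, 0))
        for k in _COMPLEXITY_KEYS
        if k in params
    )


def cv_search(
    X: np.ndarray,
    y: np.ndarray,
    model_spec: str,
    grid: dict,
    folds: int,
    seed: int,
) -> dict:
    """Exhaustive grid search scored by mean ROC AUC over stratified folds.

    A single-parameter grid is a linear search; multi-parameter grids are
    the full Cartesian product in the given key order. Ties resolve to
    the smaller model (fewer components / trees / shallower), then to
    grid order. Raises if a fold would contain a single class.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int).ravel()
    folds = int(folds)
    if min((y == 0).sum(), (y == 1).sum()) < folds:
        raise ValueError(
            f"{folds}-fold CV is infeasible: the smaller class has "
            f"{min((y == 0).sum(), (y == 1).sum())} samples — stratify less or reduce folds"
        )
    assign = _stratified_folds(y, folds, seed)
    keys = list(grid)
    points = [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]
    results = []
    for gi, params in enumerate(points):
        fold_scores = []
        for f in range(folds):
            tr, te = assign != f, assign == f
            if np.unique(y[te]).size < 2 or np.unique(y[tr]).size < 2:
                raise ValueError(
                    f"fold {f} contains a single class; use stratification or fewer folds"
                )
            try:
                _, scorer = _fit_and_score(model_spec, X[tr], y[tr], params, seed=seed + 1 + f)
                fold_scores.append(roc_auc(scorer(X[te]), y[te]))
            except ValueError as exc:  # e.g. n_components above fold rank
                logger.warning("grid point %s failed on fold %d: %s", params, f, exc)
                fold_scores.append(0.0)
        results.append(
            {
                "params": params,
                "mean_auc": float(np.mean(fold_scores)),
                "sd_auc": float(np.std(fold_scores, ddof=1)),
                "grid_index": gi,
            }
        )
    best = min(
        results,
        key=lambda r: (-round(r["mean_auc"], 12), _complexity(r["params"]), r["grid_index"]),
    )
    return {"best_params": best["params"], "best_mean_auc": best["mean_auc"], "results": results}


def _load_input(config: PipelineConfig):
    if config.preset is not None:
        if config.preset not in synth.PRESETS:
            raise ValueError(f"unknown preset {config.preset!r}")
        table, truth = synth.generate(synth.PRESETS[config.preset](seed=config.seed))
        return table, truth
    table = read_feature_table(
        config.input_path,
        label_column=config.label_column,
        positive_class=config.positive_class,
    )
    return table, None


def run_pipeline(config: PipelineConfig, write: bool = True) -> dict:
    """Execute the full workflow; returns (and optionally writes) the report bundle."""
    outdir = Path(config.outdir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
    logger.info("stage=load")
    table, truth = _load_input(config)

    logger.info("stage=split")
    train, test = train_test_split(table, config.test_fraction, seed=config.seed)

    logger.info("stage=select")
    vstats = preprocess.volcano_stats(train)
    mask = preprocess.select_features(vstats, config.fc_threshold, config.p_threshold)
    if not mask.any():
        raise ValueError("volcano selection retained no features; relax the thresholds")
    train_sel, test_sel = train.subset_features(mask), test.subset_features(mask)
    selection = vstats.to_frame()
    selection["kept"] = mask

    logger.info("stage=transform")
    train_t, test_t, scaler = preprocess.log_autoscale(train_sel, test_sel, pseudocount=True)
    feature_ids = list(train_t.feature_ids)
    Xtr, ytr = train_t.matrix, train_t.y
    Xte, yte = test_t.matrix, test_t.y

    logger.info("stage=tune")
    if config.model == "ingested_ensemble":
        with open(config.model_path) as fh:
            model = trees.ingest_ensemble(fh.read())
        search = None
        params = {}
    else:
        grid = config.grid
        search = cv_search(Xtr, ytr, config.model, grid, config.cv_folds, seed=config.seed)
        params = {**config.fixed_params, **search["best_params"]}
        logger.info("stage=fit params=%s", params)
        model, _ = _fit_and_score(config.model, Xtr, ytr, params, seed=config.seed)

    logger.info("stage=evaluate")
    if config.model == "plsda":
        scores, y_pred = plsda.predict_classify(model, Xte)
    else:
        scores = model.predict(Xte)
        y_pred = (scores >= 0.5).astype(int)
    auc = roc_auc(scores, yte)

    logger.info("stage=explain")
    report: dict = {
        "config": config.to_dict(),
        "n_train": train.n_samples,
        "n_test": test.n_samples,
        "selected_features": feature_ids,
        "best_params": params,
        "cv": None if search is None else {k: search[k] for k in ("best_params", "best_mean_auc")},
        "test_auc": auc,
    }
    S = None
    if config.model == "plsda":
        vip = analytics.ImportanceVector(
            scores=plsda.vip_scores(model), method="vip", feature_ids=feature_ids
        )
        report["vip"] = vip.to_frame()
    else:
        S = shapley.explain_matrix(model, Xte, feature_ids=feature_ids,
                                   sample_ids=list(test_t.sample_ids))
        imp = analytics.global_importance(S)
        gini = analytics.ImportanceVector(
            scores=trees.gini_importance(model, Xtr, ytr), method="gini",
            feature_ids=feature_ids,
        )
        err = analytics.error_analysis(yte, y_pred, S, test_t, top_k=config.top_k)
        report.update(
            {
                "shap": S,
                "importance": imp.to_frame(),
                "gini": gini.to_frame(),
                "beeswarm": analytics.beeswarm_data(S, test_t),
                "embedding": analytics.shap_embedding(S),
                "clustering": analytics.supervised_clustering(S, S.model_outputs),
                "dependence": analytics.dependence_data(
                    S, test_t, imp.feature_ids[imp.ranking()[0]]
                ),
                "error_analysis": err,
            }
        )
    if truth is not None:
        report["truth_informative"] = truth.informative

    manifest = {
        "package": "metashap",
        "config": config.to_dict(),
        "selected_features": feature_ids,
        "best_params": {k: v for k, v in params.items()},
        "test_auc": auc,
        "confusion_rates_pct": None
        if S is None
        else report["error_analysis"]["rates_pct"],
    }
    report["manifest"] = manifest
    if write:
        _write_report(report, outdir, config, scaler, model, yte, y_pred, scores)
    return report


def _write_report(report, outdir: Path, config, scaler, model, yte, y_pred, scores):
    selection_cols = report["selected_features"]
    pd.DataFrame(
        {"feature": selection_cols}
    ).to_csv(outdir / "selected_features.tsv", sep="\t", index=False)
    (outdir / "manifest.json").write_text(json.dumps(report["manifest"], indent=1))
    (outdir / "scaler.json").write_text(json.dumps(scaler.to_dict()))
    pd.DataFrame(
        {"y_true": yte, "y_pred": y_pred, "score": scores}
    ).to_csv(outdir / "predictions.tsv", sep="\t", index=False)
    if config.model == "plsda":
        (outdir / "model.json").write_text(model.to_json())
        report["vip"].to_csv(outdir / "vip.tsv", sep="\t", index=False)
        return
    (outdir / "model.json").write_text(model.to_json())
    S = report["shap"]
    S.to_tsv(outdir / "shap_values.tsv")
    (outdir / "shap_meta.json").write_text(json.dumps(S.sidecar()))
    report["importance"].to_csv(outdir / "importance.tsv", sep="\t", index=False)
    report["gini"].to_csv(outdir / "gini.tsv", sep="\t", index=False)
    report["beeswarm"].to_csv(outdir / "beeswarm.tsv", sep="\t", index=False)
    emb = report["embedding"]
    pd.DataFrame(emb, columns=["pc1", "pc2"]).to_csv(outdir / "embedding.tsv", sep="\t", index=False)
    clust = report["clustering"]
    (outdir / "clustering.json").write_text(
        json.dumps(
            {
                "leaf_order": clust["leaf_order"].tolist(),
                "merge_heights": clust["merge_heights"].tolist(),
                "ordered_outputs": clust["ordered_outputs"].tolist(),
                "linkage": clust["linkage"].tolist(),
                "metric": clust["metric"],
                "method": clust["method"],
            }
        )
    )
    report["dependence"].to_csv(outdir / "dependence.tsv", sep="\t", index=False)
    err = report["error_analysis"]
    (outdir / "confusion.json").write_text(
        json.dumps(
            {
                "n": err["n"],
                "counts": err["counts"],
                "rates_pct": err["rates_pct"],
                "groups": {
                    g: [
                        {
                            "index": m["index"],
                            "decomposition": {
                                "entries": m["decomposition"].to_records(),
                                "remainder": m["decomposition"].remainder,
                                "base_value": m["decomposition"].base_value,
                                "model_output": m["decomposition"].model_output,
                            },
                        }
                        for m in members
                    ]
                    for g, members in err["groups"].items()
                },
            }
        )
    )


def recovery_replicate(seed: int, n_estimators: int = 100, n_components: int = 2) -> dict:
    """One marker-recovery replicate on the urine-sex-like preset.

    Generates the preset with the given seed, splits 5/6 - 1/6, runs the
    train-only volcano selection and log+autoscale, fits the reference
    forest and a PLS-DA model, explains the held-out set with Tree SHAP,
    and reports the planted marker's rank under mean(|SHAP|) and VIP
    (1 = top) plus the held-out forest AUC.
    """
    cfg = synth.urine_sex_preset(seed=seed)
    table, truth = synth.generate(cfg)
    marker = table.feature_ids[truth.informative[0][0]]
    train, test = train_test_split(table, 1.0 / 6.0, seed=seed)
    vstats = preprocess.volcano_stats(train)
    mask = preprocess.select_features(vstats)
    train_t, test_t, _ = preprocess.log_autoscale(
        train.subset_features(mask), test.subset_features(mask), pseudocount=True
    )
    ids = list(train_t.feature_ids)
    forest = trees.fit_reference_forest(
        train_t.matrix, train_t.y, n_estimators=n_estimators, seed=seed
    )
    S = shapley.explain_matrix(forest, test_t.matrix, feature_ids=ids)
    imp = analytics.global_importance(S)
    auc = roc_auc(forest.predict(test_t.matrix), test_t.y)

    pls = plsda.fit_plsda(
        train_t.matrix, train_t.y, n_components=min(n_components, len(ids)), feature_ids=ids
    )
    vip = analytics.ImportanceVector(
        scores=plsda.vip_scores(pls), method="vip", feature_ids=ids
    )

    def rank_of(iv):
        if marker not in iv.feature_ids:
            return np.inf
        order = iv.ranking()
        return int(np.flatnonzero(np.asarray(iv.feature_ids)[order] == marker)[0]) + 1

    return {
        "marker": marker,
        "n_selected": len(ids),
        "shap_rank": rank_of(imp),
        "vip_rank": rank_of(vip),
        "test_auc": auc,
    }
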