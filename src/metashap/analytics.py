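"""SHAP-derived summaries, comparisons, local decompositions, and error analysis.

Everything here consumes a :class:`~metashap.shapley.ShapMatrix` (and,
where feature abundances matter, the matching feature table) and emits
plain plot-data structures: global importance bars, beeswarm records,
PCA embeddings of explanation space, supervised hierarchical clustering
of explanation vectors, dependence pairs, waterfall/force decompositions,
and percent-of-total confusion rates for error analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .feature_table import FeatureTable
from .shapley import Attribution, ShapMatrix

__all__ = [
    "ImportanceVector",
    "LocalDecomposition",
    "global_importance",
    "beeswarm_data",
    "shap_embedding",
    "supervised_clustering",
    "dependence_data",
    "local_decomposition",
    "importance_correlation",
    "error_analysis",
]


@dataclass
class ImportanceVector:
    """Non-negative per-feature importance with a method tag."""

    scores: np.ndarray
    method: str  # vip | mean_abs_shap | gini
    feature_ids: list

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if not np.isfinite(self.scores).all():
            raise ValueError("non-finite importance score")
        if (self.scores < 0).any():
            raise ValueError("importance scores must be non-negative")
        if len(self.feature_ids) != self.scores.shape[0]:
            raise ValueError("feature id / score length mismatch")

    def ranking(self) -> np.ndarray:
        """Feature indices sorted by descending score, ties by index."""
        order = np.lexsort((np.arange(self.scores.size), -self.scores))
        return order

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature": self.feature_ids, "score": self.scores, "method": self.method}
        )


@dataclass
class LocalDecomposition:
    """Top-k |phi| terms of one attribution plus an aggregated remainder.

    Drives both the waterfall and the force rendering; conservation
    (base + listed + remainder = model output) always holds.
    """

    entries: list  # (feature_id, feature_value, phi) sorted by |phi| desc
    remainder: float
    base_value: float
    model_output: float

    def check(self, tol: float = 1e-8) -> None:
        tot = self.base_value + sum(e[2] for e in self.entries) + self.remainder
        if abs(tot - self.model_output) > tol:
            raise AssertionError(f"decomposition not conservative: {tot} vs {self.model_output}")

    def to_records(self) -> list:
        recs = [
            {"feature": f, "value": None if v is None else float(v), "phi": float(p)}
            for f, v, p in self.entries
        ]
        return recs


def global_importance(S: ShapMatrix) -> ImportanceVector:
    """mean(|phi|) per feature — the bar-plot global importance.

    The ranking is identical to ordering by the summed absolute Shapley
    value over samples (the two differ only by the 1/n factor).
    """
    if S.n_samples == 0:
        raise ValueError("empty SHAP matrix")
    scores = np.abs(S.values).mean(axis=0)
    ids = S.feature_ids or [f"f{j}" for j in range(S.n_features)]
    return ImportanceVector(scores=scores, method="mean_abs_shap", feature_ids=list(ids))


def beeswarm_data(S: ShapMatrix, table: FeatureTable, max_display: int = 20) -> pd.DataFrame:
    """Beeswarm plot records: one row per (displayed feature, sample).

    Features are ordered by global importance descending; each record
    carries the Shapley value and a colour scalar (the feature's
    abundance min-max scaled to [0, 1]; constant features map to 0.5).
    """
    if table.n_samples != S.n_samples or table.n_features != S.n_features:
        raise ValueError("SHAP matrix and feature table dimensions disagree")
    imp = global_importance(S)
    order = imp.ranking()[: min(max_display, S.n_features)]
    recs = []
    for rank, j in enumerate(order):
        col = table.matrix[:, j]
        lo, hi = col.min(), col.max()
        color = np.full(col.shape, 0.5) if hi == lo else (col - lo) / (hi - lo)
        for i in range(S.n_samples):
            recs.append(
                {
                    "feature": imp.feature_ids[j],
                    "rank": rank,
                    "sample": (table.sample_ids[i] if table.sample_ids else i),
                    "shap_value": S.values[i, j],
                    "color": color[i],
                }
            )
    return pd.DataFrame.from_records(recs)


def shap_embedding(S: ShapMatrix) -> np.ndarray:
    """2-D principal-component projection of the explanation vectors.

    Centered SHAP matrix, top-2 right singular directions; the sign of
    each direction is fixed by making its largest-magnitude loading
    positive, so re-runs are identical.
    """
    if S.n_samples < 3:
        raise ValueError("embedding needs at least 3 samples")
    centered = S.values - S.values.mean(axis=0)
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    coords = np.zeros((S.n_samples, 2))
    for c in range(min(2, s.size)):
        v = Vt[c]
        sign = 1.0 if v[np.argmax(np.abs(v))] >= 0 else -1.0
        coords[:, c] = sign * U[:, c] * s[c]
    return coords


def supervised_clustering(S: ShapMatrix, outputs: np.ndarray | None = None) -> dict:
    """Agglomerative clustering of samples in explanation space.

    Euclidean distance, average linkage. Returns the dendrogram leaf
    ordering, the merge table (SciPy linkage matrix) with merge heights,
    and the model-output trace aligned to the leaf ordering.
    """
    if S.n_samples < 2:
        raise ValueError("clustering needs at least 2 samples")
    if outputs is None:
        outputs = S.model_outputs
    outputs = np.asarray(outputs, dtype=float)
    Z = hierarchy.linkage(pdist(S.values, metric="euclidean"), method="average")
    leaves = hierarchy.leaves_list(Z)
    return {
        "linkage": Z,
        "leaf_order": leaves,
        "merge_heights": Z[:, 2],
        "ordered_outputs": outputs[leaves],
        "metric": "euclidean",
        "method": "average",
    }


def cut_clusters(clustering: dict, k: int) -> np.ndarray:
    """Flat cluster labels from a supervised_clustering result."""
    return hierarchy.fcluster(clustering["linkage"], t=k, criterion="maxclust")


def dependence_data(
    S: ShapMatrix, table: FeatureTable, feature: str, interaction: str = "auto"
) -> pd.DataFrame:
    """Dependence-plot pairs (abundance, phi) with an interaction colour.

    ``interaction="auto"`` picks the other feature whose abundances are
    most correlated (max |Pearson r|) with the target's SHAP column;
    pass a feature id to choose explicitly, or None for no colour.
    """
    ids = list(S.feature_ids or table.feature_ids)
    if feature not in ids:
        raise KeyError(f"unknown feature id {feature!r}")
    j = ids.index(feature)
    phi = S.values[:, j]
    if interaction == "auto":
        best, best_r = None, -1.0
        for k, fid in enumerate(ids):
            if k == j:
                continue
            col = table.matrix[:, k]
            if col.std() == 0 or phi.std() == 0:
                r = 0.0
            else:
                r = abs(np.corrcoef(col, phi)[0, 1])
            if r > best_r:
                best, best_r = fid, r
        interaction = best
    df = pd.DataFrame(
        {
            "sample": table.sample_ids,
            "value": table.matrix[:, j],
            "shap_value": phi,
        }
    )
    if interaction is not None:
        df["interaction_feature"] = interaction
        df["interaction_value"] = table.matrix[:, ids.index(interaction)]
    return df


def local_decomposition(attribution: Attribution, row_values=None, top_k: int = 9) -> LocalDecomposition:
    """Waterfall/force-ready decomposition: top-k |phi| terms + remainder.

    Ties in |phi| are broken by feature index so the ordering is
    deterministic.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    phi = attribution.values
    n = phi.shape[0]
    ids = attribution.feature_ids or [f"f{j}" for j in range(n)]
    order = np.lexsort((np.arange(n), -np.abs(phi)))
    kept, rest = order[:top_k], order[top_k:]
    vals = row_values if row_values is not None else [None] * n
    entries = [(ids[j], vals[j], float(phi[j])) for j in kept]
    dec = LocalDecomposition(
        entries=entries,
        remainder=float(phi[rest].sum()),
        base_value=float(attribution.base_value),
        model_output=float(attribution.model_output),
    )
    dec.check()
    return dec


def importance_correlation(a: ImportanceVector, b: ImportanceVector) -> tuple[float, float]:
    """Pearson r between two importance vectors, with the two-sided
    p-value from the t distribution on n-2 degrees of freedom."""
    if list(a.feature_ids) != list(b.feature_ids):
        raise ValueError("importance vectors cover different features")
    if a.scores.size < 3:
        raise ValueError("need at least 3 features to correlate")
    if a.scores.std() == 0 or b.scores.std() == 0:
        raise ValueError("zero-variance importance vector")
    r, p = stats.pearsonr(a.scores, b.scores)
    return float(r), float(p)


def error_analysis(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    S: ShapMatrix | None = None,
    table: FeatureTable | None = None,
    top_k: int = 9,
) -> dict:
    """Confusion counts, percent-of-total rates, and per-group explanations.

    The four rates are percentages of the *total* test size (so they
    partition 100%), the convention used when a confusion matrix is
    annotated with overall percentages. When a SHAP matrix is supplied,
    each sample's local decomposition is attached under its outcome
    group (TP/TN/FP/FN) for explanation-driven error review.
    """
    y_true = np.asarray(y_true, dtype=int).ravel()
    y_pred = np.asarray(y_pred, dtype=int).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths disagree")
    n = y_true.size
    groups = {
        "TP": np.flatnonzero((y_true == 1) & (y_pred == 1)),
        "TN": np.flatnonzero((y_true == 0) & (y_pred == 0)),
        "FP": np.flatnonzero((y_true == 0) & (y_pred == 1)),
        "FN": np.flatnonzero((y_true == 1) & (y_pred == 0)),
    }
    counts = {g: int(idx.size) for g, idx in groups.items()}
    rates = {g: 100.0 * counts[g] / n for g in counts}
    report = {"n": n, "counts": counts, "rates_pct": rates, "groups": {}}
    for g, idx in groups.items():
        members = []
        for i in idx:
            entry = {"index": int(i)}
            if S is not None:
                row_vals = table.matrix[i] if table is not None else None
                entry["decomposition"] = local_decomposition(S.row(int(i)), row_vals, top_k)
            members.append(entry)
        report["groups"][g] = members
    return report
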