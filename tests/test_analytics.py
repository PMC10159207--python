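import numpy as np
import pytest

from metashap import (
    FeatureTable,
    ImportanceVector,
    ShapMatrix,
    beeswarm_data,
    dependence_data,
    error_analysis,
    explain_matrix,
    fit_reference_forest,
    global_importance,
    importance_correlation,
    local_decomposition,
    shap_embedding,
    supervised_clustering,
    tree_shap,
)
from metashap.analytics import cut_clusters

from conftest import make_stump, single_tree_ensemble


def make_shap(values, outputs=None, base=0.5, ids=None):
    values = np.asarray(values, dtype=float)
    if outputs is None:
        outputs = base + values.sum(axis=1)
    return ShapMatrix(
        values=values,
        base_value=base,
        model_outputs=np.asarray(outputs, dtype=float),
        feature_ids=ids or [f"f{j}" for j in range(values.shape[1])],
    )


def table_for(S, matrix=None, seed=0):
    rng = np.random.default_rng(seed)
    n, p = S.values.shape
    mat = matrix if matrix is not None else rng.random((n, p)) + 0.1
    labels = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
    return FeatureTable(
        sample_ids=[f"s{i}" for i in range(n)],
        feature_ids=list(S.feature_ids),
        matrix=mat,
        labels=labels,
        positive_class="b",
    )


# -- global importance --------------------------------------------------------


def test_global_importance_mean_abs_and_dummy_column():
    S = make_shap([[0.2, 0.0], [-0.4, 0.0], [0.6, 0.0]])
    imp = global_importance(S)
    assert imp.scores[0] == pytest.approx(0.4)
    assert imp.scores[1] == 0.0
    assert imp.method == "mean_abs_shap"


def test_global_importance_invariant_to_row_permutation():
    rng = np.random.default_rng(1)
    vals = rng.standard_normal((20, 6))
    a = global_importance(make_shap(vals))
    b = global_importance(make_shap(vals[rng.permutation(20)]))
    np.testing.assert_allclose(a.scores, b.scores)


def test_importance_ranking_matches_sum_abs_ranking():
    rng = np.random.default_rng(2)
    vals = rng.standard_normal((15, 8))
    imp = global_importance(make_shap(vals))
    by_sum = np.lexsort((np.arange(8), -np.abs(vals).sum(axis=0)))
    np.testing.assert_array_equal(imp.ranking(), by_sum)


# -- beeswarm -----------------------------------------------------------------


def test_beeswarm_record_count_and_ordering():
    rng = np.random.default_rng(3)
    S = make_shap(rng.standard_normal((10, 5)))
    t = table_for(S)
    df = beeswarm_data(S, t, max_display=3)
    assert len(df) == 10 * 3
    imp = global_importance(S)
    assert df[df["rank"] == 0]["feature"].iloc[0] == imp.feature_ids[imp.ranking()[0]]
    assert df["color"].between(0, 1).all()


def test_beeswarm_constant_feature_color_half():
    S = make_shap(np.ones((4, 2)))
    mat = np.column_stack([np.full(4, 3.0), np.arange(4.0) + 1])
    df = beeswarm_data(S, table_for(S, matrix=mat), max_display=2)
    assert (df[df["feature"] == "f0"]["color"] == 0.5).all()


# -- embedding ----------------------------------------------------------------


def test_embedding_rank_one_matrix_collapses_to_first_axis():
    u = np.arange(6.0)[:, None]
    v = np.array([[1.0, -2.0, 0.5]])
    S = make_shap(u @ v)
    coords = shap_embedding(S)
    assert np.abs(coords[:, 1]).max() <= 1e-8


def test_embedding_variance_bounded_and_deterministic():
    rng = np.random.default_rng(4)
    S = make_shap(rng.standard_normal((30, 10)))
    c1, c2 = shap_embedding(S), shap_embedding(S)
    np.testing.assert_array_equal(c1, c2)
    assert c1.var(axis=0).sum() <= S.values.var(axis=0).sum() + 1e-12
    with pytest.raises(ValueError):
        shap_embedding(make_shap(np.ones((2, 3))))


def test_embedding_separates_classes_on_preset():
    from metashap import generate, log_autoscale, urine_sex_preset

    table, _ = generate(urine_sex_preset(seed=3))
    sub = table.subset_samples(np.arange(80))
    t, _, _ = log_autoscale(sub)
    ens = fit_reference_forest(t.matrix, t.y, n_estimators=30, seed=0)
    S = explain_matrix(ens, t.matrix)
    coords = shap_embedding(S)
    from sklearn.metrics import silhouette_score

    assert silhouette_score(coords, t.y) > 0


# -- supervised clustering ----------------------------------------------------


def test_identical_rows_merge_first():
    vals = np.array([[1.0, 0.0], [1.0, 0.0], [5.0, 5.0], [-4.0, 2.0]])
    clust = supervised_clustering(make_shap(vals))
    assert clust["merge_heights"][0] == 0.0
    first = set(clust["linkage"][0, :2].astype(int))
    assert first == {0, 1}
    assert sorted(clust["leaf_order"]) == [0, 1, 2, 3]


def test_two_mechanism_clusters_recover_labels():
    """Positives driven by two disjoint marker sets separate at k=2."""
    rng = np.random.default_rng(5)
    n_half = 40
    X = rng.lognormal(0.0, 0.3, (2 * n_half + 80, 6))
    mech = np.array([0] * n_half + [1] * n_half)
    X[:n_half, 0:2] *= 6.0        # mechanism A markers
    X[n_half:2 * n_half, 2:4] *= 6.0  # mechanism B markers
    y = np.array([1] * 2 * n_half + [0] * 80)
    ens = fit_reference_forest(np.log(X), y, n_estimators=40, seed=0)
    S = explain_matrix(ens, np.log(X[: 2 * n_half]))
    clust = supervised_clustering(S, outputs=ens.predict(np.log(X[: 2 * n_half])))
    labels = cut_clusters(clust, 2)
    # plain Rand index by pair counting
    same_true = mech[:, None] == mech[None, :]
    same_pred = labels[:, None] == labels[None, :]
    iu = np.triu_indices(2 * n_half, k=1)
    rand = (same_true[iu] == same_pred[iu]).mean()
    assert rand > 0.9


# -- dependence ---------------------------------------------------------------


def test_dependence_stump_step_at_threshold():
    """For a single stump the SHAP-vs-value relation is a two-level step
    that jumps exactly at the split threshold."""
    ens = single_tree_ensemble(make_stump(threshold=2.0), n_features=2)
    xs = np.linspace(0.0, 4.0, 9)
    mat = np.column_stack([xs, np.ones(9)])
    S = explain_matrix(ens, mat, feature_ids=["f0", "f1"])
    t = table_for(S, matrix=mat)
    df = dependence_data(S, t, "f0", interaction=None)
    assert len(df) == 9
    left = df[df["value"] <= 2.0]["shap_value"].unique()
    right = df[df["value"] > 2.0]["shap_value"].unique()
    assert len(left) == 1 and len(right) == 1
    # covers 60/40, leaves 1/0: base 0.6, so phi = 0.4 left, -0.6 right
    assert left[0] == pytest.approx(0.4)
    assert right[0] == pytest.approx(-0.6)


def test_dependence_auto_interaction_excludes_self():
    rng = np.random.default_rng(6)
    S = make_shap(rng.standard_normal((12, 2)))
    t = table_for(S)
    df = dependence_data(S, t, "f0", interaction="auto")
    assert df["interaction_feature"].iloc[0] == "f1"
    with pytest.raises(KeyError):
        dependence_data(S, t, "nope")


# -- local decompositions -----------------------------------------------------


def test_local_decomposition_conservation_and_remainder():
    rng = np.random.default_rng(7)
    ens = single_tree_ensemble(make_stump(), n_features=2)
    att = tree_shap(ens, np.array([-1.0, 0.0]))
    att.feature_ids = ["f0", "f1"]
    dec = local_decomposition(att, row_values=[-1.0, 0.0], top_k=1)
    dec.check(1e-8)
    full = local_decomposition(att, top_k=5)
    assert full.remainder == 0.0


def test_local_decomposition_tie_break_by_index():
    from metashap import Attribution

    att = Attribution(values=np.array([0.3, -0.3, 0.1]), base_value=0.0, model_output=0.1)
    dec = local_decomposition(att, top_k=2)
    assert [e[0] for e in dec.entries] == ["f0", "f1"]
    with pytest.raises(ValueError):
        local_decomposition(att, top_k=0)


# -- importance correlation ---------------------------------------------------


def iv(scores, method="vip"):
    return ImportanceVector(
        scores=np.asarray(scores, float), method=method,
        feature_ids=[f"f{j}" for j in range(len(scores))],
    )


def test_correlation_identity():
    r, p = importance_correlation(iv([1, 2, 3, 4.0]), iv([1, 2, 3, 4.0], "gini"))
    assert r == pytest.approx(1.0)


def test_correlation_matches_hand_formula():
    a = np.array([0.1, 0.5, 0.9, 0.3, 0.7])
    b = np.array([0.2, 0.4, 1.0, 0.1, 0.5])
    r, p = importance_correlation(iv(a), iv(b, "mean_abs_shap"))
    ac, bc = a - a.mean(), b - b.mean()
    r_hand = (ac @ bc) / np.sqrt((ac @ ac) * (bc @ bc))
    from scipy.stats import t as tdist

    t_stat = r_hand * np.sqrt(3 / (1 - r_hand**2))
    p_hand = 2 * tdist.sf(abs(t_stat), 3)
    assert r == pytest.approx(r_hand, abs=1e-10)
    assert p == pytest.approx(p_hand, abs=1e-10)


def test_correlation_orthogonal_construction_and_errors():
    a = np.array([1.0, 2.0, 3.0, 4.0])
    b = np.array([1.0, 0.0, 0.0, 1.0])  # centered b orthogonal to centered a
    r, _ = importance_correlation(iv(a), iv(b, "gini"))
    assert r == pytest.approx(0.0, abs=1e-10)
    with pytest.raises(ValueError, match="zero-variance"):
        importance_correlation(iv(a), iv(np.ones(4), "gini"))


# -- error analysis -----------------------------------------------------------


def test_confusion_rates_percent_of_total():
    """TN=11, FP=3, FN=2, TP=15 at n=31 give 35.48/9.68/6.45/48.39 percent."""
    y_true = np.array([0] * 11 + [0] * 3 + [1] * 2 + [1] * 15)
    y_pred = np.array([0] * 11 + [1] * 3 + [0] * 2 + [1] * 15)
    rep = error_analysis(y_true, y_pred)
    assert rep["counts"] == {"TP": 15, "TN": 11, "FP": 3, "FN": 2}
    rates = {g: round(v, 2) for g, v in rep["rates_pct"].items()}
    assert rates == {"TN": 35.48, "FP": 9.68, "FN": 6.45, "TP": 48.39}
    assert sum(rep["rates_pct"].values()) == pytest.approx(100.0)


def test_error_analysis_perfect_predictions_and_decompositions():
    ens = single_tree_ensemble(make_stump(), n_features=2)
    X = np.array([[-1.0, 0.0], [1.0, 0.0], [-2.0, 1.0], [2.0, 1.0]])
    S = explain_matrix(ens, X, feature_ids=["f0", "f1"])
    y = np.array([1, 0, 1, 0])
    rep = error_analysis(y, y, S, top_k=2)
    assert rep["counts"]["FP"] == rep["counts"]["FN"] == 0
    for g in ("TP", "TN"):
        for m in rep["groups"][g]:
            m["decomposition"].check(1e-8)
    with pytest.raises(ValueError):
        error_analysis(y, y[:3])
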