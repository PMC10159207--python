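"""Array-based tree ensembles with per-node training cover.

A :class:`Tree` stores its nodes in parallel arrays (split feature,
threshold, children, leaf value, cover). *Cover* is the training-weighted
number of samples that passed through each node; it supplies the weights
for descending unconditioned branches when a conditional expectation is
taken over a tree, which is what makes exact tree Shapley attribution
possible without background data.

The module provides prediction, a minimal deterministic CART/bagging
reference trainer (Gini impurity, random feature subsets, midpoint
thresholds), Gini importance, a lossless JSON interchange format, and
adapters that ingest externally trained scikit-learn forests and XGBoost
boosters. Routing convention everywhere: left iff x[f] <= threshold.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Tree",
    "TreeEnsemble",
    "fit_reference_forest",
    "gini_importance",
    "ingest_ensemble",
    "random_ensemble",
]


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class Tree:
    """One binary decision tree in parallel-array form.

    ``split_feature`` is -1 at leaves; internal nodes carry a threshold
    and both children. ``leaf_value`` is meaningful at leaves (internal
    entries may hold node means). ``cover[node]`` must equal the sum of
    the children's covers. ``split_gain`` optionally records the
    training impurity decrease of each split (for Gini importance).
    """

    split_feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    leaf_value: np.ndarray
    cover: np.ndarray
    split_gain: np.ndarray | None = None

    def __post_init__(self):
        self.split_feature = np.asarray(self.split_feature, dtype=int)
        self.threshold = np.asarray(self.threshold, dtype=float)
        self.left = np.asarray(self.left, dtype=int)
        self.right = np.asarray(self.right, dtype=int)
        self.leaf_value = np.asarray(self.leaf_value, dtype=float)
        self.cover = np.asarray(self.cover, dtype=float)
        if self.split_gain is not None:
            self.split_gain = np.asarray(self.split_gain, dtype=float)

    @property
    def n_nodes(self) -> int:
        return self.split_feature.shape[0]

    def is_leaf(self, node: int) -> bool:
        return self.split_feature[node] < 0

    def validate(self) -> None:
        n = self.n_nodes
        for arr, name in [
            (self.threshold, "threshold"),
            (self.left, "left"),
            (self.right, "right"),
            (self.leaf_value, "leaf_value"),
            (self.cover, "cover"),
        ]:
            if arr.shape != (n,):
                raise ValueError(f"array {name} length {arr.shape} != node count {n}")
        seen = np.zeros(n, dtype=bool)
        stack = [0]
        while stack:
            node = stack.pop()
            if node < 0 or node >= n:
                raise ValueError(f"dangling child index {node}")
            if seen[node]:
                raise ValueError(f"node {node} reachable twice; tree is not a rooted binary tree")
            seen[node] = True
            if self.is_leaf(node):
                if not np.isfinite(self.leaf_value[node]):
                    raise ValueError(f"missing/non-finite leaf value at node {node}")
                continue
            l, r = self.left[node], self.right[node]
            if l == r:
                raise ValueError(f"internal node {node} lacks two distinct children")
            if not (0 <= l < n) or not (0 <= r < n):
                raise ValueError(f"dangling child index {max(l, r)}")
            if abs(self.cover[node] - (self.cover[l] + self.cover[r])) > 1e-9 * max(1.0, self.cover[node]):
                raise ValueError(
                    f"cover inconsistency at node {node}: "
                    f"{self.cover[node]} != {self.cover[l]} + {self.cover[r]}"
                )
            stack += [l, r]
        if (self.cover[seen] <= 0).any():
            raise ValueError("non-positive cover on a reachable node")

    # -- structure statistics ------------------------------------------------
    def depth(self, node: int = 0) -> int:
        if self.is_leaf(node):
            return 0
        return 1 + max(self.depth(self.left[node]), self.depth(self.right[node]))

    @property
    def n_leaves(self) -> int:
        return int((self.split_feature < 0).sum())

    def predict_one(self, x: np.ndarray) -> float:
        node = 0
        while not self.is_leaf(node):
            f = self.split_feature[node]
            node = self.left[node] if x[f] <= self.threshold[node] else self.right[node]
        return float(self.leaf_value[node])

    def cover_weighted_mean(self) -> float:
        """Expectation of the leaf value under the cover distribution (val of the empty coalition)."""

        def rec(node):
            if self.is_leaf(node):
                return self.leaf_value[node]
            l, r = self.left[node], self.right[node]
            c = self.cover[node]
            if c <= 0:
                raise ValueError(f"zero cover at internal node {node}")
            return (self.cover[l] * rec(l) + self.cover[r] * rec(r)) / c

        return float(rec(0))


@dataclass
class TreeEnsemble:
    """A weighted sum of trees plus an offset.

    ``output_kind="probability"``: the weighted leaf sum is already a
    class-1 probability (bagged classification forests).
    ``output_kind="margin"``: the sum is a log-odds margin and a logistic
    link maps it to a probability (boosted models).
    """

    trees: list
    tree_weight: np.ndarray
    base_offset: float = 0.0
    output_kind: str = "probability"
    n_features: int | None = None

    def __post_init__(self):
        self.tree_weight = np.asarray(self.tree_weight, dtype=float)
        if len(self.trees) < 1:
            raise ValueError("ensemble needs at least one tree")
        if self.tree_weight.shape != (len(self.trees),):
            raise ValueError("one weight per tree required")
        if self.output_kind not in ("probability", "margin"):
            raise ValueError(f"unknown output_kind {self.output_kind!r}")
        if self.n_features is None:
            used = [t.split_feature[t.split_feature >= 0] for t in self.trees]
            used = np.concatenate(used) if any(u.size for u in used) else np.array([-1])
            self.n_features = int(used.max()) + 1

    def validate(self) -> None:
        for t in self.trees:
            t.validate()

    # derived size statistics: T trees, L max leaves, D max depth
    @property
    def stat_T(self) -> int:
        return len(self.trees)

    @property
    def stat_L(self) -> int:
        return max(t.n_leaves for t in self.trees)

    @property
    def stat_D(self) -> int:
        return max(t.depth() for t in self.trees)

    def margin(self, X: np.ndarray) -> np.ndarray:
        """Raw additive output: base_offset + weighted leaf sum."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if not np.isfinite(X).all():
            raise ValueError("non-finite input value")
        if X.shape[1] < self.n_features:
            raise ValueError(f"need >= {self.n_features} features, got {X.shape[1]}")
        out = np.full(X.shape[0], self.base_offset)
        for w, t in zip(self.tree_weight, self.trees):
            out += w * np.array([t.predict_one(x) for x in X])
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Model output on its natural scale (probability for both kinds)."""
        raw = self.margin(X)
        return _sigmoid(raw) if self.output_kind == "margin" else raw

    def predict_one(self, x: np.ndarray) -> float:
        return float(self.predict(np.asarray(x, dtype=float)[None, :])[0])

    # -- interchange ---------------------------------------------------------
    def to_document(self) -> dict:
        return {
            "trees": [
                {
                    "split_feature": t.split_feature.tolist(),
                    "threshold": t.threshold.tolist(),
                    "left": t.left.tolist(),
                    "right": t.right.tolist(),
                    "leaf_value": t.leaf_value.tolist(),
                    "cover": t.cover.tolist(),
                    **(
                        {"split_gain": t.split_gain.tolist()}
                        if t.split_gain is not None
                        else {}
                    ),
                }
                for t in self.trees
            ],
            "tree_weight": self.tree_weight.tolist(),
            "base_offset": float(self.base_offset),
            "output_kind": self.output_kind,
            "n_features": int(self.n_features),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_document())

    # -- adapters ------------------------------------------------------------
    @classmethod
    def from_sklearn(cls, forest) -> "TreeEnsemble":
        """Ingest a fitted sklearn RandomForestClassifier/regressor.

        Uses ``weighted_n_node_samples`` as cover; classifier leaf values
        become class-1 probabilities, so predictions reproduce
        ``predict_proba(...)[:, 1]`` exactly.
        """
        trees = []
        for est in forest.estimators_:
            t = est.tree_
            value = t.value  # (n_nodes, n_outputs, n_classes) or (n_nodes, n_outputs, 1)
            if value.shape[2] == 1:
                leaf = value[:, 0, 0].astype(float)
            else:
                v = value[:, 0, :].astype(float)
                rows = v.sum(axis=1)
                leaf = v[:, 1] / np.where(rows > 0, rows, 1.0)
                if np.allclose(rows, 1.0):
                    leaf = v[:, 1]
            cover = t.weighted_n_node_samples.astype(float)
            gain = np.zeros(t.node_count)
            for node in range(t.node_count):
                l, r = t.children_left[node], t.children_right[node]
                if l != -1:
                    gain[node] = cover[node] * t.impurity[node] - (
                        cover[l] * t.impurity[l] + cover[r] * t.impurity[r]
                    )
            split_feature = np.where(t.children_left == -1, -1, t.feature)
            trees.append(
                Tree(
                    split_feature=split_feature,
                    threshold=np.where(t.children_left == -1, 0.0, t.threshold),
                    left=np.maximum(t.children_left, 0),
                    right=np.maximum(t.children_right, 0),
                    leaf_value=leaf,
                    cover=cover,
                    split_gain=gain,
                )
            )
        ens = cls(
            trees=trees,
            tree_weight=np.full(len(trees), 1.0 / len(trees)),
            base_offset=0.0,
            output_kind="probability",
            n_features=int(forest.n_features_in_),
        )
        ens.validate()
        return ens

    @classmethod
    def from_xgboost(cls, booster) -> "TreeEnsemble":
        """Ingest a binary-logistic XGBoost booster as a margin ensemble.

        Parses the booster's own full-precision JSON model. XGBoost routes
        left on x < t; thresholds are shifted to nextafter(t, -inf) so the
        x <= threshold convention used here routes identically on doubles.
        ``sum_hessian`` supplies per-node cover.
        """
        import xgboost  # noqa: F401  (lazy; optional adapter dependency)

        raw = json.loads(booster.save_raw("json").decode())
        model = raw["learner"]["gradient_booster"]["model"]
        base_score = float(raw["learner"]["learner_model_param"]["base_score"])
        objective = raw["learner"]["objective"]["name"]
        if objective.startswith(("binary:logistic", "reg:logistic")):
            base_offset = math.log(base_score / (1.0 - base_score))
        else:
            base_offset = base_score
        trees = []
        for tdoc in model["trees"]:
            leftc = np.asarray(tdoc["left_children"], dtype=int)
            rightc = np.asarray(tdoc["right_children"], dtype=int)
            cond = np.asarray(tdoc["split_conditions"], dtype=float)
            feat = np.asarray(tdoc["split_indices"], dtype=int)
            hess = np.asarray(tdoc["sum_hessian"], dtype=float)
            is_leaf = leftc == -1
            # stored hessians are float32; rebuild internal covers bottom-up
            # from the leaves so the parent-equals-children invariant is exact
            for node in range(hess.size - 1, -1, -1):
                if not is_leaf[node]:
                    hess[node] = hess[leftc[node]] + hess[rightc[node]]
            trees.append(
                Tree(
                    split_feature=np.where(is_leaf, -1, feat),
                    threshold=np.where(is_leaf, 0.0, np.nextafter(cond, -np.inf)),
                    left=np.maximum(leftc, 0),
                    right=np.maximum(rightc, 0),
                    leaf_value=np.where(is_leaf, cond, 0.0),
                    cover=hess,
                    split_gain=None,
                )
            )
        ens = cls(
            trees=trees,
            tree_weight=np.ones(len(trees)),
            base_offset=base_offset,
            output_kind="margin",
            n_features=int(raw["learner"]["learner_model_param"]["num_feature"]),
        )
        ens.validate()
        return ens


def ingest_ensemble(doc) -> TreeEnsemble:
    """Parse and validate the JSON interchange document (dict or JSON text)."""
    if isinstance(doc, (str, bytes)):
        doc = json.loads(doc)
    trees = []
    for td in doc["trees"]:
        if "cover" not in td:
            raise ValueError("tree document lacks per-node cover")
        trees.append(
            Tree(
                split_feature=td["split_feature"],
                threshold=td["threshold"],
                left=td["left"],
                right=td["right"],
                leaf_value=td["leaf_value"],
                cover=td["cover"],
                split_gain=td.get("split_gain"),
            )
        )
    ens = TreeEnsemble(
        trees=trees,
        tree_weight=np.asarray(doc["tree_weight"], dtype=float),
        base_offset=float(doc.get("base_offset", 0.0)),
        output_kind=doc.get("output_kind", "probability"),
        n_features=doc.get("n_features"),
    )
    ens.validate()
    return ens


# ---------------------------------------------------------------------------
# Reference trainer: deterministic CART bagging
# ---------------------------------------------------------------------------


def _gini(n1: float, n: float) -> float:
    if n == 0:
        return 0.0
    p1 = n1 / n
    return 1.0 - p1 * p1 - (1.0 - p1) * (1.0 - p1)


def _best_split(x_node, y_node, feat_subset, min_leaf):
    """Best (gain, feature, threshold) over the candidate features.

    Candidate thresholds are midpoints between consecutive distinct
    values; ties in gain resolve to the lowest feature index, then the
    lowest threshold (features scanned ascending, thresholds ascending,
    improvement must be strict).
    """
    n = y_node.size
    parent = _gini(y_node.sum(), n)
    best = (0.0, -1, 0.0)
    for f in np.sort(feat_subset):
        xv = x_node[:, f]
        order = np.argsort(xv, kind="stable")
        xs, ys = xv[order], y_node[order]
        cum1 = np.cumsum(ys)
        k = np.arange(1, n)
        valid = (xs[1:] > xs[:-1]) & (k >= min_leaf) & (n - k >= min_leaf)
        if not valid.any():
            continue
        n1_left = cum1[:-1]
        p1l = n1_left / k
        p1r = (cum1[-1] - n1_left) / (n - k)
        child = k * (1 - p1l**2 - (1 - p1l) ** 2) + (n - k) * (1 - p1r**2 - (1 - p1r) ** 2)
        gain = parent - child / n
        gain[~valid] = -np.inf
        kbest = int(np.argmax(gain))  # first max -> lowest threshold
        if gain[kbest] > best[0] + 1e-12:
            thr = 0.5 * (xs[kbest] + xs[kbest + 1])
            best = (float(gain[kbest]), int(f), float(thr))
    return best


def _resolve_max_features(max_features, p: int) -> int:
    if max_features is None or max_features == "all":
        return p
    if max_features == "sqrt":
        return max(1, int(math.sqrt(p)))
    if max_features == "log2":
        return max(1, int(math.log2(p)))
    if isinstance(max_features, float):
        return max(1, int(max_features * p))
    return max(1, min(int(max_features), p))


def _grow_tree(X, y, rng, max_depth, max_features, min_split, min_leaf):
    split_feature, threshold, left, right, leaf_value, cover, gain_arr = ([] for _ in range(7))
    p = X.shape[1]
    k = _resolve_max_features(max_features, p)

    def new_node():
        for arr, v in zip(
            (split_feature, threshold, left, right, leaf_value, cover, gain_arr),
            (-1, 0.0, 0, 0, 0.0, 0.0, 0.0),
        ):
            arr.append(v)
        return len(split_feature) - 1

    def build(idx, depth):
        node = new_node()
        yn = y[idx]
        cover[node] = float(idx.size)
        leaf_value[node] = float(yn.mean())
        pure = yn.min() == yn.max()
        if depth >= max_depth or idx.size < min_split or pure:
            return node
        subset = rng.choice(p, size=k, replace=False)
        gain, f, thr = _best_split(X[idx], yn, subset, min_leaf)
        if f < 0:
            return node
        go_left = X[idx, f] <= thr
        l = build(idx[go_left], depth + 1)
        r = build(idx[~go_left], depth + 1)
        split_feature[node], threshold[node] = f, thr
        left[node], right[node] = l, r
        # cover-weighted Gini decrease, unnormalized
        gain_arr[node] = cover[node] * gain
        return node

    build(np.arange(X.shape[0]), 0)
    return Tree(
        split_feature=np.array(split_feature),
        threshold=np.array(threshold),
        left=np.array(left),
        right=np.array(right),
        leaf_value=np.array(leaf_value),
        cover=np.array(cover),
        split_gain=np.array(gain_arr),
    )


def fit_reference_forest(
    X: np.ndarray,
    y: np.ndarray,
    n_estimators: int = 100,
    max_depth: int | None = None,
    max_features="sqrt",
    min_samples_split: int = 2,
    min_samples_leaf: int = 1,
    seed: int = 0,
) -> TreeEnsemble:
    """Deterministic bagged CART forest (probability-averaging output).

    Each tree is grown greedily on a bootstrap resample: best Gini split
    over a seeded random feature subset, midpoint thresholds, ties broken
    by lowest feature index then lowest threshold. Leaf values are the
    positive-class fraction of the bootstrap samples routed there; node
    cover is the bootstrap routing count; tree weights are 1/T so the
    forest output is the averaged leaf probability.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y sample counts disagree")
    if np.unique(y).size < 2 or min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least 2 samples in each class")
    if max_depth is not None and max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    if n_estimators < 1:
        raise ValueError("n_estimators must be >= 1")
    depth_cap = np.inf if max_depth is None else max_depth
    n = X.shape[0]
    trees = []
    for child_seed in np.random.SeedSequence(seed).spawn(n_estimators):
        rng = np.random.default_rng(child_seed)
        boot = rng.integers(0, n, n)
        trees.append(
            _grow_tree(
                X[boot], y[boot], rng, depth_cap, max_features, min_samples_split, min_samples_leaf
            )
        )
    ens = TreeEnsemble(
        trees=trees,
        tree_weight=np.full(n_estimators, 1.0 / n_estimators),
        base_offset=0.0,
        output_kind="probability",
        n_features=X.shape[1],
    )
    ens.validate()
    return ens


def gini_importance(
    ensemble: TreeEnsemble, X: np.ndarray | None = None, y: np.ndarray | None = None
) -> np.ndarray:
    """Per-feature mean impurity decrease, normalized to sum to 1.

    Uses the impurity-decrease records laid down by the reference trainer
    (or the sklearn adapter). For ensembles ingested without them, pass
    training data and the decreases are recomputed by routing (X, y)
    through each tree and scoring each split's Gini reduction.
    """
    p = ensemble.n_features
    totals = np.zeros(p)
    have_records = all(t.split_gain is not None for t in ensemble.trees)
    if have_records:
        for w, t in zip(ensemble.tree_weight, ensemble.trees):
            for node in range(t.n_nodes):
                if not t.is_leaf(node):
                    totals[t.split_feature[node]] += w * t.split_gain[node]
    else:
        if X is None or y is None:
            raise ValueError(
                "ensemble carries no impurity records; supply training X and y to recompute"
            )
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        for w, t in zip(ensemble.tree_weight, ensemble.trees):
            idx_at = {0: np.arange(X.shape[0])}
            order = [0]
            while order:
                node = order.pop()
                idx = idx_at.pop(node)
                if t.is_leaf(node) or idx.size == 0:
                    continue
                f, thr = t.split_feature[node], t.threshold[node]
                go_left = X[idx, f] <= thr
                li, ri = idx[go_left], idx[~go_left]
                dec = idx.size * _gini(y[idx].sum(), idx.size) - (
                    li.size * _gini(y[li].sum(), li.size) + ri.size * _gini(y[ri].sum(), ri.size)
                )
                totals[f] += w * dec
                idx_at[t.left[node]], idx_at[t.right[node]] = li, ri
                order += [t.left[node], t.right[node]]
    s = totals.sum()
    return totals / s if s > 0 else totals


def random_ensemble(
    rng: np.random.Generator,
    n_features: int,
    n_trees: int,
    max_depth: int,
    leaf_prob: float = 0.3,
    min_cover: int = 1,
) -> TreeEnsemble:
    """Structurally random probability ensemble for stress-testing attribution.

    Features and thresholds are drawn at random (thresholds ~ N(0,1), so
    standard-normal inputs exercise both branches), covers are drawn
    consistently with the parent-equals-children invariant, and leaf
    values are uniform on [0, 1].
    """

    def grow(depth, cov, arrays):
        sf, th, le, ri, lv, co = arrays
        node = len(sf)
        for arr, v in zip(arrays, (-1, 0.0, 0, 0, 0.0, float(cov))):
            arr.append(v)
        if depth >= max_depth or cov < 2 * min_cover or rng.random() < leaf_prob:
            lv[node] = float(rng.random())
            return node
        sf[node] = int(rng.integers(0, n_features))
        th[node] = float(rng.standard_normal())
        cl = int(rng.integers(min_cover, cov - min_cover + 1))
        le[node] = grow(depth + 1, cl, arrays)
        ri[node] = grow(depth + 1, cov - cl, arrays)
        return node

    trees = []
    for _ in range(n_trees):
        arrays = ([], [], [], [], [], [])
        grow(0, int(rng.integers(50, 200)), arrays)
        trees.append(
            Tree(
                split_feature=np.array(arrays[0]),
                threshold=np.array(arrays[1]),
                left=np.array(arrays[2]),
                right=np.array(arrays[3]),
                leaf_value=np.array(arrays[4]),
                cover=np.array(arrays[5]),
            )
        )
    ens = TreeEnsemble(
        trees=trees,
        tree_weight=np.full(n_trees, 1.0 / n_trees),
        base_offset=0.0,
        output_kind="probability",
        n_features=n_features,
    )
    ens.validate()
    return ens
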