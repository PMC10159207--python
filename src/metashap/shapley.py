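"""Exact Shapley attribution for tree ensembles.

The Shapley value of feature i for a sample x under a value function
val(S) (the expected model output when only the coalition S of feature
values is known) is

    phi_i = sum over S subset of {0..N-1}\\{i} of
            |S|! (N - |S| - 1)! / N! * [val(S + {i}) - val(S)],

the unique attribution satisfying symmetry, dummy, additivity, and local
accuracy (base + sum phi = model output).

Two routes are implemented:

* :func:`shapley_bruteforce` enumerates all 2^N coalitions against any
  value-function contract (cost O(2^N); guarded at N <= 20).
* :func:`tree_shap` computes the identical numbers for the tree
  conditional-expectation value function in polynomial time
  (O(T L D^2) per sample) by propagating, down each decision path, the
  weights of every coalition cardinality simultaneously (the
  extend/unwind path bookkeeping), with repeated features along a path
  collapsed to one entry.

The value function here is *path-dependent*: descending a node whose
split feature is outside the coalition averages both children weighted
by their training cover, i.e. missing features have their decision paths
ignored rather than re-sampled. An interventional variant over an
explicit background set is provided for brute-force use; it defines a
different (also exact) game.

For margin-output ensembles attributions are computed on the additive
margin scale (a post-link game would not decompose per tree); for
probability ensembles the two scales coincide.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .trees import Tree, TreeEnsemble, _sigmoid

__all__ = [
    "Attribution",
    "ShapMatrix",
    "tree_conditional_value",
    "interventional_value_fn",
    "shapley_bruteforce",
    "tree_shap",
    "explain_matrix",
]

BRUTEFORCE_GUARD = 20


@dataclass
class Attribution:
    """Per-feature Shapley values phi for one explained sample.

    ``base_value`` is val(empty coalition); local accuracy guarantees
    base_value + phi.sum() == model_output to 1e-8.
    """

    values: np.ndarray
    base_value: float
    model_output: float
    feature_ids: list | None = None
    node_visits: int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    def check_local_accuracy(self, tol: float = 1e-8) -> None:
        gap = abs(self.base_value + self.values.sum() - self.model_output)
        if gap > tol:
            raise AssertionError(f"local accuracy violated: |base + sum(phi) - f(x)| = {gap:.3g}")


@dataclass
class ShapMatrix:
    """Shapley values for a whole sample set (n_samples x n_features)."""

    values: np.ndarray
    base_value: float
    model_outputs: np.ndarray
    feature_ids: list | None = None
    sample_ids: list | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.model_outputs = np.asarray(self.model_outputs, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def mean_model_output(self) -> float:
        """Average prediction over the explained set (reported alongside
        the cover-derived base value; they are different quantities)."""
        return float(self.model_outputs.mean())

    def row(self, j: int) -> Attribution:
        return Attribution(
            values=self.values[j],
            base_value=self.base_value,
            model_output=float(self.model_outputs[j]),
            feature_ids=self.feature_ids,
        )

    def to_tsv(self, path) -> None:
        import pandas as pd

        cols = self.feature_ids or [f"f{j}" for j in range(self.n_features)]
        idx = self.sample_ids or [f"s{i}" for i in range(self.n_samples)]
        pd.DataFrame(self.values, index=idx, columns=cols).to_csv(
            path, sep="\t", float_format="%.17g", index_label="sample_id"
        )

    def sidecar(self) -> dict:
        return {
            "base_value": float(self.base_value),
            "mean_model_output": self.mean_model_output,
            "model_outputs": [float(v) for v in self.model_outputs],
            "sample_ids": self.sample_ids,
        }


# ---------------------------------------------------------------------------
# Value functions
# ---------------------------------------------------------------------------


def _tree_expectation(tree: Tree, x, in_coalition, node: int = 0) -> float:
    f = tree.split_feature[node]
    if f < 0:
        return float(tree.leaf_value[node])
    if in_coalition(f):
        nxt = tree.left[node] if x[f] <= tree.threshold[node] else tree.right[node]
        return _tree_expectation(tree, x, in_coalition, nxt)
    l, r = tree.left[node], tree.right[node]
    c = tree.cover[node]
    if c <= 0:
        raise ValueError(f"zero cover at internal node {node}")
    return (
        tree.cover[l] * _tree_expectation(tree, x, in_coalition, l)
        + tree.cover[r] * _tree_expectation(tree, x, in_coalition, r)
    ) / c


def tree_conditional_value(
    ensemble: TreeEnsemble, x: np.ndarray, S, apply_link: bool = True
) -> float:
    """Path-dependent conditional expectation val(S) for a tree ensemble.

    Per tree: at a node splitting on a coalition feature, follow x's
    branch; otherwise take the cover-weighted average of both subtrees.
    The ensemble value is base_offset plus the weighted tree sum, with
    the logistic link applied after summation for margin outputs (set
    ``apply_link=False`` to stay on the additive scale that the Shapley
    decomposition lives on).
    """
    x = np.asarray(x, dtype=float)
    S = frozenset(int(i) for i in S)
    if any(i < 0 or i >= ensemble.n_features for i in S):
        raise ValueError("coalition contains an invalid feature index")
    val = ensemble.base_offset
    member = S.__contains__
    for w, t in zip(ensemble.tree_weight, ensemble.trees):
        val += w * _tree_expectation(t, x, member)
    if apply_link and ensemble.output_kind == "margin":
        val = float(_sigmoid(val))
    return float(val)


def interventional_value_fn(ensemble: TreeEnsemble, background: np.ndarray, x: np.ndarray,
                            apply_link: bool = False):
    """Value function marginalising missing features over a background set.

    val(S) = mean over background rows b of f(z) with z taking x's values
    on S and b's elsewhere. Exact for the interventional game; intended
    for use with :func:`shapley_bruteforce` (no fast path is provided).
    """
    background = np.atleast_2d(np.asarray(background, dtype=float))
    x = np.asarray(x, dtype=float)

    def val(S):
        z = background.copy()
        idx = sorted(int(i) for i in S)
        z[:, idx] = x[idx]
        raw = ensemble.margin(z)
        out = _sigmoid(raw) if (apply_link and ensemble.output_kind == "margin") else raw
        return float(out.mean())

    return val


# ---------------------------------------------------------------------------
# Brute force (Eq. of the definition, exponential)
# ---------------------------------------------------------------------------


def shapley_bruteforce(value_fn, x, N: int, allow_large: bool = False,
                       feature_ids: list | None = None) -> Attribution:
    """Exact Shapley values by full coalition enumeration.

    ``value_fn`` maps an iterable of feature indices to a real number;
    it is evaluated once per coalition (2^N calls). Refuses N above
    20 unless ``allow_large=True``.
    """
    if N > BRUTEFORCE_GUARD and not allow_large:
        raise ValueError(
            f"N={N} exceeds the brute-force guard ({BRUTEFORCE_GUARD}); "
            "cost grows as 2^N — pass allow_large=True to override"
        )
    vals = np.empty(1 << N)
    for mask in range(1 << N):
        members = [i for i in range(N) if mask >> i & 1]
        vals[mask] = value_fn(members)
    fact = [math.factorial(k) for k in range(N + 1)]
    phi = np.zeros(N)
    full = (1 << N) - 1
    for i in range(N):
        bit = 1 << i
        for mask in range(1 << N):
            if mask & bit:
                continue
            s = bin(mask).count("1")
            w = fact[s] * fact[N - s - 1] / fact[N]
            phi[i] += w * (vals[mask | bit] - vals[mask])
    return Attribution(
        values=phi,
        base_value=float(vals[0]),
        model_output=float(vals[full]),
        feature_ids=feature_ids,
    )


# ---------------------------------------------------------------------------
# Polynomial-time tree algorithm
# ---------------------------------------------------------------------------
#
# The path state m is a list of entries [feature, zero_frac, one_frac,
# weight], one per *unique* feature encountered on the root-to-node path
# (plus a sentinel for the root). zero_frac is the fraction of paths that
# flow through the branch when the feature is missing (cover ratio),
# one_frac is 1 if x follows the branch and 0 otherwise, and the weights
# jointly track, for every coalition cardinality, the summed Shapley
# kernel mass of coalitions drawn from the path features. EXTEND pushes
# one feature onto the path; UNWIND removes one (needed both when a
# feature repeats on the path and when summing a leaf's contributions).


def _extend(m, pz, po, pi, counter):
    l = len(m)
    m = [e.copy() for e in m]
    m.append([pi, pz, po, 1.0 if l == 0 else 0.0])
    for i in range(l - 1, -1, -1):
        m[i + 1][3] += po * m[i][3] * (i + 1) / (l + 1)
        m[i][3] = pz * m[i][3] * (l - i) / (l + 1)
        counter[0] += 1
    return m


def _unwind(m, i, counter):
    L = len(m)
    out = [e.copy() for e in m[: L - 1]]
    n = m[L - 1][3]
    one, zero = m[i][2], m[i][1]
    for j in range(L - 2, -1, -1):
        counter[0] += 1
        if one != 0.0:
            t = out[j][3]
            out[j][3] = n * L / ((j + 1) * one)
            n = t - out[j][3] * zero * (L - 1 - j) / L
        else:
            out[j][3] = out[j][3] * L / (zero * (L - 1 - j))
    for j in range(i, L - 1):
        out[j][0], out[j][1], out[j][2] = m[j + 1][0], m[j + 1][1], m[j + 1][2]
    return out


def _unwound_sum(m, i, counter):
    # total weight after removing entry i, without materialising the list
    return sum(e[3] for e in _unwind(m, i, counter))


def _tree_shap_single(tree: Tree, x, phi, counter):
    def recurse(node, m, pz, po, pi):
        counter[0] += 1
        m = _extend(m, pz, po, pi, counter)
        f = tree.split_feature[node]
        if f < 0:
            v = tree.leaf_value[node]
            for i in range(1, len(m)):
                w = _unwound_sum(m, i, counter)
                phi[m[i][0]] += w * (m[i][2] - m[i][1]) * v
            return
        if x[f] <= tree.threshold[node]:
            hot, cold = tree.left[node], tree.right[node]
        else:
            hot, cold = tree.right[node], tree.left[node]
        iz, io = 1.0, 1.0
        k = next((j for j in range(1, len(m)) if m[j][0] == f), None)
        if k is not None:
            iz, io = m[k][1], m[k][2]
            m = _unwind(m, k, counter)
        rj = tree.cover[node]
        if rj <= 0:
            raise ValueError(f"zero cover at internal node {node}")
        recurse(hot, m, iz * tree.cover[hot] / rj, io, f)
        recurse(cold, m, iz * tree.cover[cold] / rj, 0.0, f)

    recurse(0, [], 1.0, 1.0, -1)


def tree_shap(ensemble: TreeEnsemble, x: np.ndarray,
              feature_ids: list | None = None) -> Attribution:
    """Exact Shapley values for the tree value function, in O(T L D^2).

    Matches :func:`shapley_bruteforce` with
    :func:`tree_conditional_value` to 1e-8 on the additive output scale.
    The per-sample node-visit/work counter is exposed on the returned
    attribution (``node_visits``) so the polynomial bound is testable.
    """
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("non-finite input value")
    phi_total = np.zeros(ensemble.n_features)
    counter = [0]
    base = ensemble.base_offset
    for w, t in zip(ensemble.tree_weight, ensemble.trees):
        phi = np.zeros(ensemble.n_features)
        _tree_shap_single(t, x, phi, counter)
        phi_total += w * phi
        base += w * t.cover_weighted_mean()
    out = ensemble.base_offset + sum(
        w * t.predict_one(x) for w, t in zip(ensemble.tree_weight, ensemble.trees)
    )
    return Attribution(
        values=phi_total,
        base_value=float(base),
        model_output=float(out),
        feature_ids=feature_ids,
        node_visits=counter[0],
    )


def explain_matrix(ensemble: TreeEnsemble, X: np.ndarray,
                   feature_ids: list | None = None,
                   sample_ids: list | None = None) -> ShapMatrix:
    """Row-wise :func:`tree_shap` over a sample matrix, shared base value."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != ensemble.n_features:
        raise ValueError(f"expected {ensemble.n_features} feature columns, got {X.shape[1]}")
    rows, outs = [], []
    base = None
    for i in range(X.shape[0]):
        att = tree_shap(ensemble, X[i])
        rows.append(att.values)
        outs.append(att.model_output)
        base = att.base_value
    return ShapMatrix(
        values=np.vstack(rows),
        base_value=float(base),
        model_outputs=np.asarray(outs),
        feature_ids=feature_ids,
        sample_ids=sample_ids,
    )
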