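"""PLS1 regression with discriminant thresholding and Wold's VIP scores.

Partial least squares discriminant analysis (PLS-DA) regresses a 0/1
class response on the autoscaled feature matrix via latent variables
chosen to maximise X-y covariance, then thresholds the continuous
prediction at 0.5. The per-component model collapses to an ordinary
linear predictor

    y_hat = X @ B_PLS + intercept,

and feature relevance is summarised by the variable importance in
projection (VIP),

    VIP_j = sqrt( p * sum_a SSY_a * (w_ja / ||w_a||)^2 / sum_a SSY_a ),

where SSY_a is the response variance explained by component a and w_a
the a-th X-weight vector. VIP scores satisfy mean(VIP^2) = 1, so scores
above 1 flag above-average relevance.

Fitting uses NIPALS with X-deflation; for a single response the inner
iteration converges in one pass, but the generic loop (tolerance 1e-12,
cap 500) is kept so the code documents the full algorithm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["PLSModel", "fit_plsda", "predict_classify", "vip_scores"]


@dataclass
class PLSModel:
    """Fitted PLS1 state.

    ``x_weights`` (W), ``x_loadings`` (P) are p x A with unit-norm weight
    columns; ``y_loadings`` (q) has length A; ``coef`` is the collapsed
    length-p coefficient vector B_PLS with ``intercept`` so that
    X @ coef + intercept reproduces the latent-score prediction.
    ``ssy`` holds the per-component explained response variance.
    """

    n_components: int
    x_weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    coef: np.ndarray
    intercept: float
    ssy: np.ndarray
    x_mean: np.ndarray
    y_mean: float
    feature_ids: list | None = None

    @property
    def n_features(self) -> int:
        return self.coef.shape[0]

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features:
            raise ValueError(f"expected {self.n_features} features, got {X.shape[1]}")
        return X @ self.coef + self.intercept

    def predict_via_scores(self, X: np.ndarray) -> np.ndarray:
        """Prediction through the latent scores; must match :meth:`predict`."""
        X = np.asarray(X, dtype=float)
        Xc = X - self.x_mean
        W, P = self.x_weights, self.x_loadings
        if self.n_components == 0:
            return np.full(X.shape[0], self.y_mean)
        R = W @ np.linalg.inv(P.T @ W)  # loadings-corrected weights
        T = Xc @ R
        return T @ self.y_loadings + self.y_mean

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": "plsda",
                "n_components": int(self.n_components),
                "x_weights": self.x_weights.tolist(),
                "x_loadings": self.x_loadings.tolist(),
                "y_loadings": self.y_loadings.tolist(),
                "coef": self.coef.tolist(),
                "intercept": float(self.intercept),
                "ssy": self.ssy.tolist(),
                "x_mean": self.x_mean.tolist(),
                "y_mean": float(self.y_mean),
                "feature_ids": self.feature_ids,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PLSModel":
        d = json.loads(text)
        if d.get("kind") != "plsda":
            raise ValueError("not a serialized PLS-DA model")
        return cls(
            n_components=int(d["n_components"]),
            x_weights=np.asarray(d["x_weights"], dtype=float),
            x_loadings=np.asarray(d["x_loadings"], dtype=float),
            y_loadings=np.asarray(d["y_loadings"], dtype=float),
            coef=np.asarray(d["coef"], dtype=float),
            intercept=float(d["intercept"]),
            ssy=np.asarray(d["ssy"], dtype=float),
            x_mean=np.asarray(d["x_mean"], dtype=float),
            y_mean=float(d["y_mean"]),
            feature_ids=d.get("feature_ids"),
        )


def fit_plsda(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    feature_ids: list | None = None,
    tol: float = 1e-12,
    max_iter: int = 500,
) -> PLSModel:
    """Fit PLS1 by NIPALS on (autoscaled) X and a binary 0/1 response.

    Raises if ``n_components`` exceeds the rank of the centered X (the
    achievable rank is reported). If the response covariance is exhausted
    early the remaining components are zero and the effective number of
    components shrinks accordingly.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X and y sample counts disagree")
    uniq = np.unique(y)
    if uniq.size < 2:
        raise ValueError("y must contain both classes")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    x_mean = X.mean(axis=0)
    Xc = X - x_mean
    rank = np.linalg.matrix_rank(Xc)
    if n_components > rank:
        raise ValueError(
            f"n_components={n_components} exceeds the achievable rank {rank} of the training X"
        )
    y_mean = y.mean()
    yc = y - y_mean

    n, p = X.shape
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    ssy = np.zeros(n_components)
    Xa, ya = Xc.copy(), yc.copy()
    a_eff = 0
    for a in range(n_components):
        u = ya.copy()
        if np.linalg.norm(Xa.T @ u) < 1e-12:
            break  # response covariance exhausted
        w = np.zeros(p)
        for _ in range(max_iter):
            w_new = Xa.T @ u
            w_new /= np.linalg.norm(w_new)
            t = Xa @ w_new
            qa = float(ya @ t) / float(t @ t)
            u_new = ya * qa / (qa * qa) if qa != 0 else ya
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w, u = w_new, u_new
        t = Xa @ w
        tt = float(t @ t)
        pa = Xa.T @ t / tt
        qa = float(ya @ t) / tt
        Xa = Xa - np.outer(t, pa)
        ya = ya - qa * t
        W[:, a], P[:, a], q[a] = w, pa, qa
        ssy[a] = qa * qa * tt
        a_eff += 1
    W, P, q, ssy = W[:, :a_eff], P[:, :a_eff], q[:a_eff], ssy[:a_eff]
    if a_eff == 0:
        coef = np.zeros(p)
    else:
        coef = W @ np.linalg.solve(P.T @ W, q)
    intercept = float(y_mean - x_mean @ coef)
    return PLSModel(
        n_components=a_eff,
        x_weights=W,
        x_loadings=P,
        y_loadings=q,
        coef=coef,
        intercept=intercept,
        ssy=ssy,
        x_mean=x_mean,
        y_mean=float(y_mean),
        feature_ids=list(feature_ids) if feature_ids is not None else None,
    )


def predict_classify(model: PLSModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Continuous scores y_hat and hard classes (positive iff y_hat >= 0.5).

    The boundary y_hat = 0.5 is assigned to the positive class; the
    discriminant rule only defines the strict inequalities, so a
    deterministic convention is required.
    """
    scores = model.predict(X)
    return scores, (scores >= 0.5).astype(int)


def vip_scores(model: PLSModel) -> np.ndarray:
    """Wold's variable importance in projection; satisfies sum(VIP^2) = p."""
    if model.x_weights.size == 0:
        raise ValueError("model has no fitted components")
    W, ssy = model.x_weights, model.ssy
    p = W.shape[0]
    wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    num = (wn**2) @ ssy
    return np.sqrt(p * num / ssy.sum())
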