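"""Thin matplotlib rendering of the plot-data produced by the analytics.

Each function takes the plain data structures (DataFrames / arrays) and
returns a matplotlib Figure; nothing here computes statistics.
"""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
from scipy.cluster import hierarchy  # noqa: E402

__all__ = [
    "plot_importance_bar",
    "plot_beeswarm",
    "plot_embedding",
    "plot_clustering_heatmap",
    "plot_dependence",
    "plot_waterfall",
    "plot_force",
]


def plot_importance_bar(importance_frame, max_display: int = 20):
    df = importance_frame.sort_values("score", ascending=False).head(max_display)
    fig, ax = plt.subplots(figsize=(6, 0.3 * len(df) + 1))
    ax.barh(df["feature"][::-1], df["score"][::-1], color="#1f77b4")
    ax.set_xlabel(f"importance ({df['method'].iloc[0]})")
    fig.tight_layout()
    return fig


def plot_beeswarm(beeswarm_frame, jitter_seed: int = 0):
    rng = np.random.default_rng(jitter_seed)
    fig, ax = plt.subplots(figsize=(7, 0.35 * beeswarm_frame["rank"].nunique() + 1))
    order = beeswarm_frame.groupby("rank")["feature"].first()
    for rank, grp in beeswarm_frame.groupby("rank"):
        yy = -rank + 0.12 * rng.standard_normal(len(grp))
        sc = ax.scatter(grp["shap_value"], yy, c=grp["color"], cmap="coolwarm",
                        s=12, vmin=0, vmax=1)
    ax.set_yticks([-r for r in order.index])
    ax.set_yticklabels(order.values)
    ax.axvline(0.0, color="gray", lw=0.8)
    ax.set_xlabel("SHAP value (impact on model output)")
    fig.colorbar(sc, ax=ax, label="feature value (min-max)")
    fig.tight_layout()
    return fig


def plot_embedding(coords, color=None, label="feature value"):
    fig, ax = plt.subplots(figsize=(5, 4))
    sc = ax.scatter(coords[:, 0], coords[:, 1], c=color, cmap="coolwarm", s=18)
    if color is not None:
        fig.colorbar(sc, ax=ax, label=label)
    ax.set_xlabel("PC1 of SHAP values")
    ax.set_ylabel("PC2 of SHAP values")
    fig.tight_layout()
    return fig


def plot_clustering_heatmap(shap_matrix, clustering, max_features: int = 20):
    order = clustering["leaf_order"]
    vals = shap_matrix.values[order]
    imp = np.abs(shap_matrix.values).mean(axis=0)
    feats = np.argsort(-imp)[:max_features]
    fig, (ax0, ax1) = plt.subplots(
        2, 1, figsize=(8, 6), height_ratios=[1, 3], sharex=True
    )
    ax0.plot(shap_matrix.model_outputs[order], lw=1.0)
    ax0.axhline(0.5, ls=":", color="gray")
    ax0.set_ylabel("f(x)")
    im = ax1.imshow(vals[:, feats].T, aspect="auto", cmap="coolwarm")
    ids = shap_matrix.feature_ids or [f"f{j}" for j in range(vals.shape[1])]
    ax1.set_yticks(range(len(feats)))
    ax1.set_yticklabels([ids[j] for j in feats], fontsize=7)
    ax1.set_xlabel("samples (explanation-similarity order)")
    fig.colorbar(im, ax=[ax0, ax1], label="SHAP value")
    return fig


def plot_dependence(dependence_frame):
    fig, ax = plt.subplots(figsize=(5, 4))
    color = dependence_frame.get("interaction_value")
    sc = ax.scatter(dependence_frame["value"], dependence_frame["shap_value"],
                    c=color, cmap="coolwarm", s=18)
    if color is not None:
        fig.colorbar(sc, ax=ax, label=str(dependence_frame["interaction_feature"].iloc[0]))
    ax.set_xlabel("feature value")
    ax.set_ylabel("SHAP value")
    fig.tight_layout()
    return fig


def _decomposition_terms(dec):
    labels = [f for f, _, _ in dec.entries]
    phis = [p for _, _, p in dec.entries]
    if dec.remainder != 0.0:
        labels.append("remaining features")
        phis.append(dec.remainder)
    return labels, phis


def plot_waterfall(dec):
    labels, phis = _decomposition_terms(dec)
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(labels) + 1.5))
    run = dec.base_value
    for k, (lab, p) in enumerate(zip(labels, phis)):
        ax.barh(-k, p, left=run, color="#d62728" if p >= 0 else "#1f77b4")
        run += p
    ax.axvline(dec.base_value, ls=":", color="gray", lw=0.8)
    ax.axvline(dec.model_output, ls="-", color="black", lw=0.8)
    ax.set_yticks([-k for k in range(len(labels))])
    ax.set_yticklabels(labels, fontsize=8)
    ax.set_xlabel(f"E[f(X)]={dec.base_value:.3f}  ->  f(x)={dec.model_output:.3f}")
    fig.tight_layout()
    return fig


def plot_force(dec):
    labels, phis = _decomposition_terms(dec)
    fig, ax = plt.subplots(figsize=(8, 1.8))
    pos_run = dec.model_output
    for lab, p in zip(labels, phis):
        if p >= 0:
            ax.barh(0, p, left=pos_run - p, color="#d62728", edgecolor="white")
            pos_run -= p
    neg_run = dec.model_output
    for lab, p in zip(labels, phis):
        if p < 0:
            ax.barh(0, -p, left=neg_run, color="#1f77b4", edgecolor="white")
            neg_run -= p
    ax.axvline(dec.model_output, color="black", lw=1.2)
    ax.set_yticks([])
    ax.set_xlabel(f"f(x) = {dec.model_output:.3f} (base {dec.base_value:.3f})")
    fig.tight_layout()
    return fig
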