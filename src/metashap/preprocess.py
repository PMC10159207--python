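"""Volcano-style univariate feature selection and the log + autoscale transform.

Selection statistics are computed on the raw-stage training table only:
log2 fold change of group arithmetic means and a pooled-variance
(Student's) two-sample t-test on log2 abundances. A feature is retained
iff |log2FC| > fc_threshold AND p < p_threshold, both strict. The
subsequent log transform + autoscaling (per-feature centering to zero
mean and unit variance) is fit on the training partition and applied to
held-out data with the training statistics, so no information leaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .feature_table import FeatureTable
import dataclasses

__all__ = ["VolcanoStats", "ScalerState", "volcano_stats", "select_features", "log_autoscale"]


@dataclass
class VolcanoStats:
    feature_ids: list
    log2_fold_change: np.ndarray
    p_value: np.ndarray
    direction: np.ndarray  # sign of the fold change

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "feature": self.feature_ids,
                "log2FC": self.log2_fold_change,
                "p": self.p_value,
                "direction": self.direction,
            }
        )


@dataclass
class ScalerState:
    """Train-fitted log + autoscale parameters (mean/sd on the log scale)."""

    feature_ids: list
    mean: np.ndarray
    sd: np.ndarray
    log_base: float
    pseudocounts: np.ndarray | None = None

    def transform(self, table: FeatureTable) -> FeatureTable:
        """Apply the train-fitted transform to any raw-stage table."""
        if table.stage != "raw":
            raise ValueError("transform expects a raw-stage table")
        idx = [table.feature_ids.index(f) for f in self.feature_ids]
        x = table.matrix[:, idx].copy()
        if self.pseudocounts is not None:
            x = np.where(x > 0, x, self.pseudocounts[None, :])
        if (x <= 0).any():
            raise ValueError("non-positive value with pseudo-counting disabled")
        logged = np.log(x) / np.log(self.log_base)
        scaled = (logged - self.mean[None, :]) / self.sd[None, :]
        return dataclasses.replace(
            table,
            feature_ids=list(self.feature_ids),
            matrix=scaled,
            stage="autoscaled",
        )

    def to_dict(self) -> dict:
        return {
            "feature_ids": list(self.feature_ids),
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "log_base": float(self.log_base),
            "pseudocounts": None if self.pseudocounts is None else self.pseudocounts.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScalerState":
        return cls(
            feature_ids=list(d["feature_ids"]),
            mean=np.asarray(d["mean"], dtype=float),
            sd=np.asarray(d["sd"], dtype=float),
            log_base=float(d["log_base"]),
            pseudocounts=None if d.get("pseudocounts") is None
            else np.asarray(d["pseudocounts"], dtype=float),
        )


def _half_min_positive(col: np.ndarray) -> float:
    pos = col[col > 0]
    return 0.5 * pos.min() if pos.size else 0.0


def volcano_stats(table: FeatureTable) -> VolcanoStats:
    """Per-feature log2 fold change and Student's t p-value.

    Fold changes use raw group means (positive over negative class); when
    a group mean is zero, half the feature's smallest positive value is
    added to both means as a pseudo-count. The t-test runs on log2
    abundances (zeros replaced by the same pseudo-count) with pooled
    variance. Features with zero pooled variance get p = 1.
    """
    if table.stage != "raw":
        raise ValueError("volcano statistics are defined on raw abundances")
    y = table.y
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ValueError("each class needs at least 2 samples")
    pos, neg = table.matrix[y == 1], table.matrix[y == 0]
    p_feat = table.n_features
    l2fc = np.zeros(p_feat)
    pvals = np.ones(p_feat)
    for j in range(p_feat):
        col = table.matrix[:, j]
        pc = _half_min_positive(col)
        m1, m0 = pos[:, j].mean(), neg[:, j].mean()
        if m1 == 0.0 or m0 == 0.0:
            m1, m0 = m1 + pc, m0 + pc
        l2fc[j] = 0.0 if (m1 == 0.0 and m0 == 0.0) else np.log2(m1 / m0)
        a = np.where(pos[:, j] > 0, pos[:, j], pc)
        b = np.where(neg[:, j] > 0, neg[:, j], pc)
        if (a <= 0).any() or (b <= 0).any():  # all-zero feature
            continue
        la, lb = np.log2(a), np.log2(b)
        if la.var(ddof=1) + lb.var(ddof=1) == 0.0:
            pvals[j] = 1.0  # degenerate constant measurement
            continue
        _, pvals[j] = stats.ttest_ind(la, lb, equal_var=True)
    return VolcanoStats(
        feature_ids=list(table.feature_ids),
        log2_fold_change=l2fc,
        p_value=pvals,
        direction=np.sign(l2fc),
    )


def select_features(
    stats_: VolcanoStats,
    fc_threshold: float = 0.5,
    p_threshold: float = 0.05,
    p_adjust: str = "none",
) -> np.ndarray:
    """Boolean retention mask: |log2FC| > fc_threshold AND p < p_threshold.

    Both inequalities are strict. ``p_adjust="bh"`` applies
    Benjamini-Hochberg to the p-values first (off by default; the
    conventional volcano uses raw p-values).
    """
    p = np.asarray(stats_.p_value, dtype=float)
    if p_adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        p = multipletests(p, method="fdr_bh")[1]
    elif p_adjust != "none":
        raise ValueError(f"unknown p_adjust {p_adjust!r}")
    return (np.abs(stats_.log2_fold_change) > fc_threshold) & (p < p_threshold)


def log_autoscale(
    train: FeatureTable,
    test: FeatureTable | None = None,
    base: float = 10.0,
    pseudocount: bool = False,
) -> tuple[FeatureTable, FeatureTable | None, ScalerState]:
    """Log-transform then autoscale, fitting mean/sd on the train table only.

    Centering and unit-variance scaling use the training mean and sd
    (ddof=1) per feature; the test table is transformed with the same
    statistics. Zero-variance training features are dropped from both
    tables with a warning. With ``pseudocount=True`` zeros are replaced
    by half the feature's smallest positive training value.

    The downstream analysis is invariant to ``base``: changing the log
    base rescales each logged feature linearly, which autoscaling absorbs.
    """
    if train.stage != "raw":
        raise ValueError("log_autoscale expects raw-stage tables")
    if base <= 0 or base == 1.0:
        raise ValueError("log base must be positive and != 1")
    x = train.matrix.copy()
    pcs = None
    if pseudocount:
        pcs = np.array([_half_min_positive(x[:, j]) for j in range(x.shape[1])])
        x = np.where(x > 0, x, pcs[None, :])
    if (x <= 0).any():
        raise ValueError("non-positive value with pseudo-counting disabled")
    logged = np.log(x) / np.log(base)
    mean = logged.mean(axis=0)
    sd = logged.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [train.feature_ids[j] for j in np.flatnonzero(~keep)]
        warnings.warn(f"dropping {len(dropped)} zero-variance feature(s): {dropped[:5]}")
    state = ScalerState(
        feature_ids=[train.feature_ids[j] for j in np.flatnonzero(keep)],
        mean=mean[keep],
        sd=sd[keep],
        log_base=float(base),
        pseudocounts=None if pcs is None else pcs[keep],
    )
    train_t = state.transform(train)
    test_t = state.transform(test) if test is not None else None
    return train_t, test_t, state
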