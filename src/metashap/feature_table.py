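"""Metabolomics feature tables: ingestion, round-tripping, and train/test partition.

A feature table is the standard object produced by a metabolomics pipeline
after spectral processing: a samples x features matrix of non-negative
relative abundances plus a binary class label per sample (case/control,
male/female, ...). Rows are samples and columns are features; exports that
store features as rows can be ingested with ``transpose=True``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FeatureTable", "read_feature_table", "write_feature_table", "train_test_split"]

_STAGES = ("raw", "logged", "autoscaled")


@dataclass
class FeatureTable:
    """A samples x features abundance matrix with binary class labels.

    Parameters
    ----------
    sample_ids : list of str
        Opaque sample identifiers, one per row.
    feature_ids : list of str
        Metabolite feature names, one per column.
    matrix : ndarray of shape (n_samples, n_features)
        Abundance values. Non-negative at the ``raw`` stage; arbitrary
        real after log transformation / autoscaling.
    labels : ndarray of shape (n_samples,)
        Class label per sample; exactly two distinct values.
    positive_class : str
        The label value mapped to y = 1.
    stage : {"raw", "logged", "autoscaled"}
        Processing stage tag.
    """

    sample_ids: list
    feature_ids: list
    matrix: np.ndarray
    labels: np.ndarray
    positive_class: str
    stage: str = "raw"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels)
        self.sample_ids = list(self.sample_ids)
        self.feature_ids = list(self.feature_ids)
        self.validate()

    def validate(self) -> None:
        n, p = self.matrix.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} matrix rows")
        if len(self.feature_ids) != p:
            raise ValueError(f"{len(self.feature_ids)} feature ids for {p} matrix columns")
        if self.labels.shape != (n,):
            raise ValueError("labels length must equal the number of samples")
        classes = np.unique(self.labels)
        # a subset produced by splitting may hold one class; more than 2 is never valid
        if classes.size > 2:
            raise ValueError(f"non-binary labels: found {classes.size} classes {list(classes)}")
        if classes.size == 2 and str(self.positive_class) not in {str(c) for c in classes}:
            raise ValueError(f"positive class {self.positive_class!r} not among labels {list(classes)}")
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if not np.isfinite(self.matrix).all():
            raise ValueError("matrix contains non-finite values")
        if self.stage == "raw" and (self.matrix < 0).any():
            raise ValueError("negative abundance in a raw-stage table")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    @property
    def y(self) -> np.ndarray:
        """Binary response: 1 for the positive class, 0 otherwise."""
        return (self.labels.astype(str) == str(self.positive_class)).astype(int)

    @property
    def classes(self) -> tuple:
        """(negative class, positive class)."""
        neg = [c for c in np.unique(self.labels) if str(c) != str(self.positive_class)]
        return (neg[0], self.positive_class)

    def subset_samples(self, idx) -> "FeatureTable":
        idx = np.asarray(idx, dtype=int)
        return dataclasses.replace(
            self,
            sample_ids=[self.sample_ids[i] for i in idx],
            matrix=self.matrix[idx],
            labels=self.labels[idx],
        )

    def subset_features(self, mask_or_idx) -> "FeatureTable":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return dataclasses.replace(
            self,
            feature_ids=[self.feature_ids[i] for i in idx],
            matrix=self.matrix[:, idx],
        )

    def to_frame(self, label_column: str = "label") -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, index=self.sample_ids, columns=self.feature_ids)
        df.insert(0, label_column, self.labels)
        return df


def _infer_sep(path: str, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("csv", "tsv"):
            raise ValueError(f"unknown dialect {dialect!r}")
        return "," if dialect == "csv" else "\t"
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_feature_table(
    path,
    label_column: str,
    dialect: str | None = None,
    positive_class: str | None = None,
    transpose: bool = False,
    missing: str = "error",
) -> FeatureTable:
    """Read a CSV/TSV feature table.

    The first column is taken as the sample identifier; ``label_column``
    names the class column. ``missing="error"`` (default) rejects empty
    cells; ``missing="half_min"`` imputes each missing cell with half the
    feature's minimum positive value, a common metabolomics convention
    for values below the detection limit.

    ``positive_class`` defaults to the lexicographically larger of the two
    labels (so "male" beats "female", "case" beats "control"... document
    the explicit choice in real analyses).
    """
    sep = _infer_sep(path, dialect)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if transpose:
        df = df.T
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found in {list(df.columns)[:5]}...")
    labels = df[label_column].astype(str).to_numpy()
    data = df.drop(columns=[label_column])
    try:
        mat = data.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"unparseable cell in feature columns: {exc}") from exc
    if np.isnan(mat).any():
        if missing == "error":
            bad = int(np.isnan(mat).sum())
            raise ValueError(f"{bad} missing cells (pass missing='half_min' to impute)")
        elif missing == "half_min":
            for j in range(mat.shape[1]):
                col = mat[:, j]
                pos = col[np.isfinite(col) & (col > 0)]
                fill = 0.5 * pos.min() if pos.size else 0.0
                col[np.isnan(col)] = fill
        else:
            raise ValueError(f"unknown missing policy {missing!r}")
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"non-binary labels: found {classes.size} classes {list(classes)}")
    if positive_class is None:
        positive_class = sorted(classes)[-1]
    return FeatureTable(
        sample_ids=[str(s) for s in data.index],
        feature_ids=[str(f) for f in data.columns],
        matrix=mat,
        labels=labels,
        positive_class=str(positive_class),
    )


def write_feature_table(table: FeatureTable, path, label_column: str = "label",
                        dialect: str | None = None) -> None:
    """Write a feature table as CSV/TSV (full float precision round-trip)."""
    sep = _infer_sep(path, dialect)
    table.to_frame(label_column).to_csv(path, sep=sep, float_format="%.17g", index_label="sample_id")


def train_test_split(
    table: FeatureTable,
    test_fraction: float,
    seed: int,
    stratified: bool = True,
) -> tuple[FeatureTable, FeatureTable]:
    """Disjoint train/test partition of a feature table.

    The test size is the nearest integer to ``n * test_fraction`` (half
    rounds up). Stratified mode (default) allocates per-class test counts
    by largest remainder, so class proportions are preserved within one
    sample per class. Deterministic for a fixed seed.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    y = table.y
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("each class needs at least 2 samples to split")
    n = table.n_samples
    n_test = int(np.floor(n * test_fraction + 0.5))
    if n_test == 0 or n_test == n:
        raise ValueError(f"test_fraction={test_fraction} yields an empty train or test set")
    rng = np.random.default_rng(seed)
    if stratified:
        test_idx = []
        classes = list(np.unique(table.labels))
        ideals = {c: (table.labels == c).sum() * test_fraction for c in classes}
        floors = {c: int(np.floor(ideals[c])) for c in classes}
        extra = n_test - sum(floors.values())
        # hand the leftover test slots to the classes with the largest remainders
        order = sorted(classes, key=lambda c: (-(ideals[c] - floors[c]), str(c)))
        counts = dict(floors)
        for c in order[:extra]:
            counts[c] += 1
        for c in classes:
            members = np.flatnonzero(table.labels == c)
            perm = rng.permutation(members.size)
            test_idx.extend(members[perm[: counts[c]]])
        test_idx = np.sort(np.asarray(test_idx, dtype=int))
    else:
        perm = rng.permutation(n)
        test_idx = np.sort(perm[:n_test])
    mask = np.zeros(n, dtype=bool)
    mask[test_idx] = True
    train = table.subset_samples(np.flatnonzero(~mask))
    test = table.subset_samples(np.flatnonzero(mask))
    if min((train.y == 0).sum(), (train.y == 1).sum()) < 1:
        raise ValueError("split left a class empty in the training set")
    return train, test
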