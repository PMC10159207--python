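import numpy as np
import pytest

from metashap import FeatureTable, Tree, TreeEnsemble


@pytest.fixture
def tiny_table():
    """4 samples x 3 features, two classes, handmade values."""
    return FeatureTable(
        sample_ids=["s1", "s2", "s3", "s4"],
        feature_ids=["met_a", "met_b", "met_c"],
        matrix=np.array(
            [
                [1.0, 10.0, 5.0],
                [2.0, 12.0, 6.0],
                [8.0, 11.0, 5.5],
                [9.0, 13.0, 6.5],
            ]
        ),
        labels=np.array(["ctrl", "ctrl", "case", "case"]),
        positive_class="case",
    )


def make_stump(feature=0, threshold=0.0, left_value=1.0, right_value=0.0,
               cover_left=60.0, cover_right=40.0):
    """Single-split tree: x[feature] <= threshold -> left_value."""
    return Tree(
        split_feature=np.array([feature, -1, -1]),
        threshold=np.array([threshold, 0.0, 0.0]),
        left=np.array([1, 0, 0]),
        right=np.array([2, 0, 0]),
        leaf_value=np.array([0.0, left_value, right_value]),
        cover=np.array([cover_left + cover_right, cover_left, cover_right]),
    )


def single_tree_ensemble(tree, n_features=None, output_kind="probability"):
    return TreeEnsemble(
        trees=[tree], tree_weight=np.array([1.0]), base_offset=0.0,
        output_kind=output_kind, n_features=n_features,
    )


@pytest.fixture
def stump_ensemble():
    """Stump with covers 60/40 and leaves 1.0/0.0 on feature 0."""
    return single_tree_ensemble(make_stump(), n_features=2)
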