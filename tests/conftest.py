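import numpy as np
import pytest
from skbio import TreeNode

from microclubs import OtuTable


@pytest.fixture
def three_leaf_tree() -> TreeNode:
    return TreeNode.read(["((A:1,B:1):1,C:2);"])


@pytest.fixture
def star_tree() -> TreeNode:
    return TreeNode.read(["(A:1,B:1,C:1,D:1);"])


@pytest.fixture
def counts_table() -> OtuTable:
    values = np.array([
        [10, 5, 0, 2],
        [8, 0, 3, 1],
        [12, 6, 1, 0],
        [0, 4, 2, 7],
    ], dtype=float)
    return OtuTable(
        ["s1", "s2", "s3", "s4"],
        ["Prevotella.01", "Ralstonia.01", "Halomonas.01", "Streptococcus.02"],
        values,
        kind="counts",
        group_of={"s1": "NS", "s2": "NS", "s3": "FS", "s4": "FS"},
    )


def euclidean_distance_matrix(points: np.ndarray) -> np.ndarray:
    diff = points[:, None, :] - points[None, :, :]
    return np.sqrt((diff ** 2).sum(-1))
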