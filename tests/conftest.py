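import os

os.environ.setdefault("MPLBACKEND", "Agg")

import numpy as np
import pytest

from trajpresence import DataMatrix, Tree


@pytest.fixture
def fig1_tree() -> Tree:
    """The 10-node worked-example MST: a long path with two short twigs."""
    return Tree.from_edges([(1, 2), (2, 3), (3, 4), (4, 5), (5, 6), (6, 7),
                            (7, 8), (3, 9), (5, 10)])


@pytest.fixture
def gaussian_matrix() -> DataMatrix:
    rng = np.random.default_rng(42)
    return DataMatrix.from_array(rng.normal(size=(60, 2)))
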