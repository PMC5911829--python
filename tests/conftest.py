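import logging

import numpy as np
import pytest

from lctax.datasets import CategoricalDataset
from lctax.lca import fit_lca
from lctax.simulate import (LCAGenSpec, TaxonicSpec, binary_item_probs,
                            make_lca_data, make_taxonic)

logging.getLogger("lctax").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def two_class_truth():
    """Well-separated 2-class binary-item generating parameters."""
    return {
        "theta": binary_item_probs(0.8, 0.2, 6),
        "class_probs": np.array([0.35, 0.65]),
        "n_categories": np.full(6, 2),
    }


@pytest.fixture(scope="session")
def two_class_data(two_class_truth):
    spec = LCAGenSpec(
        n_cases=800, n_classes=2, item_probs=two_class_truth["theta"],
        n_categories=two_class_truth["n_categories"],
        class_probs=two_class_truth["class_probs"], seed=424242,
    )
    data, classes = make_lca_data(spec)
    return data, classes


@pytest.fixture(scope="session")
def two_class_fit(two_class_data):
    data, _ = two_class_data
    return fit_lca(data, 2, n_starts=10, seed=7)


@pytest.fixture(scope="session")
def taxonic_indicators():
    mat, groups = make_taxonic(TaxonicSpec(n_cases=600, seed=909))
    return mat, groups


@pytest.fixture
def two_pattern_data():
    """Two perfectly separated binary patterns: (1,1) x 50 and (2,2) x 50."""
    responses = np.vstack([np.ones((50, 2)), np.full((50, 2), 2)]).astype(int)
    return CategoricalDataset(responses)
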