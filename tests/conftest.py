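import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from ahpkit import load_ct_case
from ahpkit.elicitation import JudgmentMatrix
from ahpkit.hierarchy import load_hierarchy

SCALE_GRID = np.array([1 / 5, 1 / 4, 1 / 3, 1 / 2, 1, 2, 3, 4, 5])


@pytest.fixture(scope="session")
def ct_case():
    return load_ct_case()


@pytest.fixture(scope="session")
def ct_hierarchy(ct_case):
    return ct_case.hierarchy


@pytest.fixture
def tiny_hierarchy():
    return load_hierarchy({
        "goal": {"id": "g", "label": "goal"},
        "categories": [
            {"id": "c1", "label": "one",
             "children": [{"id": "a"}, {"id": "b"}, {"id": "c"}]},
            {"id": "c2", "label": "two",
             "children": [{"id": "d"}, {"id": "e"}]},
        ],
    })


def random_reciprocal_matrix(rng, n, from_grid=True):
    """Random positive reciprocal matrix, optionally grid-valued."""
    a = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            v = rng.choice(SCALE_GRID) if from_grid else float(
                np.exp(rng.normal(0, 1)))
            a[i, j] = v
            a[j, i] = 1.0 / v
    return JudgmentMatrix(node_id=f"rand{n}", elements=tuple(
        f"e{k}" for k in range(n)), values=a)
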