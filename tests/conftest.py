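import numpy as np
import pytest

from triagekit import MultiLabelDataset
from triagekit.scheme import PriorityClass, PriorityScheme


@pytest.fixture
def toy_multilabel() -> MultiLabelDataset:
    """Five records over six labels; the classic worked example where the
    label index doubles as the priority rank."""
    vocab = {i: f"label{i}" for i in range(1, 7)}
    rows = [
        ("text1", frozenset({1, 3, 5}), "r1"),
        ("text2", frozenset({1, 2}), "r2"),
        ("text3", frozenset({1}), "r3"),
        ("text4", frozenset({2}), "r4"),
        ("text5", frozenset({3}), "r5"),
    ]
    return MultiLabelDataset(rows, vocab)


@pytest.fixture
def rank_scheme() -> PriorityScheme:
    """Scheme in which diagnosis 'labelK' has priority rank K."""
    return PriorityScheme(
        [PriorityClass(i, f"label{i}", frozenset({f"label{i}"})) for i in range(1, 7)]
    )


def random_prob_batch(rng: np.random.Generator, n_max: int = 5, c_max: int = 4):
    """A random (probs, one-hot targets) batch away from the 0/1 boundary."""
    n = int(rng.integers(1, n_max + 1))
    c = int(rng.integers(2, c_max + 1))
    probs = rng.dirichlet(np.full(c, 2.0), size=n)
    probs = np.clip(probs, 1e-3, None)
    probs /= probs.sum(axis=1, keepdims=True)
    targets = np.zeros((n, c))
    targets[np.arange(n), rng.integers(0, c, size=n)] = 1.0
    return probs, targets
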