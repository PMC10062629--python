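import numpy as np
import pytest

from drmrr import GTDConfig, QueryDocList, RankingDataset, SyntheticSpec, generate_dataset


@pytest.fixture
def config():
    return GTDConfig(K=3, alpha=10.0, beta=2.0, y_hat=2.0, log_base=2.0)


@pytest.fixture
def three_doc_query():
    """Grades (2, 1, 0), already in ideal order."""
    return QueryDocList(
        query_id="q1",
        features=np.array([[1.0, 0.0], [0.0, 1.0], [0.5, 0.5]]),
        labels=np.array([2.0, 1.0, 0.0]),
    )


@pytest.fixture
def small_dataset():
    return generate_dataset(SyntheticSpec(T=8, n_range=(4, 7), p=5, seed=11))


def random_query(rng, n_q, p=4, y_hat=2, ensure_nonzero=True):
    labels = rng.integers(0, y_hat + 1, size=n_q).astype(float)
    if ensure_nonzero and labels.sum() == 0:
        labels[rng.integers(n_q)] = float(rng.integers(1, y_hat + 1))
    return QueryDocList(
        query_id="r", features=rng.standard_normal((n_q, p)), labels=labels
    )
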