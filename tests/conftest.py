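import numpy as np
import pytest

from obulink import CountMatrix, GeneratorConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_matrix():
    return CountMatrix(
        feature_ids=["f1", "f2", "f3"],
        sample_ids=["A", "B", "C", "D"],
        counts=np.array(
            [
                [5, 0, 2, 7],
                [1, 3, 0, 0],
                [10, 10, 10, 10],
            ],
            dtype=float,
        ),
    )


@pytest.fixture
def tiny_config():
    """Small, fast generator configuration for unit tests."""
    return GeneratorConfig(
        n_samples=4,
        n_species=12,
        n_producers=3,
        obus_per_producer=2,
        n_background_obus=3,
        count_depth=5000,
        dispersion=0.1,
        reads_per_obu=(2, 5),
        seed=7,
    )


def random_count_matrix(rng, n_feat=None, n_samp=None, max_count=50):
    n_feat = n_feat or int(rng.integers(1, 8))
    n_samp = n_samp or int(rng.integers(2, 6))
    counts = rng.integers(0, max_count, size=(n_feat, n_samp)).astype(float)
    return CountMatrix(
        [f"f{i}" for i in range(n_feat)],
        [f"s{j}" for j in range(n_samp)],
        counts,
    )
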