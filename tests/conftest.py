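import numpy as np
import pytest

from txsig.datatypes import ExpressionMatrix, GroupAnnotation, RunConfig


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_matrix(rng):
    """13 genes x 18 samples of random log2FC values."""
    genes = tuple(f"G{i:02d}" for i in range(13))
    samples = tuple(f"S{j:02d}" for j in range(18))
    return ExpressionMatrix(genes, samples, rng.normal(size=(13, 18)), "log2fc")


@pytest.fixture
def three_group_annotation():
    mapping = {}
    for grp, n in (("Control", 6), ("BPS", 6), ("DO", 6)):
        for i in range(n):
            mapping[f"S{len(mapping):02d}"] = grp
    return GroupAnnotation(mapping)


@pytest.fixture
def fast_config():
    return RunConfig(cv_repeats=1, random_seed=0)


@pytest.fixture
def blob_matrix(rng):
    """Three well-separated sample blobs (equilateral centers 10 sd apart)."""
    centers = np.array([[0.0, 0.0], [10.0, 0.0], [5.0, 10.0 * np.sqrt(3) / 2]])
    labels = np.repeat([0, 1, 2], 12)
    values = rng.normal(size=(5, 36))
    values[:2, :] += centers[labels].T
    genes = tuple(f"g{i}" for i in range(5))
    samples = tuple(f"s{j}" for j in range(36))
    return ExpressionMatrix(genes, samples, values, "log2fc"), labels
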