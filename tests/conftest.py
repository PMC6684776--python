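import numpy as np
import pytest

from crpkit import datasets, simulate
from crpkit.io import FingerprintMatrix


@pytest.fixture(scope="session")
def peptides():
    """The five bundled CRP marker sequences."""
    return datasets.load_reference_peptides()


@pytest.fixture(scope="session")
def small_benchmark():
    """Reduced-resolution two-class dataset for fast classifier tests."""
    return simulate.default_benchmark(seed=3, n_points=3000, n_per_class=(12, 15))


def subset_matrix(m: FingerprintMatrix, idx) -> FingerprintMatrix:
    idx = np.asarray(idx, dtype=int)
    labels = None if m.class_labels is None else [m.class_labels[i] for i in idx]
    return FingerprintMatrix(m.X[idx], m.axis.copy(), [m.sample_ids[i] for i in idx],
                             labels, class_set=m.class_set)
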