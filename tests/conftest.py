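import numpy as np
import pytest

from zdsearch import (
    build_idistance,
    build_ikernel,
    generate_synthetic_descriptors,
    kmeans_partition,
)


@pytest.fixture(scope="session")
def blob_db():
    """A 500-point, 121-dim descriptor database with blob structure."""
    return generate_synthetic_descriptors(500, dim=121, n_blobs=16, seed=7)


@pytest.fixture(scope="session")
def small_db():
    """A fast low-dimensional database for property-style checks."""
    return generate_synthetic_descriptors(240, dim=24, n_blobs=8, seed=11)


@pytest.fixture(scope="session")
def blob_partition(blob_db):
    return kmeans_partition(blob_db, M=16, seed=0)


@pytest.fixture(scope="session")
def blob_idistance(blob_db, blob_partition):
    return build_idistance(blob_db, blob_partition)


@pytest.fixture(scope="session")
def blob_ikernel(blob_db, blob_partition):
    return build_ikernel(blob_db, blob_partition, g=20)


@pytest.fixture(scope="session")
def query_rows(blob_db):
    rng = np.random.default_rng(42)
    return rng.choice(len(blob_db), size=50, replace=False)
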