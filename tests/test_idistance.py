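"""iDistance keys, index construction, and exact k-NN / range search."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zdsearch import (
    DescriptorDatabase,
    IndexBuildError,
    ParameterError,
    build_idistance,
    evaluation_ratio,
    generate_synthetic_descriptors,
    idistance_key,
    kmeans_partition,
    knn_idistance,
    linear_scan_knn,
    linear_scan_range,
    random_partition,
    range_idistance,
)


def assert_same_hits(a, b):
    assert a.ids == b.ids
    assert np.allclose(a.distances, b.distances)


# ------------------------------------------------------------------------ keys


def test_key_formula():
    assert idistance_key([0.3, 0.4], 0, [0.0, 0.0]) == pytest.approx(0.5)
    O = np.zeros(2)
    p = np.array([0.3, 0.0])
    assert idistance_key(p, 2, O, C=4) == pytest.approx(8.3)


def test_cluster_keys_lie_in_their_interval(small_db):
    part = kmeans_partition(small_db, M=8, seed=0)
    index = build_idistance(small_db, part, C=4)
    for i, c in enumerate(part.clusters):
        keys = i * index.C + index.cluster_d[i]
        assert np.all(keys >= i * index.C - 1e-12)
        assert np.all(keys <= i * index.C + c.dist_max + 1e-12)


# ----------------------------------------------------------------------- build


def test_singleton_clusters_have_keys_at_interval_starts(small_db):
    part = random_partition(small_db, M=len(small_db), seed=0)
    index = build_idistance(small_db, part, C=4)
    assert np.allclose(index.keys, 4.0 * np.arange(len(small_db)))


def test_global_key_sequence_is_sorted(blob_idistance):
    assert np.all(np.diff(blob_idistance.keys) >= 0)


def test_stored_keys_match_brute_force_recomputation(blob_db, blob_idistance):
    index = blob_idistance
    for i, c in enumerate(index.partition.clusters):
        for pos, row in enumerate(index.cluster_idx[i]):
            expected = idistance_key(blob_db.X[row], i, c.center, index.C)
            assert i * index.C + index.cluster_d[i][pos] == pytest.approx(expected)


def test_build_rejects_too_small_C(blob_db, blob_partition):
    worst = max(range(blob_partition.M), key=lambda i: blob_partition.clusters[i].dist_max)
    with pytest.raises(IndexBuildError, match=f"cluster {worst}"):
        build_idistance(blob_db, blob_partition, C=1e-6)


# ------------------------------------------------------------------------- knn


def test_query_point_in_database_is_its_own_nearest(blob_db, blob_idistance):
    res = knn_idistance(blob_idistance, blob_db.X[17], k=1)
    assert res.ids == [blob_db.ids[17]]
    assert res.distances[0] == 0.0


def test_knn_matches_linear_scan_oracle(blob_db, blob_idistance, query_rows):
    for row in query_rows:
        q = blob_db.X[row]
        assert_same_hits(knn_idistance(blob_idistance, q, k=25), linear_scan_knn(blob_db, q, k=25))


def test_full_k_returns_whole_database_sorted(blob_db, blob_idistance):
    q = blob_db.X[3]
    res = knn_idistance(blob_idistance, q, k=len(blob_db))
    oracle = linear_scan_knn(blob_db, q, k=len(blob_db))
    assert_same_hits(res, oracle)
    assert np.all(np.diff(res.distances) >= 0)


@pytest.mark.parametrize("k", [0, 501])
def test_knn_rejects_out_of_range_k(blob_idistance, k):
    with pytest.raises(ParameterError):
        knn_idistance(blob_idistance, np.zeros(121), k=k)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.integers(1, 40))
def test_knn_exactness_property(seed, k):
    db = generate_synthetic_descriptors(60, dim=6, n_blobs=4, seed=seed)
    index = build_idistance(db, kmeans_partition(db, M=5, seed=seed), C=8)
    q = np.random.default_rng(seed + 1).uniform(0, 1, size=6)
    assert_same_hits(knn_idistance(index, q, k=k, delta_r=0.15), linear_scan_knn(db, q, k=k))


# ----------------------------------------------------------------------- range


def test_range_zero_theta_is_empty(blob_db, blob_idistance):
    assert len(range_idistance(blob_idistance, blob_db.X[0], theta=0.0)) == 0


def test_range_large_theta_returns_everything(blob_db, blob_idistance):
    res = range_idistance(blob_idistance, blob_db.X[0], theta=1e6)
    assert len(res) == len(blob_db)


@pytest.mark.parametrize("theta", [0.5, 1.0, 2.0])
def test_range_matches_linear_scan_oracle(blob_db, blob_idistance, query_rows, theta):
    for row in query_rows:
        q = blob_db.X[row]
        assert_same_hits(range_idistance(blob_idistance, q, theta), linear_scan_range(blob_db, q, theta))


# -------------------------------------------------------------- instrumentation


def test_evaluation_ratio_at_most_one_and_prunes_on_blobs(blob_db, blob_idistance, query_rows):
    ratios = []
    for row in query_rows:
        res = knn_idistance(blob_idistance, blob_db.X[row], k=10)
        assert res.n_distance_evaluations <= res.n_db
        ratios.append(evaluation_ratio(res))
    assert np.mean(ratios) < 1.0


def test_evaluation_ratio_monotone_in_k_and_theta(blob_db, blob_idistance, query_rows):
    mean_ratio_k = [
        np.mean([evaluation_ratio(knn_idistance(blob_idistance, blob_db.X[r], k)) for r in query_rows])
        for k in (1, 10, 50)
    ]
    assert mean_ratio_k == sorted(mean_ratio_k)
    mean_ratio_t = [
        np.mean([evaluation_ratio(range_idistance(blob_idistance, blob_db.X[r], t)) for r in query_rows])
        for t in (0.25, 0.5, 1.0)
    ]
    assert mean_ratio_t == sorted(mean_ratio_t)


def test_smaller_delta_r_on_halving_ladder_never_costs_more(blob_db, blob_idistance, query_rows):
    means = []
    for delta_r in (0.8, 0.4, 0.2, 0.1):
        means.append(
            np.mean(
                [
                    evaluation_ratio(knn_idistance(blob_idistance, blob_db.X[r], 25, delta_r=delta_r))
                    for r in query_rows
                ]
            )
        )
    assert means == sorted(means, reverse=True)
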