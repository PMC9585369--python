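"""OPTICS / DBSCAN: frozen small-instance oracles, reference cross-checks
and structural invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import cdist

from instarcluster import (
    GeneratorConfig,
    NeighborhoodParams,
    UNDEFINED,
    dbscan,
    default_extraction_radius,
    extract_clusters_reachability,
    extract_clusters_xi,
    generate_instar_dataset,
    generated_truth,
    adjusted_rand_index,
    knn_distances,
    optics_order,
)


def brute_dbscan(X, eps, min_pts):
    """Independent DBSCAN oracle: explicit core set + BFS expansion.

    Returns (labels, is_core); labels 0 = noise, clusters numbered by
    discovery order (not canonicalized).
    """
    D = cdist(X, X)
    is_core = (D <= eps).sum(axis=1) >= min_pts
    labels = np.zeros(len(X), dtype=int)
    cid = 0
    for p in range(len(X)):
        if labels[p] or not is_core[p]:
            continue
        cid += 1
        queue = [p]
        labels[p] = cid
        while queue:
            q = queue.pop()
            if not is_core[q]:
                continue
            for o in np.flatnonzero(D[q] <= eps):
                if labels[o] == 0:
                    labels[o] = cid
                    queue.append(int(o))
    return labels, is_core


def same_core_partition(labels_a, labels_b, is_core):
    """Core points must induce identical groupings and noise sets."""
    core_a, core_b = labels_a[is_core], labels_b[is_core]
    if not np.array_equal(core_a == 0, core_b == 0):
        return False
    keep = core_a != 0
    return adjusted_rand_index(core_a[keep], core_b[keep]) == 1.0


class TestKnnDistances:
    def test_two_nn_distances_of_seven_point_line(self):
        # exhaustive pairwise-distance oracle, frozen
        X = np.array([0, 0.1, 0.2, 5, 5.1, 5.2, 10.0]).reshape(-1, 1)
        prof = knn_distances(X, k=2)
        assert np.allclose(prof.per_point,
                           [0.2, 0.1, 0.2, 0.2, 0.1, 0.2, 4.9])
        assert np.allclose(prof.sorted_distances,
                           [0.1, 0.1, 0.2, 0.2, 0.2, 0.2, 4.9])

    def test_equally_spaced_points_all_distances_equal_step(self):
        X = (0.37 * np.arange(9.0)).reshape(-1, 1)
        prof = knn_distances(X, k=1)
        assert np.allclose(prof.per_point, 0.37)

    def test_k_out_of_range_raises(self):
        X = np.zeros((3, 1))
        with pytest.raises(ValueError):
            knn_distances(X, k=3)

    def test_knee_sits_between_cluster_and_gap_scales(self):
        X = np.array([0, 0.1, 0.2, 5, 5.1, 5.2, 10.0]).reshape(-1, 1)
        prof = knn_distances(X, k=2)
        assert 0.1 <= prof.knee <= 4.9


class TestOpticsOrder:
    def test_six_point_worked_example(self, six_points):
        # brute-force seed-queue walk, frozen: order follows the first
        # triplet, jumps the 8-gap, then the second triplet
        res = optics_order(six_points, NeighborhoodParams(np.inf, 2))
        assert list(res.order) == [0, 1, 2, 3, 4, 5]
        assert np.allclose(res.core_distance, 1.0)
        r = res.reachability[res.order]
        assert r[0] == UNDEFINED
        assert np.allclose(r[1:], [1, 1, 8, 1, 1])

    def test_sparse_data_everything_undefined(self):
        X = np.array([[0.0], [5.0], [9.0]])
        res = optics_order(X, NeighborhoodParams(np.inf, 5))
        assert np.all(res.core_distance == UNDEFINED)
        assert np.all(res.reachability == UNDEFINED)

    def test_order_is_permutation_and_batch_starts_undefined(
            self, default_optics):
        res = default_optics
        assert sorted(res.order) == list(range(240))
        first = res.order[0]
        assert res.reachability[first] == UNDEFINED
        assert res.predecessor[first] == -1

    def test_reachability_bounded_below_by_predecessor_core(
            self, default_optics):
        res = default_optics
        for p in range(len(res.order)):
            q = res.predecessor[p]
            if q >= 0 and np.isfinite(res.reachability[p]):
                d = np.linalg.norm(res.features[p] - res.features[q])
                assert res.reachability[p] >= res.core_distance[q] - 1e-12
                assert np.isclose(
                    res.reachability[p],
                    max(res.core_distance[q], d), rtol=1e-10)

    def test_default_table_reachability_has_four_valleys(
            self, default_optics, default_table):
        part = extract_clusters_reachability(
            default_optics, default_extraction_radius(default_table, 5))
        assert part.n_clusters == 4
        assert part.sizes_in_label_order() == (69, 42, 35, 94)


class TestThresholdExtraction:
    def test_six_point_example_two_clusters(self, six_points):
        res = optics_order(six_points, NeighborhoodParams(np.inf, 2))
        part = extract_clusters_reachability(res, 2.0)
        assert list(part.labels) == [1, 1, 1, 2, 2, 2]

    def test_threshold_below_all_core_distances_gives_all_noise(
            self, six_points):
        res = optics_order(six_points, NeighborhoodParams(np.inf, 2))
        part = extract_clusters_reachability(res, 0.5)
        assert part.n_clusters == 0
        assert part.is_noise.all()

    def test_eps_cl_above_ordering_radius_rejected(self, six_points):
        res = optics_order(six_points, NeighborhoodParams(2.0, 2))
        with pytest.raises(ValueError):
            extract_clusters_reachability(res, 3.0)


class TestXiExtraction:
    def test_two_blobs_flatten_to_two_clusters(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.5, (40, 2)),
                       rng.normal(8, 0.5, (40, 2))])
        res = optics_order(X, NeighborhoodParams(np.inf, 5))
        xc = extract_clusters_xi(res, 0.05)
        assert xc.partition.n_clusters == 2
        # oracle: threshold extraction at the inter-blob valley
        flat = extract_clusters_reachability(res, 2.0)
        keep = ~xc.partition.is_noise
        assert adjusted_rand_index(xc.partition.labels[keep],
                                   flat.labels[keep]) == 1.0

    def test_flat_profile_single_cluster(self):
        X = np.arange(30, dtype=float).reshape(-1, 1)
        res = optics_order(X, NeighborhoodParams(np.inf, 3))
        assert extract_clusters_xi(res, 0.05).partition.n_clusters == 1

    def test_default_table_four_instars(self, default_optics):
        xc = extract_clusters_xi(default_optics, 0.05)
        assert xc.partition.n_clusters == 4

    def test_invalid_xi_rejected(self, default_optics):
        with pytest.raises(ValueError):
            extract_clusters_xi(default_optics, 1.5)


class TestDbscan:
    def test_six_point_example(self, six_points):
        part = dbscan(six_points, NeighborhoodParams(2.0, 2))
        assert list(part.labels) == [1, 1, 1, 2, 2, 2]

    def test_eps_below_min_pairwise_distance_all_noise(self, six_points):
        part = dbscan(six_points, NeighborhoodParams(0.5, 2))
        assert part.is_noise.all()

    def test_default_table_reference_parameters(self, default_table):
        part = dbscan(default_table, NeighborhoodParams(0.04, 4))
        assert part.n_clusters == 4
        assert part.sizes_in_label_order() == (69, 42, 35, 94)

    def test_infinite_eps_rejected(self, six_points):
        with pytest.raises(ValueError):
            dbscan(six_points, NeighborhoodParams(np.inf, 2))

    def test_matches_sklearn_on_default_table(self, default_table):
        sklearn_cluster = pytest.importorskip("sklearn.cluster")
        ref = sklearn_cluster.DBSCAN(eps=0.04, min_samples=4).fit(
            default_table.features)
        mine = dbscan(default_table, NeighborhoodParams(0.04, 4))
        assert np.array_equal(mine.is_noise, ref.labels_ == -1)
        keep = ~mine.is_noise
        assert adjusted_rand_index(mine.labels[keep],
                                   ref.labels_[keep]) == 1.0


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    data=st.lists(
        st.tuples(st.floats(-5, 5), st.floats(-5, 5)).map(
            lambda t: (round(t[0], 3), round(t[1], 3))),
        min_size=2, max_size=25),
    eps=st.floats(0.05, 3.0),
    min_pts=st.integers(2, 5),
)
def test_threshold_extraction_equals_dbscan_on_core_points(
        data, eps, min_pts):
    """OPTICS ordered at eps=inf then cut at eps_cl is DBSCAN at eps_cl:
    identical core-point grouping and core noise set (border points may
    attach to either adjacent cluster)."""
    X = np.array(sorted(set(data)), dtype=float)
    if len(X) < 2:
        return
    res = optics_order(X, NeighborhoodParams(np.inf, min_pts))
    mine = extract_clusters_reachability(res, eps)
    oracle, is_core = brute_dbscan(X, eps, min_pts)
    assert same_core_partition(mine.labels, oracle, is_core)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_core_distance_monotone_in_min_pts(seed):
    """Raising minPts never shrinks any defined core-distance."""
    X = np.random.default_rng(seed).uniform(size=(20, 2))
    prev = optics_order(X, NeighborhoodParams(np.inf, 2)).core_distance
    for mp in (3, 5, 8):
        cur = optics_order(X, NeighborhoodParams(np.inf, mp)).core_distance
        assert np.all(cur >= prev - 1e-12)
        prev = cur


def test_partition_invariant_to_row_shuffling(default_table):
    rng = np.random.default_rng(4)
    perm = rng.permutation(len(default_table))
    shuffled = type(default_table)(
        default_table.data.iloc[perm].reset_index(drop=True))
    a = dbscan(default_table, NeighborhoodParams(0.04, 4))
    b = dbscan(shuffled, NeighborhoodParams(0.04, 4))
    assert np.array_equal(a.labels[perm], b.labels)


@pytest.mark.parametrize("rho", [0.5, 0.8])
@pytest.mark.parametrize("seed", [2, 9])
def test_exact_instar_recovery_across_correlation_levels(rho, seed):
    """OPTICS with the automatic extraction radius recovers the exact
    generated group sizes at either inter-feature correlation."""
    table = generate_instar_dataset(
        GeneratorConfig(seed=seed, inter_feature_correlation=rho))
    res = optics_order(table, NeighborhoodParams(np.inf, 5))
    part = extract_clusters_reachability(
        res, default_extraction_radius(table, 5))
    assert part.sizes_in_label_order() == (69, 42, 35, 94)
    assert adjusted_rand_index(part, generated_truth(table)) == 1.0
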