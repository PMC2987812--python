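"""DBSCAN semantics, k-dist machinery, validity indexes, eps consensus."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from dockclust import (
    ClusteringParams,
    clustering_quality,
    dbscan,
    epsilon_candidates,
    finalize_labels,
    kdist_profile,
    select_epsilon,
)
from dockclust.errors import InputError


def brute_force_dbscan(X, k, eps):
    """Transitive-closure oracle: eps-neighborhood graph over core points,
    connected components, then border attachment (any adjacent core's
    component).  Returns (core_mask, core_component_id, noise_mask)."""
    D = squareform(pdist(X))
    n = len(X)
    counts = (D <= eps).sum(axis=1)
    core = counts >= k
    adj = (D <= eps) & np.outer(core, core)
    n_comp, comp = connected_components(csr_matrix(adj), directed=False)
    comp = np.where(core, comp, -1)
    noise = np.ones(n, dtype=bool)
    noise[core] = False
    for i in range(n):
        if not core[i] and np.any(core & (D[i] <= eps)):
            noise[i] = False
    return core, comp, noise


def partition_of(labels, subset):
    """Set-of-frozensets partition of `subset` induced by labels."""
    groups = {}
    for i in subset:
        groups.setdefault(labels[i], []).append(i)
    return {frozenset(v) for v in groups.values()}


def test_single_dense_blob():
    X = np.zeros((20, 2))
    labels = dbscan(X, ClusteringParams(k=15, eps=0.5))
    assert (labels == 1).all()


def test_no_core_points_all_noise():
    X = np.arange(20, dtype=float).reshape(-1, 1) * 10.0
    labels = dbscan(X, ClusteringParams(k=3, eps=1.0))
    assert (labels == 0).all()


def test_n_below_k_warns_all_noise():
    X = np.zeros((5, 2))
    with pytest.warns(UserWarning, match="no core point"):
        labels = dbscan(X, ClusteringParams(k=15, eps=1.0))
    assert (labels == 0).all()


def test_two_blobs_match_oracle():
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(0, 0.05, (30, 2)), rng.normal(3, 0.05, (30, 2))])
    labels = dbscan(X, ClusteringParams(k=4, eps=0.15))
    core, comp, noise = brute_force_dbscan(X, 4, 0.15)
    assert np.array_equal(labels == 0, noise)
    assert partition_of(labels, np.flatnonzero(core)) == partition_of(
        comp, np.flatnonzero(core)
    )
    assert labels.max() == 2


def test_oracle_equivalence_random_instances():
    """Core partition, noise set and border validity against the
    transitive-closure oracle on many random instances."""
    rng = np.random.default_rng(1234)
    for trial in range(50):
        n = int(rng.integers(20, 200))
        dim = int(rng.integers(1, 4))
        X = rng.uniform(0, 4, size=(n, dim))
        k = int(rng.integers(3, 7))
        eps = float(rng.uniform(0.1, 0.8))
        labels = dbscan(X, ClusteringParams(k=k, eps=eps))
        core, comp, noise = brute_force_dbscan(X, k, eps)
        core_idx = np.flatnonzero(core)
        assert np.array_equal(labels == 0, noise), f"trial {trial}"
        assert partition_of(labels, core_idx) == partition_of(comp, core_idx), (
            f"trial {trial}"
        )
        # every labeled border point sits within eps of a core point of its cluster
        D = squareform(pdist(X))
        for i in np.flatnonzero((labels > 0) & ~core):
            same = np.flatnonzero((labels == labels[i]) & core)
            assert np.min(D[i, same]) <= eps, f"trial {trial}, border {i}"


def test_dbscan_matches_sklearn_on_core_points():
    from sklearn.cluster import DBSCAN as SkDBSCAN
    from sklearn.metrics import adjusted_rand_score

    rng = np.random.default_rng(7)
    X = np.vstack(
        [rng.normal(c, 0.2, (40, 3)) for c in ((0, 0, 0), (3, 0, 0), (0, 3, 3))]
    )
    k, eps = 5, 0.5
    ours = dbscan(X, ClusteringParams(k=k, eps=eps))
    sk = SkDBSCAN(eps=eps, min_samples=k).fit(X)
    core = np.zeros(len(X), bool)
    core[sk.core_sample_indices_] = True
    assert np.array_equal(ours == 0, sk.labels_ == -1)
    assert adjusted_rand_score(ours[core], sk.labels_[core]) == 1.0


def test_noise_monotone_in_eps():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(120, 3))
    params = [ClusteringParams(k=6, eps=e) for e in np.linspace(0.2, 2.0, 10)]
    noise = [(dbscan(X, p) == 0).sum() for p in params]
    assert all(a >= b for a, b in zip(noise, noise[1:]))


def test_kdist_profile_hand_countable():
    X = np.array([[0.0], [1.0], [3.0]])
    assert np.allclose(kdist_profile(X, 1), [1.0, 1.0, 2.0])
    assert np.allclose(kdist_profile(np.zeros((6, 2)), 3), np.zeros(6))
    with pytest.raises(InputError):
        kdist_profile(X, 3)


def test_kdist_profile_matches_brute_force():
    rng = np.random.default_rng(10)
    X = rng.normal(size=(100, 4))
    k = 7
    D = squareform(pdist(X))
    expected = np.sort(np.array([np.sort(D[i])[k] for i in range(100)]))
    assert np.allclose(kdist_profile(X, k), expected, atol=1e-12)


def test_epsilon_candidates_nearest_rank_percentiles():
    profile = np.arange(1.0, 101.0)
    cands = epsilon_candidates(profile)
    assert np.array_equal(cands, np.arange(5.0, 100.0, 5.0))


def test_epsilon_candidates_degenerate_profiles():
    assert np.array_equal(epsilon_candidates(np.full(10, 2.5)), [2.5])
    assert np.array_equal(epsilon_candidates(np.array([0, 0, 0, 2.0])), [2.0])
    with pytest.warns(UserWarning, match="zero"):
        cands = epsilon_candidates(np.zeros(5))
    assert len(cands) == 1 and cands[0] > 0


SIX_POINTS = np.array(
    [[0, 0], [0, 1], [1, 0], [10, 10], [10, 11], [11, 10]], dtype=float
)
SIX_LABELS = np.array([1, 1, 1, 2, 2, 2])


def independent_indexes(X, y):
    """Direct formula evaluation, written independently of the package."""
    groups = sorted(set(y))
    members = [np.flatnonzero(y == g) for g in groups]
    cents = [X[m].mean(axis=0) for m in members]
    # Davies-Bouldin
    S = [np.mean([np.linalg.norm(X[i] - c) for i in m]) for m, c in zip(members, cents)]
    db_terms = []
    for i in range(len(groups)):
        db_terms.append(
            max(
                (S[i] + S[j]) / np.linalg.norm(cents[i] - cents[j])
                for j in range(len(groups))
                if j != i
            )
        )
    db = np.mean(db_terms)
    # Calinski-Harabasz
    grand = X.mean(axis=0)
    tb = sum(len(m) * np.linalg.norm(c - grand) ** 2 for m, c in zip(members, cents))
    tw = sum(
        np.linalg.norm(X[i] - c) ** 2 for m, c in zip(members, cents) for i in m
    )
    ch = (tb / (len(groups) - 1)) / (tw / (len(X) - len(groups)))
    # C-index
    pairs = [
        (np.linalg.norm(X[i] - X[j]), y[i] == y[j])
        for i in range(len(X))
        for j in range(i + 1, len(X))
    ]
    d = sorted(p[0] for p in pairs)
    sw = sum(p[0] for p in pairs if p[1])
    nw = sum(1 for p in pairs if p[1])
    cidx = (sw - sum(d[:nw])) / (sum(d[-nw:]) - sum(d[:nw]))
    # Silhouette
    sils = []
    for i in range(len(X)):
        own = [j for j in range(len(X)) if y[j] == y[i] and j != i]
        a = np.mean([np.linalg.norm(X[i] - X[j]) for j in own])
        b = min(
            np.mean([np.linalg.norm(X[i] - X[j]) for j in np.flatnonzero(y == g)])
            for g in groups
            if g != y[i]
        )
        sils.append((b - a) / max(a, b))
    return -db, ch, -cidx, float(np.mean(sils))


def test_quality_indexes_match_direct_evaluation():
    q = clustering_quality(SIX_POINTS, SIX_LABELS)
    expected = independent_indexes(SIX_POINTS, SIX_LABELS)
    assert q.as_tuple() == pytest.approx(expected, abs=1e-9)


def test_quality_indexes_cross_checked_against_sklearn():
    from sklearn.metrics import (
        calinski_harabasz_score,
        davies_bouldin_score,
        silhouette_score,
    )

    rng = np.random.default_rng(3)
    X = np.vstack([rng.normal(c, 0.5, (25, 3)) for c in (0, 4, 8)])
    y = np.repeat([1, 2, 3], 25)
    q = clustering_quality(X, y)
    assert -q.davies_bouldin_neg == pytest.approx(davies_bouldin_score(X, y), abs=1e-9)
    assert q.calinski_harabasz == pytest.approx(calinski_harabasz_score(X, y), abs=1e-6)
    assert q.silhouette == pytest.approx(silhouette_score(X, y), abs=1e-9)


def test_quality_degenerate_perfect_clusters():
    X = np.array([[0, 0], [0, 0], [9, 9], [9, 9]], dtype=float)
    y = np.array([1, 1, 2, 2])
    q = clustering_quality(X, y)
    assert q.silhouette == pytest.approx(1.0)
    assert q.davies_bouldin_neg == pytest.approx(0.0)
    assert q.c_index_neg == pytest.approx(0.0)


def test_single_cluster_is_ineligible():
    q = clustering_quality(SIX_POINTS, np.ones(6, dtype=int))
    assert not q.eligible
    q2 = clustering_quality(SIX_POINTS, np.array([1, 1, 1, 0, 0, 0]))
    assert not q2.eligible


def test_noise_as_group_changes_only_noisy_labelings():
    y = np.array([1, 1, 1, 2, 2, 0])
    incl = clustering_quality(SIX_POINTS, y, noise_as_group=True)
    excl = clustering_quality(SIX_POINTS, y, noise_as_group=False)
    assert incl.as_tuple() != excl.as_tuple()
    both = [
        clustering_quality(SIX_POINTS, SIX_LABELS, noise_as_group=f)
        for f in (True, False)
    ]
    assert both[0].as_tuple() == both[1].as_tuple()


def test_select_epsilon_recovers_planted_blobs():
    from sklearn.metrics import adjusted_rand_score

    rng = np.random.default_rng(17)
    X = np.vstack([rng.normal(0, 0.1, (40, 2)), rng.normal(5, 0.1, (40, 2))])
    truth = np.repeat([1, 2], 40)
    params = ClusteringParams(k=5, min_cluster_size=5)
    cands = epsilon_candidates(kdist_profile(X, 5))
    eps, evals = select_epsilon(X, cands, params)
    labels = finalize_labels(dbscan(X, ClusteringParams(k=5, eps=eps, min_cluster_size=5)), params)
    assert labels.max() == 2
    assert adjusted_rand_score(truth, labels) == 1.0
    assert sum(e.chosen for e in evals) == 1


def test_select_epsilon_single_candidate_and_ties():
    rng = np.random.default_rng(2)
    X = np.vstack([rng.normal(0, 0.05, (20, 2)), rng.normal(4, 0.05, (20, 2))])
    params = ClusteringParams(k=4)
    eps, evals = select_epsilon(X, [0.3], params)
    assert eps == 0.3 and evals[0].chosen
    # two radii that induce the identical labeling tie; the smaller wins
    eps2, evals2 = select_epsilon(X, [0.3, 0.35], params)
    l1 = dbscan(X, ClusteringParams(k=4, eps=0.3))
    l2 = dbscan(X, ClusteringParams(k=4, eps=0.35))
    assert np.array_equal(l1, l2)
    assert eps2 == 0.3


def test_select_epsilon_fallback_when_nothing_eligible():
    X = np.arange(30, dtype=float).reshape(-1, 1) * 5
    params = ClusteringParams(k=10)
    with pytest.warns(UserWarning, match="non-noise"):
        eps, evals = select_epsilon(X, [0.1, 0.2], params)
    assert eps in (0.1, 0.2)
    assert all(not e.eligible for e in evals)


def test_finalize_discards_small_and_orders_by_size():
    labels = np.array([1] * 40 + [2] * 14 + [3] * 20)
    out = finalize_labels(labels, ClusteringParams(min_cluster_size=15))
    assert (out[:40] == 1).all()
    assert (out[40:54] == 0).all()  # 14-member cluster discarded
    assert (out[54:] == 2).all()


def test_finalize_all_small_and_size_ties():
    labels = np.array([1] * 5 + [2] * 6)
    assert (finalize_labels(labels, ClusteringParams(min_cluster_size=15)) == 0).all()
    # equal sizes: label 1 goes to the cluster whose first member comes first
    tied = np.array([2] * 20 + [1] * 20)
    out = finalize_labels(tied, ClusteringParams(min_cluster_size=15))
    assert (out[:20] == 1).all() and (out[20:] == 2).all()


def test_params_validation():
    with pytest.raises(InputError):
        ClusteringParams(k=1)
    with pytest.raises(InputError):
        ClusteringParams(eps=0.0)
    with pytest.raises(InputError):
        dbscan(np.zeros((20, 2)), ClusteringParams(k=4))  # eps unset
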