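"""K-modes, Gower dissimilarity, hierarchical clustering and silhouettes."""

import itertools

import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster

from sonopattern.clusters import (
    average_silhouette,
    gower_dissimilarity,
    hierarchical_fit,
    kmodes_fit,
)


def test_gower_counting_identities():
    a = np.zeros((1, 23), dtype=int)
    b = a.copy()
    b[0, :7] = 1
    c = np.ones((1, 23), dtype=int)
    x = np.vstack([a, a, b, c])
    d = gower_dissimilarity(x)
    assert d[0, 1] == 0.0
    assert d[0, 2] == pytest.approx(7 / 23)
    assert d[0, 3] == pytest.approx(1.0)
    assert np.allclose(d, d.T) and np.all(np.diag(d) == 0)


def test_gower_triangle_inequality_random():
    rng = np.random.default_rng(1)
    x = rng.integers(0, 3, size=(25, 8))
    d = gower_dissimilarity(x)
    for i, j, k in itertools.combinations(range(25), 3):
        assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


def test_kmodes_recovers_pure_blocks_and_k1_closed_form():
    block_a = np.tile([0, 0, 1, 2], (10, 1))
    block_b = np.tile([1, 1, 0, 0], (8, 1))
    x = np.vstack([block_a, block_b])
    sol = kmodes_fit(x, 2, seed=0)
    assert sol.cost == 0.0
    labels_a = set(sol.labels[:10])
    labels_b = set(sol.labels[10:])
    assert len(labels_a) == 1 and len(labels_b) == 1 and labels_a != labels_b

    rng = np.random.default_rng(2)
    y = rng.integers(0, 3, size=(30, 5))
    sol1 = kmodes_fit(y, 1, seed=0)
    modes = np.array([np.bincount(y[:, j]).argmax() for j in range(5)])
    assert sol1.cost == pytest.approx(np.sum(y != modes))


def test_kmodes_matches_bruteforce_partition_optimum():
    rng = np.random.default_rng(4)
    x = rng.integers(0, 2, size=(6, 3))
    sol = kmodes_fit(x, 2, n_init=30, seed=0)

    def partition_cost(assign):
        cost = 0
        for c in (0, 1):
            rows = x[assign == c]
            if len(rows) == 0:
                return np.inf
            for j in range(3):
                counts = np.bincount(rows[:, j], minlength=2)
                cost += len(rows) - counts.max()
        return cost

    best = min(
        partition_cost(np.array(a)) for a in itertools.product([0, 1], repeat=6)
        if len(set(a)) == 2
    )
    assert sol.cost == best


def test_kmodes_input_validation():
    x = np.tile([0, 1], (5, 1))  # a single distinct row
    with pytest.raises(ValueError):
        kmodes_fit(x, 2)
    with pytest.raises(ValueError):
        kmodes_fit(x, 0)


def test_hierarchical_block_recovery_and_degenerate_cut():
    block_a = np.tile([0, 0, 0, 0], (6, 1))
    block_b = np.tile([2, 2, 2, 2], (5, 1))
    d = gower_dissimilarity(np.vstack([block_a, block_b]))
    for link in ("average", "complete", "single"):
        sol = hierarchical_fit(d, 2, linkage_method=link)
        assert len(set(sol.labels[:6])) == 1
        assert len(set(sol.labels[6:])) == 1
        assert sol.labels[0] != sol.labels[-1]
    soln = hierarchical_fit(d, 11)
    assert len(np.unique(soln.labels)) == 11  # every point its own cluster
    with pytest.raises(ValueError):
        hierarchical_fit(d, 12)


def test_hierarchical_merge_order_matches_manual_trace():
    # hand-built 5-point dissimilarity: (0,1) closest, then (3,4), then {0,1}+2
    d = np.array(
        [
            [0.0, 0.1, 0.3, 0.9, 0.9],
            [0.1, 0.0, 0.3, 0.9, 0.9],
            [0.3, 0.3, 0.0, 0.8, 0.8],
            [0.9, 0.9, 0.8, 0.0, 0.2],
            [0.9, 0.9, 0.8, 0.2, 0.0],
        ]
    )
    sol = hierarchical_fit(d, 2, linkage_method="average")
    tree = sol.merge_tree
    assert set(tree[0, :2]) == {0.0, 1.0} and tree[0, 2] == pytest.approx(0.1)
    assert set(tree[1, :2]) == {3.0, 4.0} and tree[1, 2] == pytest.approx(0.2)
    assert tree[2, 2] == pytest.approx(0.3)  # average d({0,1},{2})
    assert list(sol.labels[:3]) == [sol.labels[0]] * 3
    assert sol.labels[3] == sol.labels[4] != sol.labels[0]


def test_silhouette_identities_and_manual_value():
    block_a = np.tile([0, 0], (4, 1))
    block_b = np.tile([1, 1], (4, 1))
    d = gower_dissimilarity(np.vstack([block_a, block_b]))
    labels = np.repeat([1, 2], 4)
    assert average_silhouette(labels, d) == pytest.approx(1.0)
    # label permutation invariance
    assert average_silhouette(3 - labels, d) == pytest.approx(1.0)

    # N=5 manual computation
    d5 = np.array(
        [
            [0.0, 0.2, 0.4, 0.8, 0.9],
            [0.2, 0.0, 0.3, 0.7, 0.8],
            [0.4, 0.3, 0.0, 0.6, 0.7],
            [0.8, 0.7, 0.6, 0.0, 0.1],
            [0.9, 0.8, 0.7, 0.1, 0.0],
        ]
    )
    lab = np.array([1, 1, 1, 2, 2])
    s = []
    for i in range(5):
        own = [j for j in range(5) if lab[j] == lab[i] and j != i]
        other = [j for j in range(5) if lab[j] != lab[i]]
        a = np.mean(d5[i, own])
        b = np.mean(d5[i, other])
        s.append((b - a) / max(a, b))
    assert average_silhouette(lab, d5) == pytest.approx(np.mean(s), abs=1e-12)
    with pytest.raises(ValueError):
        average_silhouette(np.ones(5, dtype=int), d5)


def test_silhouette_near_zero_for_random_labels_on_structureless_data():
    rng = np.random.default_rng(9)
    vals = []
    for rep in range(30):
        x = rng.integers(0, 2, size=(40, 10))
        d = gower_dissimilarity(x)
        labels = rng.integers(1, 3, size=40)
        vals.append(average_silhouette(labels, d))
    assert abs(np.mean(vals)) < 0.02


def test_kmodes_deterministic_given_seed(emul_cohort):
    x = emul_cohort.features
    a = kmodes_fit(x, 2, seed=5)
    b = kmodes_fit(x, 2, seed=5)
    assert np.array_equal(a.labels, b.labels) and a.cost == b.cost
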