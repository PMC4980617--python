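"""Prevalence, eigenvector centrality, conditional probability, bootstrap."""

import numpy as np
import pytest
from scipy import stats

from coevonet import (
    bootstrap_bands,
    bootstrap_ci,
    conditional_smoking_probability,
    eigenvector_centrality,
    prevalence,
)


@pytest.mark.parametrize(
    "states, expected",
    [([1, 1, 1], 1.0), ([1, 0, 1, 0], 0.5), ([1] * 20 + [0] * 180, 0.10)],
)
def test_prevalence(states, expected):
    assert prevalence(states) == pytest.approx(expected)


def complete(n):
    return ~np.eye(n, dtype=bool)


def star(leaves):
    adj = np.zeros((leaves + 1, leaves + 1), dtype=bool)
    adj[0, 1:] = adj[1:, 0] = True
    return adj


def test_evc_complete_graph_is_uniform():
    assert np.allclose(eigenvector_centrality(complete(5)), 1.0)


def test_evc_star_leaf_ratio():
    # leading eigenvector of a k-star: leaf/centre = 1/sqrt(k)
    v = eigenvector_centrality(star(4))
    assert v[0] == pytest.approx(1.0)
    assert np.allclose(v[1:], 0.5, atol=1e-10)


def test_evc_power_iteration_oracle(rng):
    adj = np.triu(rng.random((15, 15)) < 0.35, 1)
    adj = (adj | adj.T).astype(float)
    v = rng.random(15)
    for _ in range(5000):
        v = adj @ v
        v /= np.linalg.norm(v)
    v = np.abs(v) / np.abs(v).max()
    assert np.allclose(eigenvector_centrality(adj), v, atol=1e-6)


def test_evc_localises_on_dominant_component():
    # K4 plus an isolated edge: the edge's eigenvalue (1) loses to K4's (3)
    adj = np.zeros((6, 6), dtype=bool)
    adj[:4, :4] = complete(4)
    adj[4, 5] = adj[5, 4] = True
    v = eigenvector_centrality(adj)
    assert np.allclose(v[:4], 1.0)
    assert np.allclose(v[4:], 0.0, atol=1e-8)


def test_evc_empty_graph_warns_and_returns_zero():
    with pytest.warns(UserWarning):
        v = eigenvector_centrality(np.zeros((4, 4), dtype=bool))
    assert np.array_equal(v, np.zeros(4))


def test_evc_matches_igraph_reference():
    igraph = pytest.importorskip("igraph")
    import networkx as nx

    from coevonet import SubstrateParams, generate_ws_network

    g = generate_ws_network(SubstrateParams(40, 6, 0.2, seed=3))
    adj = nx.to_numpy_array(g, dtype=bool)
    ours = eigenvector_centrality(adj)
    theirs = igraph.Graph.Adjacency(adj.astype(int).tolist(), mode="undirected")
    ref = np.array(theirs.eigenvector_centrality(scale=True))
    assert np.allclose(ours, ref, atol=1e-6)


def test_evc_invariant_under_relabelling(rng):
    adj = np.triu(rng.random((12, 12)) < 0.4, 1)
    adj = adj | adj.T
    perm = rng.permutation(12)
    v = eigenvector_centrality(adj)
    v_perm = eigenvector_centrality(adj[np.ix_(perm, perm)])
    assert np.allclose(v[perm], v_perm, atol=1e-8)


def test_cp_everyone_smokes_is_one(ring10):
    for d in (1, 2, 5):
        assert conditional_smoking_probability(ring10, np.ones(10), d) == 1.0


def test_cp_undefined_without_smokers(ring10):
    assert np.isnan(conditional_smoking_probability(ring10, np.zeros(10), 1))


def test_cp_path_example(path4):
    # path 0-1-2-3, smokers {0,1}: conditioning ordered pairs at d=1 are
    # (0,1), (1,0), (2,1); egos smoke in two of three
    assert conditional_smoking_probability(path4, [1, 1, 0, 0], 1) == pytest.approx(2 / 3)


def test_cp_rejects_invalid_distance(ring10):
    with pytest.raises(ValueError):
        conditional_smoking_probability(ring10, np.ones(10), 0)


def cp_hand_count(dist, states, d):
    pairs = [
        (i, j)
        for i in range(len(states))
        for j in range(len(states))
        if i != j and dist[i, j] == d and states[j] == 1
    ]
    if not pairs:
        return float("nan")
    return sum(states[i] for i, _ in pairs) / len(pairs)


def test_cp_matches_ordered_pair_hand_count(rng):
    from coevonet import shortest_path_distances

    for _ in range(30):
        n = int(rng.integers(3, 9))
        adj = np.triu(rng.random((n, n)) < 0.45, 1)
        adj = adj | adj.T
        states = rng.integers(0, 2, n)
        dist = shortest_path_distances(adj)
        for d in (1, 2):
            ours = conditional_smoking_probability(dist, states, d)
            ref = cp_hand_count(dist.distances, states, d)
            if np.isnan(ref):
                assert np.isnan(ours)
            else:
                assert ours == pytest.approx(ref)


def test_bootstrap_constant_vector_gives_point_interval(rng):
    lo, hi = bootstrap_ci([3.5] * 10, rng=rng)
    assert lo == hi == 3.5


def test_bootstrap_single_run_warns(rng):
    with pytest.warns(UserWarning):
        lo, hi = bootstrap_ci([2.0], rng=rng)
    assert lo == hi == 2.0


def test_bootstrap_bands_are_nested(rng):
    values = rng.normal(size=(15, 8))
    bands = bootstrap_bands(values, levels=(0.95, 0.99), rng=rng)
    lo95, hi95 = bands[0.95]
    lo99, hi99 = bands[0.99]
    assert np.all(lo99 <= lo95) and np.all(hi99 >= hi95)


def test_bootstrap_ci_close_to_t_interval(rng):
    sample = rng.normal(size=100)
    lo, hi = bootstrap_ci(sample, level=0.95, reps=4000, rng=rng)
    t_lo, t_hi = stats.t.interval(0.95, 99, loc=sample.mean(), scale=stats.sem(sample))
    assert lo == pytest.approx(t_lo, abs=0.05)
    assert hi == pytest.approx(t_hi, abs=0.05)
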