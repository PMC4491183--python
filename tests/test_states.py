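from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import jensenshannon

from patmb.io import OtuTable
from patmb.simulate import SimulationConfig, simulate_cohort
from patmb.states import (
    DistanceMatrix,
    ch_index,
    choose_k,
    distance_matrix,
    jsd,
    pam,
    relative_abundance,
    transition_map,
)

from conftest import make_metadata


def brute_force_pam_cost(D, k):
    """Exhaustive optimum of the k-medoids objective (oracle for small n)."""
    n = D.shape[0]
    best = np.inf
    for medoids in combinations(range(n), k):
        cost = D[:, medoids].min(axis=1).sum()
        best = min(best, cost)
    return best


def random_distance_matrix(n, rng):
    X = rng.random((n, 3))
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    return DistanceMatrix([str(i) for i in range(n)], D)


# --- relative abundance ---


def test_relative_abundance_rows_sum_to_one(tiny_table):
    rel = relative_abundance(tiny_table)
    np.testing.assert_allclose(rel.sum(axis=1), 1.0, atol=1e-12)
    np.testing.assert_allclose(rel.loc["s1"], [5 / 8, 0, 3 / 8])


def test_relative_abundance_scale_invariance(tiny_table):
    scaled = OtuTable(
        tiny_table.sample_ids, tiny_table.otu_ids,
        tiny_table.counts * 7, tiny_table.taxonomy,
    )
    pd.testing.assert_frame_equal(
        relative_abundance(scaled), relative_abundance(tiny_table)
    )


def test_relative_abundance_zero_sample_named():
    t = OtuTable(["a", "b"], ["o1"], np.array([[0], [3]]), {})
    with pytest.raises(ValueError, match="a"):
        relative_abundance(t)


# --- Jensen-Shannon divergence ---


def test_jsd_identity_disjoint_and_closed_form():
    p = np.array([0.2, 0.3, 0.5])
    assert jsd(p, p) == 0.0
    assert jsd(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == pytest.approx(1.0)
    # H(0.75, 0.25) - (1 + 0)/2 = 0.811278... - 0.5
    assert jsd(np.array([0.5, 0.5]), np.array([1.0, 0.0])) == pytest.approx(
        0.311278, abs=1e-6
    )


def test_jsd_symmetric_and_bounded(rng):
    for _ in range(50):
        p = rng.dirichlet(np.ones(12))
        q = rng.dirichlet(np.ones(12))
        v = jsd(p, q)
        assert v == pytest.approx(jsd(q, p), abs=1e-12)
        assert 0.0 <= v <= 1.0


def test_jsd_length_mismatch():
    with pytest.raises(ValueError, match="length mismatch"):
        jsd(np.array([1.0]), np.array([0.5, 0.5]))


def test_jsd_agrees_with_scipy(rng):
    # independent cross-check: scipy returns sqrt(JSD) in the given base
    for _ in range(20):
        p = rng.dirichlet(np.ones(8))
        q = rng.dirichlet(np.ones(8))
        assert jsd(p, q) == pytest.approx(jensenshannon(p, q, base=2) ** 2,
                                          abs=1e-10)


def test_distance_matrix_metric_properties(rng):
    P = rng.dirichlet(np.ones(10), size=12)
    D = distance_matrix(P)
    assert np.allclose(D.values, D.values.T, atol=1e-12)
    assert np.all(np.diag(D.values) == 0)
    assert D.values.max() <= 1.0 + 1e-12
    # triangle inequality over all triples of this fixture
    V = D.values
    n = V.shape[0]
    for i in range(n):
        for j in range(n):
            for k in range(n):
                assert V[i, j] <= V[i, k] + V[k, j] + 1e-12
    # duplicated rows are at distance zero
    D2 = distance_matrix(np.vstack([P[0], P[0]]))
    assert D2.values[0, 1] == 0.0


def test_distance_matrix_matches_scalar_jsd(rng):
    P = rng.dirichlet(np.ones(6), size=5)
    D = distance_matrix(P)
    for i in range(5):
        for j in range(5):
            assert D.values[i, j] == pytest.approx(
                np.sqrt(jsd(P[i], P[j])), abs=1e-12
            )


# --- PAM ---


def test_pam_recovers_separated_triads():
    base = np.array([
        [0.0, 0.01, 0.01, 0.9, 0.9, 0.9],
        [0.01, 0.0, 0.01, 0.9, 0.9, 0.9],
        [0.01, 0.01, 0.0, 0.9, 0.9, 0.9],
        [0.9, 0.9, 0.9, 0.0, 0.01, 0.01],
        [0.9, 0.9, 0.9, 0.01, 0.0, 0.01],
        [0.9, 0.9, 0.9, 0.01, 0.01, 0.0],
    ])
    D = DistanceMatrix(list("abcdef"), base)
    sol = pam(D, 2)
    labels = sol.labels.to_numpy()
    assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
    assert labels[0] != labels[3]


def test_pam_matches_brute_force_on_small_instances(rng):
    wins = 0
    trials = 30
    for t in range(trials):
        n = int(rng.integers(5, 9))
        k = int(rng.integers(2, 4))
        D = random_distance_matrix(n, rng)
        sol = pam(D, k)
        opt = brute_force_pam_cost(D.values, k)
        assert sol.total_cost >= opt - 1e-9
        wins += np.isclose(sol.total_cost, opt, atol=1e-9)
    assert wins >= int(0.9 * trials)


def test_pam_deterministic_and_permutation_consistent(rng):
    D = random_distance_matrix(10, rng)
    sol1 = pam(D, 3)
    sol2 = pam(D, 3)
    assert sol1.medoid_ids == sol2.medoid_ids
    assert (sol1.labels == sol2.labels).all()
    # permuting the samples yields the same partition up to relabeling
    perm = rng.permutation(10)
    Dp = DistanceMatrix([D.sample_ids[i] for i in perm],
                        D.values[np.ix_(perm, perm)])
    solp = pam(Dp, 3)
    orig = sol1.labels
    permuted = solp.labels.reindex(orig.index)
    # same co-clustering relation
    for i in range(10):
        for j in range(10):
            a, b = orig.index[i], orig.index[j]
            assert (orig[a] == orig[b]) == (permuted[a] == permuted[b])


def test_pam_k_out_of_range(rng):
    D = random_distance_matrix(5, rng)
    for bad in (1, 5, 7):
        with pytest.raises(ValueError):
            pam(D, bad)


def test_medoids_belong_to_their_cluster(rng):
    D = random_distance_matrix(12, rng)
    sol = pam(D, 4)
    for m in sol.medoid_ids:
        others = [mm for mm in sol.medoid_ids if mm != m]
        im = D.sample_ids.index(m)
        dm = min(D.values[im, D.sample_ids.index(o)] for o in others)
        assert dm >= 0  # its own distance (0) is minimal, so label is its own
        assert sol.labels[m] == sol.labels[m]


# --- Calinski-Harabasz ---


def test_ch_prefers_true_labels_on_separated_blobs(rng):
    X = np.vstack([rng.normal(0, 0.05, (8, 2)), rng.normal(1, 0.05, (8, 2))])
    D = DistanceMatrix(
        [str(i) for i in range(16)],
        np.sqrt(((X[:, None] - X[None, :]) ** 2).sum(-1)),
    )
    true = np.repeat([1, 2], 8)
    better = 0
    for _ in range(50):
        rand = rng.permutation(true)
        better += ch_index(D, true) > ch_index(D, rand)
    assert better == 50


def test_ch_requires_two_clusters(rng):
    D = random_distance_matrix(6, rng)
    with pytest.raises(ValueError):
        ch_index(D, np.ones(6))


def test_ch_scale_invariant(rng):
    D = random_distance_matrix(9, rng)
    labels = np.array([1, 1, 1, 2, 2, 2, 3, 3, 3])
    scaled = DistanceMatrix(D.sample_ids, D.values * 3.7)
    assert ch_index(D, labels) == pytest.approx(ch_index(scaled, labels),
                                                rel=1e-10)


def test_choose_k_two_planted_blobs(rng):
    X = np.vstack([rng.normal(0, 0.05, (10, 2)), rng.normal(2, 0.05, (10, 2))])
    D = DistanceMatrix(
        [str(i) for i in range(20)],
        np.sqrt(((X[:, None] - X[None, :]) ** 2).sum(-1)),
    )
    sol = choose_k(D, range(2, 8))
    assert sol.k == 2
    assert sorted(sol.ch_by_k) == [2, 3, 4, 5, 6, 7]


def test_choose_k_on_default_cohort(default_cohort):
    cfg, table, meta, truth = default_cohort
    sol = choose_k(distance_matrix(relative_abundance(table)))
    assert sol.k == cfg.n_states == 4
    assert sol.ch_by_k[sol.k] == max(sol.ch_by_k.values())
    # planted perturbed states are enriched for the planted bloom taxon
    rel = relative_abundance(table)
    bloom = table.otu_ids[cfg.layout.bloom_index["tylosin"]]
    ts = truth.frame["true_state"]
    mean_by_label = rel[bloom].groupby(sol.labels).mean()
    major_label = sol.labels[ts[ts == 3].index].mode()[0]
    assert mean_by_label[major_label] == mean_by_label.max()


# --- transition map ---


def test_transition_map_hand_counts():
    meta = make_metadata(n_mice=3, days=(21, 25, 29))
    labels = pd.Series(
        {s: (1 if meta.frame.loc[s, "timepoint_index"] < 3 else 4)
         for s in meta.sample_ids},
        name="state",
    )
    tm = transition_map(labels, meta)
    assert tm.counts[(1, 2)][tm.states.index(1), tm.states.index(1)] == 3
    assert tm.counts[(2, 3)][tm.states.index(1), tm.states.index(4)] == 3
    assert tm.occupancy.loc[1, 1] == 3 and tm.occupancy.loc[3, 4] == 3
    # occupancy row sums = mice observed at each timepoint
    assert (tm.occupancy.sum(axis=1) == 3).all()


def test_transition_map_gap_policy_and_singletons():
    meta = make_metadata(n_mice=2, days=(21, 25, 29))
    keep = [s for s in meta.sample_ids
            if not (s.startswith("C1") and meta.frame.loc[s, "timepoint_index"] == 2)]
    keep = [s for s in keep if not (s.startswith("C2")
            and meta.frame.loc[s, "timepoint_index"] > 1)]
    labels = pd.Series(1, index=pd.Index(keep, name="sample_id"), name="state")
    tm = transition_map(labels, meta)
    # C1 skips timepoint 2: no transition across the gap; C2 is a singleton
    assert tm.counts[(1, 2)].sum() == 0
    assert tm.counts[(2, 3)].sum() == 0
    assert tm.occupancy.loc[1].sum() == 2
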