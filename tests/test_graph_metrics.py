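"""Structural metrics against brute-force enumeration oracles."""

import itertools

import numpy as np
import pytest

from wmnet import graph_metrics as gm


def random_digraph(rng, n, p=0.3):
    M = (rng.random((n, n)) < p).astype(int)
    np.fill_diagonal(M, 0)
    return M


# ---------------------------------------------------------------------------
# oracles (independent of the implementation: plain python enumeration)
# ---------------------------------------------------------------------------

def bfs_spl_oracle(M):
    """Mean directed shortest-path length by per-source BFS."""
    n = M.shape[0]
    out_neighbors = [np.flatnonzero(M[:, j]) for j in range(n)]  # j -> i edges
    dists = []
    for s in range(n):
        dist = {s: 0}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for v in out_neighbors[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        dists.extend(d for node, d in dist.items() if node != s)
    return (np.mean(dists) if dists else np.nan), dists


def clustering_oracle(M):
    """Average clustering by explicit neighbor-pair counting."""
    n = M.shape[0]
    A = ((M + M.T) > 0).astype(int)
    np.fill_diagonal(A, 0)
    ccs = []
    for i in range(n):
        nbrs = np.flatnonzero(A[i])
        k = len(nbrs)
        if k < 2:
            ccs.append(0.0)
            continue
        e = sum(A[u, v] for u, v in itertools.combinations(nbrs, 2))
        ccs.append(2 * e / (k * (k - 1)))
    return float(np.mean(ccs))


def cycle3_oracle(M):
    n = M.shape[0]
    count = 0
    for i, j, k in itertools.permutations(range(n), 3):
        if M[j, i] and M[k, j] and M[i, k]:      # i -> j -> k -> i
            count += 1
    return count // 3


def cycle4_oracle(M):
    n = M.shape[0]
    count = 0
    for quad in itertools.combinations(range(n), 4):
        for perm in itertools.permutations(quad):
            if perm[0] != min(perm):
                continue
            a, b, c, d = perm
            if M[b, a] and M[c, b] and M[d, c] and M[a, d]:
                count += 1
    return count


def motif_oracle(M):
    """Classify every connected triple by isomorphism against exemplars."""
    from wmnet.graph_metrics import _MOTIF_EXEMPLARS, MOTIF_NAMES
    n = M.shape[0]
    counts = np.zeros(13, dtype=int)

    def iso_class(sub):
        for cls, name in enumerate(MOTIF_NAMES):
            ref = np.zeros((3, 3), dtype=int)
            for a, b in _MOTIF_EXEMPLARS[name]:
                ref[a, b] = 1
            for perm in itertools.permutations(range(3)):
                P = np.eye(3, dtype=int)[list(perm)]
                if (P @ sub @ P.T == ref).all():
                    return cls
        return None

    for tri in itertools.combinations(range(n), 3):
        sub = M[np.ix_(tri, tri)].T            # source -> target orientation
        und = ((sub + sub.T) > 0).astype(int)
        # weak connectivity of 3 nodes: every node touched and not split
        deg = und.sum(axis=1)
        if (deg == 0).any() or und.sum() < 4:
            continue
        cls = iso_class(sub)
        assert cls is not None
        counts[cls] += 1
    return counts


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

def test_spl_closed_forms():
    ring = np.zeros((4, 4), dtype=int)
    for i in range(4):
        ring[(i + 1) % 4, i] = 1
    assert gm.avg_shortest_path(ring) == 2.0
    K = 1 - np.eye(5, dtype=int)
    assert gm.avg_shortest_path(K) == 1.0


def test_spl_unreachable_and_empty():
    M = np.zeros((3, 3), dtype=int)
    M[1, 0] = 1
    mean, unreachable = gm.avg_shortest_path(M, with_counts=True)
    assert mean == 1.0 and unreachable == 5
    assert np.isnan(gm.avg_shortest_path(np.zeros((3, 3), dtype=int)))


def test_spl_matches_bfs_oracle():
    rng = np.random.default_rng(3)
    for _ in range(25):
        M = random_digraph(rng, 12)
        expect, _ = bfs_spl_oracle(M)
        assert gm.avg_shortest_path(M) == pytest.approx(expect, abs=1e-12)


def test_clustering_closed_forms_and_oracle():
    K = 1 - np.eye(6, dtype=int)
    assert gm.avg_clustering(K) == 1.0
    star = np.zeros((5, 5), dtype=int)
    star[0, 1:] = 1
    assert gm.avg_clustering(star) == 0.0
    rng = np.random.default_rng(4)
    for _ in range(25):
        M = random_digraph(rng, 12)
        assert gm.avg_clustering(M) == pytest.approx(clustering_oracle(M), abs=1e-12)


def test_degree_blocks_and_balance():
    labels = np.arange(100) < 80
    K = 1 - np.eye(100, dtype=int)
    d = gm.degree_blocks(K, labels)
    assert d == (80 * 79, 80 * 20, 20 * 80, 20 * 19)
    assert gm.ei_balance_factor(d) == pytest.approx(6700 / 3200)
    assert gm.ei_balance_factor((10, 5, 5, 10)) == 2.0
    assert gm.ei_balance_factor((0, 3, 4, 0)) == 0.0
    assert np.isnan(gm.ei_balance_factor((1, 0, 0, 1)))
    empty = np.zeros((100, 100), dtype=int)
    assert gm.degree_blocks(empty, labels) == (0, 0, 0, 0)


def test_degree_blocks_partition_edges():
    rng = np.random.default_rng(5)
    M = random_digraph(rng, 30)
    labels = np.arange(30) < 22
    assert sum(gm.degree_blocks(M, labels)) == M.sum()


def test_degree_blocks_label_mismatch():
    with pytest.raises(ValueError):
        gm.degree_blocks(np.zeros((4, 4), dtype=int), [True, False])


def test_excitatory_input_fraction_cases():
    # node 0 receives 4 excitatory + 1 inhibitory input
    M = np.zeros((6, 6), dtype=int)
    M[0, 1:6] = 1
    labels = np.array([True, True, True, True, True, False])
    P = gm.excitatory_input_fraction(M, labels)
    assert P[0] == pytest.approx(0.8)
    assert np.isnan(P[1])                     # no inputs
    M2 = np.zeros((4, 4), dtype=int)
    M2[0, 3] = 1
    P2 = gm.excitatory_input_fraction(M2, np.array([True, True, True, False]))
    assert P2[0] == 0.0


def test_hub_measures():
    labels = np.array([True] * 3 + [False] * 2)
    p_e, p_i, f = gm.hub_measures(np.ones(5), labels)
    assert (p_e, p_i, f) == (1.0, 1.0, 1.0)
    # threshold is strict: exactly 0.8 is not a hub
    p_e, _, _ = gm.hub_measures(np.array([0.8, 0.81, 0.79, 1.0, 0.0]), labels)
    assert p_e == pytest.approx(1 / 3)
    _, p_i, f = gm.hub_measures(np.array([1, 1, 1, 0.5, 0.5]), labels)
    assert p_i == 0.0 and np.isnan(f)


def test_hub_measures_match_enumeration():
    rng = np.random.default_rng(6)
    M = random_digraph(rng, 15)
    labels = np.arange(15) < 11
    P = gm.excitatory_input_fraction(M, labels)
    expected_e = np.mean([(P[i] > 0.8) if not np.isnan(P[i]) else False
                          for i in range(11)])
    p_e, _, _ = gm.hub_measures(P, labels)
    assert p_e == pytest.approx(expected_e)


def test_3cycles_closed_forms():
    tri = np.zeros((3, 3), dtype=int)
    tri[1, 0] = tri[2, 1] = tri[0, 2] = 1
    assert gm.count_3cycles(tri) == 1
    K3 = 1 - np.eye(3, dtype=int)
    assert gm.count_3cycles(K3) == 2


def test_3cycles_match_enumeration():
    rng = np.random.default_rng(7)
    for _ in range(100):
        M = random_digraph(rng, 10)
        assert gm.count_3cycles(M) == cycle3_oracle(M)


def test_4cycles_match_enumeration():
    rng = np.random.default_rng(8)
    for _ in range(40):
        M = random_digraph(rng, 8, p=0.35)
        assert gm.count_4cycles(M) == cycle4_oracle(M)


def test_cycle_34_correlation_across_topologies():
    """3- and 4-cycle counts are strongly correlated across random networks."""
    from wmnet.connectivity import build_intra, ASSOCIATION
    c3, c4 = [], []
    for seed in range(200):
        M = build_intra(ASSOCIATION, seed=seed)
        c3.append(gm.count_3cycles(M))
        c4.append(gm.count_4cycles(M))
    r = np.corrcoef(c3, c4)[0, 1]
    assert r > 0.9


def test_motif_census_complete_triangle():
    K3 = 1 - np.eye(3, dtype=int)
    census = gm.motif_census(K3, np.ones(3, dtype=bool))
    assert census.entire[12] == 1 and census.entire[:12].sum() == 0


def test_motif_partition_and_additivity():
    rng = np.random.default_rng(9)
    for _ in range(20):
        n = 9
        M = random_digraph(rng, n)
        labels = np.arange(n) < 6
        census = gm.motif_census(M, labels)
        # entire = excitatory + inhibitory-involved, class-wise
        np.testing.assert_array_equal(
            census.entire, census.excitatory + census.inhibitory_involved)
        # total count = number of weakly connected triples
        und = ((M + M.T) > 0).astype(int)
        n_connected = sum(
            1 for tri in itertools.combinations(range(n), 3)
            if (und[np.ix_(tri, tri)].sum(axis=1) > 0).all()
            and und[np.ix_(tri, tri)].sum() >= 4)
        assert census.entire.sum() == n_connected


def test_motif_census_matches_isomorphism_oracle():
    rng = np.random.default_rng(10)
    for _ in range(100):
        M = random_digraph(rng, 9)
        census = gm.motif_census(M, np.ones(9, dtype=bool))
        np.testing.assert_array_equal(census.entire, motif_oracle(M))


def test_motif_class_count_is_13():
    assert len(gm.MOTIF_NAMES) == 13
    # grouping by edge count: 3 / 4 / 5 / 1 classes with 2 / 3 / 4-5 / 6 edges
    from wmnet.graph_metrics import _MOTIF_EXEMPLARS
    edges = [len(_MOTIF_EXEMPLARS[nm]) for nm in gm.MOTIF_NAMES]
    assert edges[:3] == [2, 2, 2]
    assert edges[3:7] == [3, 3, 3, 3]
    assert sorted(edges[7:12]) == [4, 4, 4, 4, 5]
    assert edges[12] == 6


def test_excitatory_view_invariant_to_inhibitory_edits():
    rng = np.random.default_rng(11)
    n = 14
    M = random_digraph(rng, n)
    labels = np.arange(n) < 10
    M2 = M.copy()
    M2[:, ~labels] = rng.integers(0, 2, size=(n, 4))    # rewire I columns
    M2[~labels] = rng.integers(0, 2, size=(4, n))       # rewire I rows
    np.fill_diagonal(M2, 0)
    sub = np.ix_(labels, labels)
    M2[sub] = M[sub]
    assert gm.count_3cycles(M, "excitatory", labels) == \
        gm.count_3cycles(M2, "excitatory", labels)
    assert gm.avg_clustering(M[sub]) == gm.avg_clustering(M2[sub])
    assert gm.avg_shortest_path(M[sub]) == gm.avg_shortest_path(M2[sub])


def test_feature_vector_shapes_and_determinism():
    from wmnet.connectivity import build_intra, ASSOCIATION
    M = build_intra(ASSOCIATION, seed=42)
    labels = ASSOCIATION.labels()
    fv1 = gm.feature_vector(M, labels)
    fv2 = gm.feature_vector(M, labels)
    assert list(fv1.index) == list(gm.FEATURE_NAMES)
    assert fv1.equals(fv2)
    K = 1 - np.eye(10, dtype=int)
    fvK = gm.feature_vector(K, np.arange(10) < 7)
    assert fvK["Cc_all"] == 1.0 and fvK["L_all"] == 1.0
    empty = gm.feature_vector(np.zeros((10, 10), dtype=int), np.arange(10) < 7)
    assert empty["d_EtoE"] == 0 and np.isnan(empty["F_EI"])
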