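"""Co-occurrence matrices, network maps, and overlap statistics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import hypergeom

from traceblink.network import (CoOccurrenceMatrix, bicluster, build_network,
                                compare_proportions, cooccurrence,
                                edge_overlap, EdgeOverlap, network_degree,
                                network_density, trial_response_vector)
from traceblink.synthetic import TrialSchedule


def _schedule(tones, n_frames=5000, fr=20.0):
    tones = np.asarray(tones, dtype=int)
    return TrialSchedule(tone_onsets=tones, puff_onsets=tones + 12,
                         frame_rate=fr, n_frames=n_frames,
                         blocks=np.array(["cond"] * len(tones), dtype=object))


class TestResponseVector:
    def test_no_events_zero_vector(self):
        sched = _schedule([1000])
        vec = trial_response_vector([np.empty(0, int)] * 4, sched, 0)
        assert vec.tolist() == [0, 0, 0, 0]

    def test_every_cell_in_window_all_ones(self):
        sched = _schedule([1000])
        onsets = [np.array([1000]), np.array([1010]), np.array([1019])]
        assert trial_response_vector(onsets, sched, 0).tolist() == [1, 1, 1]

    def test_onset_at_window_end_excluded(self):
        sched = _schedule([1000])
        vec = trial_response_vector([np.array([1020])], sched, 0)
        assert vec.tolist() == [0]  # [tone, tone + 1 s) is half-open


class TestCoOccurrence:
    def test_single_vector_outer_product_by_hand(self):
        mat = cooccurrence([np.array([1, 0, 1], dtype=np.uint8)])
        expected = np.array([[1, 0, 1], [0, 0, 0], [1, 0, 1]])
        np.testing.assert_array_equal(mat.A, expected)

    def test_all_zero_vectors_zero_matrix(self):
        mat = cooccurrence([np.zeros(5, dtype=np.uint8)] * 3)
        assert not mat.A.any()

    @given(st.integers(0, 2**30))
    def test_matches_brute_force_joint_counts(self, seed):
        rng = np.random.default_rng(seed)
        V = (rng.random((20, 8)) < 0.3).astype(np.uint8)
        mat = cooccurrence(list(V)).A
        for i in range(8):
            for j in range(8):
                assert mat[i, j] == int(np.sum(V[:, i] & V[:, j]))

    def test_trace_counts_total_responses(self, rng):
        V = (rng.random((20, 10)) < 0.3).astype(np.uint8)
        mat = cooccurrence(list(V))
        assert np.trace(mat.A) == V.sum()

    def test_order_invariant_over_trials(self, rng):
        V = list((rng.random((10, 6)) < 0.4).astype(np.uint8))
        np.testing.assert_array_equal(cooccurrence(V).A,
                                      cooccurrence(V[::-1]).A)


class TestBicluster:
    def _planted(self, perm=None):
        # two co-active blocks of 6 and 4 cells
        v1 = np.zeros(10, dtype=np.uint8)
        v1[:6] = 1
        v2 = np.zeros(10, dtype=np.uint8)
        v2[6:] = 1
        vecs = [v1] * 10 + [v2] * 10
        if perm is not None:
            vecs = [v[perm] for v in vecs]
        return cooccurrence(vecs)

    def test_planted_blocks_recovered(self):
        row_order, _, row_labels, _ = bicluster(self._planted(), seed=0)
        assert len(set(row_labels[:6])) == 1
        assert len(set(row_labels[6:])) == 1
        assert row_labels[0] != row_labels[-1]

    def test_permuted_blocks_recovered_up_to_relabeling(self, rng):
        perm = rng.permutation(10)
        _, _, labels, _ = bicluster(self._planted(perm), seed=0)
        group1 = {labels[np.flatnonzero(perm == i)[0]] for i in range(6)}
        group2 = {labels[np.flatnonzero(perm == i)[0]] for i in range(6, 10)}
        assert len(group1) == 1 and len(group2) == 1 and group1 != group2

    def test_all_zero_matrix_identity_order(self):
        mat = CoOccurrenceMatrix(A=np.zeros((5, 5), int), trial_ids=np.arange(3))
        row_order, col_order, _, _ = bicluster(mat)
        np.testing.assert_array_equal(row_order, np.arange(5))
        np.testing.assert_array_equal(col_order, np.arange(5))

    def test_deterministic_under_fixed_seed(self):
        a = bicluster(self._planted(), seed=7)
        b = bicluster(self._planted(), seed=7)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)


class TestNetworkMaps:
    def test_empty_union_empty_graph(self):
        mat = cooccurrence([np.ones(4, dtype=np.uint8)])
        net = build_network(mat, set())
        assert net.n == 0 and net.m == 0

    def test_mutually_coactive_triangle(self):
        mat = cooccurrence([np.array([1, 1, 1, 0], dtype=np.uint8)])
        net = build_network(mat, {0, 1, 2, 3})
        assert net.m == 3
        assert net.edges == {(0, 1), (0, 2), (1, 2)}

    def test_nonresponsive_member_breaks_edge(self):
        mat = cooccurrence([np.array([1, 1, 0], dtype=np.uint8)])
        net = build_network(mat, {0, 2})  # cell 1 not in the union
        assert net.m == 0

    def test_density_and_degree_closed_forms(self):
        tri = build_network(cooccurrence([np.ones(3, dtype=np.uint8)]),
                            {0, 1, 2})
        assert network_density(tri) == pytest.approx(1.0)
        assert network_degree(tri) == pytest.approx(2.0)

    def test_star_graph_formulas(self):
        # 10-node star: m=9 -> density 2*9/90 = 0.2, degree 18/10 = 1.8
        vecs = [np.zeros(10, dtype=np.uint8) for _ in range(9)]
        for t, leaf in enumerate(range(1, 10)):
            vecs[t][0] = 1
            vecs[t][leaf] = 1
        net = build_network(cooccurrence(vecs), set(range(10)))
        assert net.m == 9
        assert network_density(net) == pytest.approx(0.2)
        assert network_degree(net) == pytest.approx(1.8)

    def test_no_edges_zero_density_degree(self):
        net = build_network(cooccurrence([np.zeros(4, dtype=np.uint8)]),
                            {0, 1, 2, 3})
        assert network_density(net) == 0.0 and network_degree(net) == 0.0

    def test_single_node_density_undefined(self):
        net = build_network(cooccurrence([np.array([1], dtype=np.uint8)]), {0})
        with pytest.raises(ValueError):
            network_density(net)


class TestEdgeOverlap:
    def test_identical_networks_share_everything(self):
        mat = cooccurrence([np.ones(4, dtype=np.uint8)])
        n1 = build_network(mat, set(range(4)))
        n2 = build_network(mat, set(range(4)))
        ov = edge_overlap(n1, n2)
        assert ov.pct_shared == 100.0

    def test_overlap_is_symmetric(self):
        m1 = cooccurrence([np.array([1, 1, 0, 0], dtype=np.uint8)])
        m2 = cooccurrence([np.array([0, 1, 1, 0], dtype=np.uint8),
                           np.array([1, 1, 0, 0], dtype=np.uint8)])
        n1 = build_network(m1, set(range(4)))
        n2 = build_network(m2, set(range(4)))
        assert edge_overlap(n1, n2).jaccard_pct == \
            edge_overlap(n2, n1).jaccard_pct

    def test_percentages_partition_consistently(self):
        ov = EdgeOverlap(Ei1=40, Ei2=30, Es=10)
        assert ov.Et == 60
        assert ov.pct_shared == pytest.approx(100 * 10 / 60)
        assert ov.pct_individual_1 == pytest.approx(100 * 40 / 60)
        assert ov.jaccard_pct == ov.pct_shared

    def test_shared_cannot_exceed_individual(self):
        with pytest.raises(ValueError):
            EdgeOverlap(Ei1=5, Ei2=10, Es=6)


class TestFisherExact:
    def test_identical_proportions_p_one(self):
        assert compare_proportions(5, 10, 5, 10) == pytest.approx(1.0)

    def test_extreme_table_closed_form(self):
        # [[10,0],[0,10]]: the two extreme tables out of C(20,10)
        p = compare_proportions(10, 10, 0, 10)
        assert p == pytest.approx(2 / 184756, rel=1e-9)

    @given(st.integers(0, 2**30))
    def test_matches_hypergeometric_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = int(rng.integers(1, 16)), int(rng.integers(1, 16))
        k1, k2 = int(rng.integers(0, n1 + 1)), int(rng.integers(0, n2 + 1))
        p = compare_proportions(k1, n1, k2, n2)
        # oracle: sum the probabilities of all tables with the same
        # margins that are no more likely than the observed one
        K, N = k1 + k2, n1 + n2
        dist = hypergeom(N, K, n1)
        p_obs = dist.pmf(k1)
        support = np.arange(max(0, K - n2), min(K, n1) + 1)
        p_exact = float(dist.pmf(support)[dist.pmf(support)
                                          <= p_obs * (1 + 1e-9)].sum())
        assert p == pytest.approx(min(p_exact, 1.0), rel=1e-6)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            compare_proportions(5, 3, 1, 10)
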