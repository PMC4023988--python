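"""Barber modularity, cross-mode matching, and the two pipelines."""

import numpy as np
import pytest

from bicomm import (BipartiteGraph, JointPartition, Partition, barber_modularity,
                    combine_partitions, detect_combined, detect_dual)
from bicomm.dual import _crosstab_gain
from tests.conftest import barber_q_double_loop, random_bipartite


def make_joint(p1, p2, joint1, joint2):
    return JointPartition(p1, p2, np.asarray(joint1), np.asarray(joint2))


class TestBarberModularity:
    def test_two_complete_blocks_score_half(self, two_block_bipartite):
        jp = make_joint(Partition(np.array([0, 0, 1, 1])), Partition(np.array([0, 0, 1, 1])),
                        [0, 1], [0, 1])
        assert barber_modularity(two_block_bipartite, jp) == pytest.approx(0.5)

    def test_all_one_joint_community_is_zero(self, two_block_bipartite):
        jp = make_joint(Partition(np.zeros(4, int)), Partition(np.zeros(4, int)), [0], [0])
        assert barber_modularity(two_block_bipartite, jp) == pytest.approx(0.0)

    def test_matches_double_loop_oracle_on_random_graphs(self, rng):
        for _ in range(25):
            g = random_bipartite(rng, int(rng.integers(2, 12)), int(rng.integers(2, 12)))
            p1 = Partition(rng.integers(0, 3, g.n1))
            p2 = Partition(rng.integers(0, 3, g.n2))
            joint1 = rng.integers(0, 4, p1.k)
            joint2 = rng.integers(0, 4, p2.k)
            jp = make_joint(p1, p2, joint1, joint2)
            q = barber_modularity(g, jp)
            g1, g2 = jp.joint_labels()
            assert q == pytest.approx(barber_q_double_loop(g, g1, g2), abs=1e-12)
            assert -1.0 - 1e-12 <= q <= 1.0 + 1e-12

    def test_edgeless_graph_rejected(self):
        g = BipartiteGraph(2, 2, frozenset())
        jp = make_joint(Partition(np.zeros(2, int)), Partition(np.zeros(2, int)), [0], [0])
        with pytest.raises(ValueError):
            barber_modularity(g, jp)


class TestCombinePartitions:
    def test_block_structure_pairs_aligned_communities(self, two_block_bipartite):
        p = Partition(np.array([0, 0, 1, 1]))
        jp = combine_partitions(two_block_bipartite, p, p)
        g1, g2 = jp.joint_labels()
        assert np.array_equal(g1, g2)
        assert jp.barber_q == pytest.approx(0.5)
        assert jp.barber_q == pytest.approx(barber_modularity(two_block_bipartite, jp))

    def test_single_communities_give_zero(self, two_block_bipartite):
        jp = combine_partitions(two_block_bipartite,
                                Partition(np.zeros(4, int)), Partition(np.zeros(4, int)))
        assert jp.barber_q == pytest.approx(0.0)
        assert jp.n_joint == 1

    def test_three_vs_two_matching_has_three_joint_labels(self, rng):
        """Perfect per-mode partitions of a 3/2 planted graph: two of the
        three mode-1 communities pair with the mode-2 halves and the joint
        label count is max(k1, k2) = 3; the result matches exhaustive search
        over all candidate matchings."""
        from bicomm import generate, small_config
        g, truth = generate(small_config("unequal_3_2", seed=7))
        jp = combine_partitions(g, truth.labels1, truth.labels2)
        assert jp.n_joint == 3
        # exhaustive oracle over every map of the 2 mode-2 labels onto
        # {3 mode-1 labels} + {unmatched}
        G = _crosstab_gain(g, truth.labels1, truth.labels2)
        best = 0.0
        import itertools
        for assign in itertools.product(range(4), repeat=2):
            best = max(best, sum(G[t, s] for s, t in enumerate(assign) if t < 3))
        assert jp.barber_q == pytest.approx(best, abs=1e-12)

    def test_never_below_all_unmatched_baseline(self, rng):
        for _ in range(10):
            g = random_bipartite(rng, 8, 10)
            p1 = Partition(rng.integers(0, 4, 8))
            p2 = Partition(rng.integers(0, 4, 10))
            assert combine_partitions(g, p1, p2).barber_q >= -1e-12

    def test_greedy_matches_exhaustive_on_small_label_counts(self, rng):
        import bicomm.dual as dual_mod
        for _ in range(20):
            g = random_bipartite(rng, 10, 12)
            p1 = Partition(rng.integers(0, int(rng.integers(2, 5)), 10))
            p2 = Partition(rng.integers(0, int(rng.integers(2, 5)), 12))
            exact = combine_partitions(g, p1, p2).barber_q
            cap = dual_mod._EXHAUSTIVE_CAP
            dual_mod._EXHAUSTIVE_CAP = 0  # force the greedy path
            try:
                greedy = combine_partitions(g, p1, p2).barber_q
            finally:
                dual_mod._EXHAUSTIVE_CAP = cap
            assert greedy == pytest.approx(exact, abs=1e-9)

    def test_empty_partition_combination_rejected(self):
        g = BipartiteGraph(2, 2, frozenset())
        with pytest.raises(ValueError):
            combine_partitions(g, Partition(np.zeros(2, int)), Partition(np.zeros(2, int)))


class TestPipelines:
    def test_dual_recovers_planted_blocks(self, two_block_bipartite):
        jp = detect_dual(two_block_bipartite)
        assert jp.partition1 == Partition(np.array([0, 0, 1, 1]))
        assert jp.partition2 == Partition(np.array([0, 0, 1, 1]))
        assert jp.barber_q == pytest.approx(0.5)

    def test_combined_recovers_planted_blocks(self, two_block_bipartite):
        jp = detect_combined(two_block_bipartite)
        assert jp.partition1 == Partition(np.array([0, 0, 1, 1]))
        assert jp.partition2 == Partition(np.array([0, 0, 1, 1]))
        g1, g2 = jp.joint_labels()
        assert set(g1) == set(g2)  # communities span both modes
        assert jp.barber_q == pytest.approx(0.5)

    def test_single_edge_graph_degenerates_gracefully(self):
        g = BipartiteGraph(2, 2, frozenset({(0, 0)}))
        jp = detect_dual(g)
        assert jp.partition1.n == 2 and jp.partition2.n == 2

    def test_edgeless_graph_rejected(self):
        g = BipartiteGraph(2, 2, frozenset())
        with pytest.raises(ValueError):
            detect_dual(g)
        with pytest.raises(ValueError):
            detect_combined(g)

    def test_pipelines_deterministic(self, rng):
        g = random_bipartite(rng, 12, 18)
        a, b = detect_dual(g), detect_dual(g)
        assert a.partition1 == b.partition1 and a.partition2 == b.partition2
        c, d = detect_combined(g), detect_combined(g)
        assert c.partition1 == d.partition1 and c.partition2 == d.partition2

    def test_combined_barber_q_recomputable(self, rng):
        g = random_bipartite(rng, 10, 14)
        jp = detect_combined(g)
        assert jp.barber_q == pytest.approx(barber_modularity(g, jp))
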