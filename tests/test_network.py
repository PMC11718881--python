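"""Node measures, community detection, modularity, assortment."""

import numpy as np
import pytest

import herdnet as hn
from herdnet import REFERENCE_PARTITION
from herdnet.datatypes import Partition, ValidationError


class TestNodeStrength:
    def test_association_strengths_match_published(self, table5, table7):
        s = hn.node_strength(table5)
        # published strengths are sums of unrounded AI; printed inputs are
        # rounded to 3 dp, so allow 0.002
        np.testing.assert_allclose(
            s.to_numpy(), table7["S_assoc"].to_numpy(), atol=0.002
        )
        assert s["Lovelas"] == pytest.approx(0.665)

    def test_directed_total_strength(self, table6, table7):
        s = hn.node_strength(table6, mode="total")
        assert s["Vernij"] == pytest.approx(0.046)
        np.testing.assert_allclose(
            s.to_numpy(), table7["S_affil"].to_numpy(), atol=0.02
        )
        out_s = hn.node_strength(table6, mode="out")
        in_s = hn.node_strength(table6, mode="in")
        np.testing.assert_allclose(
            (out_s + in_s).to_numpy(), s.to_numpy()
        )

    def test_zero_matrix(self):
        m = hn.DyadMatrix(list("abc"), np.zeros((3, 3)))
        assert (hn.node_strength(m) == 0).all()


class TestWeightedDegree:
    def test_association_wd_matches_published(self, table5, table7):
        wd = hn.weighted_degree(table5, alpha=0.5)
        assert wd["Lovelas"] == pytest.approx(0.815, abs=5e-4)
        np.testing.assert_allclose(
            wd.to_numpy(), table7["WD_assoc"].to_numpy(), atol=0.005
        )

    def test_directed_wd_uses_outgoing_ties(self, table6, table7):
        wd = hn.weighted_degree(table6, alpha=0.5)
        assert wd["Lovelas"] == pytest.approx(0.214, abs=5e-4)
        assert wd["Vernij"] == 0.0  # receives but never initiates
        np.testing.assert_allclose(
            wd.to_numpy(), table7["WD_affil"].to_numpy(), atol=0.012
        )

    def test_interpolates_between_degree_and_strength(self, table5):
        s = hn.node_strength(table5)
        k = (table5.values > 0).sum(axis=1)
        np.testing.assert_allclose(
            hn.weighted_degree(table5, alpha=1.0).to_numpy(), s.to_numpy()
        )
        np.testing.assert_allclose(
            hn.weighted_degree(table5, alpha=0.0).to_numpy(), k
        )
        # monotone in alpha for every node (k and S on the same side)
        grid = [hn.weighted_degree(table5, a).to_numpy()
                for a in (0.0, 0.25, 0.5, 0.75, 1.0)]
        diffs = np.diff(np.stack(grid), axis=0)
        assert (np.all(diffs >= -1e-12, axis=0)
                | np.all(diffs <= 1e-12, axis=0)).all()


class TestCommunities:
    def test_association_fixture_three_clusters(self, table5):
        part = hn.detect_communities(table5, seed=0)
        assert part.n_communities == 3
        assert part.as_sets() == REFERENCE_PARTITION.as_sets()
        assert part.modularity == pytest.approx(0.593, abs=0.005)

    def test_two_cliques_closed_form(self):
        vals = np.zeros((8, 8))
        vals[:4, :4] = 1
        vals[4:, 4:] = 1
        np.fill_diagonal(vals, 0)
        m = hn.DyadMatrix([chr(65 + i) for i in range(8)], vals)
        part = hn.detect_communities(m, seed=0)
        assert part.as_sets() == {frozenset("ABCD"), frozenset("EFGH")}
        # two equal disconnected cliques: Q = 1/2 exactly
        assert part.modularity == pytest.approx(0.5)

    def test_uniform_complete_graph_single_community(self):
        n = 6
        m = hn.DyadMatrix(
            [str(i) for i in range(n)], np.ones((n, n)) - np.eye(n)
        )
        part = hn.detect_communities(m, seed=0, restarts=20)
        assert part.n_communities == 1
        assert part.modularity == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_given_seed(self, table5):
        p1 = hn.detect_communities(table5, seed=3, restarts=10)
        p2 = hn.detect_communities(table5, seed=3, restarts=10)
        assert p1.membership == p2.membership

    def test_directed_input_symmetrized(self, table6):
        part = hn.detect_communities(table6, seed=0)
        assert part.n_communities >= 2


class TestModularity:
    def test_single_block_is_zero(self, table5):
        part = Partition({i: 0 for i in table5.ids})
        assert hn.modularity(table5, part) == pytest.approx(0.0, abs=1e-12)

    def test_published_partition_value(self, table5):
        assert hn.modularity(table5, REFERENCE_PARTITION) == pytest.approx(
            0.593, abs=0.005
        )

    def test_agrees_with_igraph_oracle(self, rng):
        import igraph as ig

        for _ in range(5):
            n = 7
            vals = rng.random((n, n))
            vals = (vals + vals.T) / 2
            np.fill_diagonal(vals, 0)
            m = hn.DyadMatrix([str(i) for i in range(n)], vals)
            labels = rng.integers(0, 3, size=n)
            part = Partition(dict(zip(m.ids, labels)))
            g = ig.Graph.Weighted_Adjacency(
                vals.tolist(), mode="undirected", attr="weight", loops=False
            )
            q_ref = g.modularity(labels.tolist(), weights="weight")
            assert hn.modularity(m, part) == pytest.approx(q_ref)

    def test_detected_beats_random_partitions(self, planted, rng):
        scans, _, _ = planted
        ai = hn.association_matrix(scans)
        part = hn.detect_communities(ai, seed=1)
        labels = part.as_array(ai.ids)
        for _ in range(20):
            q = hn.modularity(
                ai, Partition(dict(zip(ai.ids, rng.permutation(labels))))
            )
            assert q <= part.modularity + 1e-12


class TestPartitionPvalue:
    def test_single_permutation_p_binary(self, table5):
        part = hn.detect_communities(table5, seed=0)
        r = hn.partition_pvalue(table5, part, n_perm=1, seed=1, restarts=5)
        assert r.p_value in (0.0, 1.0)

    def test_planted_structure_significant(self, table5):
        part = hn.detect_communities(table5, seed=0)
        r = hn.partition_pvalue(table5, part, n_perm=200, seed=1, restarts=10)
        assert r.p_value < 0.05


class TestAssortment:
    def test_published_values(self, table5, table7):
        ac_wd, res = hn.assortment_continuous(
            table5, hn.weighted_degree(table5, 0.5), n_node_perm=200, seed=0
        )
        assert ac_wd == pytest.approx(0.856, abs=0.01)
        assert res.p_value <= 0.05
        ac_di, _ = hn.assortment_continuous(
            table5, table7["DI"], n_node_perm=10, seed=0
        )
        assert ac_di == pytest.approx(0.433, abs=0.01)

    def test_perfectly_assortative_cliques(self):
        vals = np.zeros((6, 6))
        vals[:3, :3] = 1
        vals[3:, 3:] = 1
        np.fill_diagonal(vals, 0)
        m = hn.DyadMatrix(list("abcdef"), vals)
        trait = {i: (0.0 if i in "abc" else 5.0) for i in m.ids}
        ac, _ = hn.assortment_continuous(m, trait, n_node_perm=10, seed=0)
        assert ac == pytest.approx(1.0)

    def test_scale_and_shift_invariance(self, table5, table7):
        t = table7["DI"]
        ac1, _ = hn.assortment_continuous(table5, t, n_node_perm=5, seed=0)
        ac2, _ = hn.assortment_continuous(
            table5, 3.7 * t + 11.0, n_node_perm=5, seed=0
        )
        assert ac1 == pytest.approx(ac2)

    def test_constant_trait_rejected(self, table5):
        with pytest.raises(ValidationError):
            hn.assortment_continuous(
                table5, {i: 1.0 for i in table5.ids}, n_node_perm=5
            )
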