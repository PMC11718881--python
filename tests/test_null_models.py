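"""Data-stream swaps, CV statistic, dyad classification, and Mantel."""

import itertools

import numpy as np
import pytest

import herdnet as hn
from herdnet.datatypes import DegeneracyError, ValidationError
from herdnet.permutation import SwapChain

from conftest import grouped_dataset


class TestCvStatistic:
    def test_printed_value_on_association_fixture(self, table5):
        assert hn.cv_statistic(table5) == pytest.approx(1.954, abs=0.01)

    def test_constant_matrix_has_zero_cv(self):
        vals = np.full((4, 4), 0.3)
        np.fill_diagonal(vals, 0)
        assert hn.cv_statistic(hn.DyadMatrix(list("abcd"), vals)) == 0.0

    def test_two_value_hand_oracle(self):
        # off-diagonal values {0, x}: mean x/2, sd x/sqrt(2), CV = sqrt(2)
        m = hn.DyadMatrix(["a", "b"], [[0, 0], [0.4, 0]], directed=True)
        assert hn.cv_statistic(m) == pytest.approx(np.sqrt(2))

    def test_zero_mean_undefined(self):
        m = hn.DyadMatrix(list("abc"), np.zeros((3, 3)))
        with pytest.raises(ZeroDivisionError):
            hn.cv_statistic(m)


class TestSwapChain:
    def test_margins_conserved(self, planted):
        """Swaps preserve group sizes per scan and per-day observation
        counts — the conserved margins of the data-stream method."""
        scans, _, _ = planted
        rng = np.random.default_rng(0)
        chain = SwapChain(scans, rng)
        sizes_before = chain.group_size_multisets()
        daily_before = chain.daily_observation_counts().copy()
        for _ in range(300):
            chain.swap()
        assert chain.group_size_multisets() == sizes_before
        np.testing.assert_array_equal(
            chain.daily_observation_counts(), daily_before
        )

    def test_incremental_counts_match_recount(self, planted):
        scans, _, _ = planted
        rng = np.random.default_rng(1)
        chain = SwapChain(scans, rng)
        for _ in range(200):
            chain.swap()
        n = len(chain.ids)
        together = np.zeros((n, n), dtype=int)
        for groups in chain.groups:
            for g in groups:
                for a, b in itertools.permutations(sorted(g), 2):
                    together[a, b] += 1
        np.testing.assert_array_equal(chain.together, together)

    def test_constant_composition_is_degenerate(self):
        # everyone always in one group: any cross-scan move would duplicate
        ds = grouped_dataset("ABCD", [[("A", "B", "C", "D")]] * 4)
        with pytest.raises(DegeneracyError):
            chain = SwapChain(ds, np.random.default_rng(0))
            chain.swap()

    def test_single_group_per_day_is_degenerate(self):
        ds = grouped_dataset("AB", [[("A", "B")]])
        with pytest.raises(DegeneracyError):
            SwapChain(ds, np.random.default_rng(0))


class TestDatastreamPermute:
    def test_same_seed_identical_null(self, planted):
        scans, _, _ = planted
        r1 = hn.datastream_permute(scans, n_perm=50, seed=9)
        r2 = hn.datastream_permute(scans, n_perm=50, seed=9)
        np.testing.assert_array_equal(r1.null_stats, r2.null_stats)
        assert r1.p_value == r2.p_value

    def test_planted_structure_detected(self, planted):
        scans, _, _ = planted
        r = hn.datastream_permute(scans, n_perm=400, seed=2)
        assert r.p_value < 0.01
        assert r.observed_stat > np.mean(r.null_stats)

    def test_invalid_n_perm(self, planted):
        scans, _, _ = planted
        with pytest.raises(ValidationError):
            hn.datastream_permute(scans, n_perm=0)


class TestClassifyDyads:
    def test_planted_pair_preferred_and_absent_pair_avoided(self):
        # A-B nearly always together; C-D never, amid dense associations
        groupings = []
        for k in range(40):
            if k % 10 == 0:
                groupings.append([("A", "C"), ("B", "D")])
            else:
                groupings.append([("A", "B"), ("C",), ("D",)])
        ds = grouped_dataset("ABCD", groupings, start=300)
        dyads = hn.classify_dyads(ds, n_perm=400, seed=3)
        assert dyads.label("A", "B") == "preferred"
        assert dyads.label("C", "D") == "avoided"

    def test_p_matrix_shape_and_bounds(self, planted):
        scans, _, _ = planted
        cv, dyads = hn.nonrandomness_analysis(scans, n_perm=100, seed=4)
        p = dyads.p_high.values
        assert ((p >= 0) & (p <= 1)).all()
        labels = {dyads.label(a, b)
                  for a, b in itertools.combinations(dyads.ids, 2)}
        assert labels <= {"preferred", "avoided", "neutral"}


class TestMantel:
    def test_identity_correlation(self, table5):
        r = hn.mantel_test(table5, table5, n_perm=10, seed=0)
        assert r.observed_stat == pytest.approx(1.0)

    def test_exact_enumeration_matches_independent_oracle(self):
        rng = np.random.default_rng(7)
        a_vals = rng.random((4, 4))
        a_vals = (a_vals + a_vals.T) / 2
        b_vals = rng.random((4, 4))
        b_vals = (b_vals + b_vals.T) / 2
        ids = list("wxyz")
        a = hn.DyadMatrix(ids, a_vals)
        b = hn.DyadMatrix(ids, b_vals)
        res = hn.mantel_test(a, b, exact=True)

        # oracle: enumerate all 24 node permutations directly
        iu = np.triu_indices(4, 1)
        va = a.values[iu]
        null = []
        for p in itertools.permutations(range(4)):
            null.append(np.corrcoef(va, b.values[np.ix_(p, p)][iu])[0, 1])
        null = np.array(null)
        obs = np.corrcoef(va, b.values[iu])[0, 1]
        expected_p = np.mean(np.abs(null) >= abs(obs) - 1e-12)
        assert res.n_perm == 24
        assert res.observed_stat == pytest.approx(obs)
        assert res.p_value == pytest.approx(expected_p)

    def test_against_skbio_oracle(self, table5, table11):
        """Observed r and p agree with an independent Mantel
        implementation."""
        from skbio import DistanceMatrix
        from skbio.stats.distance import mantel as skbio_mantel

        # Mantel r is invariant to affine transforms; use 1-AI as distance
        def as_dm(m):
            d = 1.0 - m.values
            np.fill_diagonal(d, 0.0)
            return DistanceMatrix(d, ids=m.ids)

        r_ref, p_ref, _ = skbio_mantel(
            as_dm(table5), as_dm(table11), method="pearson",
            permutations=999, alternative="two-sided",
        )
        res = hn.mantel_test(table5, table11, n_perm=999, seed=1)
        assert res.observed_stat == pytest.approx(r_ref, abs=1e-9)
        assert abs(res.p_value - p_ref) < 0.05  # both near 0 here

    def test_constant_matrix_rejected(self, table5):
        const = hn.DyadMatrix(table5.ids, np.ones((9, 9)) - np.eye(9))
        with pytest.raises(ValidationError):
            hn.mantel_test(table5, const)

    def test_directed_input_rejected(self, table5, table6):
        with pytest.raises(ValidationError, match="symmetrize"):
            hn.mantel_test(table5, table6)
        # symmetrized directed input is accepted
        r = hn.mantel_test(table5, table6.symmetrized(), n_perm=10, seed=0)
        assert -1 <= r.observed_stat <= 1

    def test_p_invariant_to_id_ordering(self, table5, table11):
        sub = ["Bulat", "Losk", "Lovelas", "Vernij", "Zakat"]
        r1 = hn.mantel_test(
            table5.reordered(sub), table11.reordered(sub), exact=True
        )
        r2 = hn.mantel_test(
            table5.reordered(sub[::-1]), table11.reordered(sub[::-1]),
            exact=True,
        )
        assert r1.p_value == pytest.approx(r2.p_value)
        assert r1.observed_stat == pytest.approx(r2.observed_stat)
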