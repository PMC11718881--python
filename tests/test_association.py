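"""Scan-group chaining, AI arithmetic, and interaction rates."""

import itertools

import networkx as nx
import numpy as np
import pytest

import herdnet as hn
from herdnet.datatypes import ValidationError

from conftest import DAY, grouped_dataset, make_sample


class TestScanGroups:
    def test_chaining_merges_transitively(self):
        s = make_sample(
            DAY, 300,
            {i: ("rest", "stand") for i in "ABC"},
            pairs=[("A", "B"), ("B", "C")],
        )
        assert hn.scan_groups(s) == [frozenset("ABC")]

    def test_no_pairs_all_singletons(self):
        s = make_sample(DAY, 300, {i: ("rest", "stand") for i in "ABC"})
        assert sorted(hn.scan_groups(s), key=sorted) == [
            frozenset("A"), frozenset("B"), frozenset("C")
        ]

    def test_disjoint_pairs_stay_separate(self):
        s = make_sample(
            DAY, 300,
            {i: ("rest", "stand") for i in "ABCD"},
            pairs=[("A", "B"), ("C", "D")],
        )
        assert set(hn.scan_groups(s)) == {frozenset("AB"), frozenset("CD")}


class TestAssociationMatrix:
    def test_simple_proportion(self):
        groupings = [[("A", "B"), ("C",)]] * 3 + [[("A",), ("B",), ("C",)]] * 7
        ds = grouped_dataset("ABC", groupings)
        ai = hn.association_matrix(ds)
        assert ai["A", "B"] == pytest.approx(0.3)
        assert ai["A", "C"] == 0.0
        assert ai.joint_counts[0, 1] == 10

    def test_chained_dyad_counts_as_associated(self):
        ds = grouped_dataset("ABC", [[("A", "B", "C")]])
        ai = hn.association_matrix(ds)
        assert ai["A", "C"] == 1.0

    def test_joint_visibility_denominator(self):
        # B visible at only 2 of 4 scans; A-B associated at 1 of those
        samples = [
            make_sample(DAY, 300, {"A": ("rest", "stand"),
                                   "B": ("rest", "stand")},
                        pairs=[("A", "B")]),
            make_sample(DAY, 310, {"A": ("rest", "stand"),
                                   "B": ("rest", "stand")}),
            make_sample(DAY, 320, {"A": ("rest", "stand")}),
            make_sample(DAY, 330, {"A": ("rest", "stand")}),
        ]
        ds = hn.ScanDataset(individuals=["A", "B"], samples=samples)
        ai = hn.association_matrix(ds)
        assert ai["A", "B"] == pytest.approx(0.5)
        assert ai.joint_counts[0, 1] == 2
        assert not ai.never_jointly_observed.any()

    def test_never_jointly_observed_flagged(self):
        samples = [
            make_sample(DAY, 300, {"A": ("rest", "stand")}),
            make_sample(DAY, 310, {"B": ("rest", "stand")}),
        ]
        ds = hn.ScanDataset(individuals=["A", "B"], samples=samples)
        ai = hn.association_matrix(ds)
        assert ai["A", "B"] == 0.0
        assert ai.never_jointly_observed[0, 1]

    def test_unknown_id_rejected(self, planted):
        scans, _, _ = planted
        with pytest.raises(ValidationError):
            hn.association_matrix(scans, ids=["nobody"])

    def test_matches_bruteforce_oracle(self, planted):
        """Independent per-scan tally using networkx connected components."""
        scans, _, _ = planted
        ids = scans.individuals
        idx = {i: k for k, i in enumerate(ids)}
        together = np.zeros((9, 9))
        joint = np.zeros((9, 9))
        for s in scans.samples:
            g = nx.Graph()
            g.add_nodes_from(s.records)
            g.add_edges_from(tuple(p) for p in s.proximity_pairs)
            for comp in nx.connected_components(g):
                for a, b in itertools.combinations(sorted(comp), 2):
                    together[idx[a], idx[b]] += 1
                    together[idx[b], idx[a]] += 1
            for a, b in itertools.combinations(sorted(s.records), 2):
                joint[idx[a], idx[b]] += 1
                joint[idx[b], idx[a]] += 1
        expected = np.where(joint > 0, together / np.maximum(joint, 1), 0)
        ai = hn.association_matrix(scans)
        np.testing.assert_allclose(ai.values, expected)
        np.testing.assert_allclose(ai.joint_counts, joint)

    def test_bounds_and_symmetry(self, planted):
        scans, _, _ = planted
        ai = hn.association_matrix(scans)
        assert ((ai.values >= 0) & (ai.values <= 1)).all()
        np.testing.assert_allclose(ai.values, ai.values.T)


class TestInteractionRates:
    def _log(self, hours=65.0):
        return hn.ObservationLog(windows=[(DAY, 0, int(hours * 60))])

    def test_printed_maximum_rate(self):
        events = [
            hn.InteractionEvent(DAY, t, "Losk", "Zakat", "affiliative",
                                "mutual_grooming")
            for t in range(70)
        ]
        m = hn.interaction_rate_matrix(events, self._log(), "affiliative")
        assert m["Losk", "Zakat"] == pytest.approx(70 / 65)
        assert round(m["Losk", "Zakat"], 3) == 1.077

    def test_single_event_granularity(self):
        events = [hn.InteractionEvent(DAY, 0, "A", "B", "affiliative",
                                      "rubbing")]
        m = hn.interaction_rate_matrix(events, self._log(), "affiliative")
        assert m["A", "B"] == pytest.approx(1 / 65)
        assert round(m["A", "B"], 3) == 0.015

    def test_no_events_zero_matrix(self):
        m = hn.interaction_rate_matrix(
            [], self._log(), "agonistic", ids=["A", "B"]
        )
        assert (m.values == 0).all()

    def test_zero_hours_rejected(self):
        with pytest.raises(ValidationError):
            hn.ObservationLog(windows=[(DAY, 100, 100)])
        empty = hn.ObservationLog(windows=[])
        with pytest.raises(ZeroDivisionError):
            hn.interaction_rate_matrix([], empty, "affiliative", ids=["A", "B"])

    def test_nonnegative(self, planted):
        _, events, _ = planted
        log = hn.observation_log_for(
            hn.SyntheticConfig(days=10, scans_per_day=12)
        )
        m = hn.interaction_rate_matrix(events, log, "affiliative")
        assert (m.values >= 0).all()
        assert m.directed


def test_interaction_summary_percentages():
    events = []
    t = iter(range(10000))
    for _ in range(335):
        events.append(hn.InteractionEvent(DAY, next(t) % 1440, "A", "B",
                                          "affiliative", "mutual_grooming"))
    for _ in range(23):
        events.append(hn.InteractionEvent(DAY, next(t) % 1440, "A", "B",
                                          "affiliative", "mutual_sniffing"))
    for _ in range(65):
        events.append(hn.InteractionEvent(DAY, next(t) % 1440, "A", "B",
                                          "agonistic", "avoidance",
                                          role_class="defensive"))
    for _ in range(42):
        events.append(hn.InteractionEvent(DAY, next(t) % 1440, "A", "B",
                                          "agonistic", "harassment",
                                          role_class="offensive"))
    s = hn.interaction_summary(events)
    assert s["affiliative_total"] == 358
    assert s["agonistic_total"] == 107
    assert round(s["allogrooming_pct_of_affiliative"], 1) == 93.6
    assert round(s["submissive_pct_of_agonistic"], 1) == 60.7
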