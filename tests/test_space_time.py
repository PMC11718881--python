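"""Time budgets, electivity, spread of participation, enclosure split."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

import herdnet as hn
from herdnet.datatypes import ConfigError, ScanDataset, ValidationError, Zone
from herdnet.space_time import (
    spread_of_participation,
    tidy_scan_table,
    zone_counts,
)

from conftest import DAY, make_sample


def _zones(n=4, area=100.0):
    return hn.ZoneMap(
        Zone(id=f"Z{k}", area=area, enclosure="I") for k in range(n)
    )


class TestTimeBudget:
    def test_all_grazing_individual(self):
        samples = [
            make_sample(DAY, t, {"A": ("foraging", "graze")})
            for t in (310, 620, 930)  # one scan in each default bin
        ]
        ds = ScanDataset(individuals=["A"], samples=samples)
        tb = hn.time_budget(ds)
        for b in ("morning", "afternoon", "evening"):
            assert tb.loc[("A", b), "foraging"] == 1.0

    def test_rows_sum_to_one_and_match_bruteforce(self, planted):
        scans, _, _ = planted
        tb = hn.time_budget(scans)
        np.testing.assert_allclose(tb.sum(axis=1), 1.0)
        # brute-force tally for one individual/bin
        ind = scans.individuals[0]
        recs = [r for r in scans.records() if r.individual == ind
                and 300 <= r.time <= 600]
        frac = np.mean([r.behaviour_category == "foraging" for r in recs])
        assert tb.loc[(ind, "morning"), "foraging"] == pytest.approx(frac)

    def test_unbinned_bucket(self):
        samples = [make_sample(DAY, 100, {"A": ("rest", "lay")})]
        ds = ScanDataset(individuals=["A"], samples=samples)
        tb = hn.time_budget(ds)
        assert tb.loc[("A", "unbinned"), "rest"] == 1.0

    def test_overlapping_bins_rejected(self, planted):
        scans, _, _ = planted
        with pytest.raises(ConfigError):
            hn.time_budget(scans, bins=[(0, 100, "a"), (50, 200, "b")])


class TestElectivity:
    def _counts(self, rows):
        return pd.DataFrame(rows).fillna(0)

    def test_unused_zone_is_minus_one(self):
        counts = self._counts({"Z0": {"A": 10}, "Z1": {"A": 0},
                               "Z2": {"A": 5}, "Z3": {"A": 5}})
        ei = hn.electivity(counts, _zones())
        assert ei.loc["A", "Z1"] == -1.0

    def test_matching_expectation_is_zero(self):
        counts = self._counts({f"Z{k}": {"A": 5} for k in range(4)})
        ei = hn.electivity(counts, _zones())
        np.testing.assert_allclose(ei.loc["A"].to_numpy(), 0.0, atol=1e-12)

    def test_exclusive_use_hand_oracle(self):
        # only Z0 used among 4 equal zones: e = 1/4, EI = (1-e)/(1+e) = 0.6
        counts = self._counts(
            {"Z0": {"A": 7}, "Z1": {"A": 0}, "Z2": {"A": 0}, "Z3": {"A": 0}}
        )
        ei = hn.electivity(counts, _zones())
        assert ei.loc["A", "Z0"] == pytest.approx(0.6)

    def test_area_weighted_expectation(self):
        zones = hn.ZoneMap(
            [Zone(id="big", area=300.0), Zone(id="small", area=100.0)]
        )
        counts = self._counts({"big": {"A": 75}, "small": {"A": 25}})
        ei = hn.electivity(counts, zones)
        np.testing.assert_allclose(ei.loc["A"].to_numpy(), 0.0, atol=1e-12)

    def test_bounds(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 30, size=(5, 8)),
            index=[f"i{k}" for k in range(5)],
            columns=[f"Z{k}" for k in range(8)],
        )
        ei = hn.electivity(counts, _zones(8))
        assert ((ei.to_numpy() >= -1) & (ei.to_numpy() <= 1)).all()

    def test_zero_area_zone_rejected(self):
        with pytest.raises(ConfigError):
            Zone(id="bad", area=0.0)


class TestSpi:
    def test_uniform_counts_zero(self):
        assert spread_of_participation(
            pd.Series({f"Z{k}": 5 for k in range(22)})
        ) == pytest.approx(0.0)

    def test_single_zone_one(self):
        counts = pd.Series({f"Z{k}": 0 for k in range(22)})
        counts["Z3"] = 40
        assert spread_of_participation(counts) == pytest.approx(1.0)

    def test_hand_oracle_10_5_5(self):
        # N=20, M=20/3; n_a=1, F_a=10, n_b=2, F_b=10
        # SPI = (M*(2-1) + 0) / (2*(20-M)) = (20/3)/(2*40/3) = 0.25
        assert spread_of_participation(
            pd.Series({"a": 10, "b": 5, "c": 5})
        ) == pytest.approx(0.25)

    def test_monotone_toward_uniformity(self):
        # progressively flattening 4-zone distributions
        seq = [(40, 0, 0, 0), (28, 4, 4, 4), (19, 7, 7, 7), (10, 10, 10, 10)]
        spis = [
            spread_of_participation(
                pd.Series(dict(zip("abcd", c)))
            )
            for c in seq
        ]
        assert all(x > y for x, y in zip(spis, spis[1:]))

    def test_single_zone_available_undefined(self):
        with pytest.raises(ZeroDivisionError):
            spread_of_participation(pd.Series({"only": 10}))

    def test_zero_observations_rejected(self):
        with pytest.raises(ValidationError):
            spread_of_participation(pd.Series({"a": 0, "b": 0}))


class TestAvailabilitySplit:
    def _dataset(self):
        zones = hn.default_zone_map()
        samples = []
        for d in range(4):
            day = DAY + dt.timedelta(days=d)
            zone = "D1" if d < 2 else "A1"  # enclosure II only early
            samples.append(
                make_sample(day, 300, {"A": ("rest", "stand")},
                            zones={"A": zone})
            )
        return ScanDataset(individuals=["A"], samples=samples), zones

    def test_partitions_scans_and_availability(self):
        ds, zones = self._dataset()
        cut = DAY + dt.timedelta(days=2)
        a, b, avail_a, avail_b = hn.availability_split(ds, cut, zones)
        assert a.n_scans + b.n_scans == ds.n_scans
        assert {s.day for s in a.samples} == {DAY, DAY + dt.timedelta(days=1)}
        assert len(avail_a) == 22
        assert len(avail_b) == 18
        assert not any(z.startswith(("D", "E")) for z in avail_b)

    def test_stray_enclosure_two_records_warn(self):
        ds, zones = self._dataset()
        cut = DAY + dt.timedelta(days=1)  # second D1 day falls in period B
        with pytest.warns(UserWarning, match="enclosure-II"):
            hn.availability_split(ds, cut, zones)

    def test_cutover_outside_span_rejected(self):
        ds, zones = self._dataset()
        with pytest.raises(ConfigError):
            hn.availability_split(ds, DAY, zones)

    def test_identical_distribution_gives_equal_spi(self):
        zones = hn.ZoneMap([Zone(id="Z0", area=1.0), Zone(id="Z1", area=1.0)])
        samples = []
        for d in range(4):
            day = DAY + dt.timedelta(days=d)
            for k, z in enumerate(["Z0", "Z0", "Z0", "Z1"]):
                samples.append(
                    make_sample(day, 300 + 10 * k,
                                {"A": ("rest", "stand")}, zones={"A": z})
                )
        ds = ScanDataset(individuals=["A"], samples=samples)
        cut = DAY + dt.timedelta(days=2)
        a, b, avail_a, avail_b = hn.availability_split(ds, cut, zones)
        spi_a = spread_of_participation(zone_counts(a), avail_a)
        spi_b = spread_of_participation(zone_counts(b), avail_b)
        assert spi_a["A"] == pytest.approx(spi_b["A"])


class TestProfileAndTidyTable:
    def test_counts_sum_to_zone_recorded_scans(self, planted):
        scans, _, _ = planted
        counts = zone_counts(scans)
        n_zone_recs = sum(1 for r in scans.records() if r.zone is not None)
        assert counts.to_numpy().sum() == n_zone_recs

    def test_space_use_profile_bounds(self, planted):
        scans, _, _ = planted
        prof = hn.space_use_profile(scans, hn.default_zone_map())
        assert ((prof.electivity.to_numpy() >= -1)
                & (prof.electivity.to_numpy() <= 1)).all()
        assert ((prof.spi >= 0) & (prof.spi <= 1)).all()

    def test_tidy_table_columns(self, planted):
        scans, _, truth = planted
        df = tidy_scan_table(
            scans, truth.true_partition, hn.default_zone_map(),
            cutover_day=DAY + dt.timedelta(days=5),
        )
        assert set(df.columns) >= {
            "individual", "cluster", "bin", "period", "behaviour_category",
            "zone", "hay_zone",
        }
        assert set(df["period"]) == {"A", "B"}
        assert len(df) == sum(len(s.records) for s in scans.samples)
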