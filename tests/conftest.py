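import datetime as dt

import numpy as np
import pytest

from herdnet import (
    ScanDataset,
    ScanRecord,
    ScanSample,
    SyntheticConfig,
    generate,
    load_fixture,
)

DAY = dt.date(2015, 7, 21)


def make_sample(day, time, behaviours, pairs=(), zones=None):
    """Build a ScanSample from {id: (category, pattern)} plus pair tuples."""
    records = {
        ind: ScanRecord(
            day=day,
            time=time,
            individual=ind,
            behaviour_category=cat,
            activity_pattern=pat,
            zone=None if zones is None else zones.get(ind),
        )
        for ind, (cat, pat) in behaviours.items()
    }
    return ScanSample(
        day=day,
        time=time,
        records=records,
        proximity_pairs={frozenset(p) for p in pairs},
    )


def grouped_dataset(ids, groupings, day=DAY, start=300):
    """Dataset from a list of scans, each scan a list of groups (tuples).

    Every individual rests ('stand') at every scan; proximity pairs are the
    within-group dyads (chaining recovers the groups).
    """
    samples = []
    for k, groups in enumerate(groupings):
        present = [i for g in groups for i in g]
        behaviours = {i: ("rest", "stand") for i in present}
        pairs = []
        for g in groups:
            g = list(g)
            pairs.extend((g[j], g[j + 1]) for j in range(len(g) - 1))
        samples.append(
            make_sample(day, start + 10 * k, behaviours, pairs)
        )
    return ScanDataset(individuals=list(ids), samples=samples)


@pytest.fixture(scope="session")
def table5():
    return load_fixture("table5_ai")


@pytest.fixture(scope="session")
def table6():
    return load_fixture("table6_affil_rates")


@pytest.fixture(scope="session")
def table7():
    return load_fixture("table7_node_measures")


@pytest.fixture(scope="session")
def table11():
    return load_fixture("table11_bsi")


@pytest.fixture(scope="session")
def planted():
    """Small planted-structure dataset shared across tests."""
    cfg = SyntheticConfig(
        days=10, scans_per_day=12, p_within=0.6, p_between=0.05, seed=42
    )
    scans, events, truth = generate(cfg)
    return scans, events, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
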