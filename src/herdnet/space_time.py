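"""Time budgets, electivity indices, and spread of participation.

Space use is scored against zone availability: the electivity index (EI)
compares a zone's observed share of an individual's records with the share
expected from zone areas, and the spread of participation index (SPI)
summarizes how evenly an individual distributes itself over the available
zones (0 = perfectly even, 1 = a single zone).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    ConfigError,
    Partition,
    ScanDataset,
    ValidationError,
    ZoneMap,
)

__all__ = ["DEFAULT_BINS", "time_budget", "zone_counts", "electivity",
           "spread_of_participation", "availability_split",
           "SpaceUseProfile", "space_use_profile", "tidy_scan_table"]

#: Default time-of-day bins (minutes since midnight): morning 05:00-10:00,
#: afternoon 10:10-15:00, evening 15:10-20:30.
DEFAULT_BINS: tuple[tuple[int, int, str], ...] = (
    (5 * 60, 10 * 60, "morning"),
    (10 * 60 + 10, 15 * 60, "afternoon"),
    (15 * 60 + 10, 20 * 60 + 30, "evening"),
)


def _bin_label(time: int, bins: Sequence[tuple[int, int, str]]) -> str:
    for start, end, name in bins:
        if start <= time <= end:
            return name
    return "unbinned"


def time_budget(
    scans: ScanDataset,
    bins: Sequence[tuple[int, int, str]] | None = None,
    level: str = "category",
) -> pd.DataFrame:
    """Proportion of each individual's scans per behaviour per time bin.

    Returns a DataFrame indexed by (individual, bin) with one column per
    behaviour; rows sum to 1. Scans outside every bin fall in an
    ``unbinned`` bucket rather than being dropped silently.
    """
    bins = DEFAULT_BINS if bins is None else bins
    spans = sorted((s, e) for s, e, _ in bins)
    for (s1, e1), (s2, _) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise ConfigError("time bins overlap")
    rows = [
        {
            "individual": r.individual,
            "bin": _bin_label(r.time, bins),
            "behaviour": (r.behaviour_category if level == "category"
                          else r.activity_pattern),
        }
        for r in scans.records()
    ]
    df = pd.DataFrame(rows)
    counts = df.groupby(["individual", "bin", "behaviour"]).size()
    props = counts / counts.groupby(["individual", "bin"]).transform("sum")
    return props.unstack("behaviour", fill_value=0.0)


def zone_counts(scans: ScanDataset) -> pd.DataFrame:
    """Per-individual zone observation counts; records with no zone are
    excluded."""
    rows = [
        {"individual": r.individual, "zone": r.zone}
        for r in scans.records()
        if r.zone is not None
    ]
    if not rows:
        raise ValidationError("no zone-annotated records")
    df = pd.DataFrame(rows)
    return (
        df.groupby(["individual", "zone"]).size().unstack(fill_value=0)
    )


def electivity(
    counts: pd.DataFrame,
    zones: ZoneMap,
    available: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Ivlev electivity per individual per zone.

    EI_z = (o_z − e_z) / (o_z + e_z), with o_z the observed share of the
    individual's records in zone z and e_z the share of z in the total
    available area. −1 for a zone never used, 0 when used exactly as
    expected, +1 in the limit of exclusive use of a vanishing zone.
    """
    available = list(zones if available is None else available)
    areas = zones.areas(available)
    expected = areas / areas.sum()
    counts = counts.reindex(columns=available, fill_value=0)
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        empty = list(totals.index[totals == 0])
        raise ValidationError(f"no observations for {empty}")
    observed = counts.div(totals, axis=0)
    num = observed - expected
    den = observed + expected
    return num / den


def spread_of_participation(
    counts: pd.Series | pd.DataFrame,
    available: Sequence[str] | None = None,
) -> float | pd.Series:
    """Dickens' spread of participation index.

    SPI = (M(n_b − n_a) + (F_a − F_b)) / (2(N − M)) with N total
    observations, M = N / number of available zones, n_a/n_b the number of
    zones used more/less than M, and F_a/F_b the observations they hold.
    0 when all zones are used equally, 1 when a single zone holds
    everything.
    """
    if isinstance(counts, pd.DataFrame):
        return counts.apply(
            lambda row: spread_of_participation(row, available), axis=1
        ).rename("SPI")
    if available is not None:
        counts = counts.reindex(list(available), fill_value=0)
    c = counts.to_numpy(dtype=float)
    n_zones = c.size
    if n_zones < 2:
        raise ZeroDivisionError("SPI undefined with fewer than two zones")
    total = c.sum()
    if total == 0:
        raise ValidationError("SPI undefined with zero observations")
    m = total / n_zones
    above = c > m
    below = c < m
    f_a, f_b = c[above].sum(), c[below].sum()
    n_a, n_b = int(above.sum()), int(below.sum())
    if total == m:  # single zone available already excluded; safeguard
        raise ZeroDivisionError("SPI denominator is zero")
    return float((m * (n_b - n_a) + (f_a - f_b)) / (2 * (total - m)))


def availability_split(
    scans: ScanDataset,
    cutover_day: _dt.date,
    zones: ZoneMap | None = None,
) -> tuple[ScanDataset, ScanDataset, list[str], list[str]]:
    """Split a dataset at the day a secondary enclosure was closed off.

    Returns (period A scans, period B scans, zones available in A, zones
    available in B): period A covers days before ``cutover_day`` with every
    zone available; period B covers the rest with enclosure II zones
    removed from the availability set. Period-B records located in
    enclosure II trigger a validation warning via ``warnings``.
    """
    days = scans.days
    if not days or not (days[0] < cutover_day <= days[-1]):
        raise ConfigError(
            f"cutover {cutover_day} outside study span {days[0] if days else '?'}"
            f"..{days[-1] if days else '?'}"
        )
    period_a = scans.subset_days([d for d in days if d < cutover_day])
    period_b = scans.subset_days([d for d in days if d >= cutover_day])
    if zones is None:
        avail_a = sorted({r.zone for r in scans.records() if r.zone})
        avail_b = avail_a
    else:
        avail_a = sorted(zones)
        avail_b = sorted(zones.in_enclosure("I"))
        closed = set(avail_a) - set(avail_b)
        stray = [
            r for r in period_b.records() if r.zone in closed
        ]
        if stray:
            import warnings

            r = stray[0]
            warnings.warn(
                f"{len(stray)} period-B record(s) in closed enclosure-II "
                f"zones (first: {r.individual} in {r.zone} on {r.day})",
                stacklevel=2,
            )
    return period_a, period_b, avail_a, avail_b


@dataclass
class SpaceUseProfile:
    """Zone counts with electivity and spread-of-participation indices."""

    counts: pd.DataFrame          # individual x zone
    electivity: pd.DataFrame      # individual x zone, in [-1, 1]
    spi: pd.Series                # per individual, in [0, 1]
    available_zones: list[str]


def space_use_profile(
    scans: ScanDataset,
    zones: ZoneMap,
    available: Sequence[str] | None = None,
) -> SpaceUseProfile:
    counts = zone_counts(scans)
    available = list(zones if available is None else available)
    counts = counts.reindex(columns=available, fill_value=0)
    return SpaceUseProfile(
        counts=counts,
        electivity=electivity(counts, zones, available),
        spi=spread_of_participation(counts, available),
        available_zones=available,
    )


def tidy_scan_table(
    scans: ScanDataset,
    partition: Partition | None = None,
    zones: ZoneMap | None = None,
    bins: Sequence[tuple[int, int, str]] | None = None,
    cutover_day: _dt.date | None = None,
) -> pd.DataFrame:
    """One row per scan record, annotated for external mixed-model tools.

    Columns: individual, cluster, day, time, bin, period, behaviour
    category, activity pattern, zone, and a hay-zone flag. The regression
    itself is out of scope here; this is the exchange format.
    """
    bins = DEFAULT_BINS if bins is None else bins
    rows = []
    for r in scans.records():
        hay = bool(zones and r.zone and zones[r.zone].has_hay)
        rows.append(
            {
                "individual": r.individual,
                "cluster": (partition.membership.get(r.individual)
                            if partition else None),
                "day": r.day.isoformat(),
                "time": r.time,
                "bin": _bin_label(r.time, bins),
                "period": (
                    None if cutover_day is None
                    else ("A" if r.day < cutover_day else "B")
                ),
                "behaviour_category": r.behaviour_category,
                "activity_pattern": r.activity_pattern,
                "zone": r.zone,
                "hay_zone": hay,
            }
        )
    return pd.DataFrame(rows)
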