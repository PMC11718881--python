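"""Core domain types for scan-sampled social data.

The observational unit is the *scan sample*: an instantaneous record of the
behaviour, zone, and spatial grouping of every visible individual, taken at a
fixed interval (10 min in the study protocol this package emulates). Social
interactions are recorded separately as an all-occurrence event stream.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BEHAVIOUR_CATEGORIES",
    "ETHOGRAM",
    "PATTERN_TO_CATEGORY",
    "AFFILIATIVE_SUBTYPES",
    "OFFENSIVE_SUBTYPES",
    "DEFENSIVE_SUBTYPES",
    "HerdnetError",
    "FormatError",
    "ValidationError",
    "ConfigError",
    "DegeneracyError",
    "PedigreeError",
    "ReportError",
    "Individual",
    "ScanRecord",
    "ScanSample",
    "ScanDataset",
    "InteractionEvent",
    "DyadMatrix",
    "Zone",
    "ZoneMap",
    "ObservationLog",
    "Partition",
    "PermutationResult",
]

# ---------------------------------------------------------------------------
# Ethogram

BEHAVIOUR_CATEGORIES: tuple[str, ...] = (
    "foraging",
    "rest",
    "locomotion",
    "social",
    "vigilance",
    "other",
)

#: Activity patterns nested under each behavioural category.
ETHOGRAM: dict[str, frozenset[str]] = {
    "foraging": frozenset({"drink", "feed_on_hay", "graze"}),
    "rest": frozenset({"lay", "head_to_tail", "stand"}),
    "locomotion": frozenset({"gallop", "trot", "walk"}),
    "social": frozenset({"mutual_grooming"}),
    "vigilance": frozenset({"observe"}),
    "other": frozenset({"scratch", "wallow"}),
}

PATTERN_TO_CATEGORY: dict[str, str] = {
    p: c for c, ps in ETHOGRAM.items() for p in ps
}

AFFILIATIVE_SUBTYPES = frozenset({"mutual_grooming", "mutual_sniffing", "rubbing"})
OFFENSIVE_SUBTYPES = frozenset(
    {"bite", "bite_threat", "ear_threat", "harassment", "kick_threat"}
)
DEFENSIVE_SUBTYPES = frozenset({"kick", "avoidance"})


# ---------------------------------------------------------------------------
# Errors


class HerdnetError(Exception):
    """Base class for all package errors."""


class FormatError(HerdnetError):
    """A file does not conform to the expected tabular layout."""


class ValidationError(HerdnetError):
    """Data violate a domain invariant (ethogram, ids, pairing rules)."""


class ConfigError(HerdnetError):
    """An infeasible configuration value."""


class DegeneracyError(HerdnetError):
    """A permutation scheme has no legal move on the given data."""


class PedigreeError(HerdnetError):
    """A pedigree is cyclic or otherwise malformed."""


class ReportError(HerdnetError):
    """A result object cannot be serialized into a report."""


# ---------------------------------------------------------------------------
# Individuals and scans


@dataclass(frozen=True)
class Individual:
    """A study subject, optionally anchored to a studbook pedigree entry."""

    id: str
    studbook_id: int | None = None
    sire_id: int | None = None
    dam_id: int | None = None
    birth_date: _dt.date | None = None

    def __post_init__(self) -> None:
        if (
            self.sire_id is not None
            and self.dam_id is not None
            and self.sire_id == self.dam_id
        ):
            raise ValidationError(
                f"individual {self.id!r}: sire and dam cannot both be {self.sire_id}"
            )


@dataclass(frozen=True)
class ScanRecord:
    """One individual's state at one scan sample."""

    day: _dt.date
    time: int  # minutes since midnight
    individual: str
    behaviour_category: str
    activity_pattern: str
    zone: str | None = None

    def __post_init__(self) -> None:
        if self.behaviour_category not in ETHOGRAM:
            raise ValidationError(
                f"unknown behaviour category {self.behaviour_category!r} "
                f"({self.individual} at {self.day} {self.time})"
            )
        cat = PATTERN_TO_CATEGORY.get(self.activity_pattern)
        if cat is None:
            raise ValidationError(
                f"unknown activity pattern {self.activity_pattern!r} "
                f"({self.individual} at {self.day} {self.time})"
            )
        if cat != self.behaviour_category:
            raise ValidationError(
                f"activity {self.activity_pattern!r} belongs to category {cat!r}, "
                f"not {self.behaviour_category!r} "
                f"({self.individual} at {self.day} {self.time})"
            )
        if not (0 <= self.time < 24 * 60):
            raise ValidationError(
                f"time {self.time} outside 0..1439 ({self.individual} at {self.day})"
            )


@dataclass
class ScanSample:
    """All records taken at one instant, plus proximity pairs.

    ``proximity_pairs`` holds unordered id pairs observed within one body
    length of each other; spatial groups are derived from them by transitive
    chaining (see :func:`herdnet.association.scan_groups`).
    """

    day: _dt.date
    time: int
    records: dict[str, ScanRecord]
    proximity_pairs: set[frozenset[str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        for pair in self.proximity_pairs:
            if len(pair) != 2:
                raise ValidationError(f"proximity pair {set(pair)} is not a dyad")
            for ind in pair:
                if ind not in self.records:
                    raise ValidationError(
                        f"proximity pair member {ind!r} has no record at "
                        f"{self.day} {self.time}"
                    )

    @property
    def individuals(self) -> frozenset[str]:
        return frozenset(self.records)


@dataclass
class ScanDataset:
    """A time-ordered collection of scan samples."""

    individuals: list[str]
    samples: list[ScanSample]

    def __post_init__(self) -> None:
        known = set(self.individuals)
        if len(known) != len(self.individuals):
            raise ValidationError("duplicate individual ids")
        for s in self.samples:
            extra = set(s.records) - known
            if extra:
                raise ValidationError(
                    f"unknown individual(s) {sorted(extra)} at {s.day} {s.time}"
                )
        self.samples.sort(key=lambda s: (s.day, s.time))

    @property
    def n_scans(self) -> int:
        return len(self.samples)

    @property
    def days(self) -> list[_dt.date]:
        return sorted({s.day for s in self.samples})

    def records(self) -> Iterable[ScanRecord]:
        for s in self.samples:
            yield from s.records.values()

    def subset_days(self, days: Iterable[_dt.date]) -> "ScanDataset":
        keep = set(days)
        return ScanDataset(
            individuals=list(self.individuals),
            samples=[s for s in self.samples if s.day in keep],
        )


@dataclass(frozen=True)
class InteractionEvent:
    """A directed social interaction from an all-occurrence event stream."""

    day: _dt.date
    time: int
    actor: str
    recipient: str
    kind: str  # affiliative | agonistic
    subtype: str
    role_class: str | None = None  # offensive | defensive, agonistic only

    def __post_init__(self) -> None:
        if self.actor == self.recipient:
            raise ValidationError(
                f"self-interaction by {self.actor!r} at {self.day} {self.time}"
            )
        if self.kind == "affiliative":
            if self.subtype not in AFFILIATIVE_SUBTYPES:
                raise ValidationError(
                    f"{self.subtype!r} is not an affiliative behaviour"
                )
        elif self.kind == "agonistic":
            if self.role_class == "offensive":
                ok = OFFENSIVE_SUBTYPES
            elif self.role_class == "defensive":
                ok = DEFENSIVE_SUBTYPES
            else:
                raise ValidationError(
                    f"agonistic event needs role_class offensive/defensive, "
                    f"got {self.role_class!r}"
                )
            if self.subtype not in ok:
                raise ValidationError(
                    f"{self.subtype!r} is not a {self.role_class} behaviour"
                )
        else:
            raise ValidationError(f"unknown interaction kind {self.kind!r}")


# ---------------------------------------------------------------------------
# Matrices


class DyadMatrix:
    """A square individual-by-individual matrix with labelled axes.

    Symmetric variants hold association-type indices (AI, BSI, kinship);
    directed variants hold interaction rates or win counts. The diagonal is
    defined as zero.
    """

    def __init__(
        self,
        ids: Sequence[str],
        values: np.ndarray | Sequence[Sequence[float]],
        directed: bool = False,
    ) -> None:
        self.ids = list(ids)
        self.values = np.asarray(values, dtype=float).copy()
        self.directed = bool(directed)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match {n} ids"
            )
        if len(set(self.ids)) != n:
            raise ValidationError("duplicate ids in matrix")
        np.fill_diagonal(self.values, 0.0)
        if not self.directed and not np.allclose(self.values, self.values.T):
            raise ValidationError("undirected matrix must be symmetric")
        self._index = {ind: i for i, ind in enumerate(self.ids)}

    # -- access ------------------------------------------------------------

    def __getitem__(self, key: tuple[str, str]) -> float:
        a, b = key
        return float(self.values[self._index[a], self._index[b]])

    def index(self, ind: str) -> int:
        return self._index[ind]

    @property
    def n(self) -> int:
        return len(self.ids)

    def upper_triangle(self) -> np.ndarray:
        """Off-diagonal values: upper triangle if symmetric, all ordered
        pairs if directed."""
        n = self.n
        if self.directed:
            mask = ~np.eye(n, dtype=bool)
            return self.values[mask]
        return self.values[np.triu_indices(n, k=1)]

    # -- transforms --------------------------------------------------------

    def symmetrized(self) -> "DyadMatrix":
        """Sum the two directions of a directed matrix; no-op if symmetric."""
        if not self.directed:
            return DyadMatrix(self.ids, self.values, directed=False)
        return DyadMatrix(self.ids, self.values + self.values.T, directed=False)

    def reordered(self, ids: Sequence[str]) -> "DyadMatrix":
        idx = [self._index[i] for i in ids]
        return DyadMatrix(ids, self.values[np.ix_(idx, idx)], self.directed)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, directed: bool = False) -> "DyadMatrix":
        if list(df.index) != list(df.columns):
            raise FormatError("matrix CSV must have identical row/column labels")
        return cls(list(df.index), df.to_numpy(dtype=float), directed=directed)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        kind = "directed" if self.directed else "symmetric"
        return f"<DyadMatrix {kind} n={self.n}>"


# ---------------------------------------------------------------------------
# Zones and observation effort


@dataclass(frozen=True)
class Zone:
    id: str
    area: float  # m^2
    has_hay: bool = False
    has_water: bool = False
    enclosure: str = "I"

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ConfigError(f"zone {self.id!r} has non-positive area {self.area}")


class ZoneMap(Mapping[str, Zone]):
    """Mapping zone id -> :class:`Zone`."""

    def __init__(self, zones: Iterable[Zone]) -> None:
        self._zones: dict[str, Zone] = {}
        for z in zones:
            if z.id in self._zones:
                raise ConfigError(f"duplicate zone id {z.id!r}")
            self._zones[z.id] = z

    def __getitem__(self, key: str) -> Zone:
        return self._zones[key]

    def __iter__(self):
        return iter(self._zones)

    def __len__(self) -> int:
        return len(self._zones)

    def areas(self, ids: Iterable[str] | None = None) -> pd.Series:
        ids = list(self._zones if ids is None else ids)
        return pd.Series({z: self._zones[z].area for z in ids}, name="area")

    def in_enclosure(self, enclosure: str) -> list[str]:
        return [z.id for z in self._zones.values() if z.enclosure == enclosure]


@dataclass
class ObservationLog:
    """Per-day observation windows; total contact hours is their sum."""

    windows: list[tuple[_dt.date, int, int]]  # (day, start_min, end_min)

    def __post_init__(self) -> None:
        per_day: dict[_dt.date, list[tuple[int, int]]] = {}
        for day, start, end in self.windows:
            if end <= start:
                raise ValidationError(f"window on {day} has end <= start")
            per_day.setdefault(day, []).append((start, end))
        for day, ws in per_day.items():
            ws.sort()
            for (s1, e1), (s2, _) in zip(ws, ws[1:]):
                if s2 < e1:
                    raise ValidationError(f"overlapping windows on {day}")

    @property
    def total_hours(self) -> float:
        return sum(end - start for _, start, end in self.windows) / 60.0

    def contains(self, day: _dt.date, time: int) -> bool:
        return any(
            d == day and start <= time <= end for d, start, end in self.windows
        )


# ---------------------------------------------------------------------------
# Results containers


@dataclass
class Partition:
    """Individual -> community label, with the modularity of the split."""

    membership: dict[str, int]
    modularity: float | None = None

    @property
    def labels(self) -> list[int]:
        return sorted(set(self.membership.values()))

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))

    def community(self, label: int) -> frozenset[str]:
        return frozenset(i for i, c in self.membership.items() if c == label)

    def communities(self) -> list[frozenset[str]]:
        return [self.community(c) for c in self.labels]

    def as_array(self, ids: Sequence[str]) -> np.ndarray:
        return np.array([self.membership[i] for i in ids], dtype=int)

    def as_sets(self) -> set[frozenset[str]]:
        return set(self.communities())


@dataclass
class PermutationResult:
    """Observed statistic, its permutation null, and the empirical p-value."""

    observed_stat: float
    null_stats: np.ndarray
    p_value: float
    n_perm: int
    seed: int
    alternative: str = "greater"
    method: str = ""

    def __post_init__(self) -> None:
        self.null_stats = np.asarray(self.null_stats, dtype=float)
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")
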