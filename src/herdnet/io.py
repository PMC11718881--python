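"""CSV/JSON readers and writers.

All tabular files are UTF-8, comma-separated, with a mandatory header row.
Scan data live in two files: ``scans.csv`` with one row per individual per
scan, and a companion ``pairs.csv`` listing the proximity pairs observed at
each scan. Matrices are written as labelled CSV (ids as header row and first
column); reports are JSON with deterministic key order.
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .datatypes import (
    DyadMatrix,
    FormatError,
    InteractionEvent,
    ObservationLog,
    Partition,
    PermutationResult,
    ReportError,
    ScanDataset,
    ScanRecord,
    ScanSample,
    ValidationError,
    Zone,
    ZoneMap,
)

__all__ = [
    "load_scan_dataset",
    "write_scan_dataset",
    "load_events",
    "write_events",
    "load_zones",
    "write_zones",
    "load_obslog",
    "write_obslog",
    "load_matrix",
    "write_matrix",
    "load_partition",
    "write_partition",
    "write_report",
]

SCAN_COLUMNS = ["day", "time", "individual", "behaviour_category",
                "activity_pattern", "zone"]
PAIR_COLUMNS = ["day", "time", "id_a", "id_b"]
EVENT_COLUMNS = ["day", "time", "actor", "recipient", "kind", "subtype",
                 "role_class"]


def _parse_day(value: Any, context: str) -> _dt.date:
    try:
        return _dt.date.fromisoformat(str(value))
    except ValueError as exc:
        raise FormatError(f"bad date {value!r} in {context}") from exc


def _parse_time(value: Any, context: str) -> int:
    try:
        t = int(value)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"malformed time {value!r} in {context}") from exc
    if not 0 <= t < 24 * 60:
        raise FormatError(f"time {t} outside 0..1439 in {context}")
    return t


def _require_columns(df: pd.DataFrame, cols: list[str], path: Path,
                     optional: tuple[str, ...] = ()) -> None:
    missing = [c for c in cols if c not in df.columns and c not in optional]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")


def load_scan_dataset(
    scans_path: str | Path,
    pairs_path: str | Path | None = None,
) -> ScanDataset:
    """Load a scan dataset from ``scans.csv`` (+ optional ``pairs.csv``).

    Rows failing ethogram validation (activity pattern not belonging to its
    behavioural category), unknown ids in the pairs file, or malformed
    times are rejected with an error naming the offending row.
    """
    scans_path = Path(scans_path)
    df = pd.read_csv(scans_path, dtype=str, keep_default_na=False)
    _require_columns(df, SCAN_COLUMNS, scans_path, optional=("zone",))

    samples: dict[tuple[_dt.date, int], ScanSample] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        ctx = f"{scans_path} row {i}"
        day = _parse_day(row.day, ctx)
        time = _parse_time(row.time, ctx)
        zone = getattr(row, "zone", "") or None
        try:
            rec = ScanRecord(
                day=day,
                time=time,
                individual=row.individual,
                behaviour_category=row.behaviour_category,
                activity_pattern=row.activity_pattern,
                zone=zone,
            )
        except ValidationError as exc:
            raise ValidationError(f"{ctx}: {exc}") from exc
        key = (day, time)
        sample = samples.setdefault(
            key, ScanSample(day=day, time=time, records={})
        )
        if rec.individual in sample.records:
            raise ValidationError(
                f"{ctx}: duplicate record for {rec.individual!r} at {day} {time}"
            )
        sample.records[rec.individual] = rec

    if pairs_path is not None:
        pairs_path = Path(pairs_path)
        pdf = pd.read_csv(pairs_path, dtype=str, keep_default_na=False)
        _require_columns(pdf, PAIR_COLUMNS, pairs_path)
        for i, row in enumerate(pdf.itertuples(index=False), start=2):
            ctx = f"{pairs_path} row {i}"
            day = _parse_day(row.day, ctx)
            time = _parse_time(row.time, ctx)
            key = (day, time)
            if key not in samples:
                raise ValidationError(f"{ctx}: no scan at {day} {time}")
            sample = samples[key]
            for ind in (row.id_a, row.id_b):
                if ind not in sample.records:
                    raise ValidationError(
                        f"{ctx}: {ind!r} has no record at {day} {time}"
                    )
            if row.id_a == row.id_b:
                raise ValidationError(f"{ctx}: pair of {row.id_a!r} with itself")
            sample.proximity_pairs.add(frozenset((row.id_a, row.id_b)))

    individuals = sorted({r.individual for s in samples.values()
                          for r in s.records.values()})
    return ScanDataset(individuals=individuals, samples=list(samples.values()))


def write_scan_dataset(
    ds: ScanDataset,
    scans_path: str | Path,
    pairs_path: str | Path | None = None,
) -> None:
    rows = [
        {
            "day": r.day.isoformat(),
            "time": r.time,
            "individual": r.individual,
            "behaviour_category": r.behaviour_category,
            "activity_pattern": r.activity_pattern,
            "zone": r.zone or "",
        }
        for s in ds.samples
        for r in sorted(s.records.values(), key=lambda r: r.individual)
    ]
    pd.DataFrame(rows, columns=SCAN_COLUMNS).to_csv(scans_path, index=False)
    if pairs_path is not None:
        prow = []
        for s in ds.samples:
            for pair in sorted(s.proximity_pairs, key=sorted):
                a, b = sorted(pair)
                prow.append(
                    {"day": s.day.isoformat(), "time": s.time,
                     "id_a": a, "id_b": b}
                )
        pd.DataFrame(prow, columns=PAIR_COLUMNS).to_csv(pairs_path, index=False)


def load_events(path: str | Path) -> list[InteractionEvent]:
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, EVENT_COLUMNS, path, optional=("role_class",))
    events = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        ctx = f"{path} row {i}"
        try:
            events.append(
                InteractionEvent(
                    day=_parse_day(row.day, ctx),
                    time=_parse_time(row.time, ctx),
                    actor=row.actor,
                    recipient=row.recipient,
                    kind=row.kind,
                    subtype=row.subtype,
                    role_class=getattr(row, "role_class", "") or None,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{ctx}: {exc}") from exc
    return events


def write_events(events: list[InteractionEvent], path: str | Path) -> None:
    rows = [
        {
            "day": e.day.isoformat(),
            "time": e.time,
            "actor": e.actor,
            "recipient": e.recipient,
            "kind": e.kind,
            "subtype": e.subtype,
            "role_class": e.role_class or "",
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)


def load_zones(path: str | Path) -> ZoneMap:
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ["zone", "area", "has_hay", "has_water", "enclosure"],
                     path)
    return ZoneMap(
        Zone(
            id=row.zone,
            area=float(row.area),
            has_hay=row.has_hay in ("1", "True", "true"),
            has_water=row.has_water in ("1", "True", "true"),
            enclosure=row.enclosure,
        )
        for row in df.itertuples(index=False)
    )


def write_zones(zones: ZoneMap, path: str | Path) -> None:
    rows = [
        {
            "zone": z.id,
            "area": z.area,
            "has_hay": int(z.has_hay),
            "has_water": int(z.has_water),
            "enclosure": z.enclosure,
        }
        for z in zones.values()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_obslog(path: str | Path) -> ObservationLog:
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ["day", "start", "end"], path)
    return ObservationLog(
        windows=[
            (
                _parse_day(r.day, f"{path} row {i}"),
                _parse_time(r.start, f"{path} row {i}"),
                _parse_time(r.end, f"{path} row {i}"),
            )
            for i, r in enumerate(df.itertuples(index=False), start=2)
        ]
    )


def write_obslog(log: ObservationLog, path: str | Path) -> None:
    rows = [
        {"day": d.isoformat(), "start": s, "end": e} for d, s, e in log.windows
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_matrix(path: str | Path, directed: bool = False) -> DyadMatrix:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return DyadMatrix.from_dataframe(df, directed=directed)


def write_matrix(m: DyadMatrix, path: str | Path) -> None:
    m.to_dataframe().to_csv(path)


def load_partition(path: str | Path) -> Partition:
    df = pd.read_csv(path, dtype={"individual": str, "cluster": int})
    return Partition(membership=dict(zip(df["individual"], df["cluster"])))


def write_partition(p: Partition, path: str | Path) -> None:
    pd.DataFrame(
        {"individual": list(p.membership), "cluster": list(p.membership.values())}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Reports


def _jsonable(obj: Any, matrices: dict[str, DyadMatrix], prefix: str) -> Any:
    """Recursively convert results to JSON-safe values, collecting matrices."""
    if isinstance(obj, DyadMatrix):
        key = prefix.strip(".")
        matrices[key] = obj
        return {"matrix_csv": f"{key}.csv", "ids": obj.ids,
                "directed": obj.directed}
    if isinstance(obj, PermutationResult):
        return {
            "observed_stat": obj.observed_stat,
            "p_value": obj.p_value,
            "n_perm": obj.n_perm,
            "seed": obj.seed,
            "alternative": obj.alternative,
            "method": obj.method,
            "null_mean": float(np.mean(obj.null_stats))
            if obj.null_stats.size else None,
        }
    if isinstance(obj, Partition):
        return {"membership": dict(sorted(obj.membership.items())),
                "modularity": obj.modularity}
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="index"))
    if isinstance(obj, pd.Series):
        return json.loads(obj.to_json())
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, _dt.date):
        return obj.isoformat()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v, matrices, f"{prefix}.{k}")
                for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        seq = sorted(obj) if isinstance(obj, (set, frozenset)) else obj
        return [_jsonable(v, matrices, f"{prefix}.{i}")
                for i, v in enumerate(seq)]
    if obj is None or isinstance(obj, (bool, int, float, str)):
        return obj
    raise ReportError(f"cannot serialize {type(obj).__name__} at {prefix!r}")


def write_report(results: dict, path: str | Path,
                 metadata: dict | None = None) -> dict:
    """Write a nested results mapping as JSON, matrices as CSV alongside.

    Key order is deterministic; seeds and permutation counts carried by
    :class:`PermutationResult` objects are recorded verbatim, so a rerun
    with the same seed and configuration produces a byte-identical body
    (timestamps live only in ``metadata`` supplied by the caller).
    """
    path = Path(path)
    matrices: dict[str, DyadMatrix] = {}
    body = {
        "metadata": _jsonable(metadata or {}, matrices, "metadata"),
        "results": _jsonable(results, matrices, ""),
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(body, fh, indent=2, sort_keys=True)
        fh.write("\n")
    for key, m in matrices.items():
        write_matrix(m, path.parent / f"{key}.csv")
    return body
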