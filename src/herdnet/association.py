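"""Association-index and interaction-rate matrices from raw streams.

The association index (AI) for a dyad is the proportion of scan samples in
which the two individuals were members of the same spatial group, out of the
samples where both were observed. Spatial groups follow the "gambit of the
group" with transitive chaining: if A is near B and B is near C, all three
form one group and every pair within it counts as associated.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Sequence

import numpy as np

from .datatypes import (
    DyadMatrix,
    HerdnetError,
    InteractionEvent,
    ObservationLog,
    ScanDataset,
    ScanSample,
    ValidationError,
)

__all__ = ["scan_groups", "AssociationMatrix", "association_matrix",
           "interaction_rate_matrix", "interaction_summary"]


def scan_groups(sample: ScanSample) -> list[frozenset[str]]:
    """Spatial groups at one scan: connected components of the pair graph.

    Singletons (individuals with no proximity partner) form their own group.
    """
    parent: dict[str, str] = {i: i for i in sample.records}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for pair in sample.proximity_pairs:
        a, b = tuple(pair)
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    comps: dict[str, set[str]] = defaultdict(set)
    for i in sample.records:
        comps[find(i)].add(i)
    return [frozenset(c) for c in comps.values()]


class AssociationMatrix(DyadMatrix):
    """Symmetric AI matrix carrying per-dyad joint sample counts.

    ``joint_counts[i, j]`` is the number of scans at which both members of
    the dyad had records; dyads never jointly observed get AI 0 and are
    flagged in ``never_jointly_observed``.
    """

    def __init__(self, ids: Sequence[str], values: np.ndarray,
                 joint_counts: np.ndarray) -> None:
        super().__init__(ids, values, directed=False)
        self.joint_counts = np.asarray(joint_counts, dtype=int)
        mask = self.joint_counts == 0
        np.fill_diagonal(mask, False)
        self.never_jointly_observed = mask


def association_matrix(
    scans: ScanDataset, ids: Sequence[str] | None = None
) -> AssociationMatrix:
    """AI(i, j) = same-group scans / jointly observed scans, per dyad."""
    if scans.n_scans == 0:
        raise HerdnetError("cannot build an association matrix from 0 scans")
    ids = list(scans.individuals if ids is None else ids)
    known = set(scans.individuals)
    unknown = [i for i in ids if i not in known]
    if unknown:
        raise ValidationError(f"unknown individual(s) {unknown}")
    index = {ind: k for k, ind in enumerate(ids)}
    n = len(ids)
    together = np.zeros((n, n), dtype=int)
    joint = np.zeros((n, n), dtype=int)
    for sample in scans.samples:
        present = [index[i] for i in sample.records if i in index]
        for a in present:
            joint[a, present] += 1
        for group in scan_groups(sample):
            members = [index[i] for i in group if i in index]
            for a in members:
                together[a, members] += 1
    np.fill_diagonal(together, 0)
    np.fill_diagonal(joint, 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ai = np.where(joint > 0, together / np.maximum(joint, 1), 0.0)
    return AssociationMatrix(ids, ai, joint)


def interaction_rate_matrix(
    events: Iterable[InteractionEvent],
    log: ObservationLog,
    kind: str,
    ids: Sequence[str] | None = None,
) -> DyadMatrix:
    """Directed rates: events of ``kind`` from actor to recipient per
    contact hour."""
    hours = log.total_hours
    if hours <= 0:
        raise ZeroDivisionError("observation log has zero contact hours")
    events = [e for e in events if e.kind == kind]
    if ids is None:
        ids = sorted({e.actor for e in events} | {e.recipient for e in events})
    ids = list(ids)
    index = {ind: k for k, ind in enumerate(ids)}
    counts = np.zeros((len(ids), len(ids)))
    for e in events:
        try:
            counts[index[e.actor], index[e.recipient]] += 1
        except KeyError as exc:
            raise ValidationError(f"event involves unknown id {exc}") from exc
    return DyadMatrix(ids, counts / hours, directed=True)


def interaction_summary(events: Iterable[InteractionEvent]) -> dict:
    """Tally interaction bouts by kind, role class, and subtype.

    Returns raw counts plus the composition percentages commonly reported
    for such event streams: the share of affiliative bouts that were
    allogrooming and the share of agonistic bouts that were submissive.
    """
    events = list(events)
    counts: dict[str, int] = {}
    role_counts = {"offensive": 0, "defensive": 0}
    n_affil = n_agon = 0
    for e in events:
        counts[e.subtype] = counts.get(e.subtype, 0) + 1
        if e.kind == "affiliative":
            n_affil += 1
        else:
            n_agon += 1
            role_counts[e.role_class] += 1
    out = {
        "n_events": len(events),
        "affiliative_total": n_affil,
        "agonistic_total": n_agon,
        "offensive_total": role_counts["offensive"],
        "submissive_total": role_counts["defensive"],
        "subtype_counts": dict(sorted(counts.items())),
    }
    if n_affil:
        out["allogrooming_pct_of_affiliative"] = (
            100.0 * counts.get("mutual_grooming", 0) / n_affil
        )
    if n_agon:
        out["submissive_pct_of_agonistic"] = (
            100.0 * role_counts["defensive"] / n_agon
        )
    return out
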