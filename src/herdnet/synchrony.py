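"""Behavioural synchronization indices and their randomization null.

The behavioural synchronization index (BSI) of a dyad is the proportion of
jointly observed scan samples in which the two individuals showed the same
behaviour. The randomization null shuffles the scan sequence of one
randomly chosen individual at a time, which preserves every individual's
marginal behaviour distribution while destroying temporal alignment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    DyadMatrix,
    Partition,
    PermutationResult,
    ScanDataset,
    ValidationError,
)

__all__ = ["BsiMatrix", "bsi_matrix", "BsiNullResult", "bsi_null",
           "ClusterSynchrony", "cluster_synchrony"]


class BsiMatrix(DyadMatrix):
    """Symmetric BSI matrix carrying per-dyad joint scan counts."""

    def __init__(self, ids: Sequence[str], values: np.ndarray,
                 joint_counts: np.ndarray) -> None:
        super().__init__(ids, values, directed=False)
        self.joint_counts = np.asarray(joint_counts, dtype=int)
        mask = self.joint_counts == 0
        np.fill_diagonal(mask, False)
        self.missing = mask  # dyads never jointly observed

    def mean_offdiagonal(self) -> float:
        iu = np.triu_indices(self.n, k=1)
        ok = ~self.missing[iu]
        return float(self.values[iu][ok].mean())


def _label_arrays(scans: ScanDataset, level: str):
    """Per individual: integer-coded behaviour labels and scan indices."""
    if level not in ("category", "activity"):
        raise ValueError(f"unknown level {level!r}")
    ids = list(scans.individuals)
    codes: dict[str, int] = {}
    labels = {i: [] for i in ids}
    scan_idx = {i: [] for i in ids}
    for si, sample in enumerate(scans.samples):
        for ind, rec in sample.records.items():
            lab = (rec.behaviour_category if level == "category"
                   else rec.activity_pattern)
            labels[ind].append(codes.setdefault(lab, len(codes)))
            scan_idx[ind].append(si)
    return (
        ids,
        {i: np.array(labels[i], dtype=np.int64) for i in ids},
        {i: np.array(scan_idx[i], dtype=np.int64) for i in ids},
        codes,
    )


def _joint_positions(scan_idx: dict[str, np.ndarray], a: str, b: str):
    """Positions into each individual's label array for their joint scans."""
    common, pos_a, pos_b = np.intersect1d(
        scan_idx[a], scan_idx[b], assume_unique=True, return_indices=True
    )
    return pos_a, pos_b


def bsi_matrix(
    scans: ScanDataset,
    level: str = "category",
    restrict_to: str | None = None,
) -> BsiMatrix:
    """Dyadic behavioural synchronization.

    Overall BSI (``restrict_to=None``) is the share of joint scans with the
    same label. Per-behaviour BSI for behaviour ``b`` uses a Jaccard-style
    denominator: joint scans where both show ``b``, over joint scans where
    at least one does (0 when the behaviour never occurs in the dyad's
    joint scans).
    """
    ids, labels, scan_idx, codes = _label_arrays(scans, level)
    code = None
    if restrict_to is not None:
        code = codes.get(restrict_to, -1)  # -1: behaviour absent entirely
    n = len(ids)
    vals = np.zeros((n, n))
    joint = np.zeros((n, n), dtype=int)
    for a_i, b_i in itertools.combinations(range(n), 2):
        a, b = ids[a_i], ids[b_i]
        pa, pb = _joint_positions(scan_idx, a, b)
        joint[a_i, b_i] = joint[b_i, a_i] = pa.size
        if pa.size == 0:
            continue
        la, lb = labels[a][pa], labels[b][pb]
        if restrict_to is None:
            v = float(np.mean(la == lb))
        else:
            both = np.sum((la == code) & (lb == code))
            either = np.sum((la == code) | (lb == code))
            v = float(both / either) if either > 0 else 0.0
        vals[a_i, b_i] = vals[b_i, a_i] = v
    return BsiMatrix(ids, vals, joint)


@dataclass
class BsiNullResult:
    """Per-dyad synchrony p-values and the group-mean randomization test.

    ``p_high[i, j]`` is the proportion of permutations *involving the dyad*
    (the shuffled individual is i or j) whose BSI was at least the observed
    one; permutations that shuffle a third individual leave the dyad's BSI
    untouched and carry no information about it. The group-mean test uses
    every permutation.
    """

    ids: list[str]
    observed: BsiMatrix
    p_high: DyadMatrix
    mean_test: PermutationResult
    n_perm: int
    shuffle_n: int
    seed: int

    def significant_pairs(self, alpha: float = 0.05) -> set[frozenset[str]]:
        out = set()
        for a, b in itertools.combinations(self.ids, 2):
            if self.p_high[a, b] <= alpha:
                out.add(frozenset((a, b)))
        return out


def bsi_null(
    scans: ScanDataset,
    n_perm: int = 1000,
    shuffle_n: int = 100,
    seed: int = 0,
    level: str = "category",
) -> BsiNullResult:
    """Randomization test of the BSI matrix.

    Each permutation picks one individual uniformly, selects ``shuffle_n``
    of its scans without replacement (all of them if it has fewer), and
    permutes the behaviour labels among those scans; the BSI matrix is then
    recomputed. Shuffles are independent across permutations (each starts
    from the observed data).
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    observed = bsi_matrix(scans, level=level)
    ids, labels, scan_idx, _ = _label_arrays(scans, level)
    n = len(ids)
    iu = np.triu_indices(n, k=1)
    obs_vals = observed.values

    # joint-scan index pairs per dyad, precomputed once
    joint_pos: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
    for a_i, b_i in itertools.combinations(range(n), 2):
        joint_pos[(a_i, b_i)] = _joint_positions(
            scan_idx, ids[a_i], ids[b_i]
        )

    rng = np.random.default_rng(seed)
    ge_counts = np.zeros((n, n))
    involved_counts = np.zeros((n, n))
    mean_null = np.empty(n_perm)
    current = obs_vals.copy()

    for k in range(n_perm):
        target = int(rng.integers(n))
        lab = labels[ids[target]]
        m_scans = lab.size
        take = min(shuffle_n, m_scans)
        sel = rng.choice(m_scans, size=take, replace=False)
        shuffled = lab.copy()
        shuffled[sel] = shuffled[rng.permutation(sel)]
        # recompute only the shuffled individual's dyads
        row = np.zeros(n)
        for other in range(n):
            if other == target:
                continue
            a_i, b_i = min(target, other), max(target, other)
            pa, pb = joint_pos[(a_i, b_i)]
            if pa.size == 0:
                continue
            la = shuffled[pa] if a_i == target else labels[ids[a_i]][pa]
            lb = shuffled[pb] if b_i == target else labels[ids[b_i]][pb]
            row[other] = float(np.mean(la == lb))
        perm_vals = current.copy()
        perm_vals[target, :] = row
        perm_vals[:, target] = row
        mean_null[k] = perm_vals[iu].mean()
        ge = row >= obs_vals[target, :] - 1e-12
        ge[target] = False
        ge_counts[target, :] += ge
        ge_counts[:, target] += ge
        involved_counts[target, :] += 1
        involved_counts[:, target] += 1

    with np.errstate(invalid="ignore"):
        p_high = np.where(
            involved_counts > 0, ge_counts / np.maximum(involved_counts, 1), 1.0
        )
    p_high = (p_high + p_high.T) / 2  # ge_counts already mirrored; tidy float
    np.fill_diagonal(p_high, 0.0)

    obs_mean = float(obs_vals[iu].mean())
    mean_test = PermutationResult(
        observed_stat=obs_mean,
        null_stats=mean_null,
        p_value=float(np.mean(mean_null >= obs_mean - 1e-12)),
        n_perm=n_perm,
        seed=seed,
        alternative="greater",
        method="sequence-shuffle",
    )
    return BsiNullResult(
        ids=ids,
        observed=observed,
        p_high=DyadMatrix(ids, p_high, directed=False),
        mean_test=mean_test,
        n_perm=n_perm,
        shuffle_n=shuffle_n,
        seed=seed,
    )


@dataclass
class ClusterSynchrony:
    """Within- vs between-cluster synchrony contrast."""

    per_cluster_mean: dict[int, float]
    within_mean: float
    between_mean: float
    difference: float
    p_value: float
    n_perm: int
    seed: int


def cluster_synchrony(
    bsi: DyadMatrix,
    partition: Partition,
    n_perm: int = 1000,
    seed: int = 0,
) -> ClusterSynchrony:
    """Mean BSI within vs between clusters, with a node-label permutation p.

    p is the proportion of cluster-label permutations whose within-minus-
    between difference is at least the observed one.
    """
    ids = bsi.ids
    missing = [i for i in ids if i not in partition.membership]
    if missing:
        raise ValidationError(f"partition does not cover {missing}")
    labels = partition.as_array(ids)
    vals = bsi.values
    n = len(ids)
    iu = np.triu_indices(n, k=1)
    v = vals[iu]

    def contrast(lab: np.ndarray) -> tuple[float, float]:
        same = lab[iu[0]] == lab[iu[1]]
        if not same.any():
            raise ValidationError(
                "no within-cluster dyads (all clusters are singletons)"
            )
        if same.all():
            raise ValidationError(
                "no between-cluster dyads (a single cluster)"
            )
        return float(v[same].mean()), float(v[~same].mean())

    within, between = contrast(labels)
    per_cluster = {}
    for c in sorted(set(labels)):
        mask = (labels[iu[0]] == c) & (labels[iu[1]] == c)
        per_cluster[int(c)] = float(v[mask].mean()) if mask.any() else float("nan")

    rng = np.random.default_rng(seed)
    observed_diff = within - between
    count = 0
    for _ in range(n_perm):
        wp, bp = contrast(rng.permutation(labels))
        if wp - bp >= observed_diff - 1e-12:
            count += 1
    return ClusterSynchrony(
        per_cluster_mean=per_cluster,
        within_mean=within,
        between_mean=between,
        difference=observed_diff,
        p_value=count / n_perm,
        n_perm=n_perm,
        seed=seed,
    )
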