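"""Data-stream permutations, CV non-randomness tests, dyad classification,
and Mantel matrix correlation.

The data-stream null model permutes group membership directly in the scan
stream: each step picks an observation day, two spatial groups recorded on
that day, and swaps one individual between them, rejecting swaps that would
duplicate an individual within a scan. The chain is cumulative — each swap
applies to the already-permuted stream — and the test statistic is recorded
after every swap. Swaps conserve group sizes at every scan and each
individual's number of observations per day, the margins the method is
designed to hold fixed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Iterator, Sequence

import numpy as np

from .association import AssociationMatrix, association_matrix, scan_groups
from .datatypes import (
    DegeneracyError,
    DyadMatrix,
    PermutationResult,
    ScanDataset,
    ValidationError,
)

__all__ = ["cv_statistic", "SwapChain", "datastream_permute",
           "DyadClassification", "classify_dyads", "nonrandomness_analysis",
           "mantel_test"]

_SWAP_ATTEMPT_CAP = 1000


def cv_statistic(m: DyadMatrix) -> float:
    """Coefficient of variation of the off-diagonal dyadic values.

    Sample standard deviation over mean; upper triangle for symmetric
    matrices, all ordered pairs for directed ones. High CV relative to a
    permutation null indicates differentiated (non-random) relationships.
    """
    vals = m.upper_triangle()
    if vals.size < 2:
        raise ValidationError("CV needs at least two off-diagonal values")
    mean = vals.mean()
    if mean == 0:
        raise ZeroDivisionError("CV undefined: mean of dyadic values is zero")
    return float(vals.std(ddof=1) / mean)


class SwapChain:
    """Mutable permuted state of a scan stream under membership swaps.

    Tracks, incrementally, the per-dyad counts of same-group scans and of
    jointly-observed scans, so the association matrix is available cheaply
    after every swap.
    """

    def __init__(self, scans: ScanDataset, rng: np.random.Generator) -> None:
        self.ids = list(scans.individuals)
        self.rng = rng
        n = len(self.ids)
        index = {ind: k for k, ind in enumerate(self.ids)}

        self.groups: list[list[set[int]]] = []     # per scan, list of groups
        self.present: list[set[int]] = []          # per scan, who is observed
        self.day_of_scan: list[int] = []
        day_index: dict = {}
        self.day_group_refs: list[list[tuple[int, int]]] = []  # (scan, group)

        self.together = np.zeros((n, n), dtype=np.int64)
        self.joint = np.zeros((n, n), dtype=np.int64)

        for si, sample in enumerate(scans.samples):
            di = day_index.setdefault(sample.day, len(day_index))
            if di == len(self.day_group_refs):
                self.day_group_refs.append([])
            self.day_of_scan.append(di)
            groups = [set(index[i] for i in g) for g in scan_groups(sample)]
            self.groups.append(groups)
            present = set(index[i] for i in sample.records)
            self.present.append(present)
            for gi in range(len(groups)):
                self.day_group_refs[di].append((si, gi))
            pres = sorted(present)
            for a in pres:
                for b in pres:
                    if a != b:
                        self.joint[a, b] += 1
            for g in groups:
                mem = sorted(g)
                for a in mem:
                    for b in mem:
                        if a != b:
                            self.together[a, b] += 1

        self._eligible_days = [
            d for d, refs in enumerate(self.day_group_refs) if len(refs) >= 2
        ]
        if not self._eligible_days:
            raise DegeneracyError(
                "no day has two distinct groups; no swap is possible"
            )

    # -- swap mechanics ----------------------------------------------------

    def swap(self) -> None:
        """Perform one legal membership swap (rejection sampling)."""
        rng = self.rng
        for _ in range(_SWAP_ATTEMPT_CAP):
            day = self._eligible_days[rng.integers(len(self._eligible_days))]
            refs = self.day_group_refs[day]
            k1 = int(rng.integers(len(refs)))
            k2 = int(rng.integers(len(refs) - 1))
            if k2 >= k1:
                k2 += 1
            (s1, g1), (s2, g2) = refs[k1], refs[k2]
            group1, group2 = self.groups[s1][g1], self.groups[s2][g2]
            a = _random_member(group1, rng)
            b = _random_member(group2, rng)
            if s1 != s2:
                # moving across scans must not duplicate an individual
                if a in self.present[s2] or b in self.present[s1]:
                    continue
            self._apply(s1, group1, a, s2, group2, b)
            return
        raise DegeneracyError(
            f"no legal swap found in {_SWAP_ATTEMPT_CAP} attempts"
        )

    def _apply(self, s1: int, group1: set[int], a: int,
               s2: int, group2: set[int], b: int) -> None:
        T = self.together
        group1.discard(a)
        for x in group1:
            T[a, x] -= 1
            T[x, a] -= 1
        group2.discard(b)
        for x in group2:
            T[b, x] -= 1
            T[x, b] -= 1
        for x in group1:
            T[b, x] += 1
            T[x, b] += 1
        group1.add(b)
        for x in group2:
            T[a, x] += 1
            T[x, a] += 1
        group2.add(a)
        if s1 != s2:
            J = self.joint
            p1 = self.present[s1]
            p1.discard(a)
            for x in p1:
                J[a, x] -= 1
                J[x, a] -= 1
                J[b, x] += 1
                J[x, b] += 1
            p1.add(b)
            p2 = self.present[s2]
            p2.discard(b)
            for x in p2:
                J[b, x] -= 1
                J[x, b] -= 1
                J[a, x] += 1
                J[x, a] += 1
            p2.add(a)

    # -- views -------------------------------------------------------------

    def ai_values(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(
                self.joint > 0, self.together / np.maximum(self.joint, 1), 0.0
            )

    def ai_matrix(self) -> AssociationMatrix:
        return AssociationMatrix(self.ids, self.ai_values(), self.joint)

    def group_size_multisets(self) -> list[tuple[int, ...]]:
        return [tuple(sorted(len(g) for g in gs)) for gs in self.groups]

    def daily_observation_counts(self) -> np.ndarray:
        n = len(self.ids)
        counts = np.zeros((len(self.day_group_refs), n), dtype=int)
        for si, pres in enumerate(self.present):
            for x in pres:
                counts[self.day_of_scan[si], x] += 1
        return counts


def _random_member(group: set[int], rng: np.random.Generator) -> int:
    members = sorted(group)
    return members[rng.integers(len(members))]


def _chain(scans: ScanDataset, n_perm: int,
           rng: np.random.Generator) -> Iterator[AssociationMatrix]:
    chain = SwapChain(scans, rng)
    for _ in range(n_perm):
        chain.swap()
        yield chain.ai_matrix()


def datastream_permute(
    scans: ScanDataset,
    n_perm: int = 1000,
    seed: int = 0,
    statistic: Callable[[DyadMatrix], float] = cv_statistic,
    alternative: str = "greater",
) -> PermutationResult:
    """Permutation test of a network statistic under the data-stream null.

    ``p_value`` is the proportion of the ``n_perm`` post-swap statistics at
    least as extreme as the observed one (one-tailed, direction set by
    ``alternative``).
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    observed = float(statistic(association_matrix(scans)))
    rng = np.random.default_rng(seed)
    null = np.fromiter(
        (statistic(m) for m in _chain(scans, n_perm, rng)),
        dtype=float,
        count=n_perm,
    )
    p = _tail_p(null, observed, alternative)
    return PermutationResult(
        observed_stat=observed, null_stats=null, p_value=p, n_perm=n_perm,
        seed=seed, alternative=alternative, method="datastream-swap",
    )


def _tail_p(null: np.ndarray, observed: float, alternative: str) -> float:
    if alternative == "greater":
        return float(np.mean(null >= observed - 1e-12))
    if alternative == "less":
        return float(np.mean(null <= observed + 1e-12))
    if alternative == "two-sided":
        return float(np.mean(np.abs(null) >= abs(observed) - 1e-12))
    raise ValueError(f"unknown alternative {alternative!r}")


@dataclass
class DyadClassification:
    """Per-dyad upper-tail p-values and preferred/avoided/neutral labels.

    ``p_high`` is the proportion of permuted association indices at least as
    large as the observed one: small means the dyad associates more than
    expected (preferred), large means less (avoided) — the same tail read at
    both ends.
    """

    ids: list[str]
    observed: DyadMatrix
    p_high: DyadMatrix
    preferred_threshold: float = 0.05
    avoided_threshold: float = 0.95

    def label(self, a: str, b: str) -> str:
        p = self.p_high[a, b]
        if p <= self.preferred_threshold:
            return "preferred"
        if p >= self.avoided_threshold:
            return "avoided"
        return "neutral"

    def pairs_labelled(self, label: str) -> set[frozenset[str]]:
        out = set()
        for a, b in itertools.combinations(self.ids, 2):
            if self.label(a, b) == label:
                out.add(frozenset((a, b)))
        return out

    @property
    def n_dyads(self) -> int:
        n = len(self.ids)
        return n * (n - 1) // 2


def nonrandomness_analysis(
    scans: ScanDataset,
    n_perm: int = 1000,
    seed: int = 0,
    preferred_threshold: float = 0.05,
    avoided_threshold: float = 0.95,
) -> tuple[PermutationResult, DyadClassification]:
    """One chain, two read-outs: the CV non-randomness test and the
    per-dyad preferred/avoided classification."""
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    obs = association_matrix(scans)
    obs_cv = cv_statistic(obs)
    rng = np.random.default_rng(seed)
    chain = SwapChain(scans, rng)
    n = len(chain.ids)
    iu = np.triu_indices(n, k=1)
    cv_null = np.empty(n_perm)
    ge_counts = np.zeros((n, n))
    obs_vals = obs.reordered(chain.ids).values
    for k in range(n_perm):
        chain.swap()
        vals = chain.ai_values()
        ut = vals[iu]
        cv_null[k] = ut.std(ddof=1) / ut.mean()
        ge_counts += vals >= obs_vals - 1e-12
    p_high = ge_counts / n_perm
    np.fill_diagonal(p_high, 0.0)
    cv_result = PermutationResult(
        observed_stat=obs_cv, null_stats=cv_null,
        p_value=_tail_p(cv_null, obs_cv, "greater"), n_perm=n_perm,
        seed=seed, alternative="greater", method="datastream-swap",
    )
    classification = DyadClassification(
        ids=chain.ids,
        observed=obs.reordered(chain.ids),
        p_high=DyadMatrix(chain.ids, p_high, directed=False),
        preferred_threshold=preferred_threshold,
        avoided_threshold=avoided_threshold,
    )
    return cv_result, classification


def classify_dyads(
    scans: ScanDataset,
    n_perm: int = 1000,
    seed: int = 0,
    preferred_threshold: float = 0.05,
    avoided_threshold: float = 0.95,
) -> DyadClassification:
    """Label each dyad preferred / avoided / neutral against the
    data-stream null."""
    _, classification = nonrandomness_analysis(
        scans, n_perm=n_perm, seed=seed,
        preferred_threshold=preferred_threshold,
        avoided_threshold=avoided_threshold,
    )
    return classification


def mantel_test(
    a: DyadMatrix,
    b: DyadMatrix,
    n_perm: int = 1000,
    seed: int = 0,
    alternative: str = "two-sided",
    exact: bool = False,
) -> PermutationResult:
    """Mantel correlation between two symmetric dyadic matrices.

    The observed statistic is the Pearson correlation of the paired
    upper-triangle entries; the null permutes rows and columns of ``b``
    simultaneously. ``exact=True`` enumerates all node permutations
    (feasible for small groups) instead of sampling.
    """
    if a.directed or b.directed:
        raise ValidationError(
            "mantel_test needs symmetric matrices; symmetrize directed input "
            "first (DyadMatrix.symmetrized sums the two directions)"
        )
    if set(a.ids) != set(b.ids):
        raise ValidationError("matrices must cover the same individuals")
    b = b.reordered(a.ids)
    n = a.n
    iu = np.triu_indices(n, k=1)
    va = a.values[iu]
    if va.std() == 0 or b.values[iu].std() == 0:
        raise ValidationError("correlation undefined for a constant matrix")

    def corr(mat_b: np.ndarray) -> float:
        return float(np.corrcoef(va, mat_b[iu])[0, 1])

    observed = corr(b.values)
    if exact:
        perms = itertools.permutations(range(n))
        null = np.array(
            [corr(b.values[np.ix_(p, p)]) for p in perms]
        )
        n_perm = math.factorial(n)
    else:
        if n_perm < 1:
            raise ValidationError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        null = np.empty(n_perm)
        for k in range(n_perm):
            p = rng.permutation(n)
            null[k] = corr(b.values[np.ix_(p, p)])
    p_value = _tail_p(null, observed, alternative)
    return PermutationResult(
        observed_stat=observed, null_stats=null, p_value=p_value,
        n_perm=n_perm, seed=seed, alternative=alternative,
        method="mantel-pearson" + ("-exact" if exact else ""),
    )
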