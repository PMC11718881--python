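"""Pedigree kinship coefficients.

The kinship coefficient φ(i, j) is the probability that an allele sampled
at random from i is identical by descent to one sampled from j. Founders
are assumed pairwise unrelated and non-inbred, so φ(f, f) = 1/2 for a
founder f, full sibs with founder parents have φ = 1/4, and half sibs 1/8.
"""

from __future__ import annotations

from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np

from .datatypes import DyadMatrix, Individual, PedigreeError

__all__ = ["Pedigree", "kinship_matrix", "gene_drop_kinship"]


class Pedigree:
    """Parent records, topologically ordered from founders down."""

    def __init__(
        self, records: Mapping[Hashable, tuple[Hashable | None, Hashable | None]]
    ) -> None:
        self.parents: dict[Hashable, tuple[Hashable | None, Hashable | None]] = {}
        for ind, (sire, dam) in records.items():
            self.parents[ind] = (sire, dam)
        # implicit founders: parents that have no record of their own
        for sire, dam in list(self.parents.values()):
            for p in (sire, dam):
                if p is not None and p not in self.parents:
                    self.parents[p] = (None, None)
        self.order = self._toposort()
        self._rank = {ind: k for k, ind in enumerate(self.order)}

    @classmethod
    def from_individuals(cls, individuals: Iterable[Individual]) -> "Pedigree":
        return cls({i.id: (i.sire_id, i.dam_id) for i in individuals})

    def _toposort(self) -> list[Hashable]:
        order: list[Hashable] = []
        state: dict[Hashable, int] = {}  # 0 visiting, 1 done

        def visit(node: Hashable, stack: list[Hashable]) -> None:
            if state.get(node) == 1:
                return
            if state.get(node) == 0:
                raise PedigreeError(f"pedigree cycle involving {node!r}")
            state[node] = 0
            for p in self.parents[node]:
                if p is not None:
                    visit(p, stack + [node])
            state[node] = 1
            order.append(node)

        for node in self.parents:
            visit(node, [])
        return order

    def founders(self) -> list[Hashable]:
        return [i for i, (s, d) in self.parents.items() if s is None and d is None]


def kinship_matrix(
    ped: Pedigree | Mapping | Iterable[Individual],
    ids: Sequence[Hashable] | None = None,
) -> DyadMatrix:
    """Recursive kinship over the whole pedigree, returned for ``ids``.

    φ(i, i) = (1 + φ(sire_i, dam_i)) / 2 and, taking i as the later-born,
    φ(i, j) = (φ(sire_i, j) + φ(dam_i, j)) / 2, with missing parents
    contributing zero. Diagonal of the returned matrix is the DyadMatrix
    convention (zero); self-kinship is available via ``self_kinship``.
    """
    ped = _as_pedigree(ped)
    order = ped.order
    pos = {ind: k for k, ind in enumerate(order)}
    n = len(order)
    phi = np.zeros((n, n))
    for a_k, a in enumerate(order):
        sire, dam = ped.parents[a]
        s_k = pos[sire] if sire is not None else None
        d_k = pos[dam] if dam is not None else None
        phi[a_k, a_k] = 0.5 * (
            1.0 + (phi[s_k, d_k] if s_k is not None and d_k is not None else 0.0)
        )
        for b_k in range(a_k):  # b precedes a: a cannot be b's ancestor
            v = 0.0
            if s_k is not None:
                v += phi[s_k, b_k]
            if d_k is not None:
                v += phi[d_k, b_k]
            phi[a_k, b_k] = phi[b_k, a_k] = 0.5 * v
    ids = list(order if ids is None else ids)
    missing = [i for i in ids if i not in pos]
    if missing:
        raise PedigreeError(f"ids not in pedigree: {missing}")
    idx = [pos[i] for i in ids]
    sub = phi[np.ix_(idx, idx)].copy()
    self_k = np.diag(sub).copy()
    m = DyadMatrix([str(i) for i in ids], sub, directed=False)
    m.self_kinship = dict(zip(m.ids, self_k))
    return m


def gene_drop_kinship(
    ped: Pedigree | Mapping | Iterable[Individual],
    ids: Sequence[Hashable] | None = None,
    n_drops: int = 100_000,
    seed: int = 0,
) -> DyadMatrix:
    """Monte Carlo kinship by gene dropping (independent oracle).

    Each founder receives two unique alleles; every descendant inherits one
    allele from each parent uniformly at random (an absent parent
    contributes a unique allele). φ̂(i, j) is the average probability that
    randomly sampled alleles from i and j match.
    """
    ped = _as_pedigree(ped)
    rng = np.random.default_rng(seed)
    order = ped.order
    pos = {ind: k for k, ind in enumerate(order)}
    alleles: dict[Hashable, tuple[np.ndarray, np.ndarray]] = {}
    counter = 0
    for ind in order:
        sire, dam = ped.parents[ind]
        inherited = []
        for parent in (sire, dam):
            if parent is None:
                inherited.append(np.full(n_drops, counter, dtype=np.int64))
                counter += 1
            else:
                pa, pb = alleles[parent]
                pick = rng.integers(2, size=n_drops, dtype=np.int64)
                inherited.append(np.where(pick == 0, pa, pb))
        alleles[ind] = (inherited[0], inherited[1])
    ids = list(order if ids is None else ids)
    n = len(ids)
    est = np.zeros((n, n))
    for a in range(n):
        a1, a2 = alleles[ids[a]]
        for b in range(a, n):
            b1, b2 = alleles[ids[b]]
            match = (
                (a1 == b1).mean() + (a1 == b2).mean()
                + (a2 == b1).mean() + (a2 == b2).mean()
            ) / 4.0
            est[a, b] = est[b, a] = match
    self_k = np.diag(est).copy()
    m = DyadMatrix([str(i) for i in ids], est, directed=False)
    m.self_kinship = dict(zip(m.ids, self_k))
    return m


def _as_pedigree(ped) -> Pedigree:
    if isinstance(ped, Pedigree):
        return ped
    if isinstance(ped, Mapping):
        return Pedigree(ped)
    return Pedigree.from_individuals(ped)
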