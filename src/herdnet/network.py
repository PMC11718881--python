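"""Node-level sociability measures, modularity community detection, and
continuous-trait assortment.

Node strength is the sum of a node's incident edge weights; the weighted
degree generalizes it as ``k^(1-alpha) * S^alpha`` where ``k`` is the number
of nonzero ties, interpolating between the binary degree (alpha = 0) and the
strength (alpha = 1). For directed matrices both ``k`` and ``S`` are taken
over outgoing ties, matching the tnet ``degree_w`` convention used in the
animal social network literature.
"""

from __future__ import annotations

import random as _pyrandom
from typing import Sequence

import igraph as _ig
import numpy as np
import pandas as pd

from .datatypes import (
    DyadMatrix,
    HerdnetError,
    Partition,
    PermutationResult,
    ValidationError,
)

__all__ = ["node_strength", "weighted_degree", "detect_communities",
           "modularity", "partition_pvalue", "assortment_continuous"]


def node_strength(m: DyadMatrix, mode: str = "total") -> pd.Series:
    """Sum of incident weights per node.

    ``mode`` selects out-, in-, or total (out + in) sums for directed
    matrices; for symmetric matrices all modes equal the row sums.
    """
    if mode not in ("total", "out", "in"):
        raise ValueError(f"unknown mode {mode!r}")
    if not m.directed:
        s = m.values.sum(axis=1)
    elif mode == "out":
        s = m.values.sum(axis=1)
    elif mode == "in":
        s = m.values.sum(axis=0)
    else:
        s = m.values.sum(axis=1) + m.values.sum(axis=0)
    return pd.Series(s, index=m.ids, name=f"strength_{mode}")


def weighted_degree(m: DyadMatrix, alpha: float = 0.5) -> pd.Series:
    """tnet-style weighted degree ``k^(1-alpha) * S^alpha``.

    ``k`` counts nonzero ties and ``S`` sums their weights — outgoing ties
    for directed matrices, all incident ties for symmetric ones.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha={alpha} outside [0, 1]")
    k = (m.values > 0).sum(axis=1).astype(float)
    s = m.values.sum(axis=1)
    with np.errstate(invalid="ignore"):
        wd = np.where(k > 0, k ** (1.0 - alpha) * s ** alpha, 0.0)
    return pd.Series(wd, index=m.ids, name="weighted_degree")


def modularity(m: DyadMatrix, partition: Partition) -> float:
    """Weighted Newman–Girvan modularity of a partition.

    Q = (1/2W) Σ_ij [w_ij − s_i s_j / 2W] δ(c_i, c_j), computed on the
    symmetrized matrix (directed input is summed over directions).
    """
    sym = m.symmetrized()
    missing = [i for i in sym.ids if i not in partition.membership]
    if missing:
        raise ValidationError(f"partition does not cover {missing}")
    w = sym.values
    total = w.sum()  # = 2W
    if total == 0:
        raise ZeroDivisionError("modularity undefined for zero total weight")
    labels = partition.as_array(sym.ids)
    s = w.sum(axis=1)
    same = labels[:, None] == labels[None, :]
    q = (w[same].sum() - (np.outer(s, s)[same].sum()) / total) / total
    return float(q)


def detect_communities(
    m: DyadMatrix, seed: int = 0, restarts: int = 100
) -> Partition:
    """Greedy multilevel (Louvain) modularity optimization.

    The igraph multilevel algorithm is restarted over ``restarts`` random
    vertex orders and the best-modularity partition is returned; directed
    input is symmetrized by summing directions. Deterministic given the
    seed.
    """
    sym = m.symmetrized()
    n = sym.n
    if n == 0:
        raise HerdnetError("empty graph")
    if (sym.values < 0).any():
        raise ValidationError("community detection needs nonnegative weights")
    rng = np.random.default_rng(seed)
    g = _ig.Graph.Weighted_Adjacency(
        sym.values.tolist(), mode="undirected", attr="weight", loops=False
    )
    best_q, best_membership = -np.inf, np.zeros(n, dtype=int)
    for _ in range(max(1, restarts)):
        perm = rng.permutation(n)
        _pyrandom.seed(int(rng.integers(2**31)))  # igraph draws from random
        gp = g.permute_vertices(perm.tolist())
        clustering = gp.community_multilevel(weights="weight")
        membership = np.asarray(clustering.membership)[perm]
        q = modularity(sym, Partition(dict(zip(sym.ids, membership))))
        if q > best_q:
            best_q, best_membership = q, membership
    # canonical labels: 0, 1, ... in order of first appearance
    relabel: dict[int, int] = {}
    canon = [relabel.setdefault(int(c), len(relabel)) for c in best_membership]
    return Partition(
        membership=dict(zip(sym.ids, canon)), modularity=float(best_q)
    )


def partition_pvalue(
    m: DyadMatrix,
    partition: Partition,
    n_perm: int = 1000,
    seed: int = 0,
    restarts: int = 20,
) -> PermutationResult:
    """Significance of the detected modular structure.

    Null model: the multiset of dyadic weights is shuffled across dyad
    slots (destroying any community alignment while keeping the weight
    distribution), communities are re-detected, and the best modularity is
    recorded. p is the proportion of null modularities at least as large as
    the observed partition's.
    """
    sym = m.symmetrized()
    observed = modularity(sym, partition)
    rng = np.random.default_rng(seed)
    n = sym.n
    iu = np.triu_indices(n, k=1)
    weights = sym.values[iu].copy()
    null = np.empty(n_perm)
    for k in range(n_perm):
        shuffled = rng.permutation(weights)
        vals = np.zeros((n, n))
        vals[iu] = shuffled
        vals += vals.T
        shuffled_m = DyadMatrix(sym.ids, vals, directed=False)
        null[k] = detect_communities(
            shuffled_m, seed=int(rng.integers(2**31)), restarts=restarts
        ).modularity
    p = float(np.mean(null >= observed - 1e-12))
    return PermutationResult(
        observed_stat=observed, null_stats=null, p_value=p, n_perm=n_perm,
        seed=seed, alternative="greater", method="weight-shuffle",
    )


def assortment_continuous(
    m: DyadMatrix,
    trait: pd.Series | dict[str, float] | Sequence[float],
    n_node_perm: int = 1000,
    seed: int = 0,
    alternative: str = "greater",
) -> tuple[float, PermutationResult]:
    """Weighted assortativity of a continuous node trait.

    The assortment coefficient is the edge-weighted Pearson correlation of
    trait values across edge endpoints (each undirected edge contributing
    both orientations). Significance comes from node-label permutations of
    the trait.
    """
    x = _trait_vector(m, trait)
    if np.std(x) == 0:
        raise ValidationError("assortment undefined for a constant trait")
    w = m.values.copy()
    np.fill_diagonal(w, 0.0)

    def ac(xv: np.ndarray) -> float:
        total = w.sum()
        if total == 0:
            raise ZeroDivisionError("assortment undefined for empty network")
        xi = np.broadcast_to(xv[:, None], w.shape)
        xj = np.broadcast_to(xv[None, :], w.shape)
        mi = (w * xi).sum() / total
        mj = (w * xj).sum() / total
        cov = (w * xi * xj).sum() / total - mi * mj
        vi = (w * xi**2).sum() / total - mi**2
        vj = (w * xj**2).sum() / total - mj**2
        return float(cov / np.sqrt(vi * vj))

    observed = ac(x)
    rng = np.random.default_rng(seed)
    null = np.empty(n_node_perm)
    for k in range(n_node_perm):
        null[k] = ac(rng.permutation(x))
    if alternative == "greater":
        p = float(np.mean(null >= observed - 1e-12))
    elif alternative == "less":
        p = float(np.mean(null <= observed + 1e-12))
    else:
        p = float(np.mean(np.abs(null) >= abs(observed) - 1e-12))
    result = PermutationResult(
        observed_stat=observed, null_stats=null, p_value=p,
        n_perm=n_node_perm, seed=seed, alternative=alternative,
        method="node-label-permutation",
    )
    return observed, result


def _trait_vector(m: DyadMatrix, trait) -> np.ndarray:
    if isinstance(trait, pd.Series):
        missing = [i for i in m.ids if i not in trait.index]
        if missing:
            raise ValidationError(f"trait missing for {missing}")
        return trait.loc[m.ids].to_numpy(dtype=float)
    if isinstance(trait, dict):
        missing = [i for i in m.ids if i not in trait]
        if missing:
            raise ValidationError(f"trait missing for {missing}")
        return np.array([trait[i] for i in m.ids], dtype=float)
    arr = np.asarray(trait, dtype=float)
    if arr.shape != (m.n,):
        raise ValidationError("trait vector length does not match ids")
    return arr
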