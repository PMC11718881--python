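"""Win matrices, David's scores, and Landau linearity with randomization.

Winner attribution follows the field convention for mixed offensive and
submissive records: the initiator of an offensive interaction is the
winner, while the direction of defensive (submissive) interactions is
reversed so that the winner is the individual the submission is directed to.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    DyadMatrix,
    InteractionEvent,
    ValidationError,
)

__all__ = ["win_matrix", "davids_score", "landau_h", "landau_h_prime",
           "DominanceResult"]


def win_matrix(
    events: Iterable[InteractionEvent], ids: Sequence[str] | None = None
) -> DyadMatrix:
    """Count wins per ordered dyad from agonistic events.

    Offensive events credit the actor with a win over the recipient;
    defensive (submissive) events credit the recipient with a win over the
    actor.
    """
    events = [e for e in events if e.kind == "agonistic"]
    for e in events:
        if e.role_class not in ("offensive", "defensive"):
            raise ValidationError(
                f"agonistic event {e.actor}->{e.recipient} at {e.day} {e.time} "
                f"lacks a valid role_class"
            )
    if ids is None:
        ids = sorted({e.actor for e in events} | {e.recipient for e in events})
    ids = list(ids)
    index = {ind: k for k, ind in enumerate(ids)}
    w = np.zeros((len(ids), len(ids)))
    for e in events:
        if e.role_class == "offensive":
            winner, loser = e.actor, e.recipient
        else:
            winner, loser = e.recipient, e.actor
        w[index[winner], index[loser]] += 1
    return DyadMatrix(ids, w, directed=True)


def davids_score(w: DyadMatrix) -> pd.Series:
    """David's score from raw win proportions.

    P_ij = wins(i,j) / (wins(i,j) + wins(j,i)), zero for dyads with no
    encounters. DS_i = w_i + w2_i − l_i − l2_i, where w_i sums i's win
    proportions, w2_i weights them by the opponents' own w, and l, l2 are
    the loss-side analogues. Scores sum to zero over the group.
    """
    if w.n < 2:
        raise ValidationError("David's score needs at least two individuals")
    wins = w.values
    total = wins + wins.T
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(total > 0, wins / np.maximum(total, 1e-300), 0.0)
    np.fill_diagonal(p, 0.0)
    w1 = p.sum(axis=1)
    l1 = p.sum(axis=0)
    w2 = p @ w1
    l2 = p.T @ l1
    ds = w1 + w2 - l1 - l2
    return pd.Series(ds, index=w.ids, name="davids_score")


def landau_h(v: np.ndarray) -> float:
    """Landau's linearity index from dominance out-degrees ``v``.

    h = 12/(N³−N) Σ (v_i − (N−1)/2)²; 1 for a perfect linear order.
    """
    n = v.size
    if n < 3:
        raise ValidationError("linearity needs at least three individuals")
    return float(12.0 / (n**3 - n) * np.sum((v - (n - 1) / 2.0) ** 2))


@dataclass
class DominanceResult:
    """David's scores plus hierarchy linearity diagnostics."""

    davids_scores: pd.Series
    h_prime: float
    p_linearity: float
    n_rand: int
    seed: int
    n_unknown_dyads: int
    n_tied_dyads: int

    def summary(self) -> str:
        lines = ["Dominance (David's score, descending):"]
        for ind, ds in self.davids_scores.sort_values(ascending=False).items():
            lines.append(f"  {ind:<12s} {ds:8.3f}")
        lines.append(
            f"Linearity: h' = {self.h_prime:.3f}, p = {self.p_linearity:.3f} "
            f"({self.n_unknown_dyads} unknown, {self.n_tied_dyads} tied dyads; "
            f"{self.n_rand} randomizations)"
        )
        return "\n".join(lines)


def landau_h_prime(
    w: DyadMatrix, n_rand: int = 1000, seed: int = 0
) -> DominanceResult:
    """Linearity of the dominance hierarchy with unknown/tied dyads
    resolved at random.

    In each of ``n_rand`` randomizations every dyad with no encounters or an
    equal win split is assigned a random direction, all decided dyads keep
    their observed direction, and Landau's h is computed from the dominance
    out-degrees; h' is the mean. The p-value is the right-tail proportion of
    h values from fully random dominance matrices reaching h'.
    """
    if n_rand < 1:
        raise ValidationError("n_rand must be >= 1")
    n = w.n
    if n < 3:
        raise ValidationError("linearity needs at least three individuals")
    rng = np.random.default_rng(seed)
    wins = w.values
    iu = np.triu_indices(n, k=1)
    win_i = wins[iu]
    win_j = wins.T[iu]
    decided_i = win_i > win_j  # i (row) dominates j
    decided_j = win_j > win_i
    undecided = ~(decided_i | decided_j)
    n_unknown = int(np.sum((win_i == 0) & (win_j == 0)))
    n_tied = int(undecided.sum()) - n_unknown

    base_v = np.zeros(n)
    np.add.at(base_v, iu[0][decided_i], 1)
    np.add.at(base_v, iu[1][decided_j], 1)
    und_i, und_j = iu[0][undecided], iu[1][undecided]

    h_obs = np.empty(n_rand)
    for k in range(n_rand):
        v = base_v.copy()
        coin = rng.random(und_i.size) < 0.5
        np.add.at(v, und_i[coin], 1)
        np.add.at(v, und_j[~coin], 1)
        h_obs[k] = landau_h(v)
    h_prime = float(h_obs.mean())

    h_null = np.empty(n_rand)
    all_i, all_j = iu
    for k in range(n_rand):
        v = np.zeros(n)
        coin = rng.random(all_i.size) < 0.5
        np.add.at(v, all_i[coin], 1)
        np.add.at(v, all_j[~coin], 1)
        h_null[k] = landau_h(v)
    p = float(np.mean(h_null >= h_prime - 1e-12))

    return DominanceResult(
        davids_scores=davids_score(w),
        h_prime=h_prime,
        p_linearity=p,
        n_rand=n_rand,
        seed=seed,
        n_unknown_dyads=n_unknown,
        n_tied_dyads=n_tied,
    )
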