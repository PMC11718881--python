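"""Packaged worked-example data for a nine-stallion bachelor group.

These are the published summary matrices for a captive bachelor group of
Przewalski's horses (nine stallions observed over 65 contact hours):
the dyadic association-index matrix, the directed affiliative interaction
rate matrix, per-individual sociability measures, the dyadic behavioural
synchronization matrix, a one-generation pedigree, and the tallies of
interaction bouts by type. They serve as ground truth for the estimators in
this package and as ready-made inputs for matrix-level analyses.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np
import pandas as pd

from .datatypes import DyadMatrix, Individual, Partition

__all__ = ["HORSES", "REFERENCE_PARTITION", "load_fixture", "FIXTURE_NAMES"]

#: The nine stallions, in the row/column order used by every fixture matrix.
HORSES: tuple[str, ...] = (
    "Bulat",
    "Lepet",
    "Losk",
    "Lovelas",
    "Palats",
    "Parus",
    "Vernij",
    "Vitjaz",
    "Zakat",
)

#: The three social clusters reported for this group (community detection on
#: the association matrix; the interaction-based algorithm found the same).
REFERENCE_PARTITION = Partition(
    membership={
        "Bulat": 0,
        "Vitjaz": 0,
        "Parus": 0,
        "Losk": 1,
        "Palats": 1,
        "Zakat": 1,
        "Lepet": 1,
        "Lovelas": 2,
        "Vernij": 2,
    }
)

# Dyadic association indices (proportion of scans spent in the same spatial
# group), upper triangle as printed.
_AI_UPPER = {
    ("Bulat", "Lepet"): 0.012,
    ("Bulat", "Losk"): 0.005,
    ("Bulat", "Lovelas"): 0.000,
    ("Bulat", "Palats"): 0.002,
    ("Bulat", "Parus"): 0.325,
    ("Bulat", "Vernij"): 0.000,
    ("Bulat", "Vitjaz"): 0.305,
    ("Bulat", "Zakat"): 0.057,
    ("Lepet", "Losk"): 0.107,
    ("Lepet", "Lovelas"): 0.000,
    ("Lepet", "Palats"): 0.082,
    ("Lepet", "Parus"): 0.012,
    ("Lepet", "Vernij"): 0.000,
    ("Lepet", "Vitjaz"): 0.012,
    ("Lepet", "Zakat"): 0.107,
    ("Losk", "Lovelas"): 0.000,
    ("Losk", "Palats"): 0.529,
    ("Losk", "Parus"): 0.007,
    ("Losk", "Vernij"): 0.000,
    ("Losk", "Vitjaz"): 0.000,
    ("Losk", "Zakat"): 0.139,
    ("Lovelas", "Palats"): 0.000,
    ("Lovelas", "Parus"): 0.000,
    ("Lovelas", "Vernij"): 0.665,
    ("Lovelas", "Vitjaz"): 0.000,
    ("Lovelas", "Zakat"): 0.000,
    ("Palats", "Parus"): 0.015,
    ("Palats", "Vernij"): 0.000,
    ("Palats", "Vitjaz"): 0.020,
    ("Palats", "Zakat"): 0.156,
    ("Parus", "Vernij"): 0.000,
    ("Parus", "Vitjaz"): 0.357,
    ("Parus", "Zakat"): 0.012,
    ("Vernij", "Vitjaz"): 0.000,
    ("Vernij", "Zakat"): 0.000,
    ("Vitjaz", "Zakat"): 0.005,
}

# Directed affiliative interaction rates (events per contact hour),
# rows = actor, columns = recipient.
_AFFIL_ROWS = {
    "Bulat": [0.000, 0.000, 0.031, 0.000, 0.092, 0.415, 0.000, 0.062, 0.385],
    "Lepet": [0.000, 0.000, 0.015, 0.000, 0.062, 0.000, 0.000, 0.000, 0.108],
    "Losk": [0.031, 0.015, 0.000, 0.000, 0.923, 0.031, 0.000, 0.000, 1.077],
    "Lovelas": [0.000, 0.000, 0.000, 0.000, 0.000, 0.000, 0.046, 0.000, 0.000],
    "Palats": [0.031, 0.031, 0.015, 0.000, 0.000, 0.000, 0.000, 0.000, 0.723],
    "Parus": [0.046, 0.000, 0.000, 0.000, 0.000, 0.000, 0.000, 0.031, 0.031],
    "Vernij": [0.000, 0.000, 0.000, 0.000, 0.000, 0.000, 0.000, 0.000, 0.000],
    "Vitjaz": [0.354, 0.000, 0.000, 0.000, 0.015, 0.662, 0.000, 0.000, 0.000],
    "Zakat": [0.015, 0.000, 0.077, 0.000, 0.154, 0.000, 0.000, 0.000, 0.000],
}

# Per-individual sociability measures: node strength and weighted degree from
# the association and affiliative-rate networks, plus the dominance index
# (David's score from the agonistic encounters; raw counts unpublished).
_NODE_MEASURES = {
    "Bulat": (0.707, 2.060, 1.453, 2.213, 1.178),
    "Lepet": (0.333, 1.412, 0.229, 0.742, 11.964),
    "Losk": (0.787, 1.983, 2.203, 3.213, -0.333),
    "Lovelas": (0.665, 0.815, 0.046, 0.214, -6.540),
    "Palats": (0.804, 2.196, 2.035, 1.784, -2.792),
    "Parus": (0.730, 2.092, 1.209, 0.567, 2.031),
    "Vernij": (0.665, 0.815, 0.046, 0.000, -5.883),
    "Vitjaz": (0.700, 1.870, 1.117, 1.754, 1.167),
    "Zakat": (0.476, 1.691, 2.555, 0.857, -0.792),
}

# Dyadic behavioural synchronization indices (mean over activities),
# upper triangle as printed.
_BSI_UPPER = {
    ("Bulat", "Lepet"): 0.430,
    ("Bulat", "Losk"): 0.391,
    ("Bulat", "Lovelas"): 0.205,
    ("Bulat", "Palats"): 0.406,
    ("Bulat", "Parus"): 0.607,
    ("Bulat", "Vernij"): 0.204,
    ("Bulat", "Vitjaz"): 0.579,
    ("Bulat", "Zakat"): 0.390,
    ("Lepet", "Losk"): 0.485,
    ("Lepet", "Lovelas"): 0.197,
    ("Lepet", "Palats"): 0.499,
    ("Lepet", "Parus"): 0.404,
    ("Lepet", "Vernij"): 0.196,
    ("Lepet", "Vitjaz"): 0.403,
    ("Lepet", "Zakat"): 0.445,
    ("Losk", "Lovelas"): 0.213,
    ("Losk", "Palats"): 0.709,
    ("Losk", "Parus"): 0.406,
    ("Losk", "Vernij"): 0.208,
    ("Losk", "Vitjaz"): 0.336,
    ("Losk", "Zakat"): 0.553,
    ("Lovelas", "Palats"): 0.215,
    ("Lovelas", "Parus"): 0.219,
    ("Lovelas", "Vernij"): 0.881,
    ("Lovelas", "Vitjaz"): 0.176,
    ("Lovelas", "Zakat"): 0.174,
    ("Palats", "Parus"): 0.465,
    ("Palats", "Vernij"): 0.212,
    ("Palats", "Vitjaz"): 0.373,
    ("Palats", "Zakat"): 0.549,
    ("Parus", "Vernij"): 0.230,
    ("Parus", "Vitjaz"): 0.596,
    ("Parus", "Zakat"): 0.397,
    ("Vernij", "Vitjaz"): 0.186,
    ("Vernij", "Zakat"): 0.169,
    ("Vitjaz", "Zakat"): 0.349,
}

# Studbook pedigree, one generation deep: (studbook_id, sire_id, dam_id,
# birth date). Grandparents are treated as founders.
_PEDIGREE = {
    "Zakat": (5401, 3714, 2765, _dt.date(2009, 5, 25)),
    "Lepet": (3756, 1447, 1577, _dt.date(2002, 5, 25)),
    "Palats": (3502, 1447, 1864, _dt.date(2001, 4, 21)),
    "Bulat": (3099, 1608, 1382, _dt.date(2001, 4, 21)),
    "Lovelas": (3521, 1447, 2516, _dt.date(2001, 5, 12)),
    "Vernij": (3093, 1447, 2516, _dt.date(1997, 6, 6)),
    "Vitjaz": (2906, 1608, 601, _dt.date(1996, 5, 3)),
    "Losk": (2935, 1608, 490, _dt.date(1996, 5, 27)),
    "Parus": (2665, 1231, 1864, _dt.date(1994, 5, 11)),
}

# Published tallies of interaction bouts by type over the 65 contact hours.
_INTERACTION_COUNTS = {
    "affiliative_total": 358,
    "allogrooming": 335,
    "agonistic_total": 107,
    "submissive_total": 65,
    "avoidance": 62,
    "offensive_total": 42,
    "harassment": 33,
}

FIXTURE_NAMES = (
    "table5_ai",
    "table6_affil_rates",
    "table7_node_measures",
    "table11_bsi",
    "table1_pedigree",
    "interaction_counts",
)


def _symmetric_from_upper(upper: dict[tuple[str, str], float]) -> DyadMatrix:
    n = len(HORSES)
    idx = {h: i for i, h in enumerate(HORSES)}
    m = np.zeros((n, n))
    for (a, b), v in upper.items():
        m[idx[a], idx[b]] = v
        m[idx[b], idx[a]] = v
    return DyadMatrix(HORSES, m, directed=False)


def load_fixture(name: str):
    """Return a packaged fixture by name.

    Parameters
    ----------
    name
        One of ``table5_ai`` (symmetric association-index matrix),
        ``table6_affil_rates`` (directed affiliative rate matrix),
        ``table7_node_measures`` (per-individual sociability DataFrame),
        ``table11_bsi`` (symmetric synchrony matrix),
        ``table1_pedigree`` (list of :class:`~herdnet.datatypes.Individual`),
        ``interaction_counts`` (dict of printed bout tallies).
    """
    if name == "table5_ai":
        return _symmetric_from_upper(_AI_UPPER)
    if name == "table11_bsi":
        return _symmetric_from_upper(_BSI_UPPER)
    if name == "table6_affil_rates":
        m = np.array([_AFFIL_ROWS[h] for h in HORSES])
        return DyadMatrix(HORSES, m, directed=True)
    if name == "table7_node_measures":
        df = pd.DataFrame.from_dict(
            _NODE_MEASURES,
            orient="index",
            columns=["S_assoc", "WD_assoc", "S_affil", "WD_affil", "DI"],
        )
        return df.loc[list(HORSES)]
    if name == "table1_pedigree":
        return [
            Individual(
                id=h,
                studbook_id=sb,
                sire_id=sire,
                dam_id=dam,
                birth_date=bd,
            )
            for h, (sb, sire, dam, bd) in _PEDIGREE.items()
        ]
    if name == "interaction_counts":
        return dict(_INTERACTION_COUNTS)
    raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
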