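"""Statsmodels-style front end: a model bound to the raw data streams whose
``fit`` runs the full social-structure analysis and returns a results
object with estimates, permutation-based uncertainty, and a summary table.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import association as _assoc
from . import dominance as _dom
from . import network as _net
from . import permutation as _perm
from . import space_time as _st
from . import synchrony as _sync
from . import kinship as _kin
from .datatypes import (
    DyadMatrix,
    HerdnetError,
    Individual,
    InteractionEvent,
    ObservationLog,
    Partition,
    PermutationResult,
    ScanDataset,
    ZoneMap,
)

__all__ = ["SocialStructureModel", "SocialStructureResults"]


def _substream(seed: int, label: str) -> int:
    """Stable per-stage seed derived from the master seed."""
    ss = np.random.SeedSequence(seed, spawn_key=(abs(hash_label(label)),))
    return int(ss.generate_state(1)[0] % (2**31))


def hash_label(label: str) -> int:
    # deterministic across processes (unlike built-in hash for str)
    h = 0
    for ch in label:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h


class SocialStructureModel:
    """Social-structure analysis of a scan-sampled group.

    Parameters
    ----------
    scans
        Scan dataset (behaviour + proximity pairs). Required for
        association, synchrony, time-budget and space-use stages.
    events
        All-occurrence interaction stream; enables interaction-rate,
        dominance and event-summary stages.
    obslog
        Observation effort; required to convert event counts to rates. If
        omitted but scans are present, one window per day spanning the scan
        times is assumed.
    zones, pedigree, cutover_day
        Optional inputs enabling space-use and kinship stages.
    """

    def __init__(
        self,
        scans: ScanDataset | None = None,
        events: Sequence[InteractionEvent] | None = None,
        obslog: ObservationLog | None = None,
        zones: ZoneMap | None = None,
        pedigree: Sequence[Individual] | None = None,
        cutover_day: _dt.date | None = None,
    ) -> None:
        if scans is None and events is None:
            raise HerdnetError("need at least scans or events")
        self.scans = scans
        self.events = list(events) if events is not None else None
        self.zones = zones
        self.pedigree = list(pedigree) if pedigree is not None else None
        self.cutover_day = cutover_day
        if obslog is None and scans is not None:
            obslog = _infer_obslog(scans)
        self.obslog = obslog

    @classmethod
    def from_csv(
        cls,
        scans: str | None = None,
        pairs: str | None = None,
        events: str | None = None,
        obslog: str | None = None,
        zones: str | None = None,
        pedigree: str | None = None,
        cutover_day: str | None = None,
    ) -> "SocialStructureModel":
        from . import io as _io
        from .fixtures import load_fixture  # noqa: F401  (kept for symmetry)

        ped = None
        if pedigree is not None:
            df = pd.read_csv(pedigree, dtype=str, keep_default_na=False)
            ped = [
                Individual(
                    id=r.id,
                    sire_id=int(r.sire) if r.sire else None,
                    dam_id=int(r.dam) if r.dam else None,
                )
                for r in df.itertuples(index=False)
            ]
        return cls(
            scans=_io.load_scan_dataset(scans, pairs) if scans else None,
            events=_io.load_events(events) if events else None,
            obslog=_io.load_obslog(obslog) if obslog else None,
            zones=_io.load_zones(zones) if zones else None,
            pedigree=ped,
            cutover_day=(
                _dt.date.fromisoformat(cutover_day) if cutover_day else None
            ),
        )

    @classmethod
    def from_synthetic(cls, config=None, seed: int | None = None):
        """Build the model on a synthetic dataset; returns (model, truth)."""
        from . import synthetic as _syn

        config = config or _syn.SyntheticConfig()
        if seed is not None:
            from dataclasses import replace

            config = replace(config, seed=seed)
        scans, events, truth = _syn.generate(config)
        model = cls(
            scans=scans,
            events=events,
            obslog=_syn.observation_log_for(config),
            zones=_syn.default_zone_map(),
        )
        return model, truth

    # ------------------------------------------------------------------

    def fit(
        self,
        n_perm: int = 1000,
        seed: int = 0,
        alpha: float = 0.5,
        preferred_threshold: float = 0.05,
        avoided_threshold: float = 0.95,
        community_restarts: int = 100,
        partition_test_restarts: int = 10,
        run_partition_test: bool = True,
    ) -> "SocialStructureResults":
        """Run every stage the bound inputs allow and collect the results."""
        r = SocialStructureResults(
            model=self, n_perm=n_perm, seed=seed, alpha=alpha
        )

        if self.scans is not None:
            r.ai = _assoc.association_matrix(self.scans)
            r.cv_test, r.dyads = _perm.nonrandomness_analysis(
                self.scans,
                n_perm=n_perm,
                seed=_substream(seed, "datastream"),
                preferred_threshold=preferred_threshold,
                avoided_threshold=avoided_threshold,
            )
            r.partition = _net.detect_communities(
                r.ai, seed=_substream(seed, "louvain"),
                restarts=community_restarts,
            )
            if run_partition_test:
                r.partition_test = _net.partition_pvalue(
                    r.ai, r.partition, n_perm=n_perm,
                    seed=_substream(seed, "partition"),
                    restarts=partition_test_restarts,
                )
            r.bsi = _sync.bsi_matrix(self.scans)
            r.bsi_test = _sync.bsi_null(
                self.scans, n_perm=n_perm,
                seed=_substream(seed, "bsi"),
            )
            r.cluster_sync = _sync.cluster_synchrony(
                r.bsi, r.partition, n_perm=n_perm,
                seed=_substream(seed, "clustersync"),
            )
            r.mantel_ai_bsi = _perm.mantel_test(
                r.ai, r.bsi, n_perm=n_perm, seed=_substream(seed, "mantel"),
            )
            r.time_budget = _st.time_budget(self.scans)
            if self.zones is not None:
                if self.cutover_day is not None:
                    a, b, avail_a, avail_b = _st.availability_split(
                        self.scans, self.cutover_day, self.zones
                    )
                    r.space_use = {
                        "A": _st.space_use_profile(a, self.zones, avail_a),
                        "B": _st.space_use_profile(b, self.zones, avail_b),
                    }
                else:
                    r.space_use = {
                        "all": _st.space_use_profile(self.scans, self.zones)
                    }

        if self.events is not None:
            r.event_summary = _assoc.interaction_summary(self.events)
            if self.obslog is not None and self.obslog.total_hours > 0:
                ids = self.scans.individuals if self.scans else None
                r.affil_rates = _assoc.interaction_rate_matrix(
                    self.events, self.obslog, "affiliative", ids=ids
                )
                r.agon_rates = _assoc.interaction_rate_matrix(
                    self.events, self.obslog, "agonistic", ids=ids
                )
            agonistic = [e for e in self.events if e.kind == "agonistic"]
            if agonistic:
                ids = self.scans.individuals if self.scans else None
                wins = _dom.win_matrix(agonistic, ids=ids)
                if wins.n >= 3:
                    r.dominance = _dom.landau_h_prime(
                        wins, n_rand=n_perm, seed=_substream(seed, "landau")
                    )
                r.win_matrix = wins

        if self.pedigree is not None:
            ids = None
            if self.scans is not None:
                ids = list(self.scans.individuals)
            r.kinship = _kin.kinship_matrix(self.pedigree, ids=ids)
            if r.ai is not None and set(r.kinship.ids) == set(r.ai.ids):
                r.mantel_ai_kinship = _perm.mantel_test(
                    r.ai, r.kinship, n_perm=n_perm,
                    seed=_substream(seed, "mantelkin"),
                )

        r.node_measures = r._build_node_measures(alpha)
        return r


def _infer_obslog(scans: ScanDataset) -> ObservationLog:
    windows = []
    by_day: dict[_dt.date, list[int]] = {}
    for s in scans.samples:
        by_day.setdefault(s.day, []).append(s.time)
    for day, times in sorted(by_day.items()):
        # each scan represents its 10-min interval
        windows.append((day, min(times), max(times) + 10))
    return ObservationLog(windows=windows)


@dataclass
class SocialStructureResults:
    """Fitted quantities of :class:`SocialStructureModel`.

    Every attribute is ``None`` until the corresponding stage ran; the
    ``summary`` method prints whatever is available.
    """

    model: SocialStructureModel
    n_perm: int
    seed: int
    alpha: float

    ai: _assoc.AssociationMatrix | None = None
    cv_test: PermutationResult | None = None
    dyads: _perm.DyadClassification | None = None
    partition: Partition | None = None
    partition_test: PermutationResult | None = None
    affil_rates: DyadMatrix | None = None
    agon_rates: DyadMatrix | None = None
    win_matrix: DyadMatrix | None = None
    dominance: _dom.DominanceResult | None = None
    bsi: _sync.BsiMatrix | None = None
    bsi_test: _sync.BsiNullResult | None = None
    cluster_sync: _sync.ClusterSynchrony | None = None
    mantel_ai_bsi: PermutationResult | None = None
    mantel_ai_kinship: PermutationResult | None = None
    kinship: DyadMatrix | None = None
    time_budget: pd.DataFrame | None = None
    space_use: dict | None = None
    event_summary: dict | None = None
    node_measures: pd.DataFrame | None = None

    # ------------------------------------------------------------------

    def _build_node_measures(self, alpha: float) -> pd.DataFrame | None:
        cols = {}
        if self.ai is not None:
            cols["S_assoc"] = _net.node_strength(self.ai)
            cols["WD_assoc"] = _net.weighted_degree(self.ai, alpha)
        if self.affil_rates is not None:
            cols["S_affil"] = _net.node_strength(self.affil_rates, "total")
            cols["WD_affil"] = _net.weighted_degree(self.affil_rates, alpha)
        if self.dominance is not None:
            cols["DI"] = self.dominance.davids_scores
        if not cols:
            return None
        return pd.DataFrame(cols)

    def summary(self) -> str:
        lines = ["Social structure analysis", "=" * 40]
        if self.ai is not None:
            ut = self.ai.upper_triangle()
            lines.append(
                f"Association: {self.ai.n} individuals, "
                f"mean AI {ut.mean():.3f} ± {ut.std(ddof=1):.3f} (sd), "
                f"CV {ut.std(ddof=1) / ut.mean():.3f}"
            )
        if self.cv_test is not None:
            lines.append(
                f"  non-randomness (CV vs data-stream null): "
                f"p = {self.cv_test.p_value:.4g} "
                f"({self.cv_test.n_perm} permutations)"
            )
        if self.dyads is not None:
            pref = len(self.dyads.pairs_labelled("preferred"))
            avoid = len(self.dyads.pairs_labelled("avoided"))
            lines.append(
                f"  dyads: {pref} preferred, {avoid} avoided "
                f"of {self.dyads.n_dyads}"
            )
        if self.partition is not None:
            comms = [
                "{" + ",".join(sorted(c)) + "}"
                for c in self.partition.communities()
            ]
            lines.append(
                f"Communities: {self.partition.n_communities} "
                f"(Q = {self.partition.modularity:.3f}): " + " ".join(comms)
            )
        if self.partition_test is not None:
            lines.append(
                f"  modularity test: p = {self.partition_test.p_value:.4g}"
            )
        if self.event_summary is not None:
            es = self.event_summary
            lines.append(
                f"Events: {es['affiliative_total']} affiliative"
                + (
                    f" ({es['allogrooming_pct_of_affiliative']:.1f}% allogrooming)"
                    if "allogrooming_pct_of_affiliative" in es
                    else ""
                )
                + f", {es['agonistic_total']} agonistic"
                + (
                    f" ({es['submissive_pct_of_agonistic']:.1f}% submissive)"
                    if "submissive_pct_of_agonistic" in es
                    else ""
                )
            )
        if self.dominance is not None:
            lines.append(self.dominance.summary())
        if self.bsi is not None:
            lines.append(f"Synchrony: mean BSI {self.bsi.mean_offdiagonal():.3f}")
        if self.bsi_test is not None:
            lines.append(
                f"  group-mean BSI test: p = {self.bsi_test.mean_test.p_value:.4g}"
            )
        if self.cluster_sync is not None:
            cs = self.cluster_sync
            lines.append(
                f"  within-cluster {cs.within_mean:.3f} vs between "
                f"{cs.between_mean:.3f} (diff {cs.difference:.3f}, "
                f"p = {cs.p_value:.4g})"
            )
        if self.mantel_ai_bsi is not None:
            lines.append(
                f"Mantel AI~BSI: r = {self.mantel_ai_bsi.observed_stat:.3f}, "
                f"p = {self.mantel_ai_bsi.p_value:.4g}"
            )
        if self.mantel_ai_kinship is not None:
            lines.append(
                f"Mantel AI~kinship: r = "
                f"{self.mantel_ai_kinship.observed_stat:.3f}, "
                f"p = {self.mantel_ai_kinship.p_value:.4g}"
            )
        if self.space_use is not None:
            for period, prof in self.space_use.items():
                lines.append(
                    f"Space use [{period}]: mean SPI {prof.spi.mean():.3f} "
                    f"over {len(prof.available_zones)} zones"
                )
        if self.node_measures is not None:
            lines.append("Node measures:")
            lines.append(self.node_measures.round(3).to_string())
        return "\n".join(lines)

    # ------------------------------------------------------------------

    def to_report(self) -> dict:
        """Nested mapping suitable for :func:`herdnet.io.write_report`."""
        out: dict = {
            "config": {
                "n_perm": self.n_perm,
                "seed": self.seed,
                "alpha": self.alpha,
                "permutation_scheme": "cumulative-swap-chain-no-burnin",
            }
        }
        if self.ai is not None:
            out["association"] = {
                "matrix": self.ai,
                "cv_test": self.cv_test,
                "p_high": self.dyads.p_high if self.dyads else None,
            }
        if self.partition is not None:
            out["communities"] = {
                "partition": self.partition,
                "test": self.partition_test,
            }
        if self.affil_rates is not None:
            out["interaction_rates"] = {
                "affiliative": self.affil_rates,
                "agonistic": self.agon_rates,
            }
        if self.event_summary is not None:
            out["event_summary"] = self.event_summary
        if self.dominance is not None:
            out["dominance"] = {
                "davids_scores": self.dominance.davids_scores,
                "h_prime": self.dominance.h_prime,
                "p_linearity": self.dominance.p_linearity,
                "win_matrix": self.win_matrix,
            }
        if self.bsi is not None:
            out["synchrony"] = {
                "bsi": self.bsi,
                "mean_test": self.bsi_test.mean_test if self.bsi_test else None,
                "p_high": self.bsi_test.p_high if self.bsi_test else None,
            }
        if self.cluster_sync is not None:
            cs = self.cluster_sync
            out["cluster_synchrony"] = {
                "within_mean": cs.within_mean,
                "between_mean": cs.between_mean,
                "difference": cs.difference,
                "p_value": cs.p_value,
            }
        if self.mantel_ai_bsi is not None:
            out["mantel"] = {"ai_bsi": self.mantel_ai_bsi}
            if self.mantel_ai_kinship is not None:
                out["mantel"]["ai_kinship"] = self.mantel_ai_kinship
        if self.kinship is not None:
            out["kinship"] = {"matrix": self.kinship}
        if self.node_measures is not None:
            out["node_measures"] = self.node_measures
        if self.time_budget is not None:
            tb = self.time_budget.copy()
            tb.index = [f"{i}|{b}" for i, b in tb.index]
            out["time_budget"] = tb
        if self.space_use is not None:
            out["space_use"] = {
                period: {
                    "electivity": prof.electivity,
                    "spi": prof.spi,
                }
                for period, prof in self.space_use.items()
            }
        return out

    # -- plotting ------------------------------------------------------

    def plot_network(self, which: str = "ai", ax=None):
        """Draw the association (or rate) network coloured by community."""
        from . import plotting

        m = {"ai": self.ai, "affiliative": self.affil_rates,
             "agonistic": self.agon_rates}[which]
        return plotting.plot_network(m, self.partition, ax=ax)

    def plot_heatmap(self, which: str = "ai", ax=None):
        from . import plotting

        m = {"ai": self.ai, "bsi": self.bsi,
             "kinship": self.kinship}[which]
        return plotting.plot_heatmap(m, ax=ax)
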