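"""Aggregation of individual HRR networks into consensus networks.

Six modes = {co-occurrence, minimal HRR} x {all members, 50% highest GO AUROC,
50% lowest GO AUROC}: Call, CHGA, CLGA (co-occurrence) and Hall, HHGA, HLGA
(HRR).  Edges from all member networks are pooled; each pooled edge carries
its co-occurrence count (number of member networks containing it) and its
minimal HRR across members.  To target a given aggregate size the pooled
edges are sorted (co-occurrence descending, or HRR ascending), the weight of
the target-th edge becomes the threshold, and ALL edges at or beyond the
threshold are retained — tie-inclusive, so the final size may differ from the
target.  Co-occurrence aggregates additionally require an edge to occur in at
least two members, which can make them smaller than the target.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .io import canonicalize_edges
from .network import Network

logger = logging.getLogger("coexpnet")

MODES = ("Call", "CHGA", "CLGA", "Hall", "HHGA", "HLGA")
#: minimal number of member networks an edge must occur in (co-occurrence modes)
MIN_COOC = 2


@dataclass
class NetworkScore:
    """GO AUROC of one member network, used for HGA/LGA selection."""

    network_id: str
    go_auroc: float


@dataclass
class Aggregate:
    """Merged edge set over several networks."""

    edges: pd.DataFrame  # canonical columns gene_a, gene_b, hrr, cooc
    mode: str
    member_ids: list[str]
    threshold_used: int

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def nodes(self) -> set[str]:
        return set(self.edges["gene_a"]) | set(self.edges["gene_b"])

    def edge_set(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["gene_a"], self.edges["gene_b"]))


def select_members(networks: list[Network], scores: list[NetworkScore] | None,
                   selection: str) -> list[Network]:
    """Pick member networks: all, 50% highest (HGA) or 50% lowest (LGA) GO AUROC.

    Half size = ceil(n/2); AUROC ties are broken by network id so the
    partition is deterministic.
    """
    if selection == "all":
        return list(networks)
    if selection not in ("HGA", "LGA"):
        raise ValueError(f"selection must be all|HGA|LGA, got {selection!r}")
    if len(networks) < 2:
        raise ValueError("HGA/LGA selection needs at least 2 networks")
    if scores is None:
        raise ValueError("HGA/LGA selection needs per-network GO AUROC scores")
    by_id = {s.network_id: s.go_auroc for s in scores}
    missing = [n.source for n in networks if n.source not in by_id]
    if missing:
        raise ValueError(f"missing scores for networks: {missing}")
    half = math.ceil(len(networks) / 2)
    reverse = selection == "HGA"
    ordered = sorted(networks,
                     key=lambda n: ((-by_id[n.source]) if reverse else by_id[n.source],
                                    n.source))
    return ordered[:half]


def _pool_edges(members: list[Network]) -> pd.DataFrame:
    frames = [canonicalize_edges(m.edges) for m in members]
    pooled = pd.concat(frames, ignore_index=True)
    agg = (pooled.groupby(["gene_a", "gene_b"], as_index=False)
           .agg(hrr=("hrr", "min"), cooc=("hrr", "size")))
    return agg


def aggregate_cooc(members: list[Network], target_edges: int,
                   mode: str = "Call", member_ids: list[str] | None = None) -> Aggregate:
    """Co-occurrence aggregation with the >= 2 occurrence floor.

    Threshold = co-occurrence of the ``target_edges``-th edge of the pooled
    list sorted by decreasing co-occurrence (falling back to the smallest
    observed co-occurrence when the pool is smaller); every edge with
    co-occurrence >= max(threshold, 2) is retained.
    """
    if len(members) < 2:
        raise ValueError("aggregation needs at least 2 member networks")
    pooled = _pool_edges(members)
    ordered = pooled.sort_values(["cooc", "gene_a", "gene_b"],
                                 ascending=[False, True, True], kind="mergesort")
    if target_edges <= len(ordered):
        threshold = int(ordered["cooc"].iloc[target_edges - 1])
    else:
        threshold = int(ordered["cooc"].min())
    if threshold < MIN_COOC:
        logger.info("co-occurrence floor (%d) binds over the size threshold (%d)",
                    MIN_COOC, threshold)
    cut = max(threshold, MIN_COOC)
    kept = pooled[pooled["cooc"] >= cut]
    ids = member_ids if member_ids is not None else [m.source for m in members]
    return Aggregate(edges=canonicalize_edges(kept), mode=mode,
                     member_ids=list(ids), threshold_used=cut)


def aggregate_hrr(members: list[Network], target_edges: int,
                  mode: str = "Hall", member_ids: list[str] | None = None) -> Aggregate:
    """Minimal-HRR aggregation: threshold = HRR of the ``target_edges``-th
    pooled edge sorted by increasing HRR; every edge at or below it is kept."""
    if len(members) < 2:
        raise ValueError("aggregation needs at least 2 member networks")
    pooled = _pool_edges(members)
    ordered = pooled.sort_values(["hrr", "gene_a", "gene_b"], kind="mergesort")
    if target_edges <= len(ordered):
        threshold = int(ordered["hrr"].iloc[target_edges - 1])
    else:
        threshold = int(ordered["hrr"].max())
    kept = pooled[pooled["hrr"] <= threshold]
    ids = member_ids if member_ids is not None else [m.source for m in members]
    return Aggregate(edges=canonicalize_edges(kept), mode=mode,
                     member_ids=list(ids), threshold_used=threshold)


def aggregate_networks(networks: list[Network], mode: str, target_edges: int,
                       scores: list[NetworkScore] | None = None) -> Aggregate:
    """Dispatch one of the six named modes."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    selection = "all" if mode.endswith("all") else mode[1:]
    members = select_members(networks, scores, selection)
    if mode.startswith("C"):
        return aggregate_cooc(members, target_edges, mode=mode)
    return aggregate_hrr(members, target_edges, mode=mode)


def size_filter(agg: Aggregate, target_edges: int | None = None,
                lower: int | None = None, upper: int | None = None) -> bool:
    """Strict size window: keep aggregates with lower < |edges| < upper.

    Defaults scale the reference window (5e5, 1.5e6 around 1M edges) as
    0.5x and 1.5x the target size.
    """
    if lower is None or upper is None:
        if target_edges is None:
            raise ValueError("either explicit bounds or target_edges is required")
        lower = int(0.5 * target_edges) if lower is None else lower
        upper = int(1.5 * target_edges) if upper is None else upper
    if not (0 < lower < upper):
        raise ValueError("bounds must be positive with lower < upper")
    return lower < agg.n_edges < upper
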