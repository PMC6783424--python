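"""Pathway Level Coexpression (PLC) subnetworks.

A PLC is the guide-gene-anchored slice of a network: every edge touching a
guide gene (GG), plus edges between associated genes (AG, the non-guide first
neighbors of GGs) that themselves exist in the source network.  A targeted
PLC instead admits GG-touching edges in order of strength (HRR ascending or
co-occurrence descending) until a vertex budget is reached, for a small
high-confidence view of one pathway.  Guide-gene community quality is scored
with a normalized Chi-squared in [0, 1]: a Cramer's-V-style statistic of the
guide-group x community contingency table, discounted by the fraction of
guide genes the PLC captured.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .io import GuideGeneSet, canonicalize_edges

logger = logging.getLogger("coexpnet")

NODE_CLASSES = ("GG", "AG", "OG")


@dataclass
class PLC:
    """Guide-gene-anchored subnetwork with node classes and communities."""

    edges: pd.DataFrame  # canonical columns gene_a, gene_b, hrr, cooc
    node_class: dict[str, str]
    community_of_node: dict[str, int]
    guide_set: GuideGeneSet
    source: str = "network"

    @property
    def nodes(self) -> set[str]:
        return set(self.node_class)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_set(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["gene_a"], self.edges["gene_b"]))


@dataclass
class ChiSquaredReport:
    contingency: pd.DataFrame
    chi2: float
    normalized_chi2: float
    n_guides_captured: int
    n_guides_total: int


def _fast_greedy_communities(edges: pd.DataFrame) -> dict[str, int]:
    g = nx.Graph()
    g.add_edges_from(zip(edges["gene_a"], edges["gene_b"]))
    if g.number_of_nodes() == 0:
        return {}
    out: dict[str, int] = {}
    for cid, members in enumerate(nx.community.greedy_modularity_communities(g)):
        for node in members:
            out[node] = cid
    return out


def _empty_plc(guide_set: GuideGeneSet, source: str) -> PLC:
    edges = pd.DataFrame(columns=["gene_a", "gene_b", "hrr", "cooc"])
    return PLC(edges=edges, node_class={}, community_of_node={},
               guide_set=guide_set, source=source)


def extract_plc(network, guide_set: GuideGeneSet, source: str = "network") -> PLC:
    """Untargeted PLC: all GG-touching edges plus AG-AG edges of the source.

    AG = non-guide genes adjacent to at least one guide.  Every non-guide
    node is an AG by construction; the OG class only appears in targeted
    PLCs, where non-guides split into known-associated and other genes.
    """
    edges = canonicalize_edges(getattr(network, "edges", network))
    guides = guide_set.genes
    touches = edges["gene_a"].isin(guides) | edges["gene_b"].isin(guides)
    gg_edges = edges[touches]
    if gg_edges.empty:
        logger.warning("no guide gene of %r occurs in the network",
                       guide_set.pathway_name)
        return _empty_plc(guide_set, source)
    ag = (set(gg_edges["gene_a"]) | set(gg_edges["gene_b"])) - guides
    ag_edges = edges[~touches
                     & edges["gene_a"].isin(ag) & edges["gene_b"].isin(ag)]
    plc_edges = canonicalize_edges(pd.concat([gg_edges, ag_edges]))
    nodes = set(plc_edges["gene_a"]) | set(plc_edges["gene_b"])
    node_class = {n: ("GG" if n in guides else "AG") for n in nodes}
    return PLC(edges=plc_edges, node_class=node_class,
               community_of_node=_fast_greedy_communities(plc_edges),
               guide_set=guide_set, source=source)


def extract_targeted_plc(source_net, guide_set: GuideGeneSet, n_vertices: int = 30,
                         rank_by: str = "hrr",
                         known_associated: set[str] | None = None,
                         source: str = "network") -> PLC:
    """Small targeted PLC: admit GG-touching edges by strength until the
    vertex count first reaches >= ``n_vertices``.

    ``rank_by`` is "hrr" (ascending, any source) or "cooc" (descending,
    aggregates only — individual networks carry no informative co-occurrence).
    After the vertex budget is met, AG-AG edges among admitted vertices that
    exist in the source are added.  Non-guide nodes are classed AG when in
    ``known_associated``, otherwise OG.
    """
    edges = canonicalize_edges(getattr(source_net, "edges", source_net))
    if rank_by not in ("hrr", "cooc"):
        raise ValueError("rank_by must be 'hrr' or 'cooc'")
    if rank_by == "cooc" and (edges["cooc"] <= 1).all():
        raise ValueError("co-occurrence ranking requires an aggregate "
                         "(individual networks have cooc == 1 everywhere)")
    guides = guide_set.genes
    touches = edges["gene_a"].isin(guides) | edges["gene_b"].isin(guides)
    gg_edges = edges[touches]
    if gg_edges.empty:
        logger.warning("no guide gene of %r occurs in the network",
                       guide_set.pathway_name)
        return _empty_plc(guide_set, source)
    if rank_by == "hrr":
        gg_edges = gg_edges.sort_values(["hrr", "gene_a", "gene_b"], kind="mergesort")
    else:
        gg_edges = gg_edges.sort_values(["cooc", "gene_a", "gene_b"],
                                        ascending=[False, True, True], kind="mergesort")
    admitted_rows = []
    vertices: set[str] = set()
    for row in gg_edges.itertuples(index=False):
        admitted_rows.append(row)
        vertices |= {row.gene_a, row.gene_b}
        if len(vertices) >= n_vertices:
            break
    admitted = pd.DataFrame(admitted_rows, columns=gg_edges.columns)
    non_guides = vertices - guides
    extra = edges[~touches
                  & edges["gene_a"].isin(non_guides) & edges["gene_b"].isin(non_guides)]
    plc_edges = canonicalize_edges(pd.concat([admitted, extra]))
    known = known_associated or set()
    node_class = {n: ("GG" if n in guides else "AG" if n in known else "OG")
                  for n in vertices}
    return PLC(edges=plc_edges, node_class=node_class,
               community_of_node=_fast_greedy_communities(plc_edges),
               guide_set=guide_set, source=source)


def classify_nodes(plc: PLC, known_associated: set[str]) -> dict[str, str]:
    """Reclassify PLC nodes: GG if guide, AG if in ``known_associated``, else OG."""
    guides = plc.guide_set.genes
    return {n: ("GG" if n in guides else "AG" if n in known_associated else "OG")
            for n in plc.nodes}


def normalized_chi_squared(plc: PLC, guide_set: GuideGeneSet | None = None) -> ChiSquaredReport:
    """How well guide-gene sub-process groups align with PLC communities.

    Build the contingency table of captured guides (rows = guide groups,
    columns = communities); chi2 is the Pearson statistic without continuity
    correction.  normalized_chi2 = [chi2 / (n_cap * (min(r, c) - 1))] *
    (n_cap / n_total): the first factor is Cramer's V squared (1 at perfect
    group/community alignment), the second discounts PLCs that lost guide
    genes.  Degenerate tables (a single group or a single community among the
    captured guides) contribute 0.
    """
    guide_set = guide_set or plc.guide_set
    captured = sorted(guide_set.genes & set(plc.community_of_node))
    n_total = len(guide_set.genes)
    if not captured:
        empty = pd.DataFrame()
        return ChiSquaredReport(empty, 0.0, 0.0, 0, n_total)
    rows = pd.Series({g: str(guide_set.group_of_gene[g]) for g in captured})
    cols = pd.Series({g: plc.community_of_node[g] for g in captured})
    table = pd.crosstab(rows, cols)
    n_cap = len(captured)
    r, c = table.shape
    if r < 2 or c < 2:
        return ChiSquaredReport(table, 0.0, 0.0, n_cap, n_total)
    chi2 = float(chi2_contingency(table.to_numpy(), correction=False).statistic)
    norm = (chi2 / (n_cap * (min(r, c) - 1))) * (n_cap / n_total)
    norm = min(1.0, float(norm))  # guard float round-off at the Cramer bound
    return ChiSquaredReport(table, chi2, norm, n_cap, n_total)
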