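"""On-disk formats for expression matrices, edge lists, annotations and guide genes.

Everything is plain TSV (gzip transparently supported via the file extension)
so that intermediate artifacts stay inspectable with standard shell tools.
Edge identity is the unordered gene pair stored lexicographically; all readers
re-canonicalize on load so set operations on edge files are well defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("coexpnet")

EDGE_COLUMNS = ["gene_a", "gene_b", "hrr", "cooc"]


class SchemaError(ValueError):
    """A file violates its declared schema (duplicates, bad types, bad shape)."""


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance table with optional per-sample project labels.

    ``values`` carries genes as rows and samples as columns; units are the
    caller's (log-intensity, log-TPM, ...) since only correlations are consumed
    downstream.  ``sample_project`` maps sample id -> project id.
    """

    values: pd.DataFrame
    sample_project: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate gene ids: {dupes}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate sample ids: {dupes}")
        if self.sample_project is not None:
            missing = [s for s in self.samples if s not in self.sample_project.index]
            if missing:
                raise SchemaError(f"samples missing project metadata: {missing}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def zero_variance_genes(self) -> list[str]:
        """Genes with constant expression, to be excluded from correlation."""
        v = self.values.to_numpy()
        return [g for g, s in zip(self.genes, v.std(axis=1)) if s == 0.0]

    def drop_zero_variance(self) -> "ExpressionMatrix":
        flagged = self.zero_variance_genes()
        if flagged:
            logger.info("excluding %d zero-variance genes", len(flagged))
        return ExpressionMatrix(self.values.drop(index=flagged), self.sample_project)

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        proj = self.sample_project.loc[ids] if self.sample_project is not None else None
        return ExpressionMatrix(self.values.loc[:, ids], proj)


@dataclass
class AnnotationSet:
    """Gene -> set-of-terms map, stored as term id -> set of gene ids."""

    terms: dict[str, set[str]]

    def __post_init__(self) -> None:
        empty = [t for t, g in self.terms.items() if not g]
        if empty:
            raise SchemaError(f"empty annotation terms: {empty}")

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for members in self.terms.values():
            out |= members
        return out

    def terms_of_gene(self) -> dict[str, set[str]]:
        inv: dict[str, set[str]] = {}
        for term, members in self.terms.items():
            for g in members:
                inv.setdefault(g, set()).add(term)
        return inv


@dataclass
class GuideGeneSet:
    """Pathway guide genes partitioned into sub-process groups.

    Emulates pathway-database queries: ``group_of_gene`` assigns every guide to
    exactly one sub-process (e.g. biosynthesis steps of one pathway).
    """

    pathway_name: str
    genes: set[str]
    group_of_gene: dict[str, str | int]

    def __post_init__(self) -> None:
        if not self.genes:
            raise SchemaError("guide gene set is empty")
        if set(self.group_of_gene) != self.genes:
            raise SchemaError("every guide gene must belong to exactly one group")


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression(path: str | Path, metadata_path: str | Path | None = None) -> ExpressionMatrix:
    """Load a gene x sample TSV (first column gene id, header = sample ids).

    Rows with any missing value are dropped and logged; duplicated ids or
    non-numeric cells raise :class:`SchemaError` with coordinates.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise SchemaError(f"{path}: duplicated gene rows: {dupes}")
    if raw.columns.has_duplicates:
        dupes = raw.columns[raw.columns.duplicated()].unique().tolist()
        raise SchemaError(f"{path}: duplicated sample columns: {dupes}")
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & raw.notna()
    if bad.to_numpy().any():
        g, s = next(zip(*np.nonzero(bad.to_numpy())))
        raise SchemaError(
            f"{path}: non-numeric cell at gene {raw.index[g]!r}, sample {raw.columns[s]!r}: "
            f"{raw.iloc[g, s]!r}"
        )
    keep = ~values.isna().any(axis=1)
    if not keep.all():
        logger.warning("%s: dropping %d rows with missing values",
                       path, int((~keep).sum()))
    # re-parse from the raw strings: astype(float) is correctly rounded,
    # making write->read round trips bit-exact
    values = raw.loc[keep].astype(float)
    meta = read_sample_metadata(metadata_path) if metadata_path is not None else None
    return ExpressionMatrix(values, meta)


def write_expression(matrix: ExpressionMatrix, path: str | Path,
                     metadata_path: str | Path | None = None) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene")
    if metadata_path is not None and matrix.sample_project is not None:
        write_sample_metadata(matrix.sample_project, metadata_path)


def read_sample_metadata(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 2:
        raise SchemaError(f"{path}: sample metadata must have 2 columns (sample, project)")
    df.columns = ["sample", "project"]
    if df["sample"].duplicated().any():
        raise SchemaError(f"{path}: duplicated sample in metadata")
    return df.set_index("sample")["project"]


def write_sample_metadata(sample_project: pd.Series, path: str | Path) -> None:
    df = sample_project.rename("project").rename_axis("sample").reset_index()
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# edge lists
# ---------------------------------------------------------------------------

def canonicalize_edges(edges: pd.DataFrame) -> pd.DataFrame:
    """Enforce gene_a < gene_b lexicographically and the canonical sort order.

    Sort order is (hrr ascending, gene_a, gene_b) so files are comparable and
    thresholding on a written file is prefix truncation.
    """
    if not {"gene_a", "gene_b", "hrr"}.issubset(edges.columns):
        raise SchemaError("edge table needs columns gene_a, gene_b, hrr")
    out = edges.copy()
    if "cooc" not in out.columns:
        out["cooc"] = 1
    a = out["gene_a"].astype(str)
    b = out["gene_b"].astype(str)
    if (a == b).any():
        raise SchemaError("self-edge (gene_a == gene_b) is not allowed")
    swap = a > b
    out.loc[swap, ["gene_a", "gene_b"]] = out.loc[swap, ["gene_b", "gene_a"]].to_numpy()
    out["hrr"] = out["hrr"].astype(int)
    out["cooc"] = out["cooc"].astype(int)
    if (out["hrr"] < 1).any() or (out["cooc"] < 1).any():
        raise SchemaError("hrr and cooc must be positive integers")
    out = out[EDGE_COLUMNS].sort_values(["hrr", "gene_a", "gene_b"], kind="mergesort")
    return out.reset_index(drop=True)


def write_edges(network_or_edges, path: str | Path) -> None:
    """Write a network/aggregate edge table as canonical TSV."""
    edges = getattr(network_or_edges, "edges", network_or_edges)
    canonicalize_edges(edges).to_csv(path, sep="\t", index=False)


def read_edges(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    except Exception as exc:  # noqa: BLE001 - surface pandas' message with path
        raise SchemaError(f"{path}: cannot parse edge file: {exc}") from exc
    if list(df.columns) != EDGE_COLUMNS:
        raise SchemaError(f"{path}: expected columns {EDGE_COLUMNS}, got {list(df.columns)}")
    for col in ("hrr", "cooc"):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            # +2: header line plus 1-based numbering
            raise SchemaError(f"{path}: malformed {col} at line {int(bad.idxmax()) + 2}")
    dup = canonicalize_edges(df).duplicated(["gene_a", "gene_b"])
    if dup.any():
        raise SchemaError(f"{path}: duplicated gene pair in edge file")
    return canonicalize_edges(df)


# ---------------------------------------------------------------------------
# annotations and guide genes
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path) -> AnnotationSet:
    """Read a 2-column (gene, term) TSV into an :class:`AnnotationSet`."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 2:
        raise SchemaError(f"{path}: annotation TSV must have 2 columns (gene, term)")
    df.columns = ["gene", "term"]
    terms: dict[str, set[str]] = {}
    for term, sub in df.groupby("term"):
        terms[str(term)] = set(sub["gene"])
    return AnnotationSet(terms)


def write_annotation(annotation: AnnotationSet, path: str | Path) -> None:
    rows = [(g, t) for t in sorted(annotation.terms) for g in sorted(annotation.terms[t])]
    pd.DataFrame(rows, columns=["gene", "term"]).to_csv(path, sep="\t", index=False)


def read_gaf(path: str | Path) -> AnnotationSet:
    """Import GAF 2.x annotations; only the object id (col 2) and term (col 5) are used."""
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("!"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise SchemaError(f"{path}: line {lineno}: fewer than 5 GAF columns")
            gene, term = fields[1], fields[4]
            terms.setdefault(term, set()).add(gene)
    return AnnotationSet(terms)


def write_gaf(annotation: AnnotationSet, path: str | Path, db: str = "coexpnet") -> None:
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for term in sorted(annotation.terms):
            for gene in sorted(annotation.terms[term]):
                fields = [db, gene, gene, "", term, "synthetic", "IEA", "", "P",
                          "", "", "gene", "taxon:0000", "20240101", db, "", ""]
                fh.write("\t".join(fields) + "\n")


def read_guide_genes(path: str | Path) -> GuideGeneSet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 3:
        raise SchemaError(f"{path}: guide gene TSV must have 3 columns (gene, pathway, group)")
    df.columns = ["gene", "pathway", "group"]
    pathways = df["pathway"].unique()
    if len(pathways) != 1:
        raise SchemaError(f"{path}: expected a single pathway, got {list(pathways)}")
    if df["gene"].duplicated().any():
        raise SchemaError(f"{path}: a guide gene appears in two groups")
    return GuideGeneSet(
        pathway_name=str(pathways[0]),
        genes=set(df["gene"]),
        group_of_gene=dict(zip(df["gene"], df["group"])),
    )


def write_guide_genes(guides: GuideGeneSet, path: str | Path) -> None:
    rows = [(g, guides.pathway_name, guides.group_of_gene[g]) for g in sorted(guides.genes)]
    pd.DataFrame(rows, columns=["gene", "pathway", "group"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GraphML export
# ---------------------------------------------------------------------------

def to_graph(network_or_edges) -> nx.Graph:
    """Build an undirected networkx graph carrying hrr/cooc edge attributes."""
    if isinstance(network_or_edges, nx.Graph):
        return network_or_edges
    edges = getattr(network_or_edges, "edges", network_or_edges)
    g = nx.Graph()
    for row in canonicalize_edges(edges).itertuples(index=False):
        g.add_edge(row.gene_a, row.gene_b, hrr=int(row.hrr), cooc=int(row.cooc))
    return g


def export_graphml(network_or_plc, path: str | Path,
                   node_class: Mapping[str, str] | None = None,
                   community: Mapping[str, int] | None = None) -> None:
    """Write GraphML with node attributes (class GG/AG/OG, community) and edge hrr/cooc.

    Nodes without a class label are exported with class "NA" so downstream
    viewers always find the attribute.
    """
    node_class = node_class or getattr(network_or_plc, "node_class", None) or {}
    community = community or getattr(network_or_plc, "community_of_node", None) or {}
    g = to_graph(network_or_plc)
    for node in g.nodes:
        g.nodes[node]["node_class"] = str(node_class.get(node, "NA"))
        g.nodes[node]["community"] = int(community.get(node, -1))
    nx.write_graphml(g, path)
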