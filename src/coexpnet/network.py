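"""Global co-expression network construction.

Pipeline: Pearson correlation between all gene pairs, per-gene descending-PCC
ranks (rank 0 = the gene itself, ties collapsed to the minimal rank of the tie
set), the highest reciprocal rank HRR(A, B) = max(rank_A(B), rank_B(A)), and
finally a fixed-edge-count network keeping the pairs with the lowest HRR.
Low HRR means both genes rank each other highly, which is robust to the very
different rank-list shapes hub genes and peripheral genes have.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from .io import ExpressionMatrix, canonicalize_edges

#: reference edge count used on full-size compendia
DEFAULT_N_EDGES = 1_000_000
#: proportional default for small gene universes: 2% of all pairs
DEFAULT_EDGE_FRACTION = 0.02


@dataclass
class Network:
    """Fixed-size HRR network: the ``n_target`` gene pairs with lowest HRR."""

    edges: pd.DataFrame  # canonical columns gene_a, gene_b, hrr, cooc
    n_target: int
    source: str = "full"

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def nodes(self) -> set[str]:
        return set(self.edges["gene_a"]) | set(self.edges["gene_b"])

    def edge_set(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["gene_a"], self.edges["gene_b"]))


def default_n_edges(n_genes: int) -> int:
    """2% of all unordered pairs, at least 1 — the small-universe analogue of
    the 1M-edge reference size (which is <= 2% of pairs on genome-scale data)."""
    return max(1, int(DEFAULT_EDGE_FRACTION * n_genes * (n_genes - 1) / 2))


def pcc_matrix(matrix: ExpressionMatrix, block_size: int | None = None) -> pd.DataFrame:
    """All-pairs Pearson correlation; symmetric, unit diagonal.

    Zero-variance genes must have been excluded beforehand.  ``block_size``
    computes the matrix in gene blocks with identical results, keeping peak
    memory bounded for large universes.
    """
    if matrix.n_samples < 3:
        raise ValueError("correlation requires at least 3 samples")
    if matrix.zero_variance_genes():
        raise ValueError(
            f"zero-variance genes must be excluded first: {matrix.zero_variance_genes()}")
    x = matrix.values.to_numpy(dtype=float)
    z = x - x.mean(axis=1, keepdims=True)
    z /= np.linalg.norm(z, axis=1, keepdims=True)
    if block_size is None:
        c = z @ z.T
    else:
        n = z.shape[0]
        c = np.empty((n, n))
        for start in range(0, n, block_size):
            c[start:start + block_size] = z[start:start + block_size] @ z.T
    np.clip(c, -1.0, 1.0, out=c)
    np.fill_diagonal(c, 1.0)
    return pd.DataFrame(c, index=matrix.genes, columns=matrix.genes)


def rank_matrix(pcc: pd.DataFrame) -> np.ndarray:
    """Per-gene descending-PCC ranks, integers in [0, N-1].

    Row g holds rank(g -> h) for every h; the gene itself sits strictly at
    rank 0 (even when a duplicated gene also correlates at 1, keeping HRR in
    [1, N-1]) and PCC ties share the minimal rank of their tie set, so values
    may repeat and some be skipped.
    """
    c = pcc.to_numpy(copy=True)
    np.fill_diagonal(c, np.inf)
    return rankdata(-c, axis=1, method="min").astype(np.int64) - 1


def hrr_from_pcc(pcc: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    """Directed rank matrix and the symmetric HRR value of every gene pair.

    HRR(A, B) = max(rank_A(B), rank_B(A)); integer in [1, N-1] off-diagonal.
    Returns (rank matrix, canonical pair table with columns gene_a/gene_b/hrr).
    """
    ranks = rank_matrix(pcc)
    hrr = np.maximum(ranks, ranks.T)
    genes = np.asarray(pcc.index, dtype=object)
    iu, ju = np.triu_indices(len(genes), k=1)
    pairs = pd.DataFrame({
        "gene_a": genes[iu],
        "gene_b": genes[ju],
        "hrr": hrr[iu, ju],
    })
    return ranks, canonicalize_edges(pairs)


def threshold_network(hrr_pairs: pd.DataFrame, n_edges: int,
                      source: str = "full") -> Network:
    """Keep exactly the ``n_edges`` best pairs, HRR ties broken lexicographically."""
    if n_edges > len(hrr_pairs):
        raise ValueError(f"n_edges={n_edges} exceeds pair count {len(hrr_pairs)}")
    if n_edges < 1:
        raise ValueError("n_edges must be >= 1")
    edges = canonicalize_edges(hrr_pairs).head(n_edges).reset_index(drop=True)
    return Network(edges=edges, n_target=n_edges, source=source)


def build_network(matrix: ExpressionMatrix, n_edges: int | None = None,
                  source: str = "full", block_size: int | None = None) -> Network:
    """Full construction: drop constant genes, PCC, HRR, fixed-size threshold."""
    usable = matrix.drop_zero_variance()
    pcc = pcc_matrix(usable, block_size=block_size)
    _, pairs = hrr_from_pcc(pcc)
    if n_edges is None:
        n_edges = default_n_edges(usable.n_genes)
    return threshold_network(pairs, n_edges, source=source)


def sample_relatedness(matrix: ExpressionMatrix) -> float:
    """Mean pairwise Spearman correlation between sample expression profiles."""
    if matrix.n_samples < 2:
        raise ValueError("relatedness needs at least 2 samples")
    rho = spearmanr(matrix.values.to_numpy(), axis=0).statistic
    if matrix.n_samples == 2:
        return float(rho)
    iu = np.triu_indices(matrix.n_samples, k=1)
    return float(np.asarray(rho)[iu].mean())
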