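"""Compendium down-sampling: random, project-based and k-means-based subsets.

A subset is an ordered list of sample ids drawn from one compendium; no sample
appears twice within a subset.  Random subsets partition the shuffled sample
list into disjoint fixed-size chunks; the with-replacement variant re-draws
whole subsets until at least 90% of all samples are covered at least once.
Project subsets group samples by study of origin; k-means subsets cluster
samples in scaled gene-expression space, with k chosen by the elbow of the
total within-cluster sum of squares (TWSS) curve.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .io import ExpressionMatrix

logger = logging.getLogger("coexpnet")

#: clusters (and projects) must hold strictly more samples than this to be usable
MIN_SUBSET_SIZE = 10
#: k grid used on full-size compendia
DEFAULT_K_GRID = (25, 50, 100, 150, 200, 250)
#: proportionally scaled-down grid for compendia with fewer than 250 samples
SMALL_K_GRID = (2, 4, 8, 16)
#: with-replacement sampling stops once this fraction of samples is covered
COVERAGE_TARGET = 0.9


@dataclass
class SubsetSpec:
    """One down-sampled set of samples plus the parameters that produced it."""

    method: str  # random | random_replacement | project | kmeans
    sample_ids: list[str]
    replicate_id: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("a sample cannot appear twice in one subset")

    @property
    def size(self) -> int:
        return len(self.sample_ids)

    def apply(self, matrix: ExpressionMatrix) -> ExpressionMatrix:
        return matrix.subset_samples(self.sample_ids)


@dataclass
class ElbowCurve:
    """TWSS per tested k and the k chosen by the elbow rule."""

    k_values: list[int]
    twss: list[float]
    chosen_k: int

    def __post_init__(self) -> None:
        if self.chosen_k not in self.k_values:
            raise ValueError("chosen_k must be one of the tested k values")


def random_subsets(matrix: ExpressionMatrix, size: int, seed: int = 0) -> list[SubsetSpec]:
    """Disjoint chunks of exactly ``size`` samples after one shuffle.

    A trailing chunk smaller than ``size`` is discarded so every subset is
    exactly comparable; the union covers floor(n/size)*size samples.
    """
    n = matrix.n_samples
    if not 3 <= size <= n:
        raise ValueError(f"size must be in [3, {n}], got {size}")
    rng = np.random.default_rng(seed)
    shuffled = [matrix.samples[i] for i in rng.permutation(n)]
    subsets = []
    for rep, start in enumerate(range(0, n - size + 1, size)):
        subsets.append(SubsetSpec("random", shuffled[start:start + size], rep,
                                  {"size": size, "seed": seed}))
    return subsets


def random_subsets_with_replacement(matrix: ExpressionMatrix, size: int,
                                    seed: int = 0) -> list[SubsetSpec]:
    """Repeated uniform draws of ``size`` distinct samples until >= 90% of all
    samples have appeared in at least one subset.  Samples are shared across
    subsets but never duplicated within one."""
    n = matrix.n_samples
    if not 3 <= size <= n:
        raise ValueError(f"size must be in [3, {n}], got {size}")
    rng = np.random.default_rng(seed)
    samples = np.asarray(matrix.samples, dtype=object)
    covered: set[str] = set()
    subsets: list[SubsetSpec] = []
    while len(covered) < COVERAGE_TARGET * n:
        draw = [str(s) for s in rng.choice(samples, size=size, replace=False)]
        covered.update(draw)
        subsets.append(SubsetSpec("random_replacement", draw, len(subsets),
                                  {"size": size, "seed": seed}))
    return subsets


def project_subsets(matrix: ExpressionMatrix,
                    min_size: int = MIN_SUBSET_SIZE) -> list[SubsetSpec]:
    """One subset per project label; projects with <= ``min_size`` samples dropped."""
    if matrix.sample_project is None:
        raise ValueError("project down-sampling needs sample->project metadata")
    subsets = []
    for rep, project in enumerate(sorted(matrix.sample_project.unique())):
        ids = [s for s in matrix.samples if matrix.sample_project[s] == project]
        if len(ids) <= min_size:
            continue
        subsets.append(SubsetSpec("project", ids, rep, {"project": project}))
    if not subsets:
        logger.warning("no project holds more than %d samples; no subsets emitted",
                       min_size)
    return subsets


def _scaled_sample_features(matrix: ExpressionMatrix) -> np.ndarray:
    """Samples as observations, genes as features, each feature centered/scaled."""
    x = matrix.values.to_numpy(dtype=float).T  # samples x genes
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0  # constant features carry no distance information
    return (x - mu) / sd


def choose_elbow_k(k_values: list[int], twss: list[float], tss: float) -> int:
    """Elbow of the TWSS curve: the tested k furthest below the chord drawn
    from the virtual k=1 point (TWSS = total sum of squares, no clustering)
    to the largest tested k, in normalized coordinates.

    Anchoring at k=1 makes an elbow sitting at the smallest tested k
    detectable (endpoints of a chord otherwise always have distance zero) and
    needs no extra k-means run since TSS is a closed-form quantity.
    """
    ks = np.array([1] + list(k_values), dtype=float)
    ys = np.array([tss] + list(twss), dtype=float)
    span_k = ks[-1] - ks[0]
    span_y = ys[0] - ys[-1]
    if span_y <= 0:  # flat curve: keep k low
        return int(k_values[0])
    kn = (ks - ks[0]) / span_k
    yn = (ys - ys[-1]) / span_y
    # signed distance below the descending unit chord y = 1 - x
    dist = (1.0 - kn) - yn
    best = int(np.argmax(dist[1:]))  # never the virtual anchor
    return int(k_values[best])


def kmeans_subsets(matrix: ExpressionMatrix, k_grid: list[int] | None = None,
                   pre_fraction: float = 1.0, seed: int = 0,
                   k: int | None = None,
                   min_size: int = MIN_SUBSET_SIZE) -> tuple[list[SubsetSpec], ElbowCurve]:
    """Cluster samples with k-means and emit clusters of > ``min_size`` samples.

    ``pre_fraction`` < 1 first drops samples at random (without replacement)
    to that fraction of the compendium.  Each k in the grid is fitted with 10
    greedy-seeded restarts (300-iteration cap); ``k`` overrides the elbow
    choice.  Grid values >= the sample count are skipped with a warning.
    """
    if not 0 < pre_fraction <= 1:
        raise ValueError("pre_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    work = matrix
    if pre_fraction < 1:
        n_keep = int(round(pre_fraction * matrix.n_samples))
        keep = sorted(rng.choice(matrix.n_samples, size=n_keep, replace=False))
        work = matrix.subset_samples([matrix.samples[i] for i in keep])
    if k_grid is None:
        k_grid = list(DEFAULT_K_GRID if work.n_samples >= 250 else SMALL_K_GRID)
    usable = [kk for kk in k_grid if kk < work.n_samples]
    skipped = sorted(set(k_grid) - set(usable))
    if skipped:
        logger.warning("skipping k values >= sample count (%d): %s",
                       work.n_samples, skipped)
    if not usable:
        raise ValueError("all k values exceed the (pre-down-sampled) sample count")

    x = _scaled_sample_features(work)
    tss = float(((x - x.mean(axis=0)) ** 2).sum())
    twss, labels_of_k = [], {}
    for kk in usable:
        km = KMeans(n_clusters=kk, n_init=10, max_iter=300,
                    random_state=int(rng.integers(2**31)))
        labels_of_k[kk] = km.fit_predict(x)
        twss.append(float(km.inertia_))
    chosen = k if k is not None else choose_elbow_k(usable, twss, tss)
    if chosen not in labels_of_k:
        raise ValueError(f"k override {chosen} is not in the usable grid {usable}")
    curve = ElbowCurve(usable, twss, chosen)

    labels = labels_of_k[chosen]
    subsets = []
    for rep, cluster in enumerate(sorted(set(labels))):
        ids = [s for s, lab in zip(work.samples, labels) if lab == cluster]
        if len(ids) <= min_size:
            continue
        subsets.append(SubsetSpec("kmeans", ids, rep,
                                  {"k": chosen, "pre_fraction": pre_fraction,
                                   "seed": seed, "cluster": int(cluster)}))
    return subsets, curve
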