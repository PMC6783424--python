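"""Synthetic expression compendia with planted co-expression modules.

The generator emulates the statistical structure a correlation-network
pipeline consumes: groups of co-expressed genes driven by shared latent
activities, samples organized in projects whose members share activity
shifts (so within-project correlation exceeds between-project correlation),
annotation terms aligned to the planted modules with controllable noise, and
guide-gene sets partitioned into sub-process groups.

Model: for module m and sample s a latent activity a(m, s) ~ N(0, factor_sd^2)
is drawn; samples of the same project additionally share a per-(project,
module) shift ~ N(0, project_effect_sd^2).  A gene of module m measures
a(m, s) + shift + N(0, noise_sd^2); background genes are pure noise.  Under
this model the expected within-module Pearson correlation is
(factor_sd^2 + project_effect_sd^2) / (factor_sd^2 + project_effect_sd^2 + noise_sd^2),
and cross-module correlation vanishes, so the planted edge structure is
controlled by two variance knobs.

All randomness flows from a single seed through one named child generator per
sub-draw (factors, project effects, noise, sample order, ...), so changing the
module count does not perturb the noise stream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AnnotationSet, ExpressionMatrix, GuideGeneSet

_STREAMS = ("factors", "project_effects", "noise", "sample_order", "lognormal")


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named child generator: independent per stream, deterministic in seed."""
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(len(_STREAMS))[
        _STREAMS.index(stream)])


@dataclass
class CompendiumSpec:
    """Parameters of one synthetic compendium.

    ``module_sizes`` must sum to at most ``n_genes``; the remainder are
    background genes carrying pure noise.  Standard deviations are in the
    (arbitrary) expression units of the latent factors.
    """

    n_genes: int
    n_samples: int
    n_modules: int
    module_sizes: list[int]
    n_projects: int
    factor_sd: float = 1.0
    noise_sd: float = 1.0
    project_effect_sd: float = 0.0
    seed: int = 0
    lognormal: bool = False

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_samples", "n_modules", "n_projects"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if len(self.module_sizes) != self.n_modules:
            raise ValueError("module_sizes must list one size per module")
        if any(s < 1 for s in self.module_sizes):
            raise ValueError("module sizes must be >= 1")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError(
                f"module_sizes sum to {sum(self.module_sizes)} > n_genes={self.n_genes}")
        for name in ("factor_sd", "noise_sd", "project_effect_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def default(cls, seed: int = 0) -> "CompendiumSpec":
        """Default study conditions: 500 genes, 300 samples, 10 modules of 30,
        10 projects, within-module PCC ~= 0.17 (weak-correlation regime)."""
        return cls(n_genes=500, n_samples=300, n_modules=10,
                   module_sizes=[30] * 10, n_projects=10,
                   factor_sd=1.0, noise_sd=2.5, project_effect_sd=0.5, seed=seed)


@dataclass
class GroundTruth:
    """Planted structure: gene -> module id (None = background), sample -> project."""

    module_of_gene: dict[str, int | None]
    project_of_sample: dict[str, int]

    def genes_of_module(self, module: int) -> list[str]:
        return [g for g, m in self.module_of_gene.items() if m == module]

    @property
    def background_genes(self) -> list[str]:
        return [g for g, m in self.module_of_gene.items() if m is None]

    def within_module_pairs(self) -> set[tuple[str, str]]:
        """All unordered same-module gene pairs, canonically ordered."""
        pairs: set[tuple[str, str]] = set()
        modules = sorted({m for m in self.module_of_gene.values() if m is not None})
        for m in modules:
            members = sorted(self.genes_of_module(m))
            for i, a in enumerate(members):
                for b in members[i + 1:]:
                    pairs.add((a, b))
        return pairs


def simulate_compendium(spec: CompendiumSpec) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw one compendium under ``spec``; deterministic given ``spec.seed``.

    Sample columns come out in a randomized order (recorded in the ground
    truth's project map); projects are contiguous equal-sized blocks of the
    pre-shuffle sample sequence, remainder appended to the last project.
    """
    width = max(4, len(str(spec.n_genes)))
    genes = [f"g{i:0{width}d}" for i in range(spec.n_genes)]
    samples = [f"s{i:04d}" for i in range(spec.n_samples)]

    module_of_gene: dict[str, int | None] = {}
    cursor = 0
    for m, size in enumerate(spec.module_sizes):
        for g in genes[cursor:cursor + size]:
            module_of_gene[g] = m
        cursor += size
    for g in genes[cursor:]:
        module_of_gene[g] = None

    block = spec.n_samples // spec.n_projects
    project_of_sample = {}
    for i, s in enumerate(samples):
        project_of_sample[s] = min(i // max(block, 1), spec.n_projects - 1)

    activities = _rng(spec.seed, "factors").normal(
        0.0, spec.factor_sd, size=(spec.n_modules, spec.n_samples))
    shifts = _rng(spec.seed, "project_effects").normal(
        0.0, spec.project_effect_sd, size=(spec.n_projects, spec.n_modules))
    noise = _rng(spec.seed, "noise").normal(
        0.0, spec.noise_sd, size=(spec.n_genes, spec.n_samples))

    proj_idx = np.array([project_of_sample[s] for s in samples])
    x = noise
    for g_idx, g in enumerate(genes):
        m = module_of_gene[g]
        if m is not None:
            x[g_idx] += activities[m] + shifts[proj_idx, m]
    if spec.lognormal:
        x = np.exp(x)  # RNA-seq-like right skew; correlations change accordingly

    order = _rng(spec.seed, "sample_order").permutation(spec.n_samples)
    values = pd.DataFrame(x[:, order], index=genes,
                          columns=[samples[i] for i in order])
    meta = pd.Series({s: f"P{project_of_sample[s]:02d}" for s in values.columns},
                     name="project")
    truth = GroundTruth(module_of_gene,
                        {s: f"P{project_of_sample[s]:02d}" for s in samples})
    return ExpressionMatrix(values, meta.loc[values.columns]), truth


def simulate_annotation(truth: GroundTruth, terms_per_module: int = 1,
                        coverage: float = 1.0, label_noise: float = 0.0,
                        seed: int = 0) -> AnnotationSet:
    """Annotation terms aligned to planted modules, with controllable noise.

    Each module spawns ``terms_per_module`` terms; a term holds a random
    ``coverage`` fraction of the module's genes (rounded up, never empty),
    after which a ``label_noise`` fraction of its members is swapped with
    random background genes.  ``label_noise=1`` therefore destroys the
    module/term alignment down to chance overlap.
    """
    if not (0 <= coverage <= 1 and 0 <= label_noise <= 1):
        raise ValueError("coverage and label_noise must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 1)))
    background = sorted(truth.background_genes)
    modules = sorted({m for m in truth.module_of_gene.values() if m is not None})
    terms: dict[str, set[str]] = {}
    for m in modules:
        members = sorted(truth.genes_of_module(m))
        for t in range(terms_per_module):
            n_take = max(1, math.ceil(coverage * len(members)))
            chosen = set(rng.choice(members, size=n_take, replace=False))
            n_swap = int(round(label_noise * len(chosen)))
            pool = [g for g in background if g not in chosen]
            n_swap = min(n_swap, len(pool))
            if n_swap:
                out = rng.choice(sorted(chosen), size=n_swap, replace=False)
                new = rng.choice(pool, size=n_swap, replace=False)
                chosen = (chosen - set(out)) | set(new)
            terms[f"M{m:02d}_T{t}"] = chosen
    return AnnotationSet(terms)


def simulate_guide_genes(truth: GroundTruth, modules: list[int], per_module: int,
                         seed: int = 0, pathway_name: str = "synthetic_pathway") -> GuideGeneSet:
    """Guide genes drawn from the listed modules; group id = source module,
    emulating the sub-processes of a pathway-database query."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 2)))
    genes: set[str] = set()
    group: dict[str, str | int] = {}
    known = {m for m in truth.module_of_gene.values() if m is not None}
    for m in modules:
        if m not in known:
            raise ValueError(f"module {m} does not exist")
        members = sorted(truth.genes_of_module(m))
        if per_module > len(members):
            raise ValueError(
                f"per_module={per_module} exceeds size {len(members)} of module {m}")
        picked = rng.choice(members, size=per_module, replace=False)
        for g in picked:
            genes.add(str(g))
            group[str(g)] = m
    return GuideGeneSet(pathway_name=pathway_name, genes=genes, group_of_gene=group)
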