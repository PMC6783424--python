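"""Config-driven orchestration of the two synthetic-compendium experiments.

Experiment 1 (down-sampling sweep): simulate a compendium, derive subsets by
each configured strategy, build one fixed-size HRR network per subset, and
score every network (GO AUROC, sample relatedness, topology).

Experiment 2 (aggregation comparison): build many networks from random
subsets, score them, combine them under the six aggregation modes, apply the
strict size window, and score the surviving aggregates at both the whole-
network and the PLC level.

Both emit one tidy results table (one row per network/aggregate) and are
bit-reproducible under a fixed config.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import aggregate as agg_mod
from . import downsample as ds_mod
from .evaluate import neighbor_voting_auroc, topology_metrics
from .io import ExpressionMatrix
from .network import build_network, sample_relatedness
from .plc import extract_plc, normalized_chi_squared
from .synthetic import (CompendiumSpec, simulate_annotation, simulate_compendium,
                        simulate_guide_genes)

logger = logging.getLogger("coexpnet")


@dataclass
class ExperimentConfig:
    """Flat, YAML-round-trippable description of one experiment run."""

    # compendium
    n_genes: int = 500
    n_samples: int = 300
    n_modules: int = 10
    module_size: int = 30
    n_projects: int = 10
    factor_sd: float = 1.0
    noise_sd: float = 2.5
    project_effect_sd: float = 0.5
    # annotation
    terms_per_module: int = 1
    coverage: float = 0.9
    label_noise: float = 0.1
    # guide genes (PLC scoring in the aggregation experiment)
    guide_modules: tuple[int, ...] = (0, 1, 2)
    guides_per_module: int = 8
    # down-sampling plan
    methods: tuple[str, ...] = ("random", "project", "kmeans")
    subset_sizes: tuple[int, ...] = (15, 30, 60, 120)
    # networks
    network_sizes: tuple[int, ...] = (5000,)
    # aggregation
    modes: tuple[str, ...] = ("Call", "CHGA", "CLGA", "Hall", "HHGA", "HLGA")
    n_members: int = 10
    member_subset_size: int = 25
    apply_size_filter: bool = True
    # evaluation
    n_folds: int = 3
    min_term_size: int = 10
    max_term_size: int = 1000
    # reproducibility
    seed: int = 0
    out_dir: str | None = None

    def compendium_spec(self) -> CompendiumSpec:
        return CompendiumSpec(
            n_genes=self.n_genes, n_samples=self.n_samples,
            n_modules=self.n_modules, module_sizes=[self.module_size] * self.n_modules,
            n_projects=self.n_projects, factor_sd=self.factor_sd,
            noise_sd=self.noise_sd, project_effect_sd=self.project_effect_sd,
            seed=self.seed)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data = {k: (list(v) if isinstance(v, tuple) else v) for k, v in data.items()}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(data) - set(fields)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, value in data.items():
            if isinstance(value, list):
                data[key] = tuple(value)
        return cls(**data)


def _derived_seed(seed: int, *tags: int) -> int:
    return int(np.random.SeedSequence((seed, *tags)).generate_state(1)[0] % (2**31))


def _simulate_inputs(config: ExperimentConfig):
    matrix, truth = simulate_compendium(config.compendium_spec())
    annotation = simulate_annotation(
        truth, terms_per_module=config.terms_per_module, coverage=config.coverage,
        label_noise=config.label_noise, seed=_derived_seed(config.seed, 1))
    return matrix, truth, annotation


def _subsets_for_method(config: ExperimentConfig, matrix: ExpressionMatrix,
                        method: str) -> list[tuple[str, ds_mod.SubsetSpec]]:
    out = []
    if method == "random":
        for size in config.subset_sizes:
            if size > matrix.n_samples:
                continue
            for sub in ds_mod.random_subsets(matrix, size,
                                             seed=_derived_seed(config.seed, 2, size)):
                out.append((f"random_s{size}_r{sub.replicate_id}", sub))
    elif method == "random_replacement":
        for size in config.subset_sizes:
            if size > matrix.n_samples:
                continue
            for sub in ds_mod.random_subsets_with_replacement(
                    matrix, size, seed=_derived_seed(config.seed, 3, size)):
                out.append((f"randrep_s{size}_r{sub.replicate_id}", sub))
    elif method == "project":
        for sub in ds_mod.project_subsets(matrix):
            out.append((f"project_{sub.params['project']}", sub))
    elif method == "kmeans":
        subs, _curve = ds_mod.kmeans_subsets(matrix,
                                             seed=_derived_seed(config.seed, 4))
        for sub in subs:
            out.append((f"kmeans_k{sub.params['k']}_c{sub.params['cluster']}", sub))
    else:
        raise ValueError(f"unknown down-sampling method {method!r}")
    return out


def _evaluate_network(net, annotation, config: ExperimentConfig) -> dict:
    result = neighbor_voting_auroc(net, annotation, n_folds=config.n_folds,
                                   seed=_derived_seed(config.seed, 5),
                                   min_term_size=config.min_term_size,
                                   max_term_size=config.max_term_size)
    topo = topology_metrics(net)
    return {
        "go_auroc": result.go_auroc,
        "n_terms": len(result.terms_evaluated),
        "n_nodes": topo.n_nodes,
        "n_edges": topo.n_edges,
        "avg_degree": topo.avg_degree,
        "modularity": topo.modularity,
        "transitivity": topo.transitivity,
        "powerlaw_loglik": topo.powerlaw_loglik,
    }


def run_downsampling_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Down-sampling sweep: one row per (subset, network size).

    A failing stage aborts only its own row; failures are logged and listed
    in the returned table's ``attrs['failures']``.
    """
    matrix, _truth, annotation = _simulate_inputs(config)
    rows, failures = [], []
    for method in config.methods:
        try:
            named_subsets = _subsets_for_method(config, matrix, method)
        except Exception as exc:  # noqa: BLE001
            logger.error("subset generation failed for %s: %s", method, exc)
            failures.append({"stage": "downsample", "id": method, "error": str(exc)})
            continue
        for subset_id, subset in named_subsets:
            sub_matrix = subset.apply(matrix)
            for n_edges in config.network_sizes:
                try:
                    net = build_network(sub_matrix, n_edges=n_edges, source=subset_id)
                    row = {
                        "id": subset_id, "method": method,
                        "n_samples": subset.size, "network_size": n_edges,
                        "sample_relatedness": sample_relatedness(sub_matrix),
                    }
                    row.update(_evaluate_network(net, annotation, config))
                    rows.append(row)
                except Exception as exc:  # noqa: BLE001
                    logger.error("row failed (%s, %d edges): %s", subset_id, n_edges, exc)
                    failures.append({"stage": "network", "id": subset_id,
                                     "error": str(exc)})
    table = pd.DataFrame(rows)
    table.attrs["failures"] = failures
    _maybe_write(config, table, "downsampling_results.tsv")
    return table


def build_member_networks(config: ExperimentConfig,
                          matrix: ExpressionMatrix) -> list:
    """The aggregation experiment's members: networks from disjoint random
    subsets of ``member_subset_size`` samples, ``n_members`` of them."""
    subs = ds_mod.random_subsets(matrix, config.member_subset_size,
                                 seed=_derived_seed(config.seed, 6))
    if len(subs) < config.n_members:
        raise ValueError(
            f"compendium yields only {len(subs)} subsets of "
            f"{config.member_subset_size}; n_members={config.n_members}")
    nets = []
    for sub in subs[:config.n_members]:
        nets.append(build_network(sub.apply(matrix),
                                  n_edges=config.network_sizes[0],
                                  source=f"member_{sub.replicate_id}"))
    return nets


def run_aggregation_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Aggregation comparison: members scored, six modes applied, aggregates
    size-filtered, then scored at network and PLC level."""
    matrix, truth, annotation = _simulate_inputs(config)
    guide_set = simulate_guide_genes(truth, list(config.guide_modules),
                                     config.guides_per_module,
                                     seed=_derived_seed(config.seed, 7))
    target = config.network_sizes[0]
    rows, failures = [], []

    members = build_member_networks(config, matrix)
    scores = []
    for net in members:
        row = {"id": net.source, "kind": "member", "mode": "none",
               "n_samples": config.member_subset_size, "network_size": target}
        try:
            row.update(_evaluate_network(net, annotation, config))
            scores.append(agg_mod.NetworkScore(net.source, row["go_auroc"]))
            rows.append(row)
        except Exception as exc:  # noqa: BLE001
            logger.error("member %s failed: %s", net.source, exc)
            failures.append({"stage": "member", "id": net.source, "error": str(exc)})

    for mode in config.modes:
        try:
            aggregate = agg_mod.aggregate_networks(members, mode, target, scores=scores)
            if config.apply_size_filter and not agg_mod.size_filter(
                    aggregate, target_edges=target):
                logger.info("aggregate %s rejected by size filter (%d edges)",
                            mode, aggregate.n_edges)
                failures.append({"stage": "size_filter", "id": mode,
                                 "error": f"{aggregate.n_edges} edges outside window"})
                continue
            row = {"id": mode, "kind": "aggregate", "mode": mode,
                   "n_samples": config.member_subset_size, "network_size": target,
                   "members": ",".join(aggregate.member_ids),
                   "threshold_used": aggregate.threshold_used}
            row.update(_evaluate_network(aggregate, annotation, config))
            plc = extract_plc(aggregate, guide_set, source=mode)
            report = normalized_chi_squared(plc)
            row["normalized_chi2"] = report.normalized_chi2
            row["n_guides_captured"] = report.n_guides_captured
            rows.append(row)
        except Exception as exc:  # noqa: BLE001
            logger.error("aggregate %s failed: %s", mode, exc)
            failures.append({"stage": "aggregate", "id": mode, "error": str(exc)})

    table = pd.DataFrame(rows)
    table.attrs["failures"] = failures
    _maybe_write(config, table, "aggregation_results.tsv")
    return table


def _maybe_write(config: ExperimentConfig, table: pd.DataFrame, name: str) -> None:
    if config.out_dir is None:
        return
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / name, sep="\t", index=False)
    if table.attrs.get("failures"):
        pd.DataFrame(table.attrs["failures"]).to_csv(
            out / f"failures_{name}", sep="\t", index=False)
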