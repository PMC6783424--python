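"""Evaluation: neighbor-voting AUROC limits and fold mechanics, hypergeometric
enrichment against direct pmf summation, and closed-form topology metrics."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from coexpnet.evaluate import (auroc_fold_homogeneity, hypergeometric_enrichment,
                               neighbor_voting_auroc, neighbor_voting_scores,
                               permute_annotation, rank_auroc, topology_metrics)
from coexpnet.io import AnnotationSet, to_graph
from coexpnet.synthetic import CompendiumSpec, simulate_annotation, simulate_compendium

from conftest import make_network


def coannotation_network(annotation: AnnotationSet):
    """Graph whose edges are exactly the co-annotated pairs."""
    pairs = set()
    for members in annotation.terms.values():
        ms = sorted(members)
        for i, a in enumerate(ms):
            for b in ms[i + 1:]:
                pairs.add((a, b))
    return make_network([(a, b, 1) for a, b in sorted(pairs)])


def modular_annotation(n_terms=3, size=15, n_background=20) -> AnnotationSet:
    genes = iter(f"g{i:04d}" for i in range(n_terms * size + n_background))
    return AnnotationSet({f"T{t}": {next(genes) for _ in range(size)}
                          for t in range(n_terms)})


class TestRankAuroc:
    def test_perfect_separation(self):
        assert rank_auroc([0.9, 0.8], [0.1, 0.2, 0.3]) == 1.0

    def test_reversed_separation(self):
        assert rank_auroc([0.1], [0.5, 0.9]) == 0.0

    def test_midranks_for_ties(self):
        # one positive tied with one of two negatives -> AUROC (1 + 0.5)/2... :
        # pairs: vs 0.1 win, vs 0.5 tie -> (1 + 0.5)/2 = 0.75
        assert rank_auroc([0.5], [0.1, 0.5]) == 0.75

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            rank_auroc([], [0.1])


class TestNeighborVoting:
    def test_perfect_coannotation_network_scores_one(self):
        ann = modular_annotation()
        net = coannotation_network(ann)
        res = neighbor_voting_auroc(net, ann, seed=0)
        assert res.go_auroc == 1.0
        assert all(v == 1.0 for v in res.per_term_auroc.values())

    def test_permuted_labels_score_half_on_average(self):
        ann = modular_annotation(n_terms=4, size=15, n_background=0)
        net = coannotation_network(ann)
        genes = sorted(ann.genes)
        aurocs = [neighbor_voting_auroc(net, permute_annotation(ann, genes, seed=s),
                                        seed=s).go_auroc
                  for s in range(20)]
        assert np.mean(aurocs) == pytest.approx(0.5, abs=0.02)

    def test_hand_computed_single_fold(self):
        # network g1-g2, g3-g4; term {g1,g2}; hide g2: score(g2)=1, others 0
        net = make_network([("g1", "g2", 1), ("g3", "g4", 1)])
        nodes, adj = sorted(net.nodes), None
        from coexpnet.evaluate import _adjacency
        nodes, adj = _adjacency(net)
        visible = np.array([1.0, 0.0, 0.0, 0.0])  # g1 visible positive
        scores = neighbor_voting_scores(adj, visible)
        by = dict(zip(nodes, scores))
        assert by["g2"] == 1.0 and by["g3"] == 0.0 and by["g4"] == 0.0
        assert rank_auroc([by["g2"]], [by["g3"], by["g4"]]) == 1.0

    def test_isolated_nodes_score_zero_not_nan(self):
        net = make_network([("g1", "g2", 1)])
        g = to_graph(net)
        g.add_node("g3")
        from coexpnet.evaluate import _adjacency
        nodes, adj = _adjacency(g)
        scores = neighbor_voting_scores(adj, np.array([1.0, 0.0, 0.0]))
        assert scores[nodes.index("g3")] == 0.0
        assert not np.isnan(scores).any()

    def test_term_size_window_filters(self):
        ann = modular_annotation(n_terms=2, size=15)
        ann.terms["tiny"] = {"g0000", "g0001"}
        net = coannotation_network(ann)
        res = neighbor_voting_auroc(net, ann, min_term_size=10)
        assert "tiny" not in res.terms_evaluated
        with pytest.raises(ValueError, match="no evaluable"):
            neighbor_voting_auroc(net, AnnotationSet({"tiny": {"g0000", "g0001"}}),
                                  min_term_size=10)

    def test_deterministic_given_seed(self):
        ann = modular_annotation()
        net = coannotation_network(ann)
        r1 = neighbor_voting_auroc(net, ann, seed=42)
        r2 = neighbor_voting_auroc(net, ann, seed=42)
        assert r1.per_term_auroc == r2.per_term_auroc

    def test_auroc_invariant_to_gene_relabeling(self):
        ann = modular_annotation(n_terms=2, size=12, n_background=5)
        net = coannotation_network(ann)
        mapping = {g: f"z{i:04d}" for i, g in enumerate(sorted(ann.genes))}
        ann2 = AnnotationSet({t: {mapping[g] for g in m} for t, m in ann.terms.items()})
        edges2 = net.edges.assign(gene_a=net.edges["gene_a"].map(mapping),
                                  gene_b=net.edges["gene_b"].map(mapping))
        from coexpnet.network import Network
        net2 = Network(edges=edges2, n_target=net.n_target)
        r1 = neighbor_voting_auroc(net, ann, seed=0)
        r2 = neighbor_voting_auroc(net2, ann2, seed=0)
        assert r1.go_auroc == pytest.approx(r2.go_auroc)


class TestFoldHomogeneity:
    def test_perfect_network_has_zero_spread(self):
        ann = modular_annotation()
        res = neighbor_voting_auroc(coannotation_network(ann), ann, seed=0)
        hom = auroc_fold_homogeneity(res)
        assert (hom["fold_sd"] == 0.0).all()

    def test_single_fold_spread_missing(self):
        ann = modular_annotation()
        res = neighbor_voting_auroc(coannotation_network(ann), ann, n_folds=1, seed=0)
        assert auroc_fold_homogeneity(res)["fold_sd"].isna().all()

    def test_spread_matches_direct_recomputation(self):
        ann = modular_annotation(n_terms=2, size=12, n_background=30)
        net = coannotation_network(ann)
        res = neighbor_voting_auroc(net, permute_annotation(ann, sorted(ann.genes),
                                                            seed=3), seed=3)
        hom = auroc_fold_homogeneity(res)
        for term in res.terms_evaluated:
            expected = np.std(res.per_term_folds[term], ddof=1)
            assert hom.loc[term, "fold_sd"] == pytest.approx(expected)


class TestEnrichment:
    def test_exact_tail_sum_small_universe(self):
        # 10-gene universe (45 pairs), term of 3 genes (3 co-annotated pairs),
        # 5 edges of which 2 co-annotated -> p = P(X >= 2), X ~ Hypergeom(45,3,5)
        term = {"g0", "g1", "g2"}
        edges = [("g0", "g1", 1), ("g0", "g2", 1), ("g3", "g4", 1),
                 ("g5", "g6", 1), ("g7", "g8", 1)]
        net = make_network(edges)
        g = to_graph(net)
        g.add_node("g9")
        ps = hypergeometric_enrichment(g, AnnotationSet({"T": term}))
        expected = sum(hypergeom.pmf(k, 45, 3, 5) for k in (2, 3))
        assert ps["T"] == pytest.approx(min(1.0, expected), abs=1e-12)

    def test_all_coannotated_edges_minimum_p(self):
        ann = AnnotationSet({"T": {"g0", "g1", "g2"}})
        net = make_network([("g0", "g1", 1), ("g0", "g2", 1), ("g1", "g2", 1)])
        g = to_graph(net)
        for i in range(3, 8):
            g.add_node(f"g{i}")
        ps = hypergeometric_enrichment(g, ann)
        # minimum achievable: all 3 draws are successes
        expected = hypergeom.pmf(3, 28, 3, 3)
        assert ps["T"] == pytest.approx(expected, rel=1e-10)

    def test_zero_observed_gives_capped_one(self):
        ann = AnnotationSet({"T": {"g0", "g1"}})
        net = make_network([("g2", "g3", 1)])
        g = to_graph(net)
        g.add_node("g0"), g.add_node("g1")
        assert hypergeometric_enrichment(g, ann)["T"] == 1.0

    def test_bonferroni_multiplies_by_term_count(self):
        ann = AnnotationSet({"T1": {"g0", "g1"}, "T2": {"g2", "g3"}})
        net = make_network([("g0", "g1", 1), ("g2", "g3", 1), ("g4", "g5", 1)])
        ps = hypergeometric_enrichment(net, ann)
        raw = hypergeom.sf(0, 15, 1, 3)
        assert ps["T1"] == pytest.approx(min(1.0, 2 * raw))

    def test_undersized_terms_skipped(self):
        ann = AnnotationSet({"T": {"g0"}})
        assert hypergeometric_enrichment(make_network([("g0", "g1", 1)]), ann) == {}


class TestTopology:
    def test_two_triangles_modularity_half(self):
        net = make_network([("a", "b", 1), ("b", "c", 1), ("a", "c", 1),
                            ("x", "y", 1), ("y", "z", 1), ("x", "z", 1)])
        rep = topology_metrics(net)
        assert rep.modularity == pytest.approx(0.5)
        assert rep.transitivity == 1.0

    def test_k4_degree_and_transitivity(self):
        pairs = [(a, b, 1) for a, b in
                 [("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"), ("b", "d"), ("c", "d")]]
        rep = topology_metrics(make_network(pairs))
        assert rep.avg_degree == 3.0
        assert rep.transitivity == 1.0

    def test_star_transitivity_zero(self):
        rep = topology_metrics(make_network([("c", f"l{i}", 1) for i in range(5)]))
        assert rep.transitivity == 0.0
        assert rep.avg_degree == pytest.approx(2 * 5 / 6)

    def test_clique_union_modularity_closed_form(self):
        # union of cliques partitioned into its cliques: Q = sum(e_ii - a_i^2)
        sizes = [3, 4, 5]
        pairs, offset = [], 0
        for s in sizes:
            names = [f"n{offset + i}" for i in range(s)]
            pairs += [(a, b, 1) for i, a in enumerate(names) for b in names[i + 1:]]
            offset += s
        rep = topology_metrics(make_network(pairs))
        m = sum(s * (s - 1) / 2 for s in sizes)
        q = sum((s * (s - 1) / 2) / m - ((s * (s - 1) / 2) / m) ** 2 for s in sizes)
        assert rep.modularity == pytest.approx(q)

    def test_fast_greedy_matches_igraph_oracle(self):
        # independent implementation of fast-greedy modularity as cross-check
        igraph = pytest.importorskip("igraph")
        net = make_network([("a", "b", 1), ("b", "c", 1), ("a", "c", 1),
                            ("c", "d", 1), ("d", "e", 1), ("e", "f", 1),
                            ("d", "f", 1)])
        rep = topology_metrics(net)
        g = igraph.Graph.TupleList(net.edge_set())
        q = g.community_fastgreedy().as_clustering().modularity
        assert rep.modularity == pytest.approx(q, abs=1e-9)

    def test_powerlaw_loglik_finite_and_alpha_reasonable(self, rng):
        # degrees drawn from a discrete power law should recover alpha near truth
        from coexpnet.evaluate import _powerlaw_fit
        alpha_true = 2.5
        ks = np.arange(1, 1000)
        p = ks ** (-alpha_true)
        p /= p.sum()
        degrees = rng.choice(ks, size=2000, p=p)
        loglik, alpha = _powerlaw_fit(degrees)
        assert np.isfinite(loglik)
        assert alpha == pytest.approx(alpha_true, abs=0.15)

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            topology_metrics(nx.Graph())
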