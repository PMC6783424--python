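# Methods notes

## Synthetic compendium model

The generator produces the minimal statistical structure the network
pipeline consumes — controllable pairwise correlations, project-structured
samples, and annotations aligned to planted modules — and nothing more.

For module *m* and sample *s* a latent activity a(m, s) ~ N(0, factor_sd²)
is drawn; samples of the same project share an additional per-(project,
module) shift ~ N(0, project_effect_sd²). A gene of module *m* measures
a(m, s) + shift + N(0, noise_sd²); background genes are pure noise. Under
this model the expected within-module correlation is

    ρ_within = (factor_sd² + project_effect_sd²) /
               (factor_sd² + project_effect_sd² + noise_sd²)

and cross-module correlation vanishes, so two variance knobs control the
planted edge structure, and the shared project shifts control inter-sample
relatedness (samples of one project correlate through all modules at once).
A `lognormal` flag exponentiates the matrix for RNA-seq-like skew.

Design choices: a Gaussian additive factor model (not a copula or
negative-binomial count model) because the pipeline only ever consumes
correlations and ranks; projects are contiguous equal-sized sample blocks
(remainder to the last project) with the column order then shuffled; all
randomness flows from one seed through a named child generator per sub-draw
(factors, project effects, noise, sample order), so changing the module
count never perturbs the noise stream and outputs are bit-reproducible.

What the generator does **not** emulate: probe-level microarray artifacts,
library-size/count noise, batch effects beyond a shared project shift,
correlated background genes, scale-free module size distributions,
annotation term hierarchies (terms are flat). Passing tests therefore
demonstrate correctness of the algorithms and the direction of
sample-size/aggregation effects under controlled conditions — not
performance levels on any real compendium.

## Default study conditions

The built-in experiments (`ExperimentConfig`) default to 500 genes, 300
samples, 10 modules of 30 genes, 10 projects, and 5,000-edge networks
(≈ 4 % of the 124,750 pairs; the generic small-universe default elsewhere is
2 % of pairs, the proportional analogue of a million-edge genome-scale
network). factor_sd = 1, project_effect_sd = 0.5 and noise_sd = 2.5 give a
within-module correlation of ≈ 0.17, placing individual 25-sample subset
networks at GO AUROC ≈ 0.7–0.8 and the full-compendium network near 0.9 —
the regime where down-sampling and aggregation effects are visible rather
than saturated at the ceiling. These sizes keep the full two-experiment
suite at a few minutes on one CPU.

## Numerical and procedural choices

- **Ranks and ties.** Per-gene ranks are assigned on descending signed
  correlation (negative correlations rank last); tied correlations share the
  minimal rank of the tie set; the gene itself is always rank 0, even when a
  duplicated gene also correlates at exactly 1, which keeps HRR in [1, N−1].
- **Exact network size.** Individual networks hit the requested edge count
  exactly, breaking HRR ties lexicographically on the gene pair; this makes
  edge sets nested across sizes. Tie-inclusive retention is reserved for
  aggregation, where the threshold rule demands it; there the final size may
  exceed (HRR modes) or undershoot (co-occurrence ≥ 2 floor) the target.
- **Blocked correlation.** `pcc_matrix(block_size=...)` computes the matrix
  in gene blocks for bounded memory; results agree with the whole-matrix
  path to float associativity (≈ 1 ulp) and yield identical networks.
- **Elbow choice for k-means.** The chosen k maximizes the distance below
  the chord of the normalized TWSS curve, after anchoring the curve at a
  virtual k = 1 point whose TWSS is the total sum of squares (closed form,
  no extra clustering run). Without the anchor an elbow at the smallest
  tested k is undetectable, since chord endpoints always have distance zero.
  An explicit `k` override bypasses the rule. k-means runs 10 greedy-seeded
  restarts, 300 iterations, seeded; the default grid {25…250} is replaced by
  {2, 4, 8, 16} below 250 samples.
- **Neighbor voting.** Binary adjacency (a weighted 1/HRR variant exists but
  is off by default, since HRR weights are inverse significance ranks, not
  affinities); positives are dealt round-robin into folds after a seeded
  shuffle; never-annotated genes are the negatives; isolated nodes score 0;
  AUROC uses the rank-sum formulation with midranks. Terms are evaluable
  with 10–1,000 annotated genes in the node universe (configurable). The
  conventional 0.6 robust-enrichment threshold is exposed as a constant for
  reports only.
- **Enrichment unit.** The hypergeometric test draws network edges from the
  population of all unordered node pairs and counts co-annotated edges; this
  edge-based reading is isolated in one function so a gene-neighborhood
  variant would be a local swap.
- **Power-law fit.** Discrete maximum-likelihood exponent on degrees ≥ 1,
  reported as a log-likelihood (a descriptive fit quality, not a goodness
  test; no x_min scan).
- **Normalized Chi-squared.** χ² / (n_captured · (min(rows, cols) − 1)) —
  Cramér's V squared of the guide-group × community table — multiplied by
  the captured fraction n_captured / n_guides. It is 1 exactly at perfect
  grouping with full capture, 0 with no captured guides, and degenerate
  tables (one group or one community) contribute 0. The formula is a
  reconstruction satisfying those boundary properties; it lives in a single
  function so an alternative normalization is a one-line change.
- **Degenerate inputs.** Zero-variance genes are flagged at load and must be
  excluded before correlation; empty aggregates (all-disjoint members under
  the ≥ 2 co-occurrence floor) are legal results, not errors; a guide set
  absent from a network yields an empty PLC with a warning.

## Known limitations

- The co-occurrence ≥ 2 floor and tie-inclusive thresholds make aggregate
  sizes unstable at small scale: with 10 noisy 5,000-edge members,
  all-member co-occurrence aggregates overshoot the 1.5× size window while
  half-member ones undershoot 0.5×. The strict window is part of the method's
  definition and remains the pipeline default, but small-scale
  comparisons across all six modes are better run with the filter off.
- Normalized Chi-squared comparisons between HRR- and co-occurrence-based
  aggregates are capture-driven: when a compendium is small enough that
  every guide gene is captured by every aggregate, the capture factor
  saturates and the metric reduces to community cleanliness, which favors
  co-occurrence aggregates. Reproducing a capture-driven advantage of
  HRR-based aggregates requires genome-scale sparsity (networks that are
  ≈ 0.5 % of all pairs over tens of thousands of genes).
- Annotation terms are flat sets; no ontology propagation or semantic
  similarity. Edge files are plain TSV; GraphML is the only graph export.
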