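# Methods

## Scope and overall design

The package reimplements, as composable library stages, a network-aware
analysis of knockdown expression data: (i) moderated two-group
differential expression with FDR control; (ii) beta-uniform-mixture
scoring that converts per-gene p-values into signed node weights on a
protein-protein interaction graph; (iii) maximum-weight connected
subgraph (MWCS) discovery; (iv) shortest-path connector analysis
against Wnt / Ras-MAPK gene sets; and (v) copy-number-gain
stratification with a reversed group orientation. Because the original
full-size inputs (a ~12,000-node interactome with ~450,000 edges, the
microarray series, and a tumour cohort) are external downloads, every
stage is exercised on synthetic data whose generative assumptions match
what the analysis itself assumes, plus two small packaged tables of
printed values.

## Moderated differential expression

Per gene, log2FC = mean(treated) − mean(control) and the pooled
variance s² carries d = n₁+n₂−2 df. The prior (d₀, s₀²) is estimated by
moment-matching the marginal distribution of log s² under the
hierarchical scaled-χ² model (digamma/trigamma moments, Newton
inversion of the trigamma function), the moderated variance is
s̃² = (d₀s₀² + ds²)/(d₀+d), and the two-sided p comes from t on d+d₀
df. With `prior_df=0` the procedure reduces exactly to the pooled
two-sample t-test, which the tests verify against scipy; the full
procedure is cross-checked against the reference empirical-Bayes
implementation in R (limma) on a small matrix.

Numerical choices: sample variances are floored at 1e-8 (zero-variance
genes are flagged); when the across-gene spread of log variances does
not exceed its χ² sampling noise the moment estimator has no signal, so
the prior df falls back to 4 with a warning — this happens by design on
idealised homoscedastic simulations. BH adjustment is delegated to
statsmodels; ties in p need no special handling because tied p-values
receive equal q.

The significance rule is q < 0.05 together with |log2FC| ≥ log2(1.5)
(≈ 0.585, the exact logarithm rather than the rounded 0.58; no packaged
table row changes status between the two).

## BUM scoring

The mixture density is f(p) = λ + (1−λ)αp^(α−1); its value at p = 1,
π = λ + (1−λ)α, is the conservative null-density bound. Maximum
likelihood runs on the logit scale with bounded L-BFGS-B from five
fixed starts (the likelihood has a near-exchangeable α/λ ridge on flat
inputs); exact zeros are floored at 1e-300 before logs. The FDR ↔ τ
transform and its exact inverse are

    τ = [(π − λ·FDR)/(FDR·(1−λ))]^(1/(α−1)),  FDR = π/(λ + (1−λ)τ^(α−1)),

validated in the tests against the two published worked operating
points (α = 0.342 at FDR 6.21e-4 → τ = 4.46e-5; α = 0.329 at FDR
2.40e-4 → τ = 1.37e-5) and by a 10-significant-figure round-trip grid.
τ is strictly increasing in the FDR target — relaxing the cut can only
admit more genes — with τ = 1 at FDR = π.

Following the original narrative, λ may be overridden (to 0.1) after
the free fit while α is kept from that fit. When a target count K of
positive-weight genes is requested, τ is the geometric mean of the K-th
and (K+1)-th smallest p-values (scale-appropriate for values spanning
decades); an exact tie across that boundary is refused with the tied
gene ids rather than resolved arbitrarily. Node scores are
s(p) = (α−1)(ln p − ln τ).

## Module discovery

`solve_exact` enumerates connected induced subgraphs (grow/exclude
branching over a sorted frontier) with the admissible bound "current
score plus all positive weight still reachable through unexcluded
nodes", so the returned optimum is certified; it refuses instances
above a 25-node budget rather than pretending to scale. Equal-score
optima are resolved deterministically: fewer nodes first, then the
lexicographically smallest id tuple. The empty module (score 0) is a
legal optimum when all weights are negative.

`solve_heuristic` targets larger instances: positive nodes are joined
pairwise by Dijkstra paths under the node-entry cost max(0, −w(v)); a
minimum spanning structure over that metric closure is expanded back to
graph paths; a spanning tree of the expansion is then reduced to its
exact best subtree by strong pruning (one post-order dynamic program —
every connected subtree has a unique topmost node, and the optimal
subtree topped at v keeps exactly the children with positive value);
finally a greedy local step adds adjacent profitable nodes or two-node
chains and re-prunes negative leaves. The result is always feasible
(connected, no negative-weight leaf, score at least the best single
positive node) and, on every instance small enough to compare, never
exceeds the certified optimum. Without the strong-pruning and local
steps, the plain Steiner expansion keeps every positive node and
measurably underperforms.

## Connector analysis

The network is restricted to the genes selected by differential
expression or module membership, and all unweighted shortest paths from
the source gene to each annotated gene are enumerated (BFS semantics;
every path of minimum edge count is kept). A *connecting gene* is an
interior node of any such path that carries no Wnt/Ras-MAPK annotation
and is not the source; annotated genes appearing in the interior of a
longer path are pathway members, not connectors. Unreachable targets
are reported, not errors. The composite Ras-MAPK set is the union of
the MAPK and Ras member lists.

## Copy-number stratification

Samples are labelled over a gene region (default: the AURKA locus,
chr20:54,944,445–54,967,393 on build 19, 1-based inclusive SEG
convention) by the overlap-length-weighted mean of segment means across
all intersecting segments; ≥ 0.4 is a gain, below is no-gain, and
samples with no overlapping segment are excluded as no-call. When
several segments overlap the region, the weighted mean is the natural
generalisation of the single-segment rule and reduces to it when one
segment covers the region. The group comparison reuses the moderated
test with treated = no-gain and control = gain, so a gene raised by the
gain reads as a negative fold change, matching the knockdown sign
convention; stage significance uses BH-adjusted p < 1e-5.

## Synthetic data generator

The generator emulates exactly the assumptions the analysis makes, and
no more:

* **Network** — `random-uniform-edges` (G(n, p)) or
  `preferential-attachment` models with stable zero-padded string ids.
  Default: 200 genes at edge probability 0.01 (mean degree ≈ 2). The
  default is deliberately sparse: planted-module recovery is only a
  well-posed benchmark when background high-scoring genes are *not*
  cheaply reachable, and in a preferential-attachment graph of this
  size the hubs place every background positive one hop from any
  module, making the score-optimal subgraph genuinely planted-agnostic.
  A sparse uniform graph represents the periphery of a
  medium-confidence interactome, where module detection is
  informative.
* **Planted module** — seeded breadth-first growth to exactly the
  requested size; infeasible sizes fail naming the largest component.
  Every generated module is connected (asserted in tests by an
  independent connectivity check).
* **P-values** — planted genes draw from Beta(α, 1) (α = 0.2 by
  default), the exact signal component of the BUM model, so mixture
  parameter recovery is well-posed; background genes are Uniform(0, 1).
* **Expression** — per-gene N(7, 1) baselines, Gaussian noise
  (sd 0.1), planted genes shifted by 1.0 log2 unit in the treated
  group, two replicates per group by default, as in the knockdown
  experiments. This is an explicit stand-in: the original study never
  states a generative model for expression, and the generator makes no
  claim about microarray intensity behaviour (no probe effects, dye
  bias, batch structure, or count overdispersion). Homoscedastic noise
  also means the empirical-Bayes prior estimator sees no across-gene
  variance spread and falls back to its fixed prior — passing tests
  therefore say nothing about prior estimation on real arrays, which
  the limma cross-check on heteroscedastic data covers instead.
* **Segments** — one region-covering segment per sample with small
  random padding; a gain subpopulation (66% by default, matching the
  cohort rate the stratification stage is designed around) centred at
  0.58 (one extra copy in a diploid background, log2(3/2)) against 0,
  both with sd 0.1.

Each sub-generator draws from its own numpy Generator seeded as
(master seed, fixed offset), so enabling or resizing one stage never
perturbs another; dataset serialisation is byte-deterministic under a
fixed seed.

## Pipeline and reporting

`pipeline.run_experiment` executes the enabled stages in dependency
order (connector analysis requires both the module and annotation
stages, enforced as a configuration error) and emits a self-contained
JSON report: stage summaries, configuration echo with every default
constant, seed, and a SHA-256 determinism hash over the canonicalised
payload. The report schema is validated through a pydantic model on
every construction. K defaults to 50 positive-weight genes, the
original operating choice, and is capped at n−1 on small instances;
synthetic end-to-end runs use K = 20 as the scaled-down analogue
appropriate to a 200-gene graph with a 15-gene planted module.

## Problem sizes used by the test-suite benchmarks

Exact-solver certification runs 200 random graphs of up to 12 nodes
against full enumeration; mixture recovery fits 10,000 draws from
(α = 0.33, λ = 0.6); type-I-error calibration simulates 200 null
datasets of 1,000 genes (2 vs 2); planted-module recovery runs the
fit → threshold → score → solve chain over 50 seeded replicates of the
default generator and requires median Jaccard ≥ 0.6 against truth.
These sizes were chosen as the smallest at which each property is
statistically meaningful.

## Known limitations

* The exact solver is enumeration-based and budgeted; STRING-scale
  instances rely on the heuristic, which carries feasibility and
  lower-bound guarantees but no optimality certificate.
* The BUM λ is weakly identified when most p-values are signal
  (the motivating datasets hit exactly this: λ fitted near 0), hence
  the explicit override mechanism rather than any attempt to
  regularise the fit.
* The copy-number stage's moderated test is a stand-in for whatever
  cohort-scale method a real tumour analysis would use (the stage
  records this in its output metadata); it assumes approximately
  Gaussian log expression.
* Whole-percent and two-decimal reporting conventions in
  `selection_fraction` and `gain_fraction` mirror the conventions of
  the motivating study's summaries and are not configurable.
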