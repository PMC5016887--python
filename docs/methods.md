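# Methods

## Model

The package treats driver-protein identification as minimum domination. For
an undirected simple graph *G = (V, E)*, a dominating set satisfies
*x_v + Σ_{u∈N(v)} x_u ≥ 1* for every node *v* with binary indicators *x*.
The two quantities computed exactly are

1. the domination number γ(G), the optimal value of the cardinality
   program, and
2. the CI-corrected MDS: among all dominating sets of size exactly γ(G),
   one maximising Σ_v CI_ℓ(v)·x_v, where CI_ℓ(v) = (d_v − 1)·Σ_{u∈∂Ball(v,ℓ)}
   (d_u − 1) is the collective influence of node v at radius ℓ.

The second stage exists because minimum dominating sets are massively
degenerate: equally minimal solutions abound and exact solvers pick among
them arbitrarily. Weighting members by collective influence selects a
canonical, biologically motivated configuration (high-influence proteins
are more plausible drivers) and empirically makes the reported set nearly
independent of the solver: in the shipped stability ensemble the mean
cross-backend Jaccard overlap of CI-corrected sets is far higher than that
of standard MDS sets (the acceptance script recomputes both).

Assumptions: the graph is simple, undirected and unweighted; self-loops and
duplicate edges are canonicalised away on ingest. Edge weights and directed
regulation are out of scope.

## Exactness of the integer programming layer

Both stages run through HiGHS (`scipy.optimize.milp`), which returns a
branch-and-bound optimality certificate.

- Stage 1 (cardinality): the objective is all-ones, so consecutive integer
  objective values differ by 1. The solver's default relative MIP gap is
  orders of magnitude below 1/γ for any realistic γ, hence any accepted
  incumbent is provably minimum-cardinality; the code additionally rejects
  any solve whose certified absolute gap reaches 0.5. A feasible dominating
  set of certified minimum size is itself an exact optimum, so no tighter
  tolerance is needed.
- Stage 2 (collective influence): the objective coefficients are large
  integers, so a relative gap would not guarantee the exact optimum; the
  MIP gap is therefore forced to zero. `total_ci` is recomputed from the
  returned members, never read off the solver objective, and all
  downstream comparisons are exact integer comparisons.
- γ(G) enters stage 2 as a hard equality constraint, not a bound.
- Isolated nodes have a degenerate constraint *x_v ≥ 1* and are forced
  members; their CI is defined as 0 (a reduced degree of −1 would be
  meaningless), which cannot affect feasibility or the stage-2 optimum.

Backends: `highs` (variables in lexicographic node order), `highs-permuted`
(a fixed seeded permutation of the variable order) and `enumerate`
(exhaustive, ≤ 16 nodes, tests only). The two HiGHS backends are the same
exact algorithm entered from different variable orders; where the optimum
is unique they must agree, and where it is degenerate they expose the
degeneracy — exactly the phenomenon the CI correction addresses. Residual
stage-2 ties (distinct MDSs with identical maximal total CI, e.g. on
vertex-transitive graphs) are resolved backend-dependently by design; only
`size` and `total_ci` are contractual. The enumeration backend breaks such
ties canonically (lexicographically smallest member tuple).

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| ℓ | 1 | CI radius. ℓ=0 reduces to squared reduced degree (degree-like); large ℓ reaches the network boundary and drives all scores to 0. ℓ=1 keeps topological content beyond degree while remaining informative on small-diameter interactomes. |
| per-source threshold | none (mandatory) | expression cutoff per data source, same units as that source's values; a gene is called expressed if value > threshold (strict; switchable to ≥) in ≥ 1 source. No numeric default is shipped because thresholds are only meaningful relative to a source's measurement scale. |
| hk_min | 14 | minimum number of tissues (of 16) for the housekeeping bands, both for expression and for MDS membership. Not rescaled automatically when T ≠ 16. |
| ts_max | 3 | maximum number of tissues for the tissue-specific bands. |
| ts_strict | true | strict TS-MDS rule (MDS member in *every* tissue where expressed, n_mds = n_expressed); the relaxed alternative (n_mds ≥ 1) is a switch. |
| universe | union | universe for enrichment tests: union of tissue networks or the full global network. |

## Tissue-network construction

Per tissue: take the subgraph of the global network induced on proteins
called expressed in that tissue (so every retained interaction has both
partners expressed there), then keep the largest connected component.
LCC selection happens after filtering, per tissue; the global network is
never pre-trimmed. Component-size ties break toward the component holding
the lexicographically smallest label, so results are deterministic.
"Expressed in a tissue", for breadth counting, means membership in the
post-LCC tissue network — the same object all MDS solves operate on.
Tissues whose induced subgraph is empty are skipped with a warning and
recorded in the run manifest.

## Classification

With per-protein counts (n_expressed, n_mds) over T tissues, the six
classes are assigned in this order: HK-MDS (both counts ≥ hk_min), TS-MDS
(n_expressed ≤ ts_max, MDS wherever expressed under the strict rule),
Remaining-MDS (any other n_mds ≥ 1), then HK-NMDS / TS-NMDS /
Remaining-NMDS analogously for n_mds = 0. The labels partition the union
protein set by construction; tests assert the partition and the marginal
reconciliation on every fixture run.

Breadth histograms report fractions over bins 1..T, restricted to proteins
with a nonzero count for the chosen field (so the MDS-breadth histogram
describes MDS proteins only), plus the 1–3 and (T−2)–T band aggregates.

## Statistics

Enrichment is the one-sided (greater) Fisher exact test: the p-value is
the hypergeometric upper-tail sum for the observed class/annotation
overlap, computed with `scipy.stats.hypergeom`; the unit tests verify it
against an independent log-factorial summation to 1e-9 relative tolerance.
One-sided testing matches the directional question ("is the class enriched
in the annotation"); raw p-values are reported (a Benjamini–Hochberg helper
exists but is off by default). Distribution comparisons use the two-sample
two-sided Kolmogorov–Smirnov test with the asymptotic p-value — adequate at
the hundreds-to-thousands sample sizes the workflow produces; exact
small-sample p-values are out of scope.

## Synthetic data

The generators emulate the study conditions, not biology:

- **Global network**: seeded Erdős–Rényi (for neutral fixtures) or
  preferential attachment (for the heavy-tailed degree profile the
  acceptance study uses; real interactomes are closer to the latter).
- **Expression**: each gene draws an expression breadth from a bimodal
  mixture — 65.9 % housekeeping (breadth T−2..T), 10.7 % tissue-specific
  (breadth 1–3), the rest uniform in between — then a random tissue subset
  of that size; per-source values exceed the threshold in a random
  non-empty subset of the sources for each expressed cell, sub-threshold
  everywhere else. The planted breadth is returned as ground truth and is
  exactly the breadth the OR-consolidated calls reproduce.
- **Planted multi-MDS graph**: a ≤ 10-node hub motif whose minimum
  dominating sets are exactly {hub, c1} and {hub, c2} with distinct total
  CI₁; the construction is re-verified by exhaustive enumeration every time
  it is built.
- **Class attributes**: standard-normal values with a configurable upward
  location shift for designated classes, for calibration and power checks
  of the KS layer.

Not emulated: correlated expression of interacting proteins, the exact
degree distribution of curated interactomes, and real identifier
semantics. Passing fixture tests therefore demonstrates algorithmic
correctness and pipeline determinism, not biological validity of any
particular input.

## Problem sizes

The shipped test suite works on graphs of ≤ 60 nodes (with exhaustive
oracles up to 16) and the acceptance study uses a 300-protein global
network over 16 tissues — sizes at which every integer program is solved
to proven optimality in seconds while still exhibiting the degeneracy the
CI correction targets. The solver layer itself has no hard-coded size
limit; published-scale interactomes (~10⁴ proteins) are feasible but can
take substantially longer per solve.

## Known limitations

- Exact MDS is NP-hard; worst-case solve time is exponential, and dense
  Erdős–Rényi graphs beyond a few hundred nodes can already be slow.
- The reported MDS membership (not γ or total CI) is backend-dependent
  under exact stage-2 ties; pipelines needing full determinism at small
  scale can use the `enumerate` backend.
- Reproducing published per-tissue statistics requires the original
  tissue networks; rebuilt networks depend on per-source expression
  thresholds that are external configuration.
- Only unweighted, undirected networks are supported.
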