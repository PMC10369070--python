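# Methods

This note documents the models, defaults and design decisions behind
`toxnet`, and what the synthetic experiments do and do not demonstrate.

## Scaffolds

**Weighted interactome.** An undirected graph of protein identifiers
with edge confidences `u_ij ∈ (0, 1]` (the scale of curated interaction
confidence scores). Self-interactions are rejected at parse time and
duplicate undirected edges collapse to the maximum confidence —
duplicates represent repeated evidence, and the maximum preserves the
strongest one. Analyses that require connectivity operate on the
largest connected component (ties broken by the lexicographically
smallest member, so the operation is deterministic and idempotent).

**Heterogeneous network.** Proteins plus one drug node, one disease
node and a rooted hierarchy of biological-process nodes. Edge
confidences carry over from their sources: interaction scores for
protein–protein edges, bioactivity values divided by 10 (clipped to
(1e-6, 1]) for drug–protein edges so they share the (0, 1] scale, and
a fixed 0.4 for any edge touching a process node, where no comparable
confidence exists. Node-type weights `w_t > 0` bias the walk; they
default to 1.0 (neutral) because useful values are application-specific
and must come from the user's configuration.

## The four strategies

### Community selection
The detector is deliberately pluggable (seeded weighted Louvain by
default; greedy modularity as an alternative): module detection is a
mature commodity, and the scientific content here is the *selection*
logic. A cluster is selected iff it has **more than 5** genes (strict),
is over-represented for at least one disease-concept gene set, and
contains at least one drug target. Over-representation is a one-sided
hypergeometric test against the full interactome background,
Benjamini–Hochberg-corrected across all (cluster × concept) tests at
q < 0.05 by default; the correction is configurable (`correction="none"`)
because published workflows often report raw Fisher p-values. Target
*containment* is the default rule, with an over-representation variant
(`target_rule="enrich"`) available — the two readings both appear in
practice and differ materially for large clusters.

### Seed propagation
Priors: 1.0 for seeds, 0.1 for everything else; L1-normalized so the
restart mass is a distribution. The kernel is a confidence-weighted
random walk with restart — the fixed point of
`s = r·p̂ + (1−r)·W·s` with `W` the column-normalized weighted
adjacency, `r = 0.5`, L1 tolerance 1e-9, at most 10,000 iterations
(non-convergence is an error carrying the residual). Scores are
min–max rescaled to [0, 1] and the selection boundary 0.8 is
**inclusive**. Min–max rescaling is this package's convention for
putting walk scores on the selection scale; other propagation kernels
can be substituted without touching the prior scheme or the cutoff.
On realistic systems nearly all selected genes are seeds — score-based
prioritization concentrates mass on and immediately around the prior —
which is why this strategy contributes recall, not novelty.

### Steiner subnetwork
Costs are `1 − u_ij` (or `1/u_ij`), clipped to ≥ 1e-6 so they stay
positive, and multiplied by λ = 0.5 when either endpoint is a preferred
linker gene. The multiplicative discount is the simplest monotone
realization of "prefer paths through the disease neighbourhood": λ ≤ 1
can only make linker routes cheaper, and λ → 0 forces them. The tree
is the classical 2-approximation (metric closure over terminals →
MST → pruning, the `kou` construction); exact Steiner is NP-hard and
the approximation is exact on trees. Seeds missing from the scaffold
or outside the main seed component are reported and skipped rather
than fatal, mirroring the gene-mapping losses every real scaffold has.

### Heterogeneous diffusion
The raw jump propensity from node *i* to neighbour *j* of type *t* is
`w_t · u_ij / n_t` with `n_t` the count of *i*'s type-*t* neighbours.
These propensities need not sum to one, so each row is normalized into
a distribution afterwards — normalization preserves the intended
relative bias while making the walk well-defined. Profiles solve
`v = r·e_start + (1−r)·Mᵀv` (r = 0.5 default, L1 tolerance 1e-10);
isolated nodes restart deterministically so total mass is conserved at
every iteration, not only at convergence. Treatment Importance is the
elementwise product of the drug and disease profiles — symmetric, zero
wherever either walk never visits — computed jointly over proteins and
processes and filtered by type at selection time. Ranking ties at the
top-k boundary break lexicographically by node id. On a homogeneous
all-protein network with neutral weights the engine reduces exactly to
the propagation module's RWR; the test suite asserts this cross-module
identity.

## Enrichment and summarization

Annotations live in a rooted is_a DAG; gene sets are propagated to
ancestors on construction (true-path rule), so `genes(child) ⊆
genes(parent)` is an invariant, and the constructor rejects cycles and
multiple roots. Terms with fewer than 5 background-annotated genes are
never tested. The classic test is the one-sided hypergeometric upper
tail; the *elim* variant processes terms deepest-first and, whenever a
term is significant at the elim threshold (0.01), removes its annotated
study genes from all ancestors before they are tested, so generic
parents are not carried by specific children. In this implementation
elimination shrinks only the study overlap (population counts are left
untouched); with threshold 0 the variant is identical to the classic
test, a property the suite checks on random DAGs. Raw p-values with
the fixed 0.01 cut are the primary output (matching common practice in
this workflow); a BH-adjusted column is always emitted alongside.

Semantic clustering uses Lin similarity,
`2·IC(MICA)/(IC(a)+IC(b))` with corpus-based information content
`IC(t) = −ln(|genes(t)|/|genes(root)|)`; the measure is pluggable.
Terms are visited by ascending p-value (ties: term id) and greedily
join the first cluster whose representative is ≥ 0.7 similar, else
found a new cluster; the representative is the lowest-p member. The
0.7 default corresponds to a conservative "small" allowed redundancy;
clusters with at least 3 terms (inclusive) go downstream.

## Consensus

Gene support is tabulated per method; novel candidates are genes with
support ≥ 2 that appear in neither seed list. The optional expression
filter keeps genes with abundance strictly above 0 and keeps-but-flags
genes missing from the table (absence of evidence is not evidence of
absence). Term clusters merge into groups by single linkage over
{Jaccard ≥ 0.4 (inclusive) OR identical representative} — single
linkage is the minimal closure of the pairwise rules and is provably
order-independent; groups are annotated with which of the three
selection rules they satisfy (clusters from every method in play,
Jaccard link, shared representative) and selected when they satisfy at
least one. The "every method" rule requires at least two methods to be
meaningful and adapts to however many methods actually ran.

The consensus network enumerates all hop-count shortest paths on the
protein layer from each candidate to each target and disease gene
(hop-count because the path census is a topological, not a weighted,
statement), keeps the paths through at least one benchmark gene, and
for candidates with none keeps exactly one seeded-uniform shortest
path. A process node is attached when its annotated genes intersect
both the recovered path genes and the candidate-or-benchmark genes
(minimum overlap 1, configurable). Roles are assigned with priority
candidate > aop > target > disease_gene > linker.

## Synthetic study systems

The generator emulates the *shape* of the real inputs, not their size:
a preferential-attachment interactome (default 800 proteins, mean
degree 4 — large enough for community structure, small enough for
exhaustive oracles) with Beta(8, 2) edge confidences
(high-confidence-skewed like curated scores, but non-degenerate so
weighting matters). Disease genes are a snowball (network-local)
sample — the disease-module hypothesis that community-based selection
relies on; drug targets are sampled uniformly — target sets are
scattered in real interactomes. Each of the 12 planted mechanism genes
is bridged by *added* edges (never deletions, preserving the degree
character) to 2 targets and 2 disease genes, chosen so a non-adjacent
target–disease pair exists: the mechanism gene then lies on a length-2
shortest path between drug and disease neighbourhoods while belonging
to neither seed list. One leaf of the 40-term annotation DAG annotates
exactly the mechanism genes plus ≤ 3 decoys, making it enriched in any
gene set that recovers the mechanism. The benchmark ("AOP"-like) set
is 16 disease genes + 4 targets, structurally disjoint from the novel
candidates as in curated adverse-outcome annotations, which overlap
the known gene lists. Bench sizes, like seed-set sizes, scale down
proportionally for reduced systems.

What passing tests show: each engine is numerically correct against an
independent oracle, the selection boundaries match their stated
semantics, and under the planted-signal conditions the pipeline
recovers what it should (at the reference seed 0: 12/12 mechanism genes
in the diffusion top-k, 10/12 as ≥2-method novel candidates, and the
planted term's cluster in a selected group). What they do not show:
performance on real interactomes (17k nodes, heavy annotation bias,
correlated evidence), robustness to identifier-mapping noise, or any
claim about specific drugs or outcomes. Recovery through *multiple*
methods also varies across random systems — community selection in
particular can legitimately select nothing when no cluster passes all
three rules — exactly the method-to-method variability that motivates
consensus analysis in the first place.

## Numerical choices and degenerate inputs

- Iterative solvers error (with the residual) rather than return
  unconverged values; tolerances are L1: 1e-9 (propagation), 1e-10
  (diffusion).
- All orderings that affect output (cluster ids, tie-breaks, RNG draws)
  are derived from sorted node/term ids, so every stage is
  deterministic under its seed; the pipeline derives per-stage seeds
  from the global seed.
- Empty study sets, empty backgrounds, unknown terms, universe
  mismatches and negative activities are errors; empty *results*
  (no selected clusters, no significant terms, zero candidates) are
  valid outcomes that propagate as empty sets with warnings.
- Jaccard of two empty sets is defined as 0 (with a warning).
- Scenario problem sizes (800 proteins; 200-instance Steiner oracle
  sweeps at ≤ 12 nodes; 1,000-replicate calibration) are chosen so the
  whole experiment, including its brute-force oracles, runs in well
  under a minute on one core.

## Known limitations

- The elim variant follows the study-gene-removal formulation; tools
  that also shrink population counts will give slightly different
  ancestor p-values.
- Lin similarity with corpus IC is one defensible choice among several
  (SimRel, Resnik); clustering granularity depends on it.
- The 2-approximate Steiner tree can return any cost-optimal tie;
  determinism is guaranteed, global optimality only on trees.
- The generator does not simulate assay-level bioactivity records,
  annotation bias, or interactome false negatives.
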