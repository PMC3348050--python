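# Methods

## Model and procedure

The package quantifies two network-level properties of effective drug
combinations relative to degree-matched random combinations.

**Effect radius.** The genetic interaction network is an undirected,
unweighted simple graph over genes; interaction p-values gate ingestion
(strictly `p < 1e-7` by default) but do not weight edges. The distance
between two drugs is the minimum shortest-path hop distance between any
target of one and any target of the other; two drugs sharing a target have
distance 0. The effect radius `R` of a combination is the mean drug–drug
distance over its C(k,2) unordered member pairs. Pairs whose endpoints lie
in different components (or off the network entirely) have no defined
distance: they are excluded from both numerator and denominator rather than
imputed with a large constant, because the radius is defined conditional on
distance availability. The exclusion count (`n_pairs_unreachable`) is
carried in every result so the alternative convention can be audited; a
combination with no reachable pair has an UNDEFINED radius and is excluded
from distributions and strata with a logged count.

**Pathway-pair relations.** A drug is associated with every pathway whose
gene set intersects its targets. Each (pathway of drug A) × (pathway of
drug B) pair is assigned exactly one of four labels with precedence
IDENTICAL > CROSS_TALKING > INTERACTING > PARALLEL. Precedence is needed
because two overlapping pathways may also have bridging edges; sharing a
gene is the stronger, containment-like relation, so it wins. Identity is
decided by pathway identifier, so two differently named pathways with equal
gene sets are cross-talking, not identical. Multi-drug combinations
aggregate pair counts over all member-drug pairs. A member drug with no
associated pathway contributes no pairs; combinations with zero pairs carry
an empty profile and are skipped in proportion-based comparisons.

**Null model.** The cocktail network places an edge between every two drugs
co-occurring in a retained combination (k-drug combinations enter as
cliques). Random combinations are degree-preserving double-edge-swap
shuffles of this network: repeatedly pick two distinct edges (u,v), (x,y)
(with random orientation) and rewire to (u,x), (v,y) when the result stays
a simple graph. The attempt budget is `n_swaps_per_edge × |E|` with
`n_swaps_per_edge = 10` by default; rejected proposals (self-loop or
multi-edge) count against the budget. This mixes well empirically (fewer
than half the edges of a 100-node/300-edge random graph remain in place)
but is not a uniform sampler over the degree-sequence graph space, and
connectedness is not preserved. Degree sequences that admit a unique simple
graph (e.g. a star) are returned unchanged with a warning. Replicate *r* of
an ensemble uses derived seed `master_seed + r`, so one integer reproduces
the whole ensemble. Each shuffled edge is scored downstream as a pairwise
random combination; the null is over edges because that is how the cocktail
network represents co-combination.

**Comparison.** Real radii (and per-combination category proportions) are
compared against the null by the Wilcoxon rank-sum test. For pooled sample
sizes n+m ≤ 12 without ties the null distribution of the rank sum W is
enumerated exactly; the two-sided p doubles the smaller tail, capped at 1.
Otherwise the normal approximation with midranks, tie correction and
continuity correction is used (via `scipy.stats.mannwhitneyu`). A pooled
sample with zero spread is degenerate and reports p = 1 with a warning.
Null values are pooled across all replicates by default; a
`replicate_mean` mode (one mean per replicate) is provided and recorded in
every result, because either summary of the ensemble is defensible. The
default sidedness is two-sided — conservative for directional claims —
with `real_less` / `real_greater` available; the rank-biserial effect size
is printed for context. No multiple-testing correction is applied: the
pipeline reports three raw p-values.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `p_threshold` | 1e-7 | strict upper bound on interaction p-values (exclusive) |
| `n_null_replicates` | 1000 | degree-preserving shuffles in the null ensemble |
| `n_swaps_per_edge` | 10 | attempted swaps per edge per shuffle |
| `radius_stratum_threshold` | 3 | stratum boundary; R = 3 falls in the small stratum (inclusive) |
| `interacting_proportion_threshold` | 0.4 | selection bound; exactly 0.4 is excluded (strict >) |
| `alternative` | two_sided | rank-sum sidedness |
| `pooling` | pooled | null summary: pool all replicate values, or one mean per replicate |

Duplicate interaction rows collapse to the minimum p-value (conservative
retention); self-loop rows are dropped with a warning but keep the node.
Combinations referencing drugs absent from the drug table are discarded
with a warning, mirroring the discard-on-missing-annotation policy rather
than crashing. Identifier matching is exact, case-sensitive string
equality; no symbol aliasing is attempted.

## Synthetic data

The generator emulates the *shape* of the real inputs: an Erdős–Rényi
interaction network (400 genes, mean degree 3 by default; a
preferential-attachment option exists because real interaction networks are
heavy-tailed), 40 pathway gene sets of 5–15 genes with recruitment
probability 0.2 from already-used genes (so roughly a fifth of pathway
pairs share a gene, comparable to curated pathway collections — a much
higher overlap makes nearly every pair cross-talking and leaves no room for
a distinguishable interacting relation), 150 drugs with 1–5 targets and one
syntactically valid ATC code drawn from the 14 real level-1 letters, and
100 true pairwise combinations.

Two effects are planted. With probability `planted_crosstalk_bias` (0.8) a
combination's partners have their target sets replaced by the two endpoints
of an edge bridging a disjoint pathway pair, so every pathway pair induced
by those targets is bridged — this is what makes the interacting signal
recoverable; a gene-sharing pair is the fallback when the sampled network
has no bridged pair. With probability `planted_radius_bias` (0.8) the
partners receive one target each within `d_plant` (1) hops; combinations
already within `d_plant` (e.g. via a planted bridge) are left untouched so
the crosstalk planting is not diluted. Decoy interaction rows at and above
the p threshold (including one exactly at it) and a 10% fraction of drugs
stripped of targets or ATC codes deliberately exercise the strict filters.
Output files are byte-identical given a seed.

What the generator does **not** emulate: real marginal statistics of
DCDB/DrugBank/KEGG-scale data (target-count and pathway-size distributions,
ATC composition, combination-type frequencies are uniform-ish), overlapping
multi-drug regimens (true combinations are pairwise), weighted or directed
interactions, or biological correlation between a drug's therapeutic class
and its targets. Passing tests therefore demonstrate correctness of the
method's machinery and recoverability of planted signal at realistic
sparsity — not that any particular real database reproduces the analysis'
published effect sizes.

## Numerical choices and degenerate inputs

- Distances are computed by breadth-first search from each queried source
  gene and cached; the contract is the distance mapping, not the traversal
  order. `d(g, g) = 0` even for genes absent from the network.
- The exact rank-sum branch compares tail counts with a 1e-9 absolute
  guard against float noise in midrank sums.
- Radius histograms use bins `(-inf, e1], (e1, e2], ..., (e_last, inf)`
  over user-supplied edges; proportions are over defined radii only.
- Empty tally inputs produce empty tables, not errors; a gene without a
  function annotation tallies as `unclassified`.
- ATC incidence counting: a drug contributes once per (combination
  membership × level-1 class), so a drug with codes in two classes counts
  in both, and a drug in two selected combinations counts twice.
- The pipeline validates its whole configuration before any computation;
  `n_null_replicates = 0` or a missing input file is a configuration error
  (CLI exit code 2), malformed input rows are validation errors naming the
  file and line (exit code 3).

## Problem sizes

The shipped benchmark condition runs the pipeline on the default
400-gene/150-drug/100-combination bundle against a 100-replicate null
ensemble; the no-signal calibration study uses 200 seeds of a reduced
150-gene/60-drug/40-combination configuration with 20-replicate ensembles.
These sizes give stable rank-sum behaviour (thousands of pooled null
values) while keeping a full run to seconds; the `n_null_replicates`
default of 1000 matches the ensemble size a full-scale study would use.

## Known limitations

- The double-edge-swap null is approximate (non-uniform) and ignores
  connectedness; conclusions about marginal significance should not hinge
  on it.
- Pooled null values are not independent (replicates reuse the same drugs),
  which the rank-sum test formally assumes; the no-signal calibration study
  (rejection fraction well under nominal) shows the pooled test is, if
  anything, conservative at these sizes.
- UNREACHABLE exclusion biases R downward for combinations with many
  cross-component pairs; the per-result unreachable count is the audit
  trail.
- Pathway identity is by identifier only; no gene-set semantic similarity
  is computed.
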