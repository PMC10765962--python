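# Methods

## Genome model

A genome is a multiset of chromosomes; a chromosome is an ordered sequence
of signed genes and is linear or circular. Chromosome equality is invariant
under reverse-complement and, for circular chromosomes, rotation; the
canonical form (lexicographically smallest among all equivalent readings) is
used for hashing and serialization, so that generated files are
byte-reproducible. Family tokens are arbitrary strings without whitespace or
bracket characters, not only integers.

Each gene contributes a tail and a head extremity. Adjacencies are unordered
pairs of neighboring extremities, telomeres are the free ends of linear
chromosomes, and the bookkeeping identity |A(G)| + |T(G)|/2 = number of
genes holds for every genome (each gene has two extremities; an adjacency
consumes two, a telomere one). A single-gene circular chromosome carries the
exceptional self-adjacency between its own head and tail.

## Distances of canonical pairs

The breakpoint graph of a canonical pair is stored as two per-vertex
adjacency maps (one per genome); construction and decomposition are single
passes, so all σₖ distances of a canonical pair cost O(n★). Path length is
edge count; a 0-path is an isolated vertex that is telomeric in both
genomes; odd paths are counted and reported but never contribute to σₖ.
Scores are `fractions.Fraction` values throughout — σₖ lives in ½·ℤ and
printing uses exact decimal halves (`2.5`), never floats.

`INF` (the DCJ case) is a dedicated token rather than a large integer, so
the API and CLI cannot silently confuse "large finite k" with the limit.

## The double distance and the ambiguous breakpoint graph

For singular S vs duplicated D, the ambiguous breakpoint graph (ABG) has
four vertices per family (two paralogous pairs). D is singularized by
labeling the first occurrence of each family `a` and the second `b`,
reading chromosomes in file order; the double distance is provably invariant
under this choice, and the test suite re-checks the invariance by randomly
relabeling copies. Each adjacency γβ of S becomes a square with the parallel
pair {γₐβₐ, γᵦβᵦ} and the crossed pair {γₐβᵦ, γᵦβₐ}; a solution picks one
pair per square, and the k-score of the induced graph is computed by the
same decomposition code as for canonical pairs (the definitional identity
k_score = σₖ ∘ decompose ∘ induce is the implementation, not a separate
formula). Vertices in no square and no D-edge are retained: they are the
0-paths and carry score.

The exhaustive oracle enumerates the 2^(a★) resolutions in lexicographic
order (parallel before crossed), keeping the first maximum, and refuses
instances with more than 20 free squares by default (≈10⁶ resolutions keeps
the certification suites in minutes on one CPU). The NP-hard σ∞ (DCJ)
double distance is exposed only through this oracle.

## σ₄: greedy sweep

After two score-free preprocessing steps — fixing every square that closes a
2-cycle with a parallel D-edge (common adjacencies and telomeres are always
conserved, for every k including σ∞), and fixing symmetric squares (a
D-edge joining a paralogous pair; D-telomeres on a paralogous pair; D-edges
from a paralogous pair straight to S-telomeres) arbitrarily to the parallel
pair — every remaining valid 2-path is optimal and every valid 4-cycle at
least co-optimal, so the solver sweeps squares in index order, scans each
candidate edge's constant-size neighborhood for a 2-path or 4-cycle, fixes
the squares that induce the first player found, and fills untouched squares
with the parallel pair. Traversal order only selects among co-optimal
solutions; index order makes the output deterministic. A 2-path and a
4-cycle can never compete for a square once symmetric squares are gone;
a conflicting fix would raise immediately rather than silently resolve.

## σ₆: prune, triplets, bubbles, flows

Players are valid {2,4}-paths (weight ½) and {4,6}-cycles (weight 1).
The pipeline:

1. **Player enumeration / pruning.** All players are enumerated by
   depth-bounded alternating walks — paths from each S-telomere, cycles from
   each D-edge — deduplicated by their edge sets; in a graph of degree ≤ 3
   each walk is constant-size, so enumeration is linear. Edges in no player
   are pruned; players survive pruning intact, so the 6-score is unchanged.
   Squares left with edges from a single pair are resolved and fixed; fully
   pruned squares are fixed parallel.
2. **Components.** Resolved components are verified to be exactly one
   player (cycle → set C, path → set P, 0-paths included in P); the total is
   |C| + |P|/2 + Σ σ₆(M) over ambiguous components M. A resolved component
   that is not a single player is an internal error, not a recoverable case.
3. **Triplets** — three mutually connected ambiguous squares with at most
   two pruned vertices, the one shape where a D-edge can sit in four
   6-cycles — are detected by pattern and scored by enumerating their ≤ 8
   resolutions; the saturated form must score 2 and the unsaturated 1, and a
   deviation is an internal error.
4. **Cycle-only components** get the straight solution: choosing a pair for
   one square forces, through the unique cycle player carrying each chosen
   edge, the resolution of its neighbors, and so on; the better of the
   propagated solution and its all-switched complement is optimal. Balance
   is decided by explicitly decomposing both induced subgraphs rather than
   by counting shared players.
5. **Mixed components** are reduced to a maximum-weight independent set on
   the intersection graph (vertices = players, edges = shared vertices).
   The decomposition classifies intersections (telomere ends, inner D-edge
   rungs, cycle plugs), builds path-lines, pairs fully saturated lines into
   double-lines, and groups cycles into bubbles. Unbalanced bubbles fix
   their better straight side; balanced bubbles with one path contact fix
   the side avoiding the contact; even cycle-lines and double-lines with
   contacts at both ends become *balanced links* whose local choice is
   deferred behind a virtual edge joining their outer neighbors. The final
   unsaturated path-lines are solved by selecting alternate vertices —
   numbering starts at the endpoint (or, for cyclic lines, the vertex) with
   the smallest canonical key, and a cyclic line of odd length drops its
   last selected vertex — after which deferred links pick the alternating
   set compatible with the selected boundary neighbors (ties take the first
   set; both are then optimal).
6. **Fallbacks.** Any component whose shape falls outside this catalogue —
   the bounded exceptional bubbles, tangled line pairings, components
   containing always-induced players — is solved exactly: by exhausting its
   2^m resolutions when it has m ≤ 12 ambiguous squares (the exceptional
   shapes are all bounded, so this preserves linearity), and otherwise by an
   exact maximum-weight independent set computed by dynamic programming over
   a tree decomposition of the intersection graph (min-degree heuristic; the
   DP is exact for any decomposition and linear-time at bounded width, which
   these shapes have). The structural result is re-scored by explicit
   decomposition of the component; any mismatch also routes to the fallback,
   so a structural misclassification can cost time but never correctness.

The assembled solution fills untouched squares with the parallel pair and is
independently re-scored; disagreement with the component-wise total raises
an internal error rather than returning a number.

## Instance generator

The generator emulates post-duplication evolution: a seeded random singular
genome with requested chromosome counts, one randomly chosen doubling (each
circular chromosome either copied or concatenated), `n_dcj` random DCJ
operations applied to the adjacency/telomere set representation (cutting two
random adjacencies/telomeres and rejoining uniformly, which realizes
inversions, translocations, fusions and fissions, including telomeric
cases), then copy labels stripped. It does **not** emulate gene loss,
unequal family sizes, missing data, or rearrangement-rate heterogeneity
along the genome — so passing tests certify the combinatorial solvers on
the stated genome model, not robustness to annotation noise; real inputs
must already be condensed to one-gene-per-family-per-copy gene orders.

Default certification conditions: 500 seeded instances (seeds 0–499)
stratified over circular-only, linear-only and mixed genomes with 4–9
families, up to 8 DCJs and a★ ≤ 10, where every solver score is compared
with the exhaustive oracle; scaling runs use n★ = 10⁴ with DCJ count n/12 —
sizes chosen so the whole certification finishes in minutes on one CPU
while covering every structural case class (triplets, bubbles, lines and
the bounded exceptions were additionally exercised by targeted searches
during development).

## Known limitations

- No σₖ solver for finite k ≥ 8 (only the oracle); no DCJ scenario
  reconstruction; no median/halving/guided-halving problems.
- The oracle's exponential cost caps certification at a★ ≈ 20; the
  polynomial solvers themselves scale linearly.
- Wall-clock linearity is not certified, only elementary-operation counts;
  Python constant factors dominate below n★ ≈ 10³.
- The bounded exceptional component shapes are solved by exact enumeration
  rather than the case-by-case catalogue, so per-case structural labels for
  them are not reported.
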