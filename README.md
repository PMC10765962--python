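# sigmak

Genome distances between the breakpoint and the DCJ extremes, and
linear-time **double distances** for comparing a genome against the product
of a whole-genome duplication.

`sigmak` is for comparative genomicists who work with gene-order data:
genomes represented as multisets of linear and circular chromosomes, each a
sequence of signed genes classified into families.

## The σₖ distance family

For a *canonical pair* of singular genomes S₁, S₂ over the same n★ families,
the breakpoint graph has one vertex per gene extremity (Xᵗ, Xʰ) and one edge
per adjacency of each genome; its components are even-length alternating
cycles and paths. Writing cᵢ for the number of i-cycles and pⱼ for the
number of j-paths,

    σₖ = c₂ + c₄ + … + c_k + (p₀ + p₂ + … + p_{k−2}) / 2
    d_{σₖ}(S₁, S₂) = n★ − σₖ        k ∈ {2, 4, 6, …, ∞}

σ₂ gives the breakpoint distance (only common adjacencies and telomeres
count) and σ∞ the double-cut-and-join (DCJ) distance (all cycles and even
paths count); the distance shrinks monotonically in between.

## The σₖ double distance

A whole-genome duplication turns a singular genome S into a *doubled*
genome; a present-day *duplicated* genome D (two genes per family) is
compared against the best of the 2ʳ possible doublings of S (r = number of
circular chromosomes):

    d²_{σₖ}(S, D) = min over doublings B of S, over paralog labelings, of d_{σₖ}(B, Ď)

Equivalently, in the *ambiguous breakpoint graph* every adjacency of S
becomes a *square* of four candidate edges — a parallel and a crossed pair
of paralogous edges — and d²_{σₖ} = 2n★ − (best k-score over all 2^(a★)
square resolutions). This maximization is solved here

- for k = 2 by the closed multiset formula,
- for k = 4 by a greedy sweep (every valid 2-path and 4-cycle is at least
  co-optimal once common adjacencies and symmetric squares are fixed),
- for k = 6 by a structural linear-time pipeline: prune every edge that
  cannot sit in a player (a valid cycle of length ≤ 6 or even path of length
  ≤ 4), score triplets locally, propagate *straight solutions* through
  cycle-bubbles, and reduce what remains to maximum-weight independent sets
  on path-lines, double-lines and cycle-lines of the intersection graph,
- for any other k (including DCJ, where the problem is NP-hard) by an
  exhaustive oracle on small instances — the same oracle the test suite uses
  to certify the polynomial solvers on hundreds of seeded random instances.

All scores and distances are exact rationals (half-integers), never floats.

## Worked example

Genome files hold one chromosome per line (or several per line): `[1 -3 2]`
is linear, `(4)` circular, `-` marks reverse orientation. With
`S1.txt` = `(1 -3 2) [4]` and `S2.txt` = `(1 2) [3 -4]`:

```console
$ sigmak distance --k 2 S1.txt S2.txt
2.5
$ sigmak distance --k inf S1.txt S2.txt
2
```

The pair shares one adjacency (1ᵗ2ʰ) and one telomere (4ᵗ), so the
breakpoint distance is 4 − (1 + ½) = 2.5; the breakpoint graph decomposes
into one cycle and two even paths, so the DCJ distance is 4 − (1 + 1) = 2.

For the double distance, take the singular `S.txt` = `[1 2 3]` and the
duplicated `D.txt` = `[1 2 -3 1] [-3 2]`:

```console
$ sigmak double-distance --k 2 S.txt D.txt
4
$ sigmak double-distance --k 4 S.txt D.txt
3.5
$ sigmak double-distance --k 6 S.txt D.txt
3
```

The distance falls as k grows because longer cycles and paths start to
count. The same numbers are available programmatically:

```python
import sigmak as sk

s = sk.parse_genomes("[1 2 3]")[0]
d = sk.parse_genomes("[1 2 -3 1] [-3 2]")[0]
sk.double_distance(s, d, 6).distance   # Fraction(3, 1)
```

Other entry points: `sigmak generate` writes seeded random instances
(singular genome, doubled, scrambled by random DCJ operations), and
`sigmak graph --which bg|abg|pruned|intersection --dot out.dot` exports the
underlying graphs as DOT.

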