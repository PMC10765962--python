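"""Ambiguous breakpoint graph for a singular vs. duplicated genome pair.

Comparing a singular genome S with a duplicated genome D requires doubling S,
and every adjacency of S can be realized in the doubled genome in two ways
once paralogs carry copy labels a/b.  The ambiguous breakpoint graph (ABG)
makes that explicit: each family contributes two pairs of paralogous vertices,
each adjacency gamma-beta of S becomes a *square* of four candidate S-edges
(the parallel pair {gamma_a beta_a, gamma_b beta_b} and the crossed pair
{gamma_a beta_b, gamma_b beta_a}), and the singularized D contributes plain
D-edges.  A *solution* resolves every square by keeping one pair and masking
the other; the induced graph is an ordinary breakpoint graph whose k-score is
the sigma-k score.  Maximizing the k-score over the 2^(a*) solutions is
equivalent to the sigma-k double distance:

    d2_{sigma_k}(S, D) = 2 n* - max_tau k_score(tau).

This module holds the graph, solutions, induced scores, the exhaustive oracle
(exponential; used to certify the polynomial solvers on small instances) and
the closed-form sigma-2 double distance.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Optional

from .breakpoint_graph import (
    BreakpointGraph,
    decompose,
    sigma_score,
    validate_k,
)
from .genomes import (
    HEAD,
    TAIL,
    Extremity,
    Genome,
    GenomeFormatError,
    adjacency_list,
    adjacency_multiset,
    classify_genome,
    singularize,
    strip_copies,
    telomere_multiset,
)

PARALLEL = "parallel"
CROSSED = "crossed"

Solution = tuple  # tuple of PARALLEL/CROSSED, one entry per square


def _with_copy(e: Extremity, copy: str) -> Extremity:
    return Extremity(e.family, e.side, copy)


@dataclass
class Square:
    """The four candidate S-edges of one adjacency of S.

    ``index`` is 1-based, following the adjacency order of S.  ``fixed`` is
    ``None`` while the square is free, otherwise the choice it is pinned to.
    """

    index: int
    gamma: Extremity  # copy-free extremities of the S-adjacency
    beta: Extremity
    fixed: Optional[str] = None

    @property
    def adjacency(self) -> frozenset:
        return frozenset((self.gamma, self.beta))

    @property
    def ga(self) -> Extremity:
        return _with_copy(self.gamma, "a")

    @property
    def gb(self) -> Extremity:
        return _with_copy(self.gamma, "b")

    @property
    def ba(self) -> Extremity:
        return _with_copy(self.beta, "a")

    @property
    def bb(self) -> Extremity:
        return _with_copy(self.beta, "b")

    @property
    def vertices(self) -> tuple[Extremity, ...]:
        return (self.ga, self.gb, self.ba, self.bb)

    def pair(self, choice: str) -> tuple[frozenset, frozenset]:
        if choice == PARALLEL:
            return (frozenset((self.ga, self.ba)), frozenset((self.gb, self.bb)))
        if choice == CROSSED:
            return (frozenset((self.ga, self.bb)), frozenset((self.gb, self.ba)))
        raise ValueError(f"bad choice {choice!r}")

    def all_edges(self) -> list[tuple[str, frozenset]]:
        return [(c, e) for c in (PARALLEL, CROSSED) for e in self.pair(c)]

    def choice_of_edge(self, edge: frozenset) -> str:
        for c in (PARALLEL, CROSSED):
            if edge in self.pair(c):
                return c
        raise ValueError(f"edge {set(edge)} is not in square {self.index}")

    def fix(self, choice: str) -> None:
        if self.fixed is not None and self.fixed != choice:
            raise ValueError(
                f"square {self.index} already fixed to {self.fixed}, "
                f"cannot fix to {choice}"
            )
        self.fixed = choice


class OracleBoundError(ValueError):
    """Refusal to enumerate an exponentially large solution space."""


@dataclass
class AmbiguousBreakpointGraph:
    s: Genome
    d_checked: Genome  # singularized duplicated genome
    squares: list[Square] = field(init=False)
    vertices: list[Extremity] = field(init=False)
    d_edges: list[tuple[Extremity, Extremity]] = field(init=False)
    s_telomeres: frozenset = field(init=False)
    d_telomeres: frozenset = field(init=False)
    vertex_square: dict = field(init=False, repr=False)
    vertex_d: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        fams = sorted(self.s.families())
        self.vertices = [
            Extremity(f, side, copy)
            for f in fams
            for side in (TAIL, HEAD)
            for copy in ("a", "b")
        ]
        self.squares = []
        for i, adj in enumerate(adjacency_list(self.s), start=1):
            gamma, beta = sorted(adj)
            self.squares.append(Square(i, gamma, beta))
        self.d_edges = [tuple(sorted(a)) for a in adjacency_list(self.d_checked)]
        self.s_telomeres = frozenset(
            _with_copy(t, c)
            for t in telomere_multiset(self.s)
            for c in ("a", "b")
        )
        self.d_telomeres = frozenset(telomere_multiset(self.d_checked))
        self.vertex_square = {}
        for sq in self.squares:
            for v in sq.vertices:
                self.vertex_square[v] = sq.index
        self.vertex_d = {}
        for u, v in self.d_edges:
            if u in self.vertex_d or v in self.vertex_d:
                raise AssertionError("vertex carries two D-edges")
            self.vertex_d[u] = v
            self.vertex_d[v] = u

    # -- bookkeeping ---------------------------------------------------------

    @property
    def n_star(self) -> int:
        return len(self.vertices) // 4

    @property
    def a_star(self) -> int:
        return len(self.squares)

    def square(self, i: int) -> Square:
        return self.squares[i - 1]

    def free_square_indices(self) -> list[int]:
        return [sq.index for sq in self.squares if sq.fixed is None]

    def fixed_choices(self) -> dict[int, str]:
        return {sq.index: sq.fixed for sq in self.squares if sq.fixed is not None}

    def default_solution(self, fill: str = PARALLEL) -> Solution:
        return tuple(sq.fixed if sq.fixed is not None else fill for sq in self.squares)

    def complete(self, choices: dict[int, str], fill: str = PARALLEL) -> Solution:
        """Solution from per-square choices; fixed squares win, the rest take
        ``choices`` and finally ``fill``."""
        tau = []
        for sq in self.squares:
            if sq.fixed is not None:
                if sq.index in choices and choices[sq.index] != sq.fixed:
                    raise ValueError(
                        f"choice for square {sq.index} conflicts with its fix"
                    )
                tau.append(sq.fixed)
            else:
                tau.append(choices.get(sq.index, fill))
        return tuple(tau)


def build_abg(s: Genome, d: Genome) -> AmbiguousBreakpointGraph:
    """Construct the ABG; ``d`` may be raw (it is singularized here) or
    already singularized (copy labels are then taken as given)."""
    if classify_genome(s) != "singular":
        raise GenomeFormatError("first genome must be singular")
    if d.is_singularized():
        d_checked = d
        plain = strip_copies(d)
    else:
        d_checked = singularize(d)
        plain = d
    if classify_genome(plain) not in ("duplicated", "doubled"):
        raise GenomeFormatError("second genome must be duplicated")
    fams_s, fams_d = s.families(), plain.families()
    if fams_s != fams_d:
        raise GenomeFormatError(
            f"family sets differ; symmetric difference: {sorted(fams_s ^ fams_d)}"
        )
    copies = Counter(g.family_key for g in d_checked.genes)
    if any(n != 1 for n in copies.values()):
        raise GenomeFormatError("singularized genome repeats a copy label")
    return AmbiguousBreakpointGraph(s, d_checked)


# ---------------------------------------------------------------------------
# Solutions

def induce(abg: AmbiguousBreakpointGraph, tau: Solution) -> BreakpointGraph:
    """Breakpoint graph induced by a complete solution (chosen pair kept per
    square, complementary pair masked)."""
    if len(tau) != abg.a_star:
        raise ValueError(f"solution has {len(tau)} entries, expected {abg.a_star}")
    s_edges = []
    for sq, choice in zip(abg.squares, tau):
        if sq.fixed is not None and choice != sq.fixed:
            raise ValueError(
                f"solution conflicts with fixed square {sq.index} ({sq.fixed})"
            )
        s_edges.extend(tuple(e) for e in sq.pair(choice))
    return BreakpointGraph(
        list(abg.vertices), s_edges, list(abg.d_edges), label1="2S", label2="D"
    )


def switch(tau: Solution, i: int) -> Solution:
    """Flip the choice of square ``i`` (1-based); an involution."""
    if not 1 <= i <= len(tau):
        raise IndexError(f"square index {i} out of range 1..{len(tau)}")
    flipped = CROSSED if tau[i - 1] == PARALLEL else PARALLEL
    return tau[: i - 1] + (flipped,) + tau[i:]


def k_score(abg: AmbiguousBreakpointGraph, tau: Solution, k) -> Fraction:
    validate_k(k)
    return sigma_score(decompose(induce(abg, tau)), k)


def oracle_best(
    abg: AmbiguousBreakpointGraph, k, cap: int = 20
) -> tuple[Fraction, Solution]:
    """Maximum k-score over all solutions, by exhaustive enumeration.

    Ties break toward the lexicographically smallest choice tuple (parallel
    before crossed).  Respects already-fixed squares.  Refuses when more than
    ``cap`` squares are free (2^cap resolutions).
    """
    best = oracle_best_scores(abg, [k], cap=cap)[k]
    return best


def oracle_best_scores(
    abg: AmbiguousBreakpointGraph, ks: Iterable, cap: int = 20
) -> dict:
    """One enumeration sweep, best (score, solution) for every k in ``ks``."""
    ks = list(ks)
    for k in ks:
        validate_k(k)
    free = abg.free_square_indices()
    if len(free) > cap:
        raise OracleBoundError(
            f"{len(free)} free squares exceed the oracle bound {cap} "
            f"(2^{len(free)} resolutions); raise cap explicitly to force"
        )
    best: dict = {k: None for k in ks}
    for assignment in itertools.product((PARALLEL, CROSSED), repeat=len(free)):
        tau = abg.complete(dict(zip(free, assignment)))
        cs = decompose(induce(abg, tau))
        for k in ks:
            score = sigma_score(cs, k)
            if best[k] is None or score > best[k][0]:
                best[k] = (score, tau)
    return best


# ---------------------------------------------------------------------------
# Double distances

def double_distance_sigma2(s: Genome, d: Genome) -> Fraction:
    """Closed-form breakpoint (sigma-2) double distance:
    2 n* - |A(2S) ^ A(D)| - |T(2S) ^ T(D)| / 2 with multiset intersections."""
    if classify_genome(s) != "singular":
        raise GenomeFormatError("first genome must be singular")
    plain = strip_copies(d) if d.is_singularized() else d
    if classify_genome(plain) not in ("duplicated", "doubled"):
        raise GenomeFormatError("second genome must be duplicated")
    if s.families() != plain.families():
        raise GenomeFormatError(
            "family sets differ; symmetric difference: "
            f"{sorted(s.families() ^ plain.families())}"
        )
    a_s = adjacency_multiset(s)
    t_s = telomere_multiset(s)
    a2s = a_s + a_s
    t2s = t_s + t_s
    a_d = adjacency_multiset(plain)
    t_d = telomere_multiset(plain)
    common_adj = sum((a2s & a_d).values())
    common_tel = sum((t2s & t_d).values())
    return Fraction(2 * len(s.families())) - common_adj - Fraction(common_tel, 2)


@dataclass(frozen=True)
class DoubleDistanceResult:
    distance: Fraction
    score: Fraction
    solution: Solution
    k: object
    method: str


def double_distance(
    s: Genome, d: Genome, k, method: str = "auto", oracle_cap: int = 20
) -> DoubleDistanceResult:
    """Sigma-k double distance of singular ``s`` and duplicated ``d``.

    ``method`` is ``auto`` (sigma-2 closed formula, greedy sigma-4 solver,
    structural sigma-6 solver) or ``oracle`` (exhaustive; any k including
    INF, within the oracle bound).
    """
    validate_k(k)
    abg = build_abg(s, d)
    if method == "oracle":
        score, tau = oracle_best(abg, k, cap=oracle_cap)
        dist = Fraction(2 * abg.n_star) - score
        return DoubleDistanceResult(dist, score, tau, k, "oracle")
    if method != "auto":
        raise ValueError(f"unknown method {method!r}")
    if k == 2:
        from .sigma4_solver import fix_common

        fix_common(abg)
        tau = abg.default_solution()
        score = k_score(abg, tau, 2)
        dist = Fraction(2 * abg.n_star) - score
        formula = double_distance_sigma2(s, d)
        if dist != formula:
            raise AssertionError(
                f"sigma-2 self-check failed: {dist} != {formula}"
            )
        return DoubleDistanceResult(dist, score, tau, k, "sigma2-formula")
    if k == 4:
        from .sigma4_solver import solve_sigma4

        res = solve_sigma4(abg)
        return DoubleDistanceResult(res.distance, res.score, res.solution, k, "sigma4-greedy")
    if k == 6:
        from .sigma6_solver import solve_sigma6

        res = solve_sigma6(abg)
        return DoubleDistanceResult(res.distance, res.score, res.solution, k, "sigma6-structural")
    raise ValueError(
        f"no polynomial solver for k={k}; use method='oracle' on small instances"
    )


def to_dot(abg: AmbiguousBreakpointGraph) -> str:
    """DOT rendering: candidate S-edges red (solid parallel / dashed crossed),
    D-edges black, telomere classes annotated."""
    ids = {v: f"v{i}" for i, v in enumerate(abg.vertices)}
    lines = ["graph ambiguous_breakpoint_graph {", "  node [shape=circle];"]
    for v in abg.vertices:
        in_s, in_d = v in abg.s_telomeres, v in abg.d_telomeres
        color = (
            "purple" if in_s and in_d else
            "lightblue" if in_s else
            "gray" if in_d else "white"
        )
        lines.append(f'  {ids[v]} [label="{v}", style=filled, fillcolor={color}];')
    for sq in abg.squares:
        for choice, edge in sq.all_edges():
            u, v = tuple(edge)
            style = "solid" if choice == PARALLEL else "dashed"
            lines.append(
                f'  {ids[u]} -- {ids[v]} [color=red, style={style}, '
                f'label="Q{sq.index}"];'
            )
    for u, v in abg.d_edges:
        lines.append(f"  {ids[u]} -- {ids[v]} [color=black];")
    lines.append("}")
    return "\n".join(lines) + "\n"
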