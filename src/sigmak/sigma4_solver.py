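"""Greedy linear-time solver for the sigma-4 disambiguation.

For k = 4 the players are valid 2-paths and valid 4-cycles.  After all
common adjacencies (2-cycles) are fixed and symmetric squares are resolved
arbitrarily, every valid 2-path is optimal and every valid 4-cycle is at
least co-optimal, so a single greedy sweep that induces each player it finds
is optimal regardless of traversal order.  Squares never touched by a player
are fixed to the parallel pair for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional

from .ambiguous_graph import (
    CROSSED,
    PARALLEL,
    AmbiguousBreakpointGraph,
    Solution,
    Square,
    k_score,
)


@dataclass
class FixReport:
    """What the preprocessing pinned down."""

    two_cycle_squares: list = field(default_factory=list)
    zero_paths: list = field(default_factory=list)
    symmetric_squares: list = field(default_factory=list)


@dataclass(frozen=True)
class SolveResult:
    score: Fraction
    solution: Solution
    distance: Fraction
    operations: int = 0


def _available(sq: Square, edge: frozenset) -> bool:
    return sq.fixed is None or edge in sq.pair(sq.fixed)


def available_s_edge_between(
    abg: AmbiguousBreakpointGraph, u, v
) -> Optional[tuple[Square, str]]:
    """The candidate S-edge {u, v} if it exists and is not masked."""
    si = abg.vertex_square.get(u)
    if si is None or abg.vertex_square.get(v) != si:
        return None
    sq = abg.square(si)
    edge = frozenset((u, v))
    try:
        choice = sq.choice_of_edge(edge)
    except ValueError:
        return None
    if not _available(sq, edge):
        return None
    return sq, choice


def available_s_edges_at(abg: AmbiguousBreakpointGraph, v) -> list:
    """Unmasked candidate S-edges at ``v`` as (other, square, choice)."""
    si = abg.vertex_square.get(v)
    if si is None:
        return []
    sq = abg.square(si)
    out = []
    for choice in (PARALLEL, CROSSED):
        if sq.fixed is not None and choice != sq.fixed:
            continue
        for edge in sq.pair(choice):
            if v in edge:
                (other,) = edge - {v}
                out.append((other, sq, choice))
    return out


def fix_common(abg: AmbiguousBreakpointGraph) -> FixReport:
    """Pin every square whose S-edge closes a 2-cycle with a parallel D-edge.

    Common adjacencies (2-cycles) and common telomeres (0-paths) are
    conserved by some optimal solution of every sigma-k disambiguation, so
    these fixes never cost score.
    """
    report = FixReport()
    for u, v in abg.d_edges:
        hit = available_s_edge_between(abg, u, v)
        if hit is None:
            continue
        sq, choice = hit
        sq.fix(choice)  # conflicting 2-cycles are impossible: degree-1 D-edges
        report.two_cycle_squares.append(sq.index)
    report.zero_paths = sorted(abg.s_telomeres & abg.d_telomeres)
    return report


def _is_symmetric(abg: AmbiguousBreakpointGraph, sq: Square) -> bool:
    for x, y in ((sq.ga, sq.gb), (sq.ba, sq.bb)):
        dx, dy = abg.vertex_d.get(x), abg.vertex_d.get(y)
        # (i) a D-edge joins the paralogous pair
        if dx == y:
            return True
        # (ii) both paralogous vertices are D-telomeres
        if x in abg.d_telomeres and y in abg.d_telomeres:
            return True
        # (iii) both carry D-edges leading directly to S-telomeres
        if (
            dx is not None
            and dy is not None
            and dx in abg.s_telomeres
            and dy in abg.s_telomeres
        ):
            return True
    return False


def fix_symmetric_squares(abg: AmbiguousBreakpointGraph) -> FixReport:
    """Fix squares whose two resolutions always score equally.

    Three patterns qualify: a D-edge joining paralogous vertices, D-telomeres
    on a paralogous pair, and D-edges from a paralogous pair straight to
    S-telomeres.  Each is fixed to the parallel pair.
    """
    report = FixReport()
    for sq in abg.squares:
        if sq.fixed is not None:
            continue
        if _is_symmetric(abg, sq):
            sq.fix(PARALLEL)
            report.symmetric_squares.append(sq.index)
    return report


def _find_player_through(abg: AmbiguousBreakpointGraph, sq: Square, edge: frozenset):
    """Valid 2-path or valid 4-cycle using candidate S-edge ``edge``.

    Returns the list of (square, choice) fixes inducing the player, or None.
    """
    u, v = sorted(edge)
    # 2-path: S-telomere --D-- a --S-- b --(D-telomere)
    for a, b in ((u, v), (v, u)):
        if b in abg.d_telomeres:
            t = abg.vertex_d.get(a)
            if t is not None and t in abg.s_telomeres:
                return [(sq, sq.choice_of_edge(edge))]
    # 4-cycle: u --S-- v --D-- x --S-- w --D-- u
    w = abg.vertex_d.get(u)
    x = abg.vertex_d.get(v)
    if w is None or x is None or w == v or x == u or w == x:
        return None
    hit = available_s_edge_between(abg, w, x)
    if hit is None:
        return None
    sq2, choice2 = hit
    choice1 = sq.choice_of_edge(edge)
    if sq2.index == sq.index and choice2 != choice1:
        return None  # incompatible edges of the same square
    fixes = [(sq, choice1)]
    if sq2.index != sq.index:
        fixes.append((sq2, choice2))
    return fixes


def solve_sigma4(abg: AmbiguousBreakpointGraph) -> SolveResult:
    """Optimal sigma-4 disambiguation by the greedy sweep.

    Mutates ``abg`` (squares end up fixed); the returned solution re-scores
    to the reported value by construction.
    """
    fix_common(abg)
    fix_symmetric_squares(abg)
    # elementary-operation count: one per D-edge scanned during the common
    # fix, one per square visited, one per candidate edge examined
    operations = len(abg.d_edges)
    for sq in abg.squares:
        operations += 1
        if sq.fixed is not None:
            continue
        for choice in (PARALLEL, CROSSED):
            if sq.fixed is not None:
                break
            for edge in sq.pair(choice):
                operations += 1
                fixes = _find_player_through(abg, sq, edge)
                if fixes is not None:
                    # a 2-path and a 4-cycle can never compete for a square
                    # once symmetric squares are gone; Square.fix would raise
                    for fsq, fchoice in fixes:
                        fsq.fix(fchoice)
                    break
    tau = abg.default_solution(PARALLEL)
    score = k_score(abg, tau, 4)
    distance = Fraction(2 * abg.n_star) - score
    return SolveResult(score, tau, distance, operations)
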