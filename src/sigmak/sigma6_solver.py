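"""Linear-time solver for the sigma-6 disambiguation.

For k = 6 the players are valid {2,4}-paths (weight 1/2) and valid
{4,6}-cycles (weight 1).  Players can intersect, and not every player is part
of an optimal solution, so greed fails.  The pipeline instead is:

1. fix common adjacencies (2-cycles) and symmetric squares;
2. *prune*: delete every edge that cannot belong to any player, leaving the
   pruned graph PG whose 6-score equals that of the full ambiguous graph;
3. solve each connected component independently: resolved components are
   single players; *triplets* (the one shape where a D-edge sits in four
   6-cycles) are scored locally; cycle-only components get the *straight
   solution* obtained by propagating one square's choice through all its
   neighbors; mixed components are reduced to a maximum-weight independent
   set on their *intersection graph*, which decomposes into path-lines,
   double-lines and cycle-bubbles/cycle-lines that are each solvable by an
   alternating selection with deferred "balanced links";
4. assemble the solution, fill untouched squares with the parallel pair and
   re-score it as a self-check.

Components whose shape falls outside the structural catalogue (the bounded
exceptional cases) are solved exactly by exhausting their resolutions when
they have at most ``ENUM_BOUND`` ambiguous squares, and otherwise by an exact
maximum-weight independent set computed by dynamic programming over a tree
decomposition of the intersection graph (linear-time on the bounded-treewidth
shapes these components can take).
"""

from __future__ import annotations

import itertools
import logging
from collections import defaultdict
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Optional

from .ambiguous_graph import (
    CROSSED,
    PARALLEL,
    AmbiguousBreakpointGraph,
    k_score,
)
from .breakpoint_graph import BreakpointGraph
from .genomes import Extremity
from .sigma4_solver import (
    SolveResult,
    available_s_edges_at,
    fix_common,
    fix_symmetric_squares,
)

log = logging.getLogger(__name__)

HALF = Fraction(1, 2)

#: Components with at most this many ambiguous squares may be solved by
#: exhausting their 2^m local resolutions when their shape is exceptional.
ENUM_BOUND = 12


class InternalError(AssertionError):
    """A structural postcondition that should be impossible was violated."""


class _Surprise(RuntimeError):
    """Component shape outside the structural catalogue; use the fallback."""


def _hat(v: Extremity) -> Extremity:
    return Extremity(v.family, v.side, "b" if v.copy == "a" else "a")


# ---------------------------------------------------------------------------
# Players

@dataclass(frozen=True)
class Player:
    """A valid cycle of length <= 6 or valid even path of length <= 4.

    ``vertices`` are in traversal order; for paths they run from the
    S-telomere end to the D-telomere end.  ``s_edges`` holds
    ``(square_index, edge)`` pairs.
    """

    kind: str  # "cycle" | "path"
    vertices: tuple
    s_edges: tuple
    d_edges: tuple

    @property
    def weight(self) -> Fraction:
        return Fraction(1) if self.kind == "cycle" else HALF

    @property
    def length(self) -> int:
        return len(self.s_edges) + len(self.d_edges)

    @property
    def key(self):
        return (
            frozenset(("S", si, e) for si, e in self.s_edges),
            frozenset(("D", e) for e in self.d_edges),
        )

    @property
    def sort_key(self):
        return (self.kind, tuple(sorted(self.vertices)))

    # path helpers ----------------------------------------------------------

    @property
    def s_tel(self):
        return self.vertices[0]

    @property
    def d_tel(self):
        return self.vertices[-1]

    @property
    def end_region(self) -> frozenset:
        """The D-edge hanging off the S-telomere end of a path."""
        return frozenset(self.vertices[:2])

    @property
    def inner_d(self) -> Optional[frozenset]:
        """The inner D-edge of a 4-path (None for 2-paths)."""
        if self.kind != "path" or len(self.d_edges) < 2:
            return None
        (inner,) = [e for e in self.d_edges if e != self.end_region]
        return inner


def _enumerate_players(abg: AmbiguousBreakpointGraph, counter: list) -> list[Player]:
    """All valid cycles (length <= 6) and even paths (length <= 4) that are
    compatible with the squares already fixed in ``abg``."""
    players: dict = {}

    def add(kind, vertices, s_edges, d_edges):
        p = Player(kind, tuple(vertices), tuple(s_edges), tuple(d_edges))
        players.setdefault(p.key, p)

    # paths: S-telomere --D-- a --S-- b [--D-- c --S-- z]
    for t in sorted(abg.s_telomeres):
        a = abg.vertex_d.get(t)
        if a is None:
            continue
        for b, sqa, _ca in available_s_edges_at(abg, a):
            counter[0] += 1
            if b == t:
                continue
            e1 = (sqa.index, frozenset((a, b)))
            if b in abg.d_telomeres:
                add("path", (t, a, b), (e1,), (frozenset((t, a)),))
            c = abg.vertex_d.get(b)
            if c is None or c in (t, a):
                continue
            for z, sqc, cc in available_s_edges_at(abg, c):
                counter[0] += 1
                if z in (t, a, b) or z not in abg.d_telomeres:
                    continue
                if sqc.index == sqa.index and cc != sqa.choice_of_edge(
                    frozenset((a, b))
                ):
                    continue
                add(
                    "path",
                    (t, a, b, c, z),
                    (e1, (sqc.index, frozenset((c, z)))),
                    (frozenset((t, a)), frozenset((b, c))),
                )

    # cycles: alternate D,S,... starting at each D-edge, close with an S-edge
    for u, v in abg.d_edges:
        # iterative DFS: state is (vertex tuple, s_edge list); the walk
        # alternates D,S,... so the last vertex always awaits an S-step
        frontier = [((u, v), ())]
        while frontier:
            verts, s_edges = frontier.pop()
            cur = verts[-1]
            for w, sqw, cw in available_s_edges_at(abg, cur):
                counter[0] += 1
                if any(
                    si == sqw.index and abg.square(si).choice_of_edge(e) != cw
                    for si, e in s_edges
                ):
                    continue
                new_s = s_edges + ((sqw.index, frozenset((cur, w))),)
                if w == u:
                    d_edges = tuple(
                        frozenset((verts[i], verts[i + 1]))
                        for i in range(0, len(verts) - 1, 2)
                    )
                    add("cycle", verts, new_s, d_edges)
                    continue
                if w in verts or len(new_s) == 3:
                    continue
                x = abg.vertex_d.get(w)
                if x is None or x in verts or x == w:
                    continue
                frontier.append((verts + (w, x), new_s))
    return sorted(players.values(), key=lambda p: p.sort_key)


# ---------------------------------------------------------------------------
# Pruned graph

@dataclass
class Component:
    vertices: frozenset
    s_edges: frozenset  # present candidate S-edges (frozenset vertex pairs)
    d_edges: frozenset
    squares: frozenset  # indices of squares with a present edge here
    ambiguous_squares: frozenset
    players: tuple  # Player instances fully inside the component

    @property
    def sort_key(self):
        return tuple(sorted(self.vertices))


@dataclass
class PrunedGraph:
    abg: AmbiguousBreakpointGraph
    players: list
    present_s: frozenset
    present_d: frozenset
    square_class: dict
    components: list
    zero_paths: tuple
    operations: int = 0


def prune(abg: AmbiguousBreakpointGraph) -> PrunedGraph:
    """{6}-prune the ambiguous graph: keep exactly the edges that occur in at
    least one player.  Requires common 2-cycles and symmetric squares to be
    fixed already.  Squares left with edges of a single pair are resolved and
    fixed accordingly; fully pruned squares are fixed to the parallel pair.
    The 6-score is unchanged by construction, since deleted edges belong to
    no player and players survive intact.
    """
    counter = [0]
    players = _enumerate_players(abg, counter)
    present_s: set = set()
    present_d: set = set()
    for p in players:
        for _si, e in p.s_edges:
            present_s.add(e)
        for e in p.d_edges:
            present_d.add(e)

    square_class: dict = {}
    for sq in abg.squares:
        par = [e for e in sq.pair(PARALLEL) if e in present_s]
        cro = [e for e in sq.pair(CROSSED) if e in present_s]
        if sq.fixed is not None:
            square_class[sq.index] = "fixed"
        elif par and cro:
            n = len(par) + len(cro)
            square_class[sq.index] = {4: "a", 3: "b", 2: "c"}[n]
        elif par or cro:
            square_class[sq.index] = "d" if len(par) + len(cro) == 2 else "e"
            sq.fix(PARALLEL if par else CROSSED)
        else:
            square_class[sq.index] = "pruned"
            sq.fix(PARALLEL)

    # connected components over present edges
    adj: dict = defaultdict(list)
    for e in present_s | present_d:
        u, v = tuple(e)
        adj[u].append(v)
        adj[v].append(u)
    comp_of: dict = {}
    comps_vertices: list = []
    for v in sorted(adj):
        if v in comp_of:
            continue
        cid = len(comps_vertices)
        stack = [v]
        comp_of[v] = cid
        bag = [v]
        while stack:
            x = stack.pop()
            for y in adj[x]:
                if y not in comp_of:
                    comp_of[y] = cid
                    bag.append(y)
                    stack.append(y)
        comps_vertices.append(bag)

    comp_s: dict = defaultdict(set)
    comp_d: dict = defaultdict(set)
    for e in present_s:
        comp_s[comp_of[next(iter(e))]].add(e)
    for e in present_d:
        comp_d[comp_of[next(iter(e))]].add(e)
    comp_players: dict = defaultdict(list)
    for p in players:
        comp_players[comp_of[p.vertices[0]]].append(p)

    ambiguous = {i for i, c in square_class.items() if c in ("a", "b", "c")}
    components = []
    for cid, bag in enumerate(comps_vertices):
        squares = frozenset(
            si
            for e in comp_s[cid]
            for si in {abg.vertex_square[x] for x in e}
        )
        components.append(
            Component(
                vertices=frozenset(bag),
                s_edges=frozenset(comp_s[cid]),
                d_edges=frozenset(comp_d[cid]),
                squares=squares,
                ambiguous_squares=frozenset(squares & ambiguous),
                players=tuple(comp_players[cid]),
            )
        )
    components.sort(key=lambda c: c.sort_key)
    zero_paths = tuple(sorted(abg.s_telomeres & abg.d_telomeres))
    return PrunedGraph(
        abg=abg,
        players=players,
        present_s=frozenset(present_s),
        present_d=frozenset(present_d),
        square_class=square_class,
        components=components,
        zero_paths=zero_paths,
        operations=counter[0],
    )


def classify_components(pg: PrunedGraph):
    """Partition into resolved cycles ``C``, resolved paths ``P`` (including
    0-paths) and ambiguous components ``M``; the 6-score of the pruned graph
    is ``|C| + |P|/2 + sum sigma6(M)``."""
    C, P, M = [], [], []
    by_key = {
        (frozenset(("S", si, e) for si, e in p.s_edges),
         frozenset(("D", e) for e in p.d_edges)): p
        for p in pg.players
    }
    for comp in pg.components:
        if comp.ambiguous_squares:
            M.append(comp)
            continue
        key = (
            frozenset(
                ("S", min(pg.abg.vertex_square[x] for x in e), e)
                for e in comp.s_edges
            ),
            frozenset(("D", e) for e in comp.d_edges),
        )
        player = by_key.get(key)
        if player is None:
            raise InternalError(
                "resolved component is not a single player: "
                f"{sorted(comp.vertices)}"
            )
        (C if player.kind == "cycle" else P).append(comp)
    P = P + [
        Component(frozenset((v,)), frozenset(), frozenset(), frozenset(),
                  frozenset(), ())
        for v in pg.zero_paths
    ]
    return C, P, M


# ---------------------------------------------------------------------------
# Local scoring and exhaustive enumeration

def _component_score(pg: PrunedGraph, comp: Component, assignment: dict) -> Fraction:
    """6-score contribution of ``comp`` under choices for its ambiguous
    squares (missing squares default to parallel).

    Only genuine players count: cycles of length <= 6 and even paths of
    length <= 4 whose endpoints really are telomeres of the respective
    genomes.  Chosen-but-pruned edges never occur in any player, so they are
    excluded without affecting the score.
    """
    abg = pg.abg
    s_edges = []
    for si in comp.squares:
        sq = abg.square(si)
        ch = sq.fixed if sq.fixed is not None else assignment.get(si, PARALLEL)
        for e in sq.pair(ch):
            if e in comp.s_edges:
                s_edges.append(tuple(e))
    bg = BreakpointGraph(
        sorted(comp.vertices),
        s_edges,
        [tuple(e) for e in comp.d_edges],
        label1="2S",
        label2="D",
    )
    total = Fraction(0)
    for kind, order in bg.components():
        if kind == "cycle":
            if len(order) <= 6:
                total += 1
            continue
        length = len(order) - 1
        if length == 0 or length % 2 or length > 4:
            continue
        genuine = True
        for v in (order[0], order[-1]):
            if v not in bg.adj1 and v not in abg.s_telomeres:
                genuine = False
            if v not in bg.adj2 and v not in abg.d_telomeres:
                genuine = False
        if genuine:
            total += HALF
    return total


def _enumerate_component(pg: PrunedGraph, comp: Component):
    """Exact local solution by exhausting all resolutions of the component's
    ambiguous squares; deterministic lexicographic tie-break."""
    free = sorted(comp.ambiguous_squares)
    best = None
    for values in itertools.product((PARALLEL, CROSSED), repeat=len(free)):
        assignment = dict(zip(free, values))
        score = _component_score(pg, comp, assignment)
        if best is None or score > best[0]:
            best = (score, assignment)
    return best


# ---------------------------------------------------------------------------
# Triplets

@dataclass(frozen=True)
class Triplet:
    component: Component
    saturated: bool
    score: Fraction
    choices: dict


def _is_triplet(pg: PrunedGraph, comp: Component) -> bool:
    if len(comp.ambiguous_squares) != 3 or comp.squares != comp.ambiguous_squares:
        return False
    if any(p.kind == "path" for p in comp.players):
        return False
    incident = {v for e in comp.s_edges | comp.d_edges for v in e}
    square_vertices = [
        v for si in comp.squares for v in pg.abg.square(si).vertices
    ]
    pruned = [v for v in square_vertices if v not in incident]
    if len(pruned) > 2:
        return False
    if len(pruned) == 2 and (
        pg.abg.vertex_square[pruned[0]] == pg.abg.vertex_square[pruned[1]]
    ):
        return False
    for e in comp.d_edges:
        u, v = tuple(e)
        if pg.abg.vertex_square[u] == pg.abg.vertex_square[v]:
            return False
        partner = frozenset((_hat(u), _hat(v)))
        if partner not in comp.d_edges and not (
            _hat(u) in pruned or _hat(v) in pruned
        ):
            return False
    return True


def detect_triplets(pg: PrunedGraph) -> list[Triplet]:
    """Identify triplet components and fix an optimal local solution.

    A saturated triplet (all three square pairs joined by two paralogous
    D-edges) scores 2; removing one D-edge gives an unsaturated triplet
    scoring 1.  The local exhaustive enumeration confirms the score.
    """
    out = []
    for comp in pg.components:
        if comp.ambiguous_squares and _is_triplet(pg, comp):
            score, choices = _enumerate_component(pg, comp)
            saturated = len(comp.d_edges) == 6
            expected = Fraction(2) if saturated else Fraction(1)
            if score != expected:
                raise InternalError(
                    f"triplet scored {score}, expected {expected}"
                )
            out.append(Triplet(comp, saturated, score, choices))
    return out


# ---------------------------------------------------------------------------
# Straight solution for cycle-only components (cycle-bubbles)

@dataclass(frozen=True)
class BubbleSolution:
    choices: dict
    alt_choices: dict
    score: Fraction
    alt_score: Fraction

    @property
    def balanced(self) -> bool:
        return self.score == self.alt_score

    @property
    def best_choices(self) -> dict:
        return self.choices if self.score >= self.alt_score else self.alt_choices

    @property
    def best_score(self) -> Fraction:
        return max(self.score, self.alt_score)


def _propagate_straight(
    abg: AmbiguousBreakpointGraph,
    ambiguous: Iterable[int],
    cycles: list,
) -> dict:
    """Resolve all given squares by propagating pair choices along the unique
    cycle player through each chosen edge (the straight solution)."""
    by_edge: dict = defaultdict(list)
    for cyc in cycles:
        for si, e in cyc.s_edges:
            by_edge[e].append(cyc)
    ambiguous = sorted(set(ambiguous))
    choices: dict = {}
    for start in ambiguous:
        if start in choices:
            continue
        stack = [(start, PARALLEL)]
        while stack:
            si, ch = stack.pop()
            if si in choices:
                if choices[si] != ch:
                    raise _Surprise("straight propagation conflict")
                continue
            choices[si] = ch
            sq = abg.square(si)
            for e in sq.pair(ch):
                through = by_edge.get(e, [])
                if len(through) > 1:
                    raise _Surprise("ambiguous S-edge in several cycles")
                for cyc in through:
                    for sj, ej in cyc.s_edges:
                        sqj = abg.square(sj)
                        if sqj.fixed is not None:
                            continue
                        stack.append((sj, sqj.choice_of_edge(ej)))
    return choices


def _induced_cycles(abg, cycles, choices: dict) -> list:
    out = []
    for cyc in cycles:
        ok = True
        for si, e in cyc.s_edges:
            sq = abg.square(si)
            if sq.fixed is not None:
                continue
            if choices.get(si) != sq.choice_of_edge(e):
                ok = False
                break
        if ok:
            out.append(cyc)
    return out


def straight_bubble_solution(pg: PrunedGraph, comp: Component) -> BubbleSolution:
    """Straight solution of a cycle-only ambiguous component and its
    complement (every ambiguous square switched); the better of the two (or
    either, when balanced) is optimal for the component."""
    if any(p.kind == "path" for p in comp.players):
        raise ValueError("straight solution requires a cycle-only component")
    choices = _propagate_straight(
        pg.abg, comp.ambiguous_squares, list(comp.players)
    )
    alt = {
        si: (CROSSED if ch == PARALLEL else PARALLEL) for si, ch in choices.items()
    }
    score = _component_score(pg, comp, choices)
    alt_score = _component_score(pg, comp, alt)
    return BubbleSolution(choices, alt, score, alt_score)


# ---------------------------------------------------------------------------
# Intersection graph

@dataclass
class IntersectionGraph:
    players: list
    edges: set  # frozensets of player-index pairs
    kinds: dict  # pair -> "cc" | "plug" | "end_s" | "end_d" | "rung" | "weird"
    adj: dict

    def weight(self, i: int) -> Fraction:
        return self.players[i].weight

    def neighbors(self, i: int) -> set:
        return self.adj.get(i, set())


def _classify_intersection(p: Player, q: Player) -> str:
    shared = set(p.vertices) & set(q.vertices)
    if p.kind == "cycle" and q.kind == "cycle":
        return "cc"
    if p.kind != q.kind:
        path, cyc = (p, q) if p.kind == "path" else (q, p)
        inner = path.inner_d
        if inner is not None and shared == set(inner):
            return "plug"
        return "weird"
    # two paths
    if p.s_tel == q.s_tel:
        return "end_s" if shared == set(p.end_region) else "weird"
    if p.d_tel == q.d_tel:
        return "end_d" if shared == {p.d_tel} else "weird"
    ip, iq = p.inner_d, q.inner_d
    if ip is not None and ip == iq and shared == set(ip):
        return "rung"
    return "weird"


def build_intersection_graph(comp: Component) -> IntersectionGraph:
    """Vertices: players (weight 1/2 per {2,4}-path, 1 per {4,6}-cycle);
    edges: pairs of players sharing at least one vertex."""
    players = list(comp.players)
    v2p: dict = defaultdict(set)
    for i, p in enumerate(players):
        for v in p.vertices:
            v2p[v].add(i)
    edges = set()
    for group in v2p.values():
        for i, j in itertools.combinations(sorted(group), 2):
            edges.add(frozenset((i, j)))
    kinds = {
        pair: _classify_intersection(players[min(pair)], players[max(pair)])
        for pair in edges
    }
    adj: dict = defaultdict(set)
    for pair in edges:
        i, j = tuple(pair)
        adj[i].add(j)
        adj[j].add(i)
    return IntersectionGraph(players, edges, kinds, dict(adj))


# ---------------------------------------------------------------------------
# Exact MWIS via tree-decomposition DP (fallback for large odd shapes)

def _mwis_exact(nodes: list, edges: set, weight: dict):
    """Maximum-weight independent set, exact for any graph; fast when the
    tree decomposition found by the min-degree heuristic is thin."""
    if not nodes:
        return Fraction(0), set()
    import networkx as nx
    from networkx.algorithms.approximation import treewidth_min_degree

    G = nx.Graph()
    G.add_nodes_from(nodes)
    G.add_edges_from(tuple(e) for e in edges)
    adj = {v: set(G.neighbors(v)) for v in nodes}
    width, T = treewidth_min_degree(G)
    if width > 16:
        raise InternalError(f"unexpectedly dense component (treewidth {width})")
    bags = list(T.nodes)
    root = bags[0]
    parent = {root: None}
    order = [root]
    for bag in order:
        for nb in T.neighbors(bag):
            if nb not in parent:
                parent[nb] = bag
                order.append(nb)
    children: dict = defaultdict(list)
    for bag, par in parent.items():
        if par is not None:
            children[par].append(bag)

    def independent_subsets(bag):
        items = sorted(bag)
        for r in range(len(items) + 1):
            for combo in itertools.combinations(items, r):
                if all(b not in adj[a] for a, b in itertools.combinations(combo, 2)):
                    yield frozenset(combo)

    dp: dict = {}
    for bag in reversed(order):
        table = {}
        for S in independent_subsets(bag):
            val = sum((weight[v] for v in S), Fraction(0))
            picks = []
            feasible = True
            for ch in children[bag]:
                inter = bag & ch
                best = None
                for Sc, (vc, _) in dp[ch].items():
                    if Sc & inter == S & inter:
                        cand = vc - sum((weight[v] for v in Sc & S), Fraction(0))
                        if best is None or cand > best[0]:
                            best = (cand, Sc)
                if best is None:
                    feasible = False
                    break
                val += best[0]
                picks.append((ch, best[1]))
            if feasible:
                table[S] = (val, picks)
        dp[bag] = table

    best_state = max(dp[root].items(), key=lambda kv: kv[1][0])
    selected: set = set()
    stack = [(root, best_state[0])]
    while stack:
        bag, S = stack.pop()
        selected |= S
        for ch, Sc in dp[bag][S][1]:
            stack.append((ch, Sc))
    total = sum((weight[v] for v in selected), Fraction(0))
    return total, selected


# ---------------------------------------------------------------------------
# Flow decomposition of the intersection graph

@dataclass
class PathLine:
    vertices: list  # player indices in line order
    cyclic: bool = False
    saturated: bool = False

    @property
    def length(self) -> int:
        return len(self.vertices)


@dataclass
class DoubleLine:
    upper: PathLine
    lower: PathLine
    kind: str = "isolated"  # isolated | terminal | link (set by the solver)


@dataclass
class CycleBubble:
    cycles: list  # player indices
    line_order: Optional[list] = None  # set when the bubble is a cycle-line

    @property
    def is_line(self) -> bool:
        return self.line_order is not None


@dataclass
class FlowDecomposition:
    path_lines: list
    double_lines: list
    bubbles: list


def _build_path_lines(ig: IntersectionGraph) -> list[PathLine]:
    """Chains of path players linked by telomere (end) intersections."""
    path_ids = [i for i, p in enumerate(ig.players) if p.kind == "path"]
    end_adj: dict = defaultdict(set)
    for pair in ig.edges:
        if ig.kinds[pair] in ("end_s", "end_d"):
            i, j = tuple(pair)
            end_adj[i].add(j)
            end_adj[j].add(i)
    for i in path_ids:
        if len(end_adj[i]) > 2:
            raise _Surprise("path player with more than two end-intersections")
    lines = []
    seen: set = set()
    key = lambda i: ig.players[i].sort_key
    # open lines first
    for i in sorted(path_ids, key=key):
        if i in seen or len(end_adj[i]) > 1:
            continue
        order = [i]
        seen.add(i)
        cur, prev = i, None
        while True:
            nxt = [x for x in end_adj[cur] if x != prev]
            if not nxt:
                break
            prev, cur = cur, nxt[0]
            if cur in seen:
                raise _Surprise("tangled path-line")
            order.append(cur)
            seen.add(cur)
        lines.append(PathLine(order))
    # remaining are cyclic lines
    for i in sorted(path_ids, key=key):
        if i in seen:
            continue
        order = [i]
        seen.add(i)
        prev, cur = i, min(end_adj[i], key=key)
        while cur != i:
            order.append(cur)
            seen.add(cur)
            nxt = [x for x in end_adj[cur] if x != prev]
            if len(nxt) != 1:
                raise _Surprise("tangled cyclic path-line")
            prev, cur = cur, nxt[0]
        lines.append(PathLine(order, cyclic=True))
    return lines


def _pair_double_lines(ig: IntersectionGraph, lines: list[PathLine]):
    """Match saturated path-lines into double-lines via their rungs.

    Every rung must pair same-numbered vertices of two parallel lines of the
    same length; anything else is outside the catalogue.
    """
    rung_of: dict = {}
    for pair in ig.edges:
        if ig.kinds[pair] == "rung":
            i, j = tuple(pair)
            if i in rung_of or j in rung_of:
                raise _Surprise("path player with two rungs")
            rung_of[i] = j
            rung_of[j] = i
    line_of = {v: ln for ln in lines for v in ln.vertices}
    double_lines = []
    used: set = set()
    for ln in lines:
        if id(ln) in used:
            continue
        rungs = [rung_of.get(v) for v in ln.vertices]
        if all(r is None for r in rungs):
            continue
        if ln.cyclic:
            # cyclic double-lines are isolated; let the caller fall back to
            # the exact solver for these rare closed shapes
            raise _Surprise("cyclic line with rungs")
        if any(r is None for r in rungs):
            raise _Surprise("partially saturated path-line")
        partners = {line_of[r] for r in rungs}
        if len(partners) != 1:
            raise _Surprise("rungs leaving to several lines")
        other = partners.pop()
        if other is ln or other.cyclic or other.length != ln.length:
            raise _Surprise("unmatched double-line pairing")
        if rungs == list(other.vertices):
            aligned = True
        elif rungs == list(reversed(other.vertices)):
            other.vertices.reverse()
            aligned = True
        else:
            aligned = False
        if not aligned:
            raise _Surprise("rungs do not pair same-numbered vertices")
        ln.saturated = other.saturated = True
        used.add(id(ln))
        used.add(id(other))
        double_lines.append(DoubleLine(upper=ln, lower=other))
    return double_lines


def _bubbles(ig: IntersectionGraph) -> list[CycleBubble]:
    cycle_ids = [i for i, p in enumerate(ig.players) if p.kind == "cycle"]
    cadj: dict = defaultdict(set)
    for pair in ig.edges:
        if ig.kinds[pair] == "cc":
            i, j = tuple(pair)
            cadj[i].add(j)
            cadj[j].add(i)
    seen: set = set()
    bubbles = []
    key = lambda i: ig.players[i].sort_key
    for i in sorted(cycle_ids, key=key):
        if i in seen:
            continue
        bag = [i]
        seen.add(i)
        stack = [i]
        while stack:
            x = stack.pop()
            for y in cadj[x]:
                if y not in seen:
                    seen.add(y)
                    bag.append(y)
                    stack.append(y)
        bubble = CycleBubble(sorted(bag, key=key))
        # line detection: a simple open chain of cycles
        degs = {c: len(cadj[c] & set(bag)) for c in bag}
        ends = [c for c in bag if degs[c] <= 1]
        if len(bag) == 1:
            bubble.line_order = list(bag)
        elif all(d <= 2 for d in degs.values()) and len(ends) == 2:
            order = [min(ends, key=key)]
            prev = None
            while len(order) < len(bag):
                cur = order[-1]
                nxt = [x for x in cadj[cur] & set(bag) if x != prev]
                if len(nxt) != 1:
                    order = None
                    break
                prev = cur
                order.append(nxt[0])
            bubble.line_order = order
        bubbles.append(bubble)
    return bubbles


def decompose_flows(ig: IntersectionGraph) -> FlowDecomposition:
    lines = _build_path_lines(ig)
    double_lines = _pair_double_lines(ig, lines)
    bubbles = _bubbles(ig)
    return FlowDecomposition(lines, double_lines, bubbles)


# ---------------------------------------------------------------------------
# Structural solver for mixed ambiguous components

def _bubble_alternatives(pg, comp, ig, bubble):
    """Straight solution of the bubble's cycles and its complement, as the
    two disjoint sets of cycles they induce."""
    abg = pg.abg
    cycles = [ig.players[i] for i in bubble.cycles]
    amb = {
        si
        for cyc in cycles
        for si, _e in cyc.s_edges
        if abg.square(si).fixed is None
    }
    if not amb:
        raise _Surprise("bubble with a forced cycle")
    choices = _propagate_straight(abg, amb, cycles)
    alt = {si: (CROSSED if ch == PARALLEL else PARALLEL) for si, ch in choices.items()}
    induced_a = set(_induced_cycles(abg, cycles, choices))
    induced_b = set(_induced_cycles(abg, cycles, alt))
    ind_a = {i for i in bubble.cycles if ig.players[i] in induced_a}
    ind_b = {i for i in bubble.cycles if ig.players[i] in induced_b}
    if ind_a & ind_b or (ind_a | ind_b) != set(bubble.cycles):
        raise _Surprise("bubble cycles not split by the straight alternatives")
    return ind_a, ind_b


def solve_flows(pg: PrunedGraph, comp: Component, ig: IntersectionGraph):
    """Structural solution of a mixed ambiguous component.

    Returns ``(score, selected_player_ids, choices)``.  Raises
    :class:`_Surprise` when the component's shape falls outside the
    path-line / double-line / cycle-bubble catalogue; the caller then uses
    the exact fallback.
    """
    if any(k == "weird" for k in ig.kinds.values()):
        raise _Surprise("unclassifiable intersection")
    abg = pg.abg
    for i, p in enumerate(ig.players):
        if all(abg.square(si).fixed is not None for si, _e in p.s_edges):
            raise _Surprise("component contains a forced player")

    flows = decompose_flows(ig)
    in_double: set = set()
    for dl in flows.double_lines:
        in_double |= set(dl.upper.vertices) | set(dl.lower.vertices)

    line_of = {v: ln for ln in flows.path_lines for v in ln.vertices}

    def is_line_end(pid: int) -> bool:
        ln = line_of[pid]
        return (not ln.cyclic) and (
            pid == ln.vertices[0] or pid == ln.vertices[-1]
        )

    selected: set = set()
    deferred: list = []  # (left_pid, right_pid, avoid_left_set, avoid_right_set)

    # -- cycle-bubbles ------------------------------------------------------
    for bubble in flows.bubbles:
        ind_a, ind_b = _bubble_alternatives(pg, comp, ig, bubble)
        path_ints = sorted(
            (c, q)
            for c in bubble.cycles
            for q in ig.neighbors(c)
            if ig.players[q].kind == "path"
        )
        if len(ind_a) != len(ind_b):
            selected |= ind_a if len(ind_a) > len(ind_b) else ind_b
            continue
        if not path_ints:
            selected |= ind_a
            continue
        if len(path_ints) == 1:
            c, _q = path_ints[0]
            selected |= ind_b if c in ind_a else ind_a
            continue
        # >= 2 path intersections: only even cycle-lines with plug
        # connections are unbounded; everything else is a bounded exception
        if not bubble.is_line:
            raise _Surprise("balanced non-line bubble with several paths")
        order = bubble.line_order
        first, last = order[0], order[-1]
        ints_by_cycle: dict = defaultdict(list)
        for c, q in path_ints:
            ints_by_cycle[c].append(q)
        if set(ints_by_cycle) - {first, last}:
            raise _Surprise("cycle-line with a non-terminal path connection")
        if any(len(v) > 1 for v in ints_by_cycle.values()):
            raise _Surprise("cycle-line end with several path connections")
        plugs = {c: qs[0] for c, qs in ints_by_cycle.items()}
        if any(q in in_double or not is_line_end(q) for q in plugs.values()):
            raise _Surprise("cycle-line connection that is not a plug")
        if first in plugs and last in plugs:
            avoid_first = ind_b if first in ind_a else ind_a
            avoid_last = ind_b if last in ind_a else ind_a
            if avoid_first == avoid_last:
                raise _Surprise("cycle-line plugs not on opposite alternatives")
            deferred.append(
                (plugs[first], plugs[last], avoid_first, avoid_last)
            )
            continue
        c = first if first in plugs else last
        selected |= ind_b if c in ind_a else ind_a

    # -- double-lines -------------------------------------------------------
    for dl in flows.double_lines:
        up, lo = dl.upper.vertices, dl.lower.vertices
        ell = len(up)
        set0 = set(up[0::2]) | set(lo[1::2])
        set1 = set(up[1::2]) | set(lo[0::2])
        ends = {up[0], lo[0], up[-1], lo[-1]}
        outer = []  # (dl_vertex, outer_pid, side) side 0=left, 1=right
        for v in set(up) | set(lo):
            for q in ig.neighbors(v):
                if q in set(up) | set(lo):
                    continue
                if ig.players[q].kind == "cycle":
                    raise _Surprise("double-line vertex touching a cycle")
                if v not in ends:
                    raise _Surprise("double-line with a mid-line connection")
                side = 0 if v in (up[0], lo[0]) else 1
                outer.append((v, q, side))
        if ell == 1 and len(outer) > 1:
            raise _Surprise("length-1 double-line with several connections")
        if not outer:
            dl.kind = "isolated"
            selected |= set0
            continue
        if len(outer) == 1:
            dl.kind = "terminal"
            v, _q, _side = outer[0]
            selected |= set1 if v in set0 else set0
            continue
        if len(outer) == 2 and {o[2] for o in outer} == {0, 1}:
            dl.kind = "link"
            (u, uq, _), (v, vq, _) = sorted(outer, key=lambda o: o[2])
            single_sided = (u in up) == (v in up)
            balanced = (ell % 2 == 1) != single_sided
            avoid_u = set1 if u in set0 else set0
            avoid_v = set1 if v in set0 else set0
            if not balanced:
                if avoid_u != avoid_v:
                    raise _Surprise("unbalanced link without a free side")
                selected |= avoid_u
                continue
            deferred.append((uq, vq, avoid_u, avoid_v))
            continue
        raise _Surprise("double-line with unexpected connections")

    # -- remaining unsaturated path-lines ------------------------------------
    blocked = {q for i in selected for q in ig.neighbors(i)}
    available = [
        i
        for i, p in enumerate(ig.players)
        if p.kind == "path" and i not in in_double and i not in blocked
    ]
    avail_set = set(available)
    fl_adj: dict = {i: set() for i in available}
    for pair in ig.edges:
        if ig.kinds[pair] in ("end_s", "end_d"):
            i, j = tuple(pair)
            if i in avail_set and j in avail_set:
                fl_adj[i].add(j)
                fl_adj[j].add(i)
    for left, right, _a, _b in deferred:
        if left in avail_set and right in avail_set:
            fl_adj[left].add(right)
            fl_adj[right].add(left)
    key = lambda i: ig.players[i].sort_key
    seen: set = set()
    for start in sorted(available, key=key):
        if start in seen:
            continue
        bag = {start}
        stack = [start]
        while stack:
            x = stack.pop()
            for y in fl_adj[x]:
                if y not in bag:
                    bag.add(y)
                    stack.append(y)
        seen |= bag
        if any(len(fl_adj[x] & bag) > 2 for x in bag):
            raise _Surprise("final path-line is not a simple chain")
        ends = sorted((x for x in bag if len(fl_adj[x] & bag) <= 1), key=key)
        if ends:
            order = [ends[0]]
            prev = None
            while True:
                nxt = [x for x in fl_adj[order[-1]] & bag if x != prev]
                if not nxt:
                    break
                prev = order[-1]
                order.append(nxt[0])
            if len(order) != len(bag):
                raise _Surprise("disconnected final path-line")
            selected |= set(order[0::2])
        else:
            start2 = min(bag, key=key)
            order = [start2]
            prev = None
            while True:
                nxt = sorted(
                    (x for x in fl_adj[order[-1]] & bag if x != prev), key=key
                )
                if not nxt or nxt[0] == start2:
                    break
                prev = order[-1]
                order.append(nxt[0])
            ell = len(order)
            if ell != len(bag):
                raise _Surprise("tangled cyclic final path-line")
            picks = list(range(0, ell, 2))
            if ell % 2 and picks and picks[-1] == ell - 1:
                picks.pop()
            selected |= {order[i] for i in picks}

    # -- deferred balanced links ---------------------------------------------
    for left, right, avoid_left, avoid_right in deferred:
        if left in selected and right in selected:
            raise InternalError("both sides of a balanced link selected")
        if left in selected:
            selected |= avoid_left
        elif right in selected:
            selected |= avoid_right
        else:
            selected |= avoid_left

    # -- validate and convert ------------------------------------------------
    for pair in ig.edges:
        i, j = tuple(pair)
        if i in selected and j in selected:
            raise _Surprise("selection is not independent")
    choices: dict = {}
    for i in sorted(selected):
        for si, e in ig.players[i].s_edges:
            sq = abg.square(si)
            if sq.fixed is not None:
                continue
            ch = sq.choice_of_edge(e)
            if choices.setdefault(si, ch) != ch:
                raise InternalError("disjoint selected players disagree on a square")
    score = sum((ig.players[i].weight for i in selected), Fraction(0))
    return score, selected, choices


# ---------------------------------------------------------------------------
# Component dispatcher and full pipeline

def _solve_fallback(pg: PrunedGraph, comp: Component, enum_bound: int):
    if len(comp.ambiguous_squares) <= enum_bound:
        return _enumerate_component(pg, comp)
    log.info(
        "component with %d ambiguous squares solved by exact MWIS",
        len(comp.ambiguous_squares),
    )
    ig = build_intersection_graph(comp)
    abg = pg.abg
    forced = {
        i
        for i, p in enumerate(ig.players)
        if all(abg.square(si).fixed is not None for si, _e in p.s_edges)
    }
    blocked = {q for i in forced for q in ig.neighbors(i)} - forced
    nodes = [i for i in range(len(ig.players)) if i not in forced | blocked]
    node_set = set(nodes)
    edges = {
        pair for pair in ig.edges if set(pair) <= node_set
    }
    weight = {i: ig.players[i].weight for i in nodes}
    total, chosen = _mwis_exact(nodes, edges, weight)
    chosen |= forced
    total += sum((ig.players[i].weight for i in forced), Fraction(0))
    choices: dict = {}
    for i in sorted(chosen):
        for si, e in ig.players[i].s_edges:
            sq = abg.square(si)
            if sq.fixed is None:
                choices[si] = sq.choice_of_edge(e)
    check = _component_score(pg, comp, choices)
    if check != total:
        raise InternalError(
            f"MWIS fallback self-check failed: {check} != {total}"
        )
    return total, choices


def _solve_component(pg: PrunedGraph, comp: Component, enum_bound: int):
    if _is_triplet(pg, comp):
        return _enumerate_component(pg, comp)
    try:
        if all(p.kind == "cycle" for p in comp.players):
            sol = straight_bubble_solution(pg, comp)
            return sol.best_score, sol.best_choices
        ig = build_intersection_graph(comp)
        score, _selected, choices = solve_flows(pg, comp, ig)
        check = _component_score(pg, comp, choices)
        if check != score:
            raise _Surprise(
                f"structural self-check failed ({check} != {score})"
            )
        return score, choices
    except _Surprise as exc:
        log.debug("component fallback (%s)", exc)
        return _solve_fallback(pg, comp, enum_bound)


def solve_sigma6(
    abg: AmbiguousBreakpointGraph, enum_bound: int = ENUM_BOUND
) -> SolveResult:
    """Optimal sigma-6 disambiguation.

    Mutates ``abg`` (common/symmetric/resolved squares end up fixed).  The
    returned solution is independently re-scored; a mismatch with the
    assembled component scores raises :class:`InternalError`.
    """
    fix_common(abg)
    fix_symmetric_squares(abg)
    pg = prune(abg)
    C, P, M = classify_components(pg)
    total = Fraction(len(C)) + Fraction(len(P), 2)
    choices: dict = {}
    for comp in M:
        score, comp_choices = _solve_component(pg, comp, enum_bound)
        total += score
        choices.update(comp_choices)
    tau = abg.complete(choices, fill=PARALLEL)
    score = k_score(abg, tau, 6)
    if score != total:
        raise InternalError(
            f"sigma-6 assembly self-check failed: induced {score}, "
            f"assembled {total}"
        )
    distance = Fraction(2 * abg.n_star) - score
    return SolveResult(score, tau, distance, pg.operations)


# ---------------------------------------------------------------------------
# DOT exports

def pruned_to_dot(pg: PrunedGraph) -> str:
    """DOT rendering of the pruned graph: preserved candidate S-edges red
    (annotated with their square), preserved D-edges black."""
    vertices = sorted({v for e in pg.present_s | pg.present_d for v in e})
    ids = {v: f"v{i}" for i, v in enumerate(vertices)}
    lines = ["graph pruned_graph {", "  node [shape=circle];"]
    for v in vertices:
        in_s = v in pg.abg.s_telomeres
        in_d = v in pg.abg.d_telomeres
        color = (
            "purple" if in_s and in_d else
            "lightblue" if in_s else
            "gray" if in_d else "white"
        )
        lines.append(f'  {ids[v]} [label="{v}", style=filled, fillcolor={color}];')
    for e in sorted(pg.present_s, key=sorted):
        u, v = sorted(e)
        si = pg.abg.vertex_square[u]
        lines.append(f'  {ids[u]} -- {ids[v]} [color=red, label="Q{si}"];')
    for e in sorted(pg.present_d, key=sorted):
        u, v = sorted(e)
        lines.append(f"  {ids[u]} -- {ids[v]} [color=black];")
    lines.append("}")
    return "\n".join(lines) + "\n"


def intersection_to_dot(ig: IntersectionGraph) -> str:
    """DOT rendering of an intersection graph: players as nodes annotated
    with kind and weight."""
    lines = ["graph intersection_graph {", "  node [shape=box];"]
    for i, p in enumerate(ig.players):
        label = f"{p.kind} len {p.length} w {p.weight}"
        lines.append(f'  p{i} [label="{label}"];')
    for pair in sorted(ig.edges, key=sorted):
        i, j = sorted(pair)
        lines.append(f'  p{i} -- p{j} [label="{ig.kinds[pair]}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"
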