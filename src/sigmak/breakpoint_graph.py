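"""Breakpoint graph of a canonical genome pair and the sigma-k distance family.

For two singular genomes over the same ``n*`` families, the breakpoint graph
has one vertex per gene extremity and one edge per adjacency of each genome.
Every vertex has at most one edge per genome, so the components are cycles of
even length alternating between the two genomes, and paths.  With ``c_i`` the
number of i-cycles and ``p_j`` the number of j-paths,

    sigma_k = c_2 + c_4 + ... + c_k + (p_0 + p_2 + ... + p_{k-2}) / 2
    d_{sigma_k} = n* - sigma_k

``k = 2`` gives the breakpoint distance, ``k = INF`` the DCJ
(double-cut-and-join) distance, and the distance is non-increasing in ``k``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Hashable, Iterator

from .genomes import HEAD, TAIL, Extremity, Genome, adjacency_multiset

#: Token selecting the DCJ (sigma-infinity) distance.  A dedicated token, not
#: a large integer, so APIs and the CLI are unambiguous.
INF = float("inf")


def validate_k(k) -> None:
    if k == INF:
        return
    if not isinstance(k, int) or k < 2 or k % 2 != 0:
        raise ValueError(f"k must be an even integer >= 2 or INF, got {k!r}")


class CanonicalPairError(ValueError):
    """The two genomes are not a canonical pair."""


@dataclass
class BreakpointGraph:
    """Multigraph on extremities with one edge class per genome.

    Vertices are arbitrary hashable extremity identifiers; ``edges1`` and
    ``edges2`` each use every vertex at most once.  A vertex with no edge of a
    class is a telomere of that genome.
    """

    vertices: list
    edges1: list[tuple[Hashable, Hashable]]
    edges2: list[tuple[Hashable, Hashable]]
    label1: str = "genome1"
    label2: str = "genome2"
    adj1: dict = field(init=False, repr=False)
    adj2: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.adj1 = self._index(self.edges1, self.label1)
        self.adj2 = self._index(self.edges2, self.label2)
        vs = set(self.vertices)
        for m in (self.adj1, self.adj2):
            for u in m:
                if u not in vs:
                    raise ValueError(f"edge endpoint {u!r} is not a vertex")

    @staticmethod
    def _index(edges, label) -> dict:
        adj: dict = {}
        for u, v in edges:
            if u in adj or v in adj:
                raise ValueError(f"vertex reused by two {label} edges")
            adj[u] = v
            adj[v] = u
        return adj

    def n_edges(self) -> int:
        return len(self.edges1) + len(self.edges2)

    def telomeres1(self) -> set:
        return {v for v in self.vertices if v not in self.adj1}

    def telomeres2(self) -> set:
        return {v for v in self.vertices if v not in self.adj2}

    def components(self) -> Iterator[tuple[str, list]]:
        """Yield ``(kind, vertices-in-order)`` with kind ``cycle`` or ``path``.

        Path vertices are listed endpoint to endpoint; cycle vertices in cycle
        order.  Length in edges is ``len(vs) - 1`` for a path (0 for an
        isolated vertex) and ``len(vs)`` for a cycle.
        """
        seen: set = set()
        # paths first: start from vertices missing at least one edge class
        for v in self.vertices:
            if v in seen:
                continue
            in1, in2 = v in self.adj1, v in self.adj2
            if in1 and in2:
                continue
            seen.add(v)
            order = [v]
            if in1 or in2:
                use, other = (self.adj1, self.adj2) if in1 else (self.adj2, self.adj1)
                cur = v
                while cur in use:
                    cur = use[cur]
                    order.append(cur)
                    seen.add(cur)
                    use, other = other, use
            yield "path", order
        # remaining components are cycles
        for v in self.vertices:
            if v in seen:
                continue
            seen.add(v)
            order = [v]
            cur = self.adj1[v]
            use, other = self.adj2, self.adj1
            while cur != v:
                order.append(cur)
                seen.add(cur)
                cur = use[cur]
                use, other = other, use
            yield "cycle", order


@dataclass(frozen=True)
class ComponentSummary:
    """Census of a breakpoint graph: ``c[i]`` i-cycles, ``p[j]`` j-paths."""

    c: Counter
    p: Counter
    n_star: int

    @property
    def total_cycles(self) -> int:
        return sum(self.c.values())

    @property
    def total_even_paths(self) -> int:
        return sum(n for j, n in self.p.items() if j % 2 == 0)

    @property
    def total_edges(self) -> int:
        return sum(i * n for i, n in self.c.items()) + sum(
            j * n for j, n in self.p.items()
        )


def decompose(bg: BreakpointGraph) -> ComponentSummary:
    """Exact census of i-cycles and j-paths (length = number of edges)."""
    c: Counter = Counter()
    p: Counter = Counter()
    for kind, order in bg.components():
        if kind == "cycle":
            c[len(order)] += 1
        else:
            p[len(order) - 1] += 1
    n_star = len(bg.vertices) // 2
    summary = ComponentSummary(c, p, n_star)
    if summary.total_even_paths % 2 != 0:
        raise AssertionError("number of even paths must be even")
    return summary


def sigma_score(cs: ComponentSummary, k) -> Fraction:
    """Cumulative score c_2 + ... + c_k + (p_0 + ... + p_{k-2}) / 2."""
    validate_k(k)
    cycles = sum(n for i, n in cs.c.items() if i % 2 == 0 and (k == INF or i <= k))
    paths = sum(
        n for j, n in cs.p.items() if j % 2 == 0 and (k == INF or j <= k - 2)
    )
    return Fraction(cycles) + Fraction(paths, 2)


def build_breakpoint_graph(s1: Genome, s2: Genome) -> BreakpointGraph:
    """Breakpoint graph of a canonical pair (both singular, same families).

    Copy labels, if present (singularized genomes), are part of the family
    identity, so a pair of identically singularized genomes is canonical.
    """
    counts1 = Counter(g.family_key for g in s1.genes)
    counts2 = Counter(g.family_key for g in s2.genes)
    for name, counts in (("first", counts1), ("second", counts2)):
        bad = {f for f, n in counts.items() if n != 1}
        if bad:
            raise CanonicalPairError(
                f"{name} genome is not singular; repeated families: {sorted(bad)}"
            )
    if set(counts1) != set(counts2):
        diff = set(counts1) ^ set(counts2)
        raise CanonicalPairError(
            f"family sets differ; symmetric difference: {sorted(diff)}"
        )
    vertices = []
    for fam, copy in sorted(counts1, key=lambda fc: (fc[0], fc[1] or "")):
        vertices.append(Extremity(fam, TAIL, copy))
        vertices.append(Extremity(fam, HEAD, copy))
    edges1 = [tuple(a) for a in adjacency_multiset(s1)]
    edges2 = [tuple(a) for a in adjacency_multiset(s2)]
    return BreakpointGraph(
        vertices, edges1, edges2, label1=s1.name or "genome1", label2=s2.name or "genome2"
    )


def sigma_distance(s1: Genome, s2: Genome, k) -> Fraction:
    """d_{sigma_k}(s1, s2) = n* - sigma_k; symmetric, zero iff equal content
    for k = 2 and monotonically non-increasing in k."""
    validate_k(k)
    bg = build_breakpoint_graph(s1, s2)
    cs = decompose(bg)
    return Fraction(cs.n_star) - sigma_score(cs, k)


def to_dot(bg: BreakpointGraph) -> str:
    """DOT rendering: genome-1 edges blue, genome-2 edges black; telomere
    vertices tinted by which genome(s) they are telomeric in."""
    t1, t2 = bg.telomeres1(), bg.telomeres2()
    lines = ["graph breakpoint_graph {", "  node [shape=circle];"]
    ids = {v: f"v{i}" for i, v in enumerate(bg.vertices)}
    for v in bg.vertices:
        if v in t1 and v in t2:
            color = "purple"
        elif v in t1:
            color = "lightblue"
        elif v in t2:
            color = "gray"
        else:
            color = "white"
        lines.append(
            f'  {ids[v]} [label="{v}", style=filled, fillcolor={color}];'
        )
    for u, v in bg.edges1:
        lines.append(f'  {ids[u]} -- {ids[v]} [color=blue, label="{bg.label1}"];')
    for u, v in bg.edges2:
        lines.append(f'  {ids[u]} -- {ids[v]} [color=black, label="{bg.label2}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"
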