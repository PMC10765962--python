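"""Seeded instance generators and small utilities.

The generator emulates evolution after a whole-genome duplication: draw a
random singular genome, double it (choosing one of the ``2^r`` layouts for
its circular chromosomes), apply a number of random DCJ operations to the
doubled genome, and strip the copy labels.  With zero DCJs the result is an
exact doubling and every sigma-k double distance is zero; each DCJ changes
the distance by at most one, so ``n_dcj`` upper-bounds the DCJ double
distance.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from fractions import Fraction

from .genomes import (
    Chromosome,
    Extremity,
    Gene,
    Genome,
    HEAD,
    TAIL,
    labeled_doubling,
    strip_copies,
)


@dataclass(frozen=True)
class GeneratorConfig:
    n_families: int
    n_linear: int = 1
    n_circular: int = 0
    n_dcj: int = 0
    seed: int = 0
    dialect: str = "brackets"

    def __post_init__(self) -> None:
        if self.n_linear + self.n_circular < 1:
            raise ValueError("need at least one chromosome")
        if self.n_families < self.n_linear + self.n_circular:
            raise ValueError("more chromosomes than families")


def random_singular_genome(cfg: GeneratorConfig) -> Genome:
    """Random singular genome with exactly the configured chromosome counts;
    deterministic for a fixed seed."""
    rng = random.Random(cfg.seed)
    families = [str(i) for i in range(1, cfg.n_families + 1)]
    rng.shuffle(families)
    genes = [Gene(f, rng.random() < 0.5) for f in families]
    n_chrom = cfg.n_linear + cfg.n_circular
    cuts = sorted(rng.sample(range(1, cfg.n_families), n_chrom - 1)) if n_chrom > 1 else []
    bounds = [0] + cuts + [cfg.n_families]
    topologies = [False] * cfg.n_linear + [True] * cfg.n_circular
    rng.shuffle(topologies)
    chroms = [
        Chromosome(tuple(genes[bounds[i]: bounds[i + 1]]), circular=topologies[i])
        for i in range(n_chrom)
    ]
    return Genome(tuple(chroms), name=f"S{cfg.seed}")


def _rebuild_genome(adjacencies: set, telomeres: set, name=None) -> Genome:
    """Assemble chromosomes from an adjacency/telomere set over distinct
    (copy-labeled) extremities."""
    partner: dict = {}
    for adj in adjacencies:
        u, v = tuple(adj)
        partner[u] = v
        partner[v] = u

    def other_end(e: Extremity) -> Extremity:
        return Extremity(e.family, HEAD if e.side == TAIL else TAIL, e.copy)

    def gene_from(entry: Extremity) -> Gene:
        return Gene(entry.family, entry.side == TAIL, entry.copy)

    used: set = set()
    chroms: list[Chromosome] = []
    for t in sorted(telomeres):
        if t in used:
            continue
        genes = []
        entry = t
        while True:
            used.add(entry)
            genes.append(gene_from(entry))
            exit_ = other_end(entry)
            used.add(exit_)
            nxt = partner.get(exit_)
            if nxt is None:
                break
            entry = nxt
        chroms.append(Chromosome(tuple(genes), circular=False))
    remaining = sorted(set(partner) - used)
    for e in remaining:
        if e in used:
            continue
        entry = min(e, other_end(e))
        genes = []
        while entry not in used:
            used.add(entry)
            genes.append(gene_from(entry))
            exit_ = other_end(entry)
            used.add(exit_)
            entry = partner[exit_]
        chroms.append(Chromosome(tuple(genes), circular=True))
    return Genome(tuple(chroms), name=name)


def apply_random_dcjs(g: Genome, n: int, rng: random.Random) -> Genome:
    """Apply ``n`` random DCJ operations on the adjacency/telomere
    representation of ``g`` (extremities must be pairwise distinct, i.e. the
    genome is singular or carries copy labels)."""
    from .genomes import adjacency_multiset, telomere_multiset

    adjacencies = {a for a in adjacency_multiset(g)}
    telomeres = {t for t in telomere_multiset(g)}
    for _ in range(n):
        pool = sorted(adjacencies) + [t for t in sorted(telomeres)]
        if len(pool) < 2:
            break
        first, second = rng.sample(pool, 2)
        if isinstance(first, frozenset) and isinstance(second, frozenset):
            x, y = tuple(sorted(first))
            z, w = tuple(sorted(second))
            adjacencies -= {first, second}
            if rng.random() < 0.5:
                adjacencies |= {frozenset((x, z)), frozenset((y, w))}
            else:
                adjacencies |= {frozenset((x, w)), frozenset((y, z))}
        elif isinstance(first, frozenset) or isinstance(second, frozenset):
            adj, tel = (first, second) if isinstance(first, frozenset) else (second, first)
            x, y = tuple(sorted(adj))
            adjacencies.discard(adj)
            telomeres.discard(tel)
            if rng.random() < 0.5:
                adjacencies.add(frozenset((x, tel)))
                telomeres.add(y)
            else:
                adjacencies.add(frozenset((y, tel)))
                telomeres.add(x)
        else:
            telomeres -= {first, second}
            adjacencies.add(frozenset((first, second)))
    return _rebuild_genome(adjacencies, telomeres, name=g.name)


def random_duplicated_from(s: Genome, cfg: GeneratorConfig) -> Genome:
    """Duplicated genome derived from ``s``: one random doubling, then
    ``cfg.n_dcj`` random DCJs, then copy labels stripped."""
    rng = random.Random(f"dup-{cfg.seed}")
    flags = [rng.random() < 0.5 for _ in range(s.n_circular())]
    doubled = labeled_doubling(s, flags)
    evolved = apply_random_dcjs(doubled, cfg.n_dcj, rng)
    return strip_copies(
        Genome(evolved.chromosomes, name=f"D{cfg.seed}")
    )


def random_instance(cfg: GeneratorConfig) -> tuple[Genome, Genome]:
    s = random_singular_genome(cfg)
    return s, random_duplicated_from(s, cfg)


def format_rational(x: Fraction) -> str:
    """Scores live in half-integers; print them exactly (``3`` or ``3.5``),
    never as rounded floats."""
    x = Fraction(x)
    if x.denominator == 1:
        return str(x.numerator)
    if x.denominator == 2:
        sign = "-" if x < 0 else ""
        return f"{sign}{abs(x.numerator) // 2}.5"
    return str(x)
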