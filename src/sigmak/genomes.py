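"""Genome representation for gene-order comparison.

A genome is a multiset of chromosomes; a chromosome is an ordered sequence of
oriented genes and is either linear or circular.  Genes belong to families;
a *singular* genome has one gene per family, a *duplicated* genome has two
(its paralogs), and a *doubled* genome is a duplicated genome in which every
adjacency and telomere occurs exactly twice (the immediate product of a
whole-genome duplication).

The text format mirrors the field's notation: ``[1 -3 2]`` is a linear
chromosome, ``(4)`` a circular one, a ``-`` prefix marks reverse orientation,
and an optional ``>name`` header starts a new genome.  A UniMoG-style dialect
(chromosome terminated by ``|`` if linear, ``)`` if circular) is supported
behind a format flag.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterator, NamedTuple, Optional, Sequence

HEAD = "h"
TAIL = "t"

_RESERVED = set("[]()>|")


class GenomeFormatError(ValueError):
    """Raised when a genome file or genome precondition is malformed."""


class Extremity(NamedTuple):
    """One end of a gene: its head (``h``) or tail (``t``).

    ``copy`` is ``None`` for plain genomes and ``"a"``/``"b"`` after
    singularization of a duplicated genome.
    """

    family: str
    side: str
    copy: Optional[str] = None

    def __str__(self) -> str:  # e.g. "3a^h"
        return f"{self.family}{self.copy or ''}^{self.side}"


@dataclass(frozen=True)
class Gene:
    family: str
    forward: bool = True
    copy: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.family or any(c.isspace() or c in _RESERVED for c in self.family):
            raise GenomeFormatError(f"bad family token {self.family!r}")

    @property
    def family_key(self) -> tuple[str, Optional[str]]:
        return (self.family, self.copy)

    def reverse(self) -> "Gene":
        return Gene(self.family, not self.forward, self.copy)

    def left(self) -> Extremity:
        """Extremity on the left when the gene is read in chromosome order."""
        return Extremity(self.family, TAIL if self.forward else HEAD, self.copy)

    def right(self) -> Extremity:
        return Extremity(self.family, HEAD if self.forward else TAIL, self.copy)

    def token(self) -> str:
        return ("" if self.forward else "-") + self.family + (self.copy or "")

    def _key(self):
        return (self.family, self.copy or "", self.forward)


Adjacency = frozenset  # frozenset of exactly two Extremity values


def _revcomp(genes: tuple[Gene, ...]) -> tuple[Gene, ...]:
    return tuple(g.reverse() for g in reversed(genes))


@dataclass(frozen=True)
class Chromosome:
    genes: tuple[Gene, ...]
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.genes:
            raise GenomeFormatError("empty chromosome")
        object.__setattr__(self, "genes", tuple(self.genes))

    def canonical(self) -> tuple[Gene, ...]:
        """Lexicographically smallest equivalent gene sequence.

        Equality of chromosomes is invariant under reverse-complement and,
        for circular chromosomes, under rotation.
        """
        candidates = [self.genes, _revcomp(self.genes)]
        if self.circular:
            rotations = []
            for seq in candidates:
                rotations.extend(
                    seq[i:] + seq[:i] for i in range(len(seq))
                )
            candidates = rotations
        return min(candidates, key=lambda seq: [g._key() for g in seq])

    def _canon_key(self):
        return (self.circular, tuple(g._key() for g in self.canonical()))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Chromosome) and self._canon_key() == other._canon_key()

    def __hash__(self) -> int:
        return hash(self._canon_key())

    def format(self, dialect: str = "brackets") -> str:
        tokens = " ".join(g.token() for g in self.genes)
        if dialect == "brackets":
            return f"({tokens})" if self.circular else f"[{tokens}]"
        if dialect == "unimog":
            return f"{tokens} )" if self.circular else f"{tokens} |"
        raise GenomeFormatError(f"unknown dialect {dialect!r}")


@dataclass(frozen=True)
class Genome:
    chromosomes: tuple[Chromosome, ...]
    name: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))

    def _canon_key(self):
        return tuple(sorted(c._canon_key() for c in self.chromosomes))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Genome) and self._canon_key() == other._canon_key()

    def __hash__(self) -> int:
        return hash(self._canon_key())

    @property
    def genes(self) -> Iterator[Gene]:
        for chrom in self.chromosomes:
            yield from chrom.genes

    def families(self) -> set[str]:
        return {g.family for g in self.genes}

    def family_counts(self) -> Counter:
        return Counter(g.family for g in self.genes)

    def n_linear(self) -> int:
        return sum(1 for c in self.chromosomes if not c.circular)

    def n_circular(self) -> int:
        return sum(1 for c in self.chromosomes if c.circular)

    def is_singularized(self) -> bool:
        return all(g.copy is not None for g in self.genes)

    def format(self, dialect: str = "brackets") -> str:
        lines = []
        if self.name:
            lines.append(f">{self.name}")
        lines.extend(c.format(dialect) for c in self.chromosomes)
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Parsing

def _parse_token(tok: str, line_no: int) -> Gene:
    forward = True
    if tok.startswith("-"):
        forward = False
        tok = tok[1:]
    if not tok:
        raise GenomeFormatError(f"line {line_no}: empty gene token")
    try:
        return Gene(tok, forward)
    except GenomeFormatError as exc:
        raise GenomeFormatError(f"line {line_no}: {exc}") from None


def _parse_bracket_line(line: str, line_no: int) -> list[Chromosome]:
    """One or more ``[...]`` / ``(...)`` groups on a single line."""
    chroms = []
    rest = line.strip()
    while rest:
        open_ch = rest[0]
        if open_ch not in "[(":
            raise GenomeFormatError(
                f"line {line_no}: expected '[' or '(', found {open_ch!r}"
            )
        close_ch = "]" if open_ch == "[" else ")"
        end = rest.find(close_ch)
        if end < 0:
            raise GenomeFormatError(f"line {line_no}: missing {close_ch!r}")
        body = rest[1:end]
        if any(c in "[]()" for c in body):
            raise GenomeFormatError(f"line {line_no}: malformed bracket nesting")
        tokens = body.split()
        if not tokens:
            raise GenomeFormatError(f"line {line_no}: empty chromosome")
        genes = tuple(_parse_token(t, line_no) for t in tokens)
        chroms.append(Chromosome(genes, circular=open_ch == "("))
        rest = rest[end + 1:].strip()
    return chroms


def _parse_unimog_line(line: str, line_no: int) -> list[Chromosome]:
    chroms: list[Chromosome] = []
    tokens: list[Gene] = []
    for tok in line.split():
        if tok in ("|", ")"):
            if not tokens:
                raise GenomeFormatError(f"line {line_no}: empty chromosome")
            chroms.append(Chromosome(tuple(tokens), circular=tok == ")"))
            tokens = []
        else:
            tokens.append(_parse_token(tok, line_no))
    if tokens:
        raise GenomeFormatError(
            f"line {line_no}: chromosome not terminated by '|' or ')'"
        )
    return chroms


def parse_genomes(text: str, dialect: str = "brackets") -> list[Genome]:
    """Parse a genome file; returns genomes in file order.

    Round-trips through :meth:`Genome.format` up to canonical form.
    """
    if dialect not in ("brackets", "unimog"):
        raise GenomeFormatError(f"unknown dialect {dialect!r}")
    genomes: list[Genome] = []
    current: list[Chromosome] = []
    current_name: Optional[str] = None
    started = False

    def flush() -> None:
        nonlocal current, current_name, started
        if current or current_name is not None:
            if not current:
                raise GenomeFormatError(f"genome {current_name!r} has no chromosomes")
            genomes.append(Genome(tuple(current), name=current_name))
        current, current_name, started = [], None, False

    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            current_name = line[1:].strip() or None
            started = True
            continue
        if dialect == "brackets":
            current.extend(_parse_bracket_line(line, line_no))
        else:
            current.extend(_parse_unimog_line(line, line_no))
        started = True
    flush()
    if not genomes:
        raise GenomeFormatError("no genomes found in input")
    return genomes


def parse_genome(text: str, dialect: str = "brackets") -> list[Genome]:
    """Alias of :func:`parse_genomes`."""
    return parse_genomes(text, dialect)


def format_genome(g: Genome, dialect: str = "brackets") -> str:
    return g.format(dialect)


# ---------------------------------------------------------------------------
# Adjacencies and telomeres

def adjacency_list(g: Genome) -> list:
    """Adjacencies in traversal order (chromosomes in stored order, left to
    right); the order gives the deterministic square numbering downstream."""
    adj = []
    for chrom in g.chromosomes:
        genes = chrom.genes
        for i in range(len(genes) - 1):
            adj.append(frozenset((genes[i].right(), genes[i + 1].left())))
        if chrom.circular:
            adj.append(frozenset((genes[-1].right(), genes[0].left())))
    return adj


def adjacency_multiset(g: Genome) -> Counter:
    """Multiset of adjacencies: unordered pairs of neighboring extremities.

    A single-gene circular chromosome contributes the exceptional adjacency
    between the head and the tail of its own gene.
    """
    return Counter(adjacency_list(g))


def telomere_multiset(g: Genome) -> Counter:
    tel: Counter = Counter()
    for chrom in g.chromosomes:
        if not chrom.circular:
            tel[chrom.genes[0].left()] += 1
            tel[chrom.genes[-1].right()] += 1
    return tel


def classify_genome(g: Genome) -> str:
    """``singular`` / ``duplicated`` / ``doubled`` / ``other``.

    Doubled means duplicated with every adjacency and telomere occurring
    exactly twice.
    """
    counts = g.family_counts()
    if all(c == 1 for c in counts.values()):
        return "singular"
    if all(c == 2 for c in counts.values()):
        adj = adjacency_multiset(g)
        tel = telomere_multiset(g)
        if all(c == 2 for c in adj.values()) and all(c == 2 for c in tel.values()):
            return "doubled"
        return "duplicated"
    return "other"


# ---------------------------------------------------------------------------
# Doubling and singularization

def doubled_content(s: Genome) -> tuple[Counter, Counter, int]:
    """Adjacency/telomere content shared by every doubling of ``s``.

    Doubling duplicates each adjacency and telomere; each circular chromosome
    can be doubled into two copies or concatenated into one, so the number of
    distinct doubled genomes is ``2**r`` for ``r`` circular chromosomes.
    """
    if classify_genome(s) != "singular":
        raise GenomeFormatError("doubled_content requires a singular genome")
    adj = adjacency_multiset(s)
    tel = telomere_multiset(s)
    return adj + adj, tel + tel, 2 ** s.n_circular()


def enumerate_doublings(s: Genome) -> Iterator[Genome]:
    """All ``2**r`` doubled genomes obtainable by doubling ``s``."""
    if classify_genome(s) != "singular":
        raise GenomeFormatError("enumerate_doublings requires a singular genome")
    circular = [c for c in s.chromosomes if c.circular]
    linear = [c for c in s.chromosomes if not c.circular]

    def rec(i: int, acc: list[Chromosome]) -> Iterator[Genome]:
        if i == len(circular):
            chroms = list(acc)
            for c in linear:
                chroms.extend([c, c])
            yield Genome(tuple(chroms))
            return
        c = circular[i]
        yield from rec(i + 1, acc + [c, c])
        yield from rec(i + 1, acc + [Chromosome(c.genes + c.genes, circular=True)])

    yield from rec(0, [])


def labeled_doubling(s: Genome, concatenate: Sequence[bool] = ()) -> Genome:
    """One member of the doubling of ``s``, with copy labels a/b.

    ``concatenate[i]`` decides whether the i-th circular chromosome is doubled
    into a single concatenated circle (True) or two separate copies (False).
    """
    if classify_genome(s) != "singular":
        raise GenomeFormatError("labeled_doubling requires a singular genome")
    flags = list(concatenate)
    chroms: list[Chromosome] = []
    ci = 0
    for c in s.chromosomes:
        copy_a = tuple(Gene(g.family, g.forward, "a") for g in c.genes)
        copy_b = tuple(Gene(g.family, g.forward, "b") for g in c.genes)
        if c.circular:
            concat = flags[ci] if ci < len(flags) else False
            ci += 1
            if concat:
                chroms.append(Chromosome(copy_a + copy_b, circular=True))
                continue
        chroms.append(Chromosome(copy_a, circular=c.circular))
        chroms.append(Chromosome(copy_b, circular=c.circular))
    return Genome(tuple(chroms), name=s.name)


def singularize(d: Genome) -> Genome:
    """Attach copy index ``a`` to the first occurrence of each family and
    ``b`` to the second (chromosomes in stored order, genes left to right).

    Any two singularizations of the same duplicated genome yield the same
    sigma-k double distance, so the deterministic choice is only for
    reproducibility.
    """
    if d.is_singularized() or any(g.copy is not None for g in d.genes):
        raise GenomeFormatError("genome is already singularized")
    if classify_genome(d) != "duplicated" and classify_genome(d) != "doubled":
        raise GenomeFormatError("singularize requires a duplicated genome")
    seen: Counter = Counter()
    chroms = []
    for c in d.chromosomes:
        genes = []
        for g in c.genes:
            copy = "a" if seen[g.family] == 0 else "b"
            seen[g.family] += 1
            genes.append(Gene(g.family, g.forward, copy))
        chroms.append(Chromosome(tuple(genes), circular=c.circular))
    return Genome(tuple(chroms), name=d.name)


def strip_copies(g: Genome) -> Genome:
    chroms = tuple(
        Chromosome(tuple(Gene(x.family, x.forward) for x in c.genes), c.circular)
        for c in g.chromosomes
    )
    return Genome(chroms, name=g.name)


def swap_copies(g: Genome, families: set[str]) -> Genome:
    """Exchange the a/b labels of the given families (re-singularization)."""
    flip = {"a": "b", "b": "a"}
    chroms = tuple(
        Chromosome(
            tuple(
                Gene(x.family, x.forward, flip[x.copy])
                if x.family in families and x.copy in flip
                else x
                for x in c.genes
            ),
            c.circular,
        )
        for c in g.chromosomes
    )
    return Genome(chroms, name=g.name)
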