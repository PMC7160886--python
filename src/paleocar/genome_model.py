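"""Signed marker sequences, genomes, adjacencies, and the DCJ distance.

A genomic *marker* is a block of DNA identified by its homology *family*.
The double-strandedness of DNA gives each marker occurrence an orientation:
a marker ``g`` read against the reading direction of its chromosome is
written ``-g``.  A chromosome is an ordered sequence of signed markers and a
genome is a collection of such sequences.  Chromosomes are linear only;
circular chromosomes are outside the scope of this toolkit and cannot be
represented.

For *non-duplicated* genomes (every family occurs at most once) the classic
double-cut-and-join (DCJ) machinery applies: each marker ``g`` contributes a
head extremity ``g^h`` and a tail extremity ``g^t``; consecutive markers
define adjacencies (unordered extremity pairs, with singleton *telomeric*
adjacencies at chromosome ends); and the adjacency graph of two balanced
genomes decomposes into cycles and paths from which the DCJ distance is
``n - c - o/2`` where ``c`` counts cycles and ``o`` odd paths.

Markers are held internally as ``(family, sign)`` pairs with ``family`` an
opaque string (downstream family refinement mints hierarchical ids such as
``"12@c0"``) and ``sign`` in ``{+1, -1}``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence, Union

import networkx as nx
import pandas as pd

HEAD = "h"
TAIL = "t"

#: one signed marker occurrence: (family id, +1 | -1)
Marker = tuple[str, int]
#: one marker extremity: (family id, "h" | "t")
Extremity = tuple[str, str]
#: an adjacency: frozenset of one (telomeric) or two extremities
Adjacency = frozenset


class DuplicatedGenomeError(ValueError):
    """Raised when an operation requiring non-duplicated genomes sees a
    family with multiplicity > 1."""


class UnbalancedGenomesError(ValueError):
    """Raised when an operation requiring balanced genomes sees differing
    contents or multiplicities."""


def make_marker(signed_id: Union[int, str]) -> Marker:
    """Normalize a signed family identifier (``-5``, ``"-5"``, ``"F.2"``)
    into a ``(family, sign)`` pair."""
    if isinstance(signed_id, int):
        if signed_id == 0:
            raise ValueError("family identifier must be nonzero")
        return (str(abs(signed_id)), 1 if signed_id > 0 else -1)
    s = str(signed_id).strip()
    if not s or s == "-":
        raise ValueError(f"invalid signed family identifier: {signed_id!r}")
    if s.startswith("-"):
        return (s[1:], -1)
    return (s, 1)


def signed_str(marker: Marker) -> str:
    family, sign = marker
    return family if sign > 0 else "-" + family


@dataclass
class MarkerSequence:
    """One chromosome: an ordered list of signed markers."""

    markers: list[Marker] = field(default_factory=list)
    sequence_id: str = "chr"
    genome_id: str = "genome"

    @classmethod
    def from_ints(cls, ids: Iterable[int], sequence_id: str = "chr",
                  genome_id: str = "genome") -> "MarkerSequence":
        return cls([make_marker(i) for i in ids], sequence_id, genome_id)

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self) -> Iterator[Marker]:
        return iter(self.markers)

    def reversed(self) -> "MarkerSequence":
        """The same chromosome read from the other strand."""
        return MarkerSequence([(f, -s) for f, s in reversed(self.markers)],
                              self.sequence_id, self.genome_id)


@dataclass
class Genome:
    """A collection of linear chromosomes sharing one genome label."""

    chromosomes: list[MarkerSequence] = field(default_factory=list)
    genome_id: str = "genome"

    @classmethod
    def from_ints(cls, chromosomes: Iterable[Iterable[int]],
                  genome_id: str = "genome") -> "Genome":
        chroms = [
            MarkerSequence.from_ints(ids, f"chr{i + 1}", genome_id)
            for i, ids in enumerate(chromosomes)
        ]
        return cls(chroms, genome_id)

    def __iter__(self) -> Iterator[MarkerSequence]:
        return iter(self.chromosomes)

    @property
    def n_markers(self) -> int:
        return sum(len(c) for c in self.chromosomes)


SequenceLike = Union[MarkerSequence, Genome, Sequence[Marker]]


def _iter_markers(obj: SequenceLike) -> Iterator[Marker]:
    if isinstance(obj, Genome):
        for chrom in obj.chromosomes:
            yield from chrom.markers
    elif isinstance(obj, MarkerSequence):
        yield from obj.markers
    else:
        yield from obj


def content(obj: SequenceLike) -> set[str]:
    """The genome content: the set of families occurring in ``obj``,
    orientation omitted."""
    return {family for family, _ in _iter_markers(obj)}


def multiplicity_table(obj: SequenceLike) -> Counter:
    """Family -> occurrence count over all markers of ``obj``."""
    return Counter(family for family, _ in _iter_markers(obj))


def multiplicity(obj: SequenceLike, family: Union[int, str]) -> int:
    """Number of occurrences of ``family`` in ``obj`` (0 if absent)."""
    fam = str(abs(family)) if isinstance(family, int) else str(family)
    return multiplicity_table(obj)[fam]


def is_duplicated(obj: SequenceLike) -> bool:
    return any(n > 1 for n in multiplicity_table(obj).values())


def is_balanced(a: SequenceLike, b: SequenceLike) -> bool:
    """True iff ``a`` and ``b`` have identical content and per-family
    multiplicities.  Orientations are irrelevant."""
    return multiplicity_table(a) == multiplicity_table(b)


# ---------------------------------------------------------------------------
# adjacencies and the adjacency graph


def _oriented_extremities(marker: Marker) -> tuple[Extremity, Extremity]:
    """Extremities of a marker in reading direction: (entry, exit)."""
    family, sign = marker
    if sign > 0:
        return (family, TAIL), (family, HEAD)
    return (family, HEAD), (family, TAIL)


def adjacency_set(genome: Genome) -> list[Adjacency]:
    """All adjacencies of a non-duplicated genome.

    A linear chromosome of k >= 1 markers yields k-1 internal adjacencies
    plus 2 telomeric (singleton) ones.  Empty chromosomes contribute
    nothing.
    """
    if is_duplicated(genome):
        raise DuplicatedGenomeError(
            f"genome {genome.genome_id!r} is duplicated; the adjacency-set "
            "representation requires every family to occur at most once")
    adjacencies: list[Adjacency] = []
    for chrom in genome.chromosomes:
        if not chrom.markers:
            continue
        oriented = [_oriented_extremities(m) for m in chrom.markers]
        adjacencies.append(frozenset([oriented[0][0]]))  # left telomere
        for (_, exit_prev), (entry_next, _) in zip(oriented, oriented[1:]):
            adjacencies.append(frozenset([exit_prev, entry_next]))
        adjacencies.append(frozenset([oriented[-1][1]]))  # right telomere
    return adjacencies


CYCLE = "cycle"
ODD_PATH = "odd_path"
EVEN_PATH = "even_path"


@dataclass
class AdjacencyGraph:
    """Bipartite multigraph between two genomes' adjacency sets.

    Vertices are adjacencies; an edge joins u (of G) and v (of H) with
    multiplicity |u ∩ v|.  Every vertex has degree equal to its number of
    extremities, so components are simple cycles and paths; paths end at
    telomeric adjacencies.  ``components`` records (kind, edge_count) with
    kind classified by edge-count parity: cycles always have an even number
    of edges, paths are odd or even.
    """

    left_vertices: list[Adjacency]
    right_vertices: list[Adjacency]
    components: list[tuple[str, int]]

    @property
    def n_cycles(self) -> int:
        return sum(1 for kind, _ in self.components if kind == CYCLE)

    @property
    def n_odd_paths(self) -> int:
        return sum(1 for kind, _ in self.components if kind == ODD_PATH)

    @property
    def n_even_paths(self) -> int:
        return sum(1 for kind, _ in self.components if kind == EVEN_PATH)


def adjacency_graph_components(
        left: list[Adjacency], right: list[Adjacency]) -> list[tuple[str, int]]:
    """Decompose the adjacency multigraph into (kind, edge_count) components.

    The inputs must be adjacency sets of two balanced non-duplicated
    genomes (every extremity present on both sides exactly once).
    """
    graph = nx.MultiGraph()
    for i in range(len(left)):
        graph.add_node(("L", i))
    for j in range(len(right)):
        graph.add_node(("R", j))
    by_extremity: dict[Extremity, int] = {}
    for j, v in enumerate(right):
        for ext in v:
            by_extremity[ext] = j
    for i, u in enumerate(left):
        for ext in u:
            j = by_extremity.get(ext)
            if j is not None and ext in right[j]:
                graph.add_edge(("L", i), ("R", j))
    components: list[tuple[str, int]] = []
    for nodes in nx.connected_components(graph):
        sub = graph.subgraph(nodes)
        n_edges = sub.number_of_edges()
        if n_edges == 0:
            continue  # isolated vertex: unshared extremity (cannot happen when balanced)
        if all(d == 2 for _, d in sub.degree()):
            components.append((CYCLE, n_edges))
        elif n_edges % 2 == 1:
            components.append((ODD_PATH, n_edges))
        else:
            components.append((EVEN_PATH, n_edges))
    return components


def build_adjacency_graph(g: Genome, h: Genome) -> AdjacencyGraph:
    """Adjacency graph AG(G, H) of two balanced non-duplicated genomes."""
    if not is_balanced(g, h):
        raise UnbalancedGenomesError(
            f"genomes {g.genome_id!r} and {h.genome_id!r} are not balanced")
    left = adjacency_set(g)
    right = adjacency_set(h)
    return AdjacencyGraph(left, right,
                          adjacency_graph_components(left, right))


def dcj_distance(g: Genome, h: Genome) -> int:
    """Classic DCJ distance ``n - c - o/2`` for balanced non-duplicated
    genomes over n markers, with c cycles and o odd paths in AG(G, H)."""
    graph = build_adjacency_graph(g, h)
    n = g.n_markers
    twice = 2 * n - 2 * graph.n_cycles - graph.n_odd_paths
    assert twice % 2 == 0, "odd paths always come in pairs"
    return twice // 2


# ---------------------------------------------------------------------------
# marker-sequence TSV dialect
#
# One row per marker occurrence:
#   genome_id  chromosome_id  position  signed_family_id
# with position a 1-based ordinal (ascending within each chromosome) and
# signed_family_id the family string, '-'-prefixed for reverse orientation.

TSV_COLUMNS = ["genome_id", "chromosome_id", "position", "signed_family_id"]


def write_marker_tsv(path, genomes: Iterable[Genome]) -> None:
    rows = []
    for genome in genomes:
        for chrom in genome.chromosomes:
            for pos, marker in enumerate(chrom.markers, start=1):
                rows.append((genome.genome_id, chrom.sequence_id, pos,
                             signed_str(marker)))
    frame = pd.DataFrame(rows, columns=TSV_COLUMNS)
    frame.to_csv(path, sep="\t", index=False)


def read_marker_tsv(path) -> list[Genome]:
    """Read the marker TSV dialect; genomes ordered by first appearance.

    Round-trips bit-exactly with :func:`write_marker_tsv`.
    """
    frame = pd.read_csv(path, sep="\t", dtype={
        "genome_id": str, "chromosome_id": str,
        "position": int, "signed_family_id": str})
    missing = [c for c in TSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"marker TSV {path} lacks columns: {missing}")
    genomes: dict[str, Genome] = {}
    chrom_index: dict[tuple[str, str], MarkerSequence] = {}
    for row in frame.itertuples(index=False):
        gid, cid = str(row.genome_id), str(row.chromosome_id)
        genome = genomes.setdefault(gid, Genome([], gid))
        key = (gid, cid)
        chrom = chrom_index.get(key)
        if chrom is None:
            chrom = MarkerSequence([], cid, gid)
            chrom_index[key] = chrom
            genome.chromosomes.append(chrom)
        if int(row.position) != len(chrom.markers) + 1:
            raise ValueError(
                f"marker TSV {path}: positions of {gid}/{cid} are not "
                f"1-based ascending at position {row.position}")
        chrom.markers.append(make_marker(str(row.signed_family_id)))
    return list(genomes.values())
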