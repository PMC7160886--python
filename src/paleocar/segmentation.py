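"""Genome segmentation: cutting sequences into atoms from local alignments.

The segmentation stage turns raw DNA sequences plus pairwise local
alignments (of the sequence collection onto itself) into *atoms*:
non-overlapping segments such that no alignment boundary falls strictly
inside any atom, every atom meets a minimum length, and atoms are grouped
into families by the alignments connecting them.  Nucleotides not covered
by an atom lie in *waste regions*; the segmentation objective is to
minimize total waste.  The exact problem is intractable, so a heuristic is
used: alignment boundaries are closed under propagation (a breakpoint on
one side of an alignment induces the proportionally mapped breakpoint on
the other side), candidate atoms are the segments between consecutive
closed breakpoints, and a greedy improvement pass discards alignments
whose induced breakpoints create more waste than they resolve.

Coordinates are 0-based half-open throughout (and in BED output); the
exported marker TSV uses 1-based marker ordinals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import networkx as nx

from .genome_model import Genome, MarkerSequence

_STRAND_ALIASES = {"+": "+", "plus": "+", "1": "+",
                   "-": "-", "minus": "-", "-1": "-"}


@dataclass(frozen=True)
class LocalAlignment:
    """One pairwise local alignment; intervals 0-based half-open."""

    query_seq: str
    query_start: int
    query_end: int
    target_seq: str
    target_start: int
    target_end: int
    strand: str
    score: float

    def __post_init__(self):
        if self.query_end <= self.query_start:
            raise ValueError(f"empty query interval in {self}")
        if self.target_end <= self.target_start:
            raise ValueError(f"empty target interval in {self}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if (self.query_seq == self.target_seq
                and self.query_start == self.target_start
                and self.query_end == self.target_end):
            raise ValueError(f"self-alignment disallowed: {self}")


@dataclass
class Atom:
    seq: str
    start: int
    end: int
    family: Optional[str] = None
    orientation: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Segmentation:
    atoms: list[Atom]
    waste_total: int
    min_length: int
    kept_alignments: list[LocalAlignment] = field(default_factory=list)
    seq_lengths: dict = field(default_factory=dict)


def read_alignments(path, min_score: float = 0.0) -> list[LocalAlignment]:
    """Read a LASTZ-general-style alignment TSV.

    Columns: name1, start1, end1, name2, start2, end2, strand2, score
    (0-based half-open).  Lines starting with '#' and a literal header row
    are skipped; records scoring below ``min_score`` are dropped.
    """
    alignments = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "name1":
                continue
            if len(fields) < 8:
                raise ValueError(
                    f"{path}:{lineno}: expected 8 columns, got {len(fields)}")
            try:
                strand = _STRAND_ALIASES[fields[6].strip()]
                aln = LocalAlignment(
                    fields[0], int(fields[1]), int(fields[2]),
                    fields[3], int(fields[4]), int(fields[5]),
                    strand, float(fields[7]))
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if aln.score >= min_score:
                alignments.append(aln)
    return alignments


def _project(x: int, src: tuple[int, int], dst: tuple[int, int],
             strand: str) -> int:
    """Proportionally map position x from interval src to dst (linear
    interpolation, strand-aware), snapped to an integer."""
    s0, s1 = src
    d0, d1 = dst
    frac = (x - s0) / (s1 - s0)
    if strand == "+":
        return round(d0 + frac * (d1 - d0))
    return round(d1 - frac * (d1 - d0))


def close_breakpoints(alignments: Sequence[LocalAlignment],
                      seq_lengths: dict) -> dict:
    """Breakpoint closure: sequence -> sorted breakpoint positions.

    Initial breakpoints are all alignment interval endpoints plus sequence
    ends; any breakpoint strictly inside one side of an alignment induces
    the proportionally mapped breakpoint on the other side.  Iterated to a
    fixed point (termination guaranteed by integer snapping).
    """
    points = {seq: {0, length} for seq, length in seq_lengths.items()}
    for aln in alignments:
        points[aln.query_seq].update((aln.query_start, aln.query_end))
        points[aln.target_seq].update((aln.target_start, aln.target_end))
    sides = []
    for aln in alignments:
        q = (aln.query_seq, (aln.query_start, aln.query_end))
        t = (aln.target_seq, (aln.target_start, aln.target_end))
        sides.append((q, t, aln.strand))
        sides.append((t, q, aln.strand))
    changed = True
    while changed:
        changed = False
        for (src_seq, src_iv), (dst_seq, dst_iv), strand in sides:
            for x in list(points[src_seq]):
                if src_iv[0] < x < src_iv[1]:
                    y = _project(x, src_iv, dst_iv, strand)
                    if y not in points[dst_seq]:
                        points[dst_seq].add(y)
                        changed = True
    return {seq: sorted(ps) for seq, ps in points.items()}


def _covered(seg_start: int, seg_end: int, seq: str,
             alignments: Sequence[LocalAlignment]) -> bool:
    for aln in alignments:
        if (seq == aln.query_seq and seg_start >= aln.query_start
                and seg_end <= aln.query_end):
            return True
        if (seq == aln.target_seq and seg_start >= aln.target_start
                and seg_end <= aln.target_end):
            return True
    return False


def _segment_once(alignments: Sequence[LocalAlignment], seq_lengths: dict,
                  min_length: int) -> tuple[list[Atom], int]:
    breakpoints = close_breakpoints(alignments, seq_lengths)
    atoms: list[Atom] = []
    covered_total = 0
    for seq in sorted(seq_lengths):
        bps = breakpoints[seq]
        for a, b in zip(bps, bps[1:]):
            if b - a >= min_length and _covered(a, b, seq, alignments):
                atoms.append(Atom(seq, a, b))
                covered_total += b - a
    waste = sum(seq_lengths.values()) - covered_total
    return atoms, waste


def segment(alignments: Sequence[LocalAlignment], seq_lengths: dict,
            min_length: int = 100) -> Segmentation:
    """Segment sequences into atoms, minimizing waste heuristically.

    Candidate atoms are maximal segments between consecutive closed
    breakpoints; segments shorter than ``min_length`` or covered by no
    alignment become waste.  A greedy pass then repeatedly discards the
    alignment whose removal reduces waste the most (alignments whose
    induced breakpoints fragment more sequence than they resolve), which
    never increases the waste total.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    kept = list(alignments)
    atoms, waste = _segment_once(kept, seq_lengths, min_length)
    improved = True
    while improved and kept:
        improved = False
        best = None
        for idx in range(len(kept)):
            subset = kept[:idx] + kept[idx + 1:]
            cand_atoms, cand_waste = _segment_once(subset, seq_lengths,
                                                   min_length)
            if cand_waste < waste and (best is None or cand_waste < best[1]):
                best = (idx, cand_waste, cand_atoms)
        if best is not None:
            idx, waste, atoms = best
            kept.pop(idx)
            improved = True
    return Segmentation(atoms=atoms, waste_total=waste,
                        min_length=min_length, kept_alignments=kept,
                        seq_lengths=dict(seq_lengths))


def assign_families(segmentation: Segmentation,
                    alignments: Optional[Sequence[LocalAlignment]] = None,
                    overlap_frac: float = 0.8) -> Segmentation:
    """Group atoms into families via the alignments connecting them.

    An alignment links atom a to atom b when it maps at least
    ``overlap_frac`` of a onto at least ``overlap_frac`` of b; families are
    the connected components of the resulting graph, and orientations are
    assigned by breadth-first sign propagation from each component's
    representative (smallest atom by coordinate).
    """
    if alignments is None:
        alignments = segmentation.kept_alignments
    atoms = segmentation.atoms
    by_seq: dict[str, list[int]] = {}
    for idx, atom in enumerate(atoms):
        by_seq.setdefault(atom.seq, []).append(idx)

    graph = nx.Graph()
    graph.add_nodes_from(range(len(atoms)))
    for aln in alignments:
        for (src_seq, src_iv, dst_seq, dst_iv) in (
                (aln.query_seq, (aln.query_start, aln.query_end),
                 aln.target_seq, (aln.target_start, aln.target_end)),
                (aln.target_seq, (aln.target_start, aln.target_end),
                 aln.query_seq, (aln.query_start, aln.query_end))):
            for ia in by_seq.get(src_seq, []):
                a = atoms[ia]
                lo = max(a.start, src_iv[0])
                hi = min(a.end, src_iv[1])
                if hi - lo < overlap_frac * a.length:
                    continue
                pa = _project(lo, src_iv, dst_iv, aln.strand)
                pb = _project(hi, src_iv, dst_iv, aln.strand)
                plo, phi = min(pa, pb), max(pa, pb)
                for ib in by_seq.get(dst_seq, []):
                    if ib == ia:
                        continue
                    b = atoms[ib]
                    o = min(phi, b.end) - max(plo, b.start)
                    if o >= overlap_frac * b.length:
                        sign = 1 if aln.strand == "+" else -1
                        graph.add_edge(ia, ib, sign=sign)

    components = sorted(nx.connected_components(graph),
                        key=lambda c: min((atoms[i].seq, atoms[i].start)
                                          for i in c))
    new_atoms = [replace(a) for a in atoms]
    for fam_idx, comp in enumerate(components):
        fam = f"F{fam_idx + 1}"
        rep = min(comp, key=lambda i: (atoms[i].seq, atoms[i].start))
        signs = {rep: 1}
        for u, v in nx.bfs_edges(graph.subgraph(comp), rep):
            if v not in signs:
                signs[v] = signs[u] * graph[u][v]["sign"]
        for i in comp:
            new_atoms[i].family = fam
            new_atoms[i].orientation = "+" if signs[i] > 0 else "-"
    return replace(segmentation, atoms=new_atoms)


def export_markers(segmentation: Segmentation, seq_to_genome: dict,
                   min_genomes: int = 2) -> list[Genome]:
    """Turn family-assigned atoms into signed marker sequences per genome.

    Families whose atoms span fewer than ``min_genomes`` distinct genomes
    are dropped (markers private to one genome carry no comparative
    signal).
    """
    fam_genomes: dict[str, set[str]] = {}
    for atom in segmentation.atoms:
        if atom.family is None:
            raise ValueError("assign_families must be applied first")
        fam_genomes.setdefault(atom.family, set()).add(
            seq_to_genome[atom.seq])
    shared = {f for f, gs in fam_genomes.items() if len(gs) >= min_genomes}

    genomes: dict[str, Genome] = {}
    for seq in sorted({a.seq for a in segmentation.atoms}):
        gid = seq_to_genome[seq]
        genome = genomes.setdefault(gid, Genome([], gid))
        markers = [
            (a.family, 1 if a.orientation == "+" else -1)
            for a in sorted((a for a in segmentation.atoms
                             if a.seq == seq and a.family in shared),
                            key=lambda a: a.start)
        ]
        genome.chromosomes.append(MarkerSequence(markers, seq, gid))
    return list(genomes.values())


def write_atoms_bed(path, segmentation: Segmentation) -> None:
    """BED6: chrom, start, end, name=family.copyIndex, score=0, strand."""
    copy_counter: dict[str, int] = {}
    rows = []
    for atom in sorted(segmentation.atoms, key=lambda a: (a.seq, a.start)):
        fam = atom.family if atom.family is not None else "NA"
        copy_counter[fam] = copy_counter.get(fam, 0) + 1
        rows.append((atom.seq, atom.start, atom.end,
                     f"{fam}.{copy_counter[fam]}", 0, atom.orientation))
    with open(path, "w") as handle:
        for row in rows:
            handle.write("\t".join(str(x) for x in row) + "\n")


def fasta_lengths(path) -> dict:
    """Sequence id -> length from a FASTA file (only lengths and ids are
    needed by segmentation)."""
    from Bio import SeqIO
    return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
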