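"""Reference-based discovery of approximate common intervals.

A syntenic block set is anchored at an interval of a designated *reference*
genome; the interval's family content G defines the block.  Occurrences of
the block in any genome (including additional occurrences in the reference
itself) are windows whose content deviates from G by at most delta_add
inserted families, delta_loss missing families, and delta_sum of both,
where the thresholds depend on |G| through a delta table.  A quorum q
requires each reported block set to span at least q distinct genomes.

Only the input/output semantics of this stage are modeled (window scan with
family-position anchoring); no attempt is made to reproduce any particular
discovery engine's internal algorithmics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import pandas as pd

from .genome_model import Genome, MarkerSequence


@dataclass(frozen=True)
class DeltaRow:
    add: int
    loss: int
    sum: int

    def admits(self, inserted: int, missing: int) -> bool:
        return (inserted <= self.add and missing <= self.loss
                and inserted + missing <= self.sum)


class DeltaTable:
    """Per-content-size indel thresholds (delta_add, delta_loss, delta_sum).

    The published workflow configures these from supplementary tables that
    are not part of this package; the named profiles shipped here are
    conservative stand-ins with the same shape (thresholds grow with the
    content size), and arbitrary tables can be loaded from TSV.
    """

    def __init__(self, profile: str, row_fn: Callable[[int], DeltaRow]):
        self.profile = profile
        self._row_fn = row_fn

    def row(self, content_size: int) -> DeltaRow:
        r = self._row_fn(content_size)
        if not (r.add <= r.sum and r.loss <= r.sum):
            raise ValueError(
                f"invalid delta row for size {content_size}: {r}")
        return r

    @classmethod
    def default(cls) -> "DeltaTable":
        return cls("default",
                   lambda s: DeltaRow(s // 4, s // 4, s // 3))

    @classmethod
    def relaxed(cls) -> "DeltaTable":
        return cls("relaxed",
                   lambda s: DeltaRow(s // 3, s // 3, s // 2))

    @classmethod
    def zero(cls) -> "DeltaTable":
        """Exact common intervals: no insertions or losses tolerated."""
        return cls("zero", lambda s: DeltaRow(0, 0, 0))

    @classmethod
    def from_profile(cls, name: str) -> "DeltaTable":
        try:
            return {"default": cls.default, "relaxed": cls.relaxed,
                    "zero": cls.zero}[name]()
        except KeyError:
            raise ValueError(f"unknown delta profile {name!r}") from None

    @classmethod
    def from_tsv(cls, path) -> "DeltaTable":
        """Custom table: TSV with columns size, add, loss, sum.  Sizes not
        listed use the row of the largest listed size below them (step
        function); rows must be monotonically non-decreasing in size."""
        frame = pd.read_csv(path, sep="\t")
        for col in ("size", "add", "loss", "sum"):
            if col not in frame.columns:
                raise ValueError(f"delta table {path} lacks column {col!r}")
        frame = frame.sort_values("size")
        rows = [(int(r.size), DeltaRow(int(r.add), int(r.loss), int(r.sum)))
                for r in frame.itertuples(index=False)]
        for (_, a), (_, b) in zip(rows, rows[1:]):
            if b.add < a.add or b.loss < a.loss or b.sum < a.sum:
                raise ValueError(
                    f"delta table {path} is not monotone in content size")

        def row_fn(s: int) -> DeltaRow:
            best = DeltaRow(0, 0, 0)
            for size, r in rows:
                if size <= s:
                    best = r
                else:
                    break
            return best

        return cls("custom", row_fn)


@dataclass(frozen=True)
class BlockOccurrence:
    """One occurrence window of a block set; 1-based inclusive marker
    ordinals."""

    genome: str
    chromosome: str
    start: int
    end: int
    inserted: int
    missing: int
    is_reference: bool = False

    @property
    def marker_span(self) -> int:
        return self.end - self.start + 1


@dataclass
class SyntenicBlockSet:
    block_id: str
    content: frozenset
    occurrences: list[BlockOccurrence] = field(default_factory=list)
    quorum_met: bool = True

    @property
    def reference_occurrence(self) -> BlockOccurrence:
        return next(o for o in self.occurrences if o.is_reference)

    @property
    def genomes(self) -> set[str]:
        return {o.genome for o in self.occurrences}

    def marker_occurrence_ids(self) -> set[tuple[str, str, int]]:
        """All (genome, chromosome, position) triples covered by any
        occurrence of the set."""
        ids = set()
        for occ in self.occurrences:
            for pos in range(occ.start, occ.end + 1):
                ids.add((occ.genome, occ.chromosome, pos))
        return ids


def interval_deviation(ref_content: Iterable, window) -> tuple[int, int]:
    """(inserted, missing) of a window against a reference content, with
    set semantics over families."""
    ref = {str(f) for f in ref_content}
    if isinstance(window, MarkerSequence):
        fams = {f for f, _ in window.markers}
    else:
        fams = {f if isinstance(f, str) else str(abs(f)) for f in
                (m[0] if isinstance(m, tuple) else m for m in window)}
    return len(fams - ref), len(ref - fams)


def _maximal_reference_intervals(chrom: MarkerSequence, min_size: int,
                                 all_intervals: bool,
                                 max_ref_size: Optional[int]
                                 ) -> list[tuple[int, int, frozenset]]:
    """Candidate reference intervals [i, j] (1-based inclusive) with
    content size >= min_size.  Unless ``all_intervals``, only intervals
    that cannot be extended without changing their content are kept."""
    fams = [f for f, _ in chrom.markers]
    n = len(fams)
    out = []
    for i in range(n):
        seen: set[str] = set()
        for j in range(i, n):
            seen.add(fams[j])
            size = len(seen)
            if size < min_size:
                continue
            if max_ref_size is not None and size > max_ref_size:
                break
            if not all_intervals:
                left_max = i == 0 or fams[i - 1] not in seen
                right_max = j == n - 1 or fams[j + 1] not in seen
                if not (left_max and right_max):
                    continue
            out.append((i + 1, j + 1, frozenset(seen)))
    return out


def _satisfying_windows(chrom: MarkerSequence, ref_content: frozenset,
                        row: DeltaRow) -> list[tuple[int, int, int, int]]:
    """Maximal windows (start, end, inserted, missing), 1-based inclusive,
    satisfying the delta row.  Window endpoints must carry families of the
    reference content; maximality is inclusion-maximality among satisfying
    windows of the chromosome."""
    fams = [f for f, _ in chrom.markers]
    n = len(fams)
    anchors = [k for k in range(n) if fams[k] in ref_content]
    sat: list[tuple[int, int, int, int]] = []
    n_ref = len(ref_content)
    for k in anchors:
        present: set[str] = set()
        inserted = 0
        for l in range(k, n):
            if fams[l] in ref_content:
                present.add(fams[l])
            else:
                inserted += 1
                if inserted > row.add:
                    break
                continue
            missing = n_ref - len(present)
            if row.admits(inserted, missing):
                sat.append((k + 1, l + 1, inserted, missing))
    # inclusion-maximality
    sat.sort(key=lambda w: (w[0], -w[1]))
    maximal = []
    max_end = 0
    for w in sat:
        if w[1] > max_end:
            maximal.append(w)
            max_end = w[1]
    return maximal


def discover_blocks(genomes: Sequence[Genome], reference_genome_id: str,
                    delta: DeltaTable, quorum: int = 2, min_ref_size: int = 2,
                    all_intervals: bool = False,
                    max_ref_size: Optional[int] = None
                    ) -> list[SyntenicBlockSet]:
    """Discover reference-based approximate common intervals.

    For every candidate reference interval with content G of size >=
    min_ref_size, occurrence windows satisfying the delta row for |G| are
    collected from every chromosome of every genome.  Windows in the
    reference chromosome that overlap the defining interval are represented
    by the reference occurrence itself (reported with zero deviation).
    Block sets are deduplicated by content plus occurrence set, and only
    sets spanning at least ``quorum`` distinct genomes are returned.
    """
    if quorum < 2:
        raise ValueError("quorum must be >= 2")
    if min_ref_size < 2:
        raise ValueError("min_ref_size must be >= 2")
    by_id = {g.genome_id: g for g in genomes}
    if reference_genome_id not in by_id:
        raise ValueError(f"reference genome {reference_genome_id!r} absent")
    reference = by_id[reference_genome_id]

    seen_sets: set = set()
    blocks: list[SyntenicBlockSet] = []
    for ref_chrom in reference.chromosomes:
        for i, j, content in _maximal_reference_intervals(
                ref_chrom, min_ref_size, all_intervals, max_ref_size):
            row = delta.row(len(content))
            ref_occ = BlockOccurrence(reference_genome_id,
                                      ref_chrom.sequence_id, i, j, 0, 0,
                                      is_reference=True)
            occurrences = [ref_occ]
            for genome in genomes:
                for chrom in genome.chromosomes:
                    for s, e, ins, mis in _satisfying_windows(
                            chrom, content, row):
                        if (genome.genome_id == reference_genome_id
                                and chrom.sequence_id == ref_chrom.sequence_id
                                and s <= j and e >= i):
                            continue  # overlaps the defining interval
                        occurrences.append(BlockOccurrence(
                            genome.genome_id, chrom.sequence_id, s, e,
                            ins, mis))
            n_genomes = len({o.genome for o in occurrences})
            if n_genomes < quorum:
                continue
            key = (content, frozenset(
                (o.genome, o.chromosome, o.start, o.end, o.is_reference)
                for o in occurrences))
            if key in seen_sets:
                continue
            seen_sets.add(key)
            blocks.append(SyntenicBlockSet(
                block_id="", content=content, occurrences=occurrences,
                quorum_met=True))
    blocks.sort(key=lambda b: (b.reference_occurrence.chromosome,
                               b.reference_occurrence.start,
                               b.reference_occurrence.end,
                               sorted(b.content)))
    for k, b in enumerate(blocks):
        b.block_id = f"B{k:05d}"
    return blocks


def apply_overlap_cap(blocks: Sequence[SyntenicBlockSet],
                      weight: Callable[[SyntenicBlockSet], float],
                      cap: int = 30) -> list[SyntenicBlockSet]:
    """Within every connected set of mutually overlapping block sets (sets
    sharing a marker occurrence), keep only the ``cap`` highest-weight
    blocks."""
    parent = list(range(len(blocks)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    occ_to_block: dict = {}
    for idx, block in enumerate(blocks):
        for mid in block.marker_occurrence_ids():
            if mid in occ_to_block:
                a, b = find(occ_to_block[mid]), find(idx)
                if a != b:
                    parent[a] = b
            else:
                occ_to_block[mid] = idx
    groups: dict[int, list[int]] = {}
    for idx in range(len(blocks)):
        groups.setdefault(find(idx), []).append(idx)
    keep: set[int] = set()
    for members in groups.values():
        members.sort(key=lambda idx: (-weight(blocks[idx]),
                                      blocks[idx].block_id))
        keep.update(members[:cap])
    return [b for idx, b in enumerate(blocks) if idx in keep]


# ---------------------------------------------------------------------------
# block TSV

BLOCK_COLUMNS = ["block_id", "genome", "chromosome", "start_pos", "end_pos",
                 "inserted", "missing", "is_reference"]


def write_block_tsv(path, blocks: Iterable[SyntenicBlockSet]) -> None:
    rows = []
    for block in blocks:
        for occ in block.occurrences:
            rows.append((block.block_id, occ.genome, occ.chromosome,
                         occ.start, occ.end, occ.inserted, occ.missing,
                         int(occ.is_reference)))
    pd.DataFrame(rows, columns=BLOCK_COLUMNS).to_csv(
        path, sep="\t", index=False)


def read_block_tsv(path) -> list[SyntenicBlockSet]:
    frame = pd.read_csv(path, sep="\t", dtype={
        "block_id": str, "genome": str, "chromosome": str})
    blocks: dict[str, SyntenicBlockSet] = {}
    for row in frame.itertuples(index=False):
        block = blocks.setdefault(
            str(row.block_id),
            SyntenicBlockSet(block_id=str(row.block_id),
                             content=frozenset()))
        block.occurrences.append(BlockOccurrence(
            str(row.genome), str(row.chromosome), int(row.start_pos),
            int(row.end_pos), int(row.inserted), int(row.missing),
            bool(row.is_reference)))
    return list(blocks.values())
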