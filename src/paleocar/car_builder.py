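"""Assembly of contiguous ancestral regions (CARs).

The final stage of the workflow decides which refined marker families are
part of the ancestral genome content, derives weighted candidate ancestral
intervals (observed adjacencies and syntenic block contents), and greedily
inserts them in decreasing weight into a PQ-tree under the
consecutive-ones constraint.  The tree's top-level subtrees are the CARs;
Q-nodes fix the relative order of their children while P-nodes leave it
open, so the mean Q-node child count quantifies how *fixed* the
reconstructed marker order is.

Each refined family contributes at most one ancestral marker, and marker
orientations are not reconstructed: CARs are unsigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .genome_model import Genome
from .pqtree import PQNode, PQTree, adjacency_realizable, pq_insert
from .synteny import SyntenicBlockSet


@dataclass
class CandidateInterval:
    """A candidate ancestral interval: a family set that should be
    contiguous in the ancestor, with its supporting extant witnesses.

    ``alternates`` lists interchangeable realizations of the same piece of
    evidence (an ancestral adjacency witnessed through different retained
    copies of its two families), in preference order; the greedy tree
    builder commits to the first one that fits.  ``spans_split`` marks
    candidates witnessed on both sides of the configured clade split —
    such neighborhoods predate the root speciation and outrank equally
    weighted clade-confined (hence possibly derived) ones.
    """

    content: frozenset
    weight: float
    support: list = field(default_factory=list)  # (genome, chromosome, info)
    alternates: list = field(default_factory=list)
    spans_split: bool = True

    def realizations(self) -> list:
        return self.alternates if self.alternates else [self.content]


def ancestral_content(refined_genomes: Sequence[Genome],
                      clade_split: Optional[tuple] = None) -> set:
    """Families recruited into the ancestral genome content.

    A refined family qualifies when it occurs in at least two genomes; if
    a two-clade split of the genome set is given, the two witnesses must
    come from opposite sides of the split (occurrence on both sides of the
    ancestral speciation is the standard support rule; any-two-genomes is
    the fallback).
    """
    fam_genomes: dict = {}
    for genome in refined_genomes:
        for chrom in genome.chromosomes:
            for fam, _ in chrom.markers:
                fam_genomes.setdefault(fam, set()).add(genome.genome_id)
    if clade_split is None:
        return {f for f, gs in fam_genomes.items() if len(gs) >= 2}
    side_a, side_b = (set(clade_split[0]), set(clade_split[1]))
    return {f for f, gs in fam_genomes.items()
            if gs & side_a and gs & side_b}


def collect_candidates(refined_genomes: Sequence[Genome],
                       blocks: Sequence[SyntenicBlockSet],
                       scored: Sequence,
                       content: Optional[set] = None,
                       weight_mode: str = "occurrence",
                       clade_split: Optional[tuple] = None,
                       leaf_to_parent: Optional[dict] = None
                       ) -> list[CandidateInterval]:
    """Candidate ancestral intervals from extant evidence.

    (a) every adjacency of ancestral families observed in >= 2 genomes,
        read off each chromosome after projecting it onto the ancestral
        content.  Support is pooled at the level of the original
        (pre-refinement) families via ``leaf_to_parent``: refinement
        splits a family's occurrences across sub-family ids, so the
        witnesses of one ancestral adjacency may carry different refined
        id pairs.  Each supported parent-level adjacency yields one
        candidate whose alternates are its possible copy realizations —
        observed refined pairs first (same-overlap-component pairs
        preferred, then best-witnessed), then the remaining copy
        combinations.
    (b) the content of every syntenic block set, restricted to ancestral
        families via the refined family ids of the markers inside the
        reference window.

    Weights: with ``weight_mode="witness"`` (the pipeline default)
    adjacencies are weighted by their total witness count across genomes
    and retained copies — a truly ancestral adjacency recurs in several
    retained copies per genome, a fractionation or rearrangement artifact
    typically in one — and blocks by their summed local DCJ scores.  With
    ``"occurrence"`` both are weighted by the number of supporting
    genomes; with ``"dcj"`` blocks use summed local DCJ scores and
    adjacencies the number of supporting genomes.  When ``clade_split``
    is given, candidates witnessed on both sides of the split are marked
    (see :class:`CandidateInterval`).
    """
    if weight_mode not in ("occurrence", "dcj", "witness"):
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    if content is None:
        content = ancestral_content(refined_genomes)
    if leaf_to_parent is None:
        leaf_to_parent = {}
    side_a = set(clade_split[0]) if clade_split else set()
    side_b = set(clade_split[1]) if clade_split else set()

    def spans(genomes_seen: set) -> bool:
        if not clade_split:
            return True
        return bool(genomes_seen & side_a) and bool(genomes_seen & side_b)

    candidates: list[CandidateInterval] = []

    parent_support: dict = {}   # parent pair -> set of genomes
    parent_witness: dict = {}   # parent pair -> total occurrence count
    refined_pairs: dict = {}    # parent pair -> refined pair -> witnesses
    leaves_of: dict = {}        # parent family -> its leaves
    for leaf in content:
        leaves_of.setdefault(leaf_to_parent.get(leaf, leaf), []).append(leaf)
    for genome in refined_genomes:
        for chrom in genome.chromosomes:
            projected = [fam for fam, _ in chrom.markers if fam in content]
            for a, b in zip(projected, projected[1:]):
                if a == b:
                    continue
                parent_key = frozenset((leaf_to_parent.get(a, a),
                                        leaf_to_parent.get(b, b)))
                pair = frozenset((a, b))
                parent_support.setdefault(parent_key, set()).add(
                    genome.genome_id)
                parent_witness[parent_key] = \
                    parent_witness.get(parent_key, 0) + 1
                refined_pairs.setdefault(parent_key, {}).setdefault(
                    pair, []).append((genome.genome_id,
                                      chrom.sequence_id, "adjacency"))

    def _component_suffix(leaf: str) -> str:
        base = leaf.split("#")[0]
        return base.split("@")[1] if "@" in base else ""

    def _same_component(pair) -> bool:
        x, y = sorted(pair)
        return _component_suffix(x) == _component_suffix(y)

    for parent_key in sorted(parent_support, key=sorted):
        genomes_seen = parent_support[parent_key]
        if len(genomes_seen) < 2:
            continue
        if len(parent_key) == 1:
            continue  # adjacent copies of one family: no order information
        observed = sorted(
            refined_pairs[parent_key],
            key=lambda pr: (0 if _same_component(pr) else 1,
                            -len(refined_pairs[parent_key][pr]),
                            sorted(pr)))
        pa, pb = sorted(parent_key)
        unobserved = sorted(
            (frozenset((x, y))
             for x in leaves_of.get(pa, []) for y in leaves_of.get(pb, [])
             if x != y and frozenset((x, y)) not in refined_pairs[parent_key]),
            key=lambda pr: (0 if _same_component(pr) else 1, sorted(pr)))
        if weight_mode == "witness":
            weight = float(parent_witness[parent_key])
        else:
            weight = float(len(genomes_seen))
        witnesses = [w for pr in observed
                     for w in refined_pairs[parent_key][pr]]
        candidates.append(CandidateInterval(
            content=observed[0], weight=weight, support=sorted(witnesses),
            alternates=observed + unobserved,
            spans_split=spans(genomes_seen)))

    refined_at: dict = {}
    for genome in refined_genomes:
        for chrom in genome.chromosomes:
            for pos, (fam, _) in enumerate(chrom.markers, start=1):
                refined_at[(genome.genome_id, chrom.sequence_id, pos)] = fam
    scores_by_block: dict = {}
    for rec in scored:
        scores_by_block.setdefault(rec.block_id, 0.0)
        scores_by_block[rec.block_id] += rec.result.score
    for block in blocks:
        ref = block.reference_occurrence
        fams = {refined_at.get((ref.genome, ref.chromosome, pos))
                for pos in range(ref.start, ref.end + 1)}
        restricted = frozenset(f for f in fams
                               if f is not None and f in content)
        if len(restricted) < 2:
            continue
        if weight_mode in ("dcj", "witness"):
            weight = scores_by_block.get(block.block_id, 0.0)
        else:
            weight = float(len(block.genomes))
        if weight <= 0:
            continue
        support = [(o.genome, o.chromosome, block.block_id)
                   for o in block.occurrences]
        candidates.append(CandidateInterval(
            content=restricted, weight=weight, support=support,
            spans_split=spans(block.genomes)))
    return candidates


@dataclass
class InsertionLogEntry:
    content: frozenset
    weight: float
    accepted: bool


def build_pq_tree(candidates: Sequence[CandidateInterval],
                  leaves: set) -> tuple[PQTree, list[InsertionLogEntry]]:
    """Greedy weighted insertion.

    Candidates are processed in decreasing weight (ties: clade-spanning
    candidates first, then smaller content, then lexicographic); for each
    candidate the alternates are tried in preference order and the first
    one compatible with the tree is committed; candidates with no
    compatible realization are skipped."""
    tree = PQTree.universal(leaves)
    log: list[InsertionLogEntry] = []
    ordered = sorted(candidates,
                     key=lambda c: (-c.weight, 0 if c.spans_split else 1,
                                    len(c.content), sorted(c.content)))
    for cand in ordered:
        accepted = False
        chosen = cand.content
        for alt in cand.realizations():
            tree, ok = pq_insert(tree, alt)
            if ok:
                accepted, chosen = True, alt
                break
        log.append(InsertionLogEntry(chosen, cand.weight, accepted))
    return tree, log


@dataclass
class CAR:
    """One contiguous ancestral region: a run of unsigned ancestral
    markers; maximal unordered groups (P-node descendants) are wrapped in
    parentheses in the rendering."""

    car_id: str
    markers: list[str]
    rendering: str


def _render(node: PQNode) -> str:
    if node.kind == "leaf":
        return node.label
    parts = " ".join(_render(c) for c in node.children)
    if node.kind == "P":
        return f"({parts})"
    return parts


def extract_cars(tree: PQTree) -> tuple[list[CAR], Optional[float]]:
    """CARs (top-level subtrees of the tree) plus the Q-node fixation
    metric: the mean child count over all Q nodes, absent when the tree
    has none."""
    if tree.root.kind == "P":
        subtrees = tree.root.children
    else:
        subtrees = [tree.root]
    cars = []
    for k, node in enumerate(subtrees):
        rendering = _render(node)
        if node.kind == "P":
            rendering = rendering  # top-level P-group keeps its parentheses
        cars.append(CAR(car_id=f"CAR{k + 1:04d}", markers=node.leaves(),
                        rendering=rendering))
    counts = tree.q_node_child_counts()
    fixation = sum(counts) / len(counts) if counts else None
    return cars, fixation


def write_car_file(path, cars: Sequence[CAR]) -> None:
    with open(path, "w") as handle:
        for car in cars:
            handle.write(f"{car.car_id}\t{car.rendering}\n")


def adjacency_recovery(tree: PQTree, true_adjacencies: Sequence[frozenset],
                       leaf_to_ancestral: dict) -> Optional[float]:
    """Fraction of true ancestral adjacencies realizable within the tree.

    ``leaf_to_ancestral`` maps each tree leaf (refined family) to its
    ancestral family; an adjacency {a, b} counts as recovered when some
    pair of leaves mapping to a and b lies within one CAR (one top-level
    subtree) and can be made adjacent in a frontier.  Only adjacencies
    whose two families are both represented among the leaves are
    assessed; returns None if none are.
    """
    by_ancestral: dict = {}
    for leaf, anc in leaf_to_ancestral.items():
        by_ancestral.setdefault(anc, []).append(leaf)
    assessable = [adj for adj in true_adjacencies
                  if all(a in by_ancestral for a in adj)]
    if not assessable:
        return None
    subtrees = (tree.root.children if tree.root.kind == "P"
                else [tree.root])
    car_of: dict = {}
    for k, node in enumerate(subtrees):
        for leaf in node.leaves():
            car_of[leaf] = k
    recovered = 0
    for adj in assessable:
        a, b = sorted(adj)
        if any(car_of[x] == car_of[y] and adjacency_realizable(tree, x, y)
               for x in by_ancestral[a] for y in by_ancestral[b]):
            recovered += 1
    return recovered / len(assessable)
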