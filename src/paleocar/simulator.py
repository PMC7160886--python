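"""Synthetic genome evolution with rearrangement and polyploidy.

Generates datasets with the statistical structure the reconstruction
pipeline assumes: an ancestor of linear chromosomes of unique signed
markers evolves along a rooted phylogeny; each branch applies whole-genome
multiplication events (duplication or triplication, each followed by
random fractionation of the redundant copies) and a number of random DCJ
operations (inversions, translocations, fusions).  Every extant marker
occurrence is tracked back to its ancestral marker and post-polyploidy
copy lineage, so true ortholog groups and true ancestral adjacencies are
available as ground truth for recovery tests.

All randomness flows from one integer seed through per-branch
``numpy.random.SeedSequence`` spawns: identical configurations yield
byte-identical datasets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .genome_model import Genome, MarkerSequence, write_marker_tsv

#: one simulated occurrence: (ancestral marker id, copy lineage, sign)
Occurrence = tuple[str, str, int]
Chromosomes = list  # list[list[Occurrence]]

DUPLICATION = "duplication"
TRIPLICATION = "triplication"


@dataclass
class PhyloNode:
    """A phylogeny node; the event fields describe the branch leading
    into the node (the root carries no events)."""

    name: str
    dcj_ops: int = 0
    wg_events: list = field(default_factory=list)
    loss_rate: float = 0.0
    children: list = field(default_factory=list)

    def __post_init__(self):
        if not (0.0 <= self.loss_rate <= 1.0):
            raise ValueError("loss_rate must lie in [0, 1]")
        for ev in self.wg_events:
            if ev not in (DUPLICATION, TRIPLICATION):
                raise ValueError(f"unknown whole-genome event {ev!r}")

    def leaves(self) -> list["PhyloNode"]:
        if not self.children:
            return [self]
        out = []
        for child in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class SimConfig:
    n_markers: int
    n_chromosomes: int
    phylogeny: PhyloNode
    seed: int

    def __post_init__(self):
        if self.n_chromosomes > self.n_markers:
            raise ValueError("n_chromosomes must not exceed n_markers")
        if self.n_chromosomes < 0 or self.n_markers < 0:
            raise ValueError("sizes must be non-negative")


@dataclass
class TruthSet:
    """Ground truth of one simulated dataset."""

    ancestor: Genome
    #: (genome, chromosome, position) -> copy lineage label "anc.x.y"
    lineages: dict = field(default_factory=dict)
    #: (genome, chromosome, position) -> ancestral marker id
    ancestral_marker: dict = field(default_factory=dict)
    operations_log: list = field(default_factory=list)

    def true_adjacencies(self) -> set:
        """Unordered family pairs adjacent in the ancestor."""
        adjacencies = set()
        for chrom in self.ancestor.chromosomes:
            fams = [f for f, _ in chrom.markers]
            for a, b in zip(fams, fams[1:]):
                adjacencies.add(frozenset((a, b)))
        return adjacencies


def _rng(seed: int, *path: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed,
                                                        spawn_key=path))


def simulate_ancestor(config: SimConfig) -> Chromosomes:
    """Random ancestor: n unique signed markers over n_chromosomes linear
    chromosomes (markers shuffled, signs and chromosome cuts random)."""
    rng = _rng(config.seed, 0)
    n, k = config.n_markers, config.n_chromosomes
    order = rng.permutation(n)
    signs = rng.choice([1, -1], size=n)
    occurrences = [(str(order[i] + 1), str(order[i] + 1), int(signs[i]))
                   for i in range(n)]
    if k <= 1:
        return [occurrences] if occurrences else []
    cuts = sorted(rng.choice(np.arange(1, n), size=k - 1, replace=False))
    bounds = [0] + [int(c) for c in cuts] + [n]
    return [occurrences[a:b] for a, b in zip(bounds, bounds[1:])]


def _canonical(chroms: Chromosomes) -> tuple:
    def canon(chrom):
        fwd = tuple((a, l, s) for a, l, s in chrom)
        rev = tuple((a, l, -s) for a, l, s in reversed(chrom))
        return min(fwd, rev)

    return tuple(sorted(canon(c) for c in chroms))


def _reverse(segment: list) -> list:
    return [(a, l, -s) for a, l, s in reversed(segment)]


def apply_dcj_ops(chroms: Chromosomes, k: int,
                  rng: np.random.Generator,
                  log: Optional[list] = None) -> Chromosomes:
    """Apply k random DCJ operations, keeping all chromosomes linear.

    Cut points are drawn uniformly over all adjacencies including
    telomeric ones.  Intra-chromosomal cuts are resolved as inversions
    (the alternative rejoining excises a circular chromosome, which is
    disallowed and redrawn); inter-chromosomal cuts choose uniformly
    between the two non-trivial rejoinings (translocations; with telomeric
    cuts these realize fusions).  Operations that leave the genome
    unchanged are redrawn.
    """
    chroms = [list(c) for c in chroms]
    for _ in range(k):
        before = _canonical(chroms)
        for _attempt in range(100):
            slots = [(ci, p) for ci, c in enumerate(chroms)
                     for p in range(len(c) + 1)]
            if len(slots) < 2:
                break
            i1, i2 = rng.choice(len(slots), size=2, replace=False)
            (ca, a), (cb, b) = slots[int(i1)], slots[int(i2)]
            if ca == cb:
                a, b = min(a, b), max(a, b)
                cand = [list(c) for c in chroms]
                cand[ca] = (chroms[ca][:a] + _reverse(chroms[ca][a:b])
                            + chroms[ca][b:])
                op = ("inversion", ca, a, b)
            else:
                a1, a2 = chroms[ca][:a], chroms[ca][a:]
                b1, b2 = chroms[cb][:b], chroms[cb][b:]
                if rng.integers(2) == 0:
                    new_a, new_b = a1 + b2, b1 + a2
                    op = ("translocation", ca, a, cb, b, "straight")
                else:
                    new_a, new_b = a1 + _reverse(b1), _reverse(a2) + b2
                    op = ("translocation", ca, a, cb, b, "crossed")
                cand = [list(c) for ci, c in enumerate(chroms)
                        if ci not in (ca, cb)]
                cand.extend(c for c in (new_a, new_b) if c)
            if _canonical(cand) != before:
                chroms = cand
                if log is not None:
                    log.append(list(op))
                break
    return [c for c in chroms if c]


def apply_polyploidy(chroms: Chromosomes, kind: str, loss_rate: float,
                     rng: np.random.Generator,
                     log: Optional[list] = None) -> Chromosomes:
    """Whole-genome duplication/triplication followed by fractionation.

    Every chromosome is copied (x2 or x3) with the copy index appended to
    each occurrence's lineage label.  Each *redundant* copy of each
    pre-event occurrence is then lost independently with probability
    ``loss_rate``; one uniformly chosen copy per occurrence is protected,
    so every marker keeps at least one descendant.
    """
    factor = {DUPLICATION: 2, TRIPLICATION: 3}[kind]
    copies: list[Chromosomes] = []
    for copy_idx in range(factor):
        genome_copy = [
            [(anc, f"{lin}.{copy_idx + 1}", sign) for anc, lin, sign in c]
            for c in chroms
        ]
        copies.append(genome_copy)
    # group the copies of each pre-event occurrence for fractionation
    n_occ = sum(len(c) for c in chroms)
    protected = rng.integers(factor, size=n_occ)
    lost_draws = rng.random(size=(n_occ, factor))
    surviving: list[list] = []
    for copy_idx, genome_copy in enumerate(copies):
        token = 0
        kept_chroms = []
        for chrom in genome_copy:
            kept = []
            for occ in chrom:
                keep = (copy_idx == protected[token]
                        or lost_draws[token, copy_idx] >= loss_rate)
                if keep:
                    kept.append(occ)
                token += 1
            if kept:
                kept_chroms.append(kept)
        surviving.append(kept_chroms)
    if log is not None:
        log.append([kind, loss_rate])
    return [c for genome_copy in surviving for c in genome_copy]


def fractionate(chroms: Chromosomes, loss_rate: float,
                rng: np.random.Generator,
                log: Optional[list] = None) -> Chromosomes:
    """Lineage-specific fractionation of pre-existing redundancy.

    Each redundant copy of each marker family (all but one uniformly
    chosen protected occurrence) is lost independently with probability
    ``loss_rate``.  Applied on branches without whole-genome events, this
    models the continued, lineage-specific loss of copies created by an
    earlier polyploidization — the dominant mode of fractionation observed
    across plant lineages sharing an ancient polyploidy.
    """
    if loss_rate <= 0:
        return chroms
    by_family: dict = {}
    for ci, chrom in enumerate(chroms):
        for pi, (anc, _, _) in enumerate(chrom):
            by_family.setdefault(anc, []).append((ci, pi))
    doomed: set = set()
    for anc in sorted(by_family):
        occs = by_family[anc]
        if len(occs) == 1:
            continue
        protected = int(rng.integers(len(occs)))
        draws = rng.random(len(occs))
        for idx, occ in enumerate(occs):
            if idx != protected and draws[idx] < loss_rate:
                doomed.add(occ)
    out = []
    for ci, chrom in enumerate(chroms):
        kept = [occ for pi, occ in enumerate(chrom)
                if (ci, pi) not in doomed]
        if kept:
            out.append(kept)
    if log is not None:
        log.append(["fractionation", loss_rate, len(doomed)])
    return out


def _to_genome(chroms: Chromosomes, genome_id: str) -> Genome:
    sequences = []
    for idx, chrom in enumerate(chroms, start=1):
        markers = [(anc, sign) for anc, _, sign in chrom]
        sequences.append(MarkerSequence(markers, f"{genome_id}_chr{idx}",
                                        genome_id))
    return Genome(sequences, genome_id)


def simulate(config: SimConfig) -> tuple[list[Genome], TruthSet]:
    """Run the full simulation; returns leaf genomes plus ground truth."""
    ancestor_chroms = simulate_ancestor(config)
    truth = TruthSet(ancestor=_to_genome(ancestor_chroms, "ancestor"))
    leaf_genomes: list[Genome] = []

    def walk(node: PhyloNode, chroms: Chromosomes, path: tuple):
        rng = _rng(config.seed, 1, *path)
        branch_log: list = []
        for ev in node.wg_events:
            chroms = apply_polyploidy(chroms, ev, node.loss_rate, rng,
                                      branch_log)
        if not node.wg_events:
            chroms = fractionate(chroms, node.loss_rate, rng, branch_log)
        chroms = apply_dcj_ops(chroms, node.dcj_ops, rng, branch_log)
        if branch_log:
            truth.operations_log.append(
                {"node": node.name, "events": branch_log})
        if not node.children:
            genome = _to_genome(chroms, node.name)
            leaf_genomes.append(genome)
            for seq, chrom in zip(genome.chromosomes, chroms):
                for pos, (anc, lineage, _) in enumerate(chrom, start=1):
                    occ = (node.name, seq.sequence_id, pos)
                    truth.lineages[occ] = lineage
                    truth.ancestral_marker[occ] = anc
        else:
            for ci, child in enumerate(node.children):
                walk(child, chroms, path + (ci,))

    root = config.phylogeny
    # root-level events (if any) apply before the first split
    walk_root_path: tuple = ()
    walk(root, ancestor_chroms, walk_root_path)
    return leaf_genomes, truth


def emit_dataset(config: SimConfig, outdir) -> dict:
    """Write leaf marker TSVs plus truth files; returns the file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genomes, truth = simulate(config)
    files = {}
    for genome in genomes:
        path = outdir / f"{genome.genome_id}.markers.tsv"
        write_marker_tsv(path, [genome])
        files[genome.genome_id] = str(path)
    write_marker_tsv(outdir / "ancestor.tsv", [truth.ancestor])
    with open(outdir / "orthologs.tsv", "w") as handle:
        handle.write("genome_id\tchromosome_id\tposition\t"
                     "ancestral_marker\tlineage\n")
        for occ in sorted(truth.lineages):
            handle.write("\t".join(map(str, (*occ,
                                             truth.ancestral_marker[occ],
                                             truth.lineages[occ]))) + "\n")
    with open(outdir / "operations.json", "w") as handle:
        json.dump(truth.operations_log, handle, indent=1, sort_keys=True)
    files.update(ancestor=str(outdir / "ancestor.tsv"),
                 orthologs=str(outdir / "orthologs.tsv"),
                 operations=str(outdir / "operations.json"))
    return files


# ---------------------------------------------------------------------------
# study scenarios


def eudicot_phylogeny(dcj_ops: dict, loss_rate: float = 0.6,
                      asterids2_wgt: bool = True,
                      sunflower_wgd: bool = True) -> PhyloNode:
    """A five-leaf phylogeny shaped like the eudicot history: one rosid
    (grape) and four asterids (coffee, artichoke, lettuce, sunflower), a
    whole-genome triplication on the stem shared by all leaves,
    optionally a second triplication on the asterids-II stem (artichoke,
    lettuce, sunflower) and a duplication on the sunflower branch.

    Fractionation is lineage-specific: polyploidization events copy the
    genome without immediate loss, and each terminal branch then loses
    redundant copies at ``loss_rate`` — matching the observation that
    lineages sharing an ancient polyploidy retain largely independent
    subsets of the duplicated copies.

    ``dcj_ops`` maps branch names to operation counts (absent -> 0).
    """
    ops = dict(dcj_ops)

    def node(name, children=(), wg=(), loss=0.0):
        return PhyloNode(name, dcj_ops=ops.get(name, 0),
                         wg_events=list(wg), loss_rate=loss,
                         children=list(children))

    sunflower = node("sunflower", loss=loss_rate)
    if sunflower_wgd:
        sunflower = node("sunflower_wgd", [sunflower], wg=[DUPLICATION])
    lett_sun = node("lettuce_sunflower", [
        node("lettuce", loss=loss_rate),
        sunflower,
    ])
    asterids2 = node("asterids2", [node("artichoke", loss=loss_rate),
                                   lett_sun],
                     wg=[TRIPLICATION] if asterids2_wgt else [])
    asterids = node("asterids", [node("coffee", loss=loss_rate), asterids2])
    root = node("eudicots", [node("grape", loss=loss_rate), asterids],
                wg=[TRIPLICATION])
    return root


def eudicot_scenario(n_markers: int = 200, n_chromosomes: int = 5,
                     seed: int = 0, loss_rate: float = 0.6,
                     min_ops: int = 5, max_ops: int = 20,
                     asterids2_wgt: bool = True,
                     sunflower_wgd: bool = True) -> SimConfig:
    """Study configuration: eudicot-shaped phylogeny with per-branch DCJ
    operation counts drawn uniformly from [min_ops, max_ops]."""
    rng = _rng(seed, 99)
    branches = ["eudicots", "grape", "asterids", "coffee", "asterids2",
                "artichoke", "lettuce_sunflower", "lettuce", "sunflower"]
    ops = {name: int(rng.integers(min_ops, max_ops + 1))
           for name in branches}
    phylo = eudicot_phylogeny(ops, loss_rate=loss_rate,
                              asterids2_wgt=asterids2_wgt,
                              sunflower_wgd=sunflower_wgd)
    return SimConfig(n_markers=n_markers, n_chromosomes=n_chromosomes,
                     phylogeny=phylo, seed=seed)


def recovery_scenario(n_markers: int = 200, n_chromosomes: int = 5,
                      seed: int = 0) -> SimConfig:
    """Recovery-test configuration: the eudicot tree shape with a single
    triplication on the stem and a single duplication on the sunflower
    branch (no asterids-II triplication), fractionation rate 0.6, and
    5-20 DCJ operations per branch."""
    return eudicot_scenario(n_markers=n_markers,
                            n_chromosomes=n_chromosomes, seed=seed,
                            loss_rate=0.6, asterids2_wgt=False,
                            sunflower_wgd=True)
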