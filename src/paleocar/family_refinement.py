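"""Splitting marker families into sub-families from syntenic evidence.

After whole-genome multiplications, a homology family holds several
positional copies per genome and is useless for one-marker-per-family
ancestral reconstruction.  Two refinement rules split families using the
syntenic block sets and the one-to-one assignments produced by the local
DCJ similarity stage:

rule (i)   Block sets that share a marker occurrence form *overlap
           components*.  For every component O and family F whose
           occurrences intersect O, the occurrences of F inside O become a
           new family; occurrences of F outside every component keep F.

rule (ii)  Within a component, a reference occurrence m1 that is assigned
           to the same occurrence m_i of every non-reference genome S_i in
           every local DCJ computation it appears in founds a new family
           {m1, m2, ..., mk}.  Conflicting assignments (or an occurrence
           matched to two different reference anchors) leave the involved
           occurrences in their rule-(i) family.

Both rules only split: the output partition always refines the input, and
running the refinement twice is a no-op.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .genome_model import Genome, MarkerSequence
from .synteny import SyntenicBlockSet

#: (genome_id, chromosome_id, 1-based position)
OccurrenceId = tuple[str, str, int]


@dataclass
class FamilyPartition:
    """Total assignment of marker occurrences to family ids, with
    provenance for every family minted by refinement."""

    assignment: dict
    #: family -> (parent family, component id, rule in {"i", "ii"})
    provenance: dict = field(default_factory=dict)

    @classmethod
    def from_genomes(cls, genomes: Iterable[Genome]) -> "FamilyPartition":
        assignment = {}
        for genome in genomes:
            for chrom in genome.chromosomes:
                for pos, (family, _) in enumerate(chrom.markers, start=1):
                    assignment[(genome.genome_id, chrom.sequence_id,
                                pos)] = family
        return cls(assignment)

    def families(self) -> dict:
        """family id -> set of member occurrence ids."""
        members: dict = {}
        for occ, fam in self.assignment.items():
            members.setdefault(fam, set()).add(occ)
        return members

    def relabeled_genomes(self, genomes: Iterable[Genome]) -> list[Genome]:
        """Rewrite genomes with refined family ids, signs preserved."""
        out = []
        for genome in genomes:
            chroms = []
            for chrom in genome.chromosomes:
                markers = []
                for pos, (_, sign) in enumerate(chrom.markers, start=1):
                    fam = self.assignment[
                        (genome.genome_id, chrom.sequence_id, pos)]
                    markers.append((fam, sign))
                chroms.append(MarkerSequence(markers, chrom.sequence_id,
                                             genome.genome_id))
            out.append(Genome(chroms, genome.genome_id))
        return out


@dataclass
class OverlapComponent:
    component_id: str
    block_set_ids: set
    member_occurrences: set


def overlap_components(block_sets: Sequence[SyntenicBlockSet]
                       ) -> list[OverlapComponent]:
    """Connected components of the graph whose vertices are block sets,
    with an edge whenever two sets share a marker occurrence."""
    parent = list(range(len(block_sets)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    occ_owner: dict = {}
    block_occs = [b.marker_occurrence_ids() for b in block_sets]
    for idx, occs in enumerate(block_occs):
        for occ in occs:
            if occ in occ_owner:
                a, b = find(occ_owner[occ]), find(idx)
                if a != b:
                    parent[a] = b
            else:
                occ_owner[occ] = idx
    grouped: dict[int, list[int]] = {}
    for idx in range(len(block_sets)):
        grouped.setdefault(find(idx), []).append(idx)
    comps = []
    for members in grouped.values():
        occs = set().union(*(block_occs[i] for i in members))
        comps.append((min(occs), members, occs))
    comps.sort(key=lambda c: c[0])
    return [
        OverlapComponent(
            component_id=f"c{k}",
            block_set_ids={block_sets[i].block_id for i in members},
            member_occurrences=occs)
        for k, (_, members, occs) in enumerate(comps)
    ]


def refine_rule_i(partition: FamilyPartition,
                  components: Sequence[OverlapComponent]
                  ) -> FamilyPartition:
    """Split every family along overlap-component membership."""
    assignment = dict(partition.assignment)
    provenance = dict(partition.provenance)
    members = partition.families()
    for comp in components:
        by_family: dict = {}
        for occ in comp.member_occurrences:
            fam = partition.assignment.get(occ)
            if fam is not None:
                by_family.setdefault(fam, set()).add(occ)
        for fam, inside in sorted(by_family.items()):
            if inside == members[fam]:
                continue  # whole family inside the component: nothing to split
            new_id = f"{fam}@{comp.component_id}"
            for occ in inside:
                assignment[occ] = new_id
            provenance[new_id] = (fam, comp.component_id, "i")
    return FamilyPartition(assignment, provenance)


def refine_rule_ii(partition: FamilyPartition,
                   components: Sequence[OverlapComponent],
                   scored: Sequence,
                   reference_genome_id: str,
                   include_heuristic: bool = True) -> FamilyPartition:
    """Promote consistent one-to-one assignments to families of their own.

    ``scored`` holds :class:`~paleocar.local_dcj.ScoredOccurrence` records;
    results flagged as non-exact participate unless ``include_heuristic``
    is False.
    """
    block_to_comp: dict = {}
    for comp in components:
        for bid in comp.block_set_ids:
            block_to_comp[bid] = comp.component_id

    # per component: reference occurrence -> genome -> set of targets
    anchors: dict = {}
    target_anchors: dict = {}
    for rec in scored:
        if not include_heuristic and not rec.result.exact:
            continue
        comp_id = block_to_comp.get(rec.block_id)
        if comp_id is None:
            continue
        for ref_occ, tgt_occ in rec.matched_occurrences:
            if ref_occ[0] != reference_genome_id:
                continue
            anchors.setdefault(comp_id, {}).setdefault(
                ref_occ, {}).setdefault(tgt_occ[0], set()).add(tgt_occ)
            target_anchors.setdefault(tgt_occ, set()).add(ref_occ)

    assignment = dict(partition.assignment)
    provenance = dict(partition.provenance)
    members = partition.families()
    claimed: set = set()
    for comp_id in sorted(anchors):
        serial = 0
        for m1 in sorted(anchors[comp_id]):
            per_genome = anchors[comp_id][m1]
            if any(len(tgts) > 1 for tgts in per_genome.values()):
                continue  # conflicting assignments across computations
            targets = sorted(t for tgts in per_genome.values()
                             for t in tgts)
            targets = [t for t in targets
                       if len(target_anchors[t]) == 1 and t not in claimed]
            if not targets or m1 in claimed:
                continue
            group = [m1] + targets
            fams = {partition.assignment.get(occ) for occ in group}
            if len(fams) != 1 or None in fams:
                continue  # matched across families: not refinable
            fam = fams.pop()
            claimed.update(group)
            if set(group) == members[fam]:
                # the family already coincides with the group: keep its
                # label (idempotence) but record the rule-(ii) confirmation
                parent = provenance.get(fam, (fam,))[0]
                comp = provenance.get(fam, (None, comp_id))[1]
                provenance[fam] = (parent, comp, "ii")
                continue
            new_id = f"{assignment[m1]}#{serial}"
            serial += 1
            for occ in group:
                assignment[occ] = new_id
            provenance[new_id] = (fam, comp_id, "ii")
    return FamilyPartition(assignment, provenance)


def refine(partition: FamilyPartition,
           block_sets: Sequence[SyntenicBlockSet],
           scored: Sequence,
           reference_genome_id: str,
           include_heuristic: bool = True) -> FamilyPartition:
    """Full refinement: rule (i) then rule (ii)."""
    components = overlap_components(block_sets)
    step1 = refine_rule_i(partition, components)
    return refine_rule_ii(step1, components, scored, reference_genome_id,
                          include_heuristic=include_heuristic)


def rule_ii_precision(partition: FamilyPartition,
                      truth_groups: dict) -> Optional[float]:
    """Diagnostic against simulated ground truth: the fraction of
    rule-(ii) families whose members all descend from one true ortholog
    lineage (``truth_groups``: occurrence id -> lineage label).  None when
    no rule-(ii) family exists."""
    members = partition.families()
    rule_ii = [fam for fam, prov in partition.provenance.items()
               if prov[2] == "ii" and fam in members]
    if not rule_ii:
        return None
    pure = sum(
        1 for fam in rule_ii
        if len({truth_groups.get(occ) for occ in members[fam]}) == 1)
    return pure / len(rule_ii)


def root_family(partition: FamilyPartition, family: str) -> str:
    """Follow the provenance chain of a refined family back to the
    original (pre-refinement) family id."""
    seen = set()
    while family in partition.provenance and family not in seen:
        seen.add(family)
        family = partition.provenance[family][0]
    return family


PROVENANCE_COLUMNS = ["new_family", "parent_family", "component", "rule"]


def write_provenance_tsv(path, partition: FamilyPartition) -> None:
    rows = [(fam, parent, comp, rule)
            for fam, (parent, comp, rule)
            in sorted(partition.provenance.items())]
    pd.DataFrame(rows, columns=PROVENANCE_COLUMNS).to_csv(
        path, sep="\t", index=False)
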