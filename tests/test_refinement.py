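"""Family refinement: overlap components, rules (i) and (ii)."""

from paleocar.family_refinement import (
    FamilyPartition,
    overlap_components,
    refine,
    refine_rule_i,
    refine_rule_ii,
    root_family,
    rule_ii_precision,
)
from paleocar.genome_model import Genome
from paleocar.local_dcj import LocalDcjResult, ScoredOccurrence
from paleocar.synteny import BlockOccurrence, SyntenicBlockSet


def block(bid, occurrences):
    return SyntenicBlockSet(
        block_id=bid, content=frozenset(),
        occurrences=[BlockOccurrence(*occ) for occ in occurrences])


def scored(bid, genome, pairs, exact=True):
    return ScoredOccurrence(
        block_id=bid, target_genome=genome, occurrence_id=f"{bid}:x",
        result=LocalDcjResult(score=1.0, matched_pairs=[],
                              deleted_count=0, exact=exact),
        matched_occurrences=pairs)


class TestOverlapComponents:
    def test_disjoint_blocks(self):
        blocks = [block("B0", [("g1", "c", 1, 2, 0, 0, True)]),
                  block("B1", [("g1", "c", 10, 11, 0, 0, True)])]
        comps = overlap_components(blocks)
        assert len(comps) == 2

    def test_transitive_sharing(self):
        blocks = [block("B0", [("g1", "c", 1, 4, 0, 0, True)]),
                  block("B1", [("g1", "c", 4, 8, 0, 0, True)]),
                  block("B2", [("g1", "c", 8, 12, 0, 0, True)])]
        comps = overlap_components(blocks)
        assert len(comps) == 1
        assert comps[0].block_set_ids == {"B0", "B1", "B2"}

    def test_empty(self):
        assert overlap_components([]) == []


class TestRuleI:
    def test_splits_family_along_component(self):
        genomes = [Genome.from_ints([[1, 1, 1]], "g1")]
        part = FamilyPartition.from_genomes(genomes)
        comps = overlap_components(
            [block("B0", [("g1", "chr1", 1, 2, 0, 0, True)])])
        refined = refine_rule_i(part, comps)
        fams = refined.families()
        assert fams["1@c0"] == {("g1", "chr1", 1), ("g1", "chr1", 2)}
        assert fams["1"] == {("g1", "chr1", 3)}
        assert refined.provenance["1@c0"] == ("1", "c0", "i")

    def test_family_outside_components_unchanged(self):
        genomes = [Genome.from_ints([[1, 2]], "g1")]
        part = FamilyPartition.from_genomes(genomes)
        refined = refine_rule_i(part, [])
        assert refined.assignment == part.assignment

    def test_family_split_by_two_components(self):
        genomes = [Genome.from_ints([[1, 2, 1, 3, 1]], "g1")]
        part = FamilyPartition.from_genomes(genomes)
        comps = overlap_components([
            block("B0", [("g1", "chr1", 1, 2, 0, 0, True)]),
            block("B1", [("g1", "chr1", 4, 5, 0, 0, True)]),
        ])
        refined = refine_rule_i(part, comps)
        fams = refined.families()
        ones = {f: occs for f, occs in fams.items()
                if f == "1" or f.startswith("1@")}
        assert len(ones) == 3  # two component sub-families plus residue
        assert fams["1"] == {("g1", "chr1", 3)}


def three_genome_setup():
    """Reference g1 plus g2, g3; two overlapping blocks on the
    reference."""
    genomes = [Genome.from_ints([[1, 2, 3]], "g1"),
               Genome.from_ints([[1, 2, 3]], "g2"),
               Genome.from_ints([[1, 2, 3]], "g3")]
    blocks = [
        block("B0", [("g1", "chr1", 1, 2, 0, 0, True),
                     ("g2", "chr1", 1, 2, 0, 0, False)]),
        block("B1", [("g1", "chr1", 2, 3, 0, 0, True),
                     ("g3", "chr1", 2, 3, 0, 0, False)]),
    ]
    return genomes, blocks


class TestRuleII:
    def test_consistent_assignment_founds_family(self):
        genomes, blocks = three_genome_setup()
        part = FamilyPartition.from_genomes(genomes)
        comps = overlap_components(blocks)
        part = refine_rule_i(part, comps)
        records = [
            scored("B0", "g2", [((("g1", "chr1", 1)), ("g2", "chr1", 1))]),
            scored("B1", "g3", [((("g1", "chr1", 2)), ("g3", "chr1", 2))]),
        ]
        refined = refine_rule_ii(part, comps, records, "g1")
        fams = refined.families()
        assert {("g1", "chr1", 1), ("g2", "chr1", 1)} in fams.values()
        assert {("g1", "chr1", 2), ("g3", "chr1", 2)} in fams.values()

    def test_conflicting_assignments_block_family(self):
        genomes, blocks = three_genome_setup()
        # make the blocks overlap in g2 as well so m1 is matched twice
        blocks[1].occurrences.append(
            BlockOccurrence("g2", "chr1", 1, 2, 0, 0, False))
        part = FamilyPartition.from_genomes(genomes)
        comps = overlap_components(blocks)
        part = refine_rule_i(part, comps)
        records = [
            scored("B0", "g2", [(("g1", "chr1", 2), ("g2", "chr1", 2))]),
            scored("B1", "g2", [(("g1", "chr1", 2), ("g2", "chr1", 1))]),
        ]
        refined = refine_rule_ii(part, comps, records, "g1")
        assert all(prov[2] != "ii"
                   for prov in refined.provenance.values())

    def test_three_genome_family(self):
        genomes, blocks = three_genome_setup()
        blocks[1].occurrences.append(
            BlockOccurrence("g2", "chr1", 2, 3, 0, 0, False))
        part = FamilyPartition.from_genomes(genomes)
        comps = overlap_components(blocks)
        part = refine_rule_i(part, comps)
        records = [
            scored("B0", "g2", [(("g1", "chr1", 2), ("g2", "chr1", 2))]),
            scored("B1", "g2", [(("g1", "chr1", 2), ("g2", "chr1", 2))]),
            scored("B1", "g3", [(("g1", "chr1", 2), ("g3", "chr1", 2))]),
        ]
        refined = refine_rule_ii(part, comps, records, "g1")
        fams = refined.families()
        assert {("g1", "chr1", 2), ("g2", "chr1", 2),
                ("g3", "chr1", 2)} in fams.values()

    def test_heuristic_results_can_be_excluded(self):
        genomes, blocks = three_genome_setup()
        part = FamilyPartition.from_genomes(genomes)
        comps = overlap_components(blocks)
        part = refine_rule_i(part, comps)
        records = [scored("B0", "g2",
                          [(("g1", "chr1", 1), ("g2", "chr1", 1))],
                          exact=False)]
        with_h = refine_rule_ii(part, comps, records, "g1")
        without_h = refine_rule_ii(part, comps, records, "g1",
                                   include_heuristic=False)
        assert any(p[2] == "ii" for p in with_h.provenance.values())
        assert not any(p[2] == "ii"
                       for p in without_h.provenance.values())


class TestAlgebra:
    def _full(self):
        genomes, blocks = three_genome_setup()
        records = [
            scored("B0", "g2", [(("g1", "chr1", 1), ("g2", "chr1", 1))]),
            scored("B1", "g3", [(("g1", "chr1", 2), ("g3", "chr1", 2))]),
        ]
        part = FamilyPartition.from_genomes(genomes)
        return part, blocks, records

    def test_refines_input_partition(self):
        part, blocks, records = self._full()
        refined = refine(part, blocks, records, "g1")
        old = part.families()
        for occs in refined.families().values():
            parents = {part.assignment[o] for o in occs}
            assert len(parents) == 1
            assert occs <= old[parents.pop()]

    def test_idempotent(self):
        part, blocks, records = self._full()
        once = refine(part, blocks, records, "g1")
        twice = refine(once, blocks, records, "g1")
        assert twice.assignment == once.assignment

    def test_rule_ii_families_one_occurrence_per_genome(self):
        part, blocks, records = self._full()
        refined = refine(part, blocks, records, "g1")
        fams = refined.families()
        for fam, prov in refined.provenance.items():
            if prov[2] != "ii" or fam not in fams:
                continue
            genomes_seen = [occ[0] for occ in fams[fam]]
            assert len(genomes_seen) == len(set(genomes_seen))
            assert sum(1 for g in genomes_seen if g == "g1") == 1

    def test_every_occurrence_assigned_exactly_once(self):
        part, blocks, records = self._full()
        refined = refine(part, blocks, records, "g1")
        assert set(refined.assignment) == set(part.assignment)

    def test_root_family_follows_provenance(self):
        part, blocks, records = self._full()
        refined = refine(part, blocks, records, "g1")
        for fam in refined.families():
            assert root_family(refined, fam) in {"1", "2", "3"}


def test_rule_ii_precision_against_truth():
    genomes, blocks = three_genome_setup()
    records = [scored("B0", "g2", [(("g1", "chr1", 1), ("g2", "chr1", 1))])]
    part = refine(FamilyPartition.from_genomes(genomes), blocks, records,
                  "g1")
    truth = {occ: f"lineage{occ[2]}" for occ in part.assignment}
    assert rule_ii_precision(part, truth) == 1.0
    wrong = {occ: occ[0] for occ in part.assignment}  # lineage = genome
    assert rule_ii_precision(part, wrong) == 0.0
    no_rule_ii = FamilyPartition.from_genomes(genomes)
    assert rule_ii_precision(no_rule_ii, truth) is None
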