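"""Local DCJ similarity: length reward, balanced content, optimizer."""

import random

import pytest

from paleocar.genome_model import Genome, MarkerSequence
from paleocar.local_dcj import (
    ScoringParams,
    balanced_content,
    f_score,
    local_dcj_similarity,
    score_block_set,
)
from paleocar.synteny import BlockOccurrence, SyntenicBlockSet

from .oracles import exhaustive_local_dcj


class TestLengthReward:
    @pytest.mark.parametrize("length, expected", [
        (2, 1.0), (8, 0.0), (14, -1.0),
    ])
    def test_closed_form_at_L8(self, length, expected, params):
        assert f_score(length, params) == pytest.approx(expected)

    @pytest.mark.parametrize("bad", [1, 3, 0, -2, 7])
    def test_odd_or_small_lengths_rejected(self, bad, params):
        with pytest.raises(ValueError):
            f_score(bad, params)

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            ScoringParams(L=7)
        with pytest.raises(ValueError):
            ScoringParams(L=2)
        with pytest.raises(ValueError):
            ScoringParams(p=-0.1)


@pytest.mark.parametrize("s, t, expected", [
    ([1, 2, 2, 3], [2, 3, 3, 4], {"2": 1, "3": 1}),
    ([1, 2], [1, 2], {"1": 1, "2": 1}),
    ([1, 2], [3, 4], {}),
])
def test_balanced_content_min_rule(s, t, expected):
    assert balanced_content(MarkerSequence.from_ints(s),
                            MarkerSequence.from_ints(t)) == expected


def seq(ids):
    return MarkerSequence.from_ints(ids)


class TestSimilarity:
    def test_identity_scores_length(self, params):
        res = local_dcj_similarity(seq([1, 2, 3]), seq([1, 2, 3]), params)
        assert res.score == pytest.approx(3.0)
        assert res.deleted_count == 0
        assert res.matched_pairs == [(0, 0), (1, 1), (2, 2)]

    def test_inversion_long_cycle(self, params):
        res = local_dcj_similarity(seq([1, 2, 3]), seq([1, -2, 3]), params)
        assert res.score == pytest.approx(5 / 3)
        assert sorted(res.component_summary["cycles"]) == [4]

    def test_deletion_penalty(self, params):
        res = local_dcj_similarity(seq([1, 4, 2, 3]), seq([1, 2, 3]), params)
        assert res.score == pytest.approx(2.75)
        assert res.deleted_count == 1

    def test_disjoint_contents_pay_full_deletion(self, params):
        res = local_dcj_similarity(seq([1, 2]), seq([3, 4, 5]), params)
        assert res.score == pytest.approx(-5 * params.p)
        assert res.matched_pairs == []
        assert res.deleted_count == 5

    def test_deleted_count_consistent_with_matching(self, params):
        rng = random.Random(3)
        for _ in range(30):
            s = [rng.choice([1, -1]) * rng.randint(1, 4)
                 for _ in range(rng.randint(1, 6))]
            t = [rng.choice([1, -1]) * rng.randint(1, 4)
                 for _ in range(rng.randint(1, 6))]
            res = local_dcj_similarity(seq(s), seq(t), params)
            assert res.deleted_count == (len(s) + len(t)
                                         - 2 * len(res.matched_pairs))

    def test_self_similarity_equals_length(self, params):
        rng = random.Random(9)
        for _ in range(20):
            n = rng.randint(1, 7)
            ids = [rng.choice([1, -1]) * m
                   for m in rng.sample(range(1, n + 1), n)]
            res = local_dcj_similarity(seq(ids), seq(ids), params)
            assert res.score == pytest.approx(n)

    def test_score_never_increases_with_p(self):
        rng = random.Random(17)
        for _ in range(15):
            s = [rng.choice([1, -1]) * rng.randint(1, 4)
                 for _ in range(rng.randint(2, 6))]
            t = [rng.choice([1, -1]) * rng.randint(1, 4)
                 for _ in range(rng.randint(2, 6))]
            low = local_dcj_similarity(seq(s), seq(t),
                                       ScoringParams(p=0.1)).score
            high = local_dcj_similarity(seq(s), seq(t),
                                        ScoringParams(p=0.9)).score
            assert high <= low + 1e-12

    def test_matches_exhaustive_oracle(self, params):
        rng = random.Random(41)
        for _ in range(60):
            ns, nt = rng.randint(1, 6), rng.randint(1, 6)
            pool = list(range(1, 5))
            s = []
            for _ in range(ns):
                m = rng.choice(pool)
                if sum(1 for x in s if abs(x) == m) < 2:
                    s.append(rng.choice([1, -1]) * m)
            t = []
            for _ in range(nt):
                m = rng.choice(pool)
                if sum(1 for x in t if abs(x) == m) < 2:
                    t.append(rng.choice([1, -1]) * m)
            if not s or not t:
                continue
            got = local_dcj_similarity(seq(s), seq(t), params)
            want = exhaustive_local_dcj(
                [(str(abs(x)), 1 if x > 0 else -1) for x in s],
                [(str(abs(x)), 1 if x > 0 else -1) for x in t],
                L=params.L, p=params.p)
            assert got.score == pytest.approx(want)
            assert got.exact

    def test_heuristic_fallback_flags_result(self):
        tight = ScoringParams(node_budget=1)
        s = seq([1, 1, 2, 2, 3, 3])
        t = seq([3, 3, 2, 2, 1, 1])
        res = local_dcj_similarity(s, t, tight)
        assert not res.exact
        exact = local_dcj_similarity(s, t, ScoringParams())
        assert res.score <= exact.score + 1e-12


class TestScoreBlockSet:
    def _block(self, occurrences):
        return SyntenicBlockSet(block_id="B0", content=frozenset(),
                                occurrences=occurrences)

    def test_identical_occurrence_scores_interval_length(self, params):
        genomes = {
            "G": Genome.from_ints([[1, 2, 3]], "G"),
            "H": Genome.from_ints([[1, 2, 3]], "H"),
        }
        genomes["G"].chromosomes[0].sequence_id = "c"
        genomes["H"].chromosomes[0].sequence_id = "c"
        block = self._block([
            BlockOccurrence("G", "c", 1, 3, 0, 0, True),
            BlockOccurrence("H", "c", 1, 3, 0, 0),
        ])
        results = score_block_set(block, genomes, params)
        assert len(results) == 1
        assert results[0].result.score == pytest.approx(3.0)
        assert results[0].matched_occurrences == [
            (("G", "c", 1), ("H", "c", 1)),
            (("G", "c", 2), ("H", "c", 2)),
            (("G", "c", 3), ("H", "c", 3)),
        ]

    def test_reference_excluded_as_target(self, params):
        genomes = {g: Genome.from_ints([[1, 2]], g) for g in "GHI"}
        for g in genomes.values():
            g.chromosomes[0].sequence_id = "c"
        block = self._block([
            BlockOccurrence("G", "c", 1, 2, 0, 0, True),
            BlockOccurrence("H", "c", 1, 2, 0, 0),
            BlockOccurrence("I", "c", 1, 2, 0, 0),
        ])
        assert len(score_block_set(block, genomes, params)) == 2

    def test_disjoint_occurrence_scores_pure_deletion(self, params):
        genomes = {
            "G": Genome.from_ints([[1, 2]], "G"),
            "H": Genome.from_ints([[3, 4]], "H"),
        }
        for g in genomes.values():
            g.chromosomes[0].sequence_id = "c"
        block = self._block([
            BlockOccurrence("G", "c", 1, 2, 0, 0, True),
            BlockOccurrence("H", "c", 1, 2, 0, 2),
        ])
        results = score_block_set(block, genomes, params)
        assert results[0].result.score == pytest.approx(-4 * params.p)
        assert results[0].matched_occurrences == []
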