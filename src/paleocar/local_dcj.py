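"""Local DCJ similarity between pairs of syntenic substrings.

Global DCJ distance is useless for *local* comparison: like edit distance
in sequence alignment, it favors the shortest (ultimately empty) substring
pair.  The local DCJ similarity instead rewards structural similarity and
penalizes dissimilarity.  Given substrings S and T, maximal balanced
subsequences are extracted (for each family g, exactly
``min(m_S(g), m_T(g))`` occurrences are kept on both sides), occurrences
are put in one-to-one correspondence per family, and the resulting
non-duplicated balanced pair (S'', T'') is scored through its adjacency
graph:

    s_DCJ(S'', T'') = sum_{C in cycles} f(|C|)
                      + 1/2 ( sum_{O in odd paths} f(|O|+1)
                            + sum_{E in even paths} f(|E|+2) )
                      - d * p

where |.| counts edges, path lengths are corrected so that structures with
the same sorting distance have the same length, d = |S|+|T|-(|S''|+|T''|)
is the number of deleted markers, and p the deletion penalty.  The length
reward is

    f(l) = (2 - l)/(L - 2) + 1        (l even, l >= 2)

with L an even threshold demarcating short (similar) from long (dissimilar)
cycles and paths.  The similarity is the maximum of s_DCJ over all
occurrence selections and per-family bijections; d is invariant under that
choice, so only the component structure is optimized.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

from .genome_model import (
    HEAD,
    TAIL,
    Marker,
    MarkerSequence,
    adjacency_graph_components,
    multiplicity_table,
)
from .synteny import SyntenicBlockSet

#: default deletion penalty and length threshold
DEFAULT_P = 0.25
DEFAULT_L = 8


@dataclass(frozen=True)
class ScoringParams:
    """Parameters of the local DCJ similarity.

    L: even length threshold (>= 4) demarcating short from long cycles and
       paths; f(L) = 0, shorter structures score positive, longer negative.
    p: per-marker deletion penalty (>= 0).
    node_budget: cap on the number of complete assignments enumerated
       exactly; beyond it a greedy + local-search fallback is used and the
       result is flagged as heuristic.
    """

    L: int = DEFAULT_L
    p: float = DEFAULT_P
    node_budget: int = 200_000

    def __post_init__(self):
        if self.L % 2 != 0 or self.L <= 2:
            raise ValueError(f"L must be even and > 2, got {self.L}")
        if self.p < 0:
            raise ValueError(f"deletion penalty must be >= 0, got {self.p}")


def f_score(length: int, params: ScoringParams) -> float:
    """Length reward f(l) = (2 - l)/(L - 2) + 1 for even l >= 2."""
    if length % 2 != 0 or length < 2:
        raise ValueError(
            f"f is defined on even lengths >= 2, got {length}")
    return (2 - length) / (params.L - 2) + 1.0


SequenceLike = Union[MarkerSequence, Sequence[Marker]]


def _markers(obj: SequenceLike) -> list[Marker]:
    if isinstance(obj, MarkerSequence):
        return list(obj.markers)
    return list(obj)


def balanced_content(s: SequenceLike, t: SequenceLike) -> dict[str, int]:
    """Family -> min(m_S, m_T) for families present on both sides."""
    ms, mt = multiplicity_table(_markers(s)), multiplicity_table(_markers(t))
    return {g: min(ms[g], mt[g]) for g in sorted(ms.keys() & mt.keys())}


#: a matched occurrence pair: (s_position, t_position), 0-based
Pair = tuple[int, int]


@dataclass
class LocalDcjResult:
    """Outcome of one local DCJ similarity computation."""

    score: float
    matched_pairs: list[Pair]
    deleted_count: int
    component_summary: dict[str, list[int]] = field(default_factory=dict)
    exact: bool = True
    s_signs: list[int] = field(default_factory=list)
    t_signs: list[int] = field(default_factory=list)

    def serialized_pairs(self) -> str:
        parts = []
        for k, (i, j) in enumerate(self.matched_pairs):
            si = "+" if self.s_signs[k] > 0 else "-"
            sj = "+" if self.t_signs[k] > 0 else "-"
            parts.append(f"{i + 1}:{si}<->{j + 1}:{sj}")
        return ";".join(parts)


def _score_matching(s: list[Marker], t: list[Marker],
                    pairs: Sequence[Pair], params: ScoringParams,
                    d: int) -> tuple[float, dict[str, list[int]]]:
    """Score one complete matching.

    Matched occurrences are relabeled to unique ids (keeping their own
    signs) and the two projections are scored as single linear chromosomes
    with telomeres at the interval ends.
    """
    by_s = sorted(range(len(pairs)), key=lambda k: pairs[k][0])
    by_t = sorted(range(len(pairs)), key=lambda k: pairs[k][1])
    s_proj = [(str(k), s[pairs[k][0]][1]) for k in by_s]
    t_proj = [(str(k), t[pairs[k][1]][1]) for k in by_t]
    left = _linear_adjacencies(s_proj)
    right = _linear_adjacencies(t_proj)
    summary: dict[str, list[int]] = {"cycles": [], "odd_paths": [],
                                     "even_paths": []}
    score = -d * params.p
    for kind, n_edges in adjacency_graph_components(left, right):
        if kind == "cycle":
            summary["cycles"].append(n_edges)
            score += f_score(n_edges, params)
        elif kind == "odd_path":
            summary["odd_paths"].append(n_edges)
            score += 0.5 * f_score(n_edges + 1, params)
        else:
            summary["even_paths"].append(n_edges)
            score += 0.5 * f_score(n_edges + 2, params)
    return score, summary


def _linear_adjacencies(markers: list[Marker]) -> list[frozenset]:
    adjacencies = []
    if markers:
        oriented = [((f, TAIL), (f, HEAD)) if sign > 0 else
                    ((f, HEAD), (f, TAIL)) for f, sign in markers]
        adjacencies.append(frozenset([oriented[0][0]]))
        for (_, prev_exit), (next_entry, _) in zip(oriented, oriented[1:]):
            adjacencies.append(frozenset([prev_exit, next_entry]))
        adjacencies.append(frozenset([oriented[-1][1]]))
    return adjacencies


def _family_choices(s_positions: Sequence[int], t_positions: Sequence[int],
                    count: int) -> Iterable[tuple[Pair, ...]]:
    """All ways to pick `count` occurrences on each side and biject them,
    in lexicographic order of the resulting pair tuples."""
    for s_sub in itertools.combinations(s_positions, count):
        for t_sub in itertools.combinations(t_positions, count):
            for perm in itertools.permutations(t_sub):
                yield tuple(zip(s_sub, perm))


def _choice_count(n_s: int, n_t: int, count: int) -> int:
    from math import comb, factorial
    return comb(n_s, count) * comb(n_t, count) * factorial(count)


def _canonical(pairs: Iterable[Pair]) -> tuple[Pair, ...]:
    return tuple(sorted(pairs))


def local_dcj_similarity(s: SequenceLike, t: SequenceLike,
                         params: ScoringParams = ScoringParams()
                         ) -> LocalDcjResult:
    """Maximize s_DCJ over occurrence selections and per-family bijections.

    Exact (exhaustive, lexicographically tie-broken) while the assignment
    space fits in ``params.node_budget``; otherwise a greedy longest-common-
    subsequence seed refined by local search is returned with
    ``exact=False``.
    """
    s_markers, t_markers = _markers(s), _markers(t)
    bc = balanced_content(s_markers, t_markers)
    d = len(s_markers) + len(t_markers) - 2 * sum(bc.values())

    if not bc:
        return LocalDcjResult(score=-d * params.p, matched_pairs=[],
                              deleted_count=d, exact=True)

    s_pos: dict[str, list[int]] = {g: [] for g in bc}
    t_pos: dict[str, list[int]] = {g: [] for g in bc}
    for i, (fam, _) in enumerate(s_markers):
        if fam in bc:
            s_pos[fam].append(i)
    for j, (fam, _) in enumerate(t_markers):
        if fam in bc:
            t_pos[fam].append(j)

    families = sorted(bc)
    total = 1
    for g in families:
        total *= _choice_count(len(s_pos[g]), len(t_pos[g]), bc[g])
        if total > params.node_budget:
            break

    if total <= params.node_budget:
        best = None
        per_family = [list(_family_choices(s_pos[g], t_pos[g], bc[g]))
                      for g in families]
        for combo in itertools.product(*per_family):
            pairs = _canonical(p for group in combo for p in group)
            score, summary = _score_matching(s_markers, t_markers, pairs,
                                             params, d)
            key = (-score, pairs)
            if best is None or key < best[0]:
                best = (key, pairs, score, summary)
        _, pairs, score, summary = best
        exact = True
    else:
        pairs = _greedy_matching(s_markers, t_markers, bc, s_pos, t_pos)
        pairs = _local_search(s_markers, t_markers, pairs, params, d)
        score, summary = _score_matching(s_markers, t_markers, pairs,
                                         params, d)
        exact = False

    pairs = list(_canonical(pairs))
    return LocalDcjResult(
        score=score, matched_pairs=pairs, deleted_count=d,
        component_summary=summary, exact=exact,
        s_signs=[s_markers[i][1] for i, _ in pairs],
        t_signs=[t_markers[j][1] for _, j in pairs])


def _greedy_matching(s: list[Marker], t: list[Marker], bc: dict[str, int],
                     s_pos: dict[str, list[int]],
                     t_pos: dict[str, list[int]]) -> list[Pair]:
    """Crossing-free seed: longest common subsequence over family symbols,
    topped up with leftmost unused occurrences per family."""
    n, m = len(s), len(t)
    lcs = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n - 1, -1, -1):
        for j in range(m - 1, -1, -1):
            if s[i][0] == t[j][0] and s[i][0] in bc:
                lcs[i][j] = 1 + lcs[i + 1][j + 1]
            else:
                lcs[i][j] = max(lcs[i + 1][j], lcs[i][j + 1])
    pairs: list[Pair] = []
    used: dict[str, int] = {g: 0 for g in bc}
    i = j = 0
    while i < n and j < m:
        fam = s[i][0]
        if fam == t[j][0] and fam in bc and used[fam] < bc[fam]:
            pairs.append((i, j))
            used[fam] += 1
            i, j = i + 1, j + 1
        elif lcs[i + 1][j] >= lcs[i][j + 1]:
            i += 1
        else:
            j += 1
    # top up families below quota with leftmost unused occurrences
    used_s = {i for i, _ in pairs}
    used_t = {j for _, j in pairs}
    for g in sorted(bc):
        while used[g] < bc[g]:
            i = next(k for k in s_pos[g] if k not in used_s)
            j = next(k for k in t_pos[g] if k not in used_t)
            pairs.append((i, j))
            used_s.add(i)
            used_t.add(j)
            used[g] += 1
    return sorted(pairs)


def _local_search(s: list[Marker], t: list[Marker], pairs: list[Pair],
                  params: ScoringParams, d: int,
                  max_rounds: int = 20) -> list[Pair]:
    """Hill-climb: swap the t-targets of two pairs of the same family, or
    swap a matched occurrence for an unused one, while the score improves."""
    pairs = sorted(pairs)
    score, _ = _score_matching(s, t, pairs, params, d)
    by_family: dict[str, list[int]] = {}
    for k, (i, _) in enumerate(pairs):
        by_family.setdefault(s[i][0], []).append(k)
    unused_t: dict[str, list[int]] = {}
    matched_t = {j for _, j in pairs}
    for j, (fam, _) in enumerate(t):
        if fam in by_family and j not in matched_t:
            unused_t.setdefault(fam, []).append(j)
    unused_s: dict[str, list[int]] = {}
    matched_s = {i for i, _ in pairs}
    for i, (fam, _) in enumerate(s):
        if fam in by_family and i not in matched_s:
            unused_s.setdefault(fam, []).append(i)

    for _ in range(max_rounds):
        improved = False
        for fam, ks in by_family.items():
            # swap t-targets within the family
            for a, b in itertools.combinations(ks, 2):
                cand = list(pairs)
                cand[a] = (pairs[a][0], pairs[b][1])
                cand[b] = (pairs[b][0], pairs[a][1])
                cand_sorted = sorted(cand)
                new, _ = _score_matching(s, t, cand_sorted, params, d)
                if new > score + 1e-12:
                    pairs, score, improved = cand_sorted, new, True
            # swap a matched occurrence for an unused one on either side
            for a in ks:
                for j in unused_t.get(fam, []):
                    cand = list(pairs)
                    cand[a] = (pairs[a][0], j)
                    cand_sorted = sorted(cand)
                    new, _ = _score_matching(s, t, cand_sorted, params, d)
                    if new > score + 1e-12:
                        unused_t[fam].remove(j)
                        unused_t[fam].append(pairs[a][1])
                        pairs, score, improved = cand_sorted, new, True
                        break
                for i in unused_s.get(fam, []):
                    cand = list(pairs)
                    cand[a] = (i, pairs[a][1])
                    cand_sorted = sorted(cand)
                    new, _ = _score_matching(s, t, cand_sorted, params, d)
                    if new > score + 1e-12:
                        unused_s[fam].remove(i)
                        unused_s[fam].append(pairs[a][0])
                        pairs, score, improved = cand_sorted, new, True
                        break
            if improved:
                by_family = {}
                for k, (i, _) in enumerate(pairs):
                    by_family.setdefault(s[i][0], []).append(k)
                break
        if not improved:
            break
    return pairs


# ---------------------------------------------------------------------------
# scoring syntenic block sets

#: absolute marker occurrence id: (genome_id, chromosome_id, 1-based position)
OccurrenceId = tuple[str, str, int]


@dataclass
class ScoredOccurrence:
    """Local DCJ result for one (reference, target) occurrence pair of a
    syntenic block set, with matched pairs lifted to absolute marker
    occurrence ids for the family-refinement stage."""

    block_id: str
    target_genome: str
    occurrence_id: str
    result: LocalDcjResult
    matched_occurrences: list[tuple[OccurrenceId, OccurrenceId]]


def score_block_set(block: SyntenicBlockSet, genomes: dict,
                    params: ScoringParams = ScoringParams()
                    ) -> list[ScoredOccurrence]:
    """Score the reference substring of a block set against every
    non-reference occurrence's substring."""
    ref = block.reference_occurrence
    ref_sub = _substring(genomes, ref)
    results = []
    for k, occ in enumerate(block.occurrences):
        if occ.is_reference:
            continue
        sub = _substring(genomes, occ)
        res = local_dcj_similarity(ref_sub, sub, params)
        matched = [
            ((ref.genome, ref.chromosome, ref.start + i),
             (occ.genome, occ.chromosome, occ.start + j))
            for i, j in res.matched_pairs
        ]
        results.append(ScoredOccurrence(
            block_id=block.block_id, target_genome=occ.genome,
            occurrence_id=f"{block.block_id}:{k}", result=res,
            matched_occurrences=matched))
    return results


def _substring(genomes: dict, occ) -> list[Marker]:
    genome = genomes[occ.genome]
    for chrom in genome.chromosomes:
        if chrom.sequence_id == occ.chromosome:
            return chrom.markers[occ.start - 1:occ.end]
    raise KeyError(f"chromosome {occ.chromosome!r} not in {occ.genome!r}")
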