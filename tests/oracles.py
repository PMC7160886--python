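"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately written from first principles — no code is
shared with the package beyond elementary data structures — so that
agreement between an oracle and the corresponding package routine is
meaningful evidence of correctness.
"""

from __future__ import annotations

import itertools
from collections import Counter

# ---------------------------------------------------------------------------
# DCJ distance by bidirectional BFS over genome states
#
# A genome state is its adjacency set: a frozenset of frozensets of
# extremities (marker, 'h'|'t'); telomeric adjacencies are singletons.
# A DCJ operation removes up to two adjacencies and rejoins the freed
# extremities in a new way (including splitting one adjacency into two
# telomeres and joining two telomeres).


def genome_adjacencies(chromosomes):
    """Adjacency set of a genome given as lists of signed ints."""
    adj = set()
    for chrom in chromosomes:
        if not chrom:
            continue
        ends = []
        for g in chrom:
            m = abs(g)
            ends.append(((m, "t"), (m, "h")) if g > 0 else
                        ((m, "h"), (m, "t")))
        adj.add(frozenset([ends[0][0]]))
        for (_, a), (b, _) in zip(ends, ends[1:]):
            adj.add(frozenset([a, b]))
        adj.add(frozenset([ends[-1][1]]))
    return frozenset(adj)


def _dcj_neighbors(state):
    """All genome states one DCJ operation away (circular intermediates
    arise naturally and are allowed)."""
    adjacencies = list(state)
    out = set()
    # two-adjacency operations
    for u, v in itertools.combinations(adjacencies, 2):
        rest = state - {u, v}
        us, vs = sorted(u), sorted(v)
        if len(us) == 2 and len(vs) == 2:
            a, b = us
            c, d = vs
            out.add(rest | {frozenset([a, c]), frozenset([b, d])})
            out.add(rest | {frozenset([a, d]), frozenset([b, c])})
        elif len(us) == 2 and len(vs) == 1:
            a, b = us
            (c,) = vs
            out.add(rest | {frozenset([a, c]), frozenset([b])})
            out.add(rest | {frozenset([b, c]), frozenset([a])})
        elif len(us) == 1 and len(vs) == 2:
            (a,) = us
            c, d = vs
            out.add(rest | {frozenset([c, a]), frozenset([d])})
            out.add(rest | {frozenset([d, a]), frozenset([c])})
        else:
            (a,) = us
            (c,) = vs
            out.add(rest | {frozenset([a, c])})
    # single-adjacency fission: {a,b} -> {a}, {b}
    for u in adjacencies:
        if len(u) == 2:
            a, b = sorted(u)
            out.add((state - {u}) | {frozenset([a]), frozenset([b])})
    out.discard(state)
    return out


def bfs_dcj_distance(chroms_a, chroms_b, max_depth: int = 12) -> int:
    """Minimum number of DCJ operations transforming one genome into the
    other, by bidirectional breadth-first search."""
    start = genome_adjacencies(chroms_a)
    goal = genome_adjacencies(chroms_b)
    if start == goal:
        return 0
    front_a = {start}
    front_b = {goal}
    seen_a = {start: 0}
    seen_b = {goal: 0}
    depth = 0
    while depth < max_depth:
        depth += 1
        # expand the smaller frontier
        if len(front_a) <= len(front_b):
            front, seen, other = front_a, seen_a, seen_b
        else:
            front, seen, other = front_b, seen_b, seen_a
        new_front = set()
        for state in front:
            d = seen[state]
            for nxt in _dcj_neighbors(state):
                if nxt in other:
                    return d + 1 + other[nxt]
                if nxt not in seen:
                    seen[nxt] = d + 1
                    new_front.add(nxt)
        if front is front_a:
            front_a = new_front
        else:
            front_b = new_front
        if not new_front:
            break
    raise RuntimeError("genomes not connected within max_depth")


# ---------------------------------------------------------------------------
# exhaustive local DCJ similarity


def _component_lengths(left_markers, right_markers):
    """Cycle/odd-path/even-path edge counts of the adjacency graph of two
    single-chromosome, non-duplicated, balanced marker lists
    ((id, sign) pairs)."""

    def adjacencies(markers):
        adj = []
        ends = [((m, "t"), (m, "h")) if s > 0 else ((m, "h"), (m, "t"))
                for m, s in markers]
        adj.append(frozenset([ends[0][0]]))
        for (_, a), (b, _) in zip(ends, ends[1:]):
            adj.append(frozenset([a, b]))
        adj.append(frozenset([ends[-1][1]]))
        return adj

    left = adjacencies(left_markers)
    right = adjacencies(right_markers)
    # walk components by following shared extremities
    loc_right: dict = {}
    for j, v in enumerate(right):
        for e in v:
            loc_right[e] = j
    loc_left: dict = {}
    for i, u in enumerate(left):
        for e in u:
            loc_left[e] = i
    edges = []  # (left idx, right idx, extremity)
    for i, u in enumerate(left):
        for e in u:
            edges.append((i, loc_right[e], e))
    adj_edges: dict = {}
    for k, (i, j, _) in enumerate(edges):
        adj_edges.setdefault(("L", i), []).append(k)
        adj_edges.setdefault(("R", j), []).append(k)
    seen = [False] * len(edges)
    comps = []
    for k0 in range(len(edges)):
        if seen[k0]:
            continue
        # traverse the component containing edge k0
        stack = [k0]
        comp_edges = set()
        nodes = set()
        while stack:
            k = stack.pop()
            if seen[k]:
                continue
            seen[k] = True
            comp_edges.add(k)
            i, j, _ = edges[k]
            nodes.add(("L", i))
            nodes.add(("R", j))
            for node in (("L", i), ("R", j)):
                for k2 in adj_edges[node]:
                    if not seen[k2]:
                        stack.append(k2)
        n_edges = len(comp_edges)
        degrees = Counter()
        for k in comp_edges:
            i, j, _ = edges[k]
            degrees[("L", i)] += 1
            degrees[("R", j)] += 1
        if all(d == 2 for d in degrees.values()):
            comps.append(("cycle", n_edges))
        elif n_edges % 2 == 1:
            comps.append(("odd", n_edges))
        else:
            comps.append(("even", n_edges))
    return comps


def exhaustive_local_dcj(s_markers, t_markers, L: int = 8,
                         p: float = 0.25) -> float:
    """Maximum local DCJ similarity over all occurrence selections and
    per-family bijections, by complete enumeration.

    ``s_markers``/``t_markers``: lists of (family, sign) pairs.
    """

    def f(length):
        assert length % 2 == 0 and length >= 2
        return (2 - length) / (L - 2) + 1.0

    ms = Counter(m for m, _ in s_markers)
    mt = Counter(m for m, _ in t_markers)
    families = sorted(set(ms) & set(mt))
    counts = {g: min(ms[g], mt[g]) for g in families}
    d = len(s_markers) + len(t_markers) - 2 * sum(counts.values())
    if not families:
        return -d * p

    s_pos = {g: [i for i, (m, _) in enumerate(s_markers) if m == g]
             for g in families}
    t_pos = {g: [j for j, (m, _) in enumerate(t_markers) if m == g]
             for g in families}

    per_family = []
    for g in families:
        options = []
        c = counts[g]
        for ss in itertools.combinations(s_pos[g], c):
            for ts in itertools.combinations(t_pos[g], c):
                for perm in itertools.permutations(ts):
                    options.append(list(zip(ss, perm)))
        per_family.append(options)

    best = None
    for combo in itertools.product(*per_family):
        pairs = [pr for group in combo for pr in group]
        by_s = sorted(range(len(pairs)), key=lambda k: pairs[k][0])
        by_t = sorted(range(len(pairs)), key=lambda k: pairs[k][1])
        left = [(k, s_markers[pairs[k][0]][1]) for k in by_s]
        right = [(k, t_markers[pairs[k][1]][1]) for k in by_t]
        score = -d * p
        for kind, n_edges in _component_lengths(left, right):
            if kind == "cycle":
                score += f(n_edges)
            elif kind == "odd":
                score += 0.5 * f(n_edges + 1)
            else:
                score += 0.5 * f(n_edges + 2)
        if best is None or score > best:
            best = score
    return best


# ---------------------------------------------------------------------------
# brute-force approximate common intervals


def brute_force_blocks(genomes, reference_id, delta_row_fn, quorum,
                       min_ref_size):
    """All syntenic block sets by complete enumeration.

    ``genomes``: mapping genome id -> list of chromosomes, each a list of
    (family, sign); ``delta_row_fn(size) -> (add, loss, sum)``.  Returns a
    set of (content, occurrence frozenset) keys using the same occurrence
    semantics as the package: maximal satisfying windows with in-content
    endpoints; reference-chromosome windows overlapping the defining
    interval are subsumed by the reference occurrence.
    """
    found = set()
    ref_chroms = genomes[reference_id]
    for rc_name, rc in ref_chroms.items():
        fams = [m for m, _ in rc]
        n = len(fams)
        for i in range(n):
            for j in range(i, n):
                cont = frozenset(fams[i:j + 1])
                if len(cont) < min_ref_size:
                    continue
                if not ((i == 0 or fams[i - 1] not in cont)
                        and (j == n - 1 or fams[j + 1] not in cont)):
                    continue
                add, loss, dsum = delta_row_fn(len(cont))
                occs = [(reference_id, rc_name, i + 1, j + 1, True)]
                for gid, chroms in genomes.items():
                    for cname, chrom in chroms.items():
                        cf = [m for m, _ in chrom]
                        m = len(cf)
                        sat = []
                        for k in range(m):
                            for l in range(k, m):
                                if cf[k] not in cont or cf[l] not in cont:
                                    continue
                                window = cf[k:l + 1]
                                ins = sum(1 for x in window
                                          if x not in cont)
                                mis = len(cont - set(window))
                                if (ins <= add and mis <= loss
                                        and ins + mis <= dsum):
                                    sat.append((k + 1, l + 1))
                        maximal = [w for w in sat
                                   if not any(o != w and o[0] <= w[0]
                                              and o[1] >= w[1]
                                              for o in sat)]
                        for (s, e) in maximal:
                            if (gid == reference_id and cname == rc_name
                                    and s <= j + 1 and e >= i + 1):
                                continue
                            occs.append((gid, cname, s, e, False))
                if len({o[0] for o in occs}) < quorum:
                    continue
                found.add((cont, frozenset(occs)))
    return found


# ---------------------------------------------------------------------------
# consecutive-ones feasibility by permutation enumeration


def brute_c1p(leaves, sets) -> bool:
    """True iff some permutation of ``leaves`` makes every set in ``sets``
    consecutive (exponential; n <= 8)."""
    leaves = sorted(leaves)
    for perm in itertools.permutations(leaves):
        pos = {x: k for k, x in enumerate(perm)}
        ok = True
        for s in sets:
            idx = sorted(pos[x] for x in s)
            if idx and idx[-1] - idx[0] + 1 != len(idx):
                ok = False
                break
        if ok:
            return True
    return False


def set_consecutive_in(order, s) -> bool:
    idx = sorted(order.index(x) for x in s)
    return not idx or idx[-1] - idx[0] + 1 == len(idx)


# ---------------------------------------------------------------------------
# segmentation waste by alignment-subset enumeration


def brute_min_waste(alignments, seq_lengths, min_length,
                    segment_fn) -> int:
    """Minimum waste over all subsets of the alignments, where each
    subset is segmented by ``segment_fn(subset, seq_lengths, min_length)
    -> waste``.  The subset enumeration (the oracle part) is independent;
    per-subset waste uses the supplied deterministic segmentation."""
    best = None
    for r in range(len(alignments) + 1):
        for subset in itertools.combinations(alignments, r):
            waste = segment_fn(list(subset), seq_lengths, min_length)
            if best is None or waste < best:
                best = waste
    return best
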