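"""PQ-trees for the consecutive-ones property over ancestral markers.

A PQ-tree compactly represents a family of permutations of a leaf set:
P-nodes leave the order of their children free, Q-nodes fix it up to
reversal.  A collection of subsets of the leaves has the consecutive-ones
property (C1P) iff some permutation makes every subset contiguous; the
PQ-tree of the collection represents exactly those permutations.

The tree here is built *from scratch* from a collection of constraint sets
(raising :class:`C1PInfeasible` when the collection is not C1P) rather
than by online Booth–Lueker reduction.  The construction rests on two
classical facts about a C1P family: (1) the strict-overlap components of
the constraint sets have unions that behave as modules — any other
constraint set is disjoint from the union, contains it, or falls inside a
single equivalence class ("cell") of the component; and (2) within a
component the cells admit a linear order that is unique up to reversal,
computed by placing the component's sets one at a time along a
strict-overlap spanning order.  Components become Q-nodes over their
cells, nesting gives the hierarchy, and everything unconstrained is
grouped under P-nodes.  Correctness is checked in the test suite against
brute-force enumeration of all leaf orders.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional


class C1PInfeasible(Exception):
    """The constraint sets admit no common consecutive arrangement."""


@dataclass
class PQNode:
    kind: str  # "P", "Q", or "leaf"
    label: Optional[str] = None
    children: list = field(default_factory=list)

    def leaves(self) -> list[str]:
        if self.kind == "leaf":
            return [self.label]
        out = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def q_nodes(self):
        if self.kind == "Q":
            yield self
        for child in self.children:
            if child.kind != "leaf":
                yield from child.q_nodes()


def _strict_overlap(a: frozenset, b: frozenset) -> bool:
    return bool(a & b) and not a <= b and not b <= a


def _components(sets: list[frozenset]) -> list[list[int]]:
    parent = list(range(len(sets)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in itertools.combinations(range(len(sets)), 2):
        if _strict_overlap(sets[i], sets[j]):
            a, b = find(i), find(j)
            if a != b:
                parent[a] = b
    groups: dict[int, list[int]] = {}
    for i in range(len(sets)):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


def _spanning_order(sets: list[frozenset]) -> list[int]:
    """Order set indices so each (after the first) strictly overlaps an
    earlier one."""
    remaining = set(range(len(sets)))
    order = [min(remaining)]
    remaining.discard(order[0])
    while remaining:
        nxt = next(
            (j for j in sorted(remaining)
             if any(_strict_overlap(sets[j], sets[k]) for k in order)),
            None)
        assert nxt is not None, "component is strict-overlap connected"
        order.append(nxt)
        remaining.discard(nxt)
    return order


def _place_component(sets: list[frozenset]) -> list[frozenset]:
    """Linear order of the cells of one strict-overlap component, unique
    up to reversal.  Raises C1PInfeasible when no order exists."""
    order = _spanning_order(sets)
    cells: list[set] = [set(sets[order[0]])]
    placed: set = set(sets[order[0]])
    for idx in order[1:]:
        b = sets[idx]
        new = set(b) - placed
        hit = [k for k, cell in enumerate(cells) if cell & b]
        if hit != list(range(hit[0], hit[-1] + 1)):
            raise C1PInfeasible("constraint straddles separated cells")
        j, k = hit[0], hit[-1]
        for m in range(j + 1, k):
            if not cells[m] <= b:
                raise C1PInfeasible("constraint skips part of an inner cell")
        if j == k:
            cell = cells[j]
            inpart, outpart = cell & b, cell - b
            if not new:
                if not outpart:
                    continue  # b coincides with the cell
                raise C1PInfeasible("contained constraint cuts a cell")
            if j == 0:
                repl = [set(new), inpart] + ([outpart] if outpart else [])
                cells[:1] = [c for c in repl if c]
            elif j == len(cells) - 1:
                repl = ([outpart] if outpart else []) + [inpart, set(new)]
                cells[-1:] = [c for c in repl if c]
            else:
                raise C1PInfeasible("new markers cannot attach mid-sequence")
        else:
            cj_in, cj_out = cells[j] & b, cells[j] - b
            ck_in, ck_out = cells[k] & b, cells[k] - b
            middle = cells[j + 1:k]
            if not new:
                repl = (([cj_out] if cj_out else []) + [cj_in] + middle
                        + [ck_in] + ([ck_out] if ck_out else []))
                cells[j:k + 1] = repl
            elif j == 0 and not cj_out:
                cells[j:k + 1] = ([set(new), cj_in] + middle + [ck_in]
                                  + ([ck_out] if ck_out else []))
            elif k == len(cells) - 1 and not ck_out:
                cells[j:k + 1] = (([cj_out] if cj_out else []) + [cj_in]
                                  + middle + [ck_in, set(new)])
            else:
                raise C1PInfeasible("new markers cannot attach mid-sequence")
        placed |= new
    return [frozenset(c) for c in cells]


def _sort_key(node: PQNode):
    return min(node.leaves())


def build_tree(leaves: Iterable[str], sets: Iterable[frozenset]) -> PQNode:
    """PQ-tree of the constraint sets over ``leaves``.

    Raises C1PInfeasible if the sets are not C1P.  Rigid components with
    only two cells carry no more order information than an unordered pair
    and are emitted as P-nodes; Q-nodes always have >= 3 children.
    """
    universe = frozenset(str(x) for x in leaves)
    cleaned = sorted(
        {frozenset(str(x) for x in s) for s in sets
         if 1 < len(s) < len(universe)},
        key=lambda s: (len(s), sorted(s)))
    for s in cleaned:
        if not s <= universe:
            raise ValueError(f"constraint {sorted(s)} exceeds the leaf set")
    if len(universe) == 1:
        return PQNode("leaf", label=next(iter(universe)))

    comp_sets = [[cleaned[i] for i in comp] for comp in _components(cleaned)]
    comps = []  # (union, cells or None)
    for group in comp_sets:
        union = frozenset().union(*group)
        cells = _place_component(group) if len(group) > 1 else None
        comps.append([union, cells])
    # a single-set component whose set equals another component's union is
    # redundant (the union is consecutive by construction)
    unions_multi = {u for u, cells in comps if cells is not None}
    comps = [c for c in comps if not (c[1] is None and c[0] in unions_multi)]
    comps.sort(key=lambda c: (-len(c[0]), sorted(c[0])))

    n = len(comps)
    parent_of: list[Optional[tuple[int, Optional[int]]]] = [None] * n
    for i in range(n):
        u = comps[i][0]
        enclosing = [j for j in range(n)
                     if j != i and len(comps[j][0]) > len(u)
                     and u <= comps[j][0]]
        if not enclosing:
            continue
        j = min(enclosing, key=lambda j: len(comps[j][0]))
        cells = comps[j][1]
        if cells is None:
            parent_of[i] = (j, None)
        else:
            cell_idx = [k for k, cell in enumerate(cells) if u & cell]
            if len(cell_idx) != 1 or not u <= cells[cell_idx[0]]:
                raise C1PInfeasible(
                    "nested constraint straddles cells of a rigid component")
            parent_of[i] = (j, cell_idx[0])

    def group_node(items: list[PQNode]) -> PQNode:
        if len(items) == 1:
            return items[0]
        return PQNode("P", children=sorted(items, key=_sort_key))

    def comp_node(i: int) -> PQNode:
        union, cells = comps[i]
        child_idx = [c for c in range(n) if parent_of[c] and
                     parent_of[c][0] == i]
        if cells is None:
            covered = frozenset().union(
                *(comps[c][0] for c in child_idx)) if child_idx else frozenset()
            items = [comp_node(c) for c in child_idx]
            items += [PQNode("leaf", label=x) for x in union - covered]
            return group_node(items)
        cell_nodes = []
        for k, cell in enumerate(cells):
            mine = [c for c in child_idx if parent_of[c][1] == k]
            covered = frozenset().union(
                *(comps[c][0] for c in mine)) if mine else frozenset()
            items = [comp_node(c) for c in mine]
            items += [PQNode("leaf", label=x) for x in cell - covered]
            cell_nodes.append(group_node(items))
        kind = "Q" if len(cell_nodes) >= 3 else "P"
        return PQNode(kind, children=cell_nodes)

    top = [i for i in range(n) if parent_of[i] is None]
    covered = frozenset().union(*(comps[i][0] for i in top)) if top \
        else frozenset()
    items = [comp_node(i) for i in top]
    items += [PQNode("leaf", label=x) for x in universe - covered]
    if len(items) == 1 and items[0].kind != "leaf":
        return items[0]
    return PQNode("P", children=sorted(items, key=_sort_key))


@dataclass
class PQTree:
    """A PQ-tree together with the constraint sets it satisfies."""

    root: PQNode
    leaves: frozenset
    accepted: list = field(default_factory=list)

    @classmethod
    def universal(cls, leaves: Iterable[str]) -> "PQTree":
        leaves = frozenset(str(x) for x in leaves)
        return cls(build_tree(leaves, []), leaves, [])

    def frontier(self) -> list[str]:
        return self.root.leaves()

    def q_node_child_counts(self) -> list[int]:
        return [len(q.children) for q in self.root.q_nodes()]


def pq_insert(tree: PQTree, interval: Iterable
              ) -> tuple[PQTree, bool]:
    """Add one consecutiveness constraint.

    Returns the (possibly rebuilt) tree and whether the constraint was
    accepted; on failure the input tree is returned unchanged.
    """
    content = frozenset(str(x) for x in interval)
    if not content <= tree.leaves:
        raise ValueError("interval content must be a subset of the leaves")
    try:
        root = build_tree(tree.leaves, tree.accepted + [content])
    except C1PInfeasible:
        return tree, False
    return PQTree(root, tree.leaves, tree.accepted + [content]), True


# ---------------------------------------------------------------------------
# small-scale verification helpers (used by diagnostics and tests)


def all_frontiers(node: PQNode) -> set:
    """All leaf orders representable by the subtree (exponential; intended
    for small trees)."""
    if node.kind == "leaf":
        return {(node.label,)}
    child_fronts = [all_frontiers(c) for c in node.children]
    results = set()
    if node.kind == "P":
        orders = itertools.permutations(range(len(node.children)))
    else:
        orders = [tuple(range(len(node.children))),
                  tuple(reversed(range(len(node.children))))]
    for order in orders:
        for combo in itertools.product(*(child_fronts[i] for i in order)):
            results.add(tuple(x for part in combo for x in part))
    return results


def _extremal_possible(node: PQNode, leaf: str) -> bool:
    """Can ``leaf`` be placed at an end of the subtree's frontier?"""
    if node.kind == "leaf":
        return node.label == leaf
    holder = next(c for c in node.children if leaf in c.leaves())
    if node.kind == "Q" and holder not in (node.children[0],
                                           node.children[-1]):
        return False
    return _extremal_possible(holder, leaf)


def adjacency_realizable(tree: PQTree, a: str, b: str) -> bool:
    """True iff leaves a and b are adjacent in at least one frontier."""
    a, b = str(a), str(b)
    if a == b or a not in tree.leaves or b not in tree.leaves:
        return False

    def path(node: PQNode, leaf: str) -> list[PQNode]:
        if node.kind == "leaf":
            return [node] if node.label == leaf else []
        for child in node.children:
            sub = path(child, leaf)
            if sub:
                return [node] + sub
        return []

    pa, pb = path(tree.root, a), path(tree.root, b)
    lca_depth = 0
    while (lca_depth < min(len(pa), len(pb)) - 1
           and pa[lca_depth + 1] is pb[lca_depth + 1]):
        lca_depth += 1
    lca = pa[lca_depth]
    ca, cb = pa[lca_depth + 1], pb[lca_depth + 1]
    if lca.kind == "Q":
        ia = lca.children.index(ca)
        ib = lca.children.index(cb)
        if abs(ia - ib) != 1:
            return False
    return _extremal_possible(ca, a) and _extremal_possible(cb, b)
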