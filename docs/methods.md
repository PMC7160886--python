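# Methods

This note documents the models and algorithms implemented in `paleocar`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the simulator-based tests do and do not show.

## Genome model and DCJ distance

A genome is a collection of linear chromosomes, each an ordered sequence
of signed markers; a marker is identified by its family (an opaque
string — refinement mints hierarchical ids like `12@c0#1`) and an
orientation.  Circular chromosomes are out of scope and cannot be
represented; the marker-sequence TSV dialect (genome, chromosome,
1-based ordinal, signed family id) round-trips bit-exactly.

For non-duplicated genomes, each marker contributes head/tail extremities
and consecutive markers define adjacencies (singleton telomeric
adjacencies at the ends).  The adjacency graph of two balanced genomes is
the bipartite multigraph on their adjacency sets with edge multiplicity
|u ∩ v|; every vertex has degree ≤ 2, so components are cycles and paths,
and the DCJ distance is n − c − o/2 (c cycles, o odd paths).  The test
suite validates this closed form against a bidirectional breadth-first
search over actual DCJ operations (on adjacency-set states, circular
intermediates allowed) for hundreds of random genome pairs.

## Local DCJ similarity

Given substrings S and T from a syntenic block, the computation has a
fixed and an optimized part.  Fixed: the balanced content (each family g
keeps min(m_S(g), m_T(g)) occurrences on both sides — the maximality
constraint), hence also the number of deleted markers
d = |S| + |T| − 2·Σ_g min(m_S, m_T).  Optimized: which occurrences are
kept and how they are bijected per family.  Matched occurrences are
relabeled to unique ids, keeping their own signs, and the two projections
are scored as single linear chromosomes through their adjacency graph
with the length reward f(l) = (2−l)/(L−2) + 1; odd paths are scored as
f(edges+1) and even paths as f(edges+2) so that structures with equal
sorting distance have equal effective length.

Parameters: `p` (deletion penalty, default 0.25) — each marker outside
the balanced content costs p, making the score length-sensitive and hence
*local*; `L` (even length threshold, default 8) — f is positive below L,
zero at L, negative above, so L demarcates "similar" from "dissimilar"
component sizes.  f requires even l ≥ 2 and L > 2 (denominator).

**Optimization strategy.**  The assignment space factorizes per family
(choose occurrences on each side, then a bijection).  While the product
of per-family choice counts stays within `node_budget` (default 200 000)
the optimizer enumerates it exhaustively — exact by construction, with
deterministic tie-breaking (lexicographically smallest matched-pair
list).  We deliberately do not branch-and-bound: the objective is a sum
over components of the final adjacency graph, and a partial assignment
freezes no component, so no useful admissible bound is available and
pruning degenerates to enumeration anyway.  Beyond the budget, a greedy
seed (longest common subsequence over family symbols, topped up with
leftmost unused occurrences) is improved by hill-climbing over
within-family target swaps and matched-for-unused swaps; such results are
flagged `exact=False` and can be excluded from refinement via
configuration.  At syntenic-block scale (short substrings, low
multiplicities) the exact path covers almost all computations.

## Syntenic block discovery

Blocks follow reference-based approximate-common-interval semantics.
Candidate reference intervals are the *maximal* intervals (not extendable
without changing content) of content size ≥ `min_ref_size`; an optional
`max_ref_size` bounds the content size when genomes are large (the
pipeline uses 10 at simulation scale; discovery itself is exact for
whatever bound is chosen).  For a content G, occurrence windows in every
chromosome must satisfy inserted ≤ δ^add, missing ≤ δ^loss, and their sum
≤ δ^sum for |G|; windows are anchored on in-content endpoint markers and
only inclusion-maximal satisfying windows are reported.  Windows in the
reference chromosome that overlap the defining interval are subsumed by
the reference occurrence itself (reported with zero deviation).  Quorum
counts distinct genomes including the reference.

The published δ tables are supplementary material not shipped here; the
named profiles are documented stand-ins with the same shape —
`default`: δ^add = δ^loss = ⌊|G|/4⌋, δ^sum = ⌊|G|/3⌋; `relaxed`:
⌊|G|/3⌋ and ⌊|G|/2⌋; `zero`: exact common intervals — and arbitrary
tables load from TSV (step function over content size, monotonicity
enforced).  Discovery is a per-chromosome anchored window scan with
incremental deviation counters; the test suite proves input/output
equivalence with brute-force enumeration of all intervals × all windows.

## Genome segmentation

Segmentation consumes pairwise local alignments and sequence lengths
(FASTA is read only for ids/lengths).  Breakpoints (alignment interval
endpoints plus sequence ends) are closed under propagation: a breakpoint
strictly inside one side of an alignment induces the proportionally
mapped, strand-aware, integer-snapped breakpoint on the other side,
iterated to a fixed point (integer snapping guarantees termination).
Candidate atoms are the segments between consecutive closed breakpoints;
segments shorter than `min_length` (default 100 bp) or covered by no
alignment become waste.  Since the exact segmentation problem is
intractable, a greedy improvement pass repeatedly discards the alignment
whose removal reduces total waste the most and re-closes; waste is
monotonically non-increasing, and a subset-enumeration oracle in the
tests reports (does not force to zero) the optimality gap on small
instances.  Proportional mapping ignores alignment gap structure (no
CIGARs in the input format).

Atom families are connected components of the graph linking atoms that an
alignment maps onto each other with ≥ `overlap_frac` (default 0.8) mutual
coverage; orientations propagate breadth-first from each component's
representative.  Families spanning fewer than two genomes are dropped at
marker export.

## Family refinement

Block sets sharing a marker occurrence (same genome, chromosome,
position — sharing by family alone would collapse everything after a
WGD) form overlap components.  Rule (i) splits every family along
component membership; rule (ii) promotes a reference occurrence m1 and
its targets {m2, …, mk} to a new family when every non-reference genome
contributes exactly one distinct target across all local DCJ
computations of the component.  A target matched to two different
reference anchors is treated as inconsistent and stays in its rule-(i)
family; being unmatched in some computation does not violate
consistency.  New ids are hierarchical (`F@c3`, `F@c3#0`) so provenance
stays auditable; when a group coincides with an entire existing family
the label is kept, which makes the whole refinement idempotent.  The
output partition always refines the input (only splits, never merges).

## CAR assembly

Ancestral content: every refined family occurring in ≥ 2 genomes (or, if
a two-clade split of the genome set is configured and
`content_rule: split`, in at least one genome on each side).

Candidate intervals come from two sources.  (a) Adjacencies: each
chromosome is projected onto the ancestral content and consecutive pairs
are collected.  Support is pooled at the level of original
(pre-refinement) families, because refinement distributes the witnesses
of one ancestral adjacency over several sub-family id pairs; each
sufficiently supported (≥ 2 genomes) parent-level adjacency yields one
candidate whose *alternates* are its possible copy realizations, observed
pairs first (same-overlap-component pairs preferred, then best
witnessed).  A single realization per adjacency is essential: a leaf has
two neighbor slots in a linear order, and emitting every copy pair makes
the copies of one family compete for the slots of a shared neighbor.
(b) Blocks: each block set contributes its reference-window content
restricted to ancestral families.

Weights (`weight_mode`): `witness` (default) weights an adjacency by its
total witness count over genomes *and* retained copies — a truly
ancestral adjacency recurs in several surviving post-polyploidy copies,
a fractionation junction or lineage-specific rearrangement typically in
one — and blocks by their summed local DCJ scores; `occurrence` weights
both by supporting-genome count; `dcj` weights blocks by score sums and
adjacencies by genome count.  When a clade split is configured,
candidates witnessed on both sides of the root speciation are ordered
before equally weighted clade-confined ones (a Dollo-style criterion:
clade-confined neighborhoods are plausibly derived).

Candidates are inserted greedily in decreasing weight (ties: spanning
first, then smaller content, then lexicographic) into a PQ-tree; for each
candidate the first compatible alternate is committed, conflicting
candidates are skipped, and the acceptance log makes the run auditable.
The overlap cap (default 30, applied per mutually-overlapping group,
keeping the highest-weight blocks) limits only what reaches the tree
builder; refinement always sees every discovered block.

**PQ-tree.**  The tree is rebuilt from the accepted constraint sets
rather than reduced online.  The construction uses two classical facts
about a consecutive-ones family: strict-overlap components of the
constraint sets have unions that behave as modules, and within a
component the equivalence classes ("cells") admit a linear order unique
up to reversal, computed by placing the component's sets along a
strict-overlap spanning order with splitting only at run boundaries.
Components become Q-nodes over their cells (a two-cell component carries
no more order than an unordered pair and is emitted as a P-node, so
Q-nodes always have ≥ 3 children), nesting gives the hierarchy, and
unconstrained material groups under P-nodes.  Infeasibility surfaces as
an exception during placement.  The tests verify acceptance decisions
and frontier-consecutiveness against brute-force permutation enumeration
over thousands of random instances.

CARs are the top-level subtrees; marker order is the frontier with
P-groups parenthesized (P children emitted in lexicographic order of
their smallest leaf, for reproducibility); CARs are unsigned since
orientation inference is not part of the reconstruction.  The fixation
metric is the mean child count over all Q-nodes (absent when none
exist).

## Simulator

The simulator generates the statistical structure the pipeline assumes:
a random ancestor of `n_markers` unique signed markers over
`n_chromosomes` linear chromosomes evolves along a rooted phylogeny.
Per branch, whole-genome events copy every chromosome (×2 or ×3), then
random DCJ operations are applied (uniform over adjacency pairs
including telomeric ones; intra-chromosomal cuts resolve to inversions —
the alternative rejoining excises a circular chromosome, which the
linear-genome contract disallows — and no-ops are redrawn).  All
randomness derives from one seed through per-branch `SeedSequence`
spawns, so identical configurations produce byte-identical datasets.

Fractionation is modeled in two forms.  `apply_polyploidy` performs the
event-coupled form: each *redundant* copy of each pre-event occurrence is
lost independently with the given rate, one uniformly chosen copy per
occurrence being protected (so loss_rate = 1 restores pre-event
multiplicities).  `fractionate` performs the lineage form used by the
study scenarios: on a branch without events, each redundant copy of each
family is lost at the branch's rate, again with one protected survivor
per family.  The eudicot scenario places the triplication on the shared
stem and the duplication on the sunflower branch but defers loss to the
terminal branches — lineages sharing an ancient polyploidy are observed
to retain largely independent subsets of the duplicated copies, and this
independence is also what gives a reconstruction method usable signal
(if all loss happened once on the stem, every genome would inherit the
same fractionated layout and a sizable fraction of the true ancestral
adjacencies would be absent from the data altogether).

Ground truth records, per extant occurrence, the ancestral marker and
the copy lineage (suffix path through the polyploidy events), plus the
ancestor itself and an operations log.

**What the simulator does not emulate:** nucleotide-level evolution (the
segmentation stage is exercised on constructed alignment fixtures
instead, since it consumes alignments, not sequences), unequal family
sizes or tandem duplications, biased fractionation, gene conversion
between copies, and branch lengths in time units.  Passing recovery
tests therefore demonstrate correct and well-calibrated behavior under
the assumed generative model, not performance on real genomes.

## Problem sizes and measured behavior

The simulation-based evaluations use a 200-marker ancestor over five
chromosomes with 5–20 DCJ operations per branch, fractionation rate 0.6,
reference-interval contents bounded at 10 families, and an exact-search
budget of 20 000 assignments — sizes at which a full pipeline run takes
a few seconds.  Under these conditions, family refinement consistently
enlarges the reconstructed ancestral content (by roughly 60–80% over the
one-marker-per-family baseline) and improves adjacency recovery.  Strict
recovery — a true ancestral adjacency counts only if two leaves mapping
to its families lie in one CAR and can be made adjacent in some frontier
— reaches ≈ 0.82–0.89 across seeds.  The remaining gap has two causes:
a few adjacencies lack the two-genome support floor entirely, and
derived adjacencies created on shared internal branches (supported by
several genomes) or coincident fractionation junctions outrank some true
pairs in the greedy insertion.  These are properties of the evidence and
of greedy conflict resolution, not of any particular parameter setting.

## Known limitations

- The PQ-tree is rebuilt per insertion (no amortized Booth–Lueker
  templates); quadratic in accepted-constraint count, which is fine at
  the intended scale but not for hundreds of thousands of constraints.
- Exact local DCJ optimization falls back to a flagged heuristic beyond
  the node budget; refinement may then act on suboptimal assignments
  (configurable exclusion).
- Segmentation's breakpoint propagation interpolates linearly across
  alignments; gapped alignment structure is ignored.
- CAR orientation and ancestral karyotype assignment are not
  reconstructed.
- The shipped δ profiles are stand-ins; analyses of real data should
  load the intended thresholds as a custom table.
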