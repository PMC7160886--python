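# paleocar

Reconstruction of ancestral genome maps from signed genomic markers, built
for highly diverged, repeatedly polyploidized genomes such as those of
flowering plants.

After one or more rounds of whole-genome duplication (WGD) or triplication
(WGT), each marker family holds several positional copies per genome and a
fractionated, rearranged layout obscures the ancestral order.  `paleocar`
implements a rearrangement-aware, synteny-based reconstruction workflow:

1. **Segmentation** — pairwise local alignments (LASTZ-general-style TSV)
   cut the input sequences into *atoms*: non-overlapping segments with no
   alignment boundary inside them, grouped into families, minimizing the
   nucleotides left in waste regions.
2. **Synteny** — reference-based approximate common intervals: an interval
   of a designated reference genome defines a family content *G*, and
   occurrence windows in all genomes may deviate from *G* by at most
   δ<sup>add</sup> inserted, δ<sup>loss</sup> missing, δ<sup>sum</sup>
   total families (thresholds depend on |*G*| through a δ table); a quorum
   *q* sets the minimum number of genomes per block set.
3. **Local DCJ similarity** — the score at the heart of the workflow.  For
   a syntenic substring pair (S, T), maximal balanced subsequences are
   matched one-to-one per family and the non-duplicated pair (S″, T″) is
   scored through its adjacency graph:

   s_DCJ(S″,T″) = Σ_{C∈𝒞} f(|C|) + ½ ( Σ_{O∈𝒪} f(|O|+1) + Σ_{E∈ℰ} f(|E|+2) ) − d·p

   with 𝒞, 𝒪, ℰ the cycles, odd and even paths, d = |S|+|T|−(|S″|+|T″|)
   the deleted markers, p the deletion penalty, and the length reward
   f(l) = (2−l)/(L−2) + 1 (short structures indicate similarity, long ones
   the opposite).  Defaults: p = 0.25, L = 8.
4. **Family refinement** — overlapping syntenic block sets split marker
   families (rule i), and consistent one-to-one assignments across all
   local DCJ computations of a component found new one-copy-per-genome
   sub-families (rule ii).
5. **CAR assembly** — refined families supported by ≥ 2 genomes form the
   ancestral content; observed ancestral adjacencies and block contents
   become weighted candidate intervals, greedily inserted into a PQ-tree
   under the consecutive-ones constraint.  The tree's top-level subtrees
   are the contiguous ancestral regions (CARs); the mean child count of
   Q-nodes measures how fixed the reconstructed order is.

A polyploidy-aware simulator (ancestor → random DCJ operations → WGD/WGT
with lineage-specific fractionation, full ground truth) makes every stage
testable without external data.  The classic DCJ distance
d_DCJ = n − c − o/2 for balanced non-duplicated genomes is included and
oracle-verified.

## Worked example

Simulate a small five-genome eudicot-shaped dataset (WGT on the shared
stem, WGD on the sunflower branch, fractionation on terminal branches)
and reconstruct the ancestor with and without family refinement:

```sh
paleocar simulate --n-markers 40 --n-chromosomes 3 --seed 7 --outdir sim
cat > config.yaml <<'YAML'
io:
  markers:
    - sim/grape.markers.tsv
    - sim/coffee.markers.tsv
    - sim/artichoke.markers.tsv
    - sim/lettuce.markers.tsv
    - sim/sunflower.markers.tsv
  outdir: run
synteny:
  reference: grape
  max_ref_size: 8
YAML
paleocar run --config config.yaml --ablate-refinement
```

prints (abridged):

```json
{
 "ancestral_content_refined": 83,
 "ancestral_content_unrefined": 40,
 "block_count": 127,
 "block_count_after_cap": 47,
 "car_count": 12,
 "q_node_mean_children": 9.75,
 "total_markers": 776
}
```

Without refinement each of the 40 original families can contribute at
most one ancestral marker; refinement splits families into copy-specific
sub-families and recruits 83 markers — the multi-copy structure created
by the triplication becomes part of the reconstructed ancestor.  `run/`
holds the per-stage outputs: `blocks.tsv` (syntenic block sets),
`scores.tsv` (local DCJ scores and one-to-one assignments),
`refined_markers.tsv` + `provenance.tsv` (refined families), and
`cars.txt`, one CAR per line with unordered groups parenthesized:

```
CAR0001	18 38 27 22 19 8 31 1 14@c0 38@c0 16@c0 27@c0 18@c0 11@c0 33@c0#3
CAR0003	17@c0 13@c0 15@c0 22@c0 25@c0
```

Every stage is also exposed as its own subcommand (`segment`, `synteny`,
`score`, `refine`, `reconstruct`) over the same config file, and as plain
library functions (`paleocar.local_dcj.local_dcj_similarity`,
`paleocar.genome_model.dcj_distance`, ...).

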