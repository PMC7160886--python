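"""Pipeline orchestration: segment -> synteny -> score -> refine -> CARs.

A structured YAML/JSON configuration drives the stages; every run
materializes its fully-resolved configuration, all stage outputs, and a
metrics JSON into a run directory, so any stage can be re-run from cached
inputs with byte-identical results.  The pipeline may start from marker
TSVs (gene-based mode with externally built families), skipping
segmentation.
"""

from __future__ import annotations

import copy
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import __version__
from .car_builder import (
    adjacency_recovery,
    ancestral_content,
    build_pq_tree,
    collect_candidates,
    extract_cars,
    write_car_file,
)
from .family_refinement import (
    FamilyPartition,
    refine,
    root_family,
    write_provenance_tsv,
)
from .genome_model import Genome, read_marker_tsv, write_marker_tsv
from .local_dcj import ScoringParams, score_block_set
from .segmentation import (
    assign_families,
    export_markers,
    fasta_lengths,
    read_alignments,
    segment,
    write_atoms_bed,
)
from .synteny import (
    DeltaTable,
    apply_overlap_cap,
    discover_blocks,
    write_block_tsv,
)

logger = logging.getLogger("paleocar")

DEFAULT_CONFIG = {
    "seed": 0,
    "log_level": "INFO",
    "io": {
        "markers": [],          # marker TSV paths (one or more)
        "alignments": None,     # alignment TSV (segmentation mode)
        "fasta": None,          # FASTA for sequence ids and lengths
        "seq_to_genome": {},    # sequence id -> genome id (segmentation mode)
        "outdir": "run",
    },
    "segmentation": {
        "min_length": 100,
        "min_score": 0.0,
        "overlap_frac": 0.8,
        "min_genomes": 2,
    },
    "synteny": {
        "reference": None,
        "quorum": 2,
        "delta_profile": "default",
        "delta_table_path": None,
        "min_ref_size": 2,
        "max_ref_size": None,
        "all_intervals": False,
        "overlap_cap": 30,
    },
    "scoring": {
        "p": 0.25,
        "L": 8,
        "node_budget": 200000,
    },
    "refinement": {
        "enabled": True,
        "include_heuristic": True,
    },
    "car": {
        "weight_mode": "witness",
        "clade_split": None,       # [[genomes...], [genomes...]]
        "content_rule": "any2",    # "any2" | "split"
    },
}


class ConfigError(ValueError):
    pass


def resolve_config(user: Optional[dict]) -> dict:
    """Merge a user configuration over the defaults, rejecting unknown
    keys."""
    resolved = copy.deepcopy(DEFAULT_CONFIG)

    def merge(dst: dict, src: dict, path: str):
        for key, value in src.items():
            if key not in dst:
                raise ConfigError(f"unknown config key {path}{key}")
            if isinstance(dst[key], dict) and key != "seq_to_genome":
                if not isinstance(value, dict):
                    raise ConfigError(f"{path}{key} must be a mapping")
                merge(dst[key], value, f"{path}{key}.")
            else:
                dst[key] = value

    if user:
        merge(resolved, user, "")
    return resolved


def load_config(path) -> dict:
    with open(path) as handle:
        user = yaml.safe_load(handle) or {}
    return resolve_config(user)


def _delta_table(cfg: dict) -> DeltaTable:
    if cfg["synteny"]["delta_table_path"]:
        return DeltaTable.from_tsv(cfg["synteny"]["delta_table_path"])
    return DeltaTable.from_profile(cfg["synteny"]["delta_profile"])


def _scoring_params(cfg: dict) -> ScoringParams:
    s = cfg["scoring"]
    return ScoringParams(L=s["L"], p=s["p"], node_budget=s["node_budget"])


def stage_segment(cfg: dict, outdir: Path) -> Path:
    """Alignments + FASTA -> atoms BED + marker TSV."""
    io = cfg["io"]
    if not io["alignments"] or not io["fasta"]:
        raise ConfigError("segmentation requires io.alignments and io.fasta")
    seq_lengths = fasta_lengths(io["fasta"])
    alignments = read_alignments(io["alignments"],
                                 cfg["segmentation"]["min_score"])
    seg = segment(alignments, seq_lengths,
                  cfg["segmentation"]["min_length"])
    seg = assign_families(seg,
                          overlap_frac=cfg["segmentation"]["overlap_frac"])
    seq_to_genome = dict(io["seq_to_genome"]) or {
        seq: seq.split(".")[0] for seq in seq_lengths}
    genomes = export_markers(seg, seq_to_genome,
                             cfg["segmentation"]["min_genomes"])
    write_atoms_bed(outdir / "atoms.bed", seg)
    markers_path = outdir / "markers.tsv"
    write_marker_tsv(markers_path, genomes)
    logger.info("segmentation: %d atoms, waste %d bp",
                len(seg.atoms), seg.waste_total)
    return markers_path


def load_genomes(paths: Sequence) -> list[Genome]:
    genomes: list[Genome] = []
    for path in paths:
        genomes.extend(read_marker_tsv(path))
    return genomes


def run_pipeline(cfg: dict, ablate_refinement: bool = False,
                 start_from: str = "markers") -> dict:
    """Run the stages in order; returns the metrics dictionary.

    ``start_from`` is "alignments" (full run including segmentation) or
    "markers" (marker/gene-based mode).  With ``ablate_refinement`` the
    reconstruction is carried out twice, with and without family
    refinement, and both ancestral content sizes are reported.
    """
    cfg = resolve_config(cfg)
    outdir = Path(cfg["io"]["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=cfg["log_level"])
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    logger.addHandler(handler)
    try:
        return _run(cfg, outdir, ablate_refinement, start_from)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(cfg: dict, outdir: Path, ablate_refinement: bool,
         start_from: str) -> dict:
    with open(outdir / "resolved_config.yaml", "w") as handle:
        yaml.safe_dump({"version": __version__, **cfg}, handle,
                       sort_keys=True)

    if start_from == "alignments":
        marker_paths = [stage_segment(cfg, outdir)]
    elif start_from == "markers":
        marker_paths = cfg["io"]["markers"]
        if not marker_paths:
            raise ConfigError("io.markers is required in marker mode")
    else:
        raise ConfigError(f"unknown start_from {start_from!r}")

    genomes = load_genomes(marker_paths)
    if not genomes:
        raise ConfigError("no genomes loaded")
    by_id = {g.genome_id: g for g in genomes}
    reference = cfg["synteny"]["reference"] or genomes[0].genome_id
    if reference not in by_id:
        raise ConfigError(f"synteny.reference {reference!r} not among "
                          f"genomes {sorted(by_id)}")

    metrics: dict = {
        "version": __version__,
        "reference": reference,
        "marker_counts": {g.genome_id: g.n_markers for g in genomes},
        "total_markers": sum(g.n_markers for g in genomes),
    }

    # synteny
    blocks = discover_blocks(
        genomes, reference, _delta_table(cfg),
        quorum=cfg["synteny"]["quorum"],
        min_ref_size=cfg["synteny"]["min_ref_size"],
        all_intervals=cfg["synteny"]["all_intervals"],
        max_ref_size=cfg["synteny"]["max_ref_size"])
    metrics["block_count"] = len(blocks)
    logger.info("synteny: %d block sets", len(blocks))

    # local DCJ scoring
    params = _scoring_params(cfg)
    scored = []
    for block in blocks:
        scored.extend(score_block_set(block, by_id, params))
    _write_scores(outdir / "scores.tsv", scored)

    # family refinement sees every block; the overlap cap below only
    # limits what is handed to the tree builder
    base = FamilyPartition.from_genomes(genomes)
    if cfg["refinement"]["enabled"]:
        partition = refine(
            base, blocks, scored, reference,
            include_heuristic=cfg["refinement"]["include_heuristic"])
    else:
        partition = base
    refined_genomes = partition.relabeled_genomes(genomes)

    # overlap cap, weighted by summed local DCJ scores
    cap = cfg["synteny"]["overlap_cap"]
    if cap:
        weights = {}
        for rec in scored:
            weights[rec.block_id] = weights.get(rec.block_id, 0.0) \
                + rec.result.score
        blocks = apply_overlap_cap(
            blocks, lambda b: weights.get(b.block_id, 0.0), cap)
        kept_ids = {b.block_id for b in blocks}
        scored = [r for r in scored if r.block_id in kept_ids]
    metrics["block_count_after_cap"] = len(blocks)
    write_block_tsv(outdir / "blocks.tsv", blocks)
    write_marker_tsv(outdir / "refined_markers.tsv", refined_genomes)
    write_provenance_tsv(outdir / "provenance.tsv", partition)
    metrics["refined_family_count"] = len(partition.families())

    # reconstruction
    clade_split = cfg["car"]["clade_split"]
    if clade_split:
        clade_split = (tuple(clade_split[0]), tuple(clade_split[1]))
    content_split = clade_split if cfg["car"]["content_rule"] == "split" \
        else None
    content = ancestral_content(refined_genomes, content_split)
    metrics["ancestral_content"] = len(content)
    tree, cars, fixation = _reconstruct(
        cfg, refined_genomes, blocks, scored, content, clade_split,
        leaf_to_parent={f: root_family(partition, f) for f in content})
    write_car_file(outdir / "cars.txt", cars)
    metrics["car_count"] = len(cars)
    metrics["q_node_mean_children"] = fixation
    logger.info("reconstruction: %d CARs over %d markers",
                len(cars), len(content))

    if ablate_refinement:
        unref_genomes = base.relabeled_genomes(genomes)
        unref_content = ancestral_content(unref_genomes, content_split)
        unref_tree, unref_cars, unref_fix = _reconstruct(
            cfg, unref_genomes, blocks, scored, unref_content, clade_split)
        metrics["ancestral_content_refined"] = len(content)
        metrics["ancestral_content_unrefined"] = len(unref_content)
        metrics["car_count_unrefined"] = len(unref_cars)
        metrics["q_node_mean_children_unrefined"] = unref_fix

    with open(outdir / "metrics.json", "w") as handle:
        json.dump(metrics, handle, indent=1, sort_keys=True)
    return metrics


def _reconstruct(cfg, refined_genomes, blocks, scored, content,
                 clade_split, leaf_to_parent=None):
    candidates = collect_candidates(
        refined_genomes, blocks, scored, content=content,
        weight_mode=cfg["car"]["weight_mode"], clade_split=clade_split,
        leaf_to_parent=leaf_to_parent)
    tree, _ = build_pq_tree(candidates, content)
    cars, fixation = extract_cars(tree)
    return tree, cars, fixation


def _write_scores(path, scored) -> None:
    with open(path, "w") as handle:
        handle.write("block_id\ttarget_genome\toccurrence_id\tscore\t"
                     "deleted\texact\tmatched_pairs\n")
        for rec in scored:
            handle.write("\t".join(map(str, (
                rec.block_id, rec.target_genome, rec.occurrence_id,
                f"{rec.result.score:.6g}", rec.result.deleted_count,
                int(rec.result.exact),
                rec.result.serialized_pairs()))) + "\n")


# ---------------------------------------------------------------------------
# evaluation against simulated ground truth


def evaluate_recovery(cfg: dict, genomes: Sequence[Genome],
                      truth) -> dict:
    """Run the pipeline stages in memory on simulated genomes and measure
    recovery of true ancestral adjacencies, with and without family
    refinement."""
    cfg = resolve_config(cfg)
    by_id = {g.genome_id: g for g in genomes}
    reference = cfg["synteny"]["reference"] or genomes[0].genome_id
    blocks = discover_blocks(
        genomes, reference, _delta_table(cfg),
        quorum=cfg["synteny"]["quorum"],
        min_ref_size=cfg["synteny"]["min_ref_size"],
        max_ref_size=cfg["synteny"]["max_ref_size"])
    params = _scoring_params(cfg)
    scored = []
    for block in blocks:
        scored.extend(score_block_set(block, by_id, params))

    base = FamilyPartition.from_genomes(genomes)
    partition = refine(base, blocks, scored, reference)

    cap = cfg["synteny"]["overlap_cap"]
    if cap:
        weights = {}
        for rec in scored:
            weights[rec.block_id] = weights.get(rec.block_id, 0.0) \
                + rec.result.score
        blocks = apply_overlap_cap(
            blocks, lambda b: weights.get(b.block_id, 0.0), cap)
        kept = {b.block_id for b in blocks}
        scored = [r for r in scored if r.block_id in kept]

    clade_split = cfg["car"]["clade_split"]
    if clade_split:
        clade_split = (tuple(clade_split[0]), tuple(clade_split[1]))

    results: dict = {"block_count": len(blocks)}
    true_adj = truth.true_adjacencies()
    for label, part in (("refined", partition), ("unrefined", base)):
        gset = part.relabeled_genomes(genomes)
        content = ancestral_content(gset)
        leaf_to_anc = {leaf: root_family(part, leaf) for leaf in content}
        candidates = collect_candidates(
            gset, blocks, scored, content=content,
            weight_mode=cfg["car"]["weight_mode"],
            clade_split=clade_split, leaf_to_parent=leaf_to_anc)
        tree, _ = build_pq_tree(candidates, content)
        cars, fixation = extract_cars(tree)
        recovery = adjacency_recovery(tree, sorted(true_adj, key=sorted),
                                      leaf_to_anc)
        results[label] = {
            "ancestral_content": len(content),
            "car_count": len(cars),
            "q_node_mean_children": fixation,
            "adjacency_recovery": recovery,
        }
    return results
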