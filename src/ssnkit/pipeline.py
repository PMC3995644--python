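"""End-to-end orchestration: FASTA in, networks + tables + manifest out."""

from __future__ import annotations

import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .align import ScoringScheme, all_by_all, read_tabular_hits, write_edge_table
from .annotate import overlay_node
from .io import (
    PipelineConfig,
    read_annotation_table,
    read_fasta_filtered,
    write_edge_attribute_table,
    write_manifest,
    write_node_attribute_table,
    write_sif,
    write_subgroup_table,
    write_xgmml,
)
from .networks import (
    build_full_network,
    build_rep_network,
    edge_median_stats,
    greedy_identity_cluster,
    identity_lookup_from_pairs,
)
from .structnet import build_structure_network, dedupe_chains, read_structure_scores
from .structnet import StructureChainRecord
from .subgroups import designate_subgroups, propagate_members
from .thresholds import MCLParams, scan_thresholds

logger = logging.getLogger("ssnkit")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str, manifest: dict, out_dir: Path, fn):
    logger.info("stage %s", name)
    try:
        return fn()
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        (out_dir / "FAILED").write_text(f"stage {name}: {exc}\n")
        raise StageError(name, exc) from exc


def run_pipeline(config: PipelineConfig, sequences=None, pairs=None,
                 annotations=None) -> dict:
    """Run the full classification pipeline and write all outputs.

    ``sequences``, ``pairs`` and ``annotations`` may be passed in-memory
    (e.g. from the synthetic generator); otherwise they are read from the
    paths in ``config``.  Returns a bundle dict with the networks,
    designations, per-sequence labels and the manifest.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.rng_seed,
        "config": {k: v for k, v in asdict(config).items()},
        "counts": {},
    }
    counts = manifest["counts"]

    scheme = ScoringScheme(matrix_name=config.matrix_name,
                           gap_open=config.gap_open, gap_extend=config.gap_extend)

    if sequences is None:
        sequences = _stage("read_fasta", manifest, out_dir, lambda: read_fasta_filtered(
            config.fasta, min_length=config.min_sequence_length))
    counts["sequences"] = len(sequences)

    if pairs is None:
        if config.external_edges:
            pairs = _stage("load_external_edges", manifest, out_dir,
                           lambda: read_tabular_hits(config.external_edges, scheme))
        else:
            pairs = _stage("all_by_all", manifest, out_dir, lambda: all_by_all(
                sequences, scheme, report_ceiling=config.report_ceiling))
    counts["pairs"] = len(pairs)
    write_edge_table(pairs, out_dir / "edges.tsv")

    clusters = _stage("identity_clustering", manifest, out_dir,
                      lambda: greedy_identity_cluster(
                          sequences, config.rep_identity,
                          identity_lookup_from_pairs(pairs, sequences)))
    counts["rep_nodes"] = len(clusters)

    rep_net = _stage("rep_network", manifest, out_dir,
                     lambda: build_rep_network(clusters, pairs))
    counts["rep_edges"] = rep_net.n_edges

    level1 = _stage("level1_subgroups", manifest, out_dir, lambda: designate_subgroups(
        rep_net, config.level1_cutoff, min_members=config.min_members, level=1))
    level2 = _stage("level2_subgroups", manifest, out_dir, lambda: designate_subgroups(
        rep_net, config.level2_cutoff, min_members=config.min_members, level=2,
        parent_assignment=level1))
    counts["level1_subgroups"] = len(level1.subgroups)
    counts["level2_subgroups"] = len(level2.subgroups)
    counts["level2_singletons"] = sum(1 for u in level2.unassigned if u.is_singleton)

    seq_level1 = propagate_members(level1, clusters)
    seq_level2 = propagate_members(level2, clusters)
    counts["assigned_level1_members"] = sum(1 for v in seq_level1.values() if v)
    counts["unassigned_level1_members"] = sum(1 for v in seq_level1.values() if not v)
    write_subgroup_table(seq_level1, seq_level2, clusters, out_dir / "subgroups.tsv")

    if annotations is None and config.annotations:
        annotations = _stage("read_annotations", manifest, out_dir,
                             lambda: read_annotation_table(config.annotations))
    overlays = []
    node_class = {}
    if annotations:
        def build_overlays():
            out = []
            for cl in clusters:
                members = [annotations[mid] for mid in cl.member_ids
                           if mid in annotations]
                out.append(overlay_node(cl.representative_id, members))
            return out

        overlays = _stage("annotate", manifest, out_dir, build_overlays)
        node_class = {ov.node_id: ov.class_label for ov in overlays}
        extra = {
            ov.node_id: {
                "level1": level1.node_to_name.get(ov.node_id) or "",
                "level2": level2.node_to_name.get(ov.node_id) or "",
            }
            for ov in overlays
        }
        write_node_attribute_table(overlays, out_dir / "node_attributes.tsv", extra)
    counts["annotated_nodes"] = sum(1 for c in node_class.values() if c)

    scan = None
    if config.run_scan:
        scan = _stage("threshold_scan", manifest, out_dir, lambda: scan_thresholds(
            rep_net, node_class, config.scan_candidates,
            MCLParams(inflation=config.mcl_inflation)))
        scan.table.to_csv(out_dir / "threshold_scan.tsv", sep="\t", index=False)
        counts["selected_cutoff"] = scan.selected_cutoff

    # Per-level network exports at their thresholds, plus per-level2 full networks.
    from .subgroups import apply_threshold

    for tag, cutoff in (("level1", config.level1_cutoff), ("level2", config.level2_cutoff)):
        thr = apply_threshold(rep_net, cutoff)
        write_sif(thr, out_dir / f"rep_{tag}.sif")
        write_xgmml(thr, out_dir / f"rep_{tag}.xgmml", label=f"rep network {tag}")
        write_edge_attribute_table(thr, out_dir / f"rep_{tag}_edges.tsv")
        stats = edge_median_stats(thr)
        if stats:
            med_pid, med_len, n_edges = stats
            counts[f"{tag}_edges"] = n_edges
            counts[f"{tag}_median_pid"] = round(med_pid, 1)
            counts[f"{tag}_median_alnlen"] = round(med_len, 1)

    full_nets = {}
    for sg in level2.subgroups:
        full = build_full_network(sg.member_sequence_ids, pairs)
        full_thr = apply_threshold(full, config.full_cutoff)
        full_nets[sg.name] = full_thr
        write_sif(full_thr, out_dir / f"full_{sg.name}.sif")

    struct_net = None
    if config.structure_scores:
        scores = _stage("structure_scores", manifest, out_dir,
                        lambda: read_structure_scores(config.structure_scores))
        chains = _read_chain_table(config) if getattr(config, "structure_chains", "") else None
        if chains:
            reps = dedupe_chains(chains, config.struct_identity)
            rep_ids = {r.representative_id for r in reps}
            scores = [s for s in scores
                      if s.chain_id_a in rep_ids and s.chain_id_b in rep_ids]
            struct_net = build_structure_network(reps, scores, config.sn_cutoff)
        else:
            chain_ids = sorted({c for s in scores for c in (s.chain_id_a, s.chain_id_b)})
            struct_net = build_structure_network(chain_ids, scores, config.sn_cutoff)
        write_sif(struct_net, out_dir / "structures.sif")
        write_xgmml(struct_net, out_dir / "structures.xgmml", label="structure network")
        counts["structure_nodes"] = struct_net.n_nodes
        counts["structure_edges"] = struct_net.n_edges

    total = counts["assigned_level1_members"] + counts["unassigned_level1_members"]
    assert total == counts["sequences"], "member conservation violated"
    write_manifest(manifest, out_dir / "manifest.txt")

    return {
        "sequences": sequences,
        "pairs": pairs,
        "clusters": clusters,
        "rep_net": rep_net,
        "level1": level1,
        "level2": level2,
        "seq_level1": seq_level1,
        "seq_level2": seq_level2,
        "overlays": overlays,
        "scan": scan,
        "full_networks": full_nets,
        "structure_network": struct_net,
        "manifest": manifest,
    }


def _read_chain_table(config):
    path = getattr(config, "structure_chains", "")
    if not path:
        return None
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        StructureChainRecord(
            structure_id=str(r.structure_id), sequence=str(r.sequence),
            sequence_id=str(r.sequence_id) or None,
            quality=float(r.quality) if str(r.quality) else None,
            source=str(r.source) or "literature",
        )
        for r in df.itertuples(index=False)
    ]
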