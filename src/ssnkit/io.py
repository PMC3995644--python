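"""Readers and writers for the pipeline's file formats.

FASTA in (length-filtered), TSV tables out (edges, node attributes,
subgroups, annotations, threshold scans), plus Cytoscape-loadable network
exports (SIF and XGMML) and a plain-text run manifest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path
from xml.etree import ElementTree as ET
from xml.dom import minidom

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .annotate import AnnotationRecord
from .records import ConfigError, InputError, SequenceRecord

logger = logging.getLogger("ssnkit")

__all__ = [
    "PipelineConfig",
    "read_fasta_filtered",
    "write_fasta",
    "read_annotation_table",
    "write_annotation_table",
    "write_subgroup_table",
    "write_node_attribute_table",
    "write_sif",
    "write_xgmml",
    "write_manifest",
    "read_config_file",
]


class FastaParseError(InputError):
    """Malformed FASTA; carries the offending line number."""


def _validate_fasta_layout(path) -> None:
    with open(path) as handle:
        header_line = None
        saw_residues = False
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                if header_line is not None and not saw_residues:
                    raise FastaParseError(
                        f"{path}: empty record at line {header_line}"
                    )
                header_line = lineno
                saw_residues = False
            else:
                if header_line is None:
                    raise FastaParseError(
                        f"{path}: sequence data before any header at line {lineno}"
                    )
                saw_residues = True
        if header_line is not None and not saw_residues:
            raise FastaParseError(f"{path}: empty record at line {header_line}")


def read_fasta_filtered(path, min_length: int = 100):
    """Read FASTA, keeping full-length records of at least ``min_length``.

    Duplicate identifiers are rejected; input order is preserved.  Malformed
    files (residues before a header, an empty record) raise
    :class:`FastaParseError` with the line number.
    """
    _validate_fasta_layout(path)
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise InputError(f"{path}: duplicate sequence identifier {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if len(seq) >= min_length:
            records.append(SequenceRecord(rec.id, seq, description=rec.description))
    if not records:
        logger.warning("%s: no sequences of length >= %d", path, min_length)
    return records


def write_fasta(records, path) -> None:
    bio = [
        BioSeqRecord(Seq(r.sequence), id=r.id, description=r.description or "")
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# Annotation tables

_ANNO_COLUMNS = ["sequence_id", "class_label", "taxonomy_lineage",
                 "reaction_types", "reaction_source", "structure_ids"]


def write_annotation_table(truth, path) -> None:
    """Serialize a PlantedTruth's annotations (or any equivalent mapping set)."""
    rows = []
    for sid in sorted(truth.assignments):
        evidence = sorted(truth.reactions.get(sid, ()))
        structs = truth.structure_links.get(sid, ())
        rows.append({
            "sequence_id": sid,
            "class_label": truth.class_labels.get(sid) or "",
            "taxonomy_lineage": truth.taxonomy.get(sid, ""),
            "reaction_types": ",".join(rt for rt, _src in evidence),
            "reaction_source": ",".join(src for _rt, src in evidence),
            "structure_ids": ",".join(structs),
        })
    pd.DataFrame(rows, columns=_ANNO_COLUMNS).to_csv(path, sep="\t", index=False)


def read_annotation_table(path):
    """Read the annotation TSV into AnnotationRecords keyed by sequence id."""
    # keep_default_na=False: "NA" is a reaction-type code (nucleophilic
    # addition), not a missing value.
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_ANNO_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"annotation table missing columns: {sorted(missing)}")
    out = {}
    for r in df.itertuples(index=False):
        types = [t for t in r.reaction_types.split(",") if t]
        sources = [s for s in r.reaction_source.split(",") if s]
        if len(types) != len(sources):
            raise InputError(
                f"{r.sequence_id}: reaction_types and reaction_source differ in length"
            )
        lineage = tuple(p.strip() for p in r.taxonomy_lineage.split(";") if p.strip())
        structures = frozenset(
            (sid, "this_work") for sid in r.structure_ids.split(",") if sid
        )
        out[r.sequence_id] = AnnotationRecord(
            sequence_id=r.sequence_id,
            class_label=r.class_label or None,
            taxonomy_lineage=lineage,
            reaction_evidence=frozenset(zip(types, sources)),
            structure_ids=structures,
        )
    return out


def write_truth_table(truth, path) -> None:
    rows = [
        {"sequence_id": sid, "level1_group": grp, "family": fam}
        for sid, (grp, fam) in sorted(truth.assignments.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_subgroup_table(per_sequence_level1, per_sequence_level2, clusters, path) -> None:
    """Per-sequence subgroup table: id, representative, level1, level2, singleton."""
    rep_of = {}
    rep_size = {}
    for cl in clusters:
        rep_size[cl.representative_id] = len(cl.member_ids)
        for mid in cl.member_ids:
            rep_of[mid] = cl.representative_id
    rows = []
    for sid in sorted(rep_of):
        rep = rep_of[sid]
        rows.append({
            "sequence_id": sid,
            "representative_id": rep,
            "level1": per_sequence_level1.get(sid) or "",
            "level2": per_sequence_level2.get(sid) or "",
            "singleton_flag": int(rep_size[rep] == 1),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_node_attribute_table(overlays, path, extra: dict | None = None) -> None:
    """Node attribute TSV consumable by the network writers / Cytoscape."""
    rows = []
    extra = extra or {}
    for ov in overlays:
        row = {
            "node_id": ov.node_id,
            "class": ov.class_label or "",
            "taxonomy": ov.taxonomy_category or "",
            "reaction_summary": ov.reaction_summary,
            "reaction_types": ",".join(sorted(ov.reaction_types)),
            "evidence_source": ov.evidence_source,
            "structure_flag": ov.structure_flag,
        }
        row.update(extra.get(ov.node_id, {}))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Network exports

def write_sif(net, path, relation: str = "sim") -> None:
    """SIF export: 'node1 relation node2' lines; isolated nodes on their own."""
    connected = set()
    with open(path, "w") as out:
        for u, v in sorted(net.graph.edges()):
            out.write(f"{u}\t{relation}\t{v}\n")
            connected.update((u, v))
        for node in sorted(set(net.graph.nodes) - connected):
            out.write(f"{node}\n")


def write_edge_attribute_table(net, path) -> None:
    attr = "sn_score" if net.score_kind == "sn" else "e_value"
    rows = []
    for u, v, d in sorted(net.graph.edges(data=True)):
        rows.append({
            "node_a": u, "node_b": v, attr: d[attr],
            "percent_identity": d.get("percent_identity", ""),
            "alignment_length": d.get("alignment_length", ""),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _xgmml_att(parent, name, value) -> None:
    if isinstance(value, bool):
        t, v = "boolean", str(value).lower()
    elif isinstance(value, int):
        t, v = "integer", str(value)
    elif isinstance(value, float):
        t, v = "real", repr(value)
    else:
        t, v = "string", str(value)
    ET.SubElement(parent, "att", name=name, type=t, value=v)


def write_xgmml(net, path, label: str = "ssnkit network") -> None:
    """XGMML export with node and edge attributes (Cytoscape-loadable)."""
    root = ET.Element(
        "graph",
        attrib={"label": label, "directed": "0",
                "xmlns": "http://www.cs.rpi.edu/XGMML"},
    )
    ids = {node: str(i) for i, node in enumerate(sorted(net.graph.nodes), start=1)}
    for node, nid in ids.items():
        el = ET.SubElement(root, "node", attrib={"id": nid, "label": str(node)})
        for key, value in sorted(net.graph.nodes[node].items()):
            _xgmml_att(el, key, value)
        _xgmml_att(el, "member_count", net.member_count(node))
    for u, v, d in sorted(net.graph.edges(data=True)):
        el = ET.SubElement(
            root, "edge",
            attrib={"source": ids[u], "target": ids[v], "label": f"{u} (sim) {v}"},
        )
        for key, value in sorted(d.items()):
            if key == "source_pair":
                value = f"{value[0]}|{value[1]}"
            _xgmml_att(el, key, value)
    pretty = minidom.parseString(ET.tostring(root)).toprettyxml(indent="  ")
    Path(path).write_text(pretty)


# ---------------------------------------------------------------------------
# Configuration and manifest

@dataclass
class PipelineConfig:
    """End-to-end run parameters with the pipeline's standard defaults.

    The level 2 cutoff should be stricter (numerically smaller) than level 1
    and the full-network cutoff strictest; a violation is logged as a warning
    but the run proceeds.
    """

    fasta: str = ""
    annotations: str = ""
    external_edges: str = ""       # optional tabular search output
    structure_scores: str = ""     # optional structure-score TSV
    structure_chains: str = ""     # optional chain metadata TSV
    out_dir: str = "ssnkit_out"
    min_sequence_length: int = 100
    rep_identity: float = 0.5
    struct_identity: float = 0.95
    level1_cutoff: float = 1e-13
    level2_cutoff: float = 1e-25
    full_cutoff: float = 1e-31
    min_members: int = 50
    sn_cutoff: float = 20.0
    report_ceiling: float = 10.0
    gap_open: int = 11
    gap_extend: int = 1
    matrix_name: str = "BLOSUM62"
    run_scan: bool = False
    scan_candidates: tuple = (1e-13, 1e-19, 1e-25, 1e-31, 1e-37)
    mcl_inflation: float = 2.0
    rng_seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("level1_cutoff", "level2_cutoff", "full_cutoff"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.min_members < 1:
            raise ConfigError("min_members must be >= 1")
        if not 0 < self.rep_identity <= 1 or not 0 < self.struct_identity <= 1:
            raise ConfigError("identity thresholds must be in (0, 1]")
        if self.level2_cutoff > self.level1_cutoff:
            logger.warning(
                "level 2 cutoff %.3g is looser than level 1 %.3g; proceeding",
                self.level2_cutoff, self.level1_cutoff,
            )
        if self.full_cutoff > self.level2_cutoff:
            logger.warning(
                "full-network cutoff %.3g is looser than level 2 %.3g; proceeding",
                self.full_cutoff, self.level2_cutoff,
            )


def read_config_file(path) -> PipelineConfig:
    """Plain-text 'key = value' configuration file."""
    values: dict = {}
    valid = {f.name: f for f in fields(PipelineConfig)}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.split("#", 1)[0].strip()
            if not stripped:
                continue
            if "=" not in stripped:
                raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
            key, _, raw = stripped.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in valid:
                raise ConfigError(f"{path}:{lineno}: unknown option {key!r}")
            ftype = valid[key].type
            if key == "scan_candidates":
                values[key] = tuple(float(x) for x in raw.split(",") if x)
            elif ftype == "bool":
                values[key] = raw.lower() in ("1", "true", "yes", "on")
            elif ftype == "int":
                values[key] = int(raw)
            elif ftype == "float":
                values[key] = float(raw)
            else:
                values[key] = raw
    return PipelineConfig(**values)


def write_manifest(manifest: dict, path) -> None:
    """Structured-text run manifest: stage counts, config, seed, versions."""
    lines = []

    def emit(prefix, obj):
        if isinstance(obj, dict):
            for key in obj:
                emit(f"{prefix}{key}.", obj[key]) if isinstance(obj[key], dict) \
                    else lines.append(f"{prefix}{key} = {obj[key]}")
        else:
            lines.append(f"{prefix} = {obj}")

    emit("", manifest)
    Path(path).write_text("\n".join(lines) + "\n")
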