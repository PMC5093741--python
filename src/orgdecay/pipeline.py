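"""End-to-end orchestration, reports, and content-matrix rendering.

A single YAML-style config drives the stages in dependency order
(simulate -> classify -> mipts/repeats -> coverage/scaffold); every
number in the resulting report is taken directly from the corresponding
module output, and seeds plus the config echo are recorded so any run
can be reproduced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .assembly_support import (build_link_graph, coverage_profile,
                               infer_joins, map_read_pairs)
from .content import (ContentConfig, ContentMatrix, GENE_CALLS,
                      INTRON_CALLS, score_gene)
from .pseudogene import ClassifierConfig
from .seqio import (InputError, Sequence, read_sequences, write_bedgraph,
                    write_features, write_sequences)
from .synthetic_data import (GeneratorConfig, make_organelle_pair,
                             simulate_reads)
from .transfer_repeats import (DetectionConfig, find_mipts, find_repeats,
                               genes_in_mipts, mipts_to_features,
                               quantify_segments, repeats_to_features,
                               summarize_repeats)

logger = logging.getLogger("orgdecay")

ALL_STAGES = ("simulate", "classify", "mipts", "repeats", "coverage",
              "scaffold")


class ConfigurationError(InputError):
    """Invalid pipeline configuration (CLI exit code 2)."""


@dataclass
class PipelineConfig:
    outdir: str = "orgdecay_out"
    stages: dict[str, bool] = field(default_factory=lambda: {
        "simulate": True, "classify": True, "mipts": True,
        "repeats": True, "coverage": False, "scaffold": False})
    # inputs for non-simulated runs
    mito_fasta: str | None = None
    plastid_fasta: str | None = None
    reads_fastq: str | None = None
    contigs_fasta: str | None = None
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    content: ContentConfig = field(default_factory=ContentConfig)

    def validate(self) -> None:
        for s in self.stages:
            if s not in ALL_STAGES:
                raise ConfigurationError(f"unknown stage {s!r}")
        if not self.stages.get("simulate"):
            if self.stages.get("mipts") and not (self.mito_fasta
                                                 and self.plastid_fasta):
                raise ConfigurationError(
                    "mipts stage needs mito_fasta and plastid_fasta")
            if self.stages.get("repeats") and not self.mito_fasta:
                raise ConfigurationError("repeats stage needs mito_fasta")
            if self.stages.get("classify"):
                raise ConfigurationError(
                    "classify stage needs simulated references")
            if self.stages.get("coverage") and not (
                    self.mito_fasta and self.reads_fastq):
                raise ConfigurationError(
                    "coverage stage needs mito_fasta and reads_fastq")
        if self.stages.get("scaffold") and not self.stages.get("simulate") \
                and not (self.contigs_fasta and self.reads_fastq):
            raise ConfigurationError(
                "scaffold stage needs contigs_fasta and reads_fastq")


def default_config_yaml() -> str:
    """The full default configuration as a YAML document."""
    return yaml.safe_dump(_to_plain(PipelineConfig()), sort_keys=True)


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = PipelineConfig()
    for key, value in data.items():
        if not hasattr(cfg, key):
            raise ConfigurationError(f"unknown config key {key!r}")
        current = getattr(cfg, key)
        if dataclasses.is_dataclass(current) and isinstance(value, dict):
            for k2, v2 in value.items():
                if not hasattr(current, k2):
                    raise ConfigurationError(
                        f"unknown config key {key}.{k2}")
                v0 = getattr(current, k2)
                if isinstance(v0, tuple) and isinstance(v2, list):
                    v2 = tuple(v2)
                setattr(current, k2, v2)
        else:
            setattr(cfg, key, value)
    return cfg


def _to_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, float) and obj == float("inf"):
        return "inf"
    return obj


@dataclass
class RunReport:
    """Per-stage summaries; every number equals the module output it
    echoes."""
    version: str
    seed: int
    config: dict
    stages: dict[str, dict] = field(default_factory=dict)
    timestamps: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1,
                          sort_keys=True, default=str)


def _sha1(text: str) -> str:
    return hashlib.sha1(text.encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the enabled stages in dependency order and write all
    artifacts under ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(__version__, config.generator.seed,
                       _to_plain(config))
    report.timestamps["start"] = time.strftime("%Y-%m-%dT%H:%M:%S")

    mito = plastid = None
    features = manifest = None
    if config.stages.get("simulate"):
        mito, plastid, features, manifest = make_organelle_pair(
            config.generator)
        write_sequences(outdir / "mito.fasta", [mito])
        write_sequences(outdir / "plastid.fasta", [plastid])
        write_features(outdir / "mito.gff3", features["mito"])
        write_features(outdir / "plastid.gff3", features["plastid"])
        (outdir / "truth_manifest.json").write_text(manifest.to_json())
        report.stages["simulate"] = {
            "mito_length": len(mito), "plastid_length": len(plastid),
            "planted_repeats": len(manifest.planted_repeats),
            "planted_mipts": len(manifest.planted_mipts),
            "mito_sha1": _sha1(mito.residues),
            "plastid_sha1": _sha1(plastid.residues)}
        logger.info("simulate: seed=%d mito=%s", config.generator.seed,
                    _sha1(mito.residues))
    else:
        if config.mito_fasta:
            mito = read_sequences(config.mito_fasta)[0]
        if config.plastid_fasta:
            plastid = read_sequences(config.plastid_fasta)[0]

    if config.stages.get("classify"):
        tallies = {"functional": 0, "tentative": 0, "pseudogene": 0,
                   "lost": 0}
        calls = {}
        for ref in features["mito_refs"]:
            call, _ = score_gene(mito, ref, config.content,
                                 config.classifier)
            calls[ref.name] = call
            status = {"+": "functional", "+*": "tentative",
                      "ψ": "pseudogene", "-": "lost"}[call]
            tallies[status] += 1
        (outdir / "gene_calls.json").write_text(
            json.dumps(calls, indent=1, sort_keys=True, ensure_ascii=False))
        report.stages["classify"] = tallies

    if config.stages.get("mipts"):
        mipts = find_mipts(mito, plastid, config.detection)
        plast_feats = features["plastid"] if features else []
        contained = genes_in_mipts(mipts, plast_feats, mito, plastid,
                                   config.classifier)
        stats = quantify_segments([m.mito_segment for m in mipts],
                                  len(mito))
        write_features(outdir / "mipts.gff3",
                       mipts_to_features(mipts, mito.id))
        report.stages["mipts"] = {
            "count": stats.count, "covered_bp": stats.covered_bp,
            "percent": stats.percent, "min_len": stats.min_len,
            "max_len": stats.max_len,
            "contained_genes": len(contained),
            "contained_pseudogenes": sum(
                1 for _, _, s in contained if s == "pseudogene")}

    if config.stages.get("repeats"):
        pairs = find_repeats(mito, config.detection)
        summary = summarize_repeats(pairs, len(mito), config.detection)
        write_features(outdir / "repeats.gff3",
                       repeats_to_features(pairs, mito.id))
        cov = summary["coverage"]
        report.stages["repeats"] = {
            "bin_counts": summary["bin_counts"],
            "covered_bp": cov.covered_bp, "percent": cov.percent}

    reads = None
    if config.stages.get("coverage") or config.stages.get("scaffold"):
        if config.stages.get("simulate"):
            reads, _ = simulate_reads(mito, config.generator)
            read_tuples = [(p.pair_id, p.seq1, p.seq2) for p in reads]
        else:
            recs = read_sequences(config.reads_fastq, "fastq")
            read_tuples = [(recs[i].id.rsplit("/", 1)[0],
                            recs[i].residues, recs[i + 1].residues)
                           for i in range(0, len(recs) - 1, 2)]

    if config.stages.get("coverage"):
        if config.stages.get("simulate"):
            placements = []
            for p in reads:
                placements.append(p.placement1[:2])
                placements.append(p.placement2[:2])
        else:
            maps = map_read_pairs(read_tuples, [mito])
            placements = [m.mate1.interval for m in maps if m.mate1] + \
                [m.mate2.interval for m in maps if m.mate2]
        track = coverage_profile(placements, mito)
        write_bedgraph(outdir / "coverage.bedgraph", track)
        report.stages["coverage"] = {
            "mean_depth": round(float(track.depth.mean()), 3),
            "positions": int(track.depth.size)}

    if config.stages.get("scaffold"):
        if config.stages.get("simulate"):
            # split the simulated genome into three contigs
            n = len(mito)
            cuts = [0, n // 3, 2 * n // 3, n]
            contigs = [Sequence(f"contig{i}",
                                mito.residues[cuts[i]:cuts[i + 1]])
                       for i in range(3)]
        else:
            contigs = read_sequences(config.contigs_fasta)
        maps = map_read_pairs(read_tuples[:4000], contigs)
        graph = build_link_graph(maps, contigs,
                                 insert_mean=config.generator.insert_mean)
        result = infer_joins(graph)
        lines = []
        for path in result.paths:
            lines.append("\t".join(f"{c}:{o}" for c, o in path))
        (outdir / "scaffolds.tsv").write_text("\n".join(lines) + "\n")
        report.stages["scaffold"] = {
            "n_edges": len(graph.edges),
            "n_paths": len(result.paths),
            "repeat_flags": sorted(result.repeat_flags)}

    report.timestamps["end"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (outdir / "report.json").write_text(report.to_json())
    return report


# ---------------------------------------------------------------------------
# matrix rendering

def render_matrix(matrix: ContentMatrix) -> str:
    """Render a content matrix as UTF-8 TSV: header row of element
    names, one row per taxon."""
    lines = ["taxon\t" + "\t".join(matrix.elements)]
    for t in matrix.taxa:
        lines.append(t + "\t" + "\t".join(
            matrix.cells[(t, e)] for e in matrix.elements))
    return "\n".join(lines) + "\n"


def parse_matrix(text: str) -> ContentMatrix:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise InputError("empty matrix")
    header = lines[0].split("\t")
    if header[0] != "taxon":
        raise InputError("matrix header must start with 'taxon'")
    elements = header[1:]
    taxa = []
    cells = {}
    valid = set(GENE_CALLS) | set(INTRON_CALLS)
    for ln in lines[1:]:
        parts = ln.split("\t")
        if len(parts) != len(elements) + 1:
            raise InputError(f"row {parts[0]!r} has {len(parts) - 1} cells, "
                             f"expected {len(elements)}")
        taxa.append(parts[0])
        for e, v in zip(elements, parts[1:]):
            if v not in valid:
                raise InputError(f"unknown glyph {v!r}")
            cells[(parts[0], e)] = v
    return ContentMatrix(taxa, elements, cells)
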