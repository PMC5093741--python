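"""Readers/writers for external formats and the shared coordinate model.

All internal coordinates are 0-based half-open on the forward strand;
strand is carried separately.  External formats keep their native
conventions (GFF3 and BLAST tabular are 1-based inclusive) and are
converted on the way in and out.  Features crossing the origin of a
circular sequence are represented as two explicit segments; downstream
interval algebra treats the genome as linear after :func:`rotate`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence as TSequence

import gffutils
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_RESIDUES = set("ACGTN")

TOPOLOGIES = ("circular", "linear")
COMPARTMENTS = ("mitochondrial", "plastid", "read", "contig", "other")
FEATURE_KINDS = ("gene", "CDS", "tRNA", "rRNA", "intron", "domain",
                 "repeat_region", "mipt")


class ParseError(ValueError):
    """Raised when an external file violates its format dialect."""


class InputError(ValueError):
    """Raised when a semantically invalid input reaches an operation."""


def clean_residues(raw: str, context: str = "") -> str:
    """Uppercase, map U->T, and reject ambiguity codes other than N."""
    s = raw.upper().replace("U", "T")
    bad = set(s) - VALID_RESIDUES
    if bad:
        raise ParseError(
            f"invalid residue(s) {sorted(bad)} {context}: only A,C,G,T,N "
            f"(and U, mapped to T) are accepted")
    return s


@dataclass
class Sequence:
    """A DNA sequence with topology and cellular compartment."""
    id: str
    residues: str
    topology: str = "linear"
    compartment: str = "other"

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise InputError(f"unknown topology {self.topology!r}")
        if self.compartment not in COMPARTMENTS:
            raise InputError(f"unknown compartment {self.compartment!r}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Feature:
    """An annotated element located by ordered 0-based half-open segments."""
    seq_id: str
    kind: str
    name: str
    strand: str
    segments: list[tuple[int, int]]
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise InputError(f"unknown strand {self.strand!r} for {self.name}")
        for s, e in self.segments:
            if not (0 <= s < e):
                raise InputError(
                    f"bad segment [{s}, {e}) on feature {self.name}")

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.segments)

    @property
    def span(self) -> tuple[int, int]:
        return (min(s for s, _ in self.segments),
                max(e for _, e in self.segments))


@dataclass
class AlignmentHit:
    """A local homology hit, BLAST-tabular compatible.

    Intervals are 0-based half-open on the forward strand of both query
    and subject; a minus-strand hit means the query matches the
    reverse complement of the subject interval.
    """
    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    identity: float
    aln_length: int
    score: float
    evalue: float
    mismatch: int = 0
    gapopen: int = 0

    def __post_init__(self) -> None:
        if not (self.q_start < self.q_end and self.s_start < self.s_end):
            raise InputError("hit intervals must be non-empty and ordered")
        if self.identity > 1 + 1e-9:
            raise InputError("identity is a fraction in [0,1]")
        if self.aln_length < self.q_end - self.q_start:
            raise InputError("aln_length shorter than query interval")


@dataclass
class CoverageTrack:
    """Per-position sequencing depth for one genome."""
    seq_id: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if (self.depth < 0).any():
            raise InputError("depths must be non-negative")


# ---------------------------------------------------------------------------
# FASTA / FASTQ

def read_sequences(path: str | Path, format: str = "fasta",
                   compartment: str = "other",
                   topology: str = "linear") -> list[Sequence]:
    """Read FASTA or FASTQ into :class:`Sequence` records.

    Residues are uppercased, U is mapped to T, and any ambiguity code
    other than N is rejected.
    """
    path = Path(path)
    if format not in ("fasta", "fastq"):
        raise InputError(f"unknown sequence format {format!r}")
    out: list[Sequence] = []
    seen: set[str] = set()
    try:
        records = list(SeqIO.parse(str(path), format))
    except ValueError as exc:
        raise ParseError(f"{path}: malformed {format}: {exc}") from exc
    for rec in records:
        try:
            residues = clean_residues(str(rec.seq), f"in record {rec.id!r}")
        except ParseError as exc:
            raise ParseError(f"{path}, near line "
                             f"{_locate_record_line(path, rec.id)}: {exc}")
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        out.append(Sequence(rec.id, residues, topology, compartment))
    return out


def _locate_record_line(path: Path, rec_id: str) -> int:
    marker = (">" + rec_id, "@" + rec_id)
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if line.split()[:1] and line.split()[0] in marker:
                return i
    return 0


def write_sequences(path: str | Path, seqs: Iterable[Sequence],
                    format: str = "fasta") -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="")
               for s in seqs]
    if format == "fastq":
        for r in records:
            r.letter_annotations["phred_quality"] = [40] * len(r.seq)
    SeqIO.write(records, str(path), format)


def revcomp(residues: str) -> str:
    return str(Seq(residues).reverse_complement())


# ---------------------------------------------------------------------------
# GFF3

def read_features(path: str | Path) -> list[Feature]:
    """Read a GFF3 file; multi-segment features are grouped by ID/Parent.

    GFF3 is 1-based inclusive; segments come back 0-based half-open,
    ordered 5'->3' on the feature strand.
    """
    path = Path(path)
    rows = []
    for n, f in enumerate(gffutils.DataIterator(str(path))):
        if f.end < f.start:
            raise ParseError(f"{path}: feature {f.id or n} has end < start")
        if f.strand not in ("+", "-"):
            raise ParseError(
                f"{path}: feature {f.id or n} has unknown strand "
                f"{f.strand!r}")
        rows.append(f)

    grouped: dict[str, list] = {}
    order: list[str] = []
    for n, f in enumerate(rows):
        attrs = {k: v[0] for k, v in f.attributes.items()}
        key = attrs.get("Parent") or attrs.get("ID") or f"_anon{n}"
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        grouped[key].append((f, attrs))

    out: list[Feature] = []
    for key in order:
        members = grouped[key]
        f0, attrs0 = members[0]
        segments = sorted((f.start - 1, f.end) for f, _ in members)
        if f0.strand == "-":
            segments = segments[::-1]  # 5'->3' on the feature strand
        name = attrs0.get("Name") or attrs0.get("ID") or key
        clean_attrs = {k: v for k, v in attrs0.items()
                       if k not in ("ID", "Parent", "Name")}
        out.append(Feature(f0.seqid, f0.featuretype, name, f0.strand,
                           segments, clean_attrs))
    return out


def write_features(path: str | Path, features: Iterable[Feature],
                   source: str = "orgdecay") -> None:
    """Write features as GFF3 (1-based inclusive); one row per segment."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, f in enumerate(features):
            fid = f"f{i}"
            attrs = [f"ID={fid}", f"Name={f.name}"]
            attrs += [f"{k}={v}" for k, v in sorted(f.attributes.items())]
            segs = f.segments if f.strand == "+" else f.segments[::-1]
            for s, e in segs:
                fh.write("\t".join([
                    f.seq_id, source, f.kind, str(s + 1), str(e), ".",
                    f.strand, ".", ";".join(attrs)]) + "\n")


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)

_BLAST_COLS = 12


def read_hits(path: str | Path) -> list[AlignmentHit]:
    """Read 12-column BLAST tabular (outfmt 6) hits.

    pident is stored as a fraction; coordinates become 0-based half-open;
    subject rows with sstart > send are normalized to strand "-" with an
    ordered subject interval.
    """
    path = Path(path)
    out: list[AlignmentHit] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != _BLAST_COLS:
                raise ParseError(
                    f"{path}, line {ln}: expected {_BLAST_COLS} columns, "
                    f"got {len(cols)}")
            try:
                (qid, sid, pident, length, mism, gapo,
                 qs, qe, ss, se, ev, bits) = cols
                pident, ev, bits = float(pident), float(ev), float(bits)
                length, mism, gapo = int(length), int(mism), int(gapo)
                qs, qe, ss, se = int(qs), int(qe), int(ss), int(se)
            except ValueError as exc:
                raise ParseError(f"{path}, line {ln}: {exc}") from exc
            if ss > se:
                strand, ss, se = "-", se, ss
            else:
                strand = "+"
            out.append(AlignmentHit(
                qid, sid, qs - 1, qe, ss - 1, se, strand,
                pident / 100.0, length, bits, ev, mism, gapo))
    return out


def write_hits(path: str | Path, hits: Iterable[AlignmentHit]) -> None:
    with open(path, "w") as fh:
        for h in hits:
            if h.strand == "+":
                ss, se = h.s_start + 1, h.s_end
            else:
                ss, se = h.s_end, h.s_start + 1
            fh.write("\t".join(map(str, [
                h.query_id, h.subject_id, f"{h.identity * 100:.2f}",
                h.aln_length, h.mismatch, h.gapopen,
                h.q_start + 1, h.q_end, ss, se,
                f"{h.evalue:.2e}", f"{h.score:.1f}"])) + "\n")


# ---------------------------------------------------------------------------
# bedGraph

def write_bedgraph(path: str | Path, track: CoverageTrack) -> None:
    """Export a coverage track as bedGraph (0-based half-open runs)."""
    d = track.depth
    with open(path, "w") as fh:
        if len(d) == 0:
            return
        boundaries = np.flatnonzero(np.diff(d)) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [len(d)]))
        for s, e in zip(starts, ends):
            fh.write(f"{track.seq_id}\t{s}\t{e}\t{d[s]}\n")


def read_bedgraph(path: str | Path, length: int | None = None
                  ) -> CoverageTrack:
    path = Path(path)
    rows = []
    seq_id = None
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            cols = line.split()
            if len(cols) != 4:
                raise ParseError(f"{path}, line {ln}: expected 4 columns")
            seq_id = seq_id or cols[0]
            rows.append((int(cols[1]), int(cols[2]), int(cols[3])))
    n = length if length is not None else (max(e for _, e, _ in rows)
                                           if rows else 0)
    depth = np.zeros(n, dtype=np.int64)
    for s, e, v in rows:
        depth[s:e] = v
    return CoverageTrack(seq_id or "", depth)


# ---------------------------------------------------------------------------
# Circular-genome helpers

def rotate(seq: Sequence, offset: int,
           features: TSequence[Feature] = ()) -> tuple[Sequence, list[Feature]]:
    """Rotate a circular sequence so position ``offset`` becomes 0.

    Features are remapped; a feature that crosses the new origin comes
    back as two explicit segments. After rotation the genome can be
    treated as linear by interval algebra.
    """
    if seq.topology != "circular":
        raise InputError("rotate applies to circular sequences")
    n = len(seq)
    offset %= n
    rotated = Sequence(seq.id, seq.residues[offset:] + seq.residues[:offset],
                       seq.topology, seq.compartment)
    new_feats = []
    for f in features:
        segs: list[tuple[int, int]] = []
        for s, e in f.segments:
            s2, e2 = (s - offset) % n, (e - offset) % n or n
            if s2 < e2:
                segs.append((s2, e2))
            else:  # wraps the new origin: two explicit segments
                segs.append((s2, n))
                segs.append((0, e2))
        new_feats.append(Feature(f.seq_id, f.kind, f.name, f.strand, segs,
                                 dict(f.attributes)))
    return rotated, new_feats


def to_one_based(interval: tuple[int, int]) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    s, e = interval
    return s + 1, e


def to_zero_based(interval: tuple[int, int]) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    s, e = interval
    return s - 1, e
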