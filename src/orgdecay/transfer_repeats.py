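"""Detection and quantification of plastid-derived mitogenome segments
(MIPTs) and dispersed repeats.

MIPTs are found by aligning the plastome against the mitogenome on both
strands, keeping hits above an identity floor, and merging mitogenome
intervals separated by at most a configurable gap.  Dispersed repeats
come from a self-alignment of the genome with the trivial self-match
removed and symmetric duplicates collapsed.  Detected segment boundaries
are polished by trimming alignment ends that do not open with a clean
run of matches, so chance extension into flanking sequence does not
inflate planted or biological segment lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import floor

from .homology import AlignParams, AlignmentHit, local_align
from .pseudogene import ClassifierConfig, ReferenceGene, classify_gene
from .seqio import Feature, InputError, Sequence, revcomp

SIZE_BIN_ORDER = ("small", "intermediate", "large")


@dataclass
class DetectionConfig:
    """Thresholds for MIPT and repeat detection.

    Size bins are half-open on length and partition
    [repeat_min_len, infinity).
    """
    mipt_min_len: int = 100
    mipt_min_identity: float = 0.70
    mipt_merge_gap: int = 50
    min_hit_len: int = 30  # floor on single hits entering the merge
    repeat_min_len: int = 50
    repeat_min_identity: float = 0.90
    size_bins: dict[str, tuple[int, float]] = field(default_factory=lambda: {
        "small": (50, 100),
        "intermediate": (100, 1000),
        "large": (1000, float("inf"))})
    polish_min_run: int = 11  # one clean seed-length run defines a boundary
    polish_max_trim: int = 50
    align_params: AlignParams = field(default_factory=AlignParams)

    def __post_init__(self) -> None:
        edges = sorted(self.size_bins.values())
        lo = self.repeat_min_len
        for s, e in edges:
            if s != lo:
                raise InputError("size bins must partition "
                                 f"[{self.repeat_min_len}, inf); gap at {s}")
            lo = e
        if lo != float("inf"):
            raise InputError("size bins must extend to infinity")

    def bin_of(self, length: int) -> str:
        for name, (s, e) in self.size_bins.items():
            if s <= length < e:
                return name
        raise InputError(f"length {length} below repeat_min_len")


@dataclass
class MIPT:
    """A plastid-derived segment of the mitogenome."""
    mito_segment: tuple[int, int]
    source_segments: list[tuple[int, int]]
    mean_identity: float
    contained_genes: list[tuple[str, float, str]] = field(
        default_factory=list)
    # per-hit (mito interval, plastome interval, strand) coordinate map
    alignments: list[tuple[tuple[int, int], tuple[int, int], str]] = field(
        default_factory=list)

    @property
    def length(self) -> int:
        return self.mito_segment[1] - self.mito_segment[0]


@dataclass
class RepeatPair:
    """Two dispersed copies of a repeated segment."""
    copy_a: tuple[int, int]
    copy_b: tuple[int, int]
    length: int
    identity: float
    orientation: str  # direct | inverted

    def __post_init__(self) -> None:
        if self.orientation not in ("direct", "inverted"):
            raise InputError(f"bad orientation {self.orientation!r}")
        if self.copy_a == self.copy_b:
            raise InputError("repeat copies must not coincide")
        if self.copy_a > self.copy_b:
            raise InputError("copy_a must precede copy_b in genome order")


@dataclass
class SegmentStats:
    """Count, size range and genome coverage of a set of segments."""
    count: int
    min_len: int
    max_len: int
    covered_bp: int
    percent: float


def round1_half_away(x: float) -> float:
    """Round to 1 decimal, halves away from zero (2.75 -> 2.8)."""
    sign = -1.0 if x < 0 else 1.0
    return sign * floor(abs(x) * 10 + 0.5) / 10


def merge_intervals(intervals: list[tuple[int, int]], gap: int = 0
                    ) -> list[tuple[int, int]]:
    """Union of intervals, merging pieces separated by <= gap."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1] + gap:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def quantify_segments(segments: list[tuple[int, int]], genome_length: int
                      ) -> SegmentStats:
    """Summarize segments over a genome: union coverage and size range.

    ``covered_bp`` is the size of the interval union; ``percent`` is
    rounded half-away-from-zero to one decimal; min/max are over segment
    lengths before merging.
    """
    if genome_length <= 0:
        raise InputError("genome_length must be positive")
    for s, e in segments:
        if not (0 <= s < e <= genome_length):
            raise InputError(f"segment [{s},{e}) outside genome")
    if not segments:
        return SegmentStats(0, 0, 0, 0, 0.0)
    union = merge_intervals(segments)
    covered = sum(e - s for s, e in union)
    lens = [e - s for s, e in segments]
    return SegmentStats(len(segments), min(lens), max(lens), covered,
                        round1_half_away(100.0 * covered / genome_length))


# ---------------------------------------------------------------------------
# boundary polish

def _polish_hit(hit: AlignmentHit, qseq: str, sseq: str,
                config: DetectionConfig) -> AlignmentHit | None:
    """Trim hit ends that do not open with ``polish_min_run`` clean
    matches; returns None if nothing survives."""
    r = config.polish_min_run
    a = qseq[hit.q_start:hit.q_end]
    b = sseq[hit.s_start:hit.s_end]
    if hit.strand == "-":
        b = revcomp(b)
    n = min(len(a), len(b))
    if n < r:
        return hit
    limit = min(config.polish_max_trim, n - r)

    def edge_trim(x: str, y: str) -> tuple[int, int]:
        # smallest (tx, ty) with x[tx:tx+r] == y[ty:ty+r]; small offsets
        # between tx and ty absorb indels near the segment end
        for total in range(0, 2 * limit + 1):
            for tx in range(max(0, total - limit),
                            min(limit, total) + 1):
                ty = total - tx
                if abs(tx - ty) > 8:
                    continue
                if x[tx:tx + r] == y[ty:ty + r]:
                    return tx, ty
        return -1, -1

    lqt, lst = edge_trim(a, b)
    rqt, rst = edge_trim(a[::-1], b[::-1])
    if lqt < 0 or rqt < 0 or lqt + rqt >= len(a) or lst + rst >= len(b):
        return None
    if lqt == lst == rqt == rst == 0:
        return hit
    q0, q1 = hit.q_start + lqt, hit.q_end - rqt
    if hit.strand == "+":
        s0, s1 = hit.s_start + lst, hit.s_end - rst
    else:
        s0, s1 = hit.s_start + rst, hit.s_end - lst
    trimmed_cols = max(1, hit.aln_length - lqt - rqt)
    return AlignmentHit(hit.query_id, hit.subject_id, q0, q1, s0, s1,
                        hit.strand, min(1.0, hit.identity * hit.aln_length
                                        / trimmed_cols if trimmed_cols else 0),
                        trimmed_cols, hit.score, hit.evalue,
                        hit.mismatch, hit.gapopen)


# ---------------------------------------------------------------------------
# MIPTs

def find_mipts(mitogenome: Sequence, plastome: Sequence,
               config: DetectionConfig | None = None) -> list[MIPT]:
    """Locate plastid-derived segments of the mitogenome.

    Plastome-vs-mitogenome hits (both strands) above the identity floor
    are merged along the mitogenome when separated by at most
    ``mipt_merge_gap``; merged segments shorter than ``mipt_min_len``
    are discarded.  Results are sorted by mitogenome start.
    """
    config = config or DetectionConfig()
    hits = local_align(plastome, mitogenome, config.align_params)
    kept = []
    for h in hits:
        if h.identity < config.mipt_min_identity:
            continue
        if h.aln_length < config.min_hit_len:
            continue  # chance seed matches must not chain across the gap
        h = _polish_hit(h, plastome.residues, mitogenome.residues, config)
        if h is not None:
            kept.append(h)
    # cluster hits by mitogenome interval proximity
    kept.sort(key=lambda h: h.s_start)
    clusters: list[list[AlignmentHit]] = []
    for h in kept:
        if clusters and h.s_start <= max(x.s_end for x in clusters[-1]) \
                + config.mipt_merge_gap:
            clusters[-1].append(h)
        else:
            clusters.append([h])
    mipts = []
    for cl in clusters:
        m0 = min(h.s_start for h in cl)
        m1 = max(h.s_end for h in cl)
        if m1 - m0 < config.mipt_min_len:
            continue
        total = sum(h.aln_length for h in cl)
        ident = sum(h.identity * h.aln_length for h in cl) / total
        src = merge_intervals([(h.q_start, h.q_end) for h in cl])
        alignments = [((h.s_start, h.s_end), (h.q_start, h.q_end), h.strand)
                      for h in cl]
        mipts.append(MIPT((m0, m1), src, ident, [], alignments))
    mipts.sort(key=lambda m: m.mito_segment)
    return mipts


def genes_in_mipts(mipts: list[MIPT], plastid_genes: list[Feature],
                   mitogenome: Sequence, plastome: Sequence,
                   classifier_config: ClassifierConfig | None = None,
                   nearly_full_length: float = 0.90
                   ) -> list[tuple[str, float, str]]:
    """Report plastid genes carried (nearly) full-length inside MIPTs and
    classify the functional status of their mitogenome copies.

    A gene qualifies when at least ``nearly_full_length`` of its span maps
    inside some MIPT's plastome source; its mitogenome copy is extracted
    through the MIPT coordinate map and run through the pseudogene
    classifier.
    """
    classifier_config = classifier_config or ClassifierConfig()
    all_src = merge_intervals(
        [iv for m in mipts for iv in m.source_segments])
    out = []
    for gene in plastid_genes:
        if gene.kind not in ("gene", "CDS"):
            continue
        g0, g1 = gene.span
        glen = g1 - g0
        cov = sum(max(0, min(g1, e) - max(g0, s)) for s, e in all_src)
        frac = cov / glen if glen else 0.0
        if frac < nearly_full_length:
            continue
        candidate = _extract_gene_copy(mipts, gene, mitogenome)
        if gene.strand == "-":
            candidate = revcomp(candidate)
        cds = _feature_sequence(gene, plastome)
        ref = ReferenceGene(gene.name, cds)
        call = classify_gene(candidate, ref, classifier_config)
        out.append((gene.name, round(frac, 4), call.status))
        for m in mipts:
            if any(s < g1 and g0 < e for s, e in m.source_segments):
                m.contained_genes.append((gene.name, round(frac, 4),
                                          call.status))
    return out


def _feature_sequence(feature: Feature, genome: Sequence) -> str:
    parts = [genome.residues[s:e] for s, e in sorted(feature.segments)]
    seq = "".join(parts)
    return revcomp(seq) if feature.strand == "-" else seq


def _extract_gene_copy(mipts: list[MIPT], gene: Feature,
                       mitogenome: Sequence) -> str:
    """Map a plastid gene interval through MIPT alignments into the
    mitogenome and return the copied sequence in plastome-forward
    orientation."""
    g0, g1 = gene.span
    pieces: list[tuple[int, int, int, int, int, str]] = []
    for m in mipts:
        for (ms, me), (qs, qe), strand in m.alignments:
            lo, hi = max(g0, qs), min(g1, qe)
            if lo >= hi:
                continue
            pieces.append((lo, hi, qs, ms, me, strand))
    pieces.sort()
    parts = []
    done = g0  # clip overlapping hit pieces so no source base is doubled
    for lo, hi, qs, ms, me, strand in pieces:
        lo = max(lo, done)
        if lo >= hi:
            continue
        if strand == "+":
            parts.append(mitogenome.residues[ms + (lo - qs):ms + (hi - qs)])
        else:
            parts.append(revcomp(
                mitogenome.residues[me - (hi - qs):me - (lo - qs)]))
        done = hi
    return "".join(parts)


# ---------------------------------------------------------------------------
# dispersed repeats

def find_repeats(genome: Sequence, config: DetectionConfig | None = None
                 ) -> list[RepeatPair]:
    """Find dispersed repeat pairs by genome self-alignment.

    The trivial full-length self-match is never reported; symmetric
    (a,b)/(b,a) duplicates are collapsed; pairs shorter than
    ``repeat_min_len`` or below ``repeat_min_identity`` are discarded.
    """
    config = config or DetectionConfig()
    hits = local_align(genome, genome, config.align_params,
                       exclude_self=True)
    pairs: list[RepeatPair] = []
    for h in hits:
        h = _polish_hit(h, genome.residues, genome.residues, config)
        if h is None:
            continue
        a = (h.q_start, h.q_end)
        b = (h.s_start, h.s_end)
        if a == b:
            continue
        if a > b:
            a, b = b, a
        length = min(a[1] - a[0], b[1] - b[0])
        if length < config.repeat_min_len:
            continue
        if h.identity < config.repeat_min_identity:
            continue
        orientation = "direct" if h.strand == "+" else "inverted"
        pairs.append(RepeatPair(a, b, length, h.identity, orientation))
    # collapse symmetric duplicates / re-detections of the same pair
    pairs.sort(key=lambda p: (p.copy_a, p.copy_b, -p.length))
    kept: list[RepeatPair] = []
    for p in pairs:
        dup = False
        for k in kept:
            if (p.orientation == k.orientation
                    and _iv_overlap(p.copy_a, k.copy_a) > 0.9
                    and _iv_overlap(p.copy_b, k.copy_b) > 0.9):
                dup = True
                break
        if not dup:
            kept.append(p)
    return kept


def _iv_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    ov = min(a[1], b[1]) - max(a[0], b[0])
    if ov <= 0:
        return 0.0
    return ov / max(a[1] - a[0], b[1] - b[0])


def summarize_repeats(pairs: list[RepeatPair], genome_length: int,
                      config: DetectionConfig | None = None
                      ) -> dict[str, object]:
    """Per-size-bin pair counts plus coverage of the union of all copies."""
    config = config or DetectionConfig()
    counts = {name: 0 for name in config.size_bins}
    for p in pairs:
        counts[config.bin_of(p.length)] += 1
    copies = [p.copy_a for p in pairs] + [p.copy_b for p in pairs]
    stats = (quantify_segments(copies, genome_length) if copies
             else SegmentStats(0, 0, 0, 0, 0.0))
    return {"bin_counts": counts, "coverage": stats}


# ---------------------------------------------------------------------------
# feature export

def mipts_to_features(mipts: list[MIPT], seq_id: str) -> list[Feature]:
    return [Feature(seq_id, "mipt", f"mipt{i + 1}", "+", [m.mito_segment],
                    {"mean_identity": f"{m.mean_identity:.4f}"})
            for i, m in enumerate(mipts)]


def repeats_to_features(pairs: list[RepeatPair], seq_id: str
                        ) -> list[Feature]:
    out = []
    for i, p in enumerate(pairs):
        for j, iv in enumerate((p.copy_a, p.copy_b)):
            out.append(Feature(
                seq_id, "repeat_region", f"repeat{i + 1}_copy{j + 1}", "+",
                [iv], {"orientation": p.orientation,
                       "identity": f"{p.identity:.4f}"}))
    return out
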