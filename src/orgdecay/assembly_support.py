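"""Read-pair link-graph scaffolding, repeat flagging, coverage profiling
and the best-assembly selection rule.

Mates are placed at their best filtered hit (e-value <= 1e-10, length
>= 90 bp, identity >= 90% by default, matching the scaffolding filters
used throughout); pairs spanning two contigs contribute support to an
edge between the implied contig ends.  Contigs that attract conflicting
links or carry elevated depth are flagged as repeats and break scaffold
paths.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

import numpy as np

from .homology import AlignParams, SubjectIndex, filter_hits, local_align
from .seqio import CoverageTrack, InputError, Sequence

LEFT, RIGHT = "L", "R"


@dataclass
class MateHit:
    contig_id: str
    interval: tuple[int, int]
    strand: str


@dataclass
class ReadPairMapping:
    pair_id: str
    mate1: MateHit | None
    mate2: MateHit | None
    proper: bool


@dataclass
class LinkEdge:
    end_a: tuple[str, str]  # (contig_id, LEFT|RIGHT)
    end_b: tuple[str, str]
    support: int
    gap: float  # median implied gap; negative = overlap


@dataclass
class ContigGraph:
    lengths: dict[str, int]
    depths: dict[str, float]
    edges: list[LinkEdge] = field(default_factory=list)


@dataclass
class ScaffoldResult:
    paths: list[list[tuple[str, str]]]  # (contig_id, "+" | "-")
    repeat_flags: set[str]


@dataclass
class AssemblyStats:
    assembly_id: str
    organellar_bp: int
    n_contigs: int

    def __post_init__(self) -> None:
        if self.organellar_bp < 0:
            raise InputError("organellar_bp must be >= 0")
        if self.organellar_bp > 0 and self.n_contigs < 1:
            raise InputError("n_contigs must be >= 1 when bases exist")


# ---------------------------------------------------------------------------
# mapping

def map_read_pairs(pairs: list[tuple[str, str, str]],
                   contigs: list[Sequence],
                   params: AlignParams | None = None,
                   min_evalue: float = 1e-10, min_length: int = 90,
                   min_identity: float = 0.90,
                   insert_mean: float | None = None,
                   insert_sd: float | None = None
                   ) -> list[ReadPairMapping]:
    """Place each mate of each (pair_id, seq1, seq2) at its best filtered
    hit across the contigs.

    Ties are broken by higher score, then lower contig id, then lower
    coordinate.  A pair is proper when both mates sit on one contig in
    convergent orientation (and, when an insert model is given, within
    mean +- 4 sd).
    """
    params = params or AlignParams()
    indexes = [(c, SubjectIndex(c, params.word_size)) for c in
               sorted(contigs, key=lambda c: c.id)]

    def place(seq: str, pid: str) -> MateHit | None:
        best: tuple[float, str, int] | None = None
        best_hit = None
        for contig, idx in indexes:
            hits = filter_hits(
                local_align(Sequence(pid, seq), contig, params, index=idx),
                min_evalue, min_length, min_identity)
            for h in hits:
                key = (-h.score, contig.id, h.s_start)
                if best is None or key < best:
                    best = key
                    best_hit = MateHit(contig.id, (h.s_start, h.s_end),
                                       h.strand)
        return best_hit

    out = []
    for pid, s1, s2 in pairs:
        m1 = place(s1, pid)
        m2 = place(s2, pid)
        proper = False
        if m1 and m2 and m1.contig_id == m2.contig_id:
            fwd, rev = (m1, m2) if m1.strand == "+" else (m2, m1)
            if fwd.strand == "+" and rev.strand == "-" \
                    and fwd.interval[0] <= rev.interval[1]:
                span = rev.interval[1] - fwd.interval[0]
                if insert_mean is None or insert_sd is None:
                    proper = True
                else:
                    proper = abs(span - insert_mean) <= 4 * insert_sd
        out.append(ReadPairMapping(pid, m1, m2, proper))
    return out


# ---------------------------------------------------------------------------
# link graph

def _linked_end(mate: MateHit, contig_len: int) -> tuple[str, int]:
    """The contig end a mate points toward, and its overhang (distance
    from the mate to that end, including the mate)."""
    if mate.strand == "+":
        return RIGHT, contig_len - mate.interval[0]
    return LEFT, mate.interval[1]


def build_link_graph(mappings: list[ReadPairMapping],
                     contigs: list[Sequence],
                     min_support: int = 2,
                     insert_mean: float = 800.0,
                     depths: dict[str, float] | None = None) -> ContigGraph:
    """Turn cross-contig read pairs into a contig-end link graph.

    Each pair with mates on different contigs supports the edge joining
    the two ends the mates point toward; the implied gap is the insert
    size minus both overhangs (median over supporting pairs).  Edges with
    support below ``min_support`` are dropped.
    """
    lengths = {c.id: len(c) for c in contigs}
    support: dict[tuple, list[float]] = {}
    for m in mappings:
        if not (m.mate1 and m.mate2):
            continue
        if m.mate1.contig_id == m.mate2.contig_id:
            continue
        e1, o1 = _linked_end(m.mate1, lengths[m.mate1.contig_id])
        e2, o2 = _linked_end(m.mate2, lengths[m.mate2.contig_id])
        key_a = (m.mate1.contig_id, e1)
        key_b = (m.mate2.contig_id, e2)
        if key_b < key_a:
            key_a, key_b = key_b, key_a
        support.setdefault((key_a, key_b), []).append(
            insert_mean - o1 - o2)
    edges = [LinkEdge(a, b, len(gaps), statistics.median(gaps))
             for (a, b), gaps in sorted(support.items())
             if len(gaps) >= min_support]
    return ContigGraph(lengths, depths or {c.id: 0.0 for c in contigs},
                       edges)


def infer_joins(graph: ContigGraph,
                depth_repeat_factor: float = 1.5) -> ScaffoldResult:
    """Join contig ends with exactly one passing edge into scaffold paths.

    A contig is flagged as a repeat if one of its ends links to two or
    more distinct partners, or if its mean depth is at least
    ``depth_repeat_factor`` times the median contig depth.  Flagged
    contigs break paths; output paths are maximal simple chains in a
    deterministic order.
    """
    partners: dict[tuple[str, str], set[tuple[str, str]]] = {}
    for e in graph.edges:
        partners.setdefault(e.end_a, set()).add(e.end_b)
        partners.setdefault(e.end_b, set()).add(e.end_a)
    flagged = {end[0] for end, p in partners.items()
               if len({q[0] for q in p}) >= 2}
    depths = [d for d in graph.depths.values() if d > 0]
    if depths:
        med = statistics.median(depths)
        if med > 0:
            flagged |= {c for c, d in graph.depths.items()
                        if d >= depth_repeat_factor * med}

    # usable joins: both ends have exactly one edge, neither contig flagged
    joins: dict[tuple[str, str], tuple[str, str]] = {}
    for e in graph.edges:
        if e.end_a[0] in flagged or e.end_b[0] in flagged:
            continue
        if len(partners[e.end_a]) == 1 and len(partners[e.end_b]) == 1:
            joins[e.end_a] = e.end_b
            joins[e.end_b] = e.end_a

    paths: list[list[tuple[str, str]]] = []
    visited: set[str] = set()
    for contig in sorted(graph.lengths):
        if contig in visited or contig in flagged:
            continue
        # walk left as far as possible, then emit rightward
        cur, entry = contig, LEFT
        while (cur, entry) in joins:
            other = joins[(cur, entry)]
            nxt = other[0]
            if nxt in visited or nxt == contig:  # circular guard
                break
            cur, entry = nxt, _other_end(other[1])
            if cur == contig:
                break
        path = []
        start = cur
        while True:
            visited.add(cur)
            path.append((cur, "+" if entry == LEFT else "-"))
            exit_end = _other_end(entry)
            nxt = joins.get((cur, exit_end))
            if nxt is None or nxt[0] in visited or nxt[0] == start:
                break
            cur, entry = nxt[0], nxt[1]
        paths.append(path)
    # canonical direction: first contig id <= last contig id
    for i, p in enumerate(paths):
        if p[0][0] > p[-1][0]:
            paths[i] = [(c, "+" if o == "-" else "-") for c, o in
                        reversed(p)]
    paths.sort(key=lambda p: p[0][0])
    return ScaffoldResult(paths, flagged)


def _other_end(end: str) -> str:
    return RIGHT if end == LEFT else LEFT


# ---------------------------------------------------------------------------
# coverage

def coverage_profile(placements: list[tuple[int, int]],
                     genome: Sequence) -> CoverageTrack:
    """Per-position count of covering reads.

    Placement intervals may run past the genome end to indicate wrapping
    on a circular genome.
    """
    n = len(genome)
    depth = np.zeros(n, dtype=np.int64)
    for s, e in placements:
        if s >= n and genome.topology == "circular":
            k = s // n  # wrapped placement from a circular fragment
            s -= k * n
            e -= k * n
        if s < 0 or s >= n or e <= s:
            raise InputError(f"placement [{s},{e}) out of bounds")
        if e <= n:
            depth[s:e] += 1
        elif genome.topology == "circular":
            depth[s:] += 1
            depth[:e - n] += 1
        else:
            raise InputError(f"placement [{s},{e}) beyond linear genome")
    return CoverageTrack(genome.id, depth)


def depth_ratio(track: CoverageTrack, region: tuple[int, int],
                background: list[tuple[int, int]]) -> float:
    """Mean depth over a region divided by mean depth over background
    intervals."""
    n = len(track.depth)
    s, e = region
    if not (0 <= s < e <= n) or not background:
        raise InputError("regions must be non-empty and within bounds")
    bg_vals = np.concatenate([track.depth[bs:be] for bs, be in background])
    if bg_vals.size == 0 or bg_vals.mean() == 0:
        raise InputError("background depth is zero")
    return float(track.depth[s:e].mean() / bg_vals.mean())


def select_best_assembly(stats: list[AssemblyStats]) -> str:
    """Pick the assembly maximizing organellar length, breaking ties by
    fewest contigs, then by assembly id."""
    if not stats:
        raise InputError("no assemblies to choose from")
    best = min(stats, key=lambda a: (-a.organellar_bp, a.n_contigs,
                                     a.assembly_id))
    return best.assembly_id
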