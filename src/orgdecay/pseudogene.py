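"""Loss-of-function detection and pseudogene classification.

A candidate gene copy is aligned semi-globally to a functional reference
CDS; disruptions (frameshifting indels, premature stop codons,
truncations) are read off the alignment and converted into a disrupted
fraction of the reference, overall and restricted to conserved-domain
segments.  A gene is scored as a pseudogene when mutations disrupt more
than 20% of its conserved domain structure or more than 30% of the gene
overall; a copy truncated by 20-30% with no other qualifying damage is
tentatively scored as present.

"Disrupted" is positional: reference positions that are truncated away,
out of frame between a frameshift and its compensating frameshift (or
the gene end), or downstream of the first premature stop reached in
frame.  Stops encountered while the reading frame is shifted are not
called separately - the frameshift interval already covers them; this is
what lets a compensated frameshift pair disrupt only the span between
the two indels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .homology import AlignParams, global_align
from .seqio import InputError

logger = logging.getLogger("orgdecay")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"

DISRUPTION_KINDS = ("frameshift", "premature_stop", "truncation5",
                    "truncation3", "internal_deletion")


@dataclass
class ReferenceGene:
    """A functional reference CDS with optional conserved-domain segments.

    ``domains`` are nucleotide intervals (0-based half-open) on the CDS.
    """
    name: str
    cds: str
    domains: list[tuple[int, int]] = field(default_factory=list)

    def validate(self) -> None:
        L = len(self.cds)
        if L == 0 or L % 3 != 0:
            raise InputError(f"{self.name}: CDS length must be a positive "
                             "multiple of 3")
        if self.cds[:3] != START_CODON:
            raise InputError(f"{self.name}: CDS must start with ATG")
        if self.cds[-3:] not in STOP_CODONS:
            raise InputError(f"{self.name}: CDS must end with a stop codon")
        for c in range(0, L - 3, 3):
            if self.cds[c:c + 3] in STOP_CODONS:
                raise InputError(f"{self.name}: internal stop at nt {c}")
        for s, e in self.domains:
            if not (0 <= s < e <= L):
                raise InputError(f"{self.name}: domain [{s},{e}) out of CDS")


@dataclass
class Disruption:
    """One loss-of-function mutation located on the reference CDS."""
    kind: str
    ref_start: int
    ref_end: int
    indel_len: int = 0  # signed: insertion > 0, deletion < 0 (frameshift)
    in_homopolymer: bool = False
    homopolymer_len: int = 0

    def __post_init__(self) -> None:
        if self.kind not in DISRUPTION_KINDS:
            raise InputError(f"unknown disruption kind {self.kind!r}")
        if self.kind == "frameshift" and self.indel_len % 3 == 0:
            raise InputError("a frameshift indel length cannot be a "
                             "multiple of 3")


@dataclass
class ClassifierConfig:
    """Thresholds for functional-status classification."""
    domain_threshold: float = 0.20
    overall_threshold: float = 0.30
    tentative_band: tuple[float, float] = (0.20, 0.30)
    nearly_full_length: float = 0.90
    homopolymer_min_run: int = 4
    artifact_support_fraction: float = 0.80
    min_covering_reads: int = 3
    genetic_code: str = "standard"
    align_params: AlignParams = field(default_factory=AlignParams)

    def __post_init__(self) -> None:
        if not (0 < self.domain_threshold < self.overall_threshold < 1):
            raise InputError("need 0 < domain_threshold < overall_threshold "
                             "< 1")
        if self.genetic_code != "standard":
            raise InputError("only the standard genetic code is supported")


@dataclass
class PseudogeneCall:
    """Functional status of one gene copy with its disruption evidence."""
    gene: str
    status: str  # functional | tentative | pseudogene
    disruptions: list[Disruption]
    domain_disrupted_fraction: float
    overall_disrupted_fraction: float
    truncated_fraction: float


def _homopolymer_run(seq: str, pos: int, base: str) -> int:
    """Length of the maximal run of ``base`` in ``seq`` touching ``pos``."""
    n = len(seq)
    if n == 0:
        return 0
    pos = min(max(pos, 0), n - 1)
    # allow the run to sit just left of an insertion point
    if seq[pos] != base and pos > 0 and seq[pos - 1] == base:
        pos -= 1
    if seq[pos] != base:
        return 0
    i = pos
    while i > 0 and seq[i - 1] == base:
        i -= 1
    j = pos
    while j + 1 < n and seq[j + 1] == base:
        j += 1
    return j - i + 1


def detect_disruptions(candidate: str, reference: ReferenceGene,
                       config: ClassifierConfig | None = None
                       ) -> list[Disruption]:
    """Align a candidate copy to its reference CDS and list disruptions.

    Returns frameshifts (indels of length not divisible by 3), premature
    stop codons read in the reference frame (phase 0 only), 5'/3'
    truncations (unaligned reference ends) and in-frame internal
    deletions, each located in reference nucleotide coordinates.
    """
    config = config or ClassifierConfig()
    reference.validate()
    if not candidate:
        return [Disruption("truncation5", 0, len(reference.cds))]
    aln = global_align(reference.cds, candidate, config.align_params,
                       ref_id=reference.name, qry_id="candidate")
    L = len(reference.cds)
    cols = aln.columns
    disruptions: list[Disruption] = []

    # terminal reference overhangs = truncations
    lead = 0
    while lead < len(cols) and cols[lead][1] is None:
        lead += 1
    trail = 0
    while trail < len(cols) - lead and cols[-1 - trail][1] is None:
        trail += 1
    if lead:
        disruptions.append(Disruption("truncation5", 0, cols[lead - 1][0] + 1))
    if trail:
        disruptions.append(
            Disruption("truncation3", cols[len(cols) - trail][0], L))

    # interior gap runs
    body = cols[lead:len(cols) - trail]
    i = 0
    ref_to_qry: dict[int, int | None] = {}
    first_ref = next((r for r, _ in body if r is not None), 0)
    last_ref = (first_ref or 0) - 1
    while i < len(body):
        r, q = body[i]
        if r is not None and q is not None:
            ref_to_qry[r] = q
            last_ref = r
            i += 1
            continue
        j = i
        while j < len(body) and (body[j][0] is None or body[j][1] is None):
            # a gap run may mix sides only notionally; runs are one-sided
            if (body[j][0] is None) != (body[i][0] is None):
                break
            j += 1
        run = body[i:j]
        if run[0][0] is None:  # insertion in candidate
            ilen = len(run)
            pos = last_ref + 1
            if ilen % 3 != 0:
                base = candidate[run[0][1]]
                hlen = _homopolymer_run(reference.cds, pos, base)
                disruptions.append(Disruption(
                    "frameshift", pos, pos, ilen,
                    hlen >= config.homopolymer_min_run, hlen))
        else:  # deletion from candidate
            dlen = len(run)
            pos = run[0][0]
            for r2, _ in run:
                ref_to_qry[r2] = None
            last_ref = run[-1][0]
            if dlen % 3 != 0:
                base = reference.cds[pos]
                hlen = _homopolymer_run(reference.cds, pos, base)
                disruptions.append(Disruption(
                    "frameshift", pos, pos + dlen, -dlen,
                    hlen >= config.homopolymer_min_run, hlen))
            else:
                disruptions.append(
                    Disruption("internal_deletion", pos, pos + dlen))
        i = j

    # premature stops, read in the reference frame at phase 0 only
    frameshifts = sorted((d for d in disruptions if d.kind == "frameshift"),
                         key=lambda d: d.ref_start)
    phase_changes = [(d.ref_start, d.indel_len) for d in frameshifts]

    def phase_at(ref_pos: int) -> int:
        p = 0
        for pos, ilen in phase_changes:
            if pos <= ref_pos:
                p = (p + ilen) % 3
        return p

    n_codons = L // 3
    for c in range(n_codons - 1):  # exclude the terminal stop codon
        p0 = 3 * c
        if phase_at(p0) != 0:
            continue
        bases = [ref_to_qry.get(p0 + k) for k in range(3)]
        if any(b is None for b in bases):
            continue
        codon = "".join(candidate[b] for b in bases)
        if codon in STOP_CODONS:
            disruptions.append(
                Disruption("premature_stop", p0, p0 + 3))
    disruptions.sort(key=lambda d: (d.ref_start, d.kind))
    return disruptions


def disruption_fractions(disruptions: list[Disruption], ref_length_nt: int,
                         domain_segments: list[tuple[int, int]] | None = None
                         ) -> tuple[float, float, float]:
    """Convert disruptions to (domain, overall, truncated) fractions.

    Disrupted positions are the union of truncated reference positions,
    out-of-frame intervals between uncompensated frameshifts, and
    positions downstream of the first in-frame premature stop.
    """
    L = ref_length_nt
    domain_segments = domain_segments or []
    disrupted = [False] * L
    truncated = [False] * L

    for d in disruptions:
        if d.kind in ("truncation5", "truncation3"):
            for p in range(d.ref_start, d.ref_end):
                truncated[p] = True
                disrupted[p] = True

    # frameshift intervals: from the first unrestored frameshift to the
    # next compensating one (cumulative phase back to 0) or the gene end
    fss = sorted((d for d in disruptions if d.kind == "frameshift"),
                 key=lambda d: d.ref_start)
    phase = 0
    open_start: int | None = None
    for d in fss:
        new_phase = (phase + d.indel_len) % 3
        if phase == 0 and new_phase != 0:
            open_start = d.ref_start
        elif phase != 0 and new_phase == 0 and open_start is not None:
            for p in range(open_start, min(d.ref_start, L)):
                disrupted[p] = True
            open_start = None
        phase = new_phase
    if open_start is not None:
        for p in range(open_start, L):
            disrupted[p] = True

    stops = sorted((d for d in disruptions if d.kind == "premature_stop"),
                   key=lambda d: d.ref_start)
    if stops:
        for p in range(stops[0].ref_end, L):
            disrupted[p] = True

    overall = sum(disrupted) / L if L else 0.0
    trunc = sum(truncated) / L if L else 0.0
    dom_len = sum(e - s for s, e in domain_segments)
    if dom_len:
        dom_hit = sum(1 for s, e in domain_segments
                      for p in range(s, e) if disrupted[p])
        domain = dom_hit / dom_len
    else:
        domain = 0.0
    return domain, overall, trunc


def homopolymer_artifact_check(disruption: Disruption,
                               read_support: tuple[int, int] | None,
                               config: ClassifierConfig | None = None) -> str:
    """Decide whether a frameshift is a sequencing artifact.

    Frameshifts inside a mononucleotide run of at least
    ``homopolymer_min_run`` bases, covered by at least
    ``min_covering_reads`` reads of which fewer than
    ``artifact_support_fraction`` carry the indel, are artifacts
    (pyrosequencing-style homopolymer errors).  Everything else is
    supported.
    """
    config = config or ClassifierConfig()
    if disruption.kind != "frameshift":
        raise InputError("artifact check applies to frameshifts only")
    if (not disruption.in_homopolymer
            or disruption.homopolymer_len < config.homopolymer_min_run):
        return "supported"
    if read_support is None:
        logger.warning(
            "frameshift at %d lies in a %d-nt homopolymer but no read "
            "support was provided; keeping it",
            disruption.ref_start, disruption.homopolymer_len)
        return "supported"
    covering, with_indel = read_support
    if (covering >= config.min_covering_reads
            and with_indel / covering < config.artifact_support_fraction):
        return "artifact"
    return "supported"


def classify_gene(candidate: str, reference: ReferenceGene,
                  config: ClassifierConfig | None = None,
                  read_support: dict[int, tuple[int, int]] | None = None
                  ) -> PseudogeneCall:
    """Classify a candidate gene copy as functional, tentative or
    pseudogene.

    ``read_support`` optionally maps a frameshift's reference position to
    (covering_reads, reads_with_indel); frameshifts judged to be
    homopolymer sequencing artifacts are dropped before the fractions
    are computed.
    """
    config = config or ClassifierConfig()
    disruptions = detect_disruptions(candidate, reference, config)
    kept = []
    for d in disruptions:
        if d.kind == "frameshift":
            support = (read_support or {}).get(d.ref_start)
            if homopolymer_artifact_check(d, support, config) == "artifact":
                continue
        kept.append(d)
    # artifact removal can re-frame downstream stops; recompute stops from
    # surviving frameshifts only when the set changed
    if len(kept) != len(disruptions):
        kept = [d for d in kept if d.kind != "premature_stop"]
        shifts = [(d.ref_start, d.indel_len) for d in kept
                  if d.kind == "frameshift"]
        for d in disruptions:
            if d.kind != "premature_stop":
                continue
            p = 0
            for pos, ilen in sorted(shifts):
                if pos <= d.ref_start:
                    p = (p + ilen) % 3
            if p == 0:
                kept.append(d)
        kept.sort(key=lambda d: (d.ref_start, d.kind))
    domain, overall, trunc = disruption_fractions(
        kept, len(reference.cds), reference.domains)
    if (domain > config.domain_threshold
            or overall > config.overall_threshold):
        status = "pseudogene"
    elif config.tentative_band[0] <= trunc <= config.tentative_band[1]:
        status = "tentative"
    else:
        status = "functional"
    return PseudogeneCall(reference.name, status, kept, domain, overall,
                          trunc)
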