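"""Gene and intron presence scoring across taxa and the content matrix.

Each cell of the matrix holds one glyph: "+" present, "+*" tentatively
present (truncated by 20-30%), "ψ" pseudogene, "-" lost, "x" intron
missing because its host gene is lost, "ψr" intron remnant retained in a
host pseudogene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .homology import AlignParams, SubjectIndex, filter_hits, local_align
from .pseudogene import ClassifierConfig, PseudogeneCall, ReferenceGene, \
    classify_gene
from .seqio import Feature, InputError, Sequence, revcomp

logger = logging.getLogger("orgdecay")

PRESENT = "+"
TENTATIVE = "+*"
PSEUDO = "ψ"        # psi
LOST = "-"
HOST_LOST = "x"
REMNANT = "ψr"      # psi-r

GENE_CALLS = (PRESENT, TENTATIVE, PSEUDO, LOST)
INTRON_CALLS = (PRESENT, LOST, HOST_LOST, REMNANT)
GENE_CATEGORIES = ("core", "ribosomal", "sdh", "other")

_STATUS_TO_CALL = {"functional": PRESENT, "tentative": TENTATIVE,
                   "pseudogene": PSEUDO}


@dataclass(frozen=True)
class GeneEntry:
    name: str
    category: str = "other"
    complex_label: str = ""

    def __post_init__(self) -> None:
        if self.category not in GENE_CATEGORIES:
            raise InputError(f"unknown gene category {self.category!r}")


@dataclass(frozen=True)
class IntronEntry:
    host: str
    ordinal: int
    splicing: str = "cis"

    def __post_init__(self) -> None:
        if self.splicing not in ("cis", "trans"):
            raise InputError(f"unknown splicing {self.splicing!r}")

    @property
    def name(self) -> str:
        return f"{self.host}-i{self.ordinal}"


@dataclass
class ElementRegistry:
    """Ordered gene and intron element lists scored in every taxon."""
    genes: list[GeneEntry]
    introns: list[IntronEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        gene_names = {g.name for g in self.genes}
        for i in self.introns:
            if i.host not in gene_names:
                raise InputError(f"intron {i.name} host not in gene list")

    @property
    def element_names(self) -> list[str]:
        return [g.name for g in self.genes] + [i.name for i in self.introns]


@dataclass
class ContentConfig:
    """Detection thresholds for presence scoring.

    Hit filters are looser than the read-mapping filters because gene
    queries come from related species and pseudogenes decay; a gene with
    no filtered hit covering at least ``detection_min_fraction`` of the
    reference is scored lost.
    """
    detection_min_fraction: float = 0.30
    hit_min_evalue: float = 1e-10
    hit_min_length: int = 30
    hit_min_identity: float = 0.70
    flank_anchor_len: int = 20
    min_intron_gap: int = 50
    short_gene_warning: int = 300


@dataclass
class IntronRef:
    """Reference description of one intron: host, exon flank anchors and
    (optionally) the intron sequence itself."""
    host: str
    ordinal: int
    splicing: str
    left_flank: str = ""
    right_flank: str = ""
    intron_seq: str = ""

    @property
    def name(self) -> str:
        return f"{self.host}-i{self.ordinal}"


@dataclass
class ContentMatrix:
    """taxa x elements table of content calls (genes first, then introns)."""
    taxa: list[str]
    elements: list[str]
    cells: dict[tuple[str, str], str]

    def __post_init__(self) -> None:
        for t in self.taxa:
            for e in self.elements:
                if (t, e) not in self.cells:
                    raise InputError(f"cell ({t}, {e}) not populated")

    def check_host_invariant(self, registry: ElementRegistry) -> None:
        """A lost gene forces 'x' on all of its introns."""
        for t in self.taxa:
            for i in registry.introns:
                if i.name not in self.elements:
                    continue
                if (self.cells[(t, i.host)] == LOST
                        and self.cells[(t, i.name)] != HOST_LOST):
                    raise InputError(
                        f"{t}: host {i.host} lost but intron {i.name} is "
                        f"{self.cells[(t, i.name)]!r}, not {HOST_LOST!r}")


@dataclass
class AnnotationSummary:
    """Per-category gene and intron counts for one annotated genome."""
    protein_coding: int
    rRNA: int
    tRNA: int
    cis_introns: int = 0
    trans_introns: int = 0

    @property
    def total_genes(self) -> int:
        return self.protein_coding + self.rRNA + self.tRNA

    @property
    def total_introns(self) -> int:
        return self.cis_introns + self.trans_introns


def summarize_annotation(features: list[Feature]) -> AnnotationSummary:
    """Count annotated genes by category and introns by splicing mode."""
    pc = sum(1 for f in features if f.kind == "gene")
    rr = sum(1 for f in features if f.kind == "rRNA")
    tr = sum(1 for f in features if f.kind == "tRNA")
    cis = sum(1 for f in features if f.kind == "intron"
              and f.attributes.get("splicing", "cis") == "cis")
    trans = sum(1 for f in features if f.kind == "intron"
                and f.attributes.get("splicing") == "trans")
    return AnnotationSummary(pc, rr, tr, cis, trans)


# ---------------------------------------------------------------------------
# scoring

def score_gene(genome: Sequence, ref_gene: ReferenceGene,
               config: ContentConfig | None = None,
               classifier_config: ClassifierConfig | None = None,
               hits=None, index: SubjectIndex | None = None
               ) -> tuple[str, PseudogeneCall | None]:
    """Score one gene in one genome.

    Returns (call, classifier call or None).  Precomputed hits (e.g. from
    real blastn) may be passed instead of running the internal aligner.
    """
    config = config or ContentConfig()
    classifier_config = classifier_config or ClassifierConfig()
    L = len(ref_gene.cds)
    if L < config.short_gene_warning:
        logger.warning("reference gene %s is short (%d bp); absence calls "
                       "are low-confidence", ref_gene.name, L)
    if hits is None:
        query = Sequence(ref_gene.name, ref_gene.cds)
        hits = local_align(query, genome,
                           classifier_config.align_params, index=index)
    hits = filter_hits(hits, config.hit_min_evalue, config.hit_min_length,
                       config.hit_min_identity)
    covered = [False] * L
    for h in hits:
        for p in range(max(0, h.q_start), min(L, h.q_end)):
            covered[p] = True
    if sum(covered) / L < config.detection_min_fraction:
        return LOST, None
    candidate = _extract_candidate(genome, hits, L)
    call = classify_gene(candidate, ref_gene, classifier_config)
    return _STATUS_TO_CALL[call.status], call


def _extract_candidate(genome: Sequence, hits, ref_len: int) -> str:
    """Pull the genomic region implied by the best hit chain, oriented
    to the reference strand."""
    best = max(hits, key=lambda h: h.score)
    strand = best.strand
    window = 2 * ref_len
    group = [h for h in hits if h.strand == strand
             and h.s_start >= best.s_start - window
             and h.s_end <= best.s_end + window]
    s0 = min(h.s_start for h in group)
    s1 = max(h.s_end for h in group)
    seq = genome.residues[s0:s1]
    return revcomp(seq) if strand == "-" else seq


def score_intron(gene_call: str, genome: Sequence, intron_ref: IntronRef,
                 config: ContentConfig | None = None,
                 classifier_config: ClassifierConfig | None = None) -> str:
    """Score one intron given its host gene's call.

    A lost host forces "x".  Cis introns are detected by anchoring exact
    exon-flank matches and checking that they are separated by intervening
    sequence; trans introns (whose exons sit at separate loci) are
    detected by homology to the intron sequence itself.  An intron
    detected inside a host pseudogene is a remnant ("ψr").
    """
    config = config or ContentConfig()
    if gene_call == LOST:
        return HOST_LOST
    detected = _detect_intron(genome, intron_ref, config, classifier_config)
    if gene_call == PSEUDO:
        return REMNANT if detected else LOST
    return PRESENT if detected else LOST


def _detect_intron(genome: Sequence, ref: IntronRef, config: ContentConfig,
                   classifier_config: ClassifierConfig | None = None) -> bool:
    if ref.splicing == "trans" or not (ref.left_flank and ref.right_flank):
        if not ref.intron_seq:
            raise InputError(f"intron {ref.name}: trans detection needs "
                             "an intron sequence")
        return _sequence_detected(genome, ref.intron_seq, config,
                                  classifier_config)
    a = ref.left_flank[-config.flank_anchor_len:]
    b = ref.right_flank[:config.flank_anchor_len]
    for residues in (genome.residues, revcomp(genome.residues)):
        i = residues.find(a)
        while i >= 0:
            j = residues.find(b, i + len(a))
            if j >= 0 and j - (i + len(a)) >= config.min_intron_gap:
                inner = residues[i + len(a):j]
                if not ref.intron_seq:
                    return True
                if _sequence_detected(
                        Sequence("inner", inner), ref.intron_seq, config,
                        classifier_config):
                    return True
            i = residues.find(a, i + 1)
    return False


def _sequence_detected(genome: Sequence, query_seq: str,
                       config: ContentConfig,
                       classifier_config: ClassifierConfig | None) -> bool:
    params = (classifier_config or ClassifierConfig()).align_params
    if len(genome) < params.word_size or len(query_seq) < params.word_size:
        return False
    hits = local_align(Sequence("q", query_seq), genome, params)
    hits = filter_hits(hits, config.hit_min_evalue, config.hit_min_length,
                       config.hit_min_identity)
    L = len(query_seq)
    covered = [False] * L
    for h in hits:
        for p in range(h.q_start, min(L, h.q_end)):
            covered[p] = True
    return sum(covered) / L >= config.detection_min_fraction


def build_matrix(taxa: list[tuple[str, Sequence]],
                 registry: ElementRegistry,
                 gene_refs: dict[str, ReferenceGene],
                 intron_refs: dict[str, IntronRef] | None = None,
                 config: ContentConfig | None = None,
                 classifier_config: ClassifierConfig | None = None
                 ) -> ContentMatrix:
    """Score every registry element in every taxon.

    Row order follows the input taxon order; column order follows the
    registry (genes then introns).
    """
    config = config or ContentConfig()
    classifier_config = classifier_config or ClassifierConfig()
    intron_refs = intron_refs or {}
    names = [t for t, _ in taxa]
    if len(set(names)) != len(names):
        raise InputError("duplicate taxon ids")
    missing = [g.name for g in registry.genes if g.name not in gene_refs]
    if missing:
        raise InputError(f"no reference for genes: {missing}")
    cells: dict[tuple[str, str], str] = {}
    for taxon, genome in taxa:
        index = SubjectIndex(genome, classifier_config.align_params.word_size)
        gene_calls: dict[str, str] = {}
        for g in registry.genes:
            call, _ = score_gene(genome, gene_refs[g.name], config,
                                 classifier_config, index=index)
            gene_calls[g.name] = call
            cells[(taxon, g.name)] = call
        for i in registry.introns:
            iref = intron_refs.get(i.name)
            if iref is None:
                raise InputError(f"no reference for intron {i.name}")
            cells[(taxon, i.name)] = score_intron(
                gene_calls[i.host], genome, iref, config, classifier_config)
    matrix = ContentMatrix(names, registry.element_names, cells)
    matrix.check_host_invariant(registry)
    return matrix


def shared_counts(matrix: ContentMatrix, registry: ElementRegistry
                  ) -> dict[str, int]:
    """Count elements present (or tentatively present) in every taxon.

    Returns shared_genes, shared_core_genes and shared cis/trans intron
    counts; invariant under taxon order.
    """
    def shared(element: str) -> bool:
        # an empty panel shares nothing (not vacuously everything)
        return bool(matrix.taxa) and all(
            matrix.cells[(t, element)] in (PRESENT, TENTATIVE)
            for t in matrix.taxa)

    genes = [g for g in registry.genes if g.name in matrix.elements]
    introns = [i for i in registry.introns if i.name in matrix.elements]
    shared_genes = sum(1 for g in genes if shared(g.name))
    shared_core = sum(1 for g in genes
                      if g.category == "core" and shared(g.name))
    cis = sum(1 for i in introns if i.splicing == "cis" and shared(i.name))
    trans = sum(1 for i in introns
                if i.splicing == "trans" and shared(i.name))
    return {"shared_genes": shared_genes,
            "shared_core_genes": shared_core,
            "cis_introns_shared": cis,
            "trans_introns_shared": trans}
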