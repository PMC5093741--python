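"""Synthetic organelle-genome generator with full ground truth.

Generates a mitogenome/plastome pair with planted dispersed repeats,
plastid-derived insertions (MIPTs, with optional identity decay and
secondary pseudogenization), gene copies carrying known disruptions, and
paired reads - everything recorded in a :class:`TruthManifest` so each
detector can be tested by parameter recovery without touching real data.

Planted segments are maximal by construction: the generator decouples
the flanking bases of every copy from its source context, so the true
extent of a planted repeat or MIPT is exactly the planted interval.  A
screening pass removes chance shared words between the two genomes
outside planted transfers.  Background sequence is i.i.d. uniform over
{A,C,G,T}; GC skew and realistic mutation spectra are not modeled.

``paper_fixture`` returns small objects encoding printed comparative
results (conserved gene sets, the content-matrix calls, the ndh
pseudogene panel, annotation totals) for worked-example tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from types import SimpleNamespace

import numpy as np

from .content import (AnnotationSummary, ContentMatrix, ElementRegistry,
                      GeneEntry, IntronEntry, HOST_LOST, LOST, PRESENT,
                      PSEUDO, REMNANT, TENTATIVE)
from .pseudogene import (ClassifierConfig, ReferenceGene, STOP_CODONS,
                         disruption_fractions, Disruption)
from .seqio import Feature, InputError, Sequence, revcomp

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

_SAFE_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                if a + b + c not in STOP_CODONS and a + b + c != "ATG"]


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic genomes and reads.

    Read geometry follows the sequencing design the pipeline targets:
    100-bp paired-end reads from an 800-bp insert library at ~50x depth.
    Genome lengths are desk-scale (100 kb mitogenome / 30 kb plastome)
    while keeping realistic feature densities.
    """
    seed: int = 0
    mito_length: int = 100_000
    plastid_length: int = 30_000
    n_mito_genes: int = 8
    n_plastid_genes: int = 6
    gene_codon_range: tuple[int, int] = (120, 320)
    domain_fraction: float = 0.40
    # planted dispersed repeats: per-size-class counts and length ranges
    repeat_counts: dict[str, int] = field(default_factory=lambda: {
        "small": 4, "intermediate": 3, "large": 1})
    repeat_length_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"small": (50, 100),
                                 "intermediate": (100, 448),
                                 "large": (1000, 9000)})
    inverted_fraction: float = 0.25
    # plastid-to-mitochondrion transfers
    mipt_count: int = 5
    mipt_length_range: tuple[int, int] = (150, 2500)
    mipt_identity: float = 0.95
    mipt_cover_genes: int = 2  # first k MIPTs carry a full plastid gene
    mipt_secondary_disruption: bool = False
    # native-gene disruption plan: gene index -> (kind, target fraction)
    pseudogene_plan: dict[int, tuple[str, float]] = field(
        default_factory=lambda: {0: ("frameshift", 0.40),
                                 1: ("premature_stop", 0.50),
                                 2: ("truncation3", 0.25)})
    # reads
    read_length: int = 100
    insert_mean: float = 800.0
    insert_sd: float = 50.0
    depth: float = 50.0
    error_model: str = "none"  # none|uniform_substitution|homopolymer_indel
    error_rate: float = 0.0
    # cross-genome shared-word screen
    clean_word: int = 16
    feature_separation: int = 120

    def __post_init__(self) -> None:
        if self.error_model not in ("none", "uniform_substitution",
                                    "homopolymer_indel"):
            raise InputError(f"unknown error model {self.error_model!r}")


@dataclass
class TruthManifest:
    """Ground truth for everything the generator planted."""
    planted_repeats: list[dict] = field(default_factory=list)
    planted_mipts: list[dict] = field(default_factory=list)
    planted_pseudogenes: list[dict] = field(default_factory=list)
    coverage_targets: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        return cls(**json.loads(text))


@dataclass
class ReadPair:
    pair_id: str
    seq1: str
    seq2: str
    # placements on the source genome; end may run past the genome end
    # to indicate origin wrap on a circular genome
    placement1: tuple[int, int, str]
    placement2: tuple[int, int, str]


# ---------------------------------------------------------------------------
# reference genes

def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    body = "".join(rng.choice(_SAFE_CODONS) for _ in range(n_codons - 2))
    stop = ("TAA", "TAG", "TGA")[rng.integers(0, 3)]
    return "ATG" + body + stop


def make_reference_geneset(config: GeneratorConfig,
                           n: int | None = None, prefix: str = "g",
                           rng: np.random.Generator | None = None
                           ) -> list[ReferenceGene]:
    """Generate functional reference CDSs with one conserved-domain
    segment each (a ``domain_fraction`` slice placed uniformly)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = n if n is not None else config.n_mito_genes
    lo, hi = config.gene_codon_range
    if lo < 3 or hi < lo:
        raise InputError("infeasible gene codon range")
    genes = []
    for i in range(n):
        ncod = int(rng.integers(lo, hi + 1))
        cds = _random_cds(ncod, rng)
        L = len(cds)
        dlen = max(3, int(round(config.domain_fraction * L)))
        dstart = int(rng.integers(0, L - dlen + 1))
        gene = ReferenceGene(f"{prefix}{i + 1:02d}", cds,
                             [(dstart, dstart + dlen)])
        gene.validate()
        genes.append(gene)
    return genes


# ---------------------------------------------------------------------------
# disruption planting

def plant_disruption(ref: ReferenceGene, kind: str, target: float,
                     rng: np.random.Generator
                     ) -> tuple[str, float, float, float]:
    """Create a candidate copy of ``ref`` carrying one disruption whose
    disrupted extent is analytically known.

    Returns (candidate, domain_fraction, overall_fraction,
    truncated_fraction) with the planted fractions computed from the
    positional disruption model.
    """
    L = len(ref.cds)
    if kind == "frameshift":
        # 1-nt deletion at p disrupts [p, L); avoid homopolymer runs
        p = int(round((1.0 - target) * L))
        p = min(max(p, 3), L - 4)
        while p > 3 and _run_at(ref.cds, p) >= 4:
            p -= 1
        candidate = ref.cds[:p] + ref.cds[p + 1:]
        planted = [Disruption("frameshift", p, p + 1, -1)]
    elif kind == "premature_stop":
        # stop at codon c disrupts [3c+3, L)
        c = int(round(((1.0 - target) * L - 3) / 3))
        c = min(max(c, 1), L // 3 - 2)
        candidate = ref.cds[:3 * c] + "TAA" + ref.cds[3 * c + 3:]
        planted = [Disruption("premature_stop", 3 * c, 3 * c + 3)]
    elif kind == "truncation3":
        cut = int(round((1.0 - target) * L))
        cut = min(max(cut, 3), L - 3)
        candidate = ref.cds[:cut]
        planted = [Disruption("truncation3", cut, L)]
    elif kind == "truncation5":
        cut = int(round(target * L))
        cut = min(max(cut, 3), L - 3)
        candidate = ref.cds[cut:]
        planted = [Disruption("truncation5", 0, cut)]
    else:
        raise InputError(f"unknown planted disruption kind {kind!r}")
    dom, overall, trunc = disruption_fractions(planted, L, ref.domains)
    return candidate, dom, overall, trunc


def expected_status(domain_frac: float, overall_frac: float,
                    truncated_frac: float,
                    config: ClassifierConfig | None = None) -> str:
    """Status implied by planted fractions under the threshold rules."""
    config = config or ClassifierConfig()
    if (domain_frac > config.domain_threshold
            or overall_frac > config.overall_threshold):
        return "pseudogene"
    if config.tentative_band[0] <= truncated_frac <= config.tentative_band[1]:
        return "tentative"
    return "functional"


def _run_at(seq: str, pos: int) -> int:
    base = seq[pos]
    i = pos
    while i > 0 and seq[i - 1] == base:
        i -= 1
    j = pos
    while j + 1 < len(seq) and seq[j + 1] == base:
        j += 1
    return j - i + 1


# ---------------------------------------------------------------------------
# placement

class _Placer:
    """Non-overlapping slot allocator keeping a separation buffer."""

    def __init__(self, length: int, rng: np.random.Generator,
                 separation: int, margin: int = 300):
        self.free: list[tuple[int, int]] = [(margin, length - margin)]
        self.rng = rng
        self.sep = separation

    def place(self, size: int) -> int:
        fits = [i for i, (s, e) in enumerate(self.free) if e - s >= size]
        if not fits:
            raise InputError("genome too small to host planted features")
        caps = np.array([self.free[i][1] - self.free[i][0] - size + 1
                         for i in fits], dtype=float)
        pick = fits[int(self.rng.choice(len(fits), p=caps / caps.sum()))]
        s, e = self.free.pop(pick)
        off = int(self.rng.integers(s, e - size + 1))
        if off - self.sep - s > 0:
            self.free.append((s, off - self.sep))
        if e - (off + size + self.sep) > 0:
            self.free.append((off + size + self.sep, e))
        self.free.sort()
        return off


def _decay(seq: str, identity: float, rng: np.random.Generator) -> str:
    """i.i.d. substitutions at rate (1 - identity)."""
    if identity >= 1.0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < (1.0 - identity)
    for i in np.flatnonzero(hit):
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(0, 3))]
    return "".join(arr)


def _decouple_flank(genome: list[str], pos: int, forbidden: str,
                    rng: np.random.Generator) -> None:
    if 0 <= pos < len(genome) and genome[pos] == forbidden:
        choices = [b for b in "ACGT" if b != forbidden]
        genome[pos] = choices[int(rng.integers(0, 3))]


# ---------------------------------------------------------------------------
# genome pair

def make_organelle_pair(config: GeneratorConfig
                        ) -> tuple[Sequence, Sequence,
                                   dict[str, list[Feature]], TruthManifest]:
    """Generate a (mitogenome, plastome) pair with planted repeats,
    MIPTs and gene disruptions, plus annotations and the truth manifest.

    Returns (mito, plastome, features, manifest) where ``features`` maps
    "mito"/"plastid" to annotation lists, and also carries the reference
    genesets under "mito_refs"/"plastid_refs".
    """
    rng = np.random.default_rng(config.seed)
    manifest = TruthManifest()

    plast_refs = make_reference_geneset(config, config.n_plastid_genes,
                                        "pt", rng)
    mito_refs = make_reference_geneset(config, config.n_mito_genes,
                                       "mt", rng)

    plast = list(rng.choice(_BASES, config.plastid_length))
    mito = list(rng.choice(_BASES, config.mito_length))
    p_placer = _Placer(config.plastid_length, rng, config.feature_separation)
    m_placer = _Placer(config.mito_length, rng, config.feature_separation)
    plast_feats: list[Feature] = []
    mito_feats: list[Feature] = []

    # intact plastid genes
    gene_locs: dict[str, tuple[int, int, str]] = {}
    for g in plast_refs:
        strand = "+" if rng.random() < 0.5 else "-"
        seq = g.cds if strand == "+" else revcomp(g.cds)
        off = p_placer.place(len(seq))
        plast[off:off + len(seq)] = list(seq)
        gene_locs[g.name] = (off, off + len(seq), strand)
        plast_feats.append(Feature("plastid", "gene", g.name, strand,
                                   [(off, off + len(seq))]))

    # native mitochondrial genes, some with planted disruptions
    for i, g in enumerate(mito_refs):
        plan = config.pseudogene_plan.get(i)
        if plan is not None:
            kind, target = plan
            candidate, dom, overall, trunc = plant_disruption(
                g, kind, target, rng)
            manifest.planted_pseudogenes.append({
                "gene": g.name, "kind": kind,
                "domain_fraction": round(dom, 4),
                "overall_fraction": round(overall, 4),
                "truncated_fraction": round(trunc, 4),
                "expected_status": expected_status(dom, overall, trunc)})
        else:
            candidate = g.cds
            manifest.planted_pseudogenes.append({
                "gene": g.name, "kind": "none", "domain_fraction": 0.0,
                "overall_fraction": 0.0, "truncated_fraction": 0.0,
                "expected_status": "functional"})
        strand = "+" if rng.random() < 0.5 else "-"
        seq = candidate if strand == "+" else revcomp(candidate)
        off = m_placer.place(len(seq))
        mito[off:off + len(seq)] = list(seq)
        mito_feats.append(Feature("mito", "gene", g.name, strand,
                                  [(off, off + len(seq))]))

    # MIPT insertions copied from the plastome; source windows must not
    # overlap each other or two inserts would share sequence and surface
    # as an unplanted mitogenome repeat
    covered_genes = list(plast_refs[:config.mipt_cover_genes])
    used_sources: list[tuple[int, int]] = []
    for k in range(config.mipt_count):
        s0 = s1 = -1
        for _try in range(200):
            if k < len(covered_genes) and config.mipt_cover_genes:
                g0, g1, _ = gene_locs[covered_genes[k].name]
                pad = int(rng.integers(40, 200))
                c0 = max(0, g0 - pad)
                c1 = min(config.plastid_length, g1 + pad)
            else:
                lo, hi = config.mipt_length_range
                size = int(rng.integers(lo, hi + 1))
                c0 = int(rng.integers(0, config.plastid_length - size))
                c1 = c0 + size
            if all(c0 >= e + 30 or c1 <= s - 30 for s, e in used_sources):
                s0, s1 = c0, c1
                break
        if s0 < 0:
            raise InputError("plastome too small for non-overlapping "
                             "MIPT source windows")
        used_sources.append((s0, s1))
        source = "".join(plast[s0:s1])
        copy = _decay(source, config.mipt_identity, rng)
        secondary = []
        if config.mipt_secondary_disruption:
            # one frameshifting deletion mid-copy
            p = len(copy) // 2
            copy = copy[:p] + copy[p + 1:]
            secondary.append({"kind": "frameshift", "offset": p})
        strand = "+" if rng.random() < 0.5 else "-"
        planted = copy if strand == "+" else revcomp(copy)
        d0 = m_placer.place(len(planted))
        d1 = d0 + len(planted)
        mito[d0:d1] = list(planted)
        # decouple copy flanks from the source context
        if strand == "+":
            if s0 > 0:
                _decouple_flank(mito, d0 - 1, plast[s0 - 1], rng)
            if s1 < config.plastid_length:
                _decouple_flank(mito, d1, plast[s1], rng)
        else:
            if s1 < config.plastid_length:
                _decouple_flank(mito, d0 - 1, _COMP[plast[s1]], rng)
            if s0 > 0:
                _decouple_flank(mito, d1, _COMP[plast[s0 - 1]], rng)
        mito_feats.append(Feature("mito", "mipt", f"mipt{k + 1}", strand,
                                  [(d0, d1)]))
        manifest.planted_mipts.append({
            "mito_interval": [d0, d1], "source_interval": [int(s0), int(s1)],
            "strand": strand, "identity": config.mipt_identity,
            "secondary_disruptions": secondary})

    # dispersed repeats: copy mitogenome background elsewhere
    ridx = 0
    for cls in ("large", "intermediate", "small"):
        for _ in range(config.repeat_counts.get(cls, 0)):
            lo, hi = config.repeat_length_ranges[cls]
            size = int(rng.integers(lo, min(hi, config.mito_length // 4)))
            a0 = m_placer.place(size)
            a1 = a0 + size
            inverted = rng.random() < config.inverted_fraction
            src = "".join(mito[a0:a1])
            planted = revcomp(src) if inverted else src
            b0 = m_placer.place(size)
            b1 = b0 + size
            mito[b0:b1] = list(planted)
            if inverted:
                _decouple_flank(mito, b0 - 1, _COMP[mito[a1]], rng)
                _decouple_flank(mito, b1, _COMP[mito[a0 - 1]], rng)
            else:
                _decouple_flank(mito, b0 - 1, mito[a0 - 1], rng)
                _decouple_flank(mito, b1, mito[a1], rng)
            ca, cb = sorted([(a0, a1), (b0, b1)])
            manifest.planted_repeats.append({
                "copy_a": list(ca), "copy_b": list(cb), "length": size,
                "orientation": "inverted" if inverted else "direct",
                "copy_number": 2})
            ridx += 1
            mito_feats.append(Feature("mito", "repeat_region",
                                      f"rep{ridx}a", "+", [ca]))
            mito_feats.append(Feature("mito", "repeat_region",
                                      f"rep{ridx}b", "+", [cb]))

    _screen_shared_words(mito, plast, manifest, config, rng)

    mito_seq = Sequence("mito", "".join(mito), "circular", "mitochondrial")
    plast_seq = Sequence("plastid", "".join(plast), "circular", "plastid")
    features = {"mito": mito_feats, "plastid": plast_feats,
                "mito_refs": mito_refs, "plastid_refs": plast_refs}
    manifest.coverage_targets["genome"] = config.depth
    return mito_seq, plast_seq, features, manifest


def _screen_shared_words(mito: list[str], plast: list[str],
                         manifest: TruthManifest, config: GeneratorConfig,
                         rng: np.random.Generator) -> None:
    """Remove chance shared words between the genomes outside planted
    transfers by resampling a base in a modifiable copy."""
    k = config.clean_word
    mipt_dest = [tuple(m["mito_interval"]) for m in manifest.planted_mipts]
    protected_m = mipt_dest + [tuple(r["copy_a"]) for r in
                               manifest.planted_repeats] + \
        [tuple(r["copy_b"]) for r in manifest.planted_repeats]

    def in_ivs(pos: int, ivs) -> bool:
        return any(s - k < pos < e for s, e in ivs)

    for _ in range(60):
        plast_words: dict[str, int] = {}
        pstr = "".join(plast)
        rc = revcomp(pstr)
        for i in range(len(pstr) - k + 1):
            plast_words[pstr[i:i + k]] = i
            plast_words[rc[i:i + k]] = len(pstr) - i - k
        mstr = "".join(mito)
        offenders = []
        for i in range(len(mstr) - k + 1):
            w = mstr[i:i + k]
            if "N" in w or w not in plast_words:
                continue
            if in_ivs(i, mipt_dest):
                continue
            offenders.append(i)
        if not offenders:
            return
        for i in offenders:
            pos = i + k // 2
            if not in_ivs(i, protected_m):
                mito[pos] = str(rng.choice(_BASES))
    raise InputError("could not decontaminate shared words; genomes too "
                     "small for the requested features")


# ---------------------------------------------------------------------------
# reads

def simulate_reads(genome: Sequence, config: GeneratorConfig,
                   seed_offset: int = 1
                   ) -> tuple[list[ReadPair], list[dict]]:
    """Simulate paired reads at the configured depth.

    Fragment starts are uniform over the (circularized) genome; pair
    count is depth * genome_length / (2 * read_length).  The
    ``homopolymer_indel`` error model plants 1-bp indels only inside
    mononucleotide runs of >= 4 bases, mimicking pyrosequencing errors;
    ``uniform_substitution`` applies i.i.d. base errors.  Returns the
    pairs and a log of applied errors.
    """
    rng = np.random.default_rng(config.seed + seed_offset)
    G = len(genome)
    rl = config.read_length
    if rl >= G:
        raise InputError("read length must be below genome length")
    n_pairs = int(round(config.depth * G / (2 * rl)))
    doubled = genome.residues + genome.residues
    pairs: list[ReadPair] = []
    errors: list[dict] = []
    circular = genome.topology == "circular"
    for i in range(n_pairs):
        frag = int(round(rng.normal(config.insert_mean, config.insert_sd)))
        frag = max(2 * rl, min(frag, G - 1))
        if circular:
            start = int(rng.integers(0, G))
        else:
            start = int(rng.integers(0, G - frag + 1))
        r1 = doubled[start:start + rl]
        r2 = revcomp(doubled[start + frag - rl:start + frag])
        pid = f"pair{i:07d}"
        r1 = _apply_errors(r1, config, rng, errors, pid, 1)
        r2 = _apply_errors(r2, config, rng, errors, pid, 2)
        pairs.append(ReadPair(
            pid, r1, r2,
            (start, start + rl, "+"),
            (start + frag - rl, start + frag, "-")))
    return pairs, errors


def _apply_errors(read: str, config: GeneratorConfig,
                  rng: np.random.Generator, errors: list[dict],
                  pid: str, mate: int) -> str:
    if config.error_model == "none" or config.error_rate <= 0:
        return read
    if config.error_model == "uniform_substitution":
        arr = list(read)
        for p in np.flatnonzero(rng.random(len(arr)) < config.error_rate):
            choices = [b for b in "ACGT" if b != arr[p]]
            arr[int(p)] = choices[int(rng.integers(0, 3))]
        return "".join(arr)
    # homopolymer_indel: 1-bp indels inside mononucleotide runs >= 4
    runs = []
    i = 0
    while i < len(read):
        j = i
        while j < len(read) and read[j] == read[i]:
            j += 1
        if j - i >= 4:
            runs.append((i, j))
        i = j
    out = read
    shift = 0
    for s, e in runs:
        if rng.random() >= config.error_rate:
            continue
        pos = s + shift + int(rng.integers(0, e - s))
        if rng.random() < 0.5:
            out = out[:pos] + read[s] + out[pos:]
            shift += 1
            errors.append({"pair": pid, "mate": mate, "kind": "ins",
                           "base": read[s], "run_len": e - s})
        else:
            out = out[:pos] + out[pos + 1:]
            shift -= 1
            errors.append({"pair": pid, "mate": mate, "kind": "del",
                           "base": read[s], "run_len": e - s})
    return out


# ---------------------------------------------------------------------------
# encoded in-paper fixtures

CORE_GENES = ("nad1 nad2 nad3 nad4 nad4L nad5 nad6 nad7 nad9 cob "
              "cox1 cox2 cox3 atp1 atp4 atp6 atp8 atp9 "
              "ccmB ccmC ccmFc ccmFn matR mttB").split()

CONSERVED_RIBOSOMAL = "rpl10 rpl16 rps3 rps4 rps12 rps14".split()

CONSERVED_GENES = [g for g in CORE_GENES if g != "atp9"] + \
    CONSERVED_RIBOSOMAL  # the 29 genes shared by all seven taxa

VARIABLE_RIBOSOMAL = "rpl2 rps1 rps7 rps10 rps13".split()
SDH_GENES = "sdh3 sdh4".split()

FIG2_GENES = ("atp1 atp4 atp6 atp8 ccmB ccmC ccmFc ccmFn cob cox1 cox2 "
              "cox3 matR mttB nad1 nad2 nad3 nad4 nad4L nad5 nad6 nad7 "
              "nad9 rpl10 rpl16 rps3 rps4 rps12").split()

CIS_INTRONS = [("ccmFc", 1), ("nad1", 2), ("nad2", 1), ("nad2", 3),
               ("nad2", 4), ("nad4", 1), ("nad4", 2), ("nad4", 3),
               ("nad5", 1), ("nad5", 4), ("nad7", 1), ("nad7", 2),
               ("nad7", 4), ("rps3", 1)]

TRANS_INTRONS = [("nad1", 1), ("nad1", 3), ("nad1", 4), ("nad2", 2),
                 ("nad5", 2), ("nad5", 3)]

TAXA = "Cpa Bpe Ocr Ogr Pra Sam Lph".split()

NDH_GENES = "ndhA ndhB ndhC ndhD ndhE ndhF ndhG ndhH ndhI ndhJ ndhK".split()
NDH_FRAMESHIFT = ("ndhD", "ndhF")
NDH_PREMATURE_STOP = ("ndhH", "ndhJ")


def _category(gene: str) -> str:
    if gene in CORE_GENES:
        return "core"
    if gene in SDH_GENES:
        return "sdh"
    return "ribosomal"


def _fig2_registry() -> ElementRegistry:
    genes = [GeneEntry(g, _category(g)) for g in FIG2_GENES]
    introns = [IntronEntry(h, o, "cis") for h, o in CIS_INTRONS] + \
              [IntronEntry(h, o, "trans") for h, o in TRANS_INTRONS]
    return ElementRegistry(genes, introns)


def _orobanchaceae_matrix() -> SimpleNamespace:
    genes = [GeneEntry(g, _category(g)) for g in
             CORE_GENES + CONSERVED_RIBOSOMAL + VARIABLE_RIBOSOMAL
             + SDH_GENES]
    introns = ([IntronEntry(h, o, "cis") for h, o in CIS_INTRONS]
               + [IntronEntry(h, o, "trans") for h, o in TRANS_INTRONS]
               + [IntronEntry("cox2", 2, "cis"),
                  IntronEntry("rps10", 1, "cis")])
    registry = ElementRegistry(genes, introns)
    cells = {(t, e): PRESENT for t in TAXA
             for e in registry.element_names}
    cells[("Lph", "atp9")] = LOST
    for taxon, gene in [("Ogr", "rps7"), ("Ocr", "rps13"),
                        ("Pra", "rps13"), ("Cpa", "sdh3"),
                        ("Lph", "sdh3")]:
        cells[(taxon, gene)] = TENTATIVE
    for taxon, gene in [("Ocr", "rps1"), ("Ogr", "rps10"),
                        ("Ogr", "rps13"), ("Pra", "rpl2"),
                        ("Pra", "rps1"), ("Sam", "rps7"),
                        ("Ocr", "rps10"), ("Ocr", "sdh4"),
                        ("Ogr", "sdh4"), ("Sam", "sdh3")]:
        cells[(taxon, gene)] = PSEUDO
    cells[("Bpe", "cox2-i2")] = LOST
    cells[("Ocr", "rps10-i1")] = REMNANT
    cells[("Ogr", "rps10-i1")] = REMNANT
    matrix = ContentMatrix(list(TAXA), registry.element_names, cells)
    matrix.check_host_invariant(registry)
    return SimpleNamespace(matrix=matrix, registry=registry)


def _ndh_plastome() -> dict[str, tuple[ReferenceGene, str]]:
    """Synthetic 11-gene ndh panel: frameshifting indels in ndhD/ndhF and
    premature stop codons in ndhH/ndhJ, placed to exceed the classifier
    thresholds; the other seven genes are intact."""
    cfg = GeneratorConfig(seed=36285, gene_codon_range=(150, 400),
                          domain_fraction=0.5)
    rng = np.random.default_rng(cfg.seed)
    refs = make_reference_geneset(cfg, len(NDH_GENES), "ndh", rng)
    panel = {}
    for name, ref in zip(NDH_GENES, refs):
        ref.name = name
        if name in NDH_FRAMESHIFT:
            cand, *_ = plant_disruption(ref, "frameshift", 0.45, rng)
        elif name in NDH_PREMATURE_STOP:
            cand, *_ = plant_disruption(ref, "premature_stop", 0.45, rng)
        else:
            cand = ref.cds
        panel[name] = (ref, cand)
    return panel


def _cpa_annotation_summary() -> SimpleNamespace:
    return SimpleNamespace(
        summary=AnnotationSummary(protein_coding=34, rRNA=3, tRNA=30,
                                  cis_introns=17, trans_introns=6),
        genome_length=495_499,
        mipt_count=43,
        mipt_covered_bp=82_133,
        mipt_size_range=(116, 7_700),
        repeat_covered_bp=13_525,
        repeat_counts={"large": 1, "intermediate": 15, "small": 32},
        large_repeat_len=8_700,
        plastome_length=152_926)


def paper_fixture(name: str):
    """Return an encoded worked-example fixture by name.

    Names: conserved_genes, core_genes, fig2_registry,
    orobanchaceae_matrix, ndh_plastome, cpa_annotation_summary.
    """
    fixtures = {
        "conserved_genes": lambda: list(CONSERVED_GENES),
        "core_genes": lambda: list(CORE_GENES),
        "fig2_registry": _fig2_registry,
        "orobanchaceae_matrix": _orobanchaceae_matrix,
        "ndh_plastome": _ndh_plastome,
        "cpa_annotation_summary": _cpa_annotation_summary,
    }
    if name not in fixtures:
        raise InputError(f"unknown fixture {name!r}")
    return fixtures[name]()
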