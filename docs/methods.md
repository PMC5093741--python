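# Methods

This note records the models, parameter choices and numerical
conventions behind orgdecay, and what the synthetic benchmarks do and
do not demonstrate about real data.

## Coordinate model

All internal coordinates are 0-based half-open on the forward strand;
strand is carried separately.  GFF3 and BLAST tabular keep their native
1-based inclusive convention at the file boundary and are converted on
read/write (the conversion is an involution, tested as such).  Features
crossing the origin of a circular genome are represented as two
explicit segments; `rotate()` re-origins a circular genome so interval
algebra can treat it as linear.  Ambiguity codes other than N are
rejected because alignment scoring is defined over {A,C,G,T,N}.

## Local alignment (the blastn stand-in)

Seed-and-extend with exact `word_size` seeds on both strands, ungapped
x-drop extension along the seed diagonal, and a banded affine-gap
(Gotoh) refinement around the extended segment.  Defaults mirror
default blastn: match +2, mismatch −3, gap open −5, gap extend −2,
word 11, x-drop 20; a gap of length *L* costs `open + L·extend`; N is
scored as a mismatch (conservative identity).  Externally computed
blastn hits in 12-column tabular form can replace the internal aligner
anywhere — the pipeline treats hit provenance as opaque.

E-values use the ungapped Karlin–Altschul form
`E = K·m·n·exp(−λS)` with λ = 1.33, K = 0.621 and effective space
|query| × db_length.  These constants give the stated thresholds a
defined scale; they are not calibrated against any particular BLAST
build (the underlying search's exact program version and mode are a
knob, not something the package guesses), and the length/identity
filters dominate every decision downstream.  A practical consequence:
very short exact matches look "significant" on this scale, which is why
the MIPT detector applies a 30-bp per-hit floor before merging (below).

Correctness anchors: the top hit score equals an independently written
full Smith–Waterman on random 40-bp pairs whenever the pair shares an
exact seed (the test conditions on seed existence — no seed-based
heuristic can find an optimum it cannot seed), and the semi-global
aligner equals an exhaustive memoized recursion on all strings ≤ 12 nt.

## Pseudogene classification

The candidate is aligned semi-globally to the reference CDS with free
end gaps on the candidate side, so truncations surface as unaligned
reference ends rather than gap penalties.  Disruption calls:

* **frameshift** — alignment gap of length ≢ 0 (mod 3), positioned at
  the first reference position of the gap; annotated with the length of
  the mononucleotide run containing it (the run is measured on the
  reference, or on the inserted base for insertions).
* **premature stop** — the candidate is translated in the reference
  codon frame, tracking phase changes at frameshifts; stops are called
  only at phase 0.  Stops inside an out-of-frame interval are not
  separate events: the frameshift's disrupted interval already covers
  them.  This is what makes a compensated frameshift pair disrupt only
  the span between the two indels (e.g. codons 10→20 of a 100-codon
  gene ⇒ overall fraction 0.10), rather than everything downstream.
* **truncation5/3** — unaligned reference ends.
* **internal deletion** — in-frame deletions are recorded as evidence
  but contribute no disrupted positions (the remaining protein is
  shorter, not frameshifted).

"Disrupted" is positional: the thresholds (> 20% of the conserved
domain, > 30% overall, strict inequalities; tentative band [0.20, 0.30]
inclusive on the truncated fraction) are applied to the union of
truncated, out-of-frame and post-stop reference positions.  The measure
itself is a design choice — the simplest positional definition that
reproduces the worked pseudogene calls — and is documented as such
rather than presented as the only possible reading.

One deliberate non-theorem: classification is *not* monotone under
arbitrary added frameshifts, because a frame-restoring frameshift
legitimately shrinks the out-of-frame interval.  Monotonicity holds
(and is tested) for the non-compensating family: stops, truncations,
and frameshifts that open a new out-of-frame interval.

The homopolymer artifact rule (run ≥ 4 nt, ≥ 3 covering reads, indel
support < 80%) uses conventional pyrosequencing-error heuristics; the
run-length and support cutoffs are exposed in `ClassifierConfig`.
C-to-U RNA editing is not modeled; a genuine edited stop would be
miscalled, which matters for mitochondrial genes on real data but not
for the synthetic benchmarks.  Both organelles use the standard genetic
code.

## Content matrix

A gene is scored lost when no filtered hit covers ≥ 30% of the
reference (`detection_min_fraction`); otherwise the implied genomic
region is extracted and classified.  Gene-presence hit filters
(e-value ≤ 1e−10, length ≥ 30 bp, identity ≥ 70%) are looser than the
read-mapping filters because queries come from related species and
pseudogenes decay.  References shorter than 300 bp trigger a warning:
absence calls on very short genes (the atp9 problem) are
low-confidence.  Cis-spliced introns are detected by anchoring ≥ 20-bp
exact exon-flank matches separated by ≥ 50 bp of intervening sequence;
trans-spliced introns, whose exons sit at separate loci, are detected
by homology to the intron sequence itself.  A lost host gene forces `x`
on its introns (asserted on every matrix); an intron detected inside a
host pseudogene is a remnant (`ψr`).

## MIPTs and repeats

MIPT detection keeps plastome→mitogenome hits with identity ≥ 0.70
(transfers decay over time) and single-hit length ≥ 30 bp, merges
mitogenome intervals separated by ≤ 50 bp, and discards merged segments
< 100 bp.  The per-hit floor exists because chance word-size seed
matches occur every ~70 bp between unrelated sequences of these sizes
and would otherwise chain across the merge gap.  Repeats come from a
self-alignment with the trivial self-diagonal excluded, symmetric
duplicates collapsed, and floors of 50 bp / 90% identity; size bins are
small [50,100), intermediate [100,1000), large [1000,∞), consistent
with the observed repeat census they summarize.  Coverage percents are
rounded half-away-from-zero to one decimal.

Detected boundaries are *polished*: each end is trimmed to the
outermost clean run of 11 consecutive matches (one seed length), with
small offsets absorbing indels near the end.  Without this, optimal
local alignments absorb lucky flanking bases (a net-positive excursion
past the true boundary) a few percent of the time per boundary, which
would break exact recovery; with it, boundaries on exact copies are
exact with overwhelming probability, at the cost of up to a few tens of
bp of boundary slack on heavily decayed segments (where no exactness is
claimed).  A gene is reported as MIPT cargo when ≥ 90% of its span maps
inside MIPT source intervals; its mitogenome copy is extracted through
the per-hit coordinate map (overlapping hit pieces clipped so no source
base is doubled) and classified.

## Scaffolding and coverage

Mates map to their best hit passing e-value ≤ 1e−10, length ≥ 90 bp,
identity ≥ 90%, with deterministic tie-breaks (score, then contig id,
then coordinate).  Cross-contig pairs support an edge between the two
contig ends the mates point toward; implied gap = insert − both
overhangs, median over pairs.  Edges need ≥ 2 supporting pairs
(`min_support`; no published value exists for this, so it is exposed).
Ends with exactly one passing edge are joined; a contig is flagged as a
repeat when an end links ≥ 2 distinct partners or its depth is ≥ 1.5×
the median (margin below the 2× signal of a true two-copy repeat to
tolerate sampling noise), and flagged contigs break paths.  The
best-assembly rule is read lexicographically: maximal organellar bp,
then fewest contigs, then id — the sentence it implements is ambiguous
and this reading is recorded here.  Insert-size statistics are used
only for gap estimates and properness, never for discarding hits.

## Synthetic data: what it emulates and what it does not

The generator emulates the sequencing design the pipeline targets:
100-bp paired-end reads from an 800-bp insert library at ~50×, with an
optional homopolymer-indel error mode (1-bp indels only inside
mononucleotide runs ≥ 4) mimicking pyrosequencing, and a uniform
substitution mode.  Default genome sizes are desk-scale — 100-kb
circular mitogenome, 30-kb plastome — with realistic feature densities:
8 native genes (three carrying planted disruptions: an uncompensated
frameshift at 40% extent, a premature stop at 50%, a 25% truncation),
5 MIPTs of 150–2500 bp (two carrying a full plastid gene), and a repeat
census of 4 small + 3 intermediate + 1 large per run.  Planted
disruption extents are analytically known, so expected statuses follow
from the threshold rules without running the classifier.

Two constructions make *exact* recovery well-defined:

1. **Planted copies are maximal.**  The flanking bases of every copy
   are decoupled from the source context, so the true extent of a
   planted repeat/MIPT is exactly the planted interval and boundary
   equality can be asserted.
2. **Cross-genome cleanliness.**  A screening pass resamples mitogenome
   bases until the two genomes share no exact 16-mer outside planted
   transfers.  Sixteen was chosen because chance shared 16-mers number
   ~0 at these genome sizes (whereas shared 11-mers are expected in the
   hundreds and cannot be screened away), and an 11-mer chance seed
   cannot extend into anything passing the 100-bp/70% MIPT floor.
   MIPT source windows are kept non-overlapping so two insertions never
   share sequence that would surface as an unplanted repeat.

Background sequence is i.i.d. uniform over {A,C,G,T}: no GC skew, no
realistic mutation spectrum, no gene conversion, no nested or
higher-copy repeat families.  Passing recovery tests therefore
demonstrates correctness of the detection logic and its thresholds on
clean signal — not robustness to the compositional biases, recent
segmental duplications, or chimeric read artifacts of real organelle
data.  The published genome-wide counts for the real assembly
(495,499 bp; 43 MIPTs; 67 genes) depend on deposited reads and
unstated detection parameters and are reproduced only as worked
arithmetic on the printed totals, not re-derived from raw data.

## Problem sizes and determinism

Test and acceptance runs use the desk-scale defaults above: recovery on
a 100-kb/30-kb pair, depth-ratio simulation at 50× over a two-copy
8.7-kb repeat in a 30-kb collapsed reference (~9,700 read pairs),
scaffold recovery at 8× over 21 kb in three contigs.  Every random
draw flows from a single integer seed (`numpy.random.default_rng`);
fixed seed ⇒ byte-identical genomes, reads, manifests and reports
(timestamps aside).  The encoded comparative panel (seven Orobanchaceae
taxa) and the 11-gene ndh panel are deterministic fixtures; the ndh
references are generated from a fixed seed with disruptions placed to
exceed the classifier thresholds, as a synthetic stand-in for the real
plastome alignments.

## Known limitations

* E-value scale is conventional, not calibrated; filtering decisions
  rest on length/identity.
* Boundary polish trades a few tens of bp of precision on heavily
  decayed segments for exactness on clean ones.
* Trans-spliced intron detection is homology-only; it cannot
  distinguish a functional trans arrangement from a drifting fragment.
* RNA editing, multi-copy (> 2) repeat families and repeat-mediated
  recombination are out of scope.
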