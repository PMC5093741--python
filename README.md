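# orgdecay

Comparative analysis of organellar genome degradation in plants —
built around the kind of question raised by parasitic lineages, where
the plastid genome (plastome) decays as photosynthesis is abandoned
while the mitochondrial genome (mitogenome) largely keeps its function.
The package is for researchers assembling and annotating organelle
genomes who need reproducible, threshold-explicit answers to:

* **Is this gene copy still functional?** Candidate copies are aligned
  to a functional reference CDS and scored for frameshifting indels,
  premature stop codons and truncations.  A gene is called a pseudogene
  (ψ) when mutations disrupt **> 20%** of its conserved domain structure
  or **> 30%** of the gene overall; a copy truncated by 20–30% with no
  other qualifying damage is tentatively scored present (`+*`).
* **How much of the mitogenome is plastid-derived or repeated?**
  MIPTs (mitochondrial DNA of plastid origin) and dispersed repeats are
  detected by seed-and-extend local alignment, merged, size-binned
  (small [50,100), intermediate [100,1000), large ≥ 1 kb) and quantified
  as interval-union coverage of the genome.
* **Which genes and introns survive across taxa?** A taxa × elements
  content matrix with the field's glyphs — `+` present, `−` lost,
  `ψ` pseudogene, `x` intron missing because its host gene is lost,
  `ψr` intron remnant in a pseudogene — plus shared/core set counts.
* **Do read pairs support the assembly?** Mates are placed at their
  best filtered hit (e-value ≤ 1e−10, length ≥ 90 bp, identity ≥ 90%),
  cross-contig pairs build a link graph for scaffolding, collapsed
  repeats are flagged by conflicting links or ≥ 1.5× median depth, and
  per-base coverage supports n-copy depth-ratio tests.

Every stage is verifiable without external data: a synthetic-data
module generates circular organelle genome pairs with planted repeats,
MIPTs (with optional identity decay and secondary pseudogenization),
gene disruptions of analytically known extent, and paired reads — all
recorded in a truth manifest for exact parameter recovery.

## The disruption model

For a reference CDS of length *L* nt with conserved-domain segments
*D*, the disrupted position set of a candidate copy is

```
disrupted = truncated ∪ out-of-frame ∪ post-stop
```

where *truncated* are reference positions unaligned at either end,
*out-of-frame* runs from each frameshifting indel (gap length ≢ 0 mod 3)
to the next compensating frameshift that restores the frame (or to the
gene end), and *post-stop* is everything downstream of the first stop
codon read **in the reference frame** (stops inside out-of-frame
intervals are already covered by the frameshift).  Then

```
overall_fraction = |disrupted| / L
domain_fraction  = |disrupted ∩ D| / |D|
status = ψ  if domain_fraction > 0.20 or overall_fraction > 0.30
       = +* if 0.20 ≤ truncated_fraction ≤ 0.30 (and not ψ)
       = +  otherwise
```

Frameshifts inside mononucleotide runs ≥ 4 bp can be discounted as
pyrosequencing-style artifacts when ≥ 3 covering reads exist and fewer
than 80% of them carry the indel.

## Worked example

```python
from orgdecay import (GeneratorConfig, make_organelle_pair, find_mipts,
                      find_repeats, quantify_segments, summarize_repeats)

cfg = GeneratorConfig(seed=2, mipt_identity=1.0, depth=5.0)
mito, plastid, features, manifest = make_organelle_pair(cfg)

mipts = find_mipts(mito, plastid)
stats = quantify_segments([m.mito_segment for m in mipts], len(mito))
print(stats.count, stats.covered_bp, stats.percent)
# 5 5422 5.4        <- equals the truth manifest exactly

pairs = find_repeats(mito)
print(summarize_repeats(pairs, len(mito))["bin_counts"])
# {'small': 4, 'intermediate': 3, 'large': 1}
```

The printed numbers mean: all 5 planted plastid-to-mitochondrion
transfers were recovered with exact boundaries, covering 5,422 bp
(5.4%) of the 100-kb synthetic mitogenome, and the planted repeat
census (4 small + 3 intermediate + 1 large) is recovered per size bin.
The same arithmetic applied to the published *Castilleja paramensis*
totals — 82,133 bp of MIPT and 13,525 bp of repeats in a 495,499-bp
genome — prints 16.6% and 2.7%.

The same machinery is exposed on the command line
(`orgdecay simulate|align|classify|matrix|mipts|repeats|scaffold|coverage|run`;
`orgdecay config --defaults` prints every threshold).

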