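"""Disruption detection, fraction arithmetic, classification thresholds
and the homopolymer-artifact rule."""

import numpy as np
import pytest

from orgdecay.pseudogene import (ClassifierConfig, Disruption,
                                 ReferenceGene, classify_gene,
                                 detect_disruptions, disruption_fractions,
                                 homopolymer_artifact_check)
from orgdecay.seqio import InputError
from orgdecay.synthetic_data import (GeneratorConfig, expected_status,
                                     make_reference_geneset,
                                     plant_disruption)


@pytest.fixture(scope="module")
def ref100():
    """A deterministic 100-codon reference with a domain on codons 1-40."""
    cfg = GeneratorConfig(seed=99, gene_codon_range=(100, 100))
    gene = make_reference_geneset(cfg, n=1, prefix="ref")[0]
    gene.domains = [(0, 120)]
    return gene


class TestDetectDisruptions:
    def test_identity_no_disruptions(self, ref100):
        assert detect_disruptions(ref100.cds, ref100) == []

    def test_premature_stop_position(self, ref100):
        cand = ref100.cds[:147] + "TAA" + ref100.cds[150:]
        ds = detect_disruptions(cand, ref100)
        assert [(d.kind, d.ref_start, d.ref_end) for d in ds] == \
            [("premature_stop", 147, 150)]

    def test_single_nt_deletion_is_frameshift(self, ref100):
        cand = ref100.cds[:30] + ref100.cds[31:]
        ds = [d for d in detect_disruptions(cand, ref100)
              if d.kind == "frameshift"]
        assert len(ds) == 1
        assert ds[0].indel_len == -1
        assert abs(ds[0].ref_start - 30) <= 2  # alignment may slide a gap

    def test_missing_last_30_codons_is_truncation3(self, ref100):
        cand = ref100.cds[:210]
        ds = detect_disruptions(cand, ref100)
        assert [(d.kind, d.ref_start, d.ref_end) for d in ds] == \
            [("truncation3", 210, 300)]

    def test_missing_start_is_truncation5(self, ref100):
        cand = ref100.cds[60:]
        ds = detect_disruptions(cand, ref100)
        assert ds[0].kind == "truncation5"
        assert ds[0].ref_start == 0

    def test_in_frame_deletion_reported_not_frameshift(self, ref100):
        cand = ref100.cds[:30] + ref100.cds[36:]
        ds = detect_disruptions(cand, ref100)
        kinds = [d.kind for d in ds]
        assert "internal_deletion" in kinds
        assert "frameshift" not in kinds

    def test_invalid_reference_rejected(self):
        bad = ReferenceGene("bad", "ATGAAATTT")  # no terminal stop
        with pytest.raises(InputError):
            detect_disruptions("ATGAAATTT", bad)


class TestDisruptionFractions:
    def test_no_disruptions_zero(self):
        assert disruption_fractions([], 300, [(0, 120)]) == (0.0, 0.0, 0.0)

    def test_premature_stop_at_codon_50(self):
        ds = [Disruption("premature_stop", 147, 150)]
        dom, overall, trunc = disruption_fractions(ds, 300, [(0, 120)])
        assert overall == pytest.approx(0.50)
        assert dom == 0.0
        assert trunc == 0.0

    def test_compensated_frameshift_pair(self):
        """Opposite-parity frameshifts at codons 10 and 20 of a 100-codon
        gene disrupt only the span between them."""
        ds = [Disruption("frameshift", 30, 31, -1),
              Disruption("frameshift", 60, 60, 1)]
        dom, overall, trunc = disruption_fractions(ds, 300, [])
        assert overall == pytest.approx(0.10)

    def test_uncompensated_frameshift_runs_to_end(self):
        ds = [Disruption("frameshift", 30, 31, -1)]
        _, overall, _ = disruption_fractions(ds, 300, [])
        assert overall == pytest.approx(0.90)

    def test_truncation_counts_in_both_fractions(self):
        ds = [Disruption("truncation3", 225, 300)]
        dom, overall, trunc = disruption_fractions(ds, 300, [(210, 270)])
        assert overall == pytest.approx(0.25)
        assert trunc == pytest.approx(0.25)
        assert dom == pytest.approx(45 / 60)

    def test_overall_at_least_truncated(self, rng):
        for _ in range(20):
            L = 300
            ds = []
            if rng.random() < 0.7:
                cut = int(rng.integers(150, 290))
                ds.append(Disruption("truncation3", cut, L))
            if rng.random() < 0.7:
                c = int(rng.integers(1, 90))
                ds.append(Disruption("premature_stop", 3 * c, 3 * c + 3))
            dom, overall, trunc = disruption_fractions(ds, L, [(0, 90)])
            assert 0.0 <= trunc <= overall <= 1.0
            assert 0.0 <= dom <= 1.0


class TestClassifyGene:
    def test_identity_functional(self, ref100):
        call = classify_gene(ref100.cds, ref100)
        assert call.status == "functional"
        assert call.disruptions == []

    def test_heavy_overall_disruption_is_pseudogene(self, ref100):
        cand = ref100.cds[:147] + "TAA" + ref100.cds[150:]  # 50% disrupted
        assert classify_gene(cand, ref100).status == "pseudogene"

    def test_tentative_band_truncation(self, ref100):
        ref = ReferenceGene(ref100.name, ref100.cds, [])  # no domain
        cand = ref.cds[:225]  # truncated by 25%
        call = classify_gene(cand, ref)
        assert call.status == "tentative"
        assert 0.20 <= call.truncated_fraction <= 0.30

    def test_domain_rule_triggers_below_overall_threshold(self):
        """15% overall but >20% of the domain disrupted -> pseudogene."""
        cfg = GeneratorConfig(seed=5, gene_codon_range=(200, 200))
        ref = make_reference_geneset(cfg, n=1)[0]
        L = len(ref.cds)  # 600
        ref.domains = [(L - 120, L)]  # domain = last 40 codons
        cand = ref.cds[:L - 90]  # truncate 15% overall, 75% of domain
        call = classify_gene(cand, ref)
        assert call.overall_disrupted_fraction == pytest.approx(0.15)
        assert call.domain_disrupted_fraction == pytest.approx(0.75)
        assert call.status == "pseudogene"

    def test_late_stop_functional(self, ref100):
        cand = ref100.cds[:285] + "TAA" + ref100.cds[288:]  # 5% disrupted
        call = classify_gene(cand, ref100)
        assert call.status == "functional"

    def test_artifact_frameshift_dropped(self):
        """A frameshift inside a homopolymer with weak read support is
        removed before fractions are computed."""
        cfg = GeneratorConfig(seed=11, gene_codon_range=(100, 100))
        ref = make_reference_geneset(cfg, n=1)[0]
        cds = ref.cds[:60] + "AAAAAA" + ref.cds[66:]
        ref = ReferenceGene(ref.name, _fix_stops(cds), [])
        cand = ref.cds[:62] + ref.cds[63:]  # delete one A from the run
        ds = [d for d in detect_disruptions(cand, ref)
              if d.kind == "frameshift"]
        assert ds and ds[0].in_homopolymer
        supported = classify_gene(cand, ref)
        weak = classify_gene(cand, ref,
                             read_support={ds[0].ref_start: (10, 1)})
        assert supported.status == "pseudogene"
        assert weak.status == "functional"

    def test_monotone_under_added_disruptions(self, ref100):
        """Appending a non-compensating disruption never moves the call
        from pseudogene toward functional (a frame-restoring frameshift
        is excluded: it shrinks the disrupted interval by design)."""
        gen = np.random.default_rng(3)
        L = 300
        ds: list[Disruption] = []
        prev = 0
        for _ in range(8):
            kind = gen.choice(["premature_stop", "frameshift",
                               "truncation3"])
            phase = sum(d.indel_len for d in ds
                        if d.kind == "frameshift") % 3
            if kind == "premature_stop":
                c = int(gen.integers(1, 98))
                ds.append(Disruption("premature_stop", 3 * c, 3 * c + 3))
            elif kind == "frameshift" and phase == 0:
                lo = max([d.ref_start for d in ds
                          if d.kind == "frameshift"] + [3])
                p = int(gen.integers(lo, L - 4))
                ds.append(Disruption("frameshift", p, p + 1, -1))
            elif kind == "frameshift":
                continue
            else:
                cut = int(gen.integers(150, 297))
                ds.append(Disruption("truncation3", cut, L))
            dom, overall, trunc = disruption_fractions(ds, L, [(0, 120)])
            if dom > 0.20 or overall > 0.30:
                status = 2
            elif 0.20 <= trunc <= 0.30:
                status = 1
            else:
                status = 0
            if prev == 2:
                assert status == 2
            prev = max(prev, status)

    def test_planted_status_recovered_away_from_thresholds(self):
        """Planted disruptions whose fractions sit >= 0.02 from both
        thresholds are classified exactly as planted."""
        cfg = ClassifierConfig()
        gen = np.random.default_rng(17)
        gcfg = GeneratorConfig(seed=17, gene_codon_range=(150, 350))
        refs = make_reference_geneset(gcfg, n=12, prefix="t")
        kinds = ["frameshift", "premature_stop", "truncation3",
                 "truncation5"]
        checked = 0
        for i, ref in enumerate(refs):
            target = float(gen.uniform(0.05, 0.6))
            cand, dom, overall, trunc = plant_disruption(
                ref, kinds[i % 4], target, gen)
            if (abs(overall - cfg.overall_threshold) < 0.02
                    or abs(dom - cfg.domain_threshold) < 0.02
                    or abs(trunc - 0.20) < 0.02
                    or abs(trunc - 0.30) < 0.02):
                continue
            want = expected_status(dom, overall, trunc, cfg)
            assert classify_gene(cand, ref, cfg).status == want
            checked += 1
        assert checked >= 6


def _fix_stops(cds: str) -> str:
    """Repair any internal stop introduced by splicing in a run."""
    out = list(cds)
    for c in range(3, len(cds) - 3, 3):
        codon = cds[c:c + 3]
        if codon in ("TAA", "TAG", "TGA"):
            out[c] = "C"
    return "".join(out)


class TestHomopolymerArtifactCheck:
    def _fs(self, run_len):
        return Disruption("frameshift", 50, 51, -1,
                          in_homopolymer=run_len >= 4,
                          homopolymer_len=run_len)

    def test_weakly_supported_in_run_is_artifact(self):
        assert homopolymer_artifact_check(self._fs(6), (10, 1)) == "artifact"

    def test_short_run_supported_regardless(self):
        assert homopolymer_artifact_check(self._fs(3), (10, 1)) == \
            "supported"

    def test_strongly_supported_in_run_kept(self):
        assert homopolymer_artifact_check(self._fs(5), (10, 9)) == \
            "supported"

    def test_missing_support_kept_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="orgdecay"):
            assert homopolymer_artifact_check(self._fs(6), None) == \
                "supported"
        assert any("no read support" in r.message for r in caplog.records)

    def test_too_few_covering_reads_kept(self):
        assert homopolymer_artifact_check(self._fs(6), (2, 0)) == \
            "supported"

    def test_non_frameshift_rejected(self):
        with pytest.raises(InputError):
            homopolymer_artifact_check(
                Disruption("premature_stop", 0, 3), (10, 1))
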