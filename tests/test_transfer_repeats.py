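"""MIPT/repeat detection, coverage arithmetic and truth-manifest
recovery on noise-free synthetic genomes."""

import numpy as np
import pytest

from orgdecay.seqio import InputError, Sequence, revcomp
from orgdecay.synthetic_data import GeneratorConfig, make_organelle_pair
from orgdecay.transfer_repeats import (DetectionConfig, find_mipts,
                                       find_repeats, genes_in_mipts,
                                       merge_intervals, quantify_segments,
                                       round1_half_away, summarize_repeats)
from conftest import random_dna


class TestQuantifySegments:
    def test_mipt_coverage_percent(self):
        assert quantify_segments([(0, 82_133)], 495_499).percent == 16.6

    def test_repeat_coverage_percent(self):
        assert quantify_segments([(0, 13_525)], 495_499).percent == 2.7

    def test_overlap_union(self):
        s = quantify_segments([(0, 100), (50, 150)], 1000)
        assert s.covered_bp == 150
        assert (s.min_len, s.max_len) == (100, 100)

    def test_rounding_half_away_from_zero(self):
        assert round1_half_away(2.75) == 2.8
        assert round1_half_away(16.5759 * 10) / 10 == pytest.approx(16.58,
                                                                    abs=.01)
        assert quantify_segments([(0, 25)], 1000).percent == 2.5
        assert quantify_segments([(0, 125)], 10000).percent == 1.3

    def test_invalid_genome_length(self):
        with pytest.raises(InputError):
            quantify_segments([(0, 10)], 0)

    def test_out_of_bounds_segment(self):
        with pytest.raises(InputError):
            quantify_segments([(0, 20)], 10)

    def test_reorder_and_premerge_invariance(self, rng):
        segs = [(int(s), int(s) + int(l)) for s, l in
                zip(rng.integers(0, 900, 30), rng.integers(5, 80, 30))]
        a = quantify_segments(segs, 1000)
        b = quantify_segments(segs[::-1], 1000)
        assert (a.covered_bp, a.percent) == (b.covered_bp, b.percent)
        merged = merge_intervals(segs)
        assert quantify_segments(merged, 1000).covered_bp == a.covered_bp


class TestFindMipts:
    def test_unrelated_genomes_empty(self, rng):
        mito = Sequence("m", random_dna(rng, 8000))
        plast = Sequence("p", random_dna(rng, 4000))
        assert find_mipts(mito, plast) == []

    def test_single_planted_segment_exact_interval(self, rng):
        plast_seq = random_dna(rng, 4000)
        seg = plast_seq[1000:1500]
        mito_seq = random_dna(rng, 3000) + seg + random_dna(rng, 3000)
        # decouple insertion flanks from the plastome context
        mito_seq = (mito_seq[:2999]
                    + ("A" if plast_seq[999] != "A" else "C")
                    + mito_seq[3000:3500]
                    + ("A" if plast_seq[1500] != "A" else "C")
                    + mito_seq[3501:])
        mipts = find_mipts(Sequence("m", mito_seq), Sequence("p", plast_seq))
        assert len(mipts) == 1
        assert mipts[0].mito_segment == (3000, 3500)
        assert mipts[0].mean_identity == 1.0

    def test_nearby_segments_merged(self, rng):
        plast_seq = random_dna(rng, 4000)
        a, b = plast_seq[100:400], plast_seq[1000:1300]
        gap = random_dna(rng, 30)  # 30 <= merge_gap
        mito_seq = random_dna(rng, 2000) + a + gap + b \
            + random_dna(rng, 2000)
        mipts = find_mipts(Sequence("m", mito_seq), Sequence("p", plast_seq))
        assert len(mipts) == 1
        assert mipts[0].mito_segment == (2000, 2000 + 300 + 30 + 300)
        assert len(mipts[0].source_segments) == 2

    def test_distant_segments_not_merged(self, rng):
        plast_seq = random_dna(rng, 4000)
        a, b = plast_seq[100:400], plast_seq[1000:1300]
        mito_seq = random_dna(rng, 2000) + a + random_dna(rng, 500) + b \
            + random_dna(rng, 2000)
        mipts = find_mipts(Sequence("m", mito_seq), Sequence("p", plast_seq))
        assert len(mipts) == 2

    def test_short_transfer_discarded(self, rng):
        plast_seq = random_dna(rng, 4000)
        mito_seq = random_dna(rng, 2000) + plast_seq[100:180] \
            + random_dna(rng, 2000)  # 80 bp < mipt_min_len
        assert find_mipts(Sequence("m", mito_seq),
                          Sequence("p", plast_seq)) == []


class TestGenesInMipts:
    def test_contained_genes_and_secondary_disruption(self):
        cfg = GeneratorConfig(seed=13, mipt_identity=1.0,
                              mipt_secondary_disruption=True,
                              mipt_cover_genes=2)
        mito, plast, feats, man = make_organelle_pair(cfg)
        mipts = find_mipts(mito, plast)
        out = genes_in_mipts(mipts, feats["plastid"], mito, plast)
        names = {g for g, _, _ in out}
        # the two gene-covering MIPTs carry one full gene each
        assert names == {"pt01", "pt02"}
        for _, frac, status in out:
            assert frac >= 0.90
            # the planted mid-copy frameshift pseudogenizes the carried copy
            assert status == "pseudogene"

    def test_partially_contained_gene_excluded(self, rng):
        cfg = GeneratorConfig(seed=14, mipt_identity=1.0,
                              mipt_cover_genes=0, mipt_count=1,
                              mipt_length_range=(400, 500))
        mito, plast, feats, man = make_organelle_pair(cfg)
        mipts = find_mipts(mito, plast)
        out = genes_in_mipts(mipts, feats["plastid"], mito, plast)
        for name, frac, _ in out:
            assert frac >= 0.90


class TestFindRepeats:
    def test_random_genome_empty(self, rng):
        genome = Sequence("g", random_dna(rng, 10_000))
        assert find_repeats(genome) == []

    def test_planted_duplicate_located(self, rng):
        bg = random_dna(rng, 9000)
        seg = bg[1000:1200]
        gseq = bg[:4000] + seg + bg[4000:]
        # decouple destination flanks so the planted copy is maximal
        gseq = (gseq[:3999] + ("A" if bg[999] != "A" else "C")
                + gseq[4000:4200] + ("A" if bg[1200] != "A" else "C")
                + gseq[4201:])
        pairs = find_repeats(Sequence("g", gseq))
        assert len(pairs) == 1
        assert pairs[0].copy_a == (1000, 1200)
        assert pairs[0].copy_b == (4000, 4200)
        assert pairs[0].orientation == "direct"

    def test_inverted_duplicate_orientation(self, rng):
        bg = random_dna(rng, 9000)
        seg = revcomp(bg[1000:1200])
        gseq = bg[:4000] + seg + bg[4000:]
        pairs = find_repeats(Sequence("g", gseq))
        assert len(pairs) == 1
        assert pairs[0].orientation == "inverted"

    def test_full_length_self_match_never_reported(self, rng):
        genome = Sequence("g", random_dna(rng, 5000))
        for p in find_repeats(genome):
            assert p.copy_a != p.copy_b

    def test_reversed_genome_maps_orientations(self, rng):
        bg = random_dna(rng, 8000)
        gseq = bg[:3000] + bg[500:700] + bg[3000:6000] \
            + revcomp(bg[1500:1700]) + bg[6000:]
        fwd = find_repeats(Sequence("g", gseq))
        rev = find_repeats(Sequence("g", revcomp(gseq)))
        assert sorted(p.orientation for p in fwd) == \
            sorted(p.orientation for p in rev)
        n = len(gseq)
        mirrored = sorted(
            tuple(sorted([(n - p.copy_b[1], n - p.copy_b[0]),
                          (n - p.copy_a[1], n - p.copy_a[0])]))
            for p in rev)
        assert mirrored == sorted((p.copy_a, p.copy_b) for p in fwd)


class TestSummarizeRepeats:
    def _pairs(self, lengths):
        from orgdecay.transfer_repeats import RepeatPair
        out = []
        pos = 0
        for ln in lengths:
            out.append(RepeatPair((pos, pos + ln),
                                  (pos + 20_000, pos + 20_000 + ln),
                                  ln, 1.0, "direct"))
            pos += ln + 100
        return out

    def test_bin_assignment(self):
        summary = summarize_repeats(self._pairs([8700, 120, 60]), 60_000)
        assert summary["bin_counts"] == {"large": 1, "intermediate": 1,
                                         "small": 1}

    def test_half_open_bin_edges(self):
        summary = summarize_repeats(self._pairs([99, 100]), 60_000)
        assert summary["bin_counts"] == {"small": 1, "intermediate": 1,
                                         "large": 0}

    def test_coverage_over_all_copies(self):
        summary = summarize_repeats(self._pairs([100]), 60_000)
        assert summary["coverage"].covered_bp == 200

    def test_bad_bins_rejected(self):
        with pytest.raises(InputError):
            DetectionConfig(size_bins={"small": (50, 90),
                                       "large": (100, float("inf"))})


class TestTruthManifestRecovery:
    def test_mipt_recovery_exact(self, noise_free_pair):
        _, mito, plast, _, man = noise_free_pair
        mipts = find_mipts(mito, plast)
        got = sorted(m.mito_segment for m in mipts)
        want = sorted(tuple(m["mito_interval"]) for m in man.planted_mipts)
        assert got == want  # 100% precision and recall, exact boundaries

    def test_mipt_coverage_matches_manifest(self, noise_free_pair):
        _, mito, plast, _, man = noise_free_pair
        mipts = find_mipts(mito, plast)
        det = quantify_segments([m.mito_segment for m in mipts], len(mito))
        truth = quantify_segments(
            [tuple(m["mito_interval"]) for m in man.planted_mipts],
            len(mito))
        assert det.covered_bp == truth.covered_bp
        assert det.percent == truth.percent

    def test_repeat_recovery_exact(self, noise_free_pair):
        _, mito, _, _, man = noise_free_pair
        pairs = find_repeats(mito)
        got = sorted((p.copy_a, p.copy_b, p.orientation) for p in pairs)
        want = sorted((tuple(r["copy_a"]), tuple(r["copy_b"]),
                       r["orientation"]) for r in man.planted_repeats)
        assert got == want

    def test_repeat_bin_counts_match_plan(self, noise_free_pair):
        config, mito, _, _, man = noise_free_pair
        pairs = find_repeats(mito)
        summary = summarize_repeats(pairs, len(mito))
        assert summary["bin_counts"] == config.repeat_counts
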