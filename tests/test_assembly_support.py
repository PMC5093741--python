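"""Read mapping, link-graph scaffolding, coverage and assembly
selection."""

import numpy as np
import pytest

from orgdecay.assembly_support import (AssemblyStats, ContigGraph, LinkEdge,
                                       MateHit, ReadPairMapping,
                                       build_link_graph, coverage_profile,
                                       depth_ratio, infer_joins,
                                       map_read_pairs,
                                       select_best_assembly)
from orgdecay.seqio import CoverageTrack, InputError, Sequence
from orgdecay.synthetic_data import GeneratorConfig, simulate_reads
from conftest import random_dna


class TestMapReadPairs:
    def test_exact_substring_mapped_uniquely(self, rng):
        contig = Sequence("c1", random_dna(rng, 2000))
        read = contig.residues[500:600]
        m = map_read_pairs([("p1", read, read)], [contig])[0]
        assert m.mate1.contig_id == "c1"
        assert m.mate1.interval == (500, 600)

    def test_low_identity_mate_unmapped(self, rng):
        contig = Sequence("c1", random_dna(rng, 2000))
        read = list(contig.residues[500:600])
        for p in rng.choice(100, size=15, replace=False):  # 85% identity
            read[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[p]]
        m = map_read_pairs([("p1", "".join(read),
                             contig.residues[800:900])], [contig])[0]
        assert m.mate1 is None
        assert m.mate2 is not None

    def test_tie_broken_to_lexicographically_first_contig(self, rng):
        locus = random_dna(rng, 300)
        c_b = Sequence("cB", random_dna(rng, 200) + locus)
        c_a = Sequence("cA", random_dna(rng, 200) + locus)
        read = locus[50:150]
        m = map_read_pairs([("p1", read, read)], [c_b, c_a])[0]
        assert m.mate1.contig_id == "cA"

    def test_proper_pair_orientation_and_insert(self, rng):
        from orgdecay.seqio import revcomp
        contig = Sequence("c1", random_dna(rng, 3000))
        r1 = contig.residues[1000:1100]
        r2 = revcomp(contig.residues[1700:1800])
        m = map_read_pairs([("p1", r1, r2)], [contig],
                           insert_mean=800, insert_sd=50)[0]
        assert m.proper


class TestBuildLinkGraph:
    def _mapping(self, pid, c1, iv1, st1, c2, iv2, st2):
        return ReadPairMapping(pid, MateHit(c1, iv1, st1),
                               MateHit(c2, iv2, st2), False)

    def _contigs(self):
        return [Sequence("A", "A" * 5000), Sequence("B", "C" * 5000)]

    def test_internal_pairs_make_no_edges(self):
        maps = [self._mapping(f"p{i}", "A", (100, 200), "+",
                              "A", (700, 800), "-") for i in range(5)]
        g = build_link_graph(maps, self._contigs())
        assert g.edges == []

    def test_spanning_pairs_build_one_edge(self):
        maps = [self._mapping(f"p{i}", "A", (4800, 4900), "+",
                              "B", (100, 200), "-") for i in range(10)]
        g = build_link_graph(maps, self._contigs(), min_support=2)
        assert len(g.edges) == 1
        e = g.edges[0]
        assert e.support == 10
        assert {e.end_a, e.end_b} == {("A", "R"), ("B", "L")}
        # overhangs 200 each side -> implied gap 800 - 400
        assert e.gap == 400

    def test_support_below_threshold_dropped(self):
        maps = [self._mapping("p0", "A", (4800, 4900), "+",
                              "B", (100, 200), "-")]
        g = build_link_graph(maps, self._contigs(), min_support=2)
        assert g.edges == []

    def test_support_conserves_cross_pairs(self, rng):
        n_cross = 7
        maps = [self._mapping(f"x{i}", "A", (4800, 4900), "+",
                              "B", (100, 200), "-") for i in range(n_cross)]
        maps += [self._mapping(f"i{i}", "B", (1000, 1100), "+",
                               "B", (1500, 1600), "-") for i in range(4)]
        g = build_link_graph(maps, self._contigs(), min_support=1)
        assert sum(e.support for e in g.edges) == n_cross


class TestInferJoins:
    def _graph(self, edges, lengths=None, depths=None):
        contigs = sorted({c for e in edges for c, _ in (e.end_a, e.end_b)})
        lengths = lengths or {c: 1000 for c in contigs}
        depths = depths or {c: 10.0 for c in lengths}
        return ContigGraph(lengths, depths, edges)

    def test_unique_chain_joined(self):
        g = self._graph([LinkEdge(("A", "R"), ("B", "L"), 5, 0),
                         LinkEdge(("B", "R"), ("C", "L"), 5, 0)])
        res = infer_joins(g)
        assert res.paths == [[("A", "+"), ("B", "+"), ("C", "+")]]
        assert res.repeat_flags == set()

    def test_conflicting_end_flags_repeat_and_breaks(self):
        g = self._graph([LinkEdge(("A", "R"), ("B", "L"), 5, 0),
                         LinkEdge(("A", "R"), ("C", "L"), 5, 0)])
        res = infer_joins(g)
        assert "A" in res.repeat_flags
        assert [["B", "C"]] != res.paths  # B and C stay separate
        assert sorted(p[0][0] for p in res.paths) == ["B", "C"]

    def test_elevated_depth_flags_repeat(self):
        g = self._graph([LinkEdge(("A", "R"), ("B", "L"), 5, 0),
                         LinkEdge(("B", "R"), ("C", "L"), 5, 0)],
                        depths={"A": 10.0, "B": 25.0, "C": 10.0})
        res = infer_joins(g)
        assert "B" in res.repeat_flags
        assert sorted(p[0][0] for p in res.paths) == ["A", "C"]

    def test_orientation_flip_through_reversed_contig(self):
        # A right end meets B right end: B traversed reversed
        g = self._graph([LinkEdge(("A", "R"), ("B", "R"), 5, 0)])
        res = infer_joins(g)
        assert res.paths == [[("A", "+"), ("B", "-")]]

    def test_contig_order_invariance(self):
        edges = [LinkEdge(("A", "R"), ("B", "L"), 5, 0),
                 LinkEdge(("B", "R"), ("C", "L"), 5, 0)]
        r1 = infer_joins(self._graph(edges))
        r2 = infer_joins(self._graph(list(reversed(edges))))
        assert r1.paths == r2.paths

    def test_simulated_genome_join_recovery(self, rng):
        """Every true adjacency is recovered; no join contradicts the
        truth layout (zero false joins on noise-free reads)."""
        g = random_dna(rng, 24_000)
        genome = Sequence("g", g, "linear")
        cfg = GeneratorConfig(seed=77, depth=8.0)
        reads, _ = simulate_reads(genome, cfg)
        cuts = [0, 5_000, 11_000, 17_500, 24_000]
        contigs = [Sequence(f"c{i}", g[cuts[i]:cuts[i + 1]])
                   for i in range(4)]
        maps = map_read_pairs(
            [(p.pair_id, p.seq1, p.seq2) for p in reads], contigs)
        graph = build_link_graph(maps, contigs, min_support=2)
        res = infer_joins(graph)
        assert res.repeat_flags == set()
        assert res.paths == [[("c0", "+"), ("c1", "+"), ("c2", "+"),
                              ("c3", "+")]]


class TestCoverage:
    def test_single_read(self):
        genome = Sequence("g", "A" * 500)
        track = coverage_profile([(0, 100)], genome)
        assert track.depth[:100].sum() == 100
        assert track.depth[100:].sum() == 0

    def test_sum_equals_aligned_bases(self, rng):
        genome = Sequence("g", random_dna(rng, 1000))
        placements = [(int(s), int(s) + 50)
                      for s in rng.integers(0, 950, 200)]
        track = coverage_profile(placements, genome)
        assert track.depth.sum() == 200 * 50

    def test_circular_wrap(self):
        genome = Sequence("g", "A" * 100, "circular")
        track = coverage_profile([(90, 110)], genome)
        assert track.depth[90:].sum() == 10
        assert track.depth[:10].sum() == 10

    def test_simulated_depth_within_5_percent(self):
        genome = Sequence("g", "ACGT" * 5000, "circular")
        cfg = GeneratorConfig(seed=5, depth=50.0)
        reads, _ = simulate_reads(genome, cfg)
        placements = []
        for p in reads:
            placements.append(p.placement1[:2])
            placements.append(p.placement2[:2])
        track = coverage_profile(placements, genome)
        assert abs(track.depth.mean() - 50.0) / 50.0 < 0.05


class TestDepthRatio:
    def test_region_equal_background_is_one(self):
        track = CoverageTrack("g", np.full(1000, 30))
        assert depth_ratio(track, (100, 200), [(0, 1000)]) == \
            pytest.approx(1.0)

    def test_scale_invariance(self, rng):
        d = rng.integers(10, 60, 1000)
        t1 = CoverageTrack("g", d)
        t2 = CoverageTrack("g", d * 2)
        r1 = depth_ratio(t1, (100, 300), [(400, 900)])
        r2 = depth_ratio(t2, (100, 300), [(400, 900)])
        assert r1 == pytest.approx(r2)

    def test_zero_background_rejected(self):
        track = CoverageTrack("g", np.zeros(100, dtype=int))
        with pytest.raises(InputError):
            depth_ratio(track, (0, 10), [(50, 60)])

    @pytest.mark.parametrize("n_copies", [2, 3])
    def test_collapsed_repeat_ratio_converges(self, n_copies):
        """Reads from an n-copy repeat mapped onto a single-copy
        reference give an n-fold depth ratio."""
        gen = np.random.default_rng(n_copies)
        bg = random_dna(gen, 12_000)
        rep = bg[2_000:4_000]
        genome_seq = bg + rep * (n_copies - 1)
        cfg = GeneratorConfig(seed=n_copies, depth=30.0)
        reads, _ = simulate_reads(Sequence("g", genome_seq, "circular"),
                                  cfg)
        ref = Sequence("ref", bg, "circular")
        maps = map_read_pairs(
            [(p.pair_id, p.seq1, p.seq2) for p in reads], [ref])
        placements = [m.mate1.interval for m in maps if m.mate1] + \
            [m.mate2.interval for m in maps if m.mate2]
        track = coverage_profile(placements, ref)
        r = depth_ratio(track, (2_000, 4_000), [(5_000, 11_000)])
        assert r == pytest.approx(n_copies, rel=0.12)


class TestSelectBestAssembly:
    def test_length_is_primary(self):
        stats = [AssemblyStats("k61", 500_000, 10),
                 AssemblyStats("k71", 480_000, 2)]
        assert select_best_assembly(stats) == "k61"

    def test_contig_count_breaks_ties(self):
        stats = [AssemblyStats("k61", 500_000, 5),
                 AssemblyStats("k71", 500_000, 2)]
        assert select_best_assembly(stats) == "k71"

    def test_single_candidate(self):
        assert select_best_assembly([AssemblyStats("only", 1, 1)]) == "only"

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            select_best_assembly([])
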