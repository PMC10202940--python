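"""Minimizer scaffolding: sketches, mapping, graph, layout, joins, liftover."""

import numpy as np
import pytest

from goldenpath.hashing import revcomp
from goldenpath.scaffold import (
    ChainParams,
    Mapping,
    ScaffoldGraph,
    build_graph,
    build_index,
    detect_overlap,
    fill_gap,
    layout,
    liftover,
    map_all_reads,
    run_rounds,
    sketch,
    FillCandidate,
    Placement,
)
from goldenpath.simulate import SimConfig, gen_genome, score_assembly


def chain(**kw) -> ChainParams:
    return ChainParams(**kw)


@pytest.fixture(scope="module")
def genome():
    return gen_genome(SimConfig(G=120_000, seed=17))


class TestSketch:
    def test_sequence_of_length_k_has_one_minimizer(self, seq_factory):
        s = seq_factory(32)
        sk = sketch(s, 32, 100)
        assert len(sk) == 1
        assert sk.pos[0] == 0

    def test_w1_selects_every_kmer(self, seq_factory):
        s = seq_factory(200)
        sk = sketch(s, 16, 1)
        assert len(sk) == 200 - 16 + 1

    def test_matches_bruteforce_window_minima(self, seq_factory):
        from goldenpath.hashing import canonical_kmer_hashes, encode

        s = seq_factory(10_000)
        k, w = 21, 40
        sk = sketch(s, k, w)
        h, _ = canonical_kmer_hashes(encode(s), k)
        expected = set()
        for start in range(len(h) - w + 1):
            window = h[start : start + w]
            expected.add(start + int(np.argmin(window)))
        assert set(sk.pos.tolist()) == expected

    def test_positions_strictly_increasing(self, seq_factory):
        sk = sketch(seq_factory(5000), 32, 100)
        assert (np.diff(sk.pos) > 0).all()

    def test_too_short_yields_empty(self):
        assert len(sketch("ACGT", 32, 100)) == 0


class TestMapRead:
    def test_verbatim_substring_maps_forward(self, genome):
        tigs = {"t0": genome[:50_000], "t1": genome[50_000:]}
        params = chain()
        index = build_index(tigs, params)
        maps = map_all_reads(index, {"r": genome[10_000:18_000]}, params)
        (m,) = maps["r"]
        assert (m.tig, m.strand) == ("t0", "+")
        assert m.n_anchors >= 3
        # anchors collinear: tig pos = read pos + 10_000
        assert ((m.tpos - m.rpos) == 10_000).all()

    def test_reverse_complement_maps_minus(self, genome):
        tigs = {"t0": genome[:50_000], "t1": genome[50_000:]}
        params = chain()
        index = build_index(tigs, params)
        maps = map_all_reads(
            index, {"r": revcomp(genome[10_000:18_000])}, params
        )
        (m,) = maps["r"]
        assert (m.tig, m.strand) == ("t0", "-")

    def test_read_spanning_two_goldtigs(self, genome):
        tigs = {"t0": genome[:50_000], "t1": genome[50_000:]}
        params = chain()
        index = build_index(tigs, params)
        maps = map_all_reads(index, {"r": genome[42_000:58_000]}, params)
        assert sorted(m.tig for m in maps["r"]) == ["t0", "t1"]
        by_tig = {m.tig: m for m in maps["r"]}
        assert by_tig["t0"].rpos[0] < by_tig["t1"].rpos[0]

    def test_shared_minimizers_dropped_from_global_index(self, genome):
        shared = genome[30_000:40_000]
        tigs = {"a": shared, "b": shared}
        params = chain()
        assert build_index(tigs, params) == {}
        per_tig = build_index(tigs, params, per_tig_unique=True)
        assert all(len(v) == 2 for v in per_tig.values())


class TestBuildGraph:
    def _mappings(self, genome, n_span, params):
        tigs = {"t0": genome[:60_000], "t1": genome[60_000:]}
        index = build_index(tigs, params)
        reads = {
            f"s{i}": genome[52_000 + 700 * i : 68_000 + 700 * i]
            for i in range(n_span)
        }
        return tigs, map_all_reads(index, reads, params)

    def test_spanning_reads_accumulate_weight(self, genome):
        params = chain()
        tigs, maps = self._mappings(genome, 5, params)
        graph = build_graph(maps, {n: len(s) for n, s in tigs.items()}, params)
        (key, data), = graph.edges.items()
        assert key == ("t0", "+", "t1", "+")
        assert data.weight == 5
        # adjacent partition of the genome: gap estimate near zero
        assert abs(data.gap_est) < params.w

    def test_single_read_below_support_dropped(self, genome):
        params = chain(min_edge_support=2)
        tigs, maps = self._mappings(genome, 1, params)
        graph = build_graph(maps, {n: len(s) for n, s in tigs.items()}, params)
        assert graph.edges == {}

    def test_overlapping_goldtigs_negative_gap(self, genome):
        params = chain()
        tigs = {"t0": genome[:61_000], "t1": genome[60_000:]}  # 1 kb overlap
        index = build_index(tigs, params)
        reads = {
            f"s{i}": genome[52_000 + 700 * i : 68_000 + 700 * i]
            for i in range(5)
        }
        maps = map_all_reads(index, reads, params)
        graph = build_graph(maps, {n: len(s) for n, s in tigs.items()}, params)
        data = graph.edges[("t0", "+", "t1", "+")]
        assert -1000 - params.w <= data.gap_est <= -1000 + params.w

    def test_mirror_edge_is_same_edge(self, genome):
        params = chain()
        tigs, maps = self._mappings(genome, 3, params)
        rc_maps = {}
        for read, ms in maps.items():
            seq = None
        # reverse-complemented reads produce the mirror orientation but the
        # same canonical edge
        tigs2 = {"t0": genome[:60_000], "t1": genome[60_000:]}
        index = build_index(tigs2, params)
        reads_rc = {
            f"s{i}": revcomp(genome[52_000 + 700 * i : 68_000 + 700 * i])
            for i in range(3)
        }
        maps_rc = map_all_reads(index, reads_rc, params)
        g1 = build_graph(maps, {n: len(s) for n, s in tigs2.items()}, params)
        g2 = build_graph(maps_rc, {n: len(s) for n, s in tigs2.items()}, params)
        assert set(g1.edges) == set(g2.edges)


class TestLayout:
    def _graph(self, edges):
        g = ScaffoldGraph()
        for (u, ou, v, ov), w, gap in edges:
            key = ScaffoldGraph.canonical((u, ou, v, ov))
            from goldenpath.scaffold import EdgeData

            data = g.edges.setdefault(key, EdgeData())
            data.weight = w
            data.gaps = [gap]
        return g

    def test_simple_chain(self):
        g = self._graph([
            (("A", "+", "B", "+"), 5, 100),
            (("B", "+", "C", "+"), 4, 100),
        ])
        paths = layout(g, ["A", "B", "C"])
        assert [[n for n, _ in p] for p in paths] == [["A", "B", "C"]]
        assert all(o == "+" for _, o in paths[0])

    def test_conflicting_edges_heavier_wins(self):
        g = self._graph([
            (("A", "+", "B", "+"), 5, 100),
            (("A", "+", "C", "+"), 3, 100),
        ])
        paths = layout(g, ["A", "B", "C"])
        as_sets = sorted([n for n, _ in p] for p in paths)
        assert as_sets == [["A", "B"], ["C"]]

    def test_cycle_edge_rejected(self):
        g = self._graph([
            (("A", "+", "B", "+"), 5, 100),
            (("B", "+", "A", "+"), 4, 100),
        ])
        paths = layout(g, ["A", "B"])
        assert sum(len(p) - 1 for p in paths) == 1

    def test_every_tig_appears_exactly_once(self):
        g = self._graph([
            (("A", "+", "B", "-"), 5, 100),
            (("C", "-", "B", "-"), 4, 100),
            (("D", "+", "E", "+"), 2, 100),
        ])
        paths = layout(g, list("ABCDEF"))
        flat = [n for p in paths for n, _ in p]
        assert sorted(flat) == list("ABCDEF")


class TestDetectOverlap:
    def test_exact_overlap_reconstructs_truth(self, genome):
        left, right = genome[:51_000], genome[50_000:100_000]
        params = chain()
        cut = detect_overlap(left, right, -1000.0, params)
        assert cut is not None
        cut_l, cut_r = cut
        assert left[:cut_l] + right[cut_r:] == genome[:100_000]

    def test_unrelated_sequences_no_overlap(self, seq_factory):
        params = chain()
        assert detect_overlap(seq_factory(5000), seq_factory(5000),
                              -500.0, params) is None

    def test_noisy_overlap_merges_near_truth(self, genome, rng):
        def noise(s, rate=0.02):
            out = list(s)
            for p in rng.choice(len(out), int(rate * len(out)), replace=False):
                out[p] = "ACGT"[("ACGT".index(out[p]) + 1) % 4]
            return "".join(out)

        left = noise(genome[:51_000])
        right = noise(genome[50_000:100_000])
        cut = detect_overlap(left, right, -1000.0, chain())
        assert cut is not None
        cut_l, cut_r = cut
        merged = left[:cut_l] + right[cut_r:]
        assert abs(len(merged) - 100_000) <= 50

    def test_nonnegative_gap_rejected(self):
        with pytest.raises(ValueError):
            detect_overlap("A" * 100, "C" * 100, 10.0, chain())


class TestFillGap:
    def test_exact_gap_fill_reconstructs_truth(self, genome):
        left = genome[:47_000]
        right = genome[50_000:100_000]
        spanning = genome[42_000:55_000]
        cand = FillCandidate(
            name="r0", mean_anchors=10.0, seq=spanning,
            left_anchor=(44_000, 2_000), right_anchor=(1_000, 9_000), k=32,
        )
        out = fill_gap(left, right, 3000.0, [cand], chain())
        assert out is not None
        cut_l, mid, cut_r = out
        assert left[:cut_l] + mid + right[cut_r:] == genome[:100_000]

    def test_no_candidates_returns_none(self):
        assert fill_gap("A" * 100, "C" * 100, 50.0, [], chain()) is None

    def test_tie_breaks_on_read_name(self, genome):
        left = genome[:47_000]
        right = genome[50_000:100_000]
        spanning = genome[42_000:55_000]
        mk = lambda nm: FillCandidate(
            name=nm, mean_anchors=10.0, seq=spanning,
            left_anchor=(44_000, 2_000), right_anchor=(1_000, 9_000), k=32,
        )
        # same anchors, equal rank: lexicographically smaller name wins,
        # so the result is identical whichever order they arrive in
        out1 = fill_gap(left, right, 3000.0, [mk("a"), mk("b")], chain())
        out2 = fill_gap(left, right, 3000.0, [mk("b"), mk("a")], chain())
        assert out1 == out2


class TestLiftover:
    def _mapping(self, tig="t0", strand="+", rpos=(0, 100, 200),
                 tpos=(500, 600, 700)):
        return Mapping("r", tig, strand,
                       np.array(rpos, dtype=np.int64),
                       np.array(tpos, dtype=np.int64))

    def test_forward_identity_placement(self):
        params = chain(min_anchors=3)
        pl = {"t0": Placement("s0", 0, "+", 0, 10_000, 10_000)}
        out = liftover({"r": [self._mapping()]}, pl, params)
        (m,) = out["r"]
        assert m.tig == "s0"
        assert m.strand == "+"
        assert m.tpos.tolist() == [500, 600, 700]

    def test_reverse_orientation_algebra(self):
        params = chain(min_anchors=3)
        length, k = 10_000, 32
        pl = {"t0": Placement("s0", 0, "-", 0, length, length)}
        out = liftover({"r": [self._mapping()]}, pl, params)
        (m,) = out["r"]
        assert m.strand == "-"
        expected = [length - k - p for p in (500, 600, 700)]
        assert sorted(m.tpos.tolist()) == sorted(expected)

    def test_anchors_in_trimmed_region_dropped(self):
        params = chain(min_anchors=3)
        pl = {"t0": Placement("s0", 0, "+", 600, 10_000, 10_000)}
        out = liftover({"r": [self._mapping()]}, pl, params)
        assert out == {}  # 2 surviving anchors < min_anchors

    def test_offset_applied(self):
        params = chain(min_anchors=3)
        pl = {"t0": Placement("s0", 5_000, "+", 0, 10_000, 10_000)}
        out = liftover({"r": [self._mapping()]}, pl, params)
        assert out["r"][0].tpos.tolist() == [5_500, 5_600, 5_700]


class TestRunRounds:
    def _reads_covering(self, genome, step=4_000, length=16_000):
        return {
            f"r{i:03d}": genome[s : s + length]
            for i, s in enumerate(range(0, len(genome) - length + 1, step))
        }

    def test_fragmented_genome_reassembled(self, genome):
        tigs = {
            f"t{i}": genome[s : s + 30_000]
            for i, s in enumerate(range(0, 120_000, 30_000))
        }
        reads = self._reads_covering(genome)
        scaffolds, report = run_rounds(tigs, reads, chain())
        assert len(scaffolds) == 1
        score = score_assembly(scaffolds, genome)
        assert score.misjoins == 0
        assert score.genome_fraction > 0.99
        assert score.mean_identity > 0.999

    def test_perfect_assembly_early_stop(self, genome):
        scaffolds, report = run_rounds(
            {"t0": genome}, self._reads_covering(genome), chain()
        )
        assert scaffolds == {"t0": genome}
        assert report["rounds"][-1]["joins"] == 0

    def test_scaffold_count_non_increasing(self, genome):
        tigs = {
            f"t{i}": genome[s : s + 20_000]
            for i, s in enumerate(range(0, 120_000, 20_000))
        }
        reads = self._reads_covering(genome)
        counts = []
        for rounds in (1, 5):
            scaffolds, _ = run_rounds(tigs, reads, chain(rounds=rounds))
            counts.append(len(scaffolds))
        assert counts[1] <= counts[0]

    def test_sequence_conservation(self, genome):
        """Every non-N scaffold base comes verbatim from a goldtig or read."""
        tigs = {
            f"t{i}": genome[s : s + 40_000]
            for i, s in enumerate(range(0, 120_000, 40_000))
        }
        reads = self._reads_covering(genome)
        scaffolds, _ = run_rounds(tigs, reads, chain())
        for seq in scaffolds.values():
            for chunk in seq.split("N"):
                if chunk:
                    assert chunk in genome or revcomp(chunk) in genome


class TestLiftoverEquivalence:
    def test_round2_graph_matches_remapping(self, genome):
        """Lifted mappings and a fresh re-mapping yield the same scaffold
        graph (edges and weights) on an error-free fixture."""
        params = chain()
        # A,B,C,D adjacent; E is a decoy contested at B's right end
        A, B = genome[:30_000], genome[30_000:60_000]
        C, D = genome[60_000:90_000], genome[90_000:120_000]
        E = gen_genome(SimConfig(G=30_000, seed=99))
        tigs = {"A": A, "B": B, "C": C, "D": D, "E": E}
        reads = {}
        for i in range(3):  # A-B junction
            reads[f"ab{i}"] = genome[22_000 + i * 500 : 38_000 + i * 500]
        for i in range(3):  # C-D junction
            reads[f"cd{i}"] = genome[82_000 + i * 500 : 98_000 + i * 500]
        for i in range(2):  # B-C junction (outcompeted in round 1)
            reads[f"bc{i}"] = genome[52_000 + i * 500 : 68_000 + i * 500]
        for i in range(3):  # chimeric B-end + E-start: wins B's right end
            reads[f"be{i}"] = (
                genome[52_000 + i * 400 : 60_000] + E[: 8_000 + i * 400]
            )
        index = build_index(tigs, params)
        mappings = map_all_reads(index, reads, params)
        lengths = {n: len(s) for n, s in tigs.items()}
        graph1 = build_graph(mappings, lengths, params)
        paths = layout(graph1, tigs.keys())
        from goldenpath.scaffold import _materialize

        scaffolds, placements, _ = _materialize(
            paths, tigs, graph1, reads, params, 1
        )
        lifted = liftover(mappings, placements, params)
        slen = {n: len(s) for n, s in scaffolds.items()}
        g_lift = build_graph(lifted, slen, params)

        index2 = build_index(scaffolds, params)
        remapped = map_all_reads(index2, reads, params)
        g_remap = build_graph(remapped, slen, params)

        assert g_lift.summary() == g_remap.summary()
        assert len(g_lift.edges) >= 1  # the B-C evidence survives the joins
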