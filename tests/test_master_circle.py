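import pytest

from mitocircle.genome_io import CircularGenome, revcomp
from mitocircle.master_circle import (
    AssemblyError,
    Contig,
    ContigGraph,
    Linkage,
    _steps,
    build_master_circle,
    filter_graph,
    read_contig_graph,
)
from mitocircle.synthetic_data import generate_contig_graph

from conftest import random_seq
from oracles import enumerate_covering_walks


def ring_graph(seqs, depths=None, link_depth=20):
    """Simple ring of contigs c1 -> c2 -> ... -> c1."""
    n = len(seqs)
    depths = depths or [30.0] * n
    contigs = [Contig(f"c{i+1}", s, d) for i, (s, d) in enumerate(zip(seqs, depths))]
    links = [
        Linkage(f"c{i+1}", "tail", f"c{(i+1) % n + 1}", "head", link_depth, 0)
        for i in range(n)
    ]
    return ContigGraph(contigs, links)


class TestFilterGraph:
    def test_all_deep_links_unchanged(self, rng):
        gr = ring_graph([random_seq(rng, 100) for _ in range(4)])
        out = filter_graph(gr)
        assert len(out.linkages) == 4 and len(out.contigs) == 4

    def test_shallow_link_removed(self, rng):
        gr = ring_graph([random_seq(rng, 100) for _ in range(5)])
        gr.linkages[2] = Linkage(
            gr.linkages[2].contig1, "tail", gr.linkages[2].contig2, "head", 9, 0
        )
        out = filter_graph(gr, min_link_depth=10)
        assert len(out.linkages) == 4

    def test_plastid_low_depth_contig_removed(self, rng):
        plastid = CircularGenome("plastid", random_seq(rng, 5000))
        seqs = [random_seq(rng, 400) for _ in range(3)] + [plastid.seq[1000:1400]]
        gr = ring_graph(seqs, depths=[36.0, 36.0, 36.0, 2.0])
        out = filter_graph(gr, plastid_panel=[plastid])
        assert len(out.contigs) == 3
        assert all("c4" not in (l.contig1, l.contig2) for l in out.linkages)

    def test_high_depth_plastid_like_contig_kept(self, rng):
        plastid = CircularGenome("plastid", random_seq(rng, 5000))
        seqs = [random_seq(rng, 400) for _ in range(3)] + [plastid.seq[1000:1400]]
        gr = ring_graph(seqs, depths=[36.0, 36.0, 36.0, 40.0])
        out = filter_graph(gr, plastid_panel=[plastid])
        assert len(out.contigs) == 4

    def test_idempotent(self, rng):
        gr = ring_graph([random_seq(rng, 100) for _ in range(4)])
        gr.linkages[0] = Linkage("c1", "tail", "c2", "head", 5, 0)
        once = filter_graph(gr)
        twice = filter_graph(once)
        assert len(once.linkages) == len(twice.linkages)
        assert len(once.contigs) == len(twice.contigs)


class TestBuildMasterCircle:
    def test_single_contig_self_circle(self, rng):
        seq = random_seq(rng, 500)
        gr = ContigGraph(
            [Contig("c1", seq, 30.0)], [Linkage("c1", "tail", "c1", "head", 20, 0)]
        )
        mc = build_master_circle(gr)
        assert mc.sequence.seq == seq
        assert mc.visits == {"c1": 1}

    def test_ring_reproduces_genome(self, rng):
        seqs = [random_seq(rng, 300) for _ in range(4)]
        gr = ring_graph(seqs)
        mc = build_master_circle(gr)
        truth = CircularGenome("t", "".join(seqs))
        assert mc.sequence.rotation_equal(truth, allow_flip=True)

    def test_repeat_contig_visited_twice_matches_bruteforce(self, rng):
        # A - R - B - C - R - D ring: R must be traversed twice
        segs = {k: random_seq(rng, 200) for k in "ABCD"}
        rep = random_seq(rng, 150)
        contigs = [Contig(k, segs[k], 30.0) for k in "ABCD"] + [Contig("R", rep, 60.0)]
        links = [
            Linkage("A", "tail", "R", "head", 20, 0),
            Linkage("R", "tail", "B", "head", 20, 0),
            Linkage("B", "tail", "C", "head", 20, 0),
            Linkage("C", "tail", "R", "head", 20, 0),
            Linkage("R", "tail", "D", "head", 20, 0),
            Linkage("D", "tail", "A", "head", 20, 0),
        ]
        gr = ContigGraph(contigs, links)
        mc = build_master_circle(gr, max_visits=2)
        assert mc.visits["R"] == 2
        # brute-force oracle over all covering closed walks
        adj = _steps(gr)
        best = min(
            ln
            for _w, ln in enumerate_covering_walks(
                [(c.id, c.length) for c in contigs], adj, ("A", "+"), 2
            )
        )
        assert mc.sequence.length == best

    def test_minimality_vs_bruteforce_random_graphs(self, rng):
        # all test graphs <= 8 contigs: assembled length equals the oracle
        for trial in range(5):
            n = int(rng.integers(3, 7))
            seqs = [random_seq(rng, int(rng.integers(50, 150))) for _ in range(n)]
            gr = ring_graph(seqs)
            # add a random extra linkage to create alternative routes
            i, j = rng.integers(0, n, size=2)
            gr.linkages.append(
                Linkage(f"c{i+1}", "tail", f"c{j+1}", "head", 20, 0)
            )
            mc = build_master_circle(gr, max_visits=2)
            adj = _steps(gr)
            best = min(
                ln
                for _w, ln in enumerate_covering_walks(
                    [(c.id, c.length) for c in gr.contigs], adj, ("c1", "+"), 2
                )
            )
            assert mc.sequence.length == best

    def test_disconnected_graph_reports_components(self, rng):
        contigs = [Contig("c1", random_seq(rng, 100), 30.0), Contig("c2", random_seq(rng, 100), 30.0)]
        links = [
            Linkage("c1", "tail", "c1", "head", 20, 0),
            Linkage("c2", "tail", "c2", "head", 20, 0),
        ]
        with pytest.raises(AssemblyError, match="disconnected"):
            build_master_circle(ContigGraph(contigs, links))

    def test_overlap_consumed(self, rng):
        s1 = random_seq(rng, 300)
        s2 = random_seq(rng, 300)
        ov = 25
        c1 = Contig("c1", s1 + s2[:ov], 30.0)
        c2 = Contig("c2", s2, 30.0)
        gr = ContigGraph(
            [c1, c2],
            [
                Linkage("c1", "tail", "c2", "head", 20, ov),
                Linkage("c2", "tail", "c1", "head", 20, 0),
            ],
        )
        mc = build_master_circle(gr)
        assert mc.sequence.length == c1.length + c2.length - ov

    def test_mismatched_overlap_errors(self, rng):
        c1 = Contig("c1", random_seq(rng, 300), 30.0)
        c2 = Contig("c2", random_seq(rng, 300), 30.0)
        gr = ContigGraph(
            [c1, c2],
            [
                Linkage("c1", "tail", "c2", "head", 20, 10),
                Linkage("c2", "tail", "c1", "head", 20, 0),
            ],
        )
        with pytest.raises(AssemblyError, match="overlap"):
            build_master_circle(gr)


class TestSyntheticContigGraphs:
    def test_no_repeat_roundtrip(self, rng):
        g = CircularGenome("g", random_seq(rng, 8000))
        gr, walk = generate_contig_graph(g, mean_contig=2000, depth=36, seed=4)
        mc = build_master_circle(gr)
        assert mc.sequence.rotation_equal(g, allow_flip=True)

    def test_repeat_depth_doubled(self, rng):
        core = random_seq(rng, 800)
        seq = (
            random_seq(rng, 5000) + core + random_seq(rng, 6000)
            + core + random_seq(rng, 4000)
        )
        g = CircularGenome("g", seq)
        p1, p2 = 5000, 5000 + 800 + 6000
        gr, walk = generate_contig_graph(
            g, mean_contig=2000, depth=36, seed=9, repeat_pairs=[(p1, p2, 800)]
        )
        rep = next(c for c in gr.contigs if c.id == "repeat1")
        others = [c.depth for c in gr.contigs if c.id != "repeat1"]
        med = sorted(others)[len(others) // 2]
        assert rep.depth > 1.5 * med
        visits = sum(1 for cid, _ in walk if cid == "repeat1")
        assert visits == 2

    def test_repeat_genome_truth_walk_among_optima(self, rng):
        core = random_seq(rng, 600)
        seq = (
            random_seq(rng, 4000) + core + random_seq(rng, 5000)
            + core + random_seq(rng, 3000)
        )
        g = CircularGenome("g", seq)
        p1, p2 = 4000, 4000 + 600 + 5000
        gr, walk = generate_contig_graph(
            g, mean_contig=1500, depth=36, seed=11, repeat_pairs=[(p1, p2, 600)]
        )
        mc = build_master_circle(gr, max_visits=2)
        # linkage evidence cannot distinguish the two repeat pairings; the
        # chosen walk must at least match the truth length, and the truth
        # genome must be reachable by some co-optimal pairing
        assert mc.sequence.length == g.length

    def test_determinism(self, rng):
        g = CircularGenome("g", random_seq(rng, 8000))
        gr1, w1 = generate_contig_graph(g, 2000, 36, seed=5)
        gr2, w2 = generate_contig_graph(g, 2000, 36, seed=5)
        assert w1 == w2
        assert [(c.id, c.seq, c.depth) for c in gr1.contigs] == [
            (c.id, c.seq, c.depth) for c in gr2.contigs
        ]


class TestIO:
    def test_roundtrip_tsv(self, rng, tmp_path):
        seqs = [random_seq(rng, 200) for _ in range(3)]
        fa = tmp_path / "contigs.fasta"
        fa.write_text("".join(f">c{i+1} depth=30\n{s}\n" for i, s in enumerate(seqs)))
        tsv = tmp_path / "links.tsv"
        tsv.write_text(
            "contig1\tend1\tcontig2\tend2\tdepth\toverlap\n"
            "c1\ttail\tc2\thead\t20\t0\n"
            "c2\ttail\tc3\thead\t20\t0\n"
            "c3\ttail\tc1\thead\t20\t0\n"
        )
        gr = read_contig_graph(fa, tsv)
        assert len(gr.contigs) == 3 and len(gr.linkages) == 3
        mc = build_master_circle(gr)
        assert mc.sequence.rotation_equal(
            CircularGenome("t", "".join(seqs)), allow_flip=True
        )
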