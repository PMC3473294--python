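import numpy as np
import pytest

from mitocircle.genome_io import CircInterval, CircularGenome, revcomp
from mitocircle.matcher import (
    MatchFragment,
    MatcherError,
    find_local_matches,
    merge_fragments,
)

from conftest import mutate, random_seq
from oracles import best_local_alignments


def frag_key(f):
    return (f.orientation, f.a.start, f.a.span, f.b.start, f.b.span)


class TestFindLocalMatches:
    def test_identical_genomes_single_fragment(self, rng):
        seq = random_seq(rng, 1000)
        frs = find_local_matches(
            CircularGenome("a", seq), CircularGenome("b", seq), 80, 0.9
        )
        assert len(frs) == 1
        f = frs[0]
        assert f.a.span == 1000 and f.b.span == 1000
        assert f.identity == 1.0
        assert f.orientation == "direct"

    def test_no_shared_substring(self, rng):
        g1 = CircularGenome("a", random_seq(rng, 300))
        g2 = CircularGenome("b", random_seq(rng, 300))
        frs = find_local_matches(g1, g2, 80, 0.95)
        assert frs == []

    def test_planted_segment_vs_dp_oracle(self, rng):
        # 120-bp shared segment carrying 5 substitutions inside 300-bp seqs
        seg = random_seq(rng, 120)
        seg_m = mutate(seg, [10, 35, 60, 85, 110], rng)
        s1 = random_seq(rng, 90) + seg + random_seq(rng, 90)
        s2 = random_seq(rng, 100) + seg_m + random_seq(rng, 80)
        frs = find_local_matches(
            CircularGenome("a", s1, "linear"),
            CircularGenome("b", s2, "linear"),
            80,
            0.90,
        )
        assert len(frs) == 1
        f = frs[0]
        assert f.matches / f.aln_len >= 115 / 120
        (orient, a0, a1, b0, b1, _score) = best_local_alignments(s1, s2, 60)[0]
        assert orient == "direct"
        assert abs(f.a.start - a0) <= 2 and abs(f.a.end - a1) <= 2
        assert abs(f.b.start - b0) <= 2 and abs(f.b.end - b1) <= 2

    def test_oracle_equivalence_random_pairs(self, rng):
        # random pairs <= 500 bp with one planted (sometimes inverted) segment
        for trial in range(20):
            n = int(rng.integers(250, 500))
            seg_len = int(rng.integers(90, 160))
            seg = random_seq(rng, seg_len)
            nmut = int(rng.integers(0, seg_len // 25))
            seg_m = mutate(seg, rng.choice(seg_len, nmut, replace=False), rng)
            inverted = bool(rng.integers(0, 2))
            if inverted:
                seg_m = revcomp(seg_m)
            p1 = int(rng.integers(0, n - seg_len))
            p2 = int(rng.integers(0, n - seg_len))
            s1 = random_seq(rng, n)
            s2 = random_seq(rng, n)
            s1 = s1[:p1] + seg + s1[p1 + seg_len :]
            s2 = s2[:p2] + seg_m + s2[p2 + seg_len :]
            frs = find_local_matches(
                CircularGenome("a", s1, "linear"),
                CircularGenome("b", s2, "linear"),
                80,
                0.90,
            )
            oracle = best_local_alignments(s1, s2, 70)
            want = [o for o in oracle if o[0] == ("inverted" if inverted else "direct")]
            assert len(frs) >= 1, f"trial {trial}: planted segment missed"
            f = max(frs, key=lambda f: f.aln_len)
            orient, a0, a1, b0, b1, _ = want[0]
            assert f.orientation == orient
            assert abs(f.a.start - a0) <= 2 and abs(f.a.end - a1) <= 2
            assert abs(f.b.start - b0) <= 2 and abs(f.b.end - b1) <= 2

    def test_symmetry(self, rng):
        seg = random_seq(rng, 150)
        s1 = random_seq(rng, 200) + seg + random_seq(rng, 150)
        s2 = random_seq(rng, 100) + seg + random_seq(rng, 250)
        g1, g2 = CircularGenome("a", s1), CircularGenome("b", s2)
        fw = find_local_matches(g1, g2, 80, 0.9)
        bw = find_local_matches(g2, g1, 80, 0.9)
        assert sorted(frag_key(f) for f in fw) == sorted(
            (f.orientation, f.b.start, f.b.span, f.a.start, f.a.span) for f in bw
        )

    def test_strand_consistency(self, rng):
        seg = random_seq(rng, 150)
        s1 = random_seq(rng, 200) + seg + random_seq(rng, 150)
        s2 = random_seq(rng, 100) + seg + random_seq(rng, 250)
        g1, g2 = CircularGenome("a", s1), CircularGenome("b", s2)
        fw = find_local_matches(g1, g2, 80, 0.9)
        rc_fw = find_local_matches(g1, g2.reverse_complement(), 80, 0.9)
        L2 = g2.length
        mapped = sorted(
            (
                "inverted" if f.orientation == "direct" else "direct",
                f.a.start,
                f.a.span,
                (L2 - f.b.end) % L2,
                f.b.span,
            )
            for f in fw
        )
        assert mapped == sorted(frag_key(f) for f in rc_fw)

    def test_origin_crossing_match(self, rng):
        seg = random_seq(rng, 200)
        # the shared segment crosses genome b's origin
        s1 = random_seq(rng, 150) + seg + random_seq(rng, 150)
        s2_lin = random_seq(rng, 300) + seg
        g2 = CircularGenome("b", s2_lin[-100:] + s2_lin[:-100])
        frs = find_local_matches(CircularGenome("a", s1), g2, 80, 0.9)
        assert len(frs) == 1
        f = frs[0]
        assert f.a.span >= 195
        assert f.b.wraps(g2.length)

    def test_min_len_below_seed_rejected(self, rng):
        g = CircularGenome("a", random_seq(rng, 100))
        with pytest.raises(MatcherError):
            find_local_matches(g, g, min_len=10, min_identity=0.9)

    def test_bad_identity_rejected(self, rng):
        g = CircularGenome("a", random_seq(rng, 100))
        with pytest.raises(MatcherError):
            find_local_matches(g, g, min_len=80, min_identity=0.3)

    def test_self_mode_excludes_diagonal(self, rng):
        g = CircularGenome("a", random_seq(rng, 500))
        assert find_local_matches(g, g, 80, 0.9, mode="self") == []

    def test_self_mode_finds_planted_pair_once(self, rng):
        core = random_seq(rng, 150)
        seq = random_seq(rng, 400) + core + random_seq(rng, 300) + core + random_seq(rng, 200)
        g = CircularGenome("a", seq)
        frs = find_local_matches(g, g, 80, 0.9, mode="self")
        assert len(frs) == 1
        f = frs[0]
        assert f.a.start <= f.b.start
        assert f.orientation == "direct"

    def test_n_blocks_extension(self, rng):
        # N bases terminate seed extension: a segment split by N gives two
        # fragments, not one
        seg = random_seq(rng, 300)
        s1 = random_seq(rng, 100) + seg + random_seq(rng, 100)
        seg_n = seg[:150] + "N" * 5 + seg[155:]
        s2 = random_seq(rng, 100) + seg_n + random_seq(rng, 100)
        frs = find_local_matches(
            CircularGenome("a", s1, "linear"),
            CircularGenome("b", s2, "linear"),
            80,
            0.95,
        )
        assert len(frs) == 2


class TestMergeFragments:
    def mk(self, a_start, a_span, b_start, b_span, orient="direct", ident=1.0):
        span = max(a_span, b_span)
        return MatchFragment(
            a=CircInterval("A", a_start, a_span),
            b=CircInterval("B", b_start, b_span, "-" if orient == "inverted" else "+"),
            orientation=orient,
            matches=int(ident * span),
            aln_len=span,
        )

    def test_abutting_fragments_merge(self):
        frs = [self.mk(0, 100, 0, 100), self.mk(100, 100, 100, 100)]
        out = merge_fragments(frs, max_gap=100)
        assert len(out) == 1
        assert out[0].a.span == 200 and out[0].b.span == 200

    def test_gap_rule(self):
        frs = [self.mk(0, 100, 0, 100), self.mk(150, 100, 150, 100)]
        assert len(merge_fragments(frs, max_gap=100)) == 1
        assert len(merge_fragments(frs, max_gap=10)) == 2

    def test_gap_columns_count_as_mismatches(self):
        frs = [self.mk(0, 100, 0, 100), self.mk(150, 100, 150, 100)]
        out = merge_fragments(frs, max_gap=100)
        assert out[0].aln_len == 250
        assert out[0].matches == 200
        assert out[0].identity == pytest.approx(200 / 250)

    def test_orientation_guard(self):
        frs = [self.mk(0, 100, 0, 100), self.mk(100, 100, 300, 100, orient="inverted")]
        assert len(merge_fragments(frs, max_gap=100)) == 2

    def test_inverted_collinear_merge(self):
        # as a advances, b retreats for inverted pairs
        frs = [
            self.mk(0, 100, 300, 100, orient="inverted"),
            self.mk(100, 100, 200, 100, orient="inverted"),
        ]
        out = merge_fragments(frs, max_gap=10)
        assert len(out) == 1
        assert out[0].a.span == 200
        assert out[0].b.start == 200 and out[0].b.span == 200

    def test_mixed_genome_pairs_rejected(self):
        f1 = self.mk(0, 100, 0, 100)
        f2 = MatchFragment(
            a=CircInterval("X", 0, 100),
            b=CircInterval("B", 0, 100),
            orientation="direct",
            matches=100,
            aln_len=100,
        )
        with pytest.raises(MatcherError):
            merge_fragments([f1, f2])

    def test_wrap_aware_merge(self):
        # fragment ending at the origin merges with one starting at 0
        frs = [self.mk(900, 100, 900, 100), self.mk(0, 100, 0, 100)]
        out = merge_fragments(frs, max_gap=10, len_a=1000, len_b=1000)
        assert len(out) == 1
        assert out[0].a.span == 200
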