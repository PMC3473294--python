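import numpy as np
import pytest

from mitocircle.gene_content import (
    call_snps,
    compare_orf_sets,
    find_orfs,
    scan_motif,
    translate,
)
from mitocircle.genome_io import CircularGenome, read_gff3_cds, revcomp, write_gff3
from mitocircle.matcher import find_local_matches
from mitocircle.synteny import chain_fragments
from mitocircle.synthetic_data import (
    InversionEvent,
    SimConfig,
    generate_genome_pair,
)

from conftest import mutate, random_seq
from oracles import hamming_scan

CODONS_NO_STOP = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if translate(a + b + c) != "*"
]


def make_orf(rng, n_codons):
    body = "".join(rng.choice(CODONS_NO_STOP, size=n_codons))
    return "ATG" + body + "TAA"


class TestFindOrfs:
    def test_planted_300aa_orf(self, rng):
        orf = make_orf(rng, 299)  # ATG + 299 codons + TAA -> 300 aa
        seq = random_seq(rng, 1000) + orf + random_seq(rng, 1000)
        g = CircularGenome("g", seq, "linear")
        end = 1000 + len(orf)
        # an upstream in-frame chance ATG may legally extend the ORF; the
        # reported ORF must end at the planted stop and cover the insert
        found = [
            o for o in find_orfs(g, 100)
            if o.iv.strand == "+" and o.iv.end == end and o.aa_len >= 300
        ]
        assert len(found) == 1
        o = found[0]
        assert o.iv.start <= 1000 and (1000 - o.iv.start) % 3 == 0
        assert o.protein.startswith("M")
        assert "*" not in o.protein

    def test_orf_across_origin(self, rng):
        orf = make_orf(rng, 150)
        flank = random_seq(rng, 800)
        lin = flank + orf + random_seq(rng, 700)
        # rotate so the ORF spans the origin
        cut = 800 + len(orf) // 2
        g = CircularGenome("g", lin[cut:] + lin[:cut])
        end_fwd = (800 + len(orf) - cut) % g.length  # planted stop position
        found = [
            o for o in find_orfs(g, 100)
            if o.iv.strand == "+" and o.iv.end % g.length == end_fwd and o.aa_len >= 151
        ]
        assert len(found) == 1
        assert found[0].iv.wraps(g.length)

    def test_minus_strand_orf(self, rng):
        orf = make_orf(rng, 150)
        seq = random_seq(rng, 500) + revcomp(orf) + random_seq(rng, 500)
        g = CircularGenome("g", seq, "linear")
        found = [o for o in find_orfs(g, 100) if o.aa_len == 151]
        assert len(found) == 1
        assert found[0].iv.strand == "-"

    def test_rotation_invariance(self, rng):
        orf = make_orf(rng, 120)
        seq = random_seq(rng, 600) + orf + random_seq(rng, 400)
        g = CircularGenome("g", seq)
        off = 789
        o1 = {( (o.iv.start + off) % g.length, o.iv.strand, o.aa_len) for o in find_orfs(g.rotated(off), 100)}
        o2 = {(o.iv.start % g.length, o.iv.strand, o.aa_len) for o in find_orfs(g, 100)}
        assert o1 == o2

    def test_nested_same_frame_suppressed(self, rng):
        # an internal ATG in the same frame must not produce a second ORF
        body = "".join(np.random.default_rng(0).choice(CODONS_NO_STOP, size=200))
        orf = "ATG" + body[:150] + "ATG" + body[150:] + "TAA"
        seq = random_seq(rng, 300) + orf + random_seq(rng, 300)
        g = CircularGenome("g", seq, "linear")
        starts = [o.iv.start for o in find_orfs(g, 50) if o.iv.strand == "+"]
        assert starts.count(300) == 1
        assert 300 + 153 not in starts


class TestCompareOrfSets:
    def test_identical_genomes_no_unique(self, rng):
        orf = make_orf(rng, 150)
        seq = random_seq(rng, 2000) + orf + random_seq(rng, 2000)
        ga = CircularGenome("a", seq)
        gb = CircularGenome("b", seq)
        oa = find_orfs(ga, 100)
        ob = find_orfs(gb, 100)
        ua, ub = compare_orf_sets(oa, ob, ga, gb)
        assert ua == [] and ub == []

    def test_unique_orf_detected(self, rng):
        orf_shared = make_orf(rng, 120)
        orf_b_only = make_orf(rng, 140)
        common = random_seq(rng, 3000) + orf_shared + random_seq(rng, 2000)
        ga = CircularGenome("a", common + random_seq(rng, len(orf_b_only)))
        gb = CircularGenome("b", common + orf_b_only)
        oa = find_orfs(ga, 100)
        ob = find_orfs(gb, 100)
        ua, ub = compare_orf_sets(oa, ob, ga, gb)
        assert any(o.aa_len == 141 for o in ub)
        assert all(o.aa_len != 121 for o in ub)


class TestCallSnps:
    def test_identical_blocks_zero_snps(self, rng):
        seq = random_seq(rng, 10000)
        ga, gb = CircularGenome("a", seq), CircularGenome("b", seq)
        frs = find_local_matches(ga, gb, 80, 0.90)
        blocks = chain_fragments(frs, ga.length, gb.length, genome_a=ga, genome_b=gb)
        snps, indels = call_snps(blocks, ga, gb)
        assert snps == [] and indels == []

    def test_planted_cds_snp_effects(self, tmp_path):
        cfg = SimConfig(
            ancestor_length=40000,
            n_blocks=4,
            substitution_rate=0.0,
            seed=71,
            events=[InversionEvent(blocks=(3,))],
            gene_segments=(1,),
            n_cds_snps=4,
        )
        ga, gb, truth, _ = generate_genome_pair(cfg)
        gff = tmp_path / "ann.gff3"
        write_gff3(truth.gff3_rows, gff)
        anns = read_gff3_cds(gff)
        frs = find_local_matches(ga, gb, 80, 0.90)
        blocks = chain_fragments(frs, ga.length, gb.length, genome_a=ga, genome_b=gb)
        snps, indels = call_snps(blocks, ga, gb, anns)
        assert indels == []
        got = sorted((s.pos_a, s.ref_a, s.alt_b, s.aa_change) for s in snps)
        want = sorted((s.pos_a, s.ref_a, s.alt_a, s.effect) for s in truth.snps)
        assert got == want
        # codon-index consistency is asserted in SNPRecord.__post_init__
        for s in snps:
            assert s.gene == "gene1"
            assert s.codon_index == (s.cds_pos + 2) // 3

    def test_known_codon_change(self, tmp_path):
        # T->C at cds position 1010: codon 337, CTx -> CCx, L -> P
        rng = np.random.default_rng(5)
        n_codons = 400
        codons = list(rng.choice(CODONS_NO_STOP, size=n_codons))
        codons[335] = "CTA"  # the ATG is codon 1, so codon 337 is codons[335]
        cds = "ATG" + "".join(codons) + "TAA"
        # cds position 1010 (1-based) is codon 337 pos 2: offset 1009
        assert cds[1008:1011] == "CTA"
        flank5 = random_seq(rng, 2000)
        flank3 = random_seq(rng, 2000)
        sa = flank5 + cds + flank3
        sb = sa[: 2000 + 1009] + "C" + sa[2000 + 1010 :]
        ga, gb = CircularGenome("a", sa), CircularGenome("b", sb)
        gff = tmp_path / "ann.gff3"
        gff.write_text(
            "##gff-version 3\n"
            f"a\t.\tCDS\t{2001}\t{2000 + len(cds)}\t.\t+\t0\tgene=nad4-like\n"
        )
        anns = read_gff3_cds(gff)
        frs = find_local_matches(ga, gb, 80, 0.90)
        blocks = chain_fragments(frs, ga.length, gb.length, genome_a=ga, genome_b=gb)
        snps, _ = call_snps(blocks, ga, gb, anns)
        assert len(snps) == 1
        s = snps[0]
        assert s.cds_pos == 1010
        assert s.codon_index == 337
        assert s.aa_change == "L337P"

    def test_synonymous_change(self, tmp_path):
        rng = np.random.default_rng(6)
        codons = list(rng.choice(CODONS_NO_STOP, size=200))
        codons[99] = "CTA"
        cds = "ATG" + "".join(codons) + "TAA"
        sa = random_seq(rng, 3000) + cds + random_seq(rng, 3000)
        pos = 3000 + 3 + 99 * 3 + 2  # third position of codon 100 -> CTG
        sb = sa[:pos] + "G" + sa[pos + 1 :]
        ga, gb = CircularGenome("a", sa), CircularGenome("b", sb)
        gff = tmp_path / "ann.gff3"
        gff.write_text(f"a\t.\tCDS\t{3001}\t{3000 + len(cds)}\t.\t+\t0\tgene=g\n")
        snps, _ = call_snps(
            chain_fragments(find_local_matches(ga, gb, 80, 0.9), ga.length, gb.length, genome_a=ga, genome_b=gb),
            ga,
            gb,
            read_gff3_cds(gff),
        )
        assert len(snps) == 1
        assert snps[0].aa_change == "synonymous"


class TestScanMotif:
    def test_motif_equals_genome(self):
        g = CircularGenome("g", "ACGTACGTAC", "linear")
        hits = scan_motif(g, "ACGTACGTAC", 0)
        plus = [h for h in hits if h[0].strand == "+"]
        assert len(plus) == 1 and plus[0][1] == 0

    def test_planted_with_mismatch_budget(self, rng):
        motif = "CTATCAATCTCATAAGAGAAGAAAT"
        planted = mutate(motif, [5, 17], rng)
        seq = random_seq(rng, 3000) + planted + random_seq(rng, 3000)
        g = CircularGenome("g", seq)
        hits2 = scan_motif(g, motif, 2)
        assert any(h[0].start == 3000 and h[1] == 2 for h in hits2)
        hits1 = scan_motif(g, motif, 1)
        assert not any(h[0].start == 3000 for h in hits1)

    def test_matches_hamming_oracle(self, rng):
        seq = random_seq(rng, 500)
        motif = seq[100:120]
        g = CircularGenome("g", seq)
        got = sorted(
            (h[0].start, h[1]) for h in scan_motif(g, motif, 3) if h[0].strand == "+"
        )
        assert got == sorted(hamming_scan(seq, motif, 3))

    def test_wrap_hit(self, rng):
        motif = random_seq(rng, 30)
        lin = random_seq(rng, 1000) + motif
        g = CircularGenome("g", lin[-15:] + lin[:-15])  # motif crosses origin
        hits = scan_motif(g, motif, 0)
        assert any(h[0].wraps(g.length) for h in hits)
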