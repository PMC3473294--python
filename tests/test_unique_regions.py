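import pytest

from mitocircle.genome_io import CircInterval, CircularGenome, revcomp
from mitocircle.matcher import find_local_matches, merge_fragments
from mitocircle.synteny import chain_fragments
from mitocircle.synthetic_data import (
    InsertionEvent,
    InversionEvent,
    SimConfig,
    generate_genome_pair,
    generate_reference_panel,
)
from mitocircle.unique_regions import (
    UniqueRegion,
    detect_integration_signature,
    extract_unique_regions,
    mosaic_coverage,
    roman,
)

from conftest import random_seq


def blocks_for(ga, gb):
    frs = find_local_matches(ga, gb, 80, 0.90)
    return frs, chain_fragments(frs, ga.length, gb.length, genome_a=ga, genome_b=gb)


class TestRoman:
    @pytest.mark.parametrize("n,s", [(1, "I"), (2, "II"), (4, "IV"), (9, "IX"), (14, "XIV")])
    def test_values(self, n, s):
        assert roman(n) == s


class TestExtractUniqueRegions:
    def test_genome_vs_itself_empty(self, rng):
        seq = random_seq(rng, 8000)
        ga, gb = CircularGenome("a", seq), CircularGenome("b", seq)
        _, blocks = blocks_for(ga, gb)
        assert extract_unique_regions(gb, blocks, "B") == []

    def test_planted_insert_recovered(self):
        cfg = SimConfig(
            ancestor_length=40000,
            n_blocks=4,
            substitution_rate=0.0002,
            seed=31,
            events=[InsertionEvent(after_block=2, length=5000)],
        )
        ga, gb, truth, _ = generate_genome_pair(cfg)
        _, blocks = blocks_for(ga, gb)
        regions = extract_unique_regions(gb, blocks, "B")
        assert len(regions) == 1
        r = regions[0]
        t = truth.regions[0]
        assert abs(r.iv.start - t.b_start) <= 100
        assert abs(r.iv.span - t.span) <= 200
        assert r.region_id == "I"

    def test_regions_sorted_and_labeled(self):
        cfg = SimConfig(
            ancestor_length=60000,
            n_blocks=6,
            substitution_rate=0.0002,
            seed=37,
            events=[
                InsertionEvent(after_block=2, length=3000),
                InsertionEvent(after_block=4, length=2000),
            ],
        )
        ga, gb, truth, _ = generate_genome_pair(cfg)
        _, blocks = blocks_for(ga, gb)
        regions = extract_unique_regions(gb, blocks, "B")
        assert [r.region_id for r in regions] == ["I", "II"]
        assert regions[0].iv.start < regions[1].iv.start

    def test_tiling_with_min_report_one(self):
        cfg = SimConfig(
            ancestor_length=40000,
            n_blocks=4,
            substitution_rate=0.0002,
            seed=41,
            events=[InversionEvent(blocks=(2,)), InsertionEvent(after_block=3, length=4000)],
        )
        ga, gb, _truth, _ = generate_genome_pair(cfg)
        _, blocks = blocks_for(ga, gb)
        regions = extract_unique_regions(gb, blocks, "B", min_report=1)
        total = sum(b.iv_b.span for b in blocks) + sum(r.iv.span for r in regions)
        assert total == gb.length

    def test_minor_match_fraction(self):
        cfg = SimConfig(
            ancestor_length=40000,
            n_blocks=4,
            substitution_rate=0.0002,
            seed=43,
            events=[InsertionEvent(after_block=2, length=4000)],
        )
        ga, gb, _truth, _ = generate_genome_pair(cfg)
        frs, blocks = blocks_for(ga, gb)
        merged = merge_fragments(frs, 100, len_a=ga.length, len_b=gb.length)
        regions = extract_unique_regions(gb, blocks, "B", minor_fragments=merged)
        assert 0.0 <= regions[0].minor_match_fraction <= 1.0


class TestMosaicCoverage:
    def test_empty_panel_zero(self, rng):
        g = CircularGenome("g", random_seq(rng, 5000))
        region = UniqueRegion("I", CircInterval("g", 1000, 2000), (1, 2), 0.0)
        ann = mosaic_coverage(region, g, [])
        assert ann.coverage == 0.0

    def test_fully_sourced_insert(self):
        cfg = SimConfig(
            ancestor_length=40000,
            n_blocks=4,
            substitution_rate=0.0002,
            seed=47,
            events=[InsertionEvent(after_block=2, length=5000, unsourced_fraction=0.0)],
        )
        ga, gb, truth, panel = generate_genome_pair(cfg)
        _, blocks = blocks_for(ga, gb)
        regions = extract_unique_regions(gb, blocks, "B")
        ann = mosaic_coverage(regions[0], gb, panel)
        assert ann.coverage == pytest.approx(truth.regions[0].sourced_fraction, abs=0.02)

    def test_unsourced_fraction_lowers_coverage(self):
        cfg = SimConfig(
            ancestor_length=40000,
            n_blocks=4,
            substitution_rate=0.0002,
            seed=53,
            events=[InsertionEvent(after_block=2, length=6000, unsourced_fraction=0.3)],
        )
        ga, gb, truth, panel = generate_genome_pair(cfg)
        _, blocks = blocks_for(ga, gb)
        regions = extract_unique_regions(gb, blocks, "B")
        ann = mosaic_coverage(regions[0], gb, panel)
        assert ann.coverage == pytest.approx(truth.regions[0].sourced_fraction, abs=0.02)
        assert ann.coverage < 0.85

    def test_coverage_monotone_in_panel(self):
        cfg = SimConfig(
            ancestor_length=40000,
            n_blocks=4,
            substitution_rate=0.0002,
            seed=59,
            events=[InsertionEvent(after_block=2, length=5000)],
        )
        ga, gb, _truth, panel = generate_genome_pair(cfg)
        _, blocks = blocks_for(ga, gb)
        regions = extract_unique_regions(gb, blocks, "B")
        cov1 = mosaic_coverage(regions[0], gb, panel[:1]).coverage
        cov_all = mosaic_coverage(regions[0], gb, panel).coverage
        assert cov_all >= cov1


class TestIntegrationSignature:
    def test_random_flanks_incomplete(self, rng):
        g = CircularGenome("g", random_seq(rng, 10000))
        region = UniqueRegion("I", CircInterval("g", 3000, 2000), (1, 2), 0.0)
        sig = detect_integration_signature(region, g)
        assert not sig.complete

    def test_constructed_signature_exact(self, rng):
        outer = random_seq(rng, 176)
        inner = random_seq(rng, 28)
        insert = (
            outer + random_seq(rng, 150) + inner + random_seq(rng, 2000)
            + revcomp(inner) + random_seq(rng, 150) + revcomp(outer)
        )
        seq = random_seq(rng, 3000) + insert + random_seq(rng, 3000)
        g = CircularGenome("g", seq)
        region = UniqueRegion(
            "I", CircInterval("g", 3000, len(insert)), (1, 2), 0.0
        )
        sig = detect_integration_signature(region, g)
        assert sig.complete
        assert sig.outer_pair.length == 176
        assert sig.inner_pair.length == 28

    def test_pipeline_generated_signature(self):
        cfg = SimConfig(
            ancestor_length=40000,
            n_blocks=4,
            substitution_rate=0.0002,
            seed=61,
            events=[InsertionEvent(after_block=2, length=5000, with_signature=True)],
        )
        ga, gb, truth, _ = generate_genome_pair(cfg)
        _, blocks = blocks_for(ga, gb)
        regions = extract_unique_regions(gb, blocks, "B")
        sig = detect_integration_signature(regions[0], gb)
        assert sig.complete
        assert sig.outer_pair.length == truth.regions[0].outer_repeat == 176
        assert sig.inner_pair.length == truth.regions[0].inner_repeat == 28
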