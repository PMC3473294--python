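"""Full-comparison orchestration: one call runs every analysis stage in order
and writes a deterministic report bundle."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from mitocircle import __version__
from mitocircle.gene_content import (
    SNP_COLUMNS,
    call_snps,
    compare_orf_sets,
    find_orfs,
    locate_orf,
    snps_to_rows,
)
from mitocircle.genome_io import (
    CircularGenome,
    gc_content,
    write_bed,
    write_tsv,
)
from mitocircle.matcher import (
    FRAGMENT_COLUMNS,
    find_local_matches,
    fragments_to_rows,
    merge_fragments,
)
from mitocircle.rearrange import (
    EVENT_COLUMNS,
    diff_arrangements,
    events_to_rows,
    infer_events,
)
from mitocircle.repeats import (
    CATALOG_COLUMNS,
    build_repeat_catalog,
    catalog_to_rows,
    predict_subgenomic_circles,
)
from mitocircle.synteny import (
    DOTPLOT_COLUMNS,
    arrangements,
    chain_fragments,
    export_dotplot,
)
from mitocircle.unique_regions import (
    REGION_COLUMNS,
    detect_integration_signature,
    extract_unique_regions,
    mosaic_coverage,
    regions_to_rows,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All thresholds of the comparison pipeline (defaults match the
    analysis conventions documented per module)."""

    min_match_len: int = 80
    min_match_identity: float = 0.90
    min_block_len: int = 3000
    min_block_identity: float = 0.999
    chain_gap: int = 100
    repeat_min_len: int = 80
    repeat_min_identity: float = 0.90
    orf_min_aa: int = 100
    edge_window: int = 500
    min_exact_repeat: int = 10
    min_region_report: int = 100
    mosaic_min_hit: int = 30
    mosaic_min_identity: float = 0.80
    signature_window: int = 1000
    signature_min_repeat: int = 20
    min_link_depth: int = 10
    seed: int = 0


@dataclass
class CompareResult:
    genome_a: CircularGenome
    genome_b: CircularGenome
    fragments: list
    blocks: list
    arrangement_a: object
    arrangement_b: object
    breakpoints: list
    events: list
    catalog_a: list
    catalog_b: list
    subcircles_a: tuple | None
    subcircles_b: tuple | None
    regions_a: list
    regions_b: list
    mosaics: dict = field(default_factory=dict)
    signatures: dict = field(default_factory=dict)
    orfs_a: list = field(default_factory=list)
    orfs_b: list = field(default_factory=list)
    unique_orfs_a: list = field(default_factory=list)
    unique_orfs_b: list = field(default_factory=list)
    snps: list = field(default_factory=list)
    indels: list = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "genome_a": {"id": self.genome_a.id, "length": self.genome_a.length,
                         "gc": round(gc_content(self.genome_a), 4)},
            "genome_b": {"id": self.genome_b.id, "length": self.genome_b.length,
                         "gc": round(gc_content(self.genome_b), 4)},
            "n_blocks": len(self.blocks),
            "arrangement_a": self.arrangement_a.as_string(),
            "arrangement_b": self.arrangement_b.as_string(),
            "n_breakpoints": len(self.breakpoints),
            "n_events": len(self.events),
            "n_repeats_a": len(self.catalog_a),
            "n_repeats_b": len(self.catalog_b),
            "subcircles_a": self.subcircles_a,
            "subcircles_b": self.subcircles_b,
            "n_unique_regions_a": len(self.regions_a),
            "n_unique_regions_b": len(self.regions_b),
            "unique_span_a": sum(r.iv.span for r in self.regions_a),
            "unique_span_b": sum(r.iv.span for r in self.regions_b),
            "n_unique_orfs_a": len(self.unique_orfs_a),
            "n_unique_orfs_b": len(self.unique_orfs_b),
            "n_snps": len(self.snps),
        }


def _largest_direct(catalog):
    direct = [p for p in catalog if p.orientation == "direct"]
    return max(direct, key=lambda p: p.length) if direct else None


def run_compare(
    genome_a: CircularGenome,
    genome_b: CircularGenome,
    cfg: RunConfig | None = None,
    panel: list[CircularGenome] | None = None,
    annotations=None,
    run_orfs: bool = True,
) -> CompareResult:
    """Run every comparison stage in order.  Deterministic given inputs and
    config; stage failures propagate with the stage name attached."""
    cfg = cfg or RunConfig()
    stage = "matching"
    try:
        fragments = find_local_matches(
            genome_a, genome_b,
            min_len=cfg.min_match_len, min_identity=cfg.min_match_identity,
        )
        stage = "synteny"
        blocks = chain_fragments(
            fragments, genome_a.length, genome_b.length,
            min_block_len=cfg.min_block_len,
            min_block_identity=cfg.min_block_identity,
            chain_gap=cfg.chain_gap,
            genome_a=genome_a,
            genome_b=genome_b,
        )
        arr_a, arr_b = arrangements(blocks, genome_a, genome_b)
        stage = "repeats"
        catalog_a = build_repeat_catalog(
            genome_a, cfg.repeat_min_len, cfg.repeat_min_identity
        )
        catalog_b = build_repeat_catalog(
            genome_b, cfg.repeat_min_len, cfg.repeat_min_identity
        )
        sub_a = sub_b = None
        big_a = _largest_direct(catalog_a)
        big_b = _largest_direct(catalog_b)
        if big_a and big_a.copy1.overlap(big_a.copy2, genome_a.length) == 0:
            sub_a = predict_subgenomic_circles(genome_a.length, big_a)
        if big_b and big_b.copy1.overlap(big_b.copy2, genome_b.length) == 0:
            sub_b = predict_subgenomic_circles(genome_b.length, big_b)
        stage = "unique_regions"
        merged = merge_fragments(
            fragments, max_gap=cfg.chain_gap,
            len_a=genome_a.length, len_b=genome_b.length,
        )
        regions_a = extract_unique_regions(
            genome_a, blocks, "A", merged, cfg.min_region_report
        )
        regions_b = extract_unique_regions(
            genome_b, blocks, "B", merged, cfg.min_region_report
        )
        stage = "rearrangements"
        breakpoints = diff_arrangements(arr_a, arr_b)
        events = infer_events(
            breakpoints, blocks, arr_a, arr_b, genome_a, genome_b,
            catalog_a, catalog_b,
            edge_window=cfg.edge_window,
            min_exact_repeat=cfg.min_exact_repeat,
            unique_regions_b=regions_b,
        )
        stage = "mosaic"
        mosaics = {}
        signatures = {}
        for r in regions_b:
            if panel:
                mosaics[r.region_id] = mosaic_coverage(
                    r, genome_b, panel, cfg.mosaic_min_hit, cfg.mosaic_min_identity
                )
            signatures[r.region_id] = detect_integration_signature(
                r, genome_b, cfg.signature_window, cfg.signature_min_repeat
            )
        stage = "orfs"
        orfs_a = orfs_b = []
        unique_a = unique_b = []
        if run_orfs:
            orfs_a = find_orfs(genome_a, cfg.orf_min_aa)
            orfs_b = find_orfs(genome_b, cfg.orf_min_aa)
            unique_a, unique_b = compare_orf_sets(orfs_a, orfs_b, genome_a, genome_b)
        stage = "snps"
        snps, indels = call_snps(blocks, genome_a, genome_b, annotations)
    except Exception as exc:  # noqa: BLE001 - annotate and re-raise
        raise type(exc)(f"[stage: {stage}] {exc}") from exc
    return CompareResult(
        genome_a=genome_a, genome_b=genome_b,
        fragments=fragments, blocks=blocks,
        arrangement_a=arr_a, arrangement_b=arr_b,
        breakpoints=breakpoints, events=events,
        catalog_a=catalog_a, catalog_b=catalog_b,
        subcircles_a=sub_a, subcircles_b=sub_b,
        regions_a=regions_a, regions_b=regions_b,
        mosaics=mosaics, signatures=signatures,
        orfs_a=orfs_a, orfs_b=orfs_b,
        unique_orfs_a=unique_a, unique_orfs_b=unique_b,
        snps=snps, indels=indels,
    )


def write_bundle(result: CompareResult, cfg: RunConfig, outdir: str | Path) -> None:
    """Write the full report bundle (TSV/BED/JSON) plus the resolved config."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ga, gb = result.genome_a, result.genome_b

    with open(out / "run_config.json", "w") as fh:
        json.dump({"version": __version__, "config": asdict(cfg)}, fh, indent=2)

    write_tsv(fragments_to_rows(result.fragments), out / "fragments.tsv", FRAGMENT_COLUMNS)
    block_rows = [
        {
            "block_id": b.block_id,
            "a_start": b.iv_a.start + 1, "a_end": b.iv_a.end,
            "b_start": b.iv_b.start + 1, "b_end": b.iv_b.end,
            "orientation": b.orientation, "identity": f"{b.identity:.6f}",
        }
        for b in result.blocks
    ]
    write_tsv(block_rows, out / "blocks.tsv",
              ["block_id", "a_start", "a_end", "b_start", "b_end", "orientation", "identity"])
    write_bed([(b.iv_a, f"block_{b.block_id}") for b in result.blocks],
              out / "blocks_a.bed", ga.length)
    write_bed([(b.iv_b, f"block_{b.block_id}") for b in result.blocks],
              out / "blocks_b.bed", gb.length)
    with open(out / "arrangements.txt", "w") as fh:
        fh.write(f"{ga.id}\t{result.arrangement_a.as_string()}\n")
        fh.write(f"{gb.id}\t{result.arrangement_b.as_string()}\n")
    write_tsv(export_dotplot(result.blocks), out / "dotplot.tsv", DOTPLOT_COLUMNS)
    write_tsv(catalog_to_rows(result.catalog_a), out / "repeats_a.tsv", CATALOG_COLUMNS)
    write_tsv(catalog_to_rows(result.catalog_b), out / "repeats_b.tsv", CATALOG_COLUMNS)
    write_tsv(events_to_rows(result.events), out / "events.tsv", EVENT_COLUMNS)
    write_tsv(regions_to_rows(result.regions_a), out / "unique_regions_a.tsv", REGION_COLUMNS)
    write_tsv(regions_to_rows(result.regions_b), out / "unique_regions_b.tsv", REGION_COLUMNS)
    write_tsv(snps_to_rows(result.snps), out / "snps.tsv", SNP_COLUMNS)
    orf_rows = []
    for which, orfs in (("A", result.unique_orfs_a), ("B", result.unique_orfs_b)):
        genome = ga if which == "A" else gb
        regions = result.regions_a if which == "A" else result.regions_b
        for o in orfs:
            orf_rows.append(
                {
                    "genome": which, "name": o.name,
                    "start": o.iv.start + 1, "end": o.iv.end,
                    "strand": o.iv.strand, "aa_len": o.aa_len,
                    "location": locate_orf(o, result.blocks, regions, which, genome.length),
                }
            )
    write_tsv(orf_rows, out / "unique_orfs.tsv",
              ["genome", "name", "start", "end", "strand", "aa_len", "location"])
    mosaic_rows = [
        {
            "region_id": rid, "covered": m.covered,
            "coverage": f"{m.coverage:.4f}", "n_hits": len(m.hits),
        }
        for rid, m in sorted(result.mosaics.items())
    ]
    write_tsv(mosaic_rows, out / "mosaic_coverage.tsv",
              ["region_id", "covered", "coverage", "n_hits"])
    sig_rows = []
    for rid, s in sorted(result.signatures.items()):
        sig_rows.append(
            {
                "region_id": rid,
                "outer_len": s.outer_pair.length if s.outer_pair else 0,
                "inner_len": s.inner_pair.length if s.inner_pair else 0,
                "complete": s.complete,
            }
        )
    write_tsv(sig_rows, out / "integration_signatures.tsv",
              ["region_id", "outer_len", "inner_len", "complete"])
    from mitocircle.genome_io import write_gff3

    write_bed(
        [(r.iv, f"unique_{r.region_id}") for r in result.regions_b],
        out / "unique_regions_b.bed",
        gb.length,
    )
    write_gff3(
        [
            {
                "seqid": (ga if which == "A" else gb).id,
                "type": "ORF",
                "start": o.iv.start,
                "end": min(o.iv.end, (ga if which == "A" else gb).length),
                "strand": o.iv.strand,
                "attributes": f"ID={o.name}_{which}",
            }
            for which, orfs in (("A", result.unique_orfs_a), ("B", result.unique_orfs_b))
            for o in orfs
        ],
        out / "unique_orfs.gff3",
    )
    write_gff3(
        [
            {
                "seqid": ga.id,
                "type": "sequence_variant",
                "start": s.pos_a,
                "end": s.pos_a + 1,
                "strand": "+",
                "attributes": (
                    f"ref={s.ref_a};alt={s.alt_b};gene={s.gene or '.'};"
                    f"effect={s.aa_change or '.'}"
                ),
            }
            for s in result.snps
        ],
        out / "snps.gff3",
    )
    with open(out / "summary.json", "w") as fh:
        json.dump(result.summary(), fh, indent=2)
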