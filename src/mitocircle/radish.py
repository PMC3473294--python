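"""Headline analysis of the two deposited radish mitochondrial genomes.

The deposited accessions are DDBJ AB694743 (normal-type cytoplasm, 244,036
bp) and AB694744 (Ogura-type male-sterile cytoplasm, 258,426 bp).  Genome A
is the normal type by convention; every quantity below is recomputed from
the sequences with the package's default thresholds.

The sequences are not bundled with the package; download them once, e.g.:

    https://www.ncbi.nlm.nih.gov/nuccore/AB694743 (send to FASTA)
    https://www.ncbi.nlm.nih.gov/nuccore/AB694744

and place them as data/genomes/AB694743.fasta and data/genomes/AB694744.fasta.
"""

from __future__ import annotations

from pathlib import Path

from mitocircle.genome_io import CircularGenome, gc_content, load_genome
from mitocircle.matcher import find_local_matches
from mitocircle.repeats import build_repeat_catalog, predict_subgenomic_circles
from mitocircle.synteny import chain_fragments
from mitocircle.unique_regions import detect_integration_signature, extract_unique_regions

NORMAL_ACCESSION = "AB694743"
OGURA_ACCESSION = "AB694744"

#: every quantity computed by :func:`compute_targets`
TARGET_IDS = ["t1", "t2", "t3", "t4", "t5", "t6", "t7", "t8", "t11", "t12"]


def find_deposited_genomes(root: str | Path) -> tuple[Path, Path] | None:
    """Locate the two deposited FASTAs under ``root`` (searched recursively);
    returns (normal_path, ogura_path) or None if either is missing."""
    root = Path(root)
    if not root.exists():
        return None
    normal = ogura = None
    for p in sorted(root.rglob("*.f*a")) + sorted(root.rglob("*.fasta")):
        name = p.name.upper()
        if NORMAL_ACCESSION in name:
            normal = p
        elif OGURA_ACCESSION in name:
            ogura = p
    if normal and ogura:
        return normal, ogura
    return None


def _largest_direct(catalog):
    direct = [p for p in catalog if p.orientation == "direct"]
    return max(direct, key=lambda p: p.length) if direct else None


def compute_targets(
    normal_path: str | Path, ogura_path: str | Path
) -> dict[str, dict[str, float | int]]:
    """Recompute the headline numbers of the radish genome comparison.

    Returns ``{target_id: {"value": ..., "n": problem size}}`` with:

    t1  number of syntenic regions >3 kb at >=99.9% identity
    t2  length (bp) of the largest Ogura-type repeat pair
    t3  length (bp) of the largest normal-type repeat pair
    t4  larger predicted Ogura-type sub-genomic circle (bp)
    t5  larger predicted normal-type sub-genomic circle (bp)
    t6  total Ogura-type unique-region span (bp)
    t7  span of the largest Ogura-type unique region (bp)
    t8  number of short (<1 kb) Ogura-type repeat pairs
    t11 GC content (%) of the deposited genomes
    t12 exact inverted-repeat length (bp) flanking the largest unique region
    """
    ga = load_genome(normal_path)
    gb = load_genome(ogura_path)
    n_pair = ga.length + gb.length

    fragments = find_local_matches(ga, gb, min_len=80, min_identity=0.90)
    blocks = chain_fragments(
        fragments, ga.length, gb.length, min_block_len=3000,
        min_block_identity=0.999, genome_a=ga, genome_b=gb,
    )

    catalog_a = build_repeat_catalog(ga, min_len=80, min_identity=0.90)
    catalog_b = build_repeat_catalog(gb, min_len=80, min_identity=0.90)

    out: dict[str, dict] = {}
    out["t1"] = {"value": len(blocks), "n": n_pair}
    if catalog_b:
        out["t2"] = {"value": catalog_b[0].length, "n": gb.length}
    if catalog_a:
        out["t3"] = {"value": catalog_a[0].length, "n": ga.length}

    big_b = _largest_direct(catalog_b)
    if big_b is not None and big_b.copy1.overlap(big_b.copy2, gb.length) == 0:
        out["t4"] = {
            "value": max(predict_subgenomic_circles(gb.length, big_b)),
            "n": gb.length,
        }
    big_a = _largest_direct(catalog_a)
    if big_a is not None and big_a.copy1.overlap(big_a.copy2, ga.length) == 0:
        out["t5"] = {
            "value": max(predict_subgenomic_circles(ga.length, big_a)),
            "n": ga.length,
        }

    regions_b = extract_unique_regions(gb, blocks, "B", min_report=100)
    out["t6"] = {"value": sum(r.iv.span for r in regions_b), "n": gb.length}
    if regions_b:
        largest = max(regions_b, key=lambda r: r.iv.span)
        out["t7"] = {"value": largest.iv.span, "n": gb.length}
        sig = detect_integration_signature(largest, gb)
        if sig.outer_pair is not None:
            out["t12"] = {"value": sig.outer_pair.length, "n": gb.length}

    # counting convention: catalog pairs in the short size class (<1 kb);
    # the large pair (and any pair >=1 kb) is excluded
    out["t8"] = {
        "value": sum(1 for p in catalog_b if p.size_class == "short"),
        "n": gb.length,
    }

    gc_a = round(gc_content(ga) * 100, 1)
    gc_b = round(gc_content(gb) * 100, 1)
    out["t11"] = {
        "value": gc_a if gc_a == gc_b else round((gc_a + gc_b) / 2, 2),
        "n": n_pair,
    }
    return out
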