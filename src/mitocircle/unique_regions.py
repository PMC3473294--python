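"""Non-syntenic region extraction, mosaic annotation, integration signatures.

"Unique" means: outside every syntenic block with the partner genome.
Sub-threshold similarity to the partner is reported as a minor-match fraction
rather than shrinking the region.  Mosaic coverage merges panel hits on
region coordinates regardless of orientation or panel member.  The
integration signature is a nested pair of exact inverted repeats at the two
region/block junctions.
"""

from __future__ import annotations

from dataclasses import dataclass

from mitocircle.genome_io import CircInterval, CircularGenome
from mitocircle.matcher import MatchFragment, find_local_matches
from mitocircle.rearrange import find_exact_repeats_between
from mitocircle.synteny import SyntenicBlock, _complement_intervals

DEFAULT_MIN_REPORT = 100
DEFAULT_MIN_HIT = 30
DEFAULT_MIN_HIT_IDENTITY = 0.80
DEFAULT_SEARCH_WINDOW = 1000
DEFAULT_MIN_SIGNATURE_REPEAT = 20

_ROMAN = [
    (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"), (90, "XC"),
    (50, "L"), (40, "XL"), (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I"),
]


def roman(n: int) -> str:
    out = []
    for v, sym in _ROMAN:
        while n >= v:
            out.append(sym)
            n -= v
    return "".join(out)


@dataclass(frozen=True)
class UniqueRegion:
    region_id: str  # roman numeral, coordinate order
    iv: CircInterval
    flanking_blocks: tuple[int, int]  # (upstream block id, downstream block id)
    minor_match_fraction: float


@dataclass(frozen=True)
class MosaicHit:
    panel_genome_id: str
    region_sub: CircInterval  # on region-local coordinates
    panel_iv: CircInterval
    orientation: str
    identity: float


@dataclass(frozen=True)
class MosaicAnnotation:
    region_id: str
    hits: tuple[MosaicHit, ...]
    covered: int
    coverage: float


@dataclass(frozen=True)
class InvertedPair:
    length: int
    pos1: int  # genome coordinate of the copy near the left junction
    pos2: int  # genome coordinate of the copy near the right junction


@dataclass(frozen=True)
class IntegrationSignature:
    region_id: str
    outer_pair: InvertedPair | None
    inner_pair: InvertedPair | None
    complete: bool


def extract_unique_regions(
    g: CircularGenome,
    blocks: list[SyntenicBlock],
    which: str,
    minor_fragments: list[MatchFragment] | None = None,
    min_report: int = DEFAULT_MIN_REPORT,
) -> list[UniqueRegion]:
    """Complement of the syntenic blocks on genome ``which`` ("A" or "B"),
    filtered to span >= min_report, labeled I, II, ... in coordinate order.

    ``minor_fragments`` (sub-threshold matches to the partner genome, on the
    same genome side) feed the minor-match fraction of each region.
    """
    key = "iv_a" if which == "A" else "iv_b"
    ivs = sorted((getattr(b, key) for b in blocks), key=lambda iv: iv.start)
    if not blocks:
        gaps = [CircInterval(g.id, 0, g.length)]
    else:
        gaps = _complement_intervals(ivs, g.length, g.id)
    gaps = [iv for iv in gaps if iv.span >= min_report]
    regions = []
    for i, iv in enumerate(sorted(gaps, key=lambda iv: iv.start)):
        up, down = _flanking(iv, blocks, key, g.length)
        frac = _minor_fraction(iv, minor_fragments or [], which, g.length)
        regions.append(
            UniqueRegion(
                region_id=roman(i + 1),
                iv=iv,
                flanking_blocks=(up, down),
                minor_match_fraction=frac,
            )
        )
    return regions


def _flanking(
    iv: CircInterval, blocks: list[SyntenicBlock], key: str, L: int
) -> tuple[int, int]:
    if not blocks:
        return (0, 0)
    up = min(
        blocks,
        key=lambda b: (iv.start - getattr(b, key).end % L) % L,
    )
    down = min(
        blocks,
        key=lambda b: (getattr(b, key).start - iv.end % L) % L,
    )
    return (up.block_id, down.block_id)


def _minor_fraction(
    iv: CircInterval, fragments: list[MatchFragment], which: str, L: int
) -> float:
    if not fragments:
        return 0.0
    import numpy as np

    mask = np.zeros(iv.span, dtype=bool)
    for f in fragments:
        fiv = f.a if which == "A" else f.b
        off = (fiv.start % L - iv.start % L) % L
        span = min(fiv.span, L)
        if off < iv.span:
            mask[off : min(off + span, iv.span)] = True
        wrap_end = off + span - L
        if wrap_end > 0:
            mask[: min(wrap_end, iv.span)] = True
    return int(mask.sum()) / iv.span


def mosaic_coverage(
    region: UniqueRegion,
    genome: CircularGenome,
    panel: list[CircularGenome],
    min_hit: int = DEFAULT_MIN_HIT,
    min_identity: float = DEFAULT_MIN_HIT_IDENTITY,
    k: int = 15,
) -> MosaicAnnotation:
    """Fraction of the region covered by local matches to any panel genome.

    Hits are merged on region coordinates (orientation and donor identity
    ignored), matching the usual black-box mosaic presentation.
    """
    region_seq = genome.fetch(region.iv.start, region.iv.span)
    region_g = CircularGenome(f"region_{region.region_id}", region_seq, "linear")
    hits: list[MosaicHit] = []
    for donor in panel:
        if region_g.length < k:
            continue
        frags = find_local_matches(
            region_g, donor, min_len=max(min_hit, k), min_identity=min_identity, k=k
        )
        for f in frags:
            hits.append(
                MosaicHit(
                    panel_genome_id=donor.id,
                    region_sub=f.a,
                    panel_iv=f.b,
                    orientation=f.orientation,
                    identity=f.identity,
                )
            )
    covered_mask = [False] * region.iv.span
    for h in hits:
        for p in range(h.region_sub.start, min(h.region_sub.end, region.iv.span)):
            covered_mask[p] = True
    covered = sum(covered_mask)
    return MosaicAnnotation(
        region_id=region.region_id,
        hits=tuple(hits),
        covered=covered,
        coverage=covered / region.iv.span if region.iv.span else 0.0,
    )


def detect_integration_signature(
    region: UniqueRegion,
    g: CircularGenome,
    search_window: int = DEFAULT_SEARCH_WINDOW,
    min_repeat: int = DEFAULT_MIN_SIGNATURE_REPEAT,
) -> IntegrationSignature:
    """Nested exact inverted-repeat pairs at the two region/block junctions.

    The outer pair is the longest exact inverted repeat with one copy within
    ``search_window`` of each junction; the inner pair is the longest exact
    inverted repeat strictly inside the outer copies.  ``complete`` requires
    both.
    """
    L = g.length
    left_junction = region.iv.start % L
    right_junction = region.iv.end % L
    w1 = _junction_window(left_junction, search_window, g)
    w2 = _junction_window(right_junction, search_window, g)
    outer = _longest_inverted(g, w1, w2, min_repeat)
    inner = None
    if outer is not None:
        in_lo = (outer.pos1 + outer.length) % L
        in_hi = outer.pos2  # start of the right outer copy
        inner_span = (in_hi - in_lo) % L
        if inner_span > 2 * min_repeat:
            iw1 = CircInterval(g.id, in_lo, min(search_window, inner_span))
            iw2_start = (in_hi - min(search_window, inner_span)) % L
            iw2 = CircInterval(g.id, iw2_start, min(search_window, inner_span))
            cand = _longest_inverted(g, iw1, iw2, min_repeat)
            if cand is not None and _strictly_inside(cand, outer, L):
                inner = cand
    return IntegrationSignature(
        region_id=region.region_id,
        outer_pair=outer,
        inner_pair=inner,
        complete=outer is not None and inner is not None,
    )


def _junction_window(junction: int, half: int, g: CircularGenome) -> CircInterval:
    span = min(2 * half, g.length)
    return CircInterval(g.id, (junction - half) % g.length, span)


def _longest_inverted(
    g: CircularGenome, w1: CircInterval, w2: CircInterval, min_repeat: int
) -> InvertedPair | None:
    hits = [
        h for h in find_exact_repeats_between(g, w1, w2, min_repeat) if h[0] == "inverted"
    ]
    if not hits:
        return None
    _, p1, p2, ln = hits[0]  # sorted longest-first
    return InvertedPair(length=ln, pos1=p1, pos2=p2)


def _strictly_inside(inner: InvertedPair, outer: InvertedPair, L: int) -> bool:
    off_in1 = (inner.pos1 - outer.pos1) % L
    off_in2 = (inner.pos2 + inner.length - outer.pos1) % L
    outer_extent = (outer.pos2 + outer.length - outer.pos1) % L
    return (
        off_in1 >= outer.length
        and off_in2 <= outer_extent - outer.length
    )


REGION_COLUMNS = ["region_id", "start", "end", "span", "flank_up", "flank_down", "minor_match_fraction"]


def regions_to_rows(regions: list[UniqueRegion]) -> list[dict]:
    return [
        {
            "region_id": r.region_id,
            "start": r.iv.start + 1,
            "end": r.iv.end,
            "span": r.iv.span,
            "flank_up": r.flanking_blocks[0],
            "flank_down": r.flanking_blocks[1],
            "minor_match_fraction": f"{r.minor_match_fraction:.4f}",
        }
        for r in regions
    ]
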