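"""Syntenic-block chaining and signed circular block arrangements.

Blocks are maximal chains of collinear same-orientation match fragments that
pass the length and identity thresholds on both genomes.  Each genome is then
expressed as a signed circular ordering of block ids (+k direct, -k inverted
relative to genome A).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from mitocircle.genome_io import CircInterval, CircularGenome
from mitocircle.matcher import MatchFragment, merge_fragments

DEFAULT_MIN_BLOCK_LEN = 3000
DEFAULT_MIN_BLOCK_IDENTITY = 0.999
#: chaining tolerance when building blocks out of merged fragments
DEFAULT_CHAIN_GAP = 100


class SyntenyError(ValueError):
    pass


@dataclass(frozen=True)
class SyntenicBlock:
    block_id: int
    iv_a: CircInterval
    iv_b: CircInterval
    orientation: str  # "direct" | "inverted"
    identity: float


@dataclass(frozen=True)
class BlockArrangement:
    genome_id: str
    order: tuple[int, ...]  # signed block ids, circular
    gaps: tuple[CircInterval, ...]

    def as_string(self) -> str:
        return " ".join(f"{'+' if s > 0 else '-'}{abs(s)}" for s in self.order)


def chain_fragments(
    frs: list[MatchFragment],
    len_a: int,
    len_b: int,
    min_block_len: int = DEFAULT_MIN_BLOCK_LEN,
    min_block_identity: float = DEFAULT_MIN_BLOCK_IDENTITY,
    chain_gap: int = DEFAULT_CHAIN_GAP,
    genome_a: "CircularGenome | None" = None,
    genome_b: "CircularGenome | None" = None,
) -> list[SyntenicBlock]:
    """Chain cross-mode fragments into syntenic blocks.

    Fragments are merged with wrap-aware collinear chaining, filtered to
    ``>= min_block_len`` on both genomes and ``>= min_block_identity``, then
    per-genome overlaps are trimmed at the overlap midpoint (adjusting both
    intervals to preserve the a<->b correspondence).  Ids are assigned 1..n in
    genome-A coordinate order.

    When the genome sequences are supplied, block edges are first trimmed
    back to runs of exact matches: score-maximal extension leaves a few
    net-positive chance-matching columns past each junction, which would
    otherwise both blur the boundary and drag a mid-size block's identity
    below the threshold.
    """
    if not frs:
        return []
    ga = {f.a.genome_id for f in frs}
    gb = {f.b.genome_id for f in frs}
    if len(ga) > 1 or len(gb) > 1:
        raise SyntenyError("fragment list mixes genome pairs")

    chained = merge_fragments(frs, max_gap=chain_gap, len_a=len_a, len_b=len_b)
    if genome_a is not None and genome_b is not None:
        chained = [
            t for f in chained
            if (t := _trim_to_match_runs(f, genome_a, genome_b)) is not None
        ]
    kept = [
        f
        for f in chained
        if f.a.span >= min_block_len
        and f.b.span >= min_block_len
        and f.identity >= min_block_identity
    ]
    kept = _trim_overlaps(kept, len_a, len_b)
    kept = [
        f for f in kept if f.a.span >= min_block_len and f.b.span >= min_block_len
    ]
    kept.sort(key=lambda f: (f.a.start % len_a, f.b.start % len_b))
    return [
        SyntenicBlock(
            block_id=i + 1,
            iv_a=replace(f.a, start=f.a.start % len_a),
            iv_b=replace(f.b, start=f.b.start % len_b),
            orientation=f.orientation,
            identity=f.identity,
        )
        for i, f in enumerate(kept)
    ]


def _trim_to_match_runs(
    f: MatchFragment,
    genome_a: CircularGenome,
    genome_b: CircularGenome,
    run_len: int = 10,
) -> MatchFragment | None:
    """Trim both fragment ends back to the outermost run of ``run_len``
    consecutive exact matches; recompute matches over the kept columns.
    Only meaningful for equal-span (ungapped) fragments; others pass through.
    """
    import numpy as np

    if f.a.span != f.b.span:
        return f
    sa = genome_a.fetch(f.a.start % genome_a.length, f.a.span)
    sb = genome_b.fetch(f.b.start % genome_b.length, f.b.span)
    if f.orientation == "inverted":
        from mitocircle.genome_io import revcomp

        sb = revcomp(sb)
    a1 = np.frombuffer(sa.encode(), dtype=np.uint8)
    a2 = np.frombuffer(sb.encode(), dtype=np.uint8)
    eq = (a1 == a2) & (a1 != ord("N"))
    n = eq.size
    if n < run_len:
        return None
    c = np.cumsum(np.concatenate([[0], eq.view(np.int8)]))
    w = c[run_len:] - c[:-run_len]
    full = np.nonzero(w == run_len)[0]
    if full.size == 0:
        return None
    i0 = int(full[0])
    i1 = int(full[-1]) + run_len
    matches = int(c[i1] - c[i0])
    g = _cut(f, "a", "start", i0)
    g = _cut(g, "a", "end", n - i1)
    return MatchFragment(
        a=g.a, b=g.b, orientation=g.orientation,
        matches=min(matches, max(g.a.span, g.b.span)),
        aln_len=max(g.a.span, g.b.span),
    )


def _trim_overlaps(frs: list[MatchFragment], len_a: int, len_b: int) -> list[MatchFragment]:
    """Midpoint-trim pairwise overlaps on each genome, keeping a/b intervals in
    correspondence (ungapped assumption: one trimmed base on one genome is one
    trimmed base, same alignment column, on the other)."""
    frs = list(frs)
    for side in ("a", "b"):
        L = len_a if side == "a" else len_b
        frs.sort(key=lambda f: getattr(f, side).start % L)
        for i in range(len(frs)):
            for j in range(len(frs)):
                if i == j:
                    continue
                fi, fj = frs[i], frs[j]
                ivi, ivj = getattr(fi, side), getattr(fj, side)
                ov = ivi.overlap(ivj, L)
                if ov <= 0:
                    continue
                cut_i = ov // 2
                cut_j = ov - cut_i
                # the overlap sits at i's end and j's start iff j starts
                # inside i (wrap-aware); otherwise the mirror case
                if (ivj.start % L - ivi.start % L) % L < ivi.span:
                    frs[i] = _cut(fi, side, "end", cut_i)
                    frs[j] = _cut(fj, side, "start", cut_j)
                else:
                    frs[i] = _cut(fi, side, "start", cut_i)
                    frs[j] = _cut(fj, side, "end", cut_j)
    return [f for f in frs if f.a.span > 0 and f.b.span > 0]


def _cut(f: MatchFragment, side: str, which_end: str, n: int) -> MatchFragment:
    """Remove n alignment columns from the stated end of the fragment's
    ``side`` interval, trimming the partner interval correspondingly."""
    if n <= 0:
        return f
    n = min(n, f.a.span - 1, f.b.span - 1)
    if n <= 0:
        return f
    a, b = f.a, f.b
    if side == "a":
        trim_a_start = which_end == "start"
    else:
        # which end of b faces the overlap; map to alignment-column end
        if f.orientation == "direct":
            trim_a_start = which_end == "start"
        else:
            trim_a_start = which_end == "end"
    if trim_a_start:
        a = replace(a, start=a.start + n, span=a.span - n)
        if f.orientation == "direct":
            b = replace(b, start=b.start + n, span=b.span - n)
        else:
            b = replace(b, span=b.span - n)  # '-' strand: a-start columns are at b-end
    else:
        a = replace(a, span=a.span - n)
        if f.orientation == "direct":
            b = replace(b, span=b.span - n)
        else:
            b = replace(b, start=b.start + n, span=b.span - n)
    matches = max(0, min(f.matches, max(a.span, b.span)))
    return MatchFragment(a=a, b=b, orientation=f.orientation, matches=matches, aln_len=max(a.span, b.span))


def block_arrangement(
    blocks: list[SyntenicBlock],
    which: str,
    genome_length: int,
    genome_id: str | None = None,
) -> BlockArrangement:
    """Signed circular block order on genome ``which`` ("A" or "B"), with the
    complementary gap intervals."""
    if which not in ("A", "B"):
        raise SyntenyError(f"which must be 'A' or 'B', got {which!r}")
    if not blocks:
        return BlockArrangement(genome_id or "", (), ())
    key = "iv_a" if which == "A" else "iv_b"
    ivs = [(getattr(b, key), b) for b in blocks]
    gid = genome_id or ivs[0][0].genome_id
    # overlap check (precondition)
    for i in range(len(ivs)):
        for j in range(i + 1, len(ivs)):
            if ivs[i][0].overlap(ivs[j][0], genome_length) > 0:
                raise SyntenyError(
                    f"blocks {ivs[i][1].block_id} and {ivs[j][1].block_id} overlap on genome {which}"
                )
    ivs.sort(key=lambda t: t[0].start)
    order = []
    for iv, b in ivs:
        if which == "A":
            order.append(b.block_id)
        else:
            order.append(b.block_id if b.orientation == "direct" else -b.block_id)
    gaps = _complement_intervals([iv for iv, _ in ivs], genome_length, gid)
    return BlockArrangement(gid, tuple(order), tuple(gaps))


def _complement_intervals(
    ivs: list[CircInterval], genome_length: int, genome_id: str
) -> list[CircInterval]:
    """Complement of non-overlapping intervals on the circle, in coordinate order."""
    if not ivs:
        return [CircInterval(genome_id, 0, genome_length)]
    ivs = sorted(ivs, key=lambda iv: iv.start)
    gaps: list[CircInterval] = []
    for cur, nxt in zip(ivs, ivs[1:] + [ivs[0]]):
        gap_start = cur.end % genome_length
        gap_span = (nxt.start - cur.end) % genome_length
        if gap_span > 0 and gap_span < genome_length:
            gaps.append(CircInterval(genome_id, gap_start, gap_span))
    return sorted(gaps, key=lambda iv: iv.start)


def arrangements(
    blocks: list[SyntenicBlock], genome_a: CircularGenome, genome_b: CircularGenome
) -> tuple[BlockArrangement, BlockArrangement]:
    arr_a = block_arrangement(blocks, "A", genome_a.length, genome_a.id)
    arr_b = block_arrangement(blocks, "B", genome_b.length, genome_b.id)
    return arr_a, arr_b


# ---------------------------------------------------------------------------
# Dot-plot export
# ---------------------------------------------------------------------------

DOTPLOT_COLUMNS = ["a_start", "a_end", "b_start", "b_end", "orientation", "label"]


def export_dotplot(items: list) -> list[dict]:
    """Segment-endpoint table for external dot-plot rendering.  Accepts
    MatchFragments or SyntenicBlocks; inverted segments encode negative slope
    (b_start > b_end)."""
    rows = []
    for it in items:
        if isinstance(it, SyntenicBlock):
            a, b, orient, label = it.iv_a, it.iv_b, it.orientation, f"block_{it.block_id}"
        else:
            a, b, orient, label = it.a, it.b, it.orientation, "fragment"
        if orient == "direct":
            b0, b1 = b.start, b.end
        else:
            b0, b1 = b.end, b.start
        rows.append(
            {
                "a_start": a.start,
                "a_end": a.end,
                "b_start": b0,
                "b_end": b1,
                "orientation": orient,
                "label": label,
            }
        )
    return rows
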