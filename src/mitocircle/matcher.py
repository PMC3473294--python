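"""Local near-identical matching between (or within) circular genomes.

Deterministic seed-and-extend: exact k-mer seeds hashed over the doubled
circular sequences, diagonal run grouping, ungapped X-drop extension, and
fragment merging.  Identity is matches / alignment columns; gap columns
introduced by merging count as mismatches.  N bases never extend a match.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from mitocircle.genome_io import CircInterval, CircularGenome

DEFAULT_K = 15
DEFAULT_XDROP = 20
#: max distance between seed starts on one diagonal for run grouping
SEED_RUN_GAP = 120

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
_RC = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


class MatcherError(ValueError):
    pass


@dataclass(frozen=True)
class MatchFragment:
    """One ungapped-ish local alignment between two (possibly identical) genomes."""

    a: CircInterval
    b: CircInterval
    orientation: str  # "direct" | "inverted"
    matches: int
    aln_len: int

    @property
    def identity(self) -> float:
        return self.matches / self.aln_len

    def swapped(self) -> "MatchFragment":
        return replace(self, a=self.b, b=self.a)


def encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(codes, positions) of all N-free k-mers in ``arr``."""
    n = arr.size
    if n < k:
        return np.empty(0, dtype=np.int32), np.empty(0, dtype=np.int64)
    if 4**k >= 2**31:
        raise MatcherError(f"seed length {k} too large for 2-bit packing")
    m = n - k + 1
    codes = np.zeros(m, dtype=np.int32)
    for j in range(k):
        codes = codes * 4 + arr[j : m + j]
    invalid = (arr >= 4).astype(np.int32)
    cum = np.concatenate([[0], np.cumsum(invalid)])
    ok = (cum[k:] - cum[:-k]) == 0
    pos = np.nonzero(ok)[0]
    return codes[pos], pos


def _seed_pairs(
    codes1: np.ndarray,
    pos1: np.ndarray,
    codes2: np.ndarray,
    pos2: np.ndarray,
    max_hits_per_kmer: int = 2000,
    stride: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """All (pos-in-1, pos-in-2) pairs whose k-mers are equal.

    ``stride`` subsamples the query side (run grouping tolerates sparse
    anchors); the smaller array is always the one sorted.
    """
    if codes1.size == 0 or codes2.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    if stride > 1:
        codes1 = codes1[::stride]
        pos1 = pos1[::stride]
    if codes1.size < codes2.size // 2:
        b, a = _seed_pairs(codes2, pos2, codes1, pos1, max_hits_per_kmer)
        return a, b
    order = np.argsort(codes2, kind="stable")
    sc2 = codes2[order]
    sp2 = pos2[order]
    lo = np.searchsorted(sc2, codes1, side="left")
    # run-end lookup replaces a second searchsorted: nxt[i] = index of the
    # next value change in sc2 at or after i
    boundaries = np.nonzero(np.diff(sc2))[0] + 1
    run_ends = np.concatenate([boundaries, [sc2.size]])
    run_lens = np.diff(np.concatenate([[0], run_ends]))
    nxt = np.repeat(run_ends, run_lens)
    safe_lo = np.minimum(lo, sc2.size - 1)
    hi = np.where(
        (lo < sc2.size) & (sc2[safe_lo] == codes1), nxt[safe_lo], lo
    )
    counts = hi - lo
    counts = np.minimum(counts, max_hits_per_kmer)
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    a_out = np.repeat(pos1, counts)
    # offsets into sc2 per hit
    starts = np.repeat(lo, counts)
    within = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
    b_out = sp2[starts + within]
    return a_out, b_out


_EXT_CHUNK = 4096


def _extend_one_side(eq_chunks, xdrop: int) -> int:
    """Walk match/mismatch chunks outward; return how many columns the
    best-scoring X-drop extension covers (0 if none improves the score)."""
    best_len = 0
    best_score = 0
    cur = 0
    offset = 0
    for eq in eq_chunks:
        if eq.size == 0:
            break
        score = cur + np.cumsum(np.where(eq, 1, -1))
        runmax = np.maximum(np.maximum.accumulate(score), best_score)
        dropped = np.nonzero(runmax - score > xdrop)[0]
        stop = int(dropped[0]) if dropped.size else eq.size
        if stop > 0:
            local_best = int(np.argmax(score[:stop]))
            if score[local_best] > best_score:
                best_score = int(score[local_best])
                best_len = offset + local_best + 1
        if dropped.size:
            break
        cur = int(score[-1])
        offset += eq.size
    return best_len


def _eq_chunks_right(arr1, arr2, start: int, bound: int, d: int):
    pos = start
    while pos < bound:
        end = min(pos + _EXT_CHUNK, bound)
        seg1 = arr1[pos:end]
        seg2 = arr2[pos - d : end - d]
        bad = np.nonzero((seg1 >= 4) | (seg2 >= 4))[0]
        if bad.size:
            yield (seg1[: bad[0]] == seg2[: bad[0]])
            return
        yield seg1 == seg2
        pos = end


def _eq_chunks_left(arr1, arr2, end: int, bound: int, d: int):
    pos = end
    while pos > bound:
        start = max(pos - _EXT_CHUNK, bound)
        seg1 = arr1[start:pos][::-1]
        seg2 = arr2[start - d : pos - d][::-1]
        bad = np.nonzero((seg1 >= 4) | (seg2 >= 4))[0]
        if bad.size:
            yield (seg1[: bad[0]] == seg2[: bad[0]])
            return
        yield seg1 == seg2
        pos = start


def _xdrop_extend(
    arr1: np.ndarray,
    arr2: np.ndarray,
    lo: int,
    hi: int,
    d: int,
    xdrop: int,
    lo_bound: int,
    hi_bound: int,
) -> tuple[int, int]:
    """Extend the anchor [lo, hi) along diagonal d (arr2 index = arr1 index - d)
    with ungapped X-drop (+1/-1 scoring); N never matches and stops extension.
    Returns the extended [lo, hi) on arr1 coordinates."""
    r_bound = min(hi_bound, arr1.size, arr2.size + d)
    if r_bound > hi:
        hi += _extend_one_side(_eq_chunks_right(arr1, arr2, hi, r_bound, d), xdrop)
    l_bound = max(lo_bound, 0, d)
    if lo > l_bound:
        lo -= _extend_one_side(_eq_chunks_left(arr1, arr2, lo, l_bound, d), xdrop)
    return lo, hi


def _count_matches(arr1: np.ndarray, arr2: np.ndarray, lo: int, hi: int, d: int) -> int:
    seg1 = arr1[lo:hi]
    seg2 = arr2[lo - d : hi - d]
    return int(np.count_nonzero((seg1 == seg2) & (seg1 < 4)))


def _diagonal_candidates(a_pos: np.ndarray, b_pos: np.ndarray, k: int) -> list[tuple[int, int, int]]:
    """Group seed hits into per-diagonal runs -> (d, lo, hi) anchors on seq1."""
    if a_pos.size == 0:
        return []
    d = a_pos - b_pos
    order = np.lexsort((a_pos, d))
    ds = d[order]
    aps = a_pos[order]
    out: list[tuple[int, int, int]] = []
    brk = np.nonzero((np.diff(ds) != 0) | (np.diff(aps) > SEED_RUN_GAP))[0] + 1
    starts = np.concatenate([[0], brk])
    ends = np.concatenate([brk, [ds.size]])
    for s, e in zip(starts, ends):
        out.append((int(ds[s]), int(aps[s]), int(aps[e - 1]) + k))
    return out


def _extend_candidates(
    arr1: np.ndarray,
    arr2: np.ndarray,
    cands: list[tuple[int, int, int]],
    min_len: int,
    min_identity: float,
    xdrop: int,
    span_cap: int,
) -> list[tuple[int, int, int, int]]:
    """X-drop extend diagonal anchors; returns (d, lo, hi, matches) tuples.

    Candidates that land inside an already-extended interval on the same
    diagonal are skipped; overlapping extensions on one diagonal are unioned.
    """
    done: dict[int, list[tuple[int, int]]] = {}
    results: list[tuple[int, int, int, int]] = []
    split_cands: list[tuple[int, int, int]] = []
    for d, lo, hi in cands:
        # anchors must not span N bases (N terminates extension): split the
        # anchor at positions where either sequence carries an N
        seg1 = arr1[lo:hi]
        seg2 = arr2[lo - d : hi - d]
        bad = np.nonzero((seg1 >= 4) | (seg2 >= 4))[0]
        if bad.size == 0:
            split_cands.append((d, lo, hi))
        else:
            edges = np.concatenate([[-1], bad, [hi - lo]])
            for s, e in zip(edges[:-1], edges[1:]):
                if e - s - 1 > 0:
                    split_cands.append((d, lo + int(s) + 1, lo + int(e)))
    for d, lo, hi in split_cands:
        seen = done.setdefault(d, [])
        if any(s <= lo and hi <= e for s, e in seen):
            continue
        elo, ehi = _xdrop_extend(arr1, arr2, lo, hi, d, xdrop, lo - span_cap, hi + span_cap)
        if ehi - elo > span_cap:
            # cap the span for fully-wrapping diagonals (identical circles)
            ehi = elo + span_cap
        seen.append((elo, ehi))
        if ehi - elo < min_len:
            continue
        m = _count_matches(arr1, arr2, elo, ehi, d)
        if m / (ehi - elo) < min_identity:
            # trim mismatch-heavy tails: shrink to the best-identity core by
            # re-running extension from the densest seed anchor only
            continue
        results.append((d, elo, ehi, m))
    # union overlapping intervals on the same diagonal
    merged: list[tuple[int, int, int, int]] = []
    by_d: dict[int, list[tuple[int, int, int]]] = {}
    for d, lo, hi, m in results:
        by_d.setdefault(d, []).append((lo, hi, m))
    for d, ivs in by_d.items():
        ivs.sort()
        cur_lo, cur_hi, _ = ivs[0]
        for lo, hi, _m in ivs[1:]:
            if lo <= cur_hi:
                cur_hi = max(cur_hi, hi)
            else:
                mm = _count_matches(arr1, arr2, cur_lo, cur_hi, d)
                merged.append((d, cur_lo, cur_hi, mm))
                cur_lo, cur_hi = lo, hi
        mm = _count_matches(arr1, arr2, cur_lo, cur_hi, d)
        merged.append((d, cur_lo, cur_hi, mm))
    return merged


def find_local_matches(
    g1: CircularGenome,
    g2: CircularGenome,
    min_len: int = 80,
    min_identity: float = 0.90,
    mode: str = "cross",
    k: int = DEFAULT_K,
    xdrop: int = DEFAULT_XDROP,
    max_hits_per_kmer: int = 2000,
) -> list[MatchFragment]:
    """Find maximal local near-identical matches between two genomes
    (``mode="cross"``) or within one genome (``mode="self"``, pass the same
    genome twice or just ``g1``).

    Both strands are searched; circular origins are crossed transparently by
    doubling; (a,b)/(b,a) mirrors and doubled-space duplicates are removed.
    """
    if mode not in ("cross", "self"):
        raise MatcherError(f"bad mode {mode!r}")
    if mode == "self":
        g2 = g1
    if min_len < k:
        raise MatcherError(f"min_len {min_len} is below seed length {k}")
    if not (0.5 < min_identity <= 1.0):
        raise MatcherError(f"min_identity must be in (0.5, 1], got {min_identity}")
    if g1.length < k or g2.length < k:
        raise MatcherError("genome shorter than seed length")

    L1, L2 = g1.length, g2.length
    s1 = g1.doubled()
    s2 = g2.doubled()
    arr1 = encode(s1)
    arr2f = encode(s2)
    arr2r = _RC[arr2f][::-1].copy()

    c1, p1 = _kmer_codes(arr1, k)
    span_cap = min(L1, L2)
    stride = 3 if min_len >= k + 6 else 1

    raw: list[tuple[str, int, int, int, int]] = []  # (orient, d, lo, hi, matches)
    for orient, arr2 in (("direct", arr2f), ("inverted", arr2r)):
        c2, p2 = _kmer_codes(arr2, k)
        ap, bp = _seed_pairs(c1, p1, c2, p2, max_hits_per_kmer, stride=stride)
        if mode == "self" and orient == "direct":
            keep = ap != bp
            ap, bp = ap[keep], bp[keep]
        cands = _diagonal_candidates(ap, bp, k)
        for d, lo, hi, m in _extend_candidates(arr1, arr2, cands, min_len, min_identity, xdrop, span_cap):
            raw.append((orient, d, lo, hi, m))

    n2 = 2 * L2 if g2.is_circular else L2
    frags: dict[tuple, MatchFragment] = {}
    for orient, d, lo, hi, m in raw:
        span = hi - lo
        a_start = lo % L1 if g1.is_circular else lo
        if orient == "direct":
            b_lo = lo - d
            b_start = b_lo % L2 if g2.is_circular else b_lo
            b_strand = "+"
        else:
            # position q in reversed-complement space maps to forward index n2-1-q;
            # the interval [lo-d, hi-d) maps to forward [n2-(hi-d), n2-(lo-d))
            b_fwd_lo = n2 - (hi - d)
            b_start = b_fwd_lo % L2 if g2.is_circular else b_fwd_lo
            b_strand = "-"
        frag = MatchFragment(
            a=CircInterval(g1.id, a_start, span, "+"),
            b=CircInterval(g2.id, b_start, span, b_strand),
            orientation=orient,
            matches=m,
            aln_len=span,
        )
        frag = _canonicalize(frag, mode, L1, L2)
        if frag is None:
            continue
        key = (frag.orientation, frag.a.start, frag.a.span, frag.b.start, frag.b.span)
        prev = frags.get(key)
        if prev is None or frag.matches > prev.matches:
            frags[key] = frag
    out = _drop_contained(list(frags.values()), L1, L2, mode)
    out.sort(key=lambda f: (f.a.start, f.b.start, f.orientation))
    return out


def _canonicalize(frag: MatchFragment, mode: str, L1: int, L2: int) -> MatchFragment | None:
    if mode == "self":
        a, b = frag.a, frag.b
        # drop the trivial coincident interval
        if a.start == b.start and a.span == b.span and frag.orientation == "direct":
            return None
        if (b.start, b.span) < (a.start, a.span):
            a, b = b, a
        # for inverted self pairs the b interval carries the '-' strand
        if frag.orientation == "inverted":
            a = CircInterval(a.genome_id, a.start, a.span, "+")
            b = CircInterval(b.genome_id, b.start, b.span, "-")
        if a.start == b.start and a.span == b.span:
            return None  # a palindrome matching itself is not a repeat pair
        return replace(frag, a=a, b=b)
    return frag


def _drop_contained(
    frags: list[MatchFragment], L1: int, L2: int, mode: str = "cross"
) -> list[MatchFragment]:
    """Remove fragments whose a AND b intervals are contained in a longer
    fragment of the same orientation."""
    out: list[MatchFragment] = []
    frags = sorted(frags, key=lambda f: -f.aln_len)
    # X-drop trimming wobbles endpoints by chance-matching bases (bounded by
    # the drop window), so a doubled-space duplicate of a wrap-around match
    # can overhang its canonical twin
    slack = 2 * DEFAULT_XDROP

    def contains(big: CircInterval, small: CircInterval, L: int) -> bool:
        off = (small.start - big.start) % L
        if off >= L - slack:
            off -= L  # slight left overhang, within the slack only
        elif off > big.span:
            return False
        return off + small.span <= big.span + slack

    for f in frags:
        redundant = False
        for g in out:
            if g.orientation != f.orientation:
                continue
            if contains(g.a, f.a, L1) and contains(g.b, f.b, L2):
                redundant = True
                break
            # mirror containment (self mode only): f's (a,b) inside g's (b,a)
            if mode == "self" and contains(g.b, f.a, L1) and contains(g.a, f.b, L2):
                redundant = True
                break
        if not redundant:
            out.append(f)
    return out


# ---------------------------------------------------------------------------
# Fragment merging (chaining)
# ---------------------------------------------------------------------------


def merge_fragments(
    frs: list[MatchFragment],
    max_gap: int = 100,
    len_a: int | None = None,
    len_b: int | None = None,
    circular: bool = True,
) -> list[MatchFragment]:
    """Merge collinear same-orientation fragments whose gaps on both genomes
    are <= ``max_gap``.  Gap columns count as mismatches in the merged
    identity.  ``len_a``/``len_b`` enable wrap-aware gap arithmetic; when
    omitted they are inferred as 'no wrapping'.
    """
    if not frs:
        return []
    ga = {f.a.genome_id for f in frs}
    gb = {f.b.genome_id for f in frs}
    if len(ga) > 1 or len(gb) > 1:
        raise MatcherError("fragments from mismatched genome pairs")

    merged: list[MatchFragment] = []
    for orient in ("direct", "inverted"):
        group = sorted(
            (f for f in frs if f.orientation == orient),
            key=lambda f: (f.a.start, f.b.start),
        )
        while True:
            group, changed = _merge_pass(group, orient, max_gap, len_a, len_b, circular)
            if not changed:
                break
        merged.extend(group)
    merged.sort(key=lambda f: (f.a.start, f.b.start, f.orientation))
    return merged


def _gap(prev_end: int, nxt_start: int, length: int | None, circular: bool) -> int:
    g = nxt_start - prev_end
    if circular and length is not None and g < -length // 2:
        g += length
    return g


def _merge_pass(
    group: list[MatchFragment],
    orient: str,
    max_gap: int,
    len_a: int | None,
    len_b: int | None,
    circular: bool,
) -> tuple[list[MatchFragment], bool]:
    out: list[MatchFragment] = []
    used = [False] * len(group)
    changed = False
    for i, f in enumerate(group):
        if used[i]:
            continue
        cur = f
        for j in range(i + 1, len(group)):
            if used[j]:
                continue
            g = group[j]
            merged = _try_merge(cur, g, orient, max_gap, len_a, len_b, circular)
            if merged is None:
                merged = _try_merge(g, cur, orient, max_gap, len_a, len_b, circular)
            if merged is not None:
                cur = merged
                used[j] = True
                changed = True
        out.append(cur)
    return out, changed


def _try_merge(
    f: MatchFragment,
    g: MatchFragment,
    orient: str,
    max_gap: int,
    len_a: int | None,
    len_b: int | None,
    circular: bool,
) -> MatchFragment | None:
    gap_a = _gap(f.a.end, g.a.start, len_a, circular)
    if not (-max_gap <= gap_a <= max_gap):
        return None
    if orient == "direct":
        gap_b = _gap(f.b.end, g.b.start, len_b, circular)
    else:
        # as a advances, the b interval retreats on the forward strand
        gap_b = _gap(g.b.end, f.b.start, len_b, circular)
    if not (-max_gap <= gap_b <= max_gap):
        return None
    span_a = f.a.span + max(gap_a, 0) + g.a.span + min(gap_a, 0)
    span_b = f.b.span + max(gap_b, 0) + g.b.span + min(gap_b, 0)
    if span_a < 1 or span_b < 1:
        return None
    aln_len = max(span_a, span_b)
    matches = min(f.matches + g.matches, aln_len)
    a_start = f.a.start
    b_start = f.b.start if orient == "direct" else g.b.start
    return MatchFragment(
        a=CircInterval(f.a.genome_id, a_start, span_a, "+"),
        b=CircInterval(f.b.genome_id, b_start, span_b, f.b.strand),
        orientation=orient,
        matches=matches,
        aln_len=aln_len,
    )


# ---------------------------------------------------------------------------
# TSV export
# ---------------------------------------------------------------------------

FRAGMENT_COLUMNS = [
    "a_start",
    "a_span",
    "b_start",
    "b_span",
    "orientation",
    "matches",
    "aln_len",
    "identity",
]


def fragments_to_rows(frs: list[MatchFragment]) -> list[dict]:
    return [
        {
            "a_start": f.a.start,
            "a_span": f.a.span,
            "b_start": f.b.start,
            "b_span": f.b.span,
            "orientation": f.orientation,
            "matches": f.matches,
            "aln_len": f.aln_len,
            "identity": f"{f.identity:.6f}",
        }
        for f in frs
    ]
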