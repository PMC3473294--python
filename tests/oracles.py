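"""Independent oracles used by the test suite.

These deliberately avoid the package's seed-and-extend / branch-and-bound
code paths: full dynamic programming for local alignment, exhaustive
per-diagonal enumeration for repeat pairs, and naive recursive enumeration
for covering closed walks.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def rc(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def sw_local(s1: str, s2: str, match: int = 1, mismatch: int = -1, gap: int = -2):
    """Full Smith-Waterman over the |s1| x |s2| matrix.

    Returns (score, a_start, a_end, b_start, b_end) of the best local
    alignment (end-exclusive), traced back through the DP matrix.
    """
    n, m = len(s1), len(s2)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    a1 = np.frombuffer(s1.encode(), dtype=np.uint8)
    a2 = np.frombuffer(s2.encode(), dtype=np.uint8)
    for i in range(1, n + 1):
        sub = np.where(a2 == a1[i - 1], match, mismatch).astype(np.int32)
        prev = H[i - 1]
        # diagonal + vertical candidates are vectorizable; the horizontal
        # (gap in s1) dependency needs a left-to-right scan
        cand = np.maximum(np.maximum(prev[:-1] + sub, prev[1:] + gap), 0)
        row = H[i]
        left = 0
        for j in range(1, m + 1):
            v = cand[j - 1]
            if left + gap > v:
                v = left + gap
            row[j] = v
            left = v
    best = np.unravel_index(np.argmax(H), H.shape)
    score = int(H[best])
    i, j = int(best[0]), int(best[1])
    a_end, b_end = i, j
    while i > 0 and j > 0 and H[i][j] > 0:
        h = H[i][j]
        diag = H[i - 1][j - 1] + (match if s1[i - 1] == s2[j - 1] else mismatch)
        if h == diag:
            i, j = i - 1, j - 1
        elif h == H[i - 1][j] + gap:
            i -= 1
        elif h == H[i][j - 1] + gap:
            j -= 1
        else:
            break
    return score, i, a_end, j, b_end


def best_local_alignments(s1: str, s2: str, min_score: int, gap: int = -10):
    """Best local alignment per orientation with score >= min_score.

    The default gap penalty is heavy because the implementation under test
    declares an ungapped scoring model (gap columns count as mismatches);
    a cheap-gap oracle would legitimately stitch through random flanks.
    """
    out = []
    score, a0, a1_, b0, b1 = sw_local(s1, s2, gap=gap)
    if score >= min_score:
        out.append(("direct", a0, a1_, b0, b1, score))
    s2r = rc(s2)
    score, a0, a1_, b0, b1 = sw_local(s1, s2r, gap=gap)
    if score >= min_score:
        # map coordinates back to the forward strand of s2
        out.append(("inverted", a0, a1_, len(s2) - b1, len(s2) - b0, score))
    return out


def enumerate_repeat_pairs(seq: str, min_len: int, min_identity: float, circular: bool = True):
    """Exhaustive per-diagonal enumeration of maximal repeat pairs.

    A qualifying interval on a diagonal has length > min_len and identity
    > min_identity and cannot be extended by one column on either side while
    still qualifying; intervals contained in a longer qualifying interval on
    the same diagonal are dropped.  Diagonals with no 50-column window at
    >= 70% identity are pruned (a window far below the 90% threshold cannot
    host a qualifying interval).  Returns (orientation, start1, start2,
    length) canonicalized with start1 <= start2, coordinates mod L.
    """
    L = len(seq)
    s = seq + seq if circular else seq
    a = np.frombuffer(s.encode(), dtype=np.uint8)
    results = set()
    for orientation in ("direct", "inverted"):
        t = a if orientation == "direct" else np.frombuffer(
            rc(s).encode(), dtype=np.uint8
        )
        n = a.size
        for d in range(1, n):
            lo = d
            m = n - d
            if m <= min_len:
                break
            eq = (a[d:] == t[: n - d]).astype(np.int32)
            # pruning: need some 50-window with >= 35 matches
            if m >= 50:
                c = np.cumsum(np.concatenate([[0], eq]))
                win = c[50:] - c[:-50]
                if win.max() < 35:
                    continue
            elif eq.sum() < min_identity * m:
                continue
            cum = np.cumsum(np.concatenate([[0], eq]))
            js = np.arange(m + 1)

            def qual(i: int, j: int) -> bool:
                ln = j - i
                return ln > min_len and (cum[j] - cum[i]) / ln > min_identity

            found = []
            for i in range(m - min_len):
                lens = js - i
                with np.errstate(divide="ignore", invalid="ignore"):
                    ok = (lens > min_len) & (
                        (cum - cum[i]) > min_identity * lens
                    )
                if ok.any():
                    found.append((i, int(np.nonzero(ok)[0].max())))
            maximal = []
            for i, j in found:
                if i > 0 and qual(i - 1, j):
                    continue
                if j < m and qual(i, j + 1):
                    continue
                contained = any(
                    (i2 <= i and j <= j2) for i2, j2 in found if (i2, j2) != (i, j)
                )
                if not contained:
                    maximal.append((i, j))
            for i, j in maximal:
                ln = j - i
                p1 = i + d  # position in doubled coords on 'a'
                if orientation == "direct":
                    p2 = i
                else:
                    p2 = n - (i + ln)
                c1, c2 = sorted(((p1 % L), (p2 % L)))
                if circular and ln > L:
                    continue
                if c1 == c2:
                    continue
                results.add((orientation, c1, c2, ln))
    # Inability-to-extend-by-one admits staircases of overlapping intervals
    # that shift by a column; collapse overlapping same-orientation intervals
    # to the longest representative.
    accepted: list[tuple[str, int, int, int]] = []
    for cand in sorted(results, key=lambda r: (-r[3], r[1], r[2])):
        o, c1, c2, ln = cand
        dup = False
        for o2, d1, d2, ln2 in accepted:
            if o != o2:
                continue
            ov1 = min(c1 + ln, d1 + ln2) - max(c1, d1)
            ov2 = min(c2 + ln, d2 + ln2) - max(c2, d2)
            if ov1 > 0.5 * ln and ov2 > 0.5 * ln:
                dup = True
                break
        if not dup:
            accepted.append(cand)
    return sorted(accepted)


def enumerate_covering_walks(contigs, adjacency, start, max_visits: int):
    """All closed walks from ``start`` (a (contig, orientation) state) that
    visit every contig at least once and at most max_visits times.

    ``adjacency`` maps state -> list of (contig, orientation, overlap).
    Yields (walk, total_length) tuples.  Purely recursive enumeration.
    """
    lengths = {c_id: ln for c_id, ln in contigs}
    all_ids = set(lengths)

    def recurse(state, walk, counts, length):
        for nxt, orient, overlap in adjacency.get(state, []):
            if (nxt, orient) == start and set(counts) == all_ids:
                yield list(walk), length - overlap
            if counts.get(nxt, 0) >= max_visits:
                continue
            counts[nxt] = counts.get(nxt, 0) + 1
            walk.append((nxt, orient))
            yield from recurse((nxt, orient), walk, counts, length + lengths[nxt] - overlap)
            walk.pop()
            counts[nxt] -= 1
            if counts[nxt] == 0:
                del counts[nxt]

    yield from recurse(start, [start], {start[0]: 1}, lengths[start[0]])


def circular_adjacency_set(order):
    """Hand enumeration of the canonical signed adjacency set of a circular
    signed arrangement (reverse reading folded)."""
    n = len(order)
    out = set()
    for i in range(n):
        x, y = order[i], order[(i + 1) % n]
        out.add(min((x, y), (-y, -x)))
    return out


def hamming_scan(seq: str, motif: str, max_mm: int, circular: bool = True):
    """Sliding-window Hamming scan, one strand; positions mod L."""
    L = len(seq)
    s = seq + seq if circular else seq
    m = len(motif)
    limit = L if circular else L - m + 1
    hits = []
    for i in range(limit):
        w = s[i : i + m]
        mm = sum(1 for x, y in zip(w, motif) if x != y or x == "N")
        if mm <= max_mm:
            hits.append((i, mm))
    return hits
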