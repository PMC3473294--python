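"""Within-genome repeat cataloguing and sub-genomic circle prediction.

A repeat pair is two near-identical intervals in one genome (direct or
inverted).  Thresholds are strict: alignment length > min_len and identity
> min_identity.  Pair counting convention: the catalog lists canonical
maximal pairs from the self-matcher (mirrors and nested/contained pairs
collapsed); families with more than two copies appear as all canonical pairs
and share a ``family`` annotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from mitocircle.genome_io import CircInterval, CircularGenome
from mitocircle.matcher import encode, find_local_matches

DEFAULT_MIN_LEN = 80
DEFAULT_MIN_IDENTITY = 0.90
LARGE_REPEAT_THRESHOLD = 1000


class RepeatError(ValueError):
    pass


@dataclass(frozen=True)
class RepeatPair:
    name: str
    copy1: CircInterval
    copy2: CircInterval
    orientation: str  # "direct" | "inverted"
    length: int  # alignment columns
    identity: float
    size_class: str  # "large" | "short"
    family: int | None = None
    perfect_core: int = 0  # longest 100%-identity sub-run of the pair


def build_repeat_catalog(
    g: CircularGenome,
    min_len: int = DEFAULT_MIN_LEN,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    k: int = 15,
) -> list[RepeatPair]:
    """Catalogue repeat pairs in one genome via self-mode matching.

    Output is canonicalized (copy1.start <= copy2.start), deduplicated, with
    nested pairs collapsed to the maximal pair, named R1..Rn by descending
    length.  Strict thresholds: length > min_len, identity > min_identity.
    """
    frags = find_local_matches(
        g, g, min_len=max(min_len, k), min_identity=min_identity, mode="self", k=k
    )
    pairs = [
        f
        for f in frags
        if f.aln_len > min_len and f.identity > min_identity
    ]
    pairs.sort(key=lambda f: (-f.aln_len, f.a.start, f.b.start))
    out: list[RepeatPair] = []
    for i, f in enumerate(pairs):
        out.append(
            RepeatPair(
                name=f"R{i + 1}",
                copy1=f.a,
                copy2=f.b,
                orientation=f.orientation,
                length=f.aln_len,
                identity=f.identity,
                size_class="large" if f.aln_len >= LARGE_REPEAT_THRESHOLD else "short",
                perfect_core=_longest_perfect_run(g, f.a, f.b, f.orientation),
            )
        )
    return _annotate_families(out, g.length)


def _longest_perfect_run(
    g: CircularGenome, a: CircInterval, b: CircInterval, orientation: str
) -> int:
    """Longest sub-interval of the pair at 100% identity (reported alongside
    the full >90% extent for large repeats whose ends diverge)."""
    s1 = encode(g.fetch(a.start, a.span))
    s2raw = g.fetch(b.start, b.span)
    if orientation == "inverted":
        from mitocircle.genome_io import revcomp

        s2raw = revcomp(s2raw)
    s2 = encode(s2raw)
    n = min(s1.size, s2.size)
    if n == 0:
        return 0
    eq = (s1[:n] == s2[:n]) & (s1[:n] < 4)
    if not eq.any():
        return 0
    # longest run of True
    idx = np.flatnonzero(np.diff(np.concatenate([[0], eq.view(np.int8), [0]])))
    runs = idx.reshape(-1, 2)
    return int((runs[:, 1] - runs[:, 0]).max())


def _annotate_families(pairs: list[RepeatPair], genome_length: int) -> list[RepeatPair]:
    """Group pairs whose copies overlap into families (>2 copies of one
    repeat produce several canonical pairs)."""
    from dataclasses import replace

    n = len(pairs)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        parent[find(x)] = find(y)

    for i in range(n):
        for j in range(i + 1, n):
            ci = (pairs[i].copy1, pairs[i].copy2)
            cj = (pairs[j].copy1, pairs[j].copy2)
            if any(a.overlap(b, genome_length) > 0 for a in ci for b in cj):
                union(i, j)
    roots: dict[int, int] = {}
    out = []
    for i, p in enumerate(pairs):
        r = find(i)
        fam = roots.setdefault(r, len(roots) + 1)
        out.append(replace(p, family=fam))
    return out


def predict_subgenomic_circles(master_length: int, pair: RepeatPair) -> tuple[int, int]:
    """Sizes of the two circles produced by recombination across a direct
    repeat pair.  size1 is the circular distance copy1.start -> copy2.start;
    size2 is the complement; they sum to the master length exactly."""
    if pair.orientation != "direct":
        raise RepeatError(
            f"repeat pair {pair.name} is inverted: recombination yields an "
            "inversion, not two sub-genomic circles"
        )
    if pair.copy1.overlap(pair.copy2, master_length) > 0:
        raise RepeatError(f"repeat pair {pair.name}: copies overlap")
    size1 = (pair.copy2.start - pair.copy1.start) % master_length
    size2 = master_length - size1
    return size1, size2


CATALOG_COLUMNS = [
    "name",
    "copy1_start",
    "copy1_end",
    "copy2_start",
    "copy2_end",
    "orientation",
    "length",
    "identity",
    "size_class",
    "family",
    "perfect_core",
]


def catalog_to_rows(pairs: list[RepeatPair]) -> list[dict]:
    """Catalog TSV rows; coordinates 1-based inclusive, mirroring the usual
    repeat-list presentation."""
    rows = []
    for p in pairs:
        rows.append(
            {
                "name": p.name,
                "copy1_start": p.copy1.start + 1,
                "copy1_end": p.copy1.end,
                "copy2_start": p.copy2.start + 1,
                "copy2_end": p.copy2.end,
                "orientation": p.orientation,
                "length": p.length,
                "identity": f"{p.identity:.4f}",
                "size_class": p.size_class,
                "family": p.family,
                "perfect_core": p.perfect_core,
            }
        )
    return rows
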