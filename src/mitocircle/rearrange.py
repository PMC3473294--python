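"""Arrangement comparison: breakpoints and repeat-mediated event inference.

A breakpoint is a signed-block adjacency present in one genome's circular
arrangement but not the other's (an adjacency and its reverse reading are the
same breakpoint).  Events attribute breakpoint clusters to repeat pairs (or
exact short repeats) found near the implicated block edges.
"""

from __future__ import annotations

from dataclasses import dataclass

from mitocircle.genome_io import CircInterval, CircularGenome, revcomp
from mitocircle.repeats import RepeatPair
from mitocircle.synteny import BlockArrangement, SyntenicBlock

DEFAULT_EDGE_WINDOW = 500
DEFAULT_MIN_EXACT_REPEAT = 10


class RearrangeError(ValueError):
    pass


@dataclass(frozen=True)
class Breakpoint:
    adjacency: tuple[int, int]  # canonical signed pair
    present_in: str  # "A only" | "B only"


@dataclass(frozen=True)
class RepeatEvidence:
    """A repeat pair supporting an event, with each copy's distance to the
    block edge it is expected to sit at."""

    source_genome: str
    name: str
    orientation: str
    copy1: CircInterval
    copy2: CircInterval
    length: int
    distance1: int
    distance2: int


@dataclass(frozen=True)
class RecombinationEvent:
    type: str  # "inversion" | "junction-exchange" | "insertion-associated"
    blocks: tuple[int, ...]
    evidence: tuple[RepeatEvidence, ...]
    confidence: str  # "edge-exact" | "within-window" | "unexplained"


def _canonical_adjacency(x: int, y: int) -> tuple[int, int]:
    """(x,y) read in the opposite direction is (-y,-x); keep the lexicographic
    minimum of the two readings."""
    return min((x, y), (-y, -x))


def adjacency_set(arr: BlockArrangement) -> set[tuple[int, int]]:
    order = arr.order
    n = len(order)
    if n < 2:
        return set()
    out = set()
    for i in range(n):
        out.add(_canonical_adjacency(order[i], order[(i + 1) % n]))
    return out


def diff_arrangements(arr_a: BlockArrangement, arr_b: BlockArrangement) -> list[Breakpoint]:
    """Symmetric difference of the two circular signed-adjacency sets.

    Empty iff the arrangements are equal up to rotation and global flip.
    """
    if {abs(x) for x in arr_a.order} != {abs(x) for x in arr_b.order}:
        raise RearrangeError("arrangements are over different block universes")
    sa = adjacency_set(arr_a)
    sb = adjacency_set(arr_b)
    bps = [Breakpoint(adj, "A only") for adj in sorted(sa - sb)]
    bps += [Breakpoint(adj, "B only") for adj in sorted(sb - sa)]
    return bps


# ---------------------------------------------------------------------------
# Event inference
# ---------------------------------------------------------------------------


def _block_by_id(blocks: list[SyntenicBlock]) -> dict[int, SyntenicBlock]:
    return {b.block_id: b for b in blocks}


def _edge_positions(block: SyntenicBlock, which: str, genome_length: int) -> tuple[int, int]:
    iv = block.iv_a if which == "A" else block.iv_b
    return iv.start % genome_length, iv.end % genome_length


def _dist_to_edge(iv: CircInterval, edge: int, genome_length: int) -> int:
    """Distance from a repeat copy to a block edge position (0 if the copy
    covers the edge)."""
    if iv.contains(edge, genome_length):
        return 0
    d1 = (iv.start - edge) % genome_length
    d2 = (edge - iv.end % genome_length) % genome_length
    return min(d1, d2)


def _find_inverted_runs(arr_a: BlockArrangement, arr_b: BlockArrangement) -> list[tuple[int, ...]]:
    """Maximal runs of sign-flipped blocks that are contiguous in A's circular
    order.  Each run is one candidate inversion event (adjacent independent
    inversions may merge into one run; documented behaviour)."""
    sign_b = {abs(s): (1 if s > 0 else -1) for s in arr_b.order}
    order_a = [abs(s) for s in arr_a.order]
    n = len(order_a)
    flags = [sign_b.get(b, 1) < 0 for b in order_a]
    if not any(flags):
        return []
    if all(flags):
        return [tuple(order_a)]
    # rotate so position 0 is unflipped, then take maximal flipped runs
    shift = flags.index(False)
    rot = [(order_a[(shift + i) % n], flags[(shift + i) % n]) for i in range(n)]
    runs: list[list[int]] = []
    cur: list[int] = []
    for b, fl in rot:
        if fl:
            cur.append(b)
        elif cur:
            runs.append(cur)
            cur = []
    if cur:
        runs.append(cur)
    return [tuple(r) for r in runs]


def find_exact_repeats_between(
    genome: CircularGenome,
    window1: CircInterval,
    window2: CircInterval,
    min_len: int,
) -> list[tuple[str, int, int, int]]:
    """Exact repeats (>= min_len) with one copy in each window, both
    orientations.  Returns (orientation, pos1, pos2, length) with positions in
    genome coordinates.  Pure string scan; no fuzzy matching."""
    s1 = window1.extract(genome) if window1.strand == "+" else genome.fetch(window1.start, window1.span)
    s2 = genome.fetch(window2.start, window2.span)
    hits = []
    for orient, t2 in (("direct", s2), ("inverted", revcomp(s2))):
        for off1, off2, ln in _maximal_common_substrings(s1, t2, min_len):
            p1 = (window1.start + off1) % genome.length
            if orient == "direct":
                p2 = (window2.start + off2) % genome.length
            else:
                p2 = (window2.start + (len(s2) - off2 - ln)) % genome.length
            hits.append((orient, p1, p2, ln))
    hits.sort(key=lambda h: (-h[3], h[0], h[1], h[2]))
    return hits


def _maximal_common_substrings(s1: str, s2: str, min_len: int) -> list[tuple[int, int, int]]:
    """All maximal common substrings >= min_len between two short strings
    (row-vectorized O(n*m) run-length dynamic programming)."""
    import numpy as np

    n, m = len(s1), len(s2)
    if n < min_len or m < min_len:
        return []
    a1 = np.frombuffer(s1.encode(), dtype=np.uint8)
    a2 = np.frombuffer(s2.encode(), dtype=np.uint8)
    nn = ord("N")
    prev = np.zeros(m + 1, dtype=np.int32)
    ends: list[tuple[int, int, int]] = []
    for i in range(1, n + 1):
        cur = np.zeros(m + 1, dtype=np.int32)
        if a1[i - 1] != nn:
            eq = (a2 == a1[i - 1]) & (a2 != nn)
            cur[1:][eq] = prev[:-1][eq] + 1
        # a run ending at (i, j) is maximal if it cannot extend to (i+1, j+1)
        long_enough = np.nonzero(cur >= min_len)[0]
        for j in long_enough:
            ln = int(cur[j])
            extendable = (
                i < n and j < m and a1[i] == a2[j] and a1[i] != nn
            )
            if not extendable:
                ends.append((i - ln, int(j) - ln, ln))
        prev = cur
    # drop runs contained in longer runs on the same diagonal
    out = []
    for a, b, ln in ends:
        contained = any(
            (a2 <= a and a + ln <= a2 + ln2 and a - b == a2 - b2)
            for a2, b2, ln2 in ends
            if (a2, b2, ln2) != (a, b, ln)
        )
        if not contained:
            out.append((a, b, ln))
    return out


def _window(center: int, half: int, genome: CircularGenome) -> CircInterval:
    span = min(2 * half, genome.length)
    start = (center - half) % genome.length
    return CircInterval(genome.id, start, span)


def _repeat_evidence_for_edges(
    catalog: list[RepeatPair],
    genome: CircularGenome,
    edge1: int,
    edge2: int,
    want_orientation: str,
    edge_window: int,
    source: str,
) -> list[RepeatEvidence]:
    ev = []
    for rp in catalog:
        if rp.orientation != want_orientation:
            continue
        for c1, c2 in ((rp.copy1, rp.copy2), (rp.copy2, rp.copy1)):
            d1 = _dist_to_edge(c1, edge1, genome.length)
            d2 = _dist_to_edge(c2, edge2, genome.length)
            if d1 <= edge_window and d2 <= edge_window:
                ev.append(
                    RepeatEvidence(
                        source_genome=source,
                        name=rp.name,
                        orientation=rp.orientation,
                        copy1=c1,
                        copy2=c2,
                        length=rp.length,
                        distance1=d1,
                        distance2=d2,
                    )
                )
                break
    return ev


def _exact_evidence_for_edges(
    genome: CircularGenome,
    edge1: int,
    edge2: int,
    want_orientation: str,
    edge_window: int,
    min_exact_repeat: int,
    source: str,
) -> list[RepeatEvidence]:
    w1 = _window(edge1, edge_window, genome)
    w2 = _window(edge2, edge_window, genome)
    ev = []
    for orient, p1, p2, ln in find_exact_repeats_between(genome, w1, w2, min_exact_repeat):
        if orient != want_orientation:
            continue
        c1 = CircInterval(genome.id, p1, ln)
        c2 = CircInterval(genome.id, p2, ln, "-" if orient == "inverted" else "+")
        ev.append(
            RepeatEvidence(
                source_genome=source,
                name=f"exact_{ln}bp",
                orientation=orient,
                copy1=c1,
                copy2=c2,
                length=ln,
                distance1=_dist_to_edge(c1, edge1, genome.length),
                distance2=_dist_to_edge(c2, edge2, genome.length),
            )
        )
    return ev[:3]  # longest few; the scan returns them sorted by length


def infer_events(
    bps: list[Breakpoint],
    blocks: list[SyntenicBlock],
    arr_a: BlockArrangement,
    arr_b: BlockArrangement,
    genome_a: CircularGenome,
    genome_b: CircularGenome,
    catalog_a: list[RepeatPair],
    catalog_b: list[RepeatPair],
    edge_window: int = DEFAULT_EDGE_WINDOW,
    min_exact_repeat: int = DEFAULT_MIN_EXACT_REPEAT,
    unique_regions_b: list | None = None,
) -> list[RecombinationEvent]:
    """Attribute arrangement differences to repeat evidence at block edges.

    Inversions are detected as maximal sign-flipped runs; the remaining
    breakpoint clusters become junction-exchange (or insertion-associated)
    events.  Evidence orientation rules: inversion -> inverted pair flanking
    the run; junction -> direct pair at the joined edges.  Events with no
    evidence are emitted with confidence "unexplained".
    """
    if not bps:
        return []
    byid = _block_by_id(blocks)
    events: list[RecombinationEvent] = []
    explained_adjacencies: set[tuple[int, int]] = set()

    # --- inversion events from sign-flipped runs
    for run in _find_inverted_runs(arr_a, arr_b):
        first, last = byid[abs(run[0])], byid[abs(run[-1])]
        left_edge = first.iv_a.start % genome_a.length
        right_edge = last.iv_a.end % genome_a.length
        evidence: list[RepeatEvidence] = []
        for genome, catalog, source in (
            (genome_a, catalog_a, "A"),
            (genome_b, catalog_b, "B"),
        ):
            if source == "B":
                le = _map_edge(first, "start", genome_b)
                re_ = _map_edge(last, "end", genome_b)
            else:
                le, re_ = left_edge, right_edge
            evidence += _repeat_evidence_for_edges(
                catalog, genome, le, re_, "inverted", edge_window, source
            )
            if not evidence:
                evidence += _exact_evidence_for_edges(
                    genome, le, re_, "inverted", edge_window, min_exact_repeat, source
                )
        events.append(_make_event("inversion", tuple(abs(b) for b in run), evidence))
        for adj in _run_adjacencies(run, arr_a, arr_b):
            explained_adjacencies.add(adj)

    # --- cluster the remaining breakpoints by shared physical block edges:
    # one physical recombination changes two (or more) adjacencies
    remaining = [bp for bp in bps if bp.adjacency not in explained_adjacencies]
    for cluster in _cluster_breakpoints(remaining):
        blocks_involved: set[int] = set()
        evidence: list[RepeatEvidence] = []
        for bp in cluster:
            x, y = bp.adjacency
            bx, by = byid.get(abs(x)), byid.get(abs(y))
            if bx is None or by is None:
                continue
            blocks_involved.update((abs(x), abs(y)))
            if bp.present_in == "B only":
                # junction newly present in B: direct repeats expected at the
                # corresponding edges in A, where the blocks are separate
                genome, catalog, source = genome_a, catalog_a, "A"
            else:
                genome, catalog, source = genome_b, catalog_b, "B"
            which = source
            e1 = _signed_edge(bx, x, "out", genome, which)
            e2 = _signed_edge(by, y, "in", genome, which)
            ev = _repeat_evidence_for_edges(
                catalog, genome, e1, e2, "direct", edge_window, source
            )
            if not ev:
                ev = _exact_evidence_for_edges(
                    genome, e1, e2, "direct", edge_window, min_exact_repeat, source
                )
            evidence += ev
        ev_type = "junction-exchange"
        if unique_regions_b:
            flanks = {
                b for r in unique_regions_b for b in r.flanking_blocks
            }
            if blocks_involved and blocks_involved <= flanks:
                ev_type = "insertion-associated"
        evidence = _dedup_evidence(evidence)
        events.append(_make_event(ev_type, tuple(sorted(blocks_involved)), evidence))
    return events


def _cluster_breakpoints(bps: list[Breakpoint]) -> list[list[Breakpoint]]:
    """Union-find on the physical block edges an adjacency touches.

    The edge key is (block id, physical end), where the physical end of a
    signed block's 'out' side is its right end for +k and left end for -k.
    """
    def edges(adj: tuple[int, int]) -> list[tuple[int, str]]:
        x, y = adj
        out_edge = (abs(x), "R" if x > 0 else "L")
        in_edge = (abs(y), "L" if y > 0 else "R")
        return [out_edge, in_edge]

    parent: dict = {}

    def find(e):
        parent.setdefault(e, e)
        while parent[e] != e:
            parent[e] = parent[parent[e]]
            e = parent[e]
        return e

    def union(a, b):
        parent[find(a)] = find(b)

    for bp in bps:
        e1, e2 = edges(bp.adjacency)
        union(e1, e2)
    clusters: dict = {}
    for bp in bps:
        root = find(edges(bp.adjacency)[0])
        clusters.setdefault(root, []).append(bp)
    return [clusters[r] for r in sorted(clusters, key=str)]


def _dedup_evidence(evidence: list[RepeatEvidence]) -> list[RepeatEvidence]:
    seen = set()
    out = []
    for e in evidence:
        key = (e.source_genome, e.name, e.copy1.start, e.copy2.start)
        if key not in seen:
            seen.add(key)
            out.append(e)
    return out


def _map_edge(block: SyntenicBlock, which_end: str, genome_b: CircularGenome) -> int:
    iv = block.iv_b
    if which_end == "start":
        return iv.start % genome_b.length
    return iv.end % genome_b.length


def _signed_edge(
    block: SyntenicBlock, signed_id: int, direction: str, genome: CircularGenome, which: str
) -> int:
    """Edge position where a signed block is exited ('out') or entered ('in')."""
    iv = block.iv_a if which == "A" else block.iv_b
    forward = signed_id > 0
    if which == "B" and block.orientation == "inverted":
        forward = not forward
    L = genome.length
    if direction == "out":
        return iv.end % L if forward else iv.start % L
    return iv.start % L if forward else iv.end % L


def _run_adjacencies(
    run: tuple[int, ...], arr_a: BlockArrangement, arr_b: BlockArrangement
) -> set[tuple[int, int]]:
    """Adjacencies (in either genome) that touch the run's outer edges —
    considered explained by the inversion event."""
    touched = set()
    run_ids = {abs(b) for b in run}
    for arr in (arr_a, arr_b):
        order = arr.order
        n = len(order)
        for i in range(n):
            x, y = order[i], order[(i + 1) % n]
            if (abs(x) in run_ids) != (abs(y) in run_ids):
                touched.add(_canonical_adjacency(x, y))
    return touched


def _make_event(
    ev_type: str, block_ids: tuple[int, ...], evidence: list[RepeatEvidence]
) -> RecombinationEvent:
    if not evidence:
        conf = "unexplained"
    elif any(e.distance1 <= 5 and e.distance2 <= 5 for e in evidence):
        conf = "edge-exact"
    else:
        conf = "within-window"
    # mechanical orientation-rule assertion (spec invariant)
    for e in evidence:
        if ev_type == "inversion":
            assert e.orientation == "inverted", "inversion evidence must be an inverted pair"
        elif ev_type == "junction-exchange":
            assert e.orientation == "direct", "junction evidence must be a direct pair"
    return RecombinationEvent(
        type=ev_type,
        blocks=block_ids,
        evidence=tuple(evidence),
        confidence=conf,
    )


EVENT_COLUMNS = ["type", "blocks", "evidence", "confidence"]


def events_to_rows(events: list[RecombinationEvent]) -> list[dict]:
    rows = []
    for ev in events:
        ev_desc = ";".join(
            f"{e.source_genome}:{e.name}@{e.copy1.start}/{e.copy2.start}"
            f"({e.orientation},{e.length}bp,d={e.distance1}/{e.distance2})"
            for e in ev.evidence
        )
        rows.append(
            {
                "type": ev.type,
                "blocks": ",".join(map(str, ev.blocks)),
                "evidence": ev_desc or "-",
                "confidence": ev.confidence,
            }
        )
    return rows
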