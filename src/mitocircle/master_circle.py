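"""Master-circle reconstruction from contigs and depth-weighted linkages.

The parsimonious rule: find a closed walk through the linkage graph that
visits every retained contig at least once (and at most ``max_visits`` times)
while minimizing the total assembled length.  Ties break toward fewer total
visits, then the lexicographically smallest walk.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from statistics import median

import networkx as nx

from mitocircle.genome_io import CircularGenome, revcomp

DEFAULT_MIN_LINK_DEPTH = 10
DEFAULT_MAX_VISITS = 3
DEFAULT_PLASTID_IDENTITY = 0.95
DEFAULT_LOW_DEPTH_FACTOR = 0.25
EXHAUSTIVE_CONTIG_LIMIT = 12


class AssemblyError(ValueError):
    pass


@dataclass(frozen=True)
class Contig:
    id: str
    seq: str
    depth: float

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Linkage:
    """A junction between two contig ends.

    ``end`` semantics: 'tail' is the 3' (right) end of the forward-oriented
    contig, 'head' its 5' (left) end.  A walk step leaves a contig through one
    end and enters the next through one of its ends.
    """

    contig1: str
    end1: str  # "head" | "tail"
    contig2: str
    end2: str
    depth: float
    overlap: int = 0


@dataclass
class ContigGraph:
    contigs: list[Contig]
    linkages: list[Linkage]

    def __post_init__(self) -> None:
        ids = {c.id for c in self.contigs}
        for ln in self.linkages:
            if ln.contig1 not in ids or ln.contig2 not in ids:
                raise AssemblyError(f"linkage references unknown contig: {ln}")
            if ln.end1 not in ("head", "tail") or ln.end2 not in ("head", "tail"):
                raise AssemblyError(f"bad linkage end: {ln}")
            if ln.depth < 0:
                raise AssemblyError("negative linkage depth")
        for c in self.contigs:
            if c.depth < 0:
                raise AssemblyError("negative contig depth")

    def contig(self, cid: str) -> Contig:
        return next(c for c in self.contigs if c.id == cid)


@dataclass
class MasterCircle:
    walk: list[tuple[str, str]]  # (contig_id, '+' | '-'), circular
    sequence: CircularGenome
    visits: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_contig_graph(contigs_fasta: str | Path, linkage_tsv: str | Path) -> ContigGraph:
    """Contigs as multi-FASTA with ``depth=<x>`` in the description (default 1);
    linkages as TSV: contig1, end1, contig2, end2, depth, overlap."""
    from Bio import SeqIO

    contigs = []
    for rec in SeqIO.parse(str(contigs_fasta), "fasta"):
        depth = 1.0
        for token in rec.description.split():
            if token.startswith("depth="):
                depth = float(token[6:])
        contigs.append(Contig(rec.id, str(rec.seq).upper(), depth))
    linkages = []
    with open(linkage_tsv) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#") or line.startswith("contig1\t"):
                continue
            f = line.rstrip("\n").split("\t")
            linkages.append(
                Linkage(f[0], f[1], f[2], f[3], float(f[4]), int(f[5]) if len(f) > 5 else 0)
            )
    return ContigGraph(contigs, linkages)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


def filter_graph(
    gr: ContigGraph,
    min_link_depth: float = DEFAULT_MIN_LINK_DEPTH,
    plastid_panel: list[CircularGenome] | None = None,
    plastid_identity: float = DEFAULT_PLASTID_IDENTITY,
    low_depth_factor: float = DEFAULT_LOW_DEPTH_FACTOR,
) -> ContigGraph:
    """Drop linkages below the depth threshold; drop contigs that look
    plastid-derived (match a plastid panel genome at >= plastid_identity over
    >= 50% of their length) AND sit below low_depth_factor x median contig
    depth.  Idempotent."""
    linkages = [ln for ln in gr.linkages if ln.depth >= min_link_depth]
    contigs = list(gr.contigs)
    if plastid_panel:
        med = median(c.depth for c in contigs) if contigs else 0.0
        cutoff = low_depth_factor * med
        keep = []
        for c in contigs:
            if c.depth < cutoff and _matches_panel(c, plastid_panel, plastid_identity):
                linkages = [
                    ln for ln in linkages if c.id not in (ln.contig1, ln.contig2)
                ]
                continue
            keep.append(c)
        contigs = keep
    return ContigGraph(contigs, linkages)


def _matches_panel(
    contig: Contig, panel: list[CircularGenome], min_identity: float, k: int = 15
) -> bool:
    from mitocircle.matcher import find_local_matches

    if contig.length < k:
        return False
    q = CircularGenome(contig.id, contig.seq, "linear")
    half = max(k, contig.length // 2)
    for donor in panel:
        frags = find_local_matches(q, donor, min_len=min(half, contig.length), min_identity=min_identity, k=k)
        covered = 0
        for f in frags:
            covered = max(covered, f.a.span)
        if covered >= contig.length * 0.5:
            return True
    return False


# ---------------------------------------------------------------------------
# Walk search
# ---------------------------------------------------------------------------


def _steps(gr: ContigGraph) -> dict[tuple[str, str], list[tuple[str, str, int]]]:
    """Adjacency: (contig, orientation) -> [(next contig, orientation, overlap)].

    Leaving a '+'-oriented contig uses its tail; a '-'-oriented one its head.
    Entering through 'head' gives '+' orientation, through 'tail' gives '-'.
    """
    adj: dict[tuple[str, str], list[tuple[str, str, int]]] = {}
    for ln in gr.linkages:
        for c1, e1, c2, e2 in (
            (ln.contig1, ln.end1, ln.contig2, ln.end2),
            (ln.contig2, ln.end2, ln.contig1, ln.end1),
        ):
            from_state = (c1, "+") if e1 == "tail" else (c1, "-")
            to_state = (c2, "+") if e2 == "head" else (c2, "-")
            adj.setdefault(from_state, []).append((to_state[0], to_state[1], ln.overlap))
    for v in adj.values():
        v.sort()
    return adj


def build_master_circle(
    gr: ContigGraph, max_visits: int = DEFAULT_MAX_VISITS
) -> MasterCircle:
    """Minimum-total-length closed walk covering every contig (branch-and-
    bound; exhaustive within the bound for small graphs).  Raises with the
    obstruction description when no covering closed walk exists."""
    if not gr.contigs:
        raise AssemblyError("empty contig graph")
    _check_connectivity(gr)
    lengths = {c.id: c.length for c in gr.contigs}
    adj = _steps(gr)
    n = len(gr.contigs)
    start_id = min(c.id for c in gr.contigs)
    best: dict = {"walk": None, "length": None, "visits": None}

    order = sorted(lengths)
    idx = {cid: i for i, cid in enumerate(order)}

    def search(
        state: tuple[str, str],
        walk: list[tuple[str, str]],
        counts: list[int],
        length: int,
        visited_all: bool,
    ) -> None:
        if best["walk"] is not None:
            # lower bound: every unvisited contig adds at least its length
            remaining = sum(
                lengths[order[i]] for i in range(n) if counts[i] == 0
            )
            if length + remaining > best["length"]:
                return
        # try to close the circle back to the start state
        for nxt, orient, overlap in adj.get(state, []):
            if (nxt, orient) == (start_id, "+") and all(c > 0 for c in counts):
                total = length - overlap
                cand_visits = sum(counts)
                if _is_better(total, cand_visits, walk, best):
                    best["walk"] = list(walk)
                    best["length"] = total
                    best["visits"] = cand_visits
        for nxt, orient, overlap in adj.get(state, []):
            i = idx[nxt]
            if counts[i] >= max_visits:
                continue
            counts[i] += 1
            walk.append((nxt, orient))
            search((nxt, orient), walk, counts, length + lengths[nxt] - overlap, False)
            walk.pop()
            counts[i] -= 1

    counts0 = [0] * n
    counts0[idx[start_id]] = 1
    search((start_id, "+"), [(start_id, "+")], counts0, lengths[start_id], False)

    if best["walk"] is None:
        raise AssemblyError(_obstruction_report(gr))
    walk = best["walk"]
    seq = _assemble_walk(gr, walk)
    visits: dict[str, int] = {}
    for cid, _ in walk:
        visits[cid] = visits.get(cid, 0) + 1
    return MasterCircle(walk=walk, sequence=seq, visits=visits)


def _is_better(total: int, visits: int, walk: list, best: dict) -> bool:
    if best["walk"] is None:
        return True
    if total != best["length"]:
        return total < best["length"]
    if visits != best["visits"]:
        return visits < best["visits"]
    return walk < best["walk"]


def _check_connectivity(gr: ContigGraph) -> None:
    g = nx.Graph()
    for c in gr.contigs:
        g.add_node(c.id)
    for ln in gr.linkages:
        g.add_edge(ln.contig1, ln.contig2)
    comps = list(nx.connected_components(g))
    if len(comps) > 1:
        raise AssemblyError(
            "no covering closed walk: linkage graph is disconnected; components: "
            + "; ".join(",".join(sorted(c)) for c in comps)
        )


def _obstruction_report(gr: ContigGraph) -> str:
    deg: dict[tuple[str, str], int] = {}
    for ln in gr.linkages:
        deg[(ln.contig1, ln.end1)] = deg.get((ln.contig1, ln.end1), 0) + 1
        deg[(ln.contig2, ln.end2)] = deg.get((ln.contig2, ln.end2), 0) + 1
    dead = [
        f"{c.id}:{end}"
        for c in gr.contigs
        for end in ("head", "tail")
        if deg.get((c.id, end), 0) == 0
    ]
    return (
        "no covering closed walk exists within the visit cap; dead contig ends: "
        + (", ".join(dead) if dead else "none (visit cap too low?)")
    )


def _assemble_walk(gr: ContigGraph, walk: list[tuple[str, str]]) -> CircularGenome:
    """Concatenate contigs along the closed walk, verifying exact overlaps."""
    overlaps = _walk_overlaps(gr, walk)
    parts = []
    for i, (cid, orient) in enumerate(walk):
        seq = gr.contig(cid).seq
        if orient == "-":
            seq = revcomp(seq)
        ov = overlaps[i]  # overlap consumed at this contig's start
        if ov:
            prev_cid, prev_orient = walk[i - 1]
            prev_seq = gr.contig(prev_cid).seq
            if prev_orient == "-":
                prev_seq = revcomp(prev_seq)
            if prev_seq[-ov:] != seq[:ov]:
                raise AssemblyError(
                    f"mismatched overlap ({ov} bp) between {prev_cid} and {cid}"
                )
        parts.append(seq[ov:])
    return CircularGenome("master_circle", "".join(parts), "circular")


def _walk_overlaps(gr: ContigGraph, walk: list[tuple[str, str]]) -> list[int]:
    adj = _steps(gr)
    n = len(walk)
    overlaps = []
    for i in range(n):
        prev = walk[(i - 1) % n]
        cur = walk[i]
        ov = None
        for nxt, orient, overlap in adj.get(prev, []):
            if (nxt, orient) == cur:
                ov = overlap
                break
        if ov is None:
            raise AssemblyError(f"walk step {prev} -> {cur} has no supporting linkage")
        overlaps.append(ov)
    return overlaps


WALK_COLUMNS = ["step", "contig", "orientation"]


def walk_to_rows(mc: MasterCircle) -> list[dict]:
    return [
        {"step": i + 1, "contig": cid, "orientation": orient}
        for i, (cid, orient) in enumerate(mc.walk)
    ]
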