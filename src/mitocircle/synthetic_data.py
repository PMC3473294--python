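"""Synthetic genome pairs, reference panels and contig graphs with ground truth.

The generator emulates the structure of a diverged pair of circular organelle
genomes: a near-identical syntenic backbone cut into segments, repeat-mediated
inversions and junction exchanges (with the mediating repeat copies planted at
the involved segment edges), mosaic unique-region insertions built from a
donor panel, sparse substitutions, and an optional nested inverted-repeat
integration signature.  Everything is reproducible bit-for-bit from
(config, seed), and the truth table is validated against the emitted
sequences at generation time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mitocircle.genome_io import CircInterval, CircularGenome, revcomp
from mitocircle.master_circle import Contig, ContigGraph, Linkage

# independent codon table for truth effect labels (the analysis side uses
# Biopython's translation; keeping two routes makes the SNP tests dual-route)
_CODON_TABLE = {}
_BASES = "TCAG"
_AA = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, _a in enumerate(_AA):
    _CODON_TABLE[_BASES[_i // 16] + _BASES[(_i // 4) % 4] + _BASES[_i % 4]] = _a

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InversionEvent:
    """Invert the contiguous segment run ``blocks`` (1-based segment ids),
    mediated by a planted inverted repeat pair flanking the run."""

    blocks: tuple[int, ...]


@dataclass(frozen=True)
class TranspositionEvent:
    """Move the segment run ``blocks`` after segment ``after_block``,
    mediated by a planted 3-copy direct repeat family at the three involved
    segment edges (one physical junction-exchange event)."""

    blocks: tuple[int, ...]
    after_block: int


@dataclass(frozen=True)
class InsertionEvent:
    """Insert a mosaic unique region after segment ``after_block``."""

    after_block: int
    length: int = 5000
    n_fragments: int = 8
    unsourced_fraction: float = 0.0
    with_signature: bool = False
    outer_repeat: int = 176
    inner_repeat: int = 28


@dataclass(frozen=True)
class PlantedRepeatSpec:
    """A standalone repeat pair planted in segment interiors (for catalog and
    sub-circle tests)."""

    length: int
    orientation: str  # "direct" | "inverted"
    segment1: int
    segment2: int
    n_substitutions: int = 0


@dataclass
class SimConfig:
    ancestor_length: int = 60000
    n_blocks: int = 4
    substitution_rate: float = 0.001
    planted_repeats: list[PlantedRepeatSpec] = field(default_factory=list)
    events: list = field(default_factory=list)
    seed: int = 0
    gc: float = 0.45
    event_repeat_len: int = 140
    panel_donors: int = 3
    panel_relatedness: float = 0.02
    gene_segments: tuple[int, ...] = ()
    cds_codons: int = 200
    n_cds_snps: int = 3
    edge_margin: int = 200  # substitution-free margin at piece edges

    def validate(self) -> None:
        seg_ids = set(range(1, self.n_blocks + 1))
        touched: set[int] = set()
        for ev in self.events:
            if isinstance(ev, InversionEvent):
                run = ev.blocks
                zone = set(run) | {
                    _mod(run[0] - 1, self.n_blocks),
                    _mod(run[-1] + 1, self.n_blocks),
                }
            elif isinstance(ev, TranspositionEvent):
                run = ev.blocks
                if ev.after_block == _mod(run[0] - 1, self.n_blocks):
                    raise SimulationError(
                        "events geometrically infeasible: no-op transposition"
                    )
                zone = set(run) | {
                    _mod(run[0] - 1, self.n_blocks),
                    _mod(run[-1] + 1, self.n_blocks),
                    ev.after_block,
                    _mod(ev.after_block + 1, self.n_blocks),
                }
            elif isinstance(ev, InsertionEvent):
                continue
            else:
                raise SimulationError(f"unknown event {ev!r}")
            if not set(run) <= seg_ids:
                raise SimulationError(f"event references unknown segments: {ev!r}")
            if len(zone) > len(set(zone)) or (touched & zone):
                raise SimulationError(
                    "events geometrically infeasible: overlapping/adjacent segment zones"
                )
            touched |= zone


def _mod(k: int, n: int) -> int:
    return ((k - 1) % n) + 1


# ---------------------------------------------------------------------------
# Truth table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TruthBlock:
    segments: tuple[int, ...]
    a_start: int
    b_start: int
    span: int
    sign: int  # +1 direct, -1 inverted


@dataclass(frozen=True)
class TruthSNP:
    pos_a: int
    pos_b: int
    ref_a: str
    alt_a: str  # alternate base expressed on genome A's strand
    gene: str | None = None
    cds_pos: int | None = None
    codon_index: int | None = None
    effect: str | None = None  # "synonymous" or e.g. "L37P"


@dataclass(frozen=True)
class TruthRegion:
    b_start: int
    span: int
    sourced_fraction: float
    with_signature: bool
    outer_repeat: int = 0
    inner_repeat: int = 0


@dataclass(frozen=True)
class TruthRepeat:
    pos1: int
    pos2: int
    length: int
    orientation: str
    genome: str  # "A" (shared backbone) — positions in A coordinates


@dataclass
class TruthTable:
    blocks: list[TruthBlock]
    n_inversions: int
    n_junction_events: int
    inversion_runs: list[tuple[int, ...]]
    repeats: list[TruthRepeat]
    snps: list[TruthSNP]
    regions: list[TruthRegion]
    gff3_rows: list[dict] = field(default_factory=list)
    walk: list[tuple[str, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------


def random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    at = (1 - gc) / 2
    gcp = gc / 2
    return "".join(
        rng.choice(np.array(list("ACGT")), size=length, p=[at, gcp, gcp, at])
    )


class _Occupied:
    """Interval bookkeeping so planted features never collide."""

    def __init__(self) -> None:
        self.ivs: list[tuple[int, int]] = []

    def claim(self, start: int, end: int) -> None:
        for s, e in self.ivs:
            if start < e and s < end:
                raise SimulationError(
                    f"planted features collide: [{start},{end}) vs [{s},{e})"
                )
        self.ivs.append((start, end))

    def mask(self, length: int) -> np.ndarray:
        m = np.zeros(length, dtype=bool)
        for s, e in self.ivs:
            m[s:e] = True
        return m


# ---------------------------------------------------------------------------
# Reference panel
# ---------------------------------------------------------------------------


def generate_reference_panel(
    donors: int,
    relatedness: float,
    seed: int,
    ancestor: str | None = None,
    length: int = 60000,
    gc: float = 0.45,
) -> list[CircularGenome]:
    """Panel genomes derived from a common ancestor by independent
    substitutions and a rotation (a trivial rearrangement)."""
    if donors < 1:
        raise SimulationError("donors must be >= 1")
    rng = np.random.default_rng(seed)
    if ancestor is None:
        ancestor = random_sequence(length, gc, rng)
    out = []
    arr = np.frombuffer(ancestor.encode(), dtype=np.uint8).copy()
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in range(donors):
        d = arr.copy()
        if relatedness > 0:
            nmut = rng.binomial(d.size, relatedness)
            pos = rng.choice(d.size, size=nmut, replace=False)
            for p in pos:
                choices = bases[bases != d[p]]
                d[p] = rng.choice(choices)
        rot = int(rng.integers(0, d.size))
        d = np.concatenate([d[rot:], d[:rot]])
        out.append(CircularGenome(f"panel_{i + 1}", d.tobytes().decode(), "circular"))
    return out


# ---------------------------------------------------------------------------
# Genome pair generation
# ---------------------------------------------------------------------------


def generate_genome_pair(
    cfg: SimConfig,
) -> tuple[CircularGenome, CircularGenome, TruthTable, list[CircularGenome]]:
    """Generate genome A, genome B (= A transformed by the scripted events
    plus substitutions), the truth table, and the donor panel used for mosaic
    inserts."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_blocks
    L = cfg.ancestor_length
    min_seg = max(4000, cfg.event_repeat_len * 4)
    if L < n * (min_seg + 1000):
        raise SimulationError("ancestor_length too small for n_blocks")

    # --- segment partition of the ancestor circle
    extra = L - n * min_seg
    extras = rng.multinomial(extra, [1.0 / n] * n)
    seg_len = [min_seg + int(e) for e in extras]
    seg_start = np.concatenate([[0], np.cumsum(seg_len[:-1])]).astype(int)
    seg = {i + 1: (int(seg_start[i]), int(seg_start[i] + seg_len[i])) for i in range(n)}

    a_seq = np.frombuffer(random_sequence(L, cfg.gc, rng).encode(), dtype=np.uint8).copy()
    occupied = _Occupied()

    def overwrite(start: int, s: str) -> None:
        occupied.claim(start, start + len(s))
        a_seq[start : start + len(s)] = np.frombuffer(s.encode(), dtype=np.uint8)

    # --- planted CDS genes
    gff3_rows: list[dict] = []
    cds_info: list[tuple[str, int, int]] = []  # (gene, start, length) forward strand
    for gi, sid in enumerate(cfg.gene_segments):
        s, e = seg[sid]
        cds_len = cfg.cds_codons * 3 + 3
        start = s + (e - s) // 2 - cds_len // 2
        body = []
        for _ in range(cfg.cds_codons):
            while True:
                codon = random_sequence(3, cfg.gc, rng)
                if _CODON_TABLE[codon] != "*":
                    break
            body.append(codon)
        cds = "ATG" + "".join(body) + "TAA"
        overwrite(start, cds)
        gene = f"gene{gi + 1}"
        cds_info.append((gene, start, len(cds)))
        gff3_rows.append(
            {
                "seqid": "genomeA",
                "type": "gene",
                "start": start,
                "end": start + len(cds),
                "strand": "+",
                "attributes": f"ID={gene}",
            }
        )
        gff3_rows.append(
            {
                "seqid": "genomeA",
                "type": "CDS",
                "start": start,
                "end": start + len(cds),
                "strand": "+",
                "phase": "0",
                "attributes": f"ID={gene}.cds;Parent={gene};gene={gene}",
            }
        )

    # --- standalone repeat pairs
    truth_repeats: list[TruthRepeat] = []
    for spec in cfg.planted_repeats:
        if spec.orientation not in ("direct", "inverted"):
            raise SimulationError(f"bad repeat orientation {spec.orientation!r}")
        s1, e1 = seg[spec.segment1]
        s2, e2 = seg[spec.segment2]
        core = random_sequence(spec.length, cfg.gc, rng)
        copy2 = core if spec.orientation == "direct" else revcomp(core)
        if spec.n_substitutions:
            c2 = list(copy2)
            pos = rng.choice(spec.length, size=spec.n_substitutions, replace=False)
            for p in pos:
                c2[p] = rng.choice([b for b in "ACGT" if b != c2[p]])
            copy2 = "".join(c2)
        p1 = s1 + (e1 - s1) // 4
        p2 = s2 + (e2 - s2) // 4
        if spec.segment1 == spec.segment2:
            p2 = s2 + 2 * (e2 - s2) // 3
        overwrite(p1, core)
        overwrite(p2, copy2)
        truth_repeats.append(
            TruthRepeat(p1, p2, spec.length, spec.orientation, "A")
        )

    # --- event repeats at segment edges
    inv_runs: list[tuple[int, ...]] = []
    n_junctions = 0
    for ev in cfg.events:
        if isinstance(ev, InversionEvent):
            rep = random_sequence(cfg.event_repeat_len, cfg.gc, rng)
            left_seg = _mod(ev.blocks[0] - 1, n)
            right_seg = _mod(ev.blocks[-1] + 1, n)
            overwrite(seg[left_seg][1] - len(rep), rep)
            overwrite(seg[right_seg][0], revcomp(rep))
            inv_runs.append(ev.blocks)
            truth_repeats.append(
                TruthRepeat(
                    seg[left_seg][1] - len(rep), seg[right_seg][0],
                    len(rep), "inverted", "A",
                )
            )
        elif isinstance(ev, TranspositionEvent):
            rep = random_sequence(cfg.event_repeat_len, cfg.gc, rng)
            for sid in (_mod(ev.blocks[0] - 1, n), ev.blocks[-1], ev.after_block):
                overwrite(seg[sid][1] - len(rep), rep)
            n_junctions += 1

    a_str = a_seq.tobytes().decode()

    # --- donor panel (shares the ancestor backbone at panel_relatedness)
    panel = generate_reference_panel(
        cfg.panel_donors,
        cfg.panel_relatedness,
        seed=cfg.seed + 104729,
        ancestor=a_str,
    )

    # --- B piece order
    perm: list[tuple] = [("seg", k, +1) for k in range(1, n + 1)]
    for ev in cfg.events:
        if isinstance(ev, InversionEvent):
            idxs = [i for i, p in enumerate(perm) if p[0] == "seg" and p[1] in ev.blocks]
            lo, hi = min(idxs), max(idxs)
            perm[lo : hi + 1] = [
                ("seg", p[1], -p[2]) for p in reversed(perm[lo : hi + 1])
            ]
    for ev in cfg.events:
        if isinstance(ev, TranspositionEvent):
            idxs = [i for i, p in enumerate(perm) if p[0] == "seg" and p[1] in ev.blocks]
            lo, hi = min(idxs), max(idxs)
            run = perm[lo : hi + 1]
            del perm[lo : hi + 1]
            anchor = next(
                i for i, p in enumerate(perm) if p[0] == "seg" and p[1] == ev.after_block
            )
            perm[anchor + 1 : anchor + 1] = run
    insert_payloads: list[tuple[str, float, InsertionEvent]] = []
    for ev in cfg.events:
        if isinstance(ev, InsertionEvent):
            ins_seq, sourced = _build_insert(ev, panel, cfg, rng)
            anchor = next(
                i for i, p in enumerate(perm) if p[0] == "seg" and p[1] == ev.after_block
            )
            perm[anchor + 1 : anchor + 1] = [("ins", len(insert_payloads), +1)]
            insert_payloads.append((ins_seq, sourced, ev))

    # --- emit B
    b_parts: list[str] = []
    piece_b_start: list[int] = []
    off = 0
    for p in perm:
        if p[0] == "seg":
            s, e = seg[p[1]]
            chunk = a_str[s:e] if p[2] > 0 else revcomp(a_str[s:e])
        else:
            chunk = insert_payloads[p[1]][0]
        piece_b_start.append(off)
        b_parts.append(chunk)
        off += len(chunk)
    b_str = "".join(b_parts)
    LB = len(b_str)

    # --- substitutions (B only), avoiding planted features and piece edges
    b_arr = np.frombuffer(b_str.encode(), dtype=np.uint8).copy()
    occ_mask_a = occupied.mask(L)
    snps: list[TruthSNP] = []

    def map_to_a(piece_idx: int, off_in_piece: int) -> int:
        p = perm[piece_idx]
        s, e = seg[p[1]]
        if p[2] > 0:
            return s + off_in_piece
        return e - 1 - off_in_piece

    forced: dict[int, list[int]] = {}
    if cfg.gene_segments and cfg.n_cds_snps:
        # force substitutions inside the first planted CDS
        gene, gstart, glen = cds_info[0]
        offsets = rng.choice(
            np.arange(3, glen - 3), size=min(cfg.n_cds_snps, glen - 6), replace=False
        )
        forced[0] = sorted(gstart + int(o) for o in offsets)

    for pi, p in enumerate(perm):
        if p[0] != "seg":
            continue
        s, e = seg[p[1]]
        plen = e - s
        margin = min(cfg.edge_margin, plen // 4)
        eligible = np.ones(plen, dtype=bool)
        eligible[:margin] = False
        eligible[plen - margin :] = False
        # map the occupied mask (A coords) into piece-local coordinates
        occ_local = occ_mask_a[s:e]
        if p[2] < 0:
            occ_local = occ_local[::-1]
        eligible &= ~occ_local
        idx_local = np.nonzero(eligible)[0]
        nmut = rng.binomial(idx_local.size, cfg.substitution_rate)
        chosen = (
            rng.choice(idx_local, size=nmut, replace=False) if nmut else np.array([], int)
        )
        targets = sorted(int(c) for c in chosen)
        # forced CDS substitutions (A coordinates -> piece-local)
        for a_pos in forced.get(0, []) if p[1] == (cfg.gene_segments[0] if cfg.gene_segments else None) else []:
            local = (a_pos - s) if p[2] > 0 else (e - 1 - a_pos)
            if local not in targets:
                targets.append(local)
        for local in sorted(set(targets)):
            b_pos = piece_b_start[pi] + local
            old = chr(b_arr[b_pos])
            new = str(rng.choice([b for b in "ACGT" if b != old]))
            b_arr[b_pos] = ord(new)
            a_pos = map_to_a(pi, local)
            ref_a = a_str[a_pos]
            alt_a = new if p[2] > 0 else _COMP[new]
            assert ref_a != alt_a
            snp = _truth_snp_effect(a_pos, b_pos, ref_a, alt_a, cds_info, a_str)
            snps.append(snp)

    b_final = b_arr.tobytes().decode()
    genome_a = CircularGenome("genomeA", a_str, "circular")
    genome_b = CircularGenome("genomeB", b_final, "circular")

    # --- truth blocks: merge B-adjacent pieces that are A-consecutive
    blocks = _truth_blocks(perm, seg, piece_b_start, n, L, LB)
    regions = []
    for pi, p in enumerate(perm):
        if p[0] == "ins":
            ins_seq, sourced, ev = insert_payloads[p[1]]
            regions.append(
                TruthRegion(
                    b_start=piece_b_start[pi],
                    span=len(ins_seq),
                    sourced_fraction=sourced,
                    with_signature=ev.with_signature,
                    outer_repeat=ev.outer_repeat if ev.with_signature else 0,
                    inner_repeat=ev.inner_repeat if ev.with_signature else 0,
                )
            )
    truth = TruthTable(
        blocks=blocks,
        n_inversions=len(inv_runs),
        n_junction_events=n_junctions,
        inversion_runs=inv_runs,
        repeats=truth_repeats,
        snps=sorted(snps, key=lambda s: s.pos_a),
        regions=regions,
        gff3_rows=gff3_rows,
    )
    _validate_truth(genome_a, genome_b, truth)
    return genome_a, genome_b, truth, panel


def _build_insert(
    ev: InsertionEvent, panel: list[CircularGenome], cfg: SimConfig, rng: np.random.Generator
) -> tuple[str, float]:
    """Mosaic insert from donor fragments plus optional unsourced filler and
    integration-signature repeats.  Returns (sequence, sourced_fraction)."""
    parts: list[tuple[str, bool]] = []  # (seq, sourced?)
    sig_head = sig_tail = ""
    sig_overhead = 0
    if ev.with_signature:
        outer = random_sequence(ev.outer_repeat, cfg.gc, rng)
        inner = random_sequence(ev.inner_repeat, cfg.gc, rng)
        sp1 = list(random_sequence(80, cfg.gc, rng))
        sp2 = list(random_sequence(80, cfg.gc, rng))
        pad1 = list(random_sequence(10, cfg.gc, rng))
        pad2 = list(random_sequence(10, cfg.gc, rng))
        # block exact-repeat extension at every planted boundary so the
        # detected lengths equal the constructed lengths exactly
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

        def enforce_differs(lst, idx, other_base):
            if lst[idx] == comp[other_base]:
                lst[idx] = {"A": "C", "C": "A", "G": "T", "T": "G"}[lst[idx]]

        enforce_differs(pad1, -1, pad2[0])   # outer, outward
        enforce_differs(sp1, 0, sp2[-1])     # outer, inward
        enforce_differs(sp1, -1, sp2[0])     # inner, outward
        sig_head = "".join(pad1) + outer + "".join(sp1) + inner
        sig_tail = revcomp(inner) + "".join(sp2) + revcomp(outer) + "".join(pad2)
        sig_overhead = len(sig_head) + len(sig_tail)
    core_target = max(ev.length - sig_overhead, 600)
    unsourced_target = int(core_target * ev.unsourced_fraction)
    sourced_target = core_target - unsourced_target
    frag_len = max(200, sourced_target // max(ev.n_fragments, 1))
    made = 0
    while made < sourced_target:
        ln = min(frag_len, sourced_target - made)
        if ln < 50:
            break
        donor = panel[int(rng.integers(0, len(panel)))]
        start = int(rng.integers(0, donor.length - ln))
        frag = donor.seq[start : start + ln]
        if rng.random() < 0.3:
            frag = revcomp(frag)
        parts.append((frag, True))
        made += ln
    if unsourced_target > 0:
        parts.append((random_sequence(unsourced_target, cfg.gc, rng), False))
    order = rng.permutation(len(parts))
    body = "".join(parts[i][0] for i in order)
    if ev.with_signature:
        # unsourced guards so the inner pair cannot extend into the body
        g1 = list(random_sequence(5, cfg.gc, rng))
        g2 = list(random_sequence(5, cfg.gc, rng))
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        if g1[0] == comp[g2[-1]]:
            g1[0] = {"A": "C", "C": "A", "G": "T", "T": "G"}[g1[0]]
        body = "".join(g1) + body + "".join(g2)
    seq = sig_head + body + sig_tail
    sourced_len = sum(len(s) for s, ok in parts if ok)
    return seq, sourced_len / len(seq)


def _truth_blocks(perm, seg, piece_b_start, n, L, LB) -> list[TruthBlock]:
    pieces = [
        (i, p) for i, p in enumerate(perm) if p[0] == "seg"
    ]
    m = len(pieces)
    used = [False] * m
    runs: list[list[int]] = []
    # group circularly: piece j follows piece i in B if consecutive in perm
    # (ignoring nothing: inserts break adjacency) and A-consecutive same-sign
    def b_adjacent(i_idx: int, j_idx: int) -> bool:
        pi = pieces[i_idx][0]
        pj = pieces[j_idx][0]
        return (pi + 1) % len(perm) == pj

    def a_consecutive(i_idx: int, j_idx: int) -> bool:
        _, (_, ki, si) = pieces[i_idx]
        _, (_, kj, sj) = pieces[j_idx]
        if si != sj:
            return False
        if si > 0:
            return _mod(ki + 1, n) == kj
        return _mod(ki - 1, n) == kj

    nxt = {}
    for i in range(m):
        for j in range(m):
            if i != j and b_adjacent(i, j) and a_consecutive(i, j):
                nxt[i] = j
    has_prev = set(nxt.values())
    starts = [i for i in range(m) if i not in has_prev]
    if not starts:  # all pieces chain into one whole-circle block
        for i, j in list(nxt.items()):
            if j == 0:
                del nxt[i]
        starts = [0]
    for st in starts:
        run = [st]
        cur = st
        while cur in nxt:
            cur = nxt[cur]
            run.append(cur)
        runs.append(run)
    blocks = []
    for run in runs:
        segs = tuple(pieces[i][1][1] for i in run)
        sign = pieces[run[0]][1][2]
        span = sum(seg[k][1] - seg[k][0] for k in segs)
        if sign > 0:
            a_start = seg[segs[0]][0]
        else:
            a_start = seg[segs[-1]][0]
        b_start = piece_b_start[pieces[run[0]][0]]
        blocks.append(TruthBlock(segs, a_start, b_start, span, sign))
    blocks.sort(key=lambda b: b.a_start)
    return blocks


def _truth_snp_effect(
    a_pos: int, b_pos: int, ref_a: str, alt_a: str, cds_info, a_str: str
) -> TruthSNP:
    for gene, gstart, glen in cds_info:
        if gstart <= a_pos < gstart + glen:
            cds_pos = a_pos - gstart + 1
            codon_index = (cds_pos + 2) // 3
            within = (cds_pos - 1) % 3
            c0 = gstart + (codon_index - 1) * 3
            ref_codon = a_str[c0 : c0 + 3]
            alt_codon = ref_codon[:within] + alt_a + ref_codon[within + 1 :]
            ra = _CODON_TABLE.get(ref_codon, "X")
            aa = _CODON_TABLE.get(alt_codon, "X")
            effect = "synonymous" if ra == aa else f"{ra}{codon_index}{aa}"
            return TruthSNP(a_pos, b_pos, ref_a, alt_a, gene, cds_pos, codon_index, effect)
    return TruthSNP(a_pos, b_pos, ref_a, alt_a)


def _validate_truth(
    genome_a: CircularGenome, genome_b: CircularGenome, truth: TruthTable
) -> None:
    """Direct string checks that the truth table is consistent with the
    emitted sequences."""
    for blk in truth.blocks:
        sa = genome_a.fetch(blk.a_start, blk.span)
        sb = genome_b.fetch(blk.b_start, blk.span)
        if blk.sign < 0:
            sb = revcomp(sb)
        n_snps_inside = sum(
            1
            for s in truth.snps
            if (s.pos_a - blk.a_start) % genome_a.length < blk.span
        )
        diff = sum(1 for x, y in zip(sa, sb) if x != y)
        if diff != n_snps_inside:
            raise SimulationError(
                f"truth inconsistency: block {blk.segments} has {diff} mismatches, "
                f"expected {n_snps_inside} substitutions"
            )
    for s in truth.snps:
        if genome_a.seq[s.pos_a] != s.ref_a:
            raise SimulationError("truth SNP ref mismatch")


# ---------------------------------------------------------------------------
# Contig graph generation
# ---------------------------------------------------------------------------


def generate_contig_graph(
    g: CircularGenome,
    mean_contig: int,
    depth: int,
    seed: int,
    repeat_pairs: list[tuple[int, int, int]] | None = None,
) -> tuple[ContigGraph, list[tuple[str, str]]]:
    """Cut a circular genome into contigs at random points (and exactly at the
    boundaries of the given exact direct repeat copies, which are emitted once
    with ~2x depth).  Returns the graph and the truth walk.
    """
    if mean_contig >= g.length:
        raise SimulationError("mean_contig must be smaller than the genome")
    rng = np.random.default_rng(seed)
    L = g.length
    repeat_pairs = repeat_pairs or []
    fixed = set()
    repeat_spans = []
    for p1, p2, ln in repeat_pairs:
        if g.fetch(p1, ln) != g.fetch(p2, ln):
            raise SimulationError("repeat copies are not identical")
        fixed.update((p1, (p1 + ln) % L, p2, (p2 + ln) % L))
        repeat_spans.append((p1, ln))
        repeat_spans.append((p2, ln))
    n_cuts = max(3, L // mean_contig)
    cuts = set(int(c) for c in rng.choice(L, size=n_cuts, replace=False)) | fixed
    # no cuts strictly inside a repeat copy
    for p, ln in repeat_spans:
        cuts = {c for c in cuts if not (0 < (c - p) % L < ln)} | {p, (p + ln) % L}
    cuts = sorted(cuts)
    tiles = []
    for i, c in enumerate(cuts):
        nxt = cuts[(i + 1) % len(cuts)]
        span = (nxt - c) % L
        if span == 0:
            span = L
        tiles.append((c, span))

    def repeat_id(start: int, span: int) -> str | None:
        for idx, (p1, p2, ln) in enumerate(repeat_pairs):
            if span == ln and start in (p1, p2):
                return f"repeat{idx + 1}"
        return None

    contigs: dict[str, Contig] = {}
    walk: list[tuple[str, str]] = []
    tile_ids = []
    for ti, (start, span) in enumerate(tiles):
        rid = repeat_id(start, span)
        cid = rid or f"contig{ti + 1:03d}"
        seqs = g.fetch(start, span)
        copies = 2 if rid else 1
        cdepth = float(
            max(1, round(depth * copies + rng.normal(0, depth * 0.05)))
        )
        if cid not in contigs:
            contigs[cid] = Contig(cid, seqs, cdepth)
        tile_ids.append(cid)
        walk.append((cid, "+"))
    linkages = []
    seen_links = set()
    for i, cid in enumerate(tile_ids):
        nid = tile_ids[(i + 1) % len(tile_ids)]
        key = (cid, "tail", nid, "head")
        if key in seen_links:
            continue
        seen_links.add(key)
        ldepth = float(max(DEFAULT_LINK_DEPTH_FLOOR, round(depth + rng.normal(0, depth * 0.1))))
        linkages.append(Linkage(cid, "tail", nid, "head", ldepth, 0))
    graph = ContigGraph(list(contigs.values()), linkages)
    # truth check: walking the tiles reproduces the genome
    assembled = "".join(contigs[cid].seq for cid in tile_ids)
    if not CircularGenome("check", assembled, "circular").rotation_equal(g):
        raise SimulationError("contig tiling does not reproduce the genome")
    return graph, walk


DEFAULT_LINK_DEPTH_FLOOR = 12


# ---------------------------------------------------------------------------
# Random configuration sampling (acceptance-style suites)
# ---------------------------------------------------------------------------


def random_sim_config(
    seed: int,
    size_range: tuple[int, int] = (50_000, 300_000),
    max_events: int = 4,
    substitution_rate: float = 0.0002,
) -> SimConfig:
    """A deterministic random scenario: genome size in ``size_range``,
    up to ``max_events`` repeat-mediated events with disjoint segment zones,
    1-2 mosaic inserts, and one annotated gene.

    The substitution rate default is below the headline 1e-3 so that block
    identity stays safely above the 0.999 chaining threshold.
    """
    rng = np.random.default_rng(seed)
    L = int(rng.integers(size_range[0], size_range[1] + 1))
    n = int(rng.integers(4, min(11, max(5, L // 9000)) + 1))
    segs = list(range(1, n + 1))

    available = set(segs)
    events: list = []
    n_events = int(rng.integers(0, max_events + 1))
    for _ in range(n_events):
        placeable = sorted(available)
        rng.shuffle(placeable)
        placed = False
        for s in placeable:
            if rng.random() < 0.6:
                zone = {_mod(s - 1, n), s, _mod(s + 1, n)}
                if zone <= available:
                    events.append(InversionEvent(blocks=(s,)))
                    available -= zone
                    placed = True
                    break
            else:
                for m in sorted(available - {s, _mod(s - 1, n)}):
                    zone = {_mod(s - 1, n), s, _mod(s + 1, n), m, _mod(m + 1, n)}
                    if zone <= available:
                        events.append(TranspositionEvent(blocks=(s,), after_block=m))
                        available -= zone
                        placed = True
                        break
                if placed:
                    break
        if not placed:
            break

    free = sorted(available)
    n_inserts = int(rng.integers(1, 3)) if free else 0
    for i in range(min(n_inserts, len(free))):
        anchor = free[int(rng.integers(0, len(free)))]
        free.remove(anchor)
        events.append(
            InsertionEvent(
                after_block=anchor,
                length=int(rng.integers(3000, 9000)),
                n_fragments=int(rng.integers(4, 12)),
                unsourced_fraction=float(rng.choice([0.0, 0.1, 0.2])),
                with_signature=bool(rng.integers(0, 2)) if i == 0 else False,
            )
        )
        if not free:
            break

    gene_segments = (free[0],) if free else ()
    return SimConfig(
        ancestor_length=L,
        n_blocks=n,
        substitution_rate=substitution_rate,
        events=events,
        seed=seed,
        gene_segments=gene_segments,
        n_cds_snps=2 if gene_segments else 0,
    )
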