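"""ORF prediction, ORF-set comparison, SNP calling and motif scanning.

ORFs are ATG-initiated, stop-terminated, standard genetic code, scanned in
all six frames over the doubled circle so origin-crossers are found once.
SNPs are positionwise differences inside orientation-normalized syntenic
blocks; substitutions inside annotated CDS get codon-level effect labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq

from mitocircle.genome_io import (
    CDSAnnotation,
    CircInterval,
    CircularGenome,
    revcomp,
)
from mitocircle.matcher import find_local_matches
from mitocircle.synteny import SyntenicBlock

DEFAULT_MIN_AA = 100
STOP_CODONS = ("TAA", "TAG", "TGA")


class GeneContentError(ValueError):
    pass


@dataclass(frozen=True)
class ORFRecord:
    iv: CircInterval  # start codon through stop codon inclusive
    aa_len: int  # codons excluding the stop
    protein: str
    label: str | None = None

    @property
    def name(self) -> str:
        return self.label or f"orf{self.aa_len}"


@dataclass(frozen=True)
class SNPRecord:
    block_id: int
    pos_a: int
    pos_b: int
    ref_a: str
    alt_b: str
    gene: str | None = None
    cds_pos: int | None = None
    codon_index: int | None = None
    aa_change: str | None = None

    def __post_init__(self) -> None:
        if self.ref_a == self.alt_b:
            raise GeneContentError("SNP with identical alleles")
        if self.cds_pos is not None and self.codon_index is not None:
            assert self.codon_index == (self.cds_pos + 2) // 3, (
                "codon_index inconsistent with cds_pos"
            )


@dataclass(frozen=True)
class IndelRecord:
    block_id: int
    pos_a: int
    pos_b: int
    note: str


def translate(seq: str) -> str:
    return str(Seq(seq).translate())


def find_orfs(g: CircularGenome, min_aa: int = DEFAULT_MIN_AA) -> list[ORFRecord]:
    """All six-frame ATG..stop ORFs with >= min_aa codons (stop excluded).

    Within one frame, ORFs sharing a stop keep only the longest (first ATG
    after the previous stop); origin-crossing ORFs are reported once with a
    wrap-capable interval.
    """
    L = g.length
    out: dict[tuple[int, str], ORFRecord] = {}
    for strand in ("+", "-"):
        seq = g.doubled() if strand == "+" else revcomp(g.doubled())
        for frame in range(3):
            for start, end in _frame_orfs(seq, frame, min_aa):
                nt = seq[start:end]
                if strand == "+":
                    g_start = start
                else:
                    # position in revcomp(doubled) maps back to forward coords
                    g_start = len(seq) - end
                if g.is_circular:
                    if start >= L:  # duplicate copy in the doubled sequence
                        continue
                    g_start %= L
                iv = CircInterval(g.id, g_start, end - start, strand)
                key = (g_start, strand)
                rec = ORFRecord(
                    iv=iv,
                    aa_len=(end - start) // 3 - 1,
                    protein=translate(nt[:-3]),
                )
                prev = out.get(key)
                if prev is None or rec.aa_len > prev.aa_len:
                    out[key] = rec
    recs = list(out.values())
    recs.sort(key=lambda r: (r.iv.start, r.iv.strand))
    return recs


def _frame_orfs(seq: str, frame: int, min_aa: int):
    """(start, end) pairs (end exclusive, includes stop codon) of qualifying
    ORFs in one reading frame of a linear string."""
    n = len(seq)
    start = None
    for i in range(frame, n - 2, 3):
        codon = seq[i : i + 3]
        if codon in STOP_CODONS:
            if start is not None:
                aa = (i - start) // 3
                if aa >= min_aa:
                    yield start, i + 3
                start = None
        elif start is None and codon == "ATG":
            start = i


def compare_orf_sets(
    orfs_a: list[ORFRecord],
    orfs_b: list[ORFRecord],
    genome_a: CircularGenome,
    genome_b: CircularGenome,
    blocks: list[SyntenicBlock] | None = None,
    min_match_identity: float = 0.95,
    min_match_cover: float = 0.90,
) -> tuple[list[ORFRecord], list[ORFRecord]]:
    """Genome-specific ORFs: an ORF is unique if the partner genome has no
    local match at >= min_match_identity covering >= min_match_cover of its
    nucleotide length."""
    unique_a = [
        o for o in orfs_a
        if not _has_homolog(o, genome_a, genome_b, min_match_identity, min_match_cover)
    ]
    unique_b = [
        o for o in orfs_b
        if not _has_homolog(o, genome_b, genome_a, min_match_identity, min_match_cover)
    ]
    return unique_a, unique_b


def _has_homolog(
    orf: ORFRecord,
    source: CircularGenome,
    partner: CircularGenome,
    min_identity: float,
    min_cover: float,
    k: int = 15,
) -> bool:
    seq = orf.iv.extract(source)
    if len(seq) < k:
        return True
    q = CircularGenome("orf_query", seq, "linear")
    need = int(min_cover * len(seq))
    frags = find_local_matches(
        q, partner, min_len=min(max(k, need // 4), len(seq)), min_identity=min_identity, k=k
    )
    covered = np.zeros(len(seq), dtype=bool)
    for f in frags:
        covered[f.a.start : min(f.a.end, len(seq))] = True
    return int(covered.sum()) >= need


def locate_orf(
    orf: ORFRecord,
    blocks: list[SyntenicBlock],
    regions,
    which: str,
    genome_length: int,
) -> str:
    """Describe an ORF's position relative to syntenic blocks / unique regions."""
    key = "iv_a" if which == "A" else "iv_b"
    mid = (orf.iv.start + orf.iv.span // 2) % genome_length
    for b in blocks:
        if getattr(b, key).contains(mid, genome_length):
            return f"syntenic region {b.block_id}"
    for r in regions or []:
        if r.iv.contains(mid, genome_length):
            return (
                f"unique region {r.region_id} (between syntenic regions "
                f"{r.flanking_blocks[0]} and {r.flanking_blocks[1]})"
            )
    return "intergenic"


# ---------------------------------------------------------------------------
# SNP calling
# ---------------------------------------------------------------------------


def call_snps(
    blocks: list[SyntenicBlock],
    genome_a: CircularGenome,
    genome_b: CircularGenome,
    annotations: list[CDSAnnotation] | None = None,
    edge_buffer: int = 25,
) -> tuple[list[SNPRecord], list[IndelRecord]]:
    """Positionwise comparison inside blocks after orientation normalization.

    Requires substitution-only blocks (equal spans); a span mismatch is
    reported as an indel record for that block rather than positionwise SNPs.
    Substitutions inside annotated CDS (on genome A) get codon-level labels.
    The outermost ``edge_buffer`` columns of each block are skipped: block
    boundaries carry a few score-positive chance-matching columns from the
    extension step, and mismatches there are boundary artifacts, not SNPs.
    """
    snps: list[SNPRecord] = []
    indels: list[IndelRecord] = []
    anns = annotations or []
    for b in blocks:
        if b.iv_a.span != b.iv_b.span:
            indels.append(
                IndelRecord(
                    block_id=b.block_id,
                    pos_a=b.iv_a.start,
                    pos_b=b.iv_b.start,
                    note=(
                        f"span mismatch {b.iv_a.span} vs {b.iv_b.span}; "
                        "alignment refinement required for positionwise comparison"
                    ),
                )
            )
            continue
        sa = genome_a.fetch(b.iv_a.start, b.iv_a.span)
        sb = b.iv_b.extract(genome_b) if b.orientation == "direct" else None
        if b.orientation == "inverted":
            sb = revcomp(genome_b.fetch(b.iv_b.start, b.iv_b.span))
        buf = min(edge_buffer, b.iv_a.span // 4)
        for off, (ca, cb) in enumerate(zip(sa, sb)):
            if off < buf or off >= b.iv_a.span - buf:
                continue
            if ca == cb or ca == "N" or cb == "N":
                continue
            pos_a = (b.iv_a.start + off) % genome_a.length
            if b.orientation == "direct":
                pos_b = (b.iv_b.start + off) % genome_b.length
                alt = cb
            else:
                pos_b = (b.iv_b.start + b.iv_b.span - 1 - off) % genome_b.length
                alt = cb  # reported on genome A's strand
            snps.append(_annotate_snp(b.block_id, pos_a, pos_b, ca, alt, genome_a, anns))
    return snps, indels


def _annotate_snp(
    block_id: int,
    pos_a: int,
    pos_b: int,
    ref: str,
    alt: str,
    genome_a: CircularGenome,
    annotations: list[CDSAnnotation],
) -> SNPRecord:
    for ann in annotations:
        cds_pos = ann.cds_pos_of(pos_a)
        if cds_pos is None:
            continue
        codon_index = (cds_pos + 2) // 3
        within = (cds_pos - 1) % 3
        cds_seq = ann.spliced_seq(genome_a)
        c0 = (codon_index - 1) * 3
        ref_codon = cds_seq[c0 : c0 + 3]
        alt_base = alt if ann.strand == "+" else revcomp(alt)
        alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
        ref_aa = translate(ref_codon)
        alt_aa = translate(alt_codon)
        aa_change = (
            "synonymous" if ref_aa == alt_aa else f"{ref_aa}{codon_index}{alt_aa}"
        )
        return SNPRecord(
            block_id=block_id,
            pos_a=pos_a,
            pos_b=pos_b,
            ref_a=ref,
            alt_b=alt,
            gene=ann.gene,
            cds_pos=cds_pos,
            codon_index=codon_index,
            aa_change=aa_change,
        )
    return SNPRecord(
        block_id=block_id, pos_a=pos_a, pos_b=pos_b, ref_a=ref, alt_b=alt
    )


# ---------------------------------------------------------------------------
# Motif scan
# ---------------------------------------------------------------------------


def scan_motif(
    g: CircularGenome, motif: str, max_mismatch: int = 0
) -> list[tuple[CircInterval, int]]:
    """All positions (both strands, wrap-capable) where the motif occurs with
    Hamming distance <= max_mismatch.  N never matches."""
    m = len(motif)
    if m > g.length:
        raise GeneContentError("motif longer than genome")
    from mitocircle.matcher import encode

    hits: list[tuple[CircInterval, int]] = []
    for strand in ("+", "-"):
        target = motif if strand == "+" else revcomp(motif)
        tarr = encode(target)
        sarr = encode(g.doubled())
        limit = g.length if g.is_circular else g.length - m + 1
        if limit <= 0:
            continue
        mm = np.zeros(limit, dtype=np.int32)
        for j in range(m):
            col = sarr[j : j + limit]
            mm += ((col != tarr[j]) | (col >= 4)).astype(np.int32)
        for pos in np.nonzero(mm <= max_mismatch)[0]:
            hits.append((CircInterval(g.id, int(pos), m, strand), int(mm[pos])))
    hits.sort(key=lambda h: (h[0].start, h[0].strand))
    return hits


ORF_COLUMNS = ["name", "start", "end", "strand", "aa_len", "location"]
SNP_COLUMNS = [
    "block_id", "pos_a", "pos_b", "ref_a", "alt_b", "gene", "cds_pos",
    "codon_index", "aa_change",
]


def snps_to_rows(snps: list[SNPRecord]) -> list[dict]:
    return [
        {
            "block_id": s.block_id,
            "pos_a": s.pos_a + 1,
            "pos_b": s.pos_b + 1,
            "ref_a": s.ref_a,
            "alt_b": s.alt_b,
            "gene": s.gene or "-",
            "cds_pos": s.cds_pos or "-",
            "codon_index": s.codon_index or "-",
            "aa_change": s.aa_change or "-",
        }
        for s in snps
    ]
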