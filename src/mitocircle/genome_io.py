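"""Sequence I/O and circular-coordinate arithmetic.

Internal convention: 0-based, end-exclusive coordinates; an interval may wrap
the origin, in which case ``start + span > length`` and covered positions are
``(start + k) % length`` for ``k in range(span)``.  All text reports written
by this package use 1-based inclusive coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: IUPAC ambiguity codes accepted on input; anything outside ACGT becomes N.
_IUPAC = set("ACGTURYSWKMBDHVN")


class GenomeIOError(ValueError):
    """Raised on malformed sequence input (empty, multi-record, bad alphabet)."""


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CircularGenome:
    """An immutable (usually circular) nucleotide sequence.

    Attributes
    ----------
    id : str
        Record identifier.
    seq : str
        Uppercase DNA over {A, C, G, T, N}.
    topology : str
        ``"circular"`` or ``"linear"``.
    """

    id: str
    seq: str
    topology: str = "circular"

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise GenomeIOError(f"genome {self.id!r}: empty sequence")
        if self.topology not in ("circular", "linear"):
            raise GenomeIOError(f"genome {self.id!r}: bad topology {self.topology!r}")
        bad = set(self.seq) - set("ACGTN")
        if bad:
            raise GenomeIOError(f"genome {self.id!r}: illegal characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def doubled(self) -> str:
        """Sequence doubled for origin-transparent scanning (circular only)."""
        return self.seq + self.seq if self.is_circular else self.seq

    def fetch(self, start: int, span: int) -> str:
        """Substring of ``span`` bases starting at ``start``, wrapping if circular."""
        L = self.length
        if span < 0 or span > L:
            raise ValueError(f"span {span} out of range for length {L}")
        start %= L
        if start + span <= L:
            return self.seq[start : start + span]
        if not self.is_circular:
            raise ValueError("interval runs off the end of a linear genome")
        return self.seq[start:] + self.seq[: start + span - L]

    def rotated(self, offset: int) -> "CircularGenome":
        """The same circle with the origin moved forward by ``offset`` bases."""
        if not self.is_circular:
            raise ValueError("cannot rotate a linear genome")
        off = offset % self.length
        return CircularGenome(self.id, self.seq[off:] + self.seq[:off], self.topology)

    def reverse_complement(self) -> "CircularGenome":
        return CircularGenome(self.id, revcomp(self.seq), self.topology)

    def rotation_equal(self, other: "CircularGenome", allow_flip: bool = False) -> bool:
        """True if the two circles carry the same sequence up to rotation
        (and, if ``allow_flip``, strand)."""
        if self.length != other.length:
            return False
        if self.seq in other.seq + other.seq:
            return True
        if allow_flip:
            rc = revcomp(other.seq)
            return self.seq in rc + rc
        return False


@dataclass(frozen=True, order=True)
class CircInterval:
    """A (possibly origin-wrapping) interval on one genome.

    ``start`` is 0-based; the interval covers ``(start + k) % genome_length``
    for ``k in range(span)`` (end-exclusive).  ``strand`` records which strand
    the feature lives on; coordinates are always on the forward strand.
    """

    genome_id: str
    start: int
    span: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.span < 1:
            raise ValueError(f"interval span must be >= 1, got {self.span}")
        if self.start < 0:
            raise ValueError(f"interval start must be >= 0, got {self.start}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def end(self) -> int:
        """Exclusive end, possibly past the genome length (wrapping)."""
        return self.start + self.span

    def wraps(self, genome_length: int) -> bool:
        return self.start + self.span > genome_length

    def positions(self, genome_length: int) -> Iterator[int]:
        for k in range(self.span):
            yield (self.start + k) % genome_length

    def contains(self, pos: int, genome_length: int) -> bool:
        return (pos - self.start) % genome_length < self.span

    def overlap(self, other: "CircInterval", genome_length: int) -> int:
        """Number of shared positions with ``other`` on a circle of the given
        length (exact, O(1), wrap-aware)."""
        L = genome_length
        # other's footprint relative to this interval's start
        off = (other.start % L - self.start % L) % L
        span_self = min(self.span, L)
        span_other = min(other.span, L)
        # piece 1: [off, off+span_other) clipped to [0, span_self)
        ov = max(0, min(off + span_other, span_self) - off) if off < span_self else 0
        # wrap piece: [0, off+span_other-L) clipped to [0, span_self)
        wrap_end = off + span_other - L
        if wrap_end > 0:
            ov += min(wrap_end, span_self)
        return min(ov, span_self, span_other)

    def extract(self, genome: CircularGenome) -> str:
        """Sequence of the interval, reverse-complemented if strand is '-'."""
        s = genome.fetch(self.start, self.span)
        return revcomp(s) if self.strand == "-" else s


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _sanitize(raw: str, rec_id: str) -> str:
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - _IUPAC
    if bad:
        raise GenomeIOError(f"record {rec_id!r}: illegal characters {sorted(bad)}")
    n_mapped = sum(1 for c in seq if c not in "ACGTN")
    if n_mapped:
        logger.info("record %s: mapped %d non-ACGT IUPAC bases to N", rec_id, n_mapped)
        seq = "".join(c if c in "ACGTN" else "N" for c in seq)
    return seq


def load_genome(path: str | Path, topology: str = "circular", fmt: str | None = None) -> CircularGenome:
    """Load a single-record FASTA or GenBank file as a :class:`CircularGenome`.

    Non-ACGT IUPAC codes are mapped to N (count logged).  Empty and
    multi-record files are rejected.
    """
    path = Path(path)
    if fmt is None:
        fmt = "genbank" if path.suffix.lower() in (".gb", ".gbk", ".genbank") else "fasta"
    records = list(SeqIO.parse(str(path), fmt))
    if not records:
        raise GenomeIOError(f"{path}: no sequence records found")
    if len(records) > 1:
        raise GenomeIOError(f"{path}: expected a single record, found {len(records)}")
    rec = records[0]
    seq = _sanitize(str(rec.seq), rec.id)
    if not seq:
        raise GenomeIOError(f"{path}: empty sequence")
    return CircularGenome(rec.id, seq, topology)


def write_fasta(genome: CircularGenome, path: str | Path, width: int = 70) -> None:
    rec = SeqRecord(Seq(genome.seq), id=genome.id, description="")
    with open(path, "w") as fh:
        SeqIO.write([rec], fh, "fasta")
    # Biopython wraps at 60; width kept for interface stability.


def gc_content(genome: CircularGenome) -> float:
    """(G+C) / (A+C+G+T); N bases are excluded from the denominator."""
    seq = genome.seq
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    if acgt == 0:
        raise GenomeIOError(f"genome {genome.id!r}: all-N sequence, GC content undefined")
    return gc / acgt


# ---------------------------------------------------------------------------
# Interval report writers (1-based inclusive in TSV, 0-based half-open in BED)
# ---------------------------------------------------------------------------


def write_bed(intervals: list[tuple[CircInterval, str]], path: str | Path, genome_length: int) -> None:
    """Write intervals as BED (0-based half-open).  Wrapping intervals are
    split into two BED lines sharing a name."""
    with open(path, "w") as fh:
        for iv, name in intervals:
            if iv.wraps(genome_length):
                fh.write(f"{iv.genome_id}\t{iv.start}\t{genome_length}\t{name}\t0\t{iv.strand}\n")
                fh.write(f"{iv.genome_id}\t0\t{iv.end - genome_length}\t{name}\t0\t{iv.strand}\n")
            else:
                fh.write(f"{iv.genome_id}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def write_tsv(rows: list[dict], path: str | Path, columns: list[str]) -> None:
    """Plain deterministic TSV writer with a header line."""
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in columns) + "\n")


# ---------------------------------------------------------------------------
# GFF3 annotation reading (CDS features grouped by gene)
# ---------------------------------------------------------------------------


@dataclass
class CDSAnnotation:
    """A (possibly multi-part) CDS on the annotated genome.

    Parts are stored in translation order: sorted by coordinate, ascending for
    '+' strand genes and descending for '-' strand genes.
    """

    gene: str
    strand: str
    parts: list[tuple[int, int]] = field(default_factory=list)  # 0-based half-open

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.parts)

    def cds_pos_of(self, genome_pos: int) -> int | None:
        """1-based position within the spliced CDS of a genome position, or
        None if the position is not inside the CDS."""
        offset = 0
        for s, e in self.parts:
            if s <= genome_pos < e:
                if self.strand == "+":
                    return offset + (genome_pos - s) + 1
                return offset + (e - 1 - genome_pos) + 1
            offset += e - s
        return None

    def spliced_seq(self, genome: CircularGenome) -> str:
        chunks = [genome.seq[s:e] for s, e in self.parts]
        seq = "".join(chunks)
        return revcomp(seq) if self.strand == "-" else seq


def read_gff3_cds(path: str | Path) -> list[CDSAnnotation]:
    """Read CDS features from a GFF3 file, grouped by gene/Parent attribute."""
    groups: dict[str, CDSAnnotation] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "CDS":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            gene = attrs.get("gene") or attrs.get("Parent") or attrs.get("ID") or "unknown"
            strand = f[6] if f[6] in "+-" else "+"
            start = int(f[3]) - 1
            end = int(f[4])
            ann = groups.setdefault(gene, CDSAnnotation(gene=gene, strand=strand))
            ann.parts.append((start, end))
    for ann in groups.values():
        ann.parts.sort(reverse=(ann.strand == "-"))
    return list(groups.values())


def write_gff3(features: list[dict], path: str | Path) -> None:
    """Write features as GFF3.  Each feature dict needs keys: seqid, source,
    type, start (0-based), end (exclusive), strand, attributes (str)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for ft in features:
            fh.write(
                "\t".join(
                    [
                        ft["seqid"],
                        ft.get("source", "mitocircle"),
                        ft["type"],
                        str(ft["start"] + 1),
                        str(ft["end"]),
                        ft.get("score", "."),
                        ft.get("strand", "+"),
                        ft.get("phase", "."),
                        ft.get("attributes", "."),
                    ]
                )
                + "\n"
            )
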