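"""Reference, annotation and alignment I/O plus the coordinate conventions.

Every interval in this package is 0-based half-open on a named contig.
SAM input is converted from 1-based at this boundary (by pysam); BED is
consumed natively; no other module performs coordinate conversion.

``N`` bases are carried through unchanged but never match anything in any
downstream scan (conservative specificity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Records below this mapping quality are excluded from evidence extraction.
DEFAULT_MAPQ_FLOOR = 20


class GenomeIOError(ValueError):
    """Malformed input in one of the supported text formats."""


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet (involution)."""
    s = seq.upper()
    bad = set(s) - VALID_BASES
    if bad:
        raise GenomeIOError(f"illegal base(s) {sorted(bad)} in sequence")
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval ``[start, end)`` with strand in {+,-,.}."""

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise GenomeIOError(
                f"invalid interval {self.contig}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise GenomeIOError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start <= other.start
            and other.end <= self.end
        )

    def __str__(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}({self.strand})"


@dataclass
class ReferenceGenome:
    """Ordered contig-name -> uppercase A/C/G/T/N sequence."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise GenomeIOError(f"contig {name!r} has empty sequence")
            bad = set(seq) - VALID_BASES
            if bad:
                raise GenomeIOError(
                    f"contig {name!r} contains illegal base(s) {sorted(bad)}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    def fetch(self, interval: GenomicInterval) -> str:
        """Sequence of an interval on the + strand of the reference."""
        self.check_interval(interval)
        return self.contigs[interval.contig][interval.start : interval.end]

    def check_interval(self, interval: GenomicInterval) -> None:
        if interval.contig not in self.contigs:
            raise GenomeIOError(f"unknown contig {interval.contig!r}")
        if interval.end > len(self.contigs[interval.contig]):
            raise GenomeIOError(
                f"interval {interval} beyond contig end "
                f"({len(self.contigs[interval.contig])} bp)"
            )


@dataclass
class GeneAnnotation:
    """A gene body with its (sorted, non-overlapping) exons."""

    name: str
    body: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.exons:
            self.exons = [self.body]
        prev_end = None
        for exon in self.exons:
            if not self.body.contains(exon):
                raise GenomeIOError(
                    f"exon {exon} outside gene body {self.body} ({self.name})"
                )
            if prev_end is not None and exon.start < prev_end:
                raise GenomeIOError(f"exons of {self.name} overlap or are unsorted")
            prev_end = exon.end

    @property
    def strand(self) -> str:
        return self.body.strand

    def three_prime_exon(self) -> GenomicInterval:
        """The exon at the transcription-direction 3' end of the gene."""
        return self.exons[-1] if self.strand != "-" else self.exons[0]


@dataclass(slots=True)
class AlignmentRecord:
    """Minimal BWA-MEM-style alignment evidence carrier.

    ``pos`` is the 0-based leftmost aligned reference base; ``cigar`` is a
    tuple of (op, length) with op in {M,I,D,S,H}.
    """

    query_name: str
    contig: str | None
    pos: int
    cigar: tuple[tuple[str, int], ...]
    mapq: int
    strand: str
    is_paired: bool
    is_proper_pair: bool
    is_unmapped: bool
    is_secondary: bool
    mate_contig: str | None
    mate_pos: int
    template_length: int

    @property
    def reference_end(self) -> int:
        """One past the last aligned reference base (M/D consume reference)."""
        return self.pos + sum(n for op, n in self.cigar if op in "MD")

    @property
    def is_reverse(self) -> bool:
        return self.strand == "-"


def read_fasta(path: str | Path) -> ReferenceGenome:
    """Parse a FASTA file into a :class:`ReferenceGenome`.

    Sequences are uppercased; duplicate headers and non-ACGTN characters
    are rejected.
    """
    path = Path(path)
    text_head = path.read_text()[:1000].lstrip()
    if text_head and not text_head.startswith(">"):
        raise GenomeIOError(f"{path}: not FASTA (line 1 does not start with '>')")
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise GenomeIOError(f"{path}: duplicate contig header {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise GenomeIOError(f"{path}: contig {rec.id!r} is empty")
        contigs[rec.id] = seq
    return ReferenceGenome(contigs)


def write_fasta(genome: ReferenceGenome, path: str | Path, width: int = 80) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.contigs.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_bed(path: str | Path, genome: ReferenceGenome | None = None) -> list[GeneAnnotation]:
    """Parse BED6 (one gene per line) or BED12 (blocks become exons).

    Coordinates are kept exactly as written (BED is already 0-based
    half-open). Unknown contigs are allowed but flagged with a warning
    when a genome is supplied.
    """
    annotations: list[GeneAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 6:
                raise GenomeIOError(f"{path}:{lineno}: expected >=6 BED columns")
            contig, name, strand = fields[0], fields[3], fields[5]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise GenomeIOError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise GenomeIOError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            if genome is not None and contig not in genome.contigs:
                logger.warning("%s:%d: unknown contig %r", path, lineno, contig)
            body = GenomicInterval(contig, start, end, strand)
            exons: list[GenomicInterval] = []
            if len(fields) >= 12:
                n_blocks = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
                if len(sizes) != n_blocks or len(offsets) != n_blocks:
                    raise GenomeIOError(f"{path}:{lineno}: inconsistent block columns")
                exons = [
                    GenomicInterval(contig, start + off, start + off + size, strand)
                    for off, size in zip(offsets, sizes)
                ]
            annotations.append(GeneAnnotation(name, body, exons))
    return annotations


def write_bed(annotations: Iterable[GeneAnnotation], path: str | Path) -> None:
    """Write annotations as BED12 so that exon structure round-trips."""
    with open(path, "w") as fh:
        for ann in annotations:
            b = ann.body
            sizes = ",".join(str(len(e)) for e in ann.exons)
            offsets = ",".join(str(e.start - b.start) for e in ann.exons)
            fh.write(
                f"{b.contig}\t{b.start}\t{b.end}\t{ann.name}\t0\t{b.strand}\t"
                f"{b.start}\t{b.end}\t0\t{len(ann.exons)}\t{sizes}\t{offsets}\n"
            )


_CIGAR_OPS = {0: "M", 1: "I", 2: "D", 3: "N", 4: "S", 5: "H", 7: "M", 8: "M"}
_QUERY_CONSUMING = "MIS"


def read_alignments(path: str | Path) -> Iterator[AlignmentRecord]:
    """Stream AlignmentRecords from a plain SAM file.

    Unmapped and secondary records are retained but flagged. Records whose
    CIGAR does not consume the stored sequence length are skipped with a
    logged warning.
    """
    n_skipped = 0
    header_lines: list[str] = []
    body: list[str] = []
    with open(path) as fh:
        for line in fh:
            (header_lines if line.startswith("@") else body).append(line)
    header = pysam.AlignmentHeader.from_text("".join(header_lines) or "@HD\tVN:1.6\n")

    for line in body:
        line = line.rstrip("\n")
        if not line:
            continue
        try:
            aln = pysam.AlignedSegment.fromstring(line, header)
        except (ValueError, OSError) as exc:
            logger.warning("unparseable SAM record skipped: %s", exc)
            n_skipped += 1
            continue
        cigar: tuple[tuple[str, int], ...] = ()
        if aln.cigartuples:
            try:
                cigar = tuple((_CIGAR_OPS[op], n) for op, n in aln.cigartuples)
            except KeyError:
                logger.warning("unsupported CIGAR op in %s; skipped", aln.query_name)
                n_skipped += 1
                continue
            seq = aln.query_sequence
            if seq is not None:
                consumed = sum(n for op, n in cigar if op in _QUERY_CONSUMING)
                if consumed != len(seq):
                    logger.warning(
                        "CIGAR/sequence length mismatch for %s; skipped",
                        aln.query_name,
                    )
                    n_skipped += 1
                    continue
        yield AlignmentRecord(
            query_name=aln.query_name or "",
            contig=aln.reference_name,
            pos=aln.reference_start if aln.reference_start is not None else -1,
            cigar=cigar,
            mapq=aln.mapping_quality,
            strand="-" if aln.is_reverse else "+",
            is_paired=aln.is_paired,
            is_proper_pair=aln.is_proper_pair,
            is_unmapped=aln.is_unmapped,
            is_secondary=aln.is_secondary or aln.is_supplementary,
            mate_contig=aln.next_reference_name,
            mate_pos=aln.next_reference_start
            if aln.next_reference_start is not None
            else -1,
            template_length=aln.template_length,
        )
    if n_skipped:
        logger.warning("skipped %d malformed alignment records", n_skipped)
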