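"""Genomic intervals and transcript models.

Coordinates are 0-based half-open internally; GTF I/O converts to and from
the on-disk 1-based inclusive convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded interval on a chromosome, 0-based half-open.

    ``strand`` is '+', '-' or '.' (unknown).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty interval: [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Intersection length in bases; 0 if on different chromosomes."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def gap_to(self, other: "GenomicInterval") -> int | None:
        """Bases between two intervals on the same chromosome (0 if they
        touch or overlap); None if chromosomes differ."""
        if self.chrom != other.chrom:
            return None
        return max(0, max(self.start, other.start) - min(self.end, other.end))

    def __str__(self) -> str:  # "10:777270-897286" style
        return f"{self.chrom}:{self.start + 1}-{self.end}"


def parse_locus(text: str, strand: str = ".") -> GenomicInterval:
    """Parse a "chrom:start-end" locus string (1-based inclusive, as printed
    in result tables) into a GenomicInterval. Accepts '-' or the en dash."""
    chrom, _, span = text.strip().rpartition(":")
    if not chrom:
        raise ValueError(f"malformed locus string: {text!r}")
    span = span.replace("–", "-")
    lo, _, hi = span.partition("-")
    return GenomicInterval(chrom, int(lo) - 1, int(hi), strand)


@dataclass
class TranscriptModel:
    """A stranded, possibly multi-exon transcript; the atomic unit of the
    identification filters.

    Exons must share the transcript's chromosome and strand, be sorted by
    start and non-overlapping.
    """

    transcript_id: str
    locus_id: str
    exons: tuple[GenomicInterval, ...]
    biotype: str = ""

    def __post_init__(self) -> None:
        exons = tuple(self.exons)
        if not exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >= 1 exon")
        chrom, strand = exons[0].chrom, exons[0].strand
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )
        for e in exons:
            if e.chrom != chrom or e.strand != strand:
                raise ValueError(
                    f"{self.transcript_id}: exons mix chromosomes or strands"
                )
        object.__setattr__(self, "exons", exons)

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def interval(self) -> GenomicInterval:
        """Genomic span from first exon start to last exon end."""
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def spliced_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        """(donor, acceptor) coordinate pairs of the introns, used for
        known-transcript matching (intron-chain identity)."""
        return tuple(
            (a.end, b.start) for a, b in zip(self.exons, self.exons[1:])
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TranscriptModel):
            return NotImplemented
        return (
            self.transcript_id == other.transcript_id
            and self.locus_id == other.locus_id
            and self.exons == other.exons
            and self.biotype == other.biotype
        )

    def __hash__(self) -> int:
        return hash((self.transcript_id, self.exons))


def make_transcript(
    transcript_id: str,
    locus_id: str,
    chrom: str,
    strand: str,
    exon_coords: Sequence[tuple[int, int]],
    biotype: str = "",
) -> TranscriptModel:
    """Convenience constructor from (start, end) pairs."""
    exons = tuple(
        GenomicInterval(chrom, s, e, strand) for s, e in sorted(exon_coords)
    )
    return TranscriptModel(transcript_id, locus_id, exons, biotype)
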