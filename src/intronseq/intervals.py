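"""Core genomic interval types.

All internal coordinates are 0-based, half-open ``[start, end)``.  The GTF
reader and SAF writer convert to/from the 1-based inclusive convention at the
I/O boundary only, so no other code ever needs to reason about off-by-ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval on a reference sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(
                f"require start < end, got [{self.start}, {self.end}) on {self.chrom}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share at least one base (strand ignored)."""
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass
class GeneParts:
    """A gene flattened to disjoint exon parts, derived intron parts and span.

    ``exon_parts`` is the union of all exons of all transcripts of the gene,
    sorted and non-overlapping.  ``intron_parts`` are exactly the gaps between
    consecutive exon parts, and ``genebody`` spans first exon start to last
    exon end, so exon and intron parts partition the genebody.
    """

    gene_id: str
    gene_type: str
    chrom: str
    strand: str
    exon_parts: list[GenomicInterval] = field(default_factory=list)
    intron_parts: list[GenomicInterval] = field(default_factory=list)
    genebody: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if not self.exon_parts:
            raise ValueError(f"gene {self.gene_id} has no exon parts")
        for prev, cur in zip(self.exon_parts, self.exon_parts[1:]):
            if cur.start < prev.end:
                raise ValueError(f"gene {self.gene_id}: exon parts overlap or unsorted")
        expected_introns = _gaps(self.exon_parts, self.chrom, self.strand)
        if not self.intron_parts:
            self.intron_parts = expected_introns
        elif [(i.start, i.end) for i in self.intron_parts] != [
            (i.start, i.end) for i in expected_introns
        ]:
            raise ValueError(f"gene {self.gene_id}: intron parts are not the exon gaps")
        span = GenomicInterval(
            self.chrom, self.exon_parts[0].start, self.exon_parts[-1].end, self.strand
        )
        if self.genebody is None:
            self.genebody = span
        elif (self.genebody.start, self.genebody.end) != (span.start, span.end):
            raise ValueError(f"gene {self.gene_id}: genebody does not match exon span")

    @property
    def total_exon_length(self) -> int:
        return sum(iv.length for iv in self.exon_parts)

    @property
    def total_intron_length(self) -> int:
        return sum(iv.length for iv in self.intron_parts)

    @property
    def length(self) -> int:
        return self.genebody.length


def _gaps(parts: list[GenomicInterval], chrom: str, strand: str) -> list[GenomicInterval]:
    out = []
    for prev, cur in zip(parts, parts[1:]):
        if cur.start > prev.end:
            out.append(GenomicInterval(chrom, prev.end, cur.start, strand))
    return out


def union_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge possibly overlapping ``(start, end)`` pairs into a disjoint union."""
    if not intervals:
        return []
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]
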