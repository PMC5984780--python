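"""Shared annotation records.

All coordinates are 0-based half-open internally; GTF I/O converts to and
from the 1-based inclusive convention at the file boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class TEFeature:
    """One transposable-element copy (RepeatMasker-style interval)."""

    chrom: str
    start: int
    end: int
    strand: str
    family: str

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"empty TE interval {self.chrom}:{self.start}-{self.end}")

    @property
    def effective_strand(self) -> str:
        # RepeatMasker convention: unstranded repeats treated as '+'
        return "+" if self.strand == "." else self.strand


@dataclass(frozen=True)
class GeneModel:
    """A transcript with exon blocks.

    ``exons`` are 0-based half-open, sorted, non-overlapping; ``start``/
    ``end`` span the whole transcript.  Introns are the span minus exons,
    so single-exon transcripts contribute no intron space.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str
    exons: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self):
        if not self.exons:
            object.__setattr__(self, "exons", ((self.start, self.end),))
        exons = tuple(sorted(tuple(e) for e in self.exons))
        object.__setattr__(self, "exons", exons)
        if exons[0][0] != self.start or exons[-1][1] != self.end:
            raise ValueError(
                f"{self.transcript_id}: exon blocks do not span the transcript"
            )

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return tuple(out)


@dataclass(frozen=True)
class NcRNALocus:
    """An rRNA/tRNA/miRNA-precursor locus with its (sense) sequence."""

    name: str
    ncrna_class: str  # rRNA | tRNA | known_miRNA | predicted_miRNA
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str

    def __post_init__(self):
        if len(self.sequence) != self.end - self.start:
            raise ValueError(f"{self.name}: sequence length does not match interval")
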