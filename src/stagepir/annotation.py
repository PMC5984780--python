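"""Genomic association of piRNA candidates.

Each candidate is assigned one category by the fixed precedence
TE > exon > intron > intergenic (>= 1 bp overlap), with genic categories
split by read-vs-gene strand.  TE-assigned reads are further attributed to
the transposon family of their maximal-overlap TE copy, with sense/antisense
orientation taken against the annotated TE strand.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .candidacy import CandidateSet, MappedRead
from .features import GeneModel, TEFeature

CATEGORIES = (
    "TE",
    "exon_sense",
    "exon_antisense",
    "intron_sense",
    "intron_antisense",
    "intergenic",
)


class FeatureIndex:
    """Strand-aware interval store over TE, exon and gene-span annotations."""

    def __init__(self, te_features: Iterable[TEFeature], gene_models: Iterable[GeneModel]):
        self._te: dict[str, IntervalTree] = {}
        self._exon: dict[str, IntervalTree] = {}
        self._gene: dict[str, IntervalTree] = {}
        self.te_features = list(te_features)
        self.gene_models = list(gene_models)
        for i, t in enumerate(self.te_features):
            self._te.setdefault(t.chrom, IntervalTree()).addi(t.start, t.end, i)
        for m in self.gene_models:
            self._gene.setdefault(m.chrom, IntervalTree()).addi(
                m.start, m.end, (m.strand, m.transcript_id)
            )
            for s, e in m.exons:
                self._exon.setdefault(m.chrom, IntervalTree()).addi(
                    s, e, (m.strand, m.transcript_id)
                )
        self.chromosomes = sorted(
            set(self._te) | set(self._gene) | set(self._exon)
        )

    def te_overlaps(self, chrom: str, start: int, end: int) -> list[TEFeature]:
        tree = self._te.get(chrom)
        if not tree:
            return []
        return [self.te_features[iv.data] for iv in tree.overlap(start, end)]

    def exon_strands(self, chrom: str, start: int, end: int) -> set[str]:
        tree = self._exon.get(chrom)
        if not tree:
            return set()
        return {iv.data[0] for iv in tree.overlap(start, end)}

    def gene_strands(self, chrom: str, start: int, end: int) -> set[str]:
        tree = self._gene.get(chrom)
        if not tree:
            return set()
        return {iv.data[0] for iv in tree.overlap(start, end)}


def assign_category(read: MappedRead, index: FeatureIndex, known_chroms: set[str] | None = None) -> str:
    """Single deterministic category for one read.

    When a read overlaps genes on both strands at the same level, the sense
    assignment wins (deterministic tie-break).
    """
    if known_chroms is not None and read.chrom not in known_chroms:
        raise ValueError(f"read {read.read_id} on unknown chromosome {read.chrom!r}")
    if index.te_overlaps(read.chrom, read.start, read.end):
        return "TE"
    exon_strands = index.exon_strands(read.chrom, read.start, read.end)
    if exon_strands:
        return "exon_sense" if read.strand in exon_strands else "exon_antisense"
    gene_strands = index.gene_strands(read.chrom, read.start, read.end)
    if gene_strands:
        return "intron_sense" if read.strand in gene_strands else "intron_antisense"
    return "intergenic"


def association_profile(cands: CandidateSet, index: FeatureIndex) -> pd.Series:
    """Copy-weighted category fractions; exact partition summing to 1."""
    if cands.denom == 0:
        raise ValueError(f"sample {cands.sample_id} has no candidates")
    counts = {c: 0 for c in CATEGORIES}
    for r in cands.reads:
        counts[assign_category(r, index)] += r.copies
    return pd.Series(counts, name=cands.sample_id) / cands.denom


def te_family_profile(cands: CandidateSet, index: FeatureIndex) -> pd.DataFrame:
    """Sense/antisense piRPM per TE family.

    Each TE-assigned read is attributed to the family of its maximal-overlap
    TE copy (ties broken lexicographically by family name); orientation is
    the read strand against the annotated TE strand ('.' treated as '+').
    TEs without a family label fall under ``unknown_family``.
    """
    if cands.denom == 0:
        raise ValueError(f"sample {cands.sample_id} has no candidates")
    acc: dict[str, dict[str, float]] = {}
    for r in cands.reads:
        hits = index.te_overlaps(r.chrom, r.start, r.end)
        if not hits:
            continue
        scored = [
            (min(r.end, t.end) - max(r.start, t.start), t.family or "unknown_family", t)
            for t in hits
        ]
        # maximal overlap first; lexicographically smallest family on ties
        scored.sort(key=lambda x: (-x[0], x[1]))
        _, family, te = scored[0]
        orient = "sense" if r.strand == te.effective_strand else "antisense"
        fam = acc.setdefault(family, {"sense": 0.0, "antisense": 0.0})
        fam[orient] += r.copies
    rows = {
        family: {
            "sense_piRPM": vals["sense"] / cands.denom * 1e6,
            "antisense_piRPM": vals["antisense"] / cands.denom * 1e6,
        }
        for family, vals in acc.items()
    }
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    if df.empty:
        df = pd.DataFrame(columns=["sense_piRPM", "antisense_piRPM"])
    return df.rename_axis("family")
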