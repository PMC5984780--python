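"""piRNA signature statistics.

Length distribution in piRPM (piRNA reads per million candidate reads),
positional nucleotide composition for the 5'-uracil (1U) bias, the
pairable-read 5'-overlap spectrum that exposes ping-pong amplification as a
peak at 10 nt, and the composition of the 10-nt-overlap subset (10A bias).

All statistics are copy-weighted.  Reads are in the DNA alphabet; 'U' in
output tables is the display name for T.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .candidacy import CandidateSet, MappedRead

BASE_ORDER = ("U", "A", "C", "G")
_DNA_TO_DISPLAY = {"T": "U", "A": "A", "C": "C", "G": "G"}


class EmptySampleError(ValueError):
    """Raised when a statistic is requested on a sample with denom == 0."""


class EmptySubsetError(ValueError):
    """Raised when the requested read subset (e.g. d=10 pairable) is empty."""


def five_prime(read: MappedRead) -> int:
    """Genomic position of the read's 5' end.

    ``start`` on the plus strand, ``end - 1`` on the minus strand (0-based).
    """
    return read.start if read.strand == "+" else read.end - 1


# ---------------------------------------------------------------------------
# length spectrum


def length_spectrum(cands: CandidateSet, min_len: int = 15, max_len: int = 45) -> pd.Series:
    """piRPM per read length; sums to 1e6 over the candidate window."""
    if cands.denom == 0:
        raise EmptySampleError(f"sample {cands.sample_id} has no candidates")
    counts = pd.Series(0.0, index=range(min_len, max_len + 1), name="piRPM")
    for r in cands.reads:
        counts[r.length] += r.copies
    return counts / cands.denom * 1e6


# ---------------------------------------------------------------------------
# positional composition


@dataclass
class CompositionMatrix:
    """Per-position base frequencies and enrichment over a background.

    ``freq`` rows are 1-based 5'->3' positions, columns U/A/C/G; each row
    sums to 1 over the reads long enough to reach it.  ``enrichment`` is
    frequency divided by the background frequency of the same base.
    """

    freq: pd.DataFrame
    enrichment: pd.DataFrame
    background: pd.Series
    n_reads: int
    n_copies: int


def _base_background(reads: Sequence[MappedRead]) -> pd.Series:
    counts = {b: 0.0 for b in BASE_ORDER}
    for r in reads:
        for ch in r.sequence:
            counts[_DNA_TO_DISPLAY[ch]] += r.copies
    total = sum(counts.values())
    return pd.Series(counts).reindex(BASE_ORDER) / total


def positional_composition(
    reads: Sequence[MappedRead],
    K: int = 15,
    background: pd.Series | str = "sample",
) -> CompositionMatrix:
    """Copy-weighted base composition at read positions 1..K.

    ``background`` is either ``"sample"`` (the copy-weighted overall base
    frequency of the reads, the default), ``"uniform"`` (0.25 each, under
    which enrichment equals 4 x frequency), or an explicit Series.
    """
    if not reads:
        raise EmptySampleError("no reads for composition")
    counts = np.zeros((K, 4))
    col = {b: j for j, b in enumerate(BASE_ORDER)}
    for r in reads:
        for i, ch in enumerate(r.sequence[:K]):
            counts[i, col[_DNA_TO_DISPLAY[ch]]] += r.copies
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        freq = np.where(totals > 0, counts / totals, np.nan)
    freq_df = pd.DataFrame(freq, index=range(1, K + 1), columns=BASE_ORDER)
    if isinstance(background, str):
        if background == "sample":
            bg = _base_background(reads)
        elif background == "uniform":
            bg = pd.Series(0.25, index=list(BASE_ORDER))
        else:
            raise ValueError(f"unknown background {background!r}")
    else:
        bg = background.reindex(BASE_ORDER)
    enrich = freq_df.divide(bg, axis=1)
    return CompositionMatrix(
        freq=freq_df,
        enrichment=enrich,
        background=bg,
        n_reads=len(reads),
        n_copies=sum(r.copies for r in reads),
    )


# ---------------------------------------------------------------------------
# overlap spectrum (ping-pong)


def _five_prime_tables(reads: Sequence[MappedRead]):
    """Per-chromosome 5'-position sets for each strand, with copy weights."""
    plus: dict[str, dict[int, int]] = {}
    minus: dict[str, dict[int, int]] = {}
    for r in reads:
        table = plus if r.strand == "+" else minus
        d = table.setdefault(r.chrom, {})
        p = five_prime(r)
        d[p] = d.get(p, 0) + r.copies
    return plus, minus


def pairable_copies(cands: CandidateSet, d: int) -> int:
    """Copy-weighted count of reads with >= 1 partner at exactly overlap d.

    Two reads pair at overlap ``d`` when they sit on opposite strands of the
    same chromosome and their 5' ends satisfy
    ``five_prime(minus) - five_prime(plus) = d - 1``.  Each read counts once
    per ``d`` regardless of how many partners it has there.
    """
    plus, minus = _five_prime_tables(cands.reads)
    total = 0
    for chrom, ptab in plus.items():
        mtab = minus.get(chrom)
        if not mtab:
            continue
        for p, copies in ptab.items():
            if p + d - 1 in mtab:
                total += copies
    for chrom, mtab in minus.items():
        ptab = plus.get(chrom)
        if not ptab:
            continue
        for p, copies in mtab.items():
            if p - d + 1 in ptab:
                total += copies
    return total


def overlap_spectrum(cands: CandidateSet, d_max: int = 20) -> pd.Series:
    """piRPM of pairable reads at each 5'-overlap length d = 1..d_max."""
    if cands.denom == 0:
        raise EmptySampleError(f"sample {cands.sample_id} has no candidates")
    vals = {d: pairable_copies(cands, d) / cands.denom * 1e6 for d in range(1, d_max + 1)}
    return pd.Series(vals, name="piRPM").rename_axis("overlap")


def pairable_reads(cands: CandidateSet, d: int) -> list[MappedRead]:
    """The reads pairable at exactly overlap ``d`` (for subset statistics)."""
    plus, minus = _five_prime_tables(cands.reads)
    out = []
    for r in cands.reads:
        p = five_prime(r)
        if r.strand == "+":
            mtab = minus.get(r.chrom, {})
            if p + d - 1 in mtab:
                out.append(r)
        else:
            ptab = plus.get(r.chrom, {})
            if p - d + 1 in ptab:
                out.append(r)
    return out


def pingpong_subset_composition(
    cands: CandidateSet, d: int = 10, K: int = 15, background: pd.Series | str = "sample"
) -> CompositionMatrix:
    """Positional composition restricted to reads pairable at overlap ``d``.

    Raises :class:`EmptySubsetError` when no reads pair at ``d`` — an
    explicit signal rather than a zero-filled matrix.
    """
    subset = pairable_reads(cands, d)
    if not subset:
        raise EmptySubsetError(f"no reads pairable at overlap {d}")
    return positional_composition(subset, K=K, background=background)


def pingpong_enrichment(spectrum: pd.Series, d: int = 10) -> float:
    """z-score of the overlap-``d`` signal against the other overlap lengths.

    With a flat spectrum (zero background SD) the z-score is reported as 0.
    """
    if len(spectrum) < 5:
        raise ValueError("spectrum must cover >= 5 overlap lengths")
    background = spectrum.drop(index=d)
    sd = background.std(ddof=0)
    if sd == 0:
        if spectrum[d] == background.mean():
            return 0.0  # flat spectrum: no enrichment signal
        return float(np.inf if spectrum[d] > background.mean() else -np.inf)
    return float((spectrum[d] - background.mean()) / sd)
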