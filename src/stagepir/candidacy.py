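"""High-confidence piRNA candidate selection.

The cascade mirrors the standard oxidised small RNA-seq workflow: 3' adaptor
trimming with a 15-45 nt insert window, collapsing identical inserts,
exact-match genomic placement (no mismatches, no indels), hierarchical
contaminant removal (rRNA/tRNA, then known miRNA precursors, then predicted
miRNA precursors, each by strand-insensitive substring containment), and
finally the 24-34 nt piRNA candidacy window.  Every step is copy-weighted
and tallied so the per-step filter report reconciles exactly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .dna import revcomp
from .index import ExactIndex

DEFAULT_ADAPTOR = "TGGAATTCTCGGGTGCCAAGGAACTCCAGTCAC"

#: fixed step order of the cascade; a read matching several blacklists is
#: attributed to the earliest step that sees it
FILTER_STEPS = (
    "input",
    "adaptor_trimmed_15_45",
    "genome_mapped",
    "rRNA_tRNA_removed",
    "known_miRNA_removed",
    "predicted_miRNA_removed",
    "candidates_24_34",
)


@dataclass(frozen=True)
class CollapsedRead:
    """A distinct insert sequence with its collapsed copy count."""

    read_id: str
    sequence: str
    copies: int

    def __post_init__(self):
        if self.copies < 1:
            raise ValueError("copies must be >= 1")


@dataclass(frozen=True)
class MappedRead:
    """Primary exact genomic placement of a collapsed read.

    ``n_hits`` is the total number of exact placements of the sequence on
    both strands; ``n_hits == 1`` marks a uniquely mapped read.
    """

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str
    copies: int
    n_hits: int

    def __post_init__(self):
        if self.end - self.start != len(self.sequence):
            raise ValueError("interval length does not match sequence length")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CandidateSet:
    """A sample's post-filter piRNA candidates.

    ``denom`` is the copy-weighted candidate total and serves as the piRPM
    denominator for every downstream statistic.
    """

    sample_id: str
    stage: str
    reads: list[MappedRead]
    denom: int = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        total = sum(r.copies for r in self.reads)
        if self.denom is None:
            self.denom = total
        elif self.denom != total:
            raise ValueError("denom must equal the copy-weighted read total")
        for r in self.reads:
            if not 24 <= r.length <= 34:
                raise ValueError(f"candidate outside 24-34 nt: {r.read_id}")


@dataclass
class FilterReport:
    """Ordered per-step tallies (copy-weighted) of the candidacy cascade."""

    rows: list[tuple[str, int, int]]  # (step, copies removed, copies remaining)

    def __post_init__(self):
        prev = None
        for step, removed, remaining in self.rows:
            if prev is not None and removed + remaining != prev:
                raise ValueError(f"filter report inconsistent at step {step!r}")
            prev = remaining

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["step", "removed", "remaining"])

    def removed(self, step: str) -> int:
        for s, removed, _ in self.rows:
            if s == step:
                return removed
        raise KeyError(step)

    @property
    def final_remaining(self) -> int:
        return self.rows[-1][2]


# ---------------------------------------------------------------------------
# adaptor trimming


def _locate_adaptor(seq: str, adaptor: str, seed_len: int, max_mismatch: int) -> int | None:
    """Start of the best adaptor alignment in ``seq``, or None.

    The adaptor prefix must align over >= ``seed_len`` bases with at most
    ``max_mismatch`` mismatches.  An exact seed occurrence is taken first
    (fast path); otherwise the leftmost minimum-mismatch placement wins.
    """
    seed = adaptor[:seed_len]
    i = seq.find(seed)
    while i != -1:
        span = min(len(adaptor), len(seq) - i)
        mism = sum(1 for a, b in zip(seq[i : i + span], adaptor[:span]) if a != b)
        if mism <= max_mismatch:
            return i
        i = seq.find(seed, i + 1)
    best = None
    best_mism = max_mismatch + 1
    for i in range(0, len(seq) - seed_len + 1):
        span = min(len(adaptor), len(seq) - i)
        mism = 0
        for a, b in zip(seq[i : i + span], adaptor[:span]):
            if a != b:
                mism += 1
                if mism >= best_mism:
                    break
        if mism < best_mism:
            best, best_mism = i, mism
    return best if best_mism <= max_mismatch else None


def trim_adaptor(
    raw_seqs: Iterable[str],
    adaptor: str = DEFAULT_ADAPTOR,
    min_len: int = 15,
    max_len: int = 45,
    max_mismatch: int = 1,
    seed_len: int = 10,
) -> tuple[list[CollapsedRead], dict[str, int]]:
    """Trim the 3' adaptor, apply the insert-size window, and collapse.

    Reads with no adaptor hit, inserts outside ``[min_len, max_len]``, or
    ambiguous bases (N) in the insert are discarded.  Identical inserts
    are merged into one :class:`CollapsedRead` with summed copies.
    """
    if len(adaptor) < seed_len:
        raise ValueError(f"adaptor must be >= {seed_len} nt")
    adaptor = adaptor.upper()
    tally = {"input": 0, "no_adaptor": 0, "length_out_of_range": 0, "ambiguous": 0, "passed": 0}
    counter: Counter[str] = Counter()
    for seq in raw_seqs:
        seq = seq.upper()
        tally["input"] += 1
        i = _locate_adaptor(seq, adaptor, seed_len, max_mismatch)
        if i is None:
            tally["no_adaptor"] += 1
            continue
        insert = seq[:i]
        if not min_len <= len(insert) <= max_len:
            tally["length_out_of_range"] += 1
            continue
        if set(insert) - set("ACGT"):
            tally["ambiguous"] += 1
            continue
        tally["passed"] += 1
        counter[insert] += 1
    collapsed = [
        CollapsedRead(f"c{k:07d}", seq, counter[seq])
        for k, seq in enumerate(sorted(counter))
    ]
    return collapsed, tally


def collapse_sequences(seqs_with_copies: Iterable[tuple[str, int]]) -> list[CollapsedRead]:
    """Collapse pre-trimmed inserts (e.g. from a collapsed FASTA)."""
    counter: Counter[str] = Counter()
    for seq, copies in seqs_with_copies:
        counter[seq.upper()] += copies
    return [
        CollapsedRead(f"c{k:07d}", seq, counter[seq])
        for k, seq in enumerate(sorted(counter))
    ]


# ---------------------------------------------------------------------------
# mapping


def build_exact_index(genome: Mapping[str, str]) -> ExactIndex:
    """Build the all-occurrence exact index over ``genome``."""
    return ExactIndex(genome)


def map_exact(
    reads: Sequence[CollapsedRead], index: ExactIndex
) -> tuple[list[MappedRead], dict[str, int]]:
    """Place every mappable sequence at its primary location.

    The primary placement is the lexicographically smallest
    ``(chrom, start, strand)`` hit ('+' before '-'), which removes aligner
    tie-breaking nondeterminism while ``n_hits`` keeps the full placement
    count for the unique-mapper audit.  Unmapped sequences are tallied and
    dropped.
    """
    mapped = []
    unmapped = {"sequences": 0, "copies": 0}
    for read in reads:
        hits = index.find_all(read.sequence)
        if not hits:
            unmapped["sequences"] += 1
            unmapped["copies"] += read.copies
            continue
        chrom, start, strand = hits[0]
        mapped.append(
            MappedRead(
                read_id=read.read_id,
                chrom=chrom,
                start=start,
                end=start + len(read.sequence),
                strand=strand,
                sequence=read.sequence,
                copies=read.copies,
                n_hits=len(hits),
            )
        )
    return mapped, unmapped


# ---------------------------------------------------------------------------
# contaminant removal


def _blacklist_blob(blacklist: Mapping[str, str] | Iterable[str]) -> str:
    seqs = list(blacklist.values()) if isinstance(blacklist, Mapping) else list(blacklist)
    seqs = [s.upper() for s in seqs]
    # '#' separators prevent matches spanning two blacklist entries
    return "#".join(seqs + [revcomp(s) for s in seqs])


def remove_by_sequence_class(
    reads: Sequence[MappedRead],
    blacklist: Mapping[str, str] | Iterable[str],
    label: str,
) -> tuple[list[MappedRead], dict[str, int]]:
    """Drop reads contained (either orientation) in any blacklist sequence.

    Removal is strand-insensitive: a read is removed iff its sequence or
    reverse complement occurs exactly as a substring of a blacklist entry.
    An empty blacklist is a no-op with a zero tally.
    """
    blob = _blacklist_blob(blacklist)
    kept, removed_copies, removed_seqs = [], 0, 0
    for read in reads:
        if blob and read.sequence in blob:
            removed_copies += read.copies
            removed_seqs += 1
        else:
            kept.append(read)
    return kept, {"label": label, "sequences": removed_seqs, "copies": removed_copies}


# ---------------------------------------------------------------------------
# full cascade


def run_candidacy(
    raw_seqs: Iterable[str] | None,
    genome: Mapping[str, str] | ExactIndex,
    blacklists: Mapping[str, Mapping[str, str]],
    sample_id: str,
    stage: str,
    adaptor: str | None = DEFAULT_ADAPTOR,
    collapsed: Sequence[CollapsedRead] | None = None,
    min_candidate_len: int = 24,
    max_candidate_len: int = 34,
) -> tuple[CandidateSet, FilterReport]:
    """Run the fixed-order candidacy cascade for one sample.

    ``blacklists`` must provide the keys ``rrna_trna``, ``known_mirna`` and
    ``predicted_mirna`` (name -> sequence mappings; may be empty).  Input is
    either ``raw_seqs`` (adaptor-bearing reads; ``adaptor`` required) or
    pre-collapsed inserts via ``collapsed``.
    """
    index = genome if isinstance(genome, ExactIndex) else build_exact_index(genome)

    if collapsed is None:
        if adaptor is None:
            raise ValueError("adaptor required when starting from raw reads")
        collapsed, trim_tally = trim_adaptor(list(raw_seqs), adaptor)
        n_input = trim_tally["input"]
    else:
        n_input = sum(r.copies for r in collapsed)

    n_trimmed = sum(r.copies for r in collapsed)
    rows = [("input", 0, n_input), ("adaptor_trimmed_15_45", n_input - n_trimmed, n_trimmed)]

    mapped, _unmapped = map_exact(collapsed, index)
    n_mapped = sum(r.copies for r in mapped)
    rows.append(("genome_mapped", n_trimmed - n_mapped, n_mapped))

    remaining = mapped
    for key, step in (
        ("rrna_trna", "rRNA_tRNA_removed"),
        ("known_mirna", "known_miRNA_removed"),
        ("predicted_mirna", "predicted_miRNA_removed"),
    ):
        remaining, tally = remove_by_sequence_class(remaining, blacklists.get(key, {}), key)
        prev = rows[-1][2]
        rows.append((step, tally["copies"], prev - tally["copies"]))

    final = [r for r in remaining if min_candidate_len <= r.length <= max_candidate_len]
    n_final = sum(r.copies for r in final)
    rows.append(("candidates_24_34", rows[-1][2] - n_final, n_final))

    cands = CandidateSet(sample_id=sample_id, stage=stage, reads=final)
    return cands, FilterReport(rows)


def candidates_to_bed(cands: CandidateSet) -> pd.DataFrame:
    """Candidates as BED6+ (name=read_id, score=copies, +sequence, +n_hits)."""
    rows = [
        (r.chrom, r.start, r.end, r.read_id, r.copies, r.strand, r.sequence, r.n_hits)
        for r in cands.reads
    ]
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "name", "score", "strand", "sequence", "n_hits"],
    )


def candidates_from_bed(df: pd.DataFrame, sample_id: str, stage: str) -> CandidateSet:
    reads = [
        MappedRead(
            read_id=str(r.name),
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            strand=str(r.strand),
            sequence=str(r.sequence),
            copies=int(r.score),
            n_hits=int(r.n_hits),
        )
        for r in df.itertuples(index=False)
    ]
    return CandidateSet(sample_id=sample_id, stage=stage, reads=reads)
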