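"""Exact-occurrence genome index.

Small-RNA candidacy requires every read to match the genome with no
mismatches and no indels, and the unique-mapper audit needs the *total*
number of exact placements of each sequence.  General-purpose aligners
report heuristic subsets and randomise among equal-best hits, so the
pipeline uses a deterministic all-occurrence exact index instead: a sorted
array of 15-mer integer codes over the genome, with full-length string
verification of every seed hit.  Queries are looked up on both strands.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .dna import as_bytes, revcomp, validate_dna

#: seed length; also the shortest query the index accepts (the read-length
#: floor of the trimming step is 15 nt, so every retained read is indexable)
K = 15

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i


class ExactIndex:
    """All-occurrence exact-match index over a genome.

    Parameters
    ----------
    genome
        Mapping of chromosome name to uppercase DNA sequence (ACGTN).

    Notes
    -----
    Windows containing N never match (exact-match contract).  Hits are
    reported as ``(chrom, start, strand)`` with 0-based starts; a minus-hit
    at ``start`` means the query equals the reverse complement of
    ``genome[chrom][start:start+len(query)]``.
    """

    def __init__(self, genome: Mapping[str, str]):
        if not genome:
            raise ValueError("empty genome")
        self._seqs: dict[str, str] = {}
        codes_parts = []
        pos_parts = []
        chrom_ids = []
        self._chroms = sorted(genome)
        for ci, name in enumerate(self._chroms):
            seq = genome[name].upper()
            validate_dna(seq)
            self._seqs[name] = seq
            if len(seq) < K:
                continue
            b = _BASE_CODE[as_bytes(seq)]
            n_win = len(seq) - K + 1
            code = np.zeros(n_win, dtype=np.uint64)
            for k in range(K):
                code = code * np.uint64(4) + b[k : k + n_win].astype(np.uint64)
            # windows containing N (code 255) are poisoned via a bad-count
            bad = (b >= 4).astype(np.int64)
            cs = np.concatenate([[0], np.cumsum(bad)])
            valid = (cs[K:] - cs[:-K]) == 0
            idx = np.nonzero(valid)[0]
            codes_parts.append(code[idx])
            pos_parts.append(idx.astype(np.int64))
            chrom_ids.append(np.full(idx.size, ci, dtype=np.int32))
        if codes_parts:
            codes = np.concatenate(codes_parts)
            order = np.argsort(codes, kind="stable")
            self._codes = codes[order]
            self._pos = np.concatenate(pos_parts)[order]
            self._cid = np.concatenate(chrom_ids)[order]
        else:
            self._codes = np.empty(0, dtype=np.uint64)
            self._pos = np.empty(0, dtype=np.int64)
            self._cid = np.empty(0, dtype=np.int32)

    # -- queries ---------------------------------------------------------

    def _occurrences(self, query: str) -> list[tuple[str, int]]:
        """Plus-strand exact occurrences of ``query``; verified hits only."""
        n = len(query)
        if n < K:
            raise ValueError(f"query shorter than index seed ({n} < {K})")
        if "N" in query:
            return []  # N never matches exactly
        code = np.uint64(0)
        for ch in query[:K]:
            v = _BASE_CODE[ord(ch)]
            if v >= 4:
                raise ValueError(f"non-ACGTN character in query: {ch!r}")
            code = code * np.uint64(4) + np.uint64(v)
        lo = np.searchsorted(self._codes, code, side="left")
        hi = np.searchsorted(self._codes, code, side="right")
        out = []
        for j in range(lo, hi):
            chrom = self._chroms[self._cid[j]]
            p = int(self._pos[j])
            if self._seqs[chrom][p : p + n] == query:
                out.append((chrom, p))
        return out

    def find_all(self, query: str) -> list[tuple[str, int, str]]:
        """All exact placements of ``query`` on both strands.

        Returns hits sorted by ``(chrom, start, strand)`` with '+' before
        '-'; the first element is therefore the deterministic primary
        placement used by the mapper.
        """
        query = query.upper()
        validate_dna(query)
        hits = [(c, p, "+") for c, p in self._occurrences(query)]
        hits += [(c, p, "-") for c, p in self._occurrences(revcomp(query))]
        hits.sort()
        return hits

    @property
    def chromosomes(self) -> list[str]:
        return list(self._chroms)

    def sequence(self, chrom: str) -> str:
        return self._seqs[chrom]
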