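"""Shared fixtures: a small synthetic reference bundle and helpers.

Session-scoped fixtures keep the expensive builds (reference genome, one
simulated sample pushed through the candidacy cascade) shared across test
modules; tiny hand-built inputs live inline in the tests that use them.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from stagepir.candidacy import MappedRead, run_candidacy
from stagepir.simulate import (
    NoiseSpec,
    ReferenceParams,
    build_reference,
    default_cluster_specs,
    simulate_sample,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

#: reduced-size reference used by unit tests (the full-size default bundle
#: is exercised by the acceptance suite)
SMALL_PARAMS = ReferenceParams(
    genome_size=400_000,
    n_chroms=2,
    te_copies_per_family=5,
    te_block_count=2,
    te_block_size=2,
    n_genes=8,
)

SMALL_NOISE = NoiseSpec(
    degradation=40,
    te_reads=400,
    rrna_frags=150,
    trna_frags=75,
    known_mirna=75,
    predicted_mirna=40,
)


def mk_read(
    chrom="chr1",
    start=100,
    seq="T" * 28,
    strand="+",
    copies=1,
    n_hits=1,
    read_id="r1",
) -> MappedRead:
    return MappedRead(
        read_id=read_id,
        chrom=chrom,
        start=start,
        end=start + len(seq),
        strand=strand,
        sequence=seq,
        copies=copies,
        n_hits=n_hits,
    )


@pytest.fixture(scope="session")
def small_bundle():
    return build_reference(SMALL_PARAMS, seed=11)


@pytest.fixture(scope="session")
def small_specs(small_bundle):
    return default_cluster_specs(small_bundle, base_n=3000)


@pytest.fixture(scope="session")
def bc_sample(small_bundle, small_specs):
    """A BC-stage sample simulated and pushed through candidacy."""
    records, manifest = simulate_sample(
        small_bundle, small_specs, "BC", noise=SMALL_NOISE, seed=5, sample_id="BC"
    )
    cands, report = run_candidacy(
        [s for _, s in records],
        small_bundle.genome,
        small_bundle.blacklists(),
        sample_id="BC",
        stage="BC",
    )
    return {"records": records, "manifest": manifest, "cands": cands, "report": report}


def brute_force_hits(genome: dict[str, str], query: str) -> list[tuple[str, int, str]]:
    """Independent all-occurrence exact search (both strands) for oracles."""
    from stagepir.dna import revcomp

    hits = []
    for chrom in sorted(genome):
        seq = genome[chrom]
        for q, strand in ((query, "+"), (revcomp(query), "-")):
            i = seq.find(q)
            while i != -1:
                hits.append((chrom, i, strand))
                i = seq.find(q, i + 1)
    return sorted(hits)


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
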