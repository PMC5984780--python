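"""Cluster detection, merging, extension, quantification, enrichment,
MDS and synteny."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from stagepir.candidacy import CandidateSet
from stagepir.clusters import (
    ClusterParams,
    MergedCluster,
    PiCluster,
    classify_mode,
    classify_stage_enrichment,
    clusterable_copies,
    detect_clusters,
    extend_by_transcripts,
    extend_once,
    mds_embedding,
    merge_clusters,
    quantify_pirpkm,
    synteny_check,
)
from stagepir.features import GeneModel

from conftest import mk_read, rng


def cand_set(reads, sample_id="S", stage="BC"):
    return CandidateSet(sample_id=sample_id, stage=stage, reads=list(reads))


def _enc(i, length):
    """Base-4 encoding of ``i`` as DNA, for distinct read sequences."""
    s = []
    for _ in range(length):
        s.append("ACGT"[i % 4])
        i //= 4
    return "".join(s)


def spread_reads(start, end, n, strand="+", chrom="chr1", seq_char="T", prefix="r"):
    """n distinct reads spread evenly over [start, end) on one strand."""
    step = max((end - start - 34) // max(n - 1, 1), 1)
    reads = []
    for i in range(n):
        s = start + i * step
        seq = seq_char + _enc(i, 27)  # 28 nt, 5' base seq_char (T => 1U)
        reads.append(mk_read(chrom=chrom, start=s, seq=seq, strand=strand,
                             read_id=f"{prefix}{i}"))
    return reads


def pc(chrom, start, end, sample="S", mode="mono_plus"):
    return PiCluster(sample, chrom, start, end, mode, 50, 10, 0.9, 25.0)


class TestDetectClusters:
    def test_dense_run_becomes_one_cluster_spanning_reads(self):
        reads = spread_reads(10_000, 12_000, 50, strand="-")
        out = detect_clusters(cand_set(reads))
        assert len(out) == 1
        c = out[0]
        assert c.start == min(r.start for r in reads)
        assert c.end == max(r.end for r in reads)
        assert c.mode == "mono_minus"

    def test_too_few_distinct_sequences_rejected(self):
        reads = spread_reads(10_000, 12_000, 4)
        assert detect_clusters(cand_set(reads)) == []

    def test_groups_separated_by_more_than_max_gap_split(self):
        reads = spread_reads(10_000, 12_000, 30) + spread_reads(32_000, 34_000, 30, prefix="q")
        out = detect_clusters(cand_set(reads))
        assert len(out) == 2

    def test_low_u1_run_rejected(self):
        reads = spread_reads(10_000, 12_000, 50, seq_char="G")
        assert detect_clusters(cand_set(reads)) == []

    def test_short_span_rejected(self):
        reads = [mk_read(start=10_000 + i, seq="T" * 28, read_id=f"r{i}") for i in range(20)]
        assert detect_clusters(cand_set(reads), ClusterParams(min_len=1000)) == []


class TestClassifyMode:
    def test_pure_plus_is_mono(self):
        assert classify_mode(spread_reads(0, 3000, 40)) == "mono_plus"

    def test_minus_block_then_plus_block_is_bidirectional(self):
        reads = spread_reads(0, 2000, 20, strand="-") + spread_reads(2500, 4500, 20, prefix="q")
        assert classify_mode(reads) == "bidirectional"

    def test_alternating_strands_is_dual_and_matches_split_oracle(self):
        reads = []
        for i in range(40):
            strand = "+" if i % 2 == 0 else "-"
            reads.append(mk_read(start=100 * i, seq="T" * 28, strand=strand, read_id=f"r{i}"))
        # brute-force best split: try every split point and orientation
        from stagepir.signatures import five_prime

        order = sorted(reads, key=lambda r: (five_prime(r), r.strand, r.sequence))
        total = sum(r.copies for r in order)
        best = total
        for k in range(len(order) + 1):
            for a, b in (("+", "-"), ("-", "+")):
                viol = sum(r.copies for r in order[:k] if r.strand != a)
                viol += sum(r.copies for r in order[k:] if r.strand != b)
                best = min(best, viol)
        assert best > 0.10 * total
        assert classify_mode(reads) == "dual_strand"

    def test_mono_tolerates_small_minority(self):
        reads = spread_reads(0, 3000, 19) + [
            mk_read(start=500, seq="T" * 28, strand="-", read_id="m")
        ]
        assert classify_mode(reads) == "mono_plus"


class TestMergeClusters:
    def test_overlapping_pair_unions(self):
        merged = merge_clusters([[pc("chr1", 100, 2000)], [pc("chr1", 1500, 3000, "S2")]])
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end) == (100, 3000)

    def test_disjoint_clusters_unchanged(self):
        merged = merge_clusters([[pc("chr1", 100, 2000)], [pc("chr1", 5000, 6000, "S2")]])
        assert [(m.start, m.end) for m in merged] == [(100, 2000), (5000, 6000)]

    def test_touching_intervals_do_not_merge(self):
        merged = merge_clusters([[pc("chr1", 0, 1000)], [pc("chr1", 1000, 2000, "S2")]])
        assert len(merged) == 2

    def test_transitive_chain_unions_to_one(self):
        chain = [[pc("chr1", 0, 10)], [pc("chr1", 5, 20, "S2")], [pc("chr1", 15, 30, "S3")]]
        # brute-force union-find oracle over pairwise overlaps
        import networkx as nx

        flat = [c for lst in chain for c in lst]
        g = nx.Graph()
        g.add_nodes_from(range(len(flat)))
        for i, j in itertools.combinations(range(len(flat)), 2):
            a, b = flat[i], flat[j]
            if a.chrom == b.chrom and a.start < b.end and b.start < a.end:
                g.add_edge(i, j)
        n_components = nx.number_connected_components(g)
        merged = merge_clusters(chain)
        assert len(merged) == n_components == 1
        assert (merged[0].start, merged[0].end) == (0, 30)

    @given(st.lists(st.tuples(st.integers(0, 50), st.integers(1, 30)), min_size=0, max_size=12))
    def test_idempotent_and_order_invariant(self, items):
        clusters = [pc("chr1", s, s + l) for s, l in items]
        merged = merge_clusters([clusters])
        again = merge_clusters([[pc(m.chrom, m.start, m.end) for m in merged]])
        assert [(m.start, m.end) for m in merged] == [(a.start, a.end) for a in again]
        rev = merge_clusters([list(reversed(clusters))])
        assert [(m.start, m.end) for m in merged] == [(a.start, a.end) for a in rev]
        # pairwise disjoint per chromosome
        for a, b in zip(merged, merged[1:]):
            assert a.end <= b.start


def tx(tid, start, end, chrom="chr1"):
    return GeneModel(tid, tid, chrom, start, end, "+", "protein_coding")


FPKM = pd.DataFrame(
    {"ds1": [2.3, 1.5, 0.5]},
    index=pd.Index(["txA", "txB", "txC"], name="transcript_id"),
)
MODELS = [tx("txA", 1800, 4000), tx("txB", 3900, 6000), tx("txC", 5900, 9000)]


class TestExtendByTranscripts:
    def test_single_expressed_transcript_grows_cluster(self):
        reg = [MergedCluster("c1", "chr1", 1000, 2000)]
        out = extend_by_transcripts(reg, [tx("txA", 1800, 4000)], FPKM.loc[["txA"]])
        assert (out[0].start, out[0].end) == (1000, 4000)

    def test_below_threshold_fpkm_does_not_extend(self):
        reg = [MergedCluster("c1", "chr1", 1000, 2000)]
        low = pd.DataFrame({"ds1": [0.5]}, index=pd.Index(["txA"], name="transcript_id"))
        out = extend_by_transcripts(reg, [tx("txA", 1800, 4000)], low)
        assert (out[0].start, out[0].end) == (1000, 2000)

    def test_chained_transcripts_reach_fixpoint_not_single_pass(self):
        reg = [MergedCluster("c1", "chr1", 1000, 2000)]
        out = extend_by_transcripts(reg, MODELS, FPKM)
        # txC (FPKM 0.5) gates the chain at txB's end
        assert (out[0].start, out[0].end) == (1000, 6000)
        # regression guard: one pass alone stops at txA's span
        reg2 = [MergedCluster("c1", "chr1", 1000, 2000)]
        expressed = [m for m in MODELS if m.transcript_id in ("txA", "txB")]
        extend_once(reg2, expressed)
        assert (reg2[0].start, reg2[0].end) == (1000, 4000)

    def test_monotone_boundaries_only_grow(self):
        reg = [MergedCluster("c1", "chr1", 1000, 7000)]
        out = extend_by_transcripts(reg, MODELS, FPKM)
        assert out[0].start <= 1000 and out[0].end >= 7000


class TestQuantifyPirpkm:
    def _setup(self):
        reg = [MergedCluster("c1", "chr1", 10_000, 15_000)]
        inside = [mk_read(start=10_000 + 40 * i, seq="T" * 28, read_id=f"i{i}") for i in range(25)]
        outside = [mk_read(start=100_000 + 40 * i, seq="T" * 28, read_id=f"o{i}") for i in range(25)]
        cands = cand_set(inside * 2 + outside * 2)  # 50 copies in, 50 out
        return reg, cands

    def test_arithmetic(self):
        # 50 copies in a 5-kb cluster; with denom rescaled to one million
        # this is the canonical 10.0 piRPKM case
        reg = [MergedCluster("c1", "chr1", 10_000, 15_000)]
        reads = [
            mk_read(start=10_100 + i * 50, seq="T" * 28, copies=20_000, read_id=f"r{i}")
            for i in range(50)
        ]
        cands = cand_set(reads)
        assert cands.denom == 1_000_000
        mat, _ = quantify_pirpkm(reg, {"S": cands})
        assert mat.loc["c1", "S"] == pytest.approx(1e6 / 5.0)  # all copies inside
        # and the explicit formula on a mixed in/out composition
        reg2 = [MergedCluster("c1", "chr1", 10_000, 15_000)]
        mixed = cand_set(
            [mk_read(start=10_100, seq="T" * 28, copies=50, read_id="a"),
             mk_read(start=900_000, seq="T" * 28, copies=999_950, read_id="b")]
        )
        mat2, _ = quantify_pirpkm(reg2, {"S": mixed})
        assert mat2.loc["c1", "S"] == pytest.approx(10.0)

    def test_copy_scaling_invariance(self):
        reg, cands = self._setup()
        mat1, _ = quantify_pirpkm(reg, {"S": cands})
        for k in (2, 10):
            scaled = cand_set(
                [mk_read(r.chrom, r.start, r.sequence, r.strand, r.copies * k,
                         r.n_hits, r.read_id) for r in cands.reads]
            )
            mat2, _ = quantify_pirpkm(reg, {"S": scaled})
            assert np.allclose(mat1.to_numpy(), mat2.to_numpy(), rtol=1e-12, atol=0)

    def test_five_prime_at_end_coordinate_not_assigned(self):
        reg = [MergedCluster("c1", "chr1", 10_000, 15_000)]
        boundary = mk_read(start=15_000, seq="T" * 28, read_id="b")
        inside = mk_read(start=14_999, seq="T" * 28, read_id="i")
        mat, _ = quantify_pirpkm(reg, {"S": cand_set([boundary, inside])})
        # only the read whose 5' sits inside the half-open interval counts
        assert mat.loc["c1", "S"] == pytest.approx(1 / 5.0 / (2 / 1e6))

    def test_zero_denom_sample_raises(self):
        reg = [MergedCluster("c1", "chr1", 0, 5000)]
        with pytest.raises(ValueError):
            quantify_pirpkm(reg, {"S": cand_set([])})

    def test_eg_stage_is_mean_of_member_samples(self):
        reg, cands = self._setup()
        e11 = cand_set(cands.reads, sample_id="E11G", stage="E11G")
        e14 = cand_set(cands.reads[:25], sample_id="E14G", stage="E14G")
        e11.sample_id, e14.sample_id = "E11G", "E14G"
        mat, stage = quantify_pirpkm(reg, {"E11G": e11, "E14G": e14})
        assert stage.loc["c1", "EG"] == pytest.approx(mat.loc["c1"].mean())


class TestStageEnrichment:
    def test_clear_top_stage_is_enriched(self):
        m = pd.DataFrame({"BC": [0.5], "PGC": [0.2], "EG": [0.1], "AT": [0.05]}, index=["c"])
        assert classify_stage_enrichment(m)["c"] == "BC-piRC"

    def test_insufficient_fold_is_shared(self):
        m = pd.DataFrame({"BC": [0.5], "PGC": [0.4], "EG": [0.1], "AT": [0.05]}, index=["c"])
        assert classify_stage_enrichment(m)["c"] == "shared"

    def test_all_below_cutoff_not_expressed(self):
        m = pd.DataFrame({"BC": [0.05], "PGC": [0.04], "EG": [0.0], "AT": [0.0]}, index=["c"])
        assert classify_stage_enrichment(m)["c"] == "not_expressed"

    def test_exact_tie_at_top_is_shared(self):
        m = pd.DataFrame({"BC": [0.4], "PGC": [0.4], "EG": [0.1], "AT": [0.0]}, index=["c"])
        assert classify_stage_enrichment(m)["c"] == "shared"


class TestMds:
    def test_identical_samples_embed_at_distance_zero(self):
        m = pd.DataFrame(rng(1).random((10, 1)), columns=["A"])
        m = pd.concat([m, m.rename(columns={"A": "B"}), m.rename(columns={"A": "C"})], axis=1)
        coords, _ = mds_embedding(m)
        d = np.linalg.norm(coords.loc["A"] - coords.loc["B"])
        assert d == pytest.approx(0.0, abs=1e-9)

    def test_collinear_profiles_put_all_variance_on_dim1(self):
        # three samples on a line in log space
        base = np.full(5, 1.0)
        m = pd.DataFrame(
            {"A": 10.0 ** (base), "B": 10.0 ** (base + 1), "C": 10.0 ** (base + 2)}
        ) - 0.01  # cancel the embedding pseudocount exactly
        coords, fractions = mds_embedding(m)
        assert fractions[0] == pytest.approx(1.0)
        assert fractions[1] == pytest.approx(0.0, abs=1e-9)

    def test_three_point_configuration_reproduced_exactly(self):
        r = rng(3)
        m = pd.DataFrame(10.0 ** r.normal(0, 1, (6, 3)) - 0.01, columns=["A", "B", "C"])
        X = np.log10(m.to_numpy().T + 0.01)
        coords, _ = mds_embedding(m, k=2)
        for i, j in itertools.combinations(range(3), 2):
            want = np.linalg.norm(X[i] - X[j])
            got = np.linalg.norm(coords.iloc[i] - coords.iloc[j])
            assert got == pytest.approx(want, abs=1e-8)


class TestSynteny:
    ANCHOR = {
        "pair1": {
            "chicken": ("chr1", (1000, 4000), (9000, 12_000)),
            "zebrafinch": ("s7", (500, 2000), (8000, 9000)),
        }
    }

    def test_conserved_when_both_species_have_interior_cluster(self):
        clusters = {"chicken": [("chr1", 5000, 8000)], "zebrafinch": [("s7", 3000, 6000)]}
        assert synteny_check(self.ANCHOR, clusters)["pair1"]

    def test_missing_partner_cluster_not_conserved(self):
        clusters = {"chicken": [("chr1", 5000, 8000)], "zebrafinch": []}
        assert not synteny_check(self.ANCHOR, clusters)["pair1"]

    def test_straddling_cluster_not_conserved(self):
        clusters = {
            "chicken": [("chr1", 8000, 10_000)],  # crosses geneB's start
            "zebrafinch": [("s7", 3000, 6000)],
        }
        assert not synteny_check(self.ANCHOR, clusters)["pair1"]

    def test_overlapping_anchors_raise(self):
        bad = {"p": {"chicken": ("chr1", (1000, 5000), (4000, 9000))}}
        with pytest.raises(ValueError, match="overlap"):
            synteny_check(bad, {"chicken": []})


class TestClusterableCopies:
    def test_counts_only_five_prime_inside(self):
        reg = [MergedCluster("c1", "chr1", 1000, 2000)]
        inside = mk_read(start=1500, seq="T" * 28, read_id="a")
        minus_in = mk_read(start=990, seq="T" * 28, strand="-", read_id="b")  # 5' 1017
        out = mk_read(start=5000, seq="T" * 28, read_id="c")
        assert clusterable_copies(reg, cand_set([inside, minus_in, out])) == 2
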