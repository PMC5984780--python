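"""Candidacy cascade: trimming, exact mapping, contaminant removal."""

import pytest

from stagepir.candidacy import (
    DEFAULT_ADAPTOR,
    build_exact_index,
    map_exact,
    remove_by_sequence_class,
    run_candidacy,
    trim_adaptor,
    collapse_sequences,
)
from stagepir.dna import revcomp
from stagepir.index import ExactIndex

from conftest import brute_force_hits, mk_read, rng


class TestTrimAdaptor:
    def test_full_adaptor_is_cut_at_its_start(self):
        reads = ["T" * 28 + DEFAULT_ADAPTOR]
        collapsed, tally = trim_adaptor(reads)
        assert len(collapsed) == 1
        assert collapsed[0].sequence == "T" * 28
        assert tally["passed"] == 1

    def test_insert_below_size_window_is_discarded(self):
        # 10 nt insert < the 15 nt floor of the size window
        collapsed, tally = trim_adaptor(["ACGTACGTAC" + DEFAULT_ADAPTOR])
        assert collapsed == []
        assert tally["length_out_of_range"] == 1

    def test_identical_inserts_collapse_with_summed_copies(self):
        insert = "ACGT" * 7
        collapsed, _ = trim_adaptor([insert + DEFAULT_ADAPTOR] * 2)
        assert len(collapsed) == 1
        assert collapsed[0].copies == 2

    def test_one_mismatch_in_adaptor_still_trims(self):
        mutated = "C" + DEFAULT_ADAPTOR[1:]
        collapsed, _ = trim_adaptor(["ACGT" * 6 + mutated])
        assert collapsed and collapsed[0].sequence == "ACGT" * 6

    def test_read_without_adaptor_is_discarded(self):
        collapsed, tally = trim_adaptor(["A" * 40])
        assert collapsed == []
        assert tally["no_adaptor"] == 1

    def test_n_in_insert_is_discarded(self):
        collapsed, tally = trim_adaptor(["ACGTN" * 5 + DEFAULT_ADAPTOR])
        assert collapsed == []
        assert tally["ambiguous"] == 1

    def test_empty_input_gives_empty_output_and_zero_tally(self):
        collapsed, tally = trim_adaptor([])
        assert collapsed == [] and tally["input"] == 0


class TestExactIndex:
    def test_plus_strand_hits(self):
        idx = ExactIndex({"c": "ACGTACGTAA" * 3})
        # use a 15+ nt query built on the repeat; spec-sized micro example
        hits = idx.find_all("ACGTACGTAAACGTA")
        assert all(s == "+" for *_, s in hits)
        assert [p for _, p, _ in hits] == [0, 10]

    def test_minus_strand_hits_at_same_loci(self):
        genome = {"c": "ACGTACGTAA" * 3}
        q = "ACGTACGTAAACGTA"
        plus = ExactIndex(genome).find_all(q)
        minus = ExactIndex(genome).find_all(revcomp(q))
        assert [(c, p) for c, p, _ in plus] == [(c, p) for c, p, _ in minus]
        assert all(s == "-" for *_, s in minus)

    def test_absent_query_has_no_hits(self):
        idx = ExactIndex({"c": "A" * 50})
        assert idx.find_all("C" * 20) == []

    def test_non_dna_genome_rejected(self):
        with pytest.raises(ValueError):
            ExactIndex({"c": "ACGTX" * 10})

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_genome(self, seed):
        r = rng(seed)
        genome = {"g": "".join("ACGT"[i] for i in r.integers(0, 4, 10_000))}
        idx = ExactIndex(genome)
        for _ in range(100):
            L = int(r.integers(24, 35))
            s = int(r.integers(0, 10_000 - L))
            q = genome["g"][s : s + L]
            if r.random() < 0.5:
                q = revcomp(q)
            assert idx.find_all(q) == brute_force_hits(genome, q)


class TestMapExact:
    def test_multimapper_gets_lexicographic_primary_and_full_n_hits(self):
        unit = "ACGTTGCACGTACGA"  # 15 nt, non-palindromic
        genome = {"a": "CC" + unit + "GG" + unit, "b": unit}
        reads = collapse_sequences([(unit, 3)])
        mapped, unmapped = map_exact(reads, build_exact_index(genome))
        assert unmapped["copies"] == 0
        (m,) = mapped
        assert (m.chrom, m.start, m.strand) == ("a", 2, "+")
        assert m.n_hits == 3
        assert m.copies == 3

    def test_unique_mapper_has_n_hits_one(self):
        genome = {"a": "A" * 30 + "ACGTTGCACGTACGA" + "G" * 30}
        mapped, _ = map_exact(collapse_sequences([("ACGTTGCACGTACGA", 1)]), build_exact_index(genome))
        assert mapped[0].n_hits == 1

    def test_unmappable_sequence_is_tallied_and_dropped(self):
        genome = {"a": "A" * 60}
        mapped, unmapped = map_exact(
            collapse_sequences([("CGCGCGCGCGCGCGCG", 4)]), build_exact_index(genome)
        )
        assert mapped == []
        assert unmapped == {"sequences": 1, "copies": 4}


class TestRemoveBySequenceClass:
    RRNA = {"rrna1": "ACGT" * 30}

    def test_contained_read_removed(self):
        read = mk_read(seq=("ACGT" * 30)[3:31])
        kept, tally = remove_by_sequence_class([read], self.RRNA, "rrna")
        assert kept == [] and tally["copies"] == 1

    def test_revcomp_containment_also_removed(self):
        read = mk_read(seq=revcomp(("ACGT" * 30)[3:31]), strand="-")
        kept, tally = remove_by_sequence_class([read], self.RRNA, "rrna")
        assert kept == []

    def test_non_matching_read_retained(self):
        read = mk_read(seq="TTGGCCAATTGGCCAATTGGCCAATTGG")
        kept, tally = remove_by_sequence_class([read], self.RRNA, "rrna")
        assert kept == [read] and tally["copies"] == 0

    def test_empty_blacklist_is_noop(self):
        read = mk_read()
        kept, tally = remove_by_sequence_class([read], {}, "rrna")
        assert kept == [read] and tally["copies"] == 0


class TestRunCandidacy:
    def _genome(self):
        r = rng(123)
        return {"chr1": "".join("ACGT"[i] for i in r.integers(0, 4, 5000))}

    def test_planted_composition_yields_exact_tallies(self):
        """10 rRNA fragments, 5 miRNAs, 60 piRNAs, 20 short mapped reads."""
        genome = self._genome()
        g = genome["chr1"]
        rrna_seq = g[100:400]
        mirna_seq = g[600:680]
        reads = []
        reads += [rrna_seq[10:38] + DEFAULT_ADAPTOR] * 10  # 28 nt rRNA frags
        reads += [mirna_seq[5:27] + DEFAULT_ADAPTOR] * 5  # 22 nt mature miRNA
        reads += [g[1000 + 40 * i : 1028 + 40 * i] + DEFAULT_ADAPTOR for i in range(60)]
        reads += [g[3000 + 30 * i : 3020 + 30 * i] + DEFAULT_ADAPTOR for i in range(20)]
        cands, report = run_candidacy(
            reads,
            genome,
            {"rrna_trna": {"rrna1": rrna_seq}, "known_mirna": {"mir1": mirna_seq}},
            "S1",
            "BC",
        )
        assert report.removed("rRNA_tRNA_removed") == 10
        assert report.removed("known_miRNA_removed") == 5
        assert report.removed("candidates_24_34") == 20  # 20 nt reads fail the window
        assert cands.denom == 60

    def test_zero_contaminants_passes_everything_in_window(self):
        genome = self._genome()
        reads = [genome["chr1"][50 * i : 50 * i + 30] + DEFAULT_ADAPTOR for i in range(10)]
        cands, report = run_candidacy(reads, genome, {}, "S1", "BC")
        assert cands.denom == 10
        assert all(report.removed(s) == 0 for s, _, _ in report.rows[2:])

    def test_all_unmapped_gives_empty_candidate_set(self):
        genome = self._genome()
        reads = ["CGCG" * 7 + DEFAULT_ADAPTOR]
        cands, report = run_candidacy(reads, genome, {}, "S1", "BC")
        assert cands.denom == 0 and cands.reads == []
        assert report.removed("genome_mapped") == 1

    def test_conservation_removed_plus_remaining_balances(self, bc_sample):
        rows = bc_sample["report"].rows
        for (_s, _r, prev_remaining), (_, removed, remaining) in zip(rows, rows[1:]):
            assert removed + remaining == prev_remaining

    def test_rrna_mirna_collision_attributed_to_earlier_step(self):
        """A read contained in both blacklists is charged to rRNA/tRNA."""
        genome = self._genome()
        shared = genome["chr1"][2000:2028]
        blk = {
            "rrna_trna": {"rrna1": genome["chr1"][1990:2040]},
            "known_mirna": {"mir1": genome["chr1"][1995:2035]},
        }
        _, report = run_candidacy([shared + DEFAULT_ADAPTOR], genome, blk, "S1", "BC")
        assert report.removed("rRNA_tRNA_removed") == 1
        assert report.removed("known_miRNA_removed") == 0

    def test_default_fixture_recall_precision(self, bc_sample):
        from stagepir.simulate import evaluate_candidacy

        ev = evaluate_candidacy(bc_sample["manifest"], bc_sample["cands"])
        assert ev["recall"] >= 0.99
        assert ev["precision"] >= 0.99
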