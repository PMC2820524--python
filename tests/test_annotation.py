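import re

import numpy as np
import pytest

from tetracer.annotation import (
    AnnotatedElement,
    annotate_element,
    build_consensus,
    classify_element,
    find_tirs,
    find_tsd,
    longest_orf,
    reconstruct_split_element,
    refine_element_boundaries,
)
from tetracer.seq_core import GenomicInterval, SequenceRecord, reverse_complement
from tetracer.simulate import make_tir_element, plant_element_copies, random_dna, _rng

TIR27 = "CAATGAGTTATATCACTAGAGGAGACA"


def brute_force_tir(element, min_len, max_len, max_mismatch):
    """Exhaustive check over all terminal window lengths."""
    best = None
    for L in range(min_len, min(max_len, len(element) // 2) + 1):
        mism = sum(
            a != b
            for a, b in zip(element[:L], reverse_complement(element[-L:]))
        )
        if mism <= max_mismatch:
            best = L
    return best


class TestFindTirs:
    def test_printed_27bp_tir_recovered_exactly(self):
        el = make_tir_element(600, tir=TIR27, seed=11)
        tir = find_tirs(el, max_mismatch=0)
        assert tir.length == 27
        assert el[:27] == TIR27
        assert tir.mismatches == 0

    def test_random_sequence_has_no_tir(self):
        rng = _rng(1, "no-tir")
        seq = random_dna(rng, 1000)
        expected = brute_force_tir(seq, 10, 500, 0)
        got = find_tirs(seq, min_len=10)
        assert (got.length if got else None) == expected

    def test_short_construction_matches_exhaustive_scan(self):
        el = "ACGTAC" + "AAAA" + reverse_complement("ACGTAC")
        assert find_tirs(el, min_len=4).length == 6
        assert brute_force_tir(el, 4, len(el) // 2, 0) == 6

    def test_contract_errors(self):
        with pytest.raises(ValueError):
            find_tirs("ACGTACGT", min_len=5, max_len=4)
        with pytest.raises(ValueError):
            find_tirs("ACGT", min_len=10)


class TestFindTsd:
    def test_printed_octamer_detected(self):
        rng = _rng(2, "tsd")
        host = SequenceRecord(
            "h",
            random_dna(rng, 150) + "GTGTGGCT" + random_dna(rng, 200)
            + "GTGTGGCT" + random_dna(rng, 150),
        )
        tsd = find_tsd(host, GenomicInterval("h", 158, 358))
        assert tsd is not None and tsd.seq == "GTGTGGCT" and tsd.length == 8

    def test_no_shared_flank_returns_none(self):
        host = SequenceRecord("h", "A" * 30 + "CCCC" + "G" * 30)
        assert find_tsd(host, GenomicInterval("h", 30, 34), min_len=2, max_len=8) is None

    def test_enumerates_longest_k(self):
        host = SequenceRecord("h", "G" * 20 + "TACGT" + "CCCCC" + "TACGT" + "A" * 20)
        # flanks share exactly ACGT (4 bp) immediately around the element?
        # construct: left flank ends with ACGT, right flank starts with ACGT
        host = SequenceRecord("h", "G" * 20 + "ACGT" + "CCCCC" + "ACGTTTTT" + "G" * 16)
        tsd = find_tsd(host, GenomicInterval("h", 24, 29), min_len=2, max_len=10)
        assert tsd is not None and tsd.length == 4 and tsd.seq == "ACGT"

    def test_insufficient_flank_raises(self):
        host = SequenceRecord("h", "ACGTACGTAC")
        with pytest.raises(ValueError):
            find_tsd(host, GenomicInterval("h", 2, 8), max_len=5)


class TestBuildConsensus:
    def test_majority_column(self):
        assert build_consensus(["A", "A", "C"], 0.5).consensus == "A"

    def test_identical_copies_reproduced(self):
        assert build_consensus(["ACGT", "ACGT", "ACGT"]).consensus == "ACGT"

    def test_tie_emits_minimal_iupac(self):
        assert build_consensus(["A", "C", "A", "C"], 0.5).consensus == "M"

    def test_gap_majority_column_dropped(self):
        assert build_consensus(["A-G", "A-G", "ACG", "A-G"]).consensus == "AG"

    def test_no_base_at_threshold_gives_code_of_all(self):
        # threshold 0.9: A (0.5) and C (0.5) both below -> code of {A, C}
        assert build_consensus(["A", "A", "C", "C"], 0.9).consensus == "M"

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError):
            build_consensus(["AC", "A"])

    def test_low_divergence_recovers_generator_consensus(self):
        rng = _rng(3, "cons")
        truth = random_dna(rng, 300)
        from tetracer.simulate import evolve_sequence_k2p

        copies = [evolve_sequence_k2p(truth, 0.01, rng=rng) for _ in range(9)]
        cons = build_consensus(copies, 0.5).consensus
        assert sum(a != b for a, b in zip(cons, truth)) == 0


def orf_oracle(seq):
    """Regex-based six-frame ORF scan, independent of the implementation."""
    best = 0
    for s in (seq, reverse_complement(seq)):
        for frame in range(3):
            codons = re.findall("...", s[frame:])
            i = 0
            while i < len(codons):
                if codons[i] == "ATG":
                    for j in range(i + 1, len(codons)):
                        if codons[j] in ("TAA", "TAG", "TGA"):
                            best = max(best, j - i)
                            i = j
                            break
                    else:
                        pass
                i += 1
    return best


class TestLongestOrf:
    def test_manual_translation(self):
        assert longest_orf("ATGAAATAA") == 2

    def test_no_start_codon(self):
        assert longest_orf("CCCCCC") == 0

    @pytest.mark.parametrize("seed", [2, 5, 9])
    def test_matches_six_frame_oracle(self, seed):
        seq = random_dna(_rng(seed, "orf"), 300)
        assert longest_orf(seq) == orf_oracle(seq)


class TestClassifyElement:
    def _element(self, tir, tsd, orf):
        el = AnnotatedElement(interval=GenomicInterval("h", 0, 100))
        el.tir = tir
        el.tsd = tsd
        el.longest_orf_codons = orf
        return el

    def test_decision_table(self):
        from tetracer.annotation import TargetSiteDuplication, TirPair

        tir = TirPair(GenomicInterval("e", 0, 27), GenomicInterval("e", 73, 100), 27, 0)
        tsd = TargetSiteDuplication(
            "GTGTGGCT", 8, GenomicInterval("h", 0, 8), GenomicInterval("h", 100, 108)
        )
        assert classify_element(self._element(tir, tsd, 12), "ACGT" * 30) == "nonautonomous_class_II"
        assert classify_element(self._element(tir, tsd, 150), "ACGT" * 30) == "class_II_autonomous"
        assert classify_element(self._element(None, None, 0), "ACGT" * 20 + "A" * 10) == "class_I_like"
        assert classify_element(self._element(None, None, 0), "ACGT" * 30) == "unclassified"

    def test_pure_function_of_features(self):
        el = AnnotatedElement(interval=GenomicInterval("h", 0, 10))
        assert classify_element(el, "ACGTACGTAC") == classify_element(el, "ACGTACGTAC")


class TestAnnotateElement:
    def test_planted_element_fully_annotated(self):
        el_seq = make_tir_element(400, tir=TIR27, seed=21)
        backbone = SequenceRecord("chr1", random_dna(_rng(21, "host"), 4000))
        genome, truth = plant_element_copies(backbone, el_seq, 1, 0.0, tsd_len=8, seed=21)
        c = truth.data["copies"][0]
        ann = annotate_element(genome, GenomicInterval(genome.id, c["genome_start"], c["genome_end"]))
        assert ann.tir.length == 27
        assert ann.tsd.length == 8
        assert ann.classification == "nonautonomous_class_II"
        assert ann.terminal_motif_match  # CAATG matches YARNG

    def test_boundary_refinement_recovers_shifted_interval(self):
        el_seq = make_tir_element(400, tir=TIR27, seed=22)
        backbone = SequenceRecord("chr1", random_dna(_rng(22, "host"), 4000))
        genome, truth = plant_element_copies(backbone, el_seq, 1, 0.0, tsd_len=8, seed=22)
        c = truth.data["copies"][0]
        sloppy = GenomicInterval(genome.id, c["genome_start"] - 8, c["genome_end"] + 5)
        refined = refine_element_boundaries(genome, sloppy)
        assert (refined.start, refined.end) == (c["genome_start"], c["genome_end"])


class TestReconstructSplitElement:
    def test_component_lengths_sum(self):
        # joining a 440 bp and an 876 bp part restores the 1316 bp element
        host = SequenceRecord("h", random_dna(_rng(4, "split"), 3000))
        p1 = GenomicInterval("h", 100, 540)
        p2 = GenomicInterval("h", 1564, 2440)
        rec = reconstruct_split_element(host, (p1, p2))
        assert len(rec.seq) == 1316

    def test_zero_length_inner_equals_contiguous_slice(self):
        host = SequenceRecord("h", random_dna(_rng(5, "split0"), 500))
        rec = reconstruct_split_element(
            host, (GenomicInterval("h", 10, 60), GenomicInterval("h", 60, 120))
        )
        assert rec.seq == host.seq[10:120]

    def test_round_trip_through_nested_insertion(self):
        rng = _rng(6, "nested")
        outer = make_tir_element(600, seed=6)
        inner = random_dna(rng, 200)
        split_at = 250
        host_seq = random_dna(rng, 300) + outer[:split_at] + inner + outer[split_at:] + random_dna(rng, 300)
        host = SequenceRecord("h", host_seq)
        p1 = GenomicInterval("h", 300, 300 + split_at)
        inner_iv = GenomicInterval("h", 300 + split_at, 300 + split_at + 200)
        p2 = GenomicInterval("h", 300 + split_at + 200, 300 + 200 + 600)
        rec = reconstruct_split_element(host, (p1, p2), inner_iv)
        assert rec.seq == outer

    def test_overlapping_parts_rejected(self):
        host = SequenceRecord("h", "ACGT" * 100)
        with pytest.raises(ValueError):
            reconstruct_split_element(
                host, (GenomicInterval("h", 0, 50), GenomicInterval("h", 40, 90))
            )
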