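"""NG86 Ka/Ks estimation against independent oracles.

The pathway oracle re-derives difference counts by explicit permutation
walks using Biopython's translation only; Biopython's own NG86
implementation (Bio.codonalign.codonseq.cal_dn_ds) cross-checks whole-pair
estimates on stop-free regions.
"""

import math
from itertools import permutations

import pytest
from Bio.Seq import Seq

from dazfam import kaks
from dazfam.kaks import (CodonAlignment, KaKsError, SENSE_CODONS,
                         SelectionCall, kaks_pair, ng_counts,
                         pairwise_kaks_matrix, thread_codons)
from dazfam.msa import MultipleAlignment
from dazfam.seq import NucSequence

STOPS = {"TAA", "TAG", "TGA"}


def oracle_syn_sites(codon):
    aa = str(Seq(codon).translate())
    s = 0
    for pos in range(3):
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            mut = codon[:pos] + nt + codon[pos + 1:]
            if mut not in STOPS and str(Seq(mut).translate()) == aa:
                s += 1
    return s / 3.0


def oracle_pathways(ca, cb):
    """Average (Sd, Nd) over stop-free minimal pathways (all pathways if
    none avoids a stop, stop-touching steps nonsynonymous)."""
    diff = [i for i in range(3) if ca[i] != cb[i]]
    if not diff:
        return 0.0, 0.0
    walks = []
    for order in permutations(diff):
        cur, steps, stopped = ca, [], False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            steps.append((cur, nxt))
            stopped = stopped or nxt in STOPS
            cur = nxt
        walks.append((stopped, steps))
    usable = [s for stop, s in walks if not stop] or [s for _, s in walks]
    sd = nd = 0.0
    for steps in usable:
        for c1, c2 in steps:
            if c1 in STOPS or c2 in STOPS:
                nd += 1
            elif str(Seq(c1).translate()) == str(Seq(c2).translate()):
                sd += 1
            else:
                nd += 1
    return sd / len(usable), nd / len(usable)


class TestNgCounts:
    def test_lysine_codon_sites(self):
        # AAA: only AAA->AAG (pos 3) is synonymous; AAA->TAA is a stop and
        # counts as nonsynonymous
        sa, sb, sd, nd = ng_counts("AAA", "AAA")
        assert sa == sb == pytest.approx(1 / 3)
        assert sd == nd == 0.0

    def test_single_synonymous_difference(self):
        _, _, sd, nd = ng_counts("TTT", "TTC")
        assert (sd, nd) == (1.0, 0.0)

    def test_two_step_pathway_average(self):
        sa, sb, sd, nd = ng_counts("AAA", "AGG")
        assert sd + nd == pytest.approx(2.0)
        assert (sd, nd) == pytest.approx(oracle_pathways("AAA", "AGG"))

    def test_stop_codon_rejected(self):
        with pytest.raises(KaKsError, match="stop"):
            ng_counts("TAA", "AAA")

    def test_sites_conservation_over_sample(self):
        # S + N = 3 for every codon (stop-bound mutations count toward N)
        for codon in SENSE_CODONS[::7]:
            s = kaks.syn_sites(codon)
            assert 0.0 <= s <= 3.0
            assert s == pytest.approx(oracle_syn_sites(codon))


class TestKaksPair:
    def test_identical_rows_report_zero_over_zero(self):
        row = ("a", "ATGAAACCC")
        r = kaks_pair(row, ("b", "ATGAAACCC"))
        assert r.Ka == r.Ks == 0.0
        assert r.ratio is None and r.ratio_note == "0/0"
        assert SelectionCall.from_result(r).regime == "purifying"

    def test_hand_computed_synonymous_example(self):
        r = kaks_pair(("a", "AAA" * 10), ("b", "AAA" * 9 + "AAG"))
        assert r.S_sites == pytest.approx(10 / 3)
        assert r.pS == pytest.approx(0.3)
        assert r.Ks == pytest.approx(0.3831, abs=1e-4)
        assert r.Ka == 0.0 and r.ratio == 0.0

    def test_symmetry(self):
        pad = "CTG" * 6
        a = ("a", "ATGAAACCCGGGTTT" + pad)
        b = ("b", "ATGAAGCCATGGTTC" + pad)
        r1, r2 = kaks_pair(a, b), kaks_pair(b, a)
        assert (r1.Ks, r1.Ka) == pytest.approx((r2.Ks, r2.Ka))
        assert (r1.S_sites, r1.N_sites) == pytest.approx(
            (r2.S_sites, r2.N_sites))

    def test_sites_sum_to_three_per_codon(self):
        pad = "CTG" * 6
        r = kaks_pair(("a", "ATGAAACCCGGGTTT" + pad),
                      ("b", "ATGAAGCCATGGTTC" + pad))
        assert r.S_sites + r.N_sites == pytest.approx(3 * r.codons_compared)

    def test_gap_columns_pairwise_deleted(self):
        r = kaks_pair(("a", "ATG---CCC"), ("b", "ATGAAACCC"))
        assert r.codons_compared == 2

    def test_infinite_ratio_sentinel(self):
        r = kaks_pair(("a", "GAT"), ("b", "GAA"))  # D->E, nonsyn only
        assert r.Ks == 0.0 and r.Ka > 0
        assert r.ratio == math.inf and r.ratio_note == "inf"

    def test_saturation_raises(self):
        # every codon differs synonymously -> pS = 1/ (10/3 ... ) large
        a = ("a", "TTA" * 9)
        b = ("b", "CTG" * 9)   # Leu -> Leu two-position changes
        with pytest.raises(KaKsError, match="saturated"):
            kaks_pair(a, b)

    def test_matches_biopython_ng86(self):
        from Bio import codonalign
        from Bio.Seq import Seq as BSeq
        pad = "CTGCCGGCA" * 3
        a = "ATGAAACCCGGGTTTCTGGACTACAAGGAC" + pad
        b = "ATGAAGCCCGGATTCCTTGACTATAAAGAT" + pad
        r = kaks_pair(("a", a), ("b", b))
        ca = codonalign.codonseq.CodonSeq(a)
        cb = codonalign.codonseq.CodonSeq(b)
        dn, ds = codonalign.codonseq.cal_dn_ds(ca, cb, method="NG86")
        assert r.Ka == pytest.approx(dn, abs=5e-3)
        assert r.Ks == pytest.approx(ds, abs=5e-3)


class TestThreading:
    def test_gap_free_concatenation(self):
        m = MultipleAlignment([("a", "MK"), ("b", "MR")])
        ca = thread_codons(m, {"a": NucSequence("a", "ATGAAA"),
                               "b": NucSequence("b", "ATGCGG")})
        assert ca.rows == [("a", "ATGAAA"), ("b", "ATGCGG")]

    def test_protein_gap_becomes_triple_gap(self):
        m = MultipleAlignment([("a", "M-K"), ("b", "MVK")])
        ca = thread_codons(m, {"a": NucSequence("a", "ATGAAA"),
                               "b": NucSequence("b", "ATGGTGAAA")})
        assert dict(ca.rows)["a"] == "ATG---AAA"

    def test_trailing_stop_stripped(self):
        m = MultipleAlignment([("a", "MK"), ("b", "MK")])
        ca = thread_codons(m, {"a": NucSequence("a", "ATGAAATAA"),
                               "b": NucSequence("b", "ATGAAA")})
        assert dict(ca.rows)["a"] == "ATGAAA"

    def test_internal_stop_rejected(self):
        m = MultipleAlignment([("a", "MK"), ("b", "MK")])
        with pytest.raises(KaKsError, match="[Ss]top"):
            thread_codons(m, {"a": NucSequence("a", "ATGTAAATGAAA"[0:6]),
                              "b": NucSequence("b", "TAAAAA")})

    def test_translation_mismatch_names_row_and_position(self):
        m = MultipleAlignment([("a", "MK"), ("b", "MR")])
        with pytest.raises(KaKsError, match="'b' at residue 1"):
            thread_codons(m, {"a": NucSequence("a", "ATGAAA"),
                              "b": NucSequence("b", "ATGAAA")})


class TestMatrix:
    def test_all_pairs_with_selection_calls(self):
        pad = "CTGCCG" * 4
        rows = [("a", "ATGAAACCC" + pad), ("b", "ATGAAGCCC" + pad),
                ("c", "ATGAAACCG" + pad)]
        results, calls, errors = pairwise_kaks_matrix(CodonAlignment(rows))
        assert len(results) == len(calls) == 3
        assert errors == []
        assert all(c.regime == "purifying" for c in calls)

    def test_per_pair_errors_do_not_abort(self):
        rows = [("a", "TTA" * 9), ("b", "CTG" * 9), ("c", "TTA" * 9)]
        results, calls, errors = pairwise_kaks_matrix(CodonAlignment(rows))
        assert len(errors) == 2           # both saturated pairs vs the rest
        assert len(results) == 1          # a-c identical still reported

    def test_selection_regime_thresholds(self):
        mk = lambda ratio: SelectionCall(("x", "y"), ratio, "")
        for ratio, want in [(0.05, "purifying"), (0.5, "unresolved"),
                            (1.5, "positive")]:
            r = kaks.KaKsResult(("x", "y"), 1, 2, 0, 0, 0, 0, 1.0,
                                ratio, ratio, "", 1)
            assert SelectionCall.from_result(r).regime == want
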