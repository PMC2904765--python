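import copy

import pytest

from dazfam import classify as cls
from dazfam import pipeline
from dazfam.msa import RnpPattern
from dazfam.seq import GeneModel, ProtSequence, SequenceError


class TestMatchRnp:
    def test_exact_motif_matches_pattern_with_alternate(self):
        # the ancestral-style motif matches the consensus pattern exactly
        pat = RnpPattern.parse("PNRI(V)FVGG")
        assert cls.match_rnp("PNRIFVGG", pat) == 0

    def test_majority_string_matches_itself(self):
        pat = RnpPattern.parse("DRAGV(I)SKGYGFV(I)")
        assert cls.match_rnp(pat.primary, pat) == 0

    def test_dazl_rnp1_mismatches_boule_pattern(self):
        # position-wise comparison of the two families' RNP1 motifs over the
        # equal-length window: the DAZL motif cannot satisfy the BOULE pattern
        boule = RnpPattern.parse("DRAGV(I)SKGYGFV(I)")
        window = RnpPattern(boule.primary[4:12], boule.allowed[4:12])
        assert cls.match_rnp("KGYGFVSF", window) >= 1


class TestDetectDeletion:
    def test_dazl_candidate_has_deletion_at_template_column(self, bench,
                                                            bundle):
        boule_profile = bundle.signatures["BOULE"][1]
        lt = bench.truth.leaves["D4"]
        flag, col, _ = cls.detect_deletion(lt.protein, boule_profile,
                                           bundle.deletion_column)
        assert flag
        assert abs(col - bundle.deletion_column) <= 2

    def test_boule_consensus_has_no_deletion(self, bundle):
        boule_profile = bundle.signatures["BOULE"][1]
        flag, col, _ = cls.detect_deletion(
            ProtSequence("self", boule_profile.majority), boule_profile,
            bundle.deletion_column)
        assert not flag and col is None

    def test_three_column_gap_is_not_the_deletion(self, bundle):
        boule_profile = bundle.signatures["BOULE"][1]
        c = bundle.deletion_column
        residues = boule_profile.majority
        mutant = residues[:c] + residues[c + 3:]   # 3-aa deletion at site
        flag, _, notes = cls.detect_deletion(
            ProtSequence("m", mutant), boule_profile, c)
        assert not flag
        assert any("not 2" in n for n in notes)


class TestSharedJunctions:
    def _model(self, junction_codons, cds_codons=200):
        bounds = [0] + [3 * j for j in junction_codons] + [3 * cds_codons]
        exons = [(a + 1000, b + 1000) for a, b in zip(bounds, bounds[1:])]
        return GeneModel("g", "s", "+", exons)

    def test_canonical_model_shares_all_three(self):
        # RRM at codons 60..152; template junctions 20/45/70 codons in
        model = self._model([20, 80, 105, 130])
        assert cls.shared_junctions(model, (180, 456), (20, 45, 70)) == 3

    def test_fused_exons_lose_one_junction(self):
        model = self._model([20, 80, 130])   # middle junction fused away
        assert cls.shared_junctions(model, (180, 456), (20, 45, 70)) == 2

    def test_intronless_gene_shares_none(self):
        model = self._model([])
        assert cls.shared_junctions(model, (180, 456), (20, 45, 70)) == 0

    def test_span_outside_cds_rejected(self):
        model = self._model([20])
        with pytest.raises(SequenceError, match="outside"):
            cls.shared_junctions(model, (500, 700), (20,))


class TestClassify:
    def test_heldout_members_recover_their_family(self, bench, bundle):
        for leaf in bench.test_ids:
            lt = bench.truth.leaves[leaf]
            r = cls.classify(lt.protein, lt.gene_model, bundle.signatures,
                             bench.reference_proteome, bench.family_labels,
                             deletion_column=bundle.deletion_column)
            assert r.call == lt.family, (leaf, r.evidence_notes)

    def test_scrambled_negatives_are_never_boule(self, bench, bundle):
        for prot in bench.negatives:
            r = cls.classify(prot, None, bundle.signatures,
                             bench.reference_proteome, bench.family_labels,
                             deletion_column=bundle.deletion_column)
            assert r.call != cls.BOULE

    def test_divergent_duplicate_with_fewer_junctions_downgraded(
            self, bench, bundle):
        """A candidate whose motifs diverge beyond the mismatch budget but
        whose RRM still aligns — the second-anemone-protein situation —
        is a divergent paralog, not a family member and not a rejection."""
        lt = bench.truth.leaves["B5"]
        residues = list(lt.protein.residues)
        # corrupt 4 motif positions (> max_mismatch, < divergence floor)
        for k in (0, 2, 4, 6):
            pos = lt.rnp2_codon + k
            residues[pos] = "W" if residues[pos] != "W" else "Y"
        mutant = ProtSequence("divergent", "".join(residues))
        r = cls.classify(mutant, None, bundle.signatures,
                         bench.reference_proteome, bench.family_labels,
                         deletion_column=bundle.deletion_column)
        assert r.call == cls.DIVERGENT_PARALOG

    def test_dazl_call_requires_the_deletion(self, bench, bundle):
        """Restoring two residues at the deletion site of a DAZL candidate
        removes the diagnostic gap; the DAZL call must not survive."""
        lt = bench.truth.leaves["D4"]
        residues = lt.protein.residues
        col = bundle.deletion_column
        boule = bundle.signatures["BOULE"][1].majority
        loc = cls.locate_rrm(lt.protein, bundle.signatures["DAZL"][1])
        assert loc is not None
        _, (rrm_start, _), _ = loc
        insert_at = rrm_start + col
        patched = ProtSequence(
            "undeleted", residues[:insert_at] + boule[col:col + 2]
            + residues[insert_at:])
        r = cls.classify(patched, None, bundle.signatures,
                         bench.reference_proteome, bench.family_labels,
                         deletion_column=col)
        assert r.call != cls.DAZL
        assert not r.deletion_detected

    def test_missing_gene_model_skips_junction_criterion(self, bench,
                                                         bundle):
        lt = bench.truth.leaves["B6"]
        r = cls.classify(lt.protein, None, bundle.signatures,
                         bench.reference_proteome, bench.family_labels,
                         deletion_column=bundle.deletion_column)
        assert r.call == cls.BOULE
        assert r.junctions_shared is None

    def test_monotonic_in_mismatch_budget(self, bench, bundle):
        """Raising max_mismatch never turns a BOULE call into NOT_HOMOLOG."""
        lt = bench.truth.leaves["B7"]
        calls = []
        for mm in (0, 1, 2, 4, 8):
            th = cls.Thresholds(max_mismatch=mm)
            r = cls.classify(lt.protein, None, bundle.signatures,
                             bench.reference_proteome, bench.family_labels,
                             thresholds=th,
                             deletion_column=bundle.deletion_column)
            calls.append(r.call)
        seen_boule = False
        for call in calls:
            seen_boule = seen_boule or call == cls.BOULE
            if seen_boule:
                assert call != cls.NOT_HOMOLOG

    def test_deterministic(self, bench, bundle):
        lt = bench.truth.leaves["D5"]
        r1 = cls.classify(lt.protein, lt.gene_model, bundle.signatures,
                          bench.reference_proteome, bench.family_labels,
                          deletion_column=bundle.deletion_column)
        r2 = cls.classify(lt.protein, lt.gene_model, bundle.signatures,
                          bench.reference_proteome, bench.family_labels,
                          deletion_column=bundle.deletion_column)
        assert r1 == r2

    def test_requires_both_signatures(self, bench, bundle):
        lt = bench.truth.leaves["B5"]
        with pytest.raises(SequenceError, match="BOULE and DAZL"):
            cls.classify(lt.protein, None,
                         {"BOULE": bundle.signatures["BOULE"]})

    def test_report_table_has_one_row_per_candidate(self, bench, bundle):
        report = pipeline.classification_stage(bench, bundle)
        text = cls.results_to_tsv(report.results)
        assert len(text.strip().split("\n")) == 1 + len(report.results)
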