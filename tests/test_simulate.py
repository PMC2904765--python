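import numpy as np
import pytest

from dazfam import kaks
from dazfam.seq import read_fasta, read_gene_models
from dazfam.simulate import (ExonPlan, FamilyBranchSpec, SignatureSpec,
                             SimulationConfig, SimulationError,
                             evolve_family, exonize_and_embed,
                             make_benchmark)

TREE = "((A:0.2,B:0.2):0.1,(C:0.2,D:0.2):0.1,E:0.25);"


def _cfg(**kw):
    defaults = dict(tree=TREE, omega=0.2, root_length_codons=160,
                    signature=SignatureSpec(rrm_start=30, rrm_len=92),
                    exon_plan=ExonPlan(junction_codons=(10, 50, 75, 100)),
                    genome_length=5000, seed=5)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestEvolveFamily:
    def test_omega_zero_freezes_every_protein(self):
        cfg = _cfg(omega=0.0,
                   signature=SignatureSpec(rrm_start=30, rrm_len=92,
                                           omega_core=0.0))
        truth = evolve_family(cfg)
        proteins = {t.protein.residues for t in truth.leaves.values()}
        assert len(proteins) == 1  # only synonymous changes possible

    def test_same_seed_is_byte_identical(self):
        t1, t2 = evolve_family(_cfg()), evolve_family(_cfg())
        for leaf in t1.leaves:
            assert t1.leaves[leaf].cds.residues == \
                t2.leaves[leaf].cds.residues
        assert t1.branch_counts == t2.branch_counts

    def test_adding_a_taxon_does_not_perturb_existing_lineages(self):
        """Per-branch RNG streams hash node labels, so a new sister clade
        leaves untouched lineages byte-identical."""
        t1 = evolve_family(_cfg())
        bigger = TREE.replace("E:0.25", "(E:0.25,F:0.2):0.01")
        t2 = evolve_family(_cfg(tree=bigger))
        for leaf in "ABCD":
            assert t1.leaves[leaf].cds.residues == \
                t2.leaves[leaf].cds.residues

    def test_deletion_marks_exactly_the_dazl_clade(self):
        cfg = _cfg(tree="((A:0.1,B:0.1):0.05,(C:0.1,D:0.1)DZ:0.05,E:0.1);",
                   dazl=FamilyBranchSpec(branch_label="DZ",
                                         deletion_codon=60))
        truth = evolve_family(cfg)
        assert truth.dazl_ids == ["C", "D"]
        for leaf, t in truth.leaves.items():
            expect = 158 if t.family == "DAZL" else 160
            assert len(t.cds.residues) == 3 * expect

    def test_missing_branch_omega_raises(self):
        cfg = _cfg(omega={"A": 0.1})
        with pytest.raises(SimulationError, match="omega not configured"):
            evolve_family(cfg)

    def test_realized_dnds_converges_to_omega(self):
        """Law of large numbers: over a long branch and many codons, the
        realized proportion of accepted nonsynonymous proposals matches the
        configured omega when measured as an NG86 estimate."""
        cfg = SimulationConfig(tree="(X:0.3,Y:0.3);", omega=0.5,
                               root_length_codons=10_000,
                               signature=SignatureSpec(rrm_start=0,
                                                       rrm_len=92,
                                                       omega_core=0.5),
                               seed=11)
        truth = evolve_family(cfg)
        r = kaks.kaks_pair(("X", truth.leaves["X"].cds.residues),
                           ("Y", truth.leaves["Y"].cds.residues))
        assert r.ratio_value == pytest.approx(0.5, abs=0.05)

    def test_signature_span_must_fit(self):
        with pytest.raises(SimulationError, match="shorter than"):
            SimulationConfig(tree=TREE, root_length_codons=50)

    def test_indels_change_lengths_but_preserve_structure(self):
        """With a nonzero indel rate, flanking codons are inserted/deleted;
        the RRM span, junction bookkeeping and splice round-trip survive,
        and the aligner recovers the homology with gaps."""
        from dazfam.kaks import thread_codons
        from dazfam.msa import progressive_msa

        cfg = _cfg(indel_rate=0.02)
        truth = exonize_and_embed(evolve_family(cfg))
        lengths = {len(t.cds.residues) for t in truth.leaves.values()}
        assert len(lengths) > 1
        for t in truth.leaves.values():
            s, e = t.rrm_codon_span
            assert e - s == 92
            assert t.gene_model.spliced_cds(t.genome).residues == \
                t.cds.residues
        aligned = progressive_msa([t.protein for t in truth.leaves.values()])
        assert any("-" in row for _, row in aligned.rows)
        threaded = thread_codons(
            aligned, {l: t.cds for l, t in truth.leaves.items()})
        assert threaded.n_codons == aligned.length


class TestExonize:
    def test_splice_roundtrip_for_every_leaf(self):
        truth = exonize_and_embed(evolve_family(_cfg()))
        for t in truth.leaves.values():
            assert t.gene_model.spliced_cds(t.genome).residues == \
                t.cds.residues

    def test_forced_minus_strand_gene(self):
        truth = exonize_and_embed(evolve_family(_cfg()),
                                  forced_strands={"A": "-"})
        t = truth.leaves["A"]
        assert t.gene_strand == "-" and t.gene_model.strand == "-"
        assert t.gene_model.spliced_cds(t.genome).residues == t.cds.residues

    def test_fused_junction_drops_one_intron(self):
        plain = exonize_and_embed(evolve_family(_cfg()))
        fused = exonize_and_embed(evolve_family(_cfg()),
                                  fused_junctions={"B": 2})
        assert fused.leaves["B"].gene_model.n_junctions == \
            plain.leaves["B"].gene_model.n_junctions - 1

    def test_intronless_leaf_is_single_exon(self):
        truth = exonize_and_embed(evolve_family(_cfg()),
                                  intronless={"C"})
        assert truth.leaves["C"].gene_model.n_junctions == 0

    def test_introns_are_gt_ag(self):
        truth = exonize_and_embed(evolve_family(_cfg()))
        for t in truth.leaves.values():
            exons = sorted(t.gene_model.exons)
            genome = t.genome.residues
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                intron = genome[e1:s2]
                if t.gene_strand == "+":
                    assert intron[:2] == "GT" and intron[-2:] == "AG"
                else:
                    assert intron[:2] == "CT" and intron[-2:] == "AC"


class TestBenchmark:
    def test_written_bundle_reads_back(self, bench, tmp_path):
        out = tmp_path / "bundle"
        bench.write(out)
        cds = read_fasta(out / "cds.fasta", "nuc")
        prots = read_fasta(out / "proteins.fasta", "prot")
        genomes = read_fasta(out / "genomes.fasta", "nuc")
        models = read_gene_models(out / "models.gff3")
        assert len(cds) == len(prots) == len(bench.truth.leaves)
        assert len(genomes) == len(bench.truth.leaves)
        assert len(models) == len(bench.truth.leaves)
        truth_lines = (out / "truth.tsv").read_text().strip().split("\n")
        assert len(truth_lines) == 1 + len(bench.truth.leaves) + \
            len(bench.negatives)

    def test_refuses_to_clobber_without_overwrite(self, bench, tmp_path):
        out = tmp_path / "bundle"
        bench.write(out)
        with pytest.raises(SimulationError, match="not empty"):
            bench.write(out)
        bench.write(out, overwrite=True)

    def test_null_preset_contains_no_family(self):
        nb = make_benchmark("null", seed=3)
        assert nb.truth.leaves == {}
        assert len(nb.null_genomes) == 3

    def test_unknown_preset_rejected(self):
        with pytest.raises(SimulationError, match="unknown preset"):
            make_benchmark("nope")

    def test_scrambled_negatives_differ_only_in_motifs(self, bench):
        for sid in bench.scrambled_ids:
            leaf = sid.replace("_scrambled", "")
            orig = bench.truth.leaves[leaf].protein.residues
            scram = next(p for p in bench.negatives if p.id == sid)
            assert len(scram) == len(orig)
            assert sorted(scram.residues) == sorted(orig)
            assert scram.residues != orig
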