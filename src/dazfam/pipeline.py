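"""End-to-end orchestration of the comparative-genomics stages.

Each stage function operates on a :class:`~dazfam.simulate.Benchmark`
bundle (or equivalent in-memory objects) and returns plain results; the CLI
and the analysis drivers are thin wrappers around these.  A
:class:`RunManifest` records config, seeds, input checksums, outputs and
warnings so identical runs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import classify as cls
from . import kaks as kk
from . import msa, phylo, search
from .seq import ProtSequence
from .simulate import Benchmark, FamilyTruth, make_benchmark


@dataclass
class RunManifest:
    config: dict
    seeds: dict
    input_checksums: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    stage_status: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=1, sort_keys=True) + "\n"


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# Stage: consensus + signatures
# ---------------------------------------------------------------------------

@dataclass
class SignatureBundle:
    signatures: dict  # family -> (FamilySignature, ConsensusProfile)
    deletion_column: Optional[int]
    query: ProtSequence  # BOULE RRM consensus used for translated search


def derive_signatures(bench: Benchmark,
                      size_range_kda: tuple[float, float] = (15.0, 45.0),
                      alt_threshold: float = 0.25) -> SignatureBundle:
    """Derive per-family consensus profiles and signatures from training leaves.

    RRM regions of the training proteins are aligned per family; RNP spans
    are located in each consensus with the family's canonical motif strings;
    the junction template is read off the training gene models as
    RRM-relative codon offsets.
    """
    truth = bench.truth
    cfg = truth.config
    signatures = {}
    for family in ("BOULE", "DAZL"):
        regions = []
        template: tuple[int, ...] = ()
        for leaf in bench.training_ids:
            lt = truth.leaves[leaf]
            if lt.family != family:
                continue
            s, e = lt.rrm_codon_span
            regions.append(ProtSequence(leaf, lt.protein.residues[s:e]))
            if lt.gene_model is not None:
                offs = lt.gene_model.junction_cds_offsets()
                template = tuple(sorted(
                    round(o / 3) - s for o in offs
                    if 3 * s <= o < 3 * e))
        if len(regions) < 2:
            raise ValueError(f"need >= 2 training members for {family}")
        aligned = msa.progressive_msa(regions)
        profile = msa.build_consensus(aligned, alt_threshold=alt_threshold,
                                      source_family=family)
        if family == "BOULE":
            msa.locate_rnp_spans(profile, cfg.signature.rnp2,
                                 cfg.signature.rnp1)
        else:
            msa.locate_rnp_spans(profile, cfg.dazl.rnp2, cfg.dazl.rnp1)
        sig = msa.derive_signature(profile, size_range_kda=size_range_kda,
                                   junction_template=template)
        signatures[family] = (sig, profile)
    deletion_column = cls.deletion_template_column(
        signatures["BOULE"][1], signatures["DAZL"][1])
    query = ProtSequence("boule_rrm_consensus",
                         signatures["BOULE"][1].majority)
    return SignatureBundle(signatures, deletion_column, query)


# ---------------------------------------------------------------------------
# Stage: translated search
# ---------------------------------------------------------------------------

@dataclass
class SearchReport:
    hits: list
    recall: float              # fraction of embedded genes recovered as top hit
    n_targets: int
    null_hits: int

    @property
    def recall_pct(self) -> float:
        return 100.0 * self.recall


def search_stage(bench: Benchmark, query: ProtSequence,
                 min_score: Optional[float] = None) -> SearchReport:
    """Search the embedded test genomes and the null genomes.

    A gene counts as recovered when the top hit on its genome overlaps the
    gene's genomic span on the correct strand.
    """
    truth = bench.truth
    genomes = [truth.leaves[l].genome for l in bench.test_ids
               if truth.leaves[l].genome is not None]
    hits = search.search_targets(query, genomes, min_score) if genomes else []
    recovered = 0
    for leaf in bench.test_ids:
        lt = truth.leaves[leaf]
        if lt.genome is None:
            continue
        top = [h for h in hits if h.target_id == lt.genome.id]
        if not top:
            continue
        h = top[0]
        gs, ge = lt.gene_genomic_span
        hs, he = h.target_nuc_span
        if min(ge, he) > max(gs, hs) and h.strand == lt.gene_strand:
            recovered += 1
    null_hits = (search.search_targets(query, bench.null_genomes, min_score)
                 if bench.null_genomes else [])
    n = len(genomes)
    return SearchReport(hits=hits, recall=recovered / n if n else 0.0,
                        n_targets=n, null_hits=len(null_hits))


# ---------------------------------------------------------------------------
# Stage: classification
# ---------------------------------------------------------------------------

@dataclass
class ClassificationReport:
    results: list
    n_test: int
    n_correct: int
    n_negatives: int
    false_boule: int
    dazl_without_deletion: int

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_test if self.n_test else 0.0

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * self.accuracy


def classification_stage(bench: Benchmark, bundle: SignatureBundle,
                         thresholds: Optional[cls.Thresholds] = None,
                         use_gene_models: bool = True,
                         ) -> ClassificationReport:
    """Classify held-out leaves and negatives against the derived signatures."""
    truth = bench.truth
    results = []
    n_correct = 0
    for leaf in bench.test_ids:
        lt = truth.leaves[leaf]
        model = lt.gene_model if use_gene_models else None
        r = cls.classify(lt.protein, model, bundle.signatures,
                         bench.reference_proteome, bench.family_labels,
                         thresholds, bundle.deletion_column)
        results.append(r)
        if r.call == lt.family:
            n_correct += 1
    false_boule = 0
    dazl_without_deletion = 0
    for prot in bench.negatives:
        r = cls.classify(prot, None, bundle.signatures,
                         bench.reference_proteome, bench.family_labels,
                         thresholds, bundle.deletion_column)
        results.append(r)
        if r.call == cls.BOULE:
            false_boule += 1
        if r.call == cls.DAZL and not r.deletion_detected:
            dazl_without_deletion += 1
    return ClassificationReport(
        results=results, n_test=len(bench.test_ids), n_correct=n_correct,
        n_negatives=len(bench.negatives), false_boule=false_boule,
        dazl_without_deletion=dazl_without_deletion)


# ---------------------------------------------------------------------------
# Stage: phylogeny
# ---------------------------------------------------------------------------

@dataclass
class PhylogenyReport:
    tree: phylo.PhyloTree
    newick: str
    dazl_monophyletic: bool
    dropped_replicates: int


def phylogeny_stage(bench: Benchmark, bootstrap_replicates: int = 200,
                    seed: int = 0, outgroup: Optional[str] = None,
                    ) -> PhylogenyReport:
    """NJ tree (Poisson distances) of all leaf RRM regions with bootstrap.

    Checks the family structure of the tree: all deletion-bearing (DAZL)
    leaves should cluster in one clade, mirroring the DAZ/DAZL homologs
    forming a single branch within the broader family tree.
    """
    truth = bench.truth
    regions = []
    for leaf in sorted(truth.leaves):
        lt = truth.leaves[leaf]
        s, e = lt.rrm_codon_span
        regions.append(ProtSequence(leaf, lt.protein.residues[s:e]))
    aligned = msa.progressive_msa(regions)
    tree, dropped = phylo.bootstrap_support(aligned, B=bootstrap_replicates,
                                            seed=seed)
    if outgroup is not None:
        tree = phylo.root_by_outgroup(tree, outgroup)
    dazl = set(truth.dazl_ids)
    mono = frozenset(dazl) in tree.bipartitions() if 1 < len(dazl) else True
    return PhylogenyReport(tree=tree, newick=tree.newick(),
                           dazl_monophyletic=mono,
                           dropped_replicates=dropped)


# ---------------------------------------------------------------------------
# Stage: Ka/Ks
# ---------------------------------------------------------------------------

@dataclass
class KaKsReport:
    results: list
    calls: list
    errors: list
    max_ratio: float
    all_purifying: bool

    def to_tsv(self) -> str:
        header = ("seq_a\tseq_b\tS\tN\tSd\tNd\tpS\tpN\tKs\tKa\tratio\tregime")
        lines = [header]
        by_pair = {c.pair: c.regime for c in self.calls}
        for r in self.results:
            ratio = "NA" if r.ratio is None else f"{r.ratio:.4f}"
            lines.append(
                f"{r.pair[0]}\t{r.pair[1]}\t{r.S_sites:.2f}\t{r.N_sites:.2f}"
                f"\t{r.Sd:.2f}\t{r.Nd:.2f}\t{r.pS:.4f}\t{r.pN:.4f}"
                f"\t{r.Ks:.4f}\t{r.Ka:.4f}\t{ratio}\t{by_pair[r.pair]}")
        return "\n".join(lines) + "\n"


def kaks_stage(truth: FamilyTruth, ids: Optional[Sequence[str]] = None,
               ) -> KaKsReport:
    """Pairwise NG86 Ka/Ks over the (gap-free) codon sequences of a family."""
    ids = sorted(truth.leaves) if ids is None else list(ids)
    lengths = {len(truth.leaves[i].cds.residues) for i in ids}
    if len(lengths) == 1:
        rows = [(i, truth.leaves[i].cds.residues) for i in ids]
        ca = kk.CodonAlignment(rows)
    else:
        # thread through the protein alignment when lengths differ
        prots = [truth.leaves[i].protein for i in ids]
        aligned = msa.progressive_msa(prots)
        ca = kk.thread_codons(aligned,
                              {i: truth.leaves[i].cds for i in ids})
    results, calls, errors = kk.pairwise_kaks_matrix(ca)
    mr = kk.max_ratio(results) if results else float("nan")
    return KaKsReport(results=results, calls=calls, errors=errors,
                      max_ratio=mr,
                      all_purifying=all(c.regime == "purifying"
                                        for c in calls))


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(preset: str = "default", seed: int = 0,
                 out_dir: str | Path = "results/pipeline",
                 bootstrap_replicates: int = 200,
                 thresholds: Optional[cls.Thresholds] = None,
                 overwrite: bool = True) -> RunManifest:
    """Run simulate → consensus → search → classify → tree → kaks.

    Writes stage outputs (TSV/FASTA/GFF3/newick/JSON) under ``out_dir`` and
    returns a manifest; identical preset/seed reproduce identical files.
    A stage failure is recorded in the manifest without aborting later
    stages that do not depend on it.
    """
    out = Path(out_dir)
    manifest = RunManifest(
        config={"preset": preset, "bootstrap_replicates": bootstrap_replicates},
        seeds={"master": seed})
    out.mkdir(parents=True, exist_ok=True)
    bench = make_benchmark(preset, seed=seed)
    inputs = out / "inputs"
    bench.write(inputs, overwrite=overwrite)
    for f in sorted(inputs.iterdir()):
        manifest.input_checksums[f.name] = file_checksum(f)
    manifest.stage_status["simulate"] = "ok"

    if preset == "null":
        (out / "classification.tsv").write_text(
            cls.results_to_tsv([]))
        manifest.stage_status.update(
            {s: "skipped (null preset)" for s in
             ("consensus", "search", "classify", "tree", "kaks")})
        manifest.outputs["classification"] = str(out / "classification.tsv")
        (out / "manifest.json").write_text(manifest.to_json())
        return manifest

    bundle = derive_signatures(bench)
    for fam, (_, prof) in bundle.signatures.items():
        (out / f"consensus_{fam.lower()}.json").write_text(prof.to_json())
    manifest.stage_status["consensus"] = "ok"

    try:
        sr = search_stage(bench, bundle.query)
        (out / "hits.tsv").write_text(search.hits_to_tsv(sr.hits))
        (out / "hits.bed").write_text(search.hits_to_bed(sr.hits))
        manifest.stage_status["search"] = "ok"
        manifest.outputs["search_recall_pct"] = sr.recall_pct
        manifest.outputs["null_hits"] = sr.null_hits
    except Exception as exc:  # recorded, not fatal for later stages
        manifest.stage_status["search"] = f"failed: {exc}"
        manifest.warnings.append(f"search: {exc}")

    try:
        cr = classification_stage(bench, bundle, thresholds)
        (out / "classification.tsv").write_text(cls.results_to_tsv(cr.results))
        manifest.stage_status["classify"] = "ok"
        manifest.outputs["classification_accuracy_pct"] = cr.accuracy_pct
        manifest.outputs["false_boule_calls"] = cr.false_boule
    except Exception as exc:
        manifest.stage_status["classify"] = f"failed: {exc}"
        manifest.warnings.append(f"classify: {exc}")

    try:
        pr = phylogeny_stage(bench, bootstrap_replicates, seed=seed)
        (out / "tree.nwk").write_text(pr.newick + "\n")
        manifest.stage_status["tree"] = "ok"
        manifest.outputs["dazl_monophyletic"] = pr.dazl_monophyletic
        if pr.dropped_replicates:
            manifest.warnings.append(
                f"tree: {pr.dropped_replicates} bootstrap replicates dropped")
    except Exception as exc:
        manifest.stage_status["tree"] = f"failed: {exc}"
        manifest.warnings.append(f"tree: {exc}")

    try:
        kr = kaks_stage(bench.truth, bench.truth.boule_ids)
        (out / "kaks_boule.tsv").write_text(kr.to_tsv())
        manifest.stage_status["kaks"] = "ok"
        manifest.outputs["kaks_max_ratio_boule"] = kr.max_ratio
    except Exception as exc:
        manifest.stage_status["kaks"] = f"failed: {exc}"
        manifest.warnings.append(f"kaks: {exc}")

    manifest.outputs["out_dir"] = str(out)
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
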