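"""Ground-truth synthetic gene families.

Evolves a codon sequence along a tree under per-branch dN/dS by
acceptance–rejection: point mutations are proposed uniformly over codon
positions at a rate proportional to branch length, synonymous changes are
always accepted, nonsynonymous changes are accepted with probability omega
(omega_core inside the conserved RRM mask), and proposals creating stop
codons are rejected outright.  One labeled branch can found a second
(DAZL-like) family: its RNP motif codons are rewritten and a 2-codon
deletion applied, so deletion-bearing leaves and only those are DAZL in
truth.  Leaf coding sequences are then exonized at fixed junction offsets
(introns with GT..AG ends) and embedded at random positions/strands in
random background genomes, giving search, classification, phylogeny and
Ka/Ks stages a complete benchmark with known truth.

The scheme is deliberately simple (uniform proposals, no 61x61 rate matrix,
not time-reversible); it is exactly the process the NG86 estimator models,
which is what makes the parameter-recovery tests sharp.

Seed policy: one master seed; per-branch and per-leaf streams are derived
by stable hashing of node labels, so adding taxa does not perturb existing
lineages.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .phylo import Node, PhyloTree, read_newick
from .seq import (GeneModel, NucSequence, ProtSequence, SequenceError,
                  translate, write_fasta, write_gene_models)

_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOPS = frozenset(_TABLE.stop_codons)
_NUC = "ACGT"
_CODONS_FOR: dict[str, list[str]] = {}
for _codon, _aa in sorted(_TABLE.forward_table.items()):
    _CODONS_FOR.setdefault(_aa, []).append(_codon)


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SignatureSpec:
    """Where the conserved RRM core and its two RNP motifs live at the root."""

    rrm_start: int = 60          # codon offset of the RRM in the root CDS
    rrm_len: int = 92            # codons
    rnp2_offset: int = 12        # codon offset of RNP2 within the RRM
    rnp1_offset: int = 60        # codon offset of RNP1 within the RRM
    rnp2: str = "PNRIFVGG"
    rnp1: str = "DRAGVSKGYGFV"
    omega_core: float = 0.01     # conserved RRM core
    omega_motif: float = 0.01    # RNP motif positions, the most constrained


@dataclass(frozen=True)
class FamilyBranchSpec:
    """The branch founding the deletion-bearing (DAZL) family."""

    branch_label: str
    deletion_codon: int = 90     # absolute codon position in root coordinates
    rnp2: str = "VFVGGI"
    rnp1: str = "KGYGFVSF"


@dataclass(frozen=True)
class ExonPlan:
    junction_codons: tuple[int, ...] = (20, 80, 105, 130)
    intron_length: tuple[int, int] = (60, 200)


@dataclass
class SimulationConfig:
    tree: str                                  # newick, lengths = expected
    omega: float | dict[str, float] = 0.1      # proposals per codon
    root_length_codons: int = 250
    signature: SignatureSpec = field(default_factory=SignatureSpec)
    dazl: Optional[FamilyBranchSpec] = None
    indel_rate: float = 0.0
    exon_plan: ExonPlan = field(default_factory=ExonPlan)
    genome_length: int = 8000
    gc_content: float = 0.42
    seed: int = 0

    def __post_init__(self) -> None:
        sig = self.signature
        if isinstance(self.omega, (int, float)) and self.omega < 0:
            raise SimulationError("omega must be >= 0")
        if self.root_length_codons < sig.rrm_start + sig.rrm_len:
            raise SimulationError("root CDS shorter than the signature span")
        jc = self.exon_plan.junction_codons
        if any(b <= a for a, b in zip(jc, jc[1:])):
            raise SimulationError("junction offsets must be strictly increasing")
        if jc and jc[-1] >= self.root_length_codons:
            raise SimulationError("junction offset beyond the CDS")


@dataclass
class LeafTruth:
    leaf: str
    family: str                                # BOULE or DAZL
    cds: NucSequence
    protein: ProtSequence
    rrm_codon_span: tuple[int, int]            # codons in this leaf's CDS
    rnp2_codon: int
    rnp1_codon: int
    junction_codons: tuple[int, ...]
    genome: Optional[NucSequence] = None
    gene_model: Optional[GeneModel] = None
    gene_genomic_span: Optional[tuple[int, int]] = None
    gene_strand: Optional[str] = None


@dataclass
class FamilyTruth:
    config: SimulationConfig
    tree: PhyloTree
    leaves: dict[str, LeafTruth]
    branch_counts: dict[str, tuple[int, int, int]]  # proposed, syn, nonsyn

    @property
    def boule_ids(self) -> list[str]:
        return sorted(l for l, t in self.leaves.items() if t.family == "BOULE")

    @property
    def dazl_ids(self) -> list[str]:
        return sorted(l for l, t in self.leaves.items() if t.family == "DAZL")


# ---------------------------------------------------------------------------
# Core evolution
# ---------------------------------------------------------------------------

def _branch_rng(master_seed: int, label: str, salt: str = "") -> np.random.Generator:
    return np.random.default_rng(
        [int(master_seed) & 0x7FFFFFFF, zlib.crc32((label + salt).encode())])


def _node_label(node: Node) -> str:
    if node.name:
        return node.name
    return ",".join(sorted(l.name for l in node.leaves()))


def _random_sense_codon(rng: np.random.Generator) -> str:
    while True:
        codon = "".join(_NUC[k] for k in rng.integers(0, 4, 3))
        if codon not in STOPS:
            return codon


def _codon_encoding(aa: str, rng: np.random.Generator) -> str:
    try:
        options = _CODONS_FOR[aa]
    except KeyError:
        raise SimulationError(f"no codon encodes residue {aa!r}")
    return options[rng.integers(0, len(options))]


@dataclass
class _Lineage:
    codons: list[str]
    family: str
    rrm_start: int
    rrm_len: int
    rnp2_codon: int
    rnp1_codon: int
    rnp2_len: int
    rnp1_len: int
    junctions: tuple[int, ...]

    @property
    def mask(self) -> frozenset:
        return frozenset(range(self.rrm_start, self.rrm_start + self.rrm_len))

    @property
    def motif_codons(self) -> frozenset:
        return frozenset(range(self.rnp2_codon, self.rnp2_codon + self.rnp2_len)) | \
            frozenset(range(self.rnp1_codon, self.rnp1_codon + self.rnp1_len))


@lru_cache(maxsize=None)
def _codon_neighbor_counts(codon: str) -> tuple[int, int]:
    """(synonymous, stop) counts among the 9 single-nucleotide neighbors."""
    aa = _TABLE.forward_table[codon]
    syn = stop = 0
    for pos in range(3):
        for nt in _NUC:
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1:]
            if mutant in STOPS:
                stop += 1
            elif _TABLE.forward_table[mutant] == aa:
                syn += 1
    return syn, stop


def _evolve_branch(state: _Lineage, length: float, omega: float,
                   omega_core: float, omega_motif: float,
                   rng: np.random.Generator) -> tuple[int, int, int]:
    """Acceptance–rejection substitution along one branch.

    Proposals hitting stop codons are rejected outright; because the
    standard site-counting convention still books those opportunities as
    nonsynonymous sites, synonymous acceptances are thinned by the same
    per-codon stop factor (9-s-t)/(9-s), so the realized dN/dS per
    synonymous/nonsynonymous *site* equals the configured omega exactly,
    codon by codon.
    """
    n = len(state.codons)
    n_prop = int(rng.poisson(length * n)) if length > 0 else 0
    mask = state.mask
    motifs = state.motif_codons
    syn_acc = nonsyn_acc = 0
    for _ in range(n_prop):
        ci = int(rng.integers(0, n))
        pos = int(rng.integers(0, 3))
        codon = state.codons[ci]
        alternatives = [b for b in _NUC if b != codon[pos]]
        nt = alternatives[int(rng.integers(0, 3))]
        mutant = codon[:pos] + nt + codon[pos + 1:]
        if mutant in STOPS:
            continue
        if ci in motifs:
            om = omega_motif
        elif ci in mask:
            om = omega_core
        else:
            om = omega
        if _TABLE.forward_table[mutant] == _TABLE.forward_table[codon]:
            s, t = _codon_neighbor_counts(codon)
            p = (9 - s - t) / (9 - s) * min(1.0, 1.0 / om if om > 0 else 1.0)
            if rng.random() < p:
                state.codons[ci] = mutant
                syn_acc += 1
        else:
            if rng.random() < min(om, 1.0):
                state.codons[ci] = mutant
                nonsyn_acc += 1
    return n_prop, syn_acc, nonsyn_acc


def _found_dazl(state: _Lineage, spec: FamilyBranchSpec,
                rng: np.random.Generator) -> _Lineage:
    codons = list(state.codons)
    for off, motif in ((state.rnp2_codon, spec.rnp2),
                       (state.rnp1_codon, spec.rnp1)):
        for k, aa in enumerate(motif):
            codons[off + k] = _codon_encoding(aa, rng)
    d = spec.deletion_codon
    if not state.rrm_start <= d <= state.rrm_start + state.rrm_len - 2:
        raise SimulationError("deletion must fall inside the RRM")
    if state.rnp2_codon <= d < state.rnp2_codon + len(spec.rnp2) or \
            state.rnp1_codon <= d < state.rnp1_codon + len(spec.rnp1):
        raise SimulationError("deletion overlaps an RNP motif")
    del codons[d:d + 2]

    def shift(x: int) -> int:
        return x - 2 if x > d else x

    return _Lineage(
        codons=codons, family="DAZL", rrm_start=state.rrm_start,
        rrm_len=state.rrm_len - 2, rnp2_codon=shift(state.rnp2_codon),
        rnp1_codon=shift(state.rnp1_codon), rnp2_len=len(spec.rnp2),
        rnp1_len=len(spec.rnp1),
        junctions=tuple(shift(j) for j in state.junctions))


def _apply_indels(state: _Lineage, length: float, indel_rate: float,
                  rng: np.random.Generator) -> int:
    """Codon-level insertions/deletions in the flanks (outside the RRM).

    Events arrive at ``indel_rate x length`` expected per codon; each is a
    single-codon insertion (random sense codon) or deletion with equal
    probability, placed uniformly outside the RRM so the signature span,
    motifs and RRM-internal junction offsets stay intact; junction offsets
    up- or downstream shift accordingly.
    """
    if indel_rate <= 0 or length <= 0:
        return 0
    n_events = int(rng.poisson(indel_rate * length * len(state.codons)))
    applied = 0
    for _ in range(n_events):
        n = len(state.codons)
        flanks = [i for i in range(n)
                  if not state.rrm_start <= i < state.rrm_start + state.rrm_len]
        if not flanks:
            break
        pos = flanks[int(rng.integers(0, len(flanks)))]
        insert = bool(rng.random() < 0.5)
        if not insert and n <= state.rrm_len + 1:
            continue  # never shrink to just the RRM

        def shift(x: int, at: int, delta: int) -> int:
            return x + delta if x > at or (insert and x == at) else x

        delta = 1 if insert else -1
        if insert:
            state.codons.insert(pos, _random_sense_codon(rng))
        else:
            del state.codons[pos]
        state.rrm_start = shift(state.rrm_start, pos, delta)
        state.rnp2_codon = shift(state.rnp2_codon, pos, delta)
        state.rnp1_codon = shift(state.rnp1_codon, pos, delta)
        kept = []
        for j in state.junctions:
            j2 = shift(j, pos, delta)
            if 0 < j2 < len(state.codons):
                kept.append(j2)
        state.junctions = tuple(kept)
        applied += 1
    return applied


def _branch_omega(cfg: SimulationConfig, label: str) -> float:
    if isinstance(cfg.omega, dict):
        if label not in cfg.omega:
            raise SimulationError(f"omega not configured for branch {label!r}")
        return float(cfg.omega[label])
    return float(cfg.omega)


def evolve_family(cfg: SimulationConfig) -> FamilyTruth:
    """Simulate the family; reproducible given the config (incl. seed)."""
    tree = read_newick(cfg.tree)
    sig = cfg.signature
    root_rng = _branch_rng(cfg.seed, "__root__")
    codons = [_random_sense_codon(root_rng)
              for _ in range(cfg.root_length_codons)]
    for off, motif in ((sig.rrm_start + sig.rnp2_offset, sig.rnp2),
                       (sig.rrm_start + sig.rnp1_offset, sig.rnp1)):
        for k, aa in enumerate(motif):
            codons[off + k] = _codon_encoding(aa, root_rng)
    root_state = _Lineage(
        codons=codons, family="BOULE", rrm_start=sig.rrm_start,
        rrm_len=sig.rrm_len, rnp2_codon=sig.rrm_start + sig.rnp2_offset,
        rnp1_codon=sig.rrm_start + sig.rnp1_offset,
        rnp2_len=len(sig.rnp2), rnp1_len=len(sig.rnp1),
        junctions=cfg.exon_plan.junction_codons)

    leaves: dict[str, LeafTruth] = {}
    branch_counts: dict[str, tuple[int, int, int]] = {}

    def walk(node: Node, state: _Lineage) -> None:
        label = _node_label(node)
        rng = _branch_rng(cfg.seed, label)
        if cfg.dazl is not None and label == cfg.dazl.branch_label:
            state = _found_dazl(state, cfg.dazl, rng)
        if node.length > 0 or node.is_leaf:
            counts = _evolve_branch(state, node.length,
                                    _branch_omega(cfg, label),
                                    sig.omega_core, sig.omega_motif, rng)
            branch_counts[label] = counts
            _apply_indels(state, node.length, cfg.indel_rate, rng)
        if node.is_leaf:
            cds = NucSequence(node.name, "".join(state.codons))
            leaves[node.name] = LeafTruth(
                leaf=node.name, family=state.family, cds=cds,
                protein=translate(cds),
                rrm_codon_span=(state.rrm_start,
                                state.rrm_start + state.rrm_len),
                rnp2_codon=state.rnp2_codon, rnp1_codon=state.rnp1_codon,
                junction_codons=state.junctions)
            return
        for child in node.children:
            walk(child, replace(state, codons=list(state.codons)))

    for child in tree.root.children:
        walk(child, replace(root_state, codons=list(root_state.codons)))
    if not leaves:
        raise SimulationError("tree has no leaves")
    return FamilyTruth(config=cfg, tree=tree, leaves=leaves,
                       branch_counts=branch_counts)


# ---------------------------------------------------------------------------
# Exonization and genomic embedding
# ---------------------------------------------------------------------------

def _random_background(rng: np.random.Generator, length: int,
                       gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def _random_intron(rng: np.random.Generator, lo: int, hi: int,
                   gc: float) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "GT" + _random_background(rng, max(n - 4, 0), gc) + "AG"


def exonize_and_embed(truth: FamilyTruth,
                      forced_strands: Optional[dict[str, str]] = None,
                      fused_junctions: Optional[dict[str, int]] = None,
                      intronless: Optional[set[str]] = None) -> FamilyTruth:
    """Split each leaf CDS into exons and embed it in a background genome.

    ``fused_junctions`` removes the given junction index for a leaf (the
    Drosophila-style exon fusion); leaves in ``intronless`` are embedded as
    a single exon.  Splicing each written gene model back out of its genome
    reproduces the CDS exactly (verified here).
    """
    cfg = truth.config
    lo, hi = cfg.exon_plan.intron_length
    for leaf, lt in sorted(truth.leaves.items()):
        rng = _branch_rng(cfg.seed, leaf, salt="|genome")
        junctions = [3 * j for j in lt.junction_codons]
        if fused_junctions and leaf in fused_junctions:
            junctions = [x for k, x in enumerate(junctions)
                         if k != fused_junctions[leaf]]
        if intronless and leaf in intronless:
            junctions = []
        cds = lt.cds.residues
        if junctions and junctions[-1] >= len(cds):
            raise SimulationError(f"junction beyond CDS for {leaf}")
        bounds = [0] + junctions + [len(cds)]
        exon_seqs = [cds[a:b] for a, b in zip(bounds, bounds[1:])]
        introns = [_random_intron(rng, lo, hi, cfg.gc_content)
                   for _ in range(len(exon_seqs) - 1)]
        gene = exon_seqs[0]
        for intron, exon in zip(introns, exon_seqs[1:]):
            gene += intron + exon
        if len(gene) >= cfg.genome_length:
            raise SimulationError(
                f"gene for {leaf} ({len(gene)} nt) does not fit the "
                f"genome ({cfg.genome_length} nt)")
        strand = (forced_strands or {}).get(
            leaf, "+" if rng.random() < 0.5 else "-")
        placed = gene if strand == "+" else str(Seq(gene).reverse_complement())
        pos = int(rng.integers(0, cfg.genome_length - len(gene)))
        background = _random_background(rng, cfg.genome_length, cfg.gc_content)
        genomic = background[:pos] + placed + background[pos + len(placed):]
        genome = NucSequence(f"genome_{leaf}", genomic)

        # exon coordinates on the forward strand, then transcript order
        exon_coords = []
        acc = pos if strand == "+" else pos
        offset = 0
        for k, ex in enumerate(exon_seqs):
            start = offset
            exon_coords.append((start, start + len(ex)))
            offset += len(ex) + (len(introns[k]) if k < len(introns) else 0)
        if strand == "+":
            fwd = [(pos + s, pos + e) for s, e in exon_coords]
            ordered = fwd
        else:
            # gene string was reverse-complemented: local coord x maps to
            # pos + len(gene) - x on the forward strand
            fwd = [(pos + len(gene) - e, pos + len(gene) - s)
                   for s, e in exon_coords]
            ordered = fwd  # transcript order = original exon order
        model = GeneModel(gene_id=f"{leaf}_gene", seq_id=genome.id,
                          strand=strand, exons=ordered)
        spliced = model.spliced_cds(genome)
        if spliced.residues != cds:
            raise SimulationError(f"splice round-trip failed for {leaf}")
        lt.genome = genome
        lt.gene_model = model
        lt.gene_genomic_span = (pos, pos + len(gene))
        lt.gene_strand = strand
    return truth


# ---------------------------------------------------------------------------
# Benchmark presets
# ---------------------------------------------------------------------------

DEFAULT_TREE = (
    "((B1:0.08,B2:0.08):0.05,((B3:0.08,B4:0.08):0.05,"
    "(B5:0.08,(B6:0.08,B7:0.08):0.05):0.05):0.04,"
    "((D1:0.08,D2:0.08):0.05,(D3:0.08,(D4:0.08,D5:0.08):0.05):0.05)"
    "DAZLANC:0.12);")

HARD_TREE = (
    "((B1:0.6,B2:0.6):0.3,(B3:0.6,B4:0.6):0.3,"
    "((D1:0.6,D2:0.6):0.3,(D3:0.6,D4:0.6):0.3)DAZLANC:0.4);")


@dataclass
class Benchmark:
    preset: str
    truth: FamilyTruth
    training_ids: list[str]
    test_ids: list[str]
    negatives: list[ProtSequence]      # scrambled signatures + random decoys
    scrambled_ids: list[str]
    reference_proteome: list[ProtSequence]
    family_labels: dict[str, str]
    null_genomes: list[NucSequence]

    def write(self, out_dir: str | Path, overwrite: bool = False) -> None:
        out = Path(out_dir)
        if out.exists() and any(out.iterdir()) and not overwrite:
            raise SimulationError(f"output directory {out} is not empty "
                                  "(pass overwrite)")
        out.mkdir(parents=True, exist_ok=True)
        leaves = [self.truth.leaves[l] for l in sorted(self.truth.leaves)]
        write_fasta([l.cds for l in leaves], out / "cds.fasta")
        write_fasta([l.protein for l in leaves], out / "proteins.fasta")
        write_fasta([l.genome for l in leaves if l.genome is not None],
                    out / "genomes.fasta")
        write_fasta(self.negatives, out / "negatives.fasta")
        write_fasta(self.reference_proteome, out / "reference_proteome.fasta")
        if self.null_genomes:
            write_fasta(self.null_genomes, out / "null_genomes.fasta")
        write_gene_models([l.gene_model for l in leaves
                           if l.gene_model is not None], out / "models.gff3")
        rows = ["id\tfamily\trole"]
        for l in leaves:
            role = "training" if l.leaf in self.training_ids else "test"
            rows.append(f"{l.leaf}\t{l.family}\t{role}")
        for p in self.negatives:
            rows.append(f"{p.id}\tNEGATIVE\tnegative")
        (out / "truth.tsv").write_text("\n".join(rows) + "\n")
        (out / "config.json").write_text(json.dumps({
            "preset": self.preset, "seed": self.truth.config.seed,
            "tree": self.truth.config.tree,
            "omega": self.truth.config.omega,
            "root_length_codons": self.truth.config.root_length_codons,
        }, indent=1) + "\n")


def _scramble_signature(lt: LeafTruth, rng: np.random.Generator,
                        sig: SignatureSpec) -> ProtSequence:
    """Shuffle the residues at the RNP motif positions of a real leaf protein.

    Produces a negative that keeps overall RRM similarity but lacks the
    signature — the classifier must never call it BOULE.
    """
    residues = list(lt.protein.residues)
    positions = (list(range(lt.rnp2_codon, lt.rnp2_codon + len(sig.rnp2)))
                 + list(range(lt.rnp1_codon, lt.rnp1_codon + len(sig.rnp1))))
    motif = [residues[p] for p in positions]
    for _ in range(50):
        perm = list(rng.permutation(len(motif)))
        moved = sum(1 for k, q in enumerate(perm) if motif[k] != motif[q])
        if moved >= len(motif) - 2:
            break
    for k, p in enumerate(positions):
        residues[p] = motif[perm[k]]
    return ProtSequence(f"{lt.leaf}_scrambled", "".join(residues))


def _random_protein(rng: np.random.Generator, length: int,
                    name: str) -> ProtSequence:
    aas = "ACDEFGHIKLMNPQRSTVWY"
    return ProtSequence(name, "".join(
        aas[k] for k in rng.integers(0, 20, length)))


def make_benchmark(preset: str = "default", seed: int = 0) -> Benchmark:
    """Build a preset benchmark bundle (see module docstring).

    ``default``: 7 BOULE + 5 DAZL leaves at mild divergence; training leaves
    feed consensus/signature derivation, held-out leaves plus
    signature-scrambled and random negatives are the classification set;
    test-leaf genes are exonized and embedded in genomes (random strands).
    ``hard``: fewer taxa, long branches and a relaxed RRM core (~20%
    within-RRM divergence).  ``null``: background genomes with no embedded
    family member.
    """
    if preset not in ("default", "hard", "null"):
        raise SimulationError(f"unknown preset {preset!r}")
    rng = np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(preset.encode())])
    if preset == "null":
        cfg = SimulationConfig(tree="(A:0.1,B:0.1,C:0.1);", seed=seed)
        null = [NucSequence(f"null_genome_{k}",
                            _random_background(rng, cfg.genome_length,
                                               cfg.gc_content))
                for k in range(3)]
        empty = FamilyTruth(config=cfg, tree=read_newick(cfg.tree),
                            leaves={}, branch_counts={})
        return Benchmark(preset, empty, [], [], [], [], [], {}, null)

    if preset == "default":
        cfg = SimulationConfig(
            tree=DEFAULT_TREE, omega=0.1, seed=seed,
            dazl=FamilyBranchSpec(branch_label="DAZLANC"))
        training = ["B1", "B2", "B3", "B4", "D1", "D2", "D3"]
        test = ["B5", "B6", "B7", "D4", "D5"]
    else:  # hard
        cfg = SimulationConfig(
            tree=HARD_TREE, omega=0.25, seed=seed,
            signature=SignatureSpec(omega_core=0.25, omega_motif=0.05),
            dazl=FamilyBranchSpec(branch_label="DAZLANC"))
        training = ["B1", "B2", "D1", "D2"]
        test = ["B3", "B4", "D3", "D4"]

    truth = evolve_family(cfg)
    # alternate strands deterministically so both are always exercised
    strands = {leaf: ("+" if k % 2 == 0 else "-")
               for k, leaf in enumerate(sorted(truth.leaves))}
    truth = exonize_and_embed(truth, forced_strands=strands)

    negatives = [_scramble_signature(truth.leaves[l], rng, cfg.signature)
                 for l in test if truth.leaves[l].family == "BOULE"]
    scrambled_ids = [p.id for p in negatives]
    negatives += [_random_protein(rng, cfg.root_length_codons, f"decoy_{k}")
                  for k in range(2)]

    reference = [truth.leaves[l].protein for l in training]
    labels = {l: truth.leaves[l].family for l in training}
    for k in range(3):
        p = _random_protein(rng, 200, f"ref_other_{k}")
        reference.append(p)
        labels[p.id] = "OTHER"

    null = [NucSequence(f"null_genome_{k}",
                        _random_background(rng, cfg.genome_length,
                                           cfg.gc_content))
            for k in range(3)]
    return Benchmark(preset, truth, training, test, negatives, scrambled_ids,
                     reference, labels, null)
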