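"""Sequence and gene-model primitives shared by every pipeline stage.

Nucleotide and protein sequences are thin validated containers; gene models
hold exon structures in 0-based half-open coordinates in transcript
orientation.  FASTA I/O goes through Bio.SeqIO, GFF3 reading through
gffutils; coordinate conversion (GFF3 is 1-based inclusive) happens at the
parsing boundary only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUC_ALPHABET = set("ACGTN")
PROT_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")

#: average (not monoisotopic) residue masses in Da; the size criteria the
#: classifier applies ("around 30 kDa") operate at this granularity.
RESIDUE_MASS_DA = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS_DA = 18.0153
#: mean of the 20 residue masses, used for 'X' only when explicitly enabled
AVERAGE_RESIDUE_MASS_DA = sum(RESIDUE_MASS_DA.values()) / 20.0


class SequenceError(ValueError):
    """Raised for alphabet violations, duplicate IDs and malformed inputs."""


@dataclass(frozen=True)
class NucSequence:
    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.residues:
            raise SequenceError(f"nucleotide sequence {self.id!r} is empty")
        bad = set(self.residues) - NUC_ALPHABET
        if bad:
            raise SequenceError(
                f"invalid nucleotide character(s) {sorted(bad)} in record {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "NucSequence":
        return NucSequence(self.id, str(Seq(self.residues).reverse_complement()),
                           self.description)


@dataclass(frozen=True)
class ProtSequence:
    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.residues:
            raise SequenceError(f"protein sequence {self.id!r} is empty")
        if any(c.isspace() for c in self.residues):
            raise SequenceError(f"whitespace inside protein record {self.id!r}")
        bad = set(self.residues) - PROT_ALPHABET
        if bad:
            raise SequenceError(
                f"invalid amino-acid character(s) {sorted(bad)} in record {self.id!r}"
            )
        if "*" in self.residues[:-1]:
            raise SequenceError(
                f"internal stop '*' in protein record {self.id!r}; "
                "'*' is permitted only as a trailing stop marker"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def strip_stop(self) -> "ProtSequence":
        if self.residues.endswith("*"):
            return ProtSequence(self.id, self.residues[:-1], self.description)
        return self


@dataclass
class GeneModel:
    """Exon structure of one coding gene.

    ``exons`` are (start, end) 0-based half-open intervals on the *forward*
    strand of ``seq_id``, ordered 5'→3' in transcript orientation (i.e. for a
    minus-strand gene the first exon has the highest coordinates).
    """

    gene_id: str
    seq_id: str
    strand: Literal["+", "-"]
    exons: list[tuple[int, int]]
    coding_frame_offset: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise SequenceError(f"unknown strand {self.strand!r} for {self.gene_id}")
        if not self.exons:
            raise SequenceError(f"gene model {self.gene_id} has no exons")
        for s, e in self.exons:
            if e <= s:
                raise SequenceError(
                    f"degenerate exon ({s},{e}) in gene model {self.gene_id}")
        fwd = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(fwd, fwd[1:]):
            if s2 < e1:
                raise SequenceError(
                    f"overlapping exons in gene model {self.gene_id}")
        if not 0 <= self.coding_frame_offset <= 2:
            raise SequenceError("coding_frame_offset must be 0..2")

    @property
    def n_junctions(self) -> int:
        return len(self.exons) - 1

    def spliced_cds(self, genome: NucSequence) -> NucSequence:
        """Extract and splice exons from the genome, in transcript orientation."""
        parts = [genome.residues[s:e] for s, e in sorted(self.exons)]
        cds = "".join(parts)
        if self.strand == "-":
            cds = str(Seq(cds).reverse_complement())
        cds = cds[self.coding_frame_offset:]
        return NucSequence(self.gene_id, cds)

    def junction_cds_offsets(self) -> list[int]:
        """CDS-relative nucleotide offsets of the exon–exon junctions."""
        lengths = [e - s for s, e in self.exons]  # already transcript order
        offsets, acc = [], 0
        for ln in lengths[:-1]:
            acc += ln
            offsets.append(acc - self.coding_frame_offset)
        return offsets


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, alphabet: Literal["nuc", "prot"],
               strip_gaps: bool = False):
    """Read a FASTA file into ``NucSequence`` or ``ProtSequence`` records.

    Gap characters '-' are rejected for nucleotide input; for protein input
    they are rejected unless ``strip_gaps=True``, in which case they are
    removed with a warning (aligned FASTA fed back as plain sequences).
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"no FASTA records in {path}")
    seen: set[str] = set()
    out = []
    for rec in records:
        if rec.id in seen:
            raise SequenceError(f"duplicate FASTA ID {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = str(rec.seq)
        if "-" in residues:
            if alphabet == "prot" and strip_gaps:
                warnings.warn(f"stripping gap characters from record {rec.id!r}")
                residues = residues.replace("-", "")
            else:
                raise SequenceError(f"gap character '-' in record {rec.id!r}")
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        if alphabet == "nuc":
            out.append(NucSequence(rec.id, residues, desc))
        else:
            out.append(ProtSequence(rec.id, residues, desc))
    return out


def write_fasta(seqs: Iterable[NucSequence | ProtSequence], path: str | Path,
                width: int = 60) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description=s.description)
        for s in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GFF3 I/O (gene/mRNA/exon/CDS subset)
# ---------------------------------------------------------------------------

def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Parse a GFF3 subset into gene models.

    One model per mRNA (or per gene when no mRNA feature is present); exon
    coordinates converted from 1-based inclusive to 0-based half-open and
    re-ordered to transcript orientation for minus-strand genes.
    """
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    models: list[GeneModel] = []
    parents = list(db.features_of_type("mRNA")) or list(db.features_of_type("gene"))
    if not parents:
        raise SequenceError(f"no gene/mRNA features in {path}")
    for parent in parents:
        exons = [(f.start - 1, f.end)
                 for f in db.children(parent, featuretype="exon", order_by="start")]
        if not exons:
            raise SequenceError(f"gene model {parent.id} has no exon features")
        if parent.strand not in "+-":
            raise SequenceError(f"unknown strand {parent.strand!r} for {parent.id}")
        if parent.strand == "-":
            exons = exons[::-1]
        frame = 0
        cds = list(db.children(parent, featuretype="CDS", order_by="start"))
        if cds:
            first = cds[-1] if parent.strand == "-" else cds[0]
            if first.frame in {"0", "1", "2"}:
                frame = int(first.frame)
        models.append(GeneModel(parent.id, parent.seqid, parent.strand, exons, frame))
    return models


def write_gene_models(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as a minimal deterministic GFF3 (gene + exon rows)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            fwd = sorted(m.exons)
            start, end = fwd[0][0] + 1, fwd[-1][1]
            fh.write(f"{m.seq_id}\tdazfam\tgene\t{start}\t{end}\t.\t{m.strand}\t.\t"
                     f"ID={m.gene_id}\n")
            fh.write(f"{m.seq_id}\tdazfam\tmRNA\t{start}\t{end}\t.\t{m.strand}\t.\t"
                     f"ID={m.gene_id}.t1;Parent={m.gene_id}\n")
            for i, (s, e) in enumerate(fwd, 1):
                fh.write(f"{m.seq_id}\tdazfam\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                         f"ID={m.gene_id}.e{i};Parent={m.gene_id}.t1\n")
            # CDS rows mirror exons; frame on the transcript-first CDS row
            for i, (s, e) in enumerate(fwd, 1):
                is_first = (i == 1 and m.strand == "+") or \
                           (i == len(fwd) and m.strand == "-")
                frame = str(m.coding_frame_offset) if is_first else "."
                fh.write(f"{m.seq_id}\tdazfam\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t"
                         f"{frame}\tID={m.gene_id}.c{i};Parent={m.gene_id}.t1\n")


# ---------------------------------------------------------------------------
# Translation and protein metrics
# ---------------------------------------------------------------------------

def translate(seq: NucSequence, frame: int = 0,
              strand: Literal["+", "-"] = "+") -> ProtSequence:
    """Translate with the standard genetic code (table 1).

    Minus strand means reverse-complement first, then apply the frame offset.
    Trailing partial codons are dropped; codons containing 'N' yield 'X';
    stops are '*'.  An internal stop raises (this entry point is for coding
    sequences); use :func:`translate_raw` for six-frame genomic translation.
    """
    return ProtSequence(seq.id, _translate_str(seq, frame, strand), seq.description)


class _RawProt(ProtSequence):
    """Protein sequence that tolerates internal stops (six-frame output)."""

    def __post_init__(self) -> None:  # skip the internal-stop check
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.residues:
            raise SequenceError(f"protein sequence {self.id!r} is empty")
        bad = set(self.residues) - PROT_ALPHABET
        if bad:
            raise SequenceError(
                f"invalid amino-acid character(s) {sorted(bad)} in record {self.id!r}")


def _translate_str(seq: NucSequence, frame: int, strand: str) -> str:
    if frame not in (0, 1, 2):
        raise SequenceError("frame must be 0, 1 or 2")
    nt = seq.residues
    if strand == "-":
        nt = str(Seq(nt).reverse_complement())
    elif strand != "+":
        raise SequenceError(f"unknown strand {strand!r}")
    nt = nt[frame:]
    if len(nt) < 3:
        raise SequenceError("sequence too short to translate in this frame")
    nt = nt[: len(nt) - len(nt) % 3]
    aa = []
    for i in range(0, len(nt), 3):
        codon = nt[i:i + 3]
        aa.append("X" if "N" in codon else str(Seq(codon).translate(table=1)))
    return "".join(aa)


def translate_raw(seq: NucSequence, frame: int = 0,
                  strand: Literal["+", "-"] = "+") -> ProtSequence:
    """Like :func:`translate` but internal stops are allowed in the result."""
    return _RawProt(seq.id, _translate_str(seq, frame, strand), seq.description)


def molecular_weight_kda(seq: ProtSequence, allow_x: bool = False) -> float:
    """Average-mass molecular weight in kDa (residue masses + one water).

    'X' residues are an error unless ``allow_x=True``, in which case each X
    contributes the mean of the 20 standard residue masses.
    """
    residues = seq.strip_stop().residues
    if "*" in residues:
        raise SequenceError(f"internal stop in {seq.id!r}")
    total = WATER_MASS_DA
    for aa in residues:
        if aa == "X":
            if not allow_x:
                raise SequenceError(
                    f"'X' residue in {seq.id!r}; pass allow_x=True to use an "
                    "average residue mass")
            total += AVERAGE_RESIDUE_MASS_DA
        else:
            total += RESIDUE_MASS_DA[aa]
    return total / 1000.0
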