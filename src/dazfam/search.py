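"""Tblastn-style translated homolog search, re-implemented exactly.

A consensus protein query is aligned (Smith–Waterman, affine gaps) against
all six translation frames of each nucleotide target; hits above a score
threshold are mapped back to forward-strand nucleotide spans for
intersection with gene models.  Ranking is by raw score (no E-value
statistics); candidate proteins are validated by reciprocal best hit
against a labeled reference proteome, mirroring the "BLAST back against the
human proteome, expect BOULE on top" check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from . import _align
from .msa import DEFAULT_GAP_EXTEND, DEFAULT_GAP_OPEN, DEFAULT_MATRIX
from .seq import NucSequence, ProtSequence, SequenceError, translate_raw

FRAMES = (1, 2, 3, -1, -2, -3)


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    target_id: str
    frame: Optional[int]  # +1..+3 / -1..-3; None for protein-protein hits
    target_nuc_span: Optional[tuple[int, int]]  # forward strand, half-open
    aligned_query: str
    aligned_subject: str
    raw_score: float
    percent_identity: float

    @property
    def strand(self) -> Optional[str]:
        if self.frame is None:
            return None
        return "+" if self.frame > 0 else "-"


def _percent_identity(row_q: str, row_s: str) -> float:
    cols = len(row_q)
    if cols == 0:
        return 0.0
    ident = sum(1 for a, b in zip(row_q, row_s) if a == b and a != "-")
    return 100.0 * ident / cols


def six_frame_translate(seq: NucSequence):
    """All six translation frames with coordinate maps.

    Returns a list of (frame, ProtSequence, span_of) where
    ``span_of(protein_pos)`` gives the (start, end) forward-strand codon span
    of that residue.  Frames +1..+3 read the forward strand with offsets
    0..2; -1..-3 read the reverse complement the same way.
    """
    if len(seq) < 3:
        raise SequenceError("sequence shorter than one codon")
    L = len(seq)
    out = []
    for frame in FRAMES:
        offset = abs(frame) - 1
        if L - offset < 3:
            continue
        strand = "+" if frame > 0 else "-"
        prot = translate_raw(seq, offset, strand)

        def span_of(p: int, offset=offset, strand=strand) -> tuple[int, int]:
            s, e = offset + 3 * p, offset + 3 * p + 3
            if strand == "-":
                s, e = L - e, L - s
            return s, e

        out.append((frame, prot, span_of))
    return out


def smith_waterman(query: ProtSequence, subject: ProtSequence,
                   matrix: str = DEFAULT_MATRIX,
                   gap_open: float = DEFAULT_GAP_OPEN,
                   gap_extend: float = DEFAULT_GAP_EXTEND) -> AlignmentHit:
    """Optimal local alignment of two proteins as an AlignmentHit.

    A raw score of 0 (no positive-scoring alignment) is a valid no-hit
    result with empty aligned rows.
    """
    rq, rs, score, _, _ = _align.local_align(query.residues, subject.residues,
                                             matrix, gap_open, gap_extend)
    return AlignmentHit(query_id=query.id, target_id=subject.id, frame=None,
                        target_nuc_span=None, aligned_query=rq,
                        aligned_subject=rs, raw_score=score,
                        percent_identity=_percent_identity(rq, rs))


def query_self_score(query: ProtSequence, matrix: str = DEFAULT_MATRIX) -> float:
    """Diagonal self-score of the query (basis of the default threshold)."""
    alphabet, sub = _align.load_matrix(matrix)
    codes = _align.encode(query.residues, alphabet)
    return float(sub[codes, codes].sum())


def _merge_overlapping(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    """Drop the lower-scoring of two same-target, same-strand hits whose
    nucleotide spans overlap by more than 50% of the shorter span."""
    kept: list[AlignmentHit] = []
    for hit in sorted(hits, key=lambda h: (-h.raw_score, h.target_id,
                                           h.target_nuc_span[0])):
        redundant = False
        for other in kept:
            if (other.target_id == hit.target_id
                    and other.strand == hit.strand):
                s1, e1 = hit.target_nuc_span
                s2, e2 = other.target_nuc_span
                overlap = max(0, min(e1, e2) - max(s1, s2))
                if overlap > 0.5 * min(e1 - s1, e2 - s2):
                    redundant = True
                    break
        if not redundant:
            kept.append(hit)
    return kept


def search_targets(profile_query: ProtSequence,
                   targets: Sequence[NucSequence],
                   min_score: Optional[float] = None,
                   matrix: str = DEFAULT_MATRIX,
                   gap_open: float = DEFAULT_GAP_OPEN,
                   gap_extend: float = DEFAULT_GAP_EXTEND,
                   ) -> list[AlignmentHit]:
    """Search nucleotide targets with a protein query across six frames.

    ``min_score`` defaults to 20% of the query self-score, calibrated so
    that single-exon fragments of an intron-split RRM still score above it
    while the maximum local score in random background sequence (empirically
    ~10% of self-score for an 8 kb target) stays well below.  Hits are merged
    (same strand, >50% span overlap keeps the higher score) and returned
    sorted by raw score descending, ties by (target_id, span start).  An
    empty list is a valid no-hit outcome.
    """
    if not targets:
        raise SequenceError("no search targets supplied")
    if min_score is None:
        min_score = 0.2 * query_self_score(profile_query, matrix)
    hits: list[AlignmentHit] = []
    for target in targets:
        for frame, prot, span_of in six_frame_translate(target):
            rq, rs, score, _, (bs, be) = _align.local_align(
                profile_query.residues, prot.residues, matrix, gap_open,
                gap_extend)
            if score < min_score or score <= 0:
                continue
            nuc_start = min(span_of(bs)[0], span_of(be - 1)[0])
            nuc_end = max(span_of(bs)[1], span_of(be - 1)[1])
            hits.append(AlignmentHit(
                query_id=profile_query.id, target_id=target.id, frame=frame,
                target_nuc_span=(nuc_start, nuc_end), aligned_query=rq,
                aligned_subject=rs, raw_score=score,
                percent_identity=_percent_identity(rq, rs)))
    hits = _merge_overlapping(hits)
    hits.sort(key=lambda h: (-h.raw_score, h.target_id, h.target_nuc_span[0]))
    return hits


def reciprocal_best_hit(candidate: ProtSequence,
                        reference_proteome: Sequence[ProtSequence],
                        family_labels: dict[str, str],
                        claimed_family: str,
                        matrix: str = DEFAULT_MATRIX,
                        gap_open: float = DEFAULT_GAP_OPEN,
                        gap_extend: float = DEFAULT_GAP_EXTEND,
                        ) -> tuple[str, str, bool]:
    """Best hit of a candidate in a labeled reference proteome.

    Returns (top_hit_id, top_hit_family, is_confirming); confirming means the
    unique top hit's family equals ``claimed_family``.  A score tie across
    different families is non-confirming.
    """
    if not reference_proteome:
        raise SequenceError("reference proteome is empty")
    missing = [p.id for p in reference_proteome if p.id not in family_labels]
    if missing:
        raise SequenceError(f"unlabeled reference protein(s) {missing}")
    scored = []
    for ref in reference_proteome:
        hit = smith_waterman(candidate, ref, matrix, gap_open, gap_extend)
        scored.append((hit.raw_score, ref.id))
    scored.sort(key=lambda t: (-t[0], t[1]))
    top_score, top_id = scored[0]
    tied = {family_labels[i] for s, i in scored if abs(s - top_score) < 1e-9}
    family = family_labels[top_id]
    confirming = (len(tied) == 1 and family == claimed_family
                  and top_score > 0)
    return top_id, family, confirming


def hits_to_tsv(hits: Sequence[AlignmentHit]) -> str:
    """Hit table (query, target, frame, start, end, score, pident)."""
    lines = ["query\ttarget\tframe\tstart\tend\tscore\tpident"]
    for h in hits:
        start, end = h.target_nuc_span if h.target_nuc_span else ("", "")
        lines.append(f"{h.query_id}\t{h.target_id}\t{h.frame}\t{start}\t{end}"
                     f"\t{h.raw_score:.1f}\t{h.percent_identity:.1f}")
    return "\n".join(lines) + "\n"


def hits_to_bed(hits: Sequence[AlignmentHit]) -> str:
    """Hit spans as BED6 (0-based half-open, strand column)."""
    lines = []
    for h in hits:
        if h.target_nuc_span is None:
            continue
        s, e = h.target_nuc_span
        lines.append(f"{h.target_id}\t{s}\t{e}\t{h.query_id}\t"
                     f"{h.raw_score:.0f}\t{h.strand}")
    return "\n".join(lines) + "\n"
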