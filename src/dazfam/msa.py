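"""Progressive multiple alignment and consensus-profile derivation.

The consensus machinery mirrors how family signatures are built in
comparative surveys of RRM proteins: align the homologs of each family,
derive a per-column consensus with parenthesised alternate residues
(e.g. ``PNRI(V)FVGG``), and record the spans of the two RNP submotifs that
carry most of the discriminating information.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _align
from .seq import ProtSequence, SequenceError

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 0.2


@dataclass
class MultipleAlignment:
    """Rows of (seq_id, aligned string); all rows the same length."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.rows:
            raise SequenceError("alignment has no rows")
        lengths = {len(r) for _, r in self.rows}
        if len(lengths) != 1:
            raise SequenceError("alignment rows differ in length")

    @property
    def length(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.rows]

    def row(self, seq_id: str) -> str:
        for i, r in self.rows:
            if i == seq_id:
                return r
        raise KeyError(seq_id)

    def degapped(self) -> list[ProtSequence]:
        return [ProtSequence(i, r.replace("-", "")) for i, r in self.rows]

    def column(self, i: int) -> str:
        return "".join(r[i] for _, r in self.rows)


def pairwise_global_align(a: ProtSequence, b: ProtSequence,
                          matrix: str = DEFAULT_MATRIX,
                          gap_open: float = DEFAULT_GAP_OPEN,
                          gap_extend: float = DEFAULT_GAP_EXTEND,
                          ) -> MultipleAlignment:
    """Optimal global (Needleman–Wunsch, affine-gap) alignment of two proteins."""
    ra, rb, _ = _align.global_align(a.residues, b.residues, matrix,
                                    gap_open, gap_extend)
    return MultipleAlignment([(a.id, ra), (b.id, rb)])


def alignment_score(msa: MultipleAlignment, matrix: str = DEFAULT_MATRIX,
                    gap_open: float = DEFAULT_GAP_OPEN,
                    gap_extend: float = DEFAULT_GAP_EXTEND) -> float:
    """Sum-of-pairs score of a two-row alignment."""
    if len(msa.rows) != 2:
        raise ValueError("alignment_score expects a pairwise alignment")
    return _align.score_alignment(msa.rows[0][1], msa.rows[1][1], matrix,
                                  gap_open, gap_extend)


def p_distance(row_a: str, row_b: str) -> float:
    """Proportion of mismatches over columns where both rows have residues."""
    pairs = [(x, y) for x, y in zip(row_a, row_b) if x != "-" and y != "-"]
    if not pairs:
        return 1.0
    return sum(1 for x, y in pairs if x != y) / len(pairs)


# ---------------------------------------------------------------------------
# Progressive MSA
# ---------------------------------------------------------------------------

def _profile_freqs(rows: list[str], alphabet: str) -> np.ndarray:
    """(ncols, |alphabet|) per-column residue frequencies; gaps contribute 0."""
    ncols = len(rows[0])
    out = np.zeros((ncols, len(alphabet)))
    index = {c: k for k, c in enumerate(alphabet)}
    for r in rows:
        for i, c in enumerate(r):
            if c != "-":
                out[i, index[c]] += 1.0
    return out / len(rows)


def _merge_profiles(rows1: list[tuple[str, str]], rows2: list[tuple[str, str]],
                    matrix: str, gap_open: float, gap_extend: float):
    alphabet, sub = _align.load_matrix(matrix)
    p1 = _profile_freqs([r for _, r in rows1], alphabet)
    p2 = _profile_freqs([r for _, r in rows2], alphabet)
    scores = p1 @ sub @ p2.T
    ops, _, _, _ = _align.align_path(scores, gap_open, gap_extend, local=False)
    out1 = {i: [] for i, _ in rows1}
    out2 = {i: [] for i, _ in rows2}
    i = j = 0
    for op in ops:
        if op in "DU":
            for sid, r in rows1:
                out1[sid].append(r[i])
            i += 1
        else:
            for sid in out1:
                out1[sid].append("-")
        if op in "DL":
            for sid, r in rows2:
                out2[sid].append(r[j])
            j += 1
        else:
            for sid in out2:
                out2[sid].append("-")
    merged = [(sid, "".join(out1[sid])) for sid, _ in rows1]
    merged += [(sid, "".join(out2[sid])) for sid, _ in rows2]
    return merged


def _nj_merge_order(D: np.ndarray) -> list[tuple[int, int]]:
    """Neighbor-joining join order on a distance matrix.

    Returns the sequence of (cluster_i, cluster_j) index pairs joined; the
    joined cluster takes index i (lowest), matching the profile-merge loop.
    Ties in the Q criterion break on the lowest (i, j) pair.
    """
    n = D.shape[0]
    active = list(range(n))
    d = D.copy()
    order: list[tuple[int, int]] = []
    while len(active) > 2:
        r = len(active)
        sums = d[np.ix_(active, active)].sum(axis=1)
        best = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                q = (r - 2) * d[active[ai], active[aj]] - sums[ai] - sums[aj]
                if best is None or q < best[0] - 1e-12:
                    best = (q, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        order.append((i, j))
        # distance of the joined cluster (kept at slot i) to the rest
        for k in active:
            if k not in (i, j):
                d[i, k] = d[k, i] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        active.remove(j)
    if len(active) == 2:
        order.append((active[0], active[1]))
    return order


def progressive_msa(seqs: Sequence[ProtSequence],
                    matrix: str = DEFAULT_MATRIX,
                    gap_open: float = DEFAULT_GAP_OPEN,
                    gap_extend: float = DEFAULT_GAP_EXTEND,
                    ) -> MultipleAlignment:
    """ClustalW-style progressive alignment.

    Guide order comes from neighbor joining on p-distances of all pairwise
    global alignments; profiles are merged in that order with the same
    affine-gap parameters ("once a gap, always a gap").
    """
    if len(seqs) < 2:
        raise SequenceError("progressive_msa needs at least 2 sequences")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise SequenceError(f"duplicate sequence ID(s) {dup}")
    n = len(seqs)
    if n == 2:
        return pairwise_global_align(seqs[0], seqs[1], matrix, gap_open,
                                     gap_extend)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pa = pairwise_global_align(seqs[i], seqs[j], matrix, gap_open,
                                       gap_extend)
            D[i, j] = D[j, i] = p_distance(pa.rows[0][1], pa.rows[1][1])
    clusters: dict[int, list[tuple[str, str]]] = {
        i: [(s.id, s.residues)] for i, s in enumerate(seqs)}
    for i, j in _nj_merge_order(D):
        clusters[i] = _merge_profiles(clusters[i], clusters[j], matrix,
                                      gap_open, gap_extend)
        del clusters[j]
    (final,) = clusters.values()
    by_id = dict(final)
    return MultipleAlignment([(s.id, by_id[s.id]) for s in seqs])


# ---------------------------------------------------------------------------
# Consensus profiles
# ---------------------------------------------------------------------------

@dataclass
class ConsensusProfile:
    """Per-column consensus of a family alignment.

    ``columns[i]`` maps residue → frequency (over non-gap residues, summing
    to 1); ``majority[i]`` is the argmax (alphabetical tie-break);
    ``alternates[i]`` is the second residue when frequent enough.  RNP spans
    are half-open column intervals into the retained columns.
    """

    columns: list[dict[str, float]]
    majority: str
    alternates: list[Optional[str]]
    rnp2_span: Optional[tuple[int, int]] = None
    rnp1_span: Optional[tuple[int, int]] = None
    source_family: Optional[str] = None
    dropped_columns: list[int] = field(default_factory=list)

    def notation(self, start: int = 0, end: Optional[int] = None) -> str:
        """Consensus string with parenthesised alternates, e.g. ``PNRI(V)FVGG``."""
        end = len(self.majority) if end is None else end
        out = []
        for i in range(start, end):
            out.append(self.majority[i])
            if self.alternates[i]:
                out.append(f"({self.alternates[i]})")
        return "".join(out)

    def rnp2_notation(self) -> str:
        if self.rnp2_span is None:
            raise SequenceError("RNP2 span not set on profile")
        return self.notation(*self.rnp2_span)

    def rnp1_notation(self) -> str:
        if self.rnp1_span is None:
            raise SequenceError("RNP1 span not set on profile")
        return self.notation(*self.rnp1_span)

    def __len__(self) -> int:
        return len(self.majority)

    def to_json(self) -> str:
        return json.dumps({
            "columns": self.columns,
            "majority": self.majority,
            "alternates": self.alternates,
            "rnp2_span": self.rnp2_span,
            "rnp1_span": self.rnp1_span,
            "source_family": self.source_family,
            "dropped_columns": self.dropped_columns,
            "notation": self.notation(),
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ConsensusProfile":
        d = json.loads(text)
        return cls(columns=d["columns"], majority=d["majority"],
                   alternates=d["alternates"],
                   rnp2_span=tuple(d["rnp2_span"]) if d["rnp2_span"] else None,
                   rnp1_span=tuple(d["rnp1_span"]) if d["rnp1_span"] else None,
                   source_family=d["source_family"],
                   dropped_columns=d["dropped_columns"])


def build_consensus(msa: MultipleAlignment, alt_threshold: float = 0.25,
                    majority_ceiling: float = 0.9,
                    max_gap_fraction: float = 0.5,
                    source_family: Optional[str] = None) -> ConsensusProfile:
    """Derive a consensus profile from a family alignment.

    Columns with more than ``max_gap_fraction`` gaps are dropped (recorded in
    ``dropped_columns``).  An alternate residue is emitted when its frequency
    is at least ``alt_threshold`` and the majority frequency is below
    ``majority_ceiling``.
    """
    if len(msa.rows) < 2:
        raise SequenceError("consensus needs an alignment of >= 2 rows")
    nrows = len(msa.rows)
    columns: list[dict[str, float]] = []
    majority: list[str] = []
    alternates: list[Optional[str]] = []
    dropped: list[int] = []
    for i in range(msa.length):
        col = msa.column(i)
        residues = [c for c in col if c != "-"]
        gap_fraction = 1.0 - len(residues) / nrows
        if gap_fraction > max_gap_fraction or not residues:
            dropped.append(i)
            if not residues:
                warnings.warn(f"all-gap column {i} dropped")
            continue
        counts: dict[str, int] = {}
        for c in residues:
            counts[c] = counts.get(c, 0) + 1
        total = len(residues)
        freqs = {c: k / total for c, k in sorted(counts.items())}
        # argmax with alphabetical tie-break
        best = sorted(freqs, key=lambda c: (-freqs[c], c))[0]
        alt = None
        rest = sorted((c for c in freqs if c != best),
                      key=lambda c: (-freqs[c], c))
        if rest and freqs[rest[0]] >= alt_threshold and freqs[best] < majority_ceiling:
            alt = rest[0]
        columns.append(freqs)
        majority.append(best)
        alternates.append(alt)
    return ConsensusProfile(columns=columns, majority="".join(majority),
                            alternates=alternates, source_family=source_family,
                            dropped_columns=dropped)


def locate_rnp_spans(profile: ConsensusProfile, rnp2: str, rnp1: str) -> None:
    """Set RNP spans by locating motif strings in the consensus majority.

    Motifs are located by exact substring search first, then by local
    alignment; RNP2 must precede RNP1 (the RRM layout).
    """
    for name, motif in (("rnp2", rnp2), ("rnp1", rnp1)):
        pos = profile.majority.find(motif)
        if pos >= 0:
            span = (pos, pos + len(motif))
        else:
            _, _, score, (qs, qe), (ts, te) = _align.local_align(
                motif, profile.majority)
            if score <= 0:
                raise SequenceError(f"cannot locate {name.upper()} motif "
                                    f"{motif!r} in consensus")
            span = (ts, te)
        setattr(profile, f"{name}_span", span)
    if profile.rnp2_span[0] >= profile.rnp1_span[0]:
        raise SequenceError("RNP2 must precede RNP1 in the RRM")


# ---------------------------------------------------------------------------
# Family signatures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RnpPattern:
    """A consensus motif with per-position alternate residues.

    Parsed from / rendered to the parenthesised notation ``PNRI(V)FVGG``:
    position 4 allows I or V.
    """

    primary: str
    allowed: tuple[frozenset, ...]

    @classmethod
    def parse(cls, notation: str) -> "RnpPattern":
        primary: list[str] = []
        allowed: list[frozenset] = []
        i = 0
        while i < len(notation):
            c = notation[i]
            if c == "(":
                close = notation.index(")", i)
                alts = notation[i + 1:close]
                if not primary or not alts:
                    raise SequenceError(f"malformed pattern {notation!r}")
                allowed[-1] = allowed[-1] | frozenset(alts)
                i = close + 1
            else:
                primary.append(c)
                allowed.append(frozenset(c))
                i += 1
        if not primary:
            raise SequenceError("empty RNP pattern")
        return cls("".join(primary), tuple(allowed))

    @property
    def notation(self) -> str:
        out = []
        for p, al in zip(self.primary, self.allowed):
            out.append(p)
            extra = sorted(al - {p})
            if extra:
                out.append(f"({''.join(extra)})")
        return "".join(out)

    def __len__(self) -> int:
        return len(self.primary)

    def mismatches(self, residues: str) -> int:
        """Count positions of ``residues`` not matching majority or alternates.

        ``residues`` must have the pattern's length; '-' never matches.
        """
        if len(residues) != len(self):
            raise SequenceError("candidate region length != pattern length")
        return sum(1 for c, al in zip(residues, self.allowed) if c not in al)


@dataclass(frozen=True)
class FamilySignature:
    """Discriminating features of one family (BOULE or DAZL).

    The deletion flag encodes the two-residue deletion that shortens the
    DAZL RRM relative to BOULE; the junction template lists the internal
    exon–intron junctions as codon offsets from the RRM start (canonically
    three for BOULE).
    """

    family: str
    rnp2: RnpPattern
    rnp1: RnpPattern
    deletion_expected: bool
    size_range_kda: tuple[float, float]
    junction_template: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.family not in ("BOULE", "DAZL"):
            raise SequenceError(f"unknown family {self.family!r}")
        if self.family == "BOULE" and self.deletion_expected:
            raise SequenceError("BOULE signature must not expect a deletion")
        if self.family == "DAZL" and not self.deletion_expected:
            raise SequenceError("DAZL signature must expect the 2-aa deletion")


def derive_signature(profile: ConsensusProfile,
                     size_range_kda: tuple[float, float] = (15.0, 45.0),
                     junction_template: Sequence[int] = (),
                     ) -> FamilySignature:
    """Build a family signature from a consensus profile with RNP spans set."""
    if profile.rnp2_span is None or profile.rnp1_span is None:
        raise SequenceError("profile RNP spans must be set before "
                            "deriving a signature")
    if profile.source_family not in ("BOULE", "DAZL"):
        raise SequenceError("profile.source_family must be BOULE or DAZL")
    return FamilySignature(
        family=profile.source_family,
        rnp2=RnpPattern.parse(profile.rnp2_notation()),
        rnp1=RnpPattern.parse(profile.rnp1_notation()),
        deletion_expected=(profile.source_family == "DAZL"),
        size_range_kda=tuple(size_range_kda),
        junction_template=tuple(junction_template),
    )


def merge_consensus(profile_a: ConsensusProfile, profile_b: ConsensusProfile,
                    matrix: str = DEFAULT_MATRIX,
                    gap_open: float = DEFAULT_GAP_OPEN,
                    gap_extend: float = DEFAULT_GAP_EXTEND,
                    alt_threshold: float = 0.25) -> ConsensusProfile:
    """Merge two group consensus sequences by pairwise global alignment.

    This is the step that combines, e.g., an insect and a mammalian family
    consensus into a single cross-group consensus; the merged length is the
    number of alignment columns retained (gap-free here, since majority
    strings have no gaps and a global alignment keeps every column).
    """
    a = ProtSequence("A", profile_a.majority)
    b = ProtSequence("B", profile_b.majority)
    pa = pairwise_global_align(a, b, matrix, gap_open, gap_extend)
    return build_consensus(pa, alt_threshold=alt_threshold,
                           max_gap_fraction=0.51)
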