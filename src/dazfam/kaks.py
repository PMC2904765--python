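"""Pairwise Ka/Ks estimation (Nei–Gojobori 1986 with Jukes–Cantor correction).

The estimator counts fractional synonymous/nonsynonymous sites per codon by
enumerating the nine single-nucleotide neighbors, averages difference counts
over all minimal mutational pathways between codon pairs (pathways through
stop codons excluded when a stop-free alternative exists), converts the
proportions with the Jukes–Cantor multiple-hit correction
d = -(3/4) ln(1 - 4p/3), and reports Ka/Ks together with the selection-regime
call: > 1 positive selection, < 0.1 purifying, otherwise unresolved.

Mutations creating stop codons are counted as nonsynonymous in the site
totals, so every codon contributes 3 sites split between S and N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from typing import Optional

from Bio.Data import CodonTable

from .msa import MultipleAlignment
from .seq import NucSequence, SequenceError, translate

_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(_TABLE.forward_table))  # 61 codons
_NUC = "ACGT"

PURIFYING_THRESHOLD = 0.1
POSITIVE_THRESHOLD = 1.0


def _aa(codon: str) -> str:
    if codon in STOP_CODONS:
        return "*"
    return _TABLE.forward_table[codon]


class KaKsError(ValueError):
    pass


@dataclass(frozen=True)
class KaKsResult:
    pair: tuple[str, str]
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float
    Ka: float
    ratio: Optional[float]      # None for the 0/0 case
    ratio_note: str             # "", "0/0", or "inf"
    codons_compared: int

    @property
    def ratio_value(self) -> float:
        """Numeric ratio with the 0/0 sentinel reported as 0."""
        return 0.0 if self.ratio is None else self.ratio


@dataclass(frozen=True)
class SelectionCall:
    pair: tuple[str, str]
    ratio: Optional[float]
    regime: str  # purifying | unresolved | positive

    @classmethod
    def from_result(cls, res: KaKsResult) -> "SelectionCall":
        r = res.ratio_value
        if r > POSITIVE_THRESHOLD:
            regime = "positive"
        elif r < PURIFYING_THRESHOLD:
            regime = "purifying"
        else:
            regime = "unresolved"
        return cls(res.pair, res.ratio, regime)


# ---------------------------------------------------------------------------
# Codon alignment threading
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    """Rows of (seq_id, aligned codon string); gaps are '---' triplets."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.rows:
            raise KaKsError("codon alignment has no rows")
        lengths = {len(r) for _, r in self.rows}
        if len(lengths) != 1 or next(iter(lengths)) % 3 != 0:
            raise KaKsError("codon alignment rows must share a length "
                            "divisible by 3")

    @property
    def n_codons(self) -> int:
        return len(self.rows[0][1]) // 3

    def codon(self, row: int, i: int) -> str:
        return self.rows[row][1][3 * i: 3 * i + 3]


def thread_codons(protein_msa: MultipleAlignment,
                  cds_by_id: dict[str, NucSequence]) -> CodonAlignment:
    """Expand a protein alignment to codons using each row's CDS.

    Each CDS must translate exactly to its de-gapped protein row (a trailing
    stop codon is stripped); protein gaps become '---'.
    """
    rows = []
    for sid, prow in protein_msa.rows:
        if sid not in cds_by_id:
            raise KaKsError(f"no CDS supplied for row {sid!r}")
        cds = cds_by_id[sid].residues
        protein = prow.replace("-", "")
        if len(cds) == 3 * len(protein) + 3 and cds[-3:] in STOP_CODONS:
            cds = cds[:-3]
        if len(cds) != 3 * len(protein):
            raise KaKsError(
                f"CDS length for {sid!r} ({len(cds)}) does not match "
                f"3 x protein length ({3 * len(protein)})")
        translated = translate(NucSequence(sid, cds)).residues
        for pos, (have, want) in enumerate(zip(translated, protein)):
            if have == "*":
                raise KaKsError(f"internal stop codon in CDS {sid!r} at "
                                f"codon {pos}")
            if have != want:
                raise KaKsError(
                    f"translation mismatch for {sid!r} at residue {pos}: "
                    f"CDS gives {have!r}, alignment row has {want!r}")
        out = []
        k = 0
        for c in prow:
            if c == "-":
                out.append("---")
            else:
                out.append(cds[3 * k: 3 * k + 3])
                k += 1
        rows.append((sid, "".join(out)))
    return CodonAlignment(rows)


# ---------------------------------------------------------------------------
# NG86 counting
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def syn_sites(codon: str) -> float:
    """Fractional synonymous sites of one codon (stop neighbors count as N)."""
    if codon in STOP_CODONS:
        raise KaKsError(f"stop codon {codon} has no site decomposition")
    if len(codon) != 3 or any(c not in _NUC for c in codon):
        raise KaKsError(f"invalid codon {codon!r}")
    aa = _aa(codon)
    s = 0
    for pos in range(3):
        for nt in _NUC:
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1:]
            if mutant not in STOP_CODONS and _aa(mutant) == aa:
                s += 1
    return s / 3.0


@lru_cache(maxsize=None)
def _pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (Sd, Nd) between two sense codons."""
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff):
        current = codon_a
        steps = []
        hits_stop = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            steps.append((current, nxt))
            if nxt in STOP_CODONS:
                hits_stop = True
            current = nxt
        paths.append((hits_stop, steps))
    usable = [steps for hits, steps in paths if not hits]
    counting_stops_as_nonsyn = False
    if not usable:
        usable = [steps for _, steps in paths]
        counting_stops_as_nonsyn = True
    sd = nd = 0.0
    for steps in usable:
        for c1, c2 in steps:
            if c1 in STOP_CODONS or c2 in STOP_CODONS:
                nd += 1  # only reachable when every pathway hits a stop
            elif _aa(c1) == _aa(c2):
                sd += 1
            else:
                nd += 1
    k = len(usable)
    return sd / k, nd / k


def ng_counts(codon_a: str, codon_b: str) -> tuple[float, float, float, float]:
    """NG86 per-codon-pair counts.

    Returns (s_sites_a, s_sites_b, Sd, Nd): the fractional synonymous site
    counts of each codon and the pathway-averaged synonymous/nonsynonymous
    difference counts (Sd + Nd equals the number of differing positions).
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    for c in (codon_a, codon_b):
        if "-" in c:
            raise KaKsError("gap codon passed to ng_counts")
        if c in STOP_CODONS:
            raise KaKsError(f"stop codon {c} passed to ng_counts")
    sa, sb = syn_sites(codon_a), syn_sites(codon_b)
    sd, nd = _pathway_counts(codon_a, codon_b)
    return sa, sb, sd, nd


def jukes_cantor(p: float) -> float:
    if p < 0:
        raise KaKsError("negative proportion")
    if p >= 0.75:
        raise KaKsError(f"saturated: proportion {p:.4f} >= 3/4, "
                        "Jukes-Cantor correction undefined")
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def kaks_pair(row_a: tuple[str, str], row_b: tuple[str, str]) -> KaKsResult:
    """NG86 Ka/Ks for two rows of a codon alignment.

    Codon columns with a gap in either row are excluded (pairwise deletion).
    """
    (id_a, seq_a), (id_b, seq_b) = row_a, row_b
    if len(seq_a) != len(seq_b) or len(seq_a) % 3:
        raise KaKsError("rows must be aligned codon strings of equal length")
    s_a = s_b = sd = nd = 0.0
    codons = 0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i:i + 3], seq_b[i:i + 3]
        if "-" in ca or "-" in cb:
            continue
        xa, xb, d_s, d_n = ng_counts(ca, cb)
        s_a += xa
        s_b += xb
        sd += d_s
        nd += d_n
        codons += 1
    if codons == 0:
        raise KaKsError(f"no shared gap-free codon columns for "
                        f"({id_a}, {id_b})")
    S = 0.5 * (s_a + s_b)
    N = 3.0 * codons - S
    pS = sd / S if S > 0 else 0.0
    pN = nd / N if N > 0 else 0.0
    Ks = jukes_cantor(pS)
    Ka = jukes_cantor(pN)
    if Ks == 0.0 and Ka == 0.0:
        ratio, note = None, "0/0"
    elif Ks == 0.0:
        ratio, note = math.inf, "inf"
    else:
        ratio, note = Ka / Ks, ""
    return KaKsResult(pair=(id_a, id_b), S_sites=S, N_sites=N, Sd=sd, Nd=nd,
                      pS=pS, pN=pN, Ks=Ks, Ka=Ka, ratio=ratio,
                      ratio_note=note, codons_compared=codons)


def pairwise_kaks_matrix(ca: CodonAlignment):
    """All unordered pairwise NG86 comparisons of a codon alignment.

    Returns (results, calls, errors): per-pair KaKsResult and SelectionCall
    lists plus a list of (pair, message) for pairs that failed (saturation,
    no shared columns) without aborting the rest of the matrix.
    """
    if len(ca.rows) < 2:
        raise KaKsError("need >= 2 rows")
    results: list[KaKsResult] = []
    calls: list[SelectionCall] = []
    errors: list[tuple[tuple[str, str], str]] = []
    for i in range(len(ca.rows)):
        for j in range(i + 1, len(ca.rows)):
            pair = (ca.rows[i][0], ca.rows[j][0])
            try:
                res = kaks_pair(ca.rows[i], ca.rows[j])
            except KaKsError as exc:
                errors.append((pair, str(exc)))
                continue
            results.append(res)
            calls.append(SelectionCall.from_result(res))
    return results, calls, errors


def max_ratio(results: list[KaKsResult]) -> float:
    """Maximum defined pairwise ratio (0/0 sentinels count as 0)."""
    if not results:
        raise KaKsError("no results")
    return max(r.ratio_value for r in results)
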