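"""Affine-gap pairwise alignment engine (Gotoh dynamic programming).

Both the progressive aligner and the translated-search stage sit on this
module.  Conventions, fixed for determinism:

* a gap of length L costs ``gap_open + gap_extend * L`` (ClustalW-style GOP
  charged once at opening plus GEP per gapped position);
* traceback tie-break prefers diagonal, then up (gap in ``b``), then left
  (gap in ``a``);
* the local-alignment start cell is the maximum-score cell that comes first
  in row-major order.

The DP works on an arbitrary pre-computed score matrix, so the same engine
aligns residue strings (scores looked up in a substitution matrix) and MSA
profiles (expected column–column scores).  Recurrences are vectorised along
the first axis; the within-column affine scan uses a prefix-max identity
folded into ``np.maximum.accumulate`` so each column is O(m) in numpy.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

_EPS = 1e-9
NEG = -1e30


@lru_cache(maxsize=8)
def load_matrix(name: str) -> tuple[str, np.ndarray]:
    """Return (alphabet, matrix) for a named substitution matrix."""
    try:
        m = substitution_matrices.load(name)
    except FileNotFoundError as exc:
        raise ValueError(f"unknown substitution matrix {name!r}") from exc
    return str(m.alphabet), np.asarray(m, dtype=float)


def encode(seq: str, alphabet: str) -> np.ndarray:
    idx = np.full(128, -1, dtype=np.int64)
    for i, c in enumerate(alphabet):
        idx[ord(c)] = i
    codes = idx[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        bad = sorted({c for c in seq if c not in alphabet})
        raise ValueError(f"residue(s) {bad} not in substitution-matrix alphabet")
    return codes


def residue_scores(a: str, b: str, matrix: str) -> np.ndarray:
    alphabet, sub = load_matrix(matrix)
    return sub[encode(a, alphabet)[:, None], encode(b, alphabet)[None, :]]


def _fill(scores: np.ndarray, gap_open: float, gap_extend: float, local: bool):
    """Fill H (best), E (gap in a / left) and F (gap in b / up) matrices."""
    m, n = scores.shape
    go, ge = float(gap_open), float(gap_extend)
    first = go + ge  # cost of the first gapped position
    H = np.full((m + 1, n + 1), NEG)
    E = np.full((m + 1, n + 1), NEG)
    F = np.full((m + 1, n + 1), NEG)
    H[0, 0] = 0.0
    if local:
        H[:, 0] = 0.0
        H[0, :] = 0.0
    else:
        H[1:, 0] = -(go + ge * np.arange(1, m + 1))
        H[0, 1:] = -(go + ge * np.arange(1, n + 1))
        F[1:, 0] = H[1:, 0]
        E[0, 1:] = H[0, 1:]

    i_idx = np.arange(1, m + 1)
    for j in range(1, n + 1):
        E[1:, j] = np.maximum(H[1:, j - 1] - first, E[1:, j - 1] - ge)
        diag = H[:-1, j - 1] + scores[:, j - 1]
        H0 = np.maximum(diag, E[1:, j])
        if local:
            H0 = np.maximum(H0, 0.0)
        # F via a prefix-max scan.  With A[i] = max_{k<i}(Hcol[k] + k*ge),
        # F[i] = A[i] - go - i*ge, and Hcol[i] = max(H0[i], F[i]).  Because
        # F[i] + i*ge = A[i] - go <= A[i], the recursion
        # A[i+1] = max(A[i], Hcol[i] + i*ge) collapses to an accumulate over
        # H0 alone (plus the boundary row 0), so no Python inner loop.
        cand = np.concatenate(([H[0, j]], H0 + i_idx * ge))
        A = np.maximum.accumulate(cand)[:-1]  # A[i] for i = 1..m
        F[1:, j] = A - first - (i_idx - 1) * ge
        H[1:, j] = np.maximum(H0, F[1:, j])
    return H, E, F


def _traceback(H, E, F, scores, gap_open, gap_extend, local,
               start=None):
    """Walk back from ``start`` (local) or the corner (global).

    Returns (ops, (start_i, start_j)) where ops is a list over the alignment
    5'→3' of 'D' (diagonal), 'U' (consume a / gap in b), 'L' (consume b /
    gap in a).
    """
    go, ge = float(gap_open), float(gap_extend)
    first = go + ge
    m, n = scores.shape
    i, j = (start if local else (m, n))
    ops: list[str] = []
    state = "H"
    while True:
        if local and state == "H" and H[i, j] <= _EPS:
            break
        if not local and i == 0 and j == 0:
            break
        if state == "H":
            if not local and i == 0:
                state = "E"
                continue
            if not local and j == 0:
                state = "F"
                continue
            diag = H[i - 1, j - 1] + scores[i - 1, j - 1] if i > 0 and j > 0 else NEG
            if i > 0 and j > 0 and abs(H[i, j] - diag) < _EPS:
                ops.append("D")
                i, j = i - 1, j - 1
            elif i > 0 and abs(H[i, j] - F[i, j]) < _EPS:
                state = "F"
            elif j > 0 and abs(H[i, j] - E[i, j]) < _EPS:
                state = "E"
            else:  # numerical safety net; should not happen
                raise AssertionError("traceback failed")
        elif state == "F":  # gap in b, consume a (move up)
            ops.append("U")
            opened = abs(F[i, j] - (H[i - 1, j] - first)) < _EPS
            extended = i >= 2 and abs(F[i, j] - (F[i - 1, j] - ge)) < _EPS
            if not (extended and not opened):
                state = "H"
            i -= 1
        else:  # "E": gap in a, consume b (move left)
            ops.append("L")
            opened = abs(E[i, j] - (H[i, j - 1] - first)) < _EPS
            extended = j >= 2 and abs(E[i, j] - (E[i, j - 1] - ge)) < _EPS
            if not (extended and not opened):
                state = "H"
            j -= 1
    ops.reverse()
    return ops, (i, j)


def align_path(scores: np.ndarray, gap_open: float, gap_extend: float,
               local: bool):
    """Optimal alignment over a score matrix.

    Returns (ops, score, (a_start, a_end), (b_start, b_end)); for a local
    alignment with no positive-scoring cell, ops is empty and score 0.
    """
    H, E, F = _fill(scores, gap_open, gap_extend, local)
    m, n = scores.shape
    if local:
        flat = int(np.argmax(H))
        ei, ej = divmod(flat, H.shape[1])
        score = float(H[ei, ej])
        if score <= _EPS:
            return [], 0.0, (0, 0), (0, 0)
        ops, (si, sj) = _traceback(H, E, F, scores, gap_open, gap_extend,
                                   True, start=(ei, ej))
        return ops, score, (si, ei), (sj, ej)
    ops, _ = _traceback(H, E, F, scores, gap_open, gap_extend, False)
    return ops, float(H[m, n]), (0, m), (0, n)


def _ops_to_rows(a: str, b: str, ops, a_off: int = 0, b_off: int = 0):
    ra, rb = [], []
    i, j = a_off, b_off
    for op in ops:
        if op == "D":
            ra.append(a[i]); rb.append(b[j]); i += 1; j += 1
        elif op == "U":
            ra.append(a[i]); rb.append("-"); i += 1
        else:
            ra.append("-"); rb.append(b[j]); j += 1
    return "".join(ra), "".join(rb)


def global_align(a: str, b: str, matrix: str = "BLOSUM62",
                 gap_open: float = 10.0, gap_extend: float = 0.2):
    """Needleman–Wunsch with affine gaps; returns (row_a, row_b, score)."""
    if not a or not b:
        raise ValueError("cannot globally align an empty sequence")
    ops, score, _, _ = align_path(residue_scores(a, b, matrix),
                                  gap_open, gap_extend, local=False)
    ra, rb = _ops_to_rows(a, b, ops)
    return ra, rb, score


def local_align(a: str, b: str, matrix: str = "BLOSUM62",
                gap_open: float = 10.0, gap_extend: float = 0.2):
    """Smith–Waterman with affine gaps.

    Returns (row_a, row_b, score, (a_start, a_end), (b_start, b_end)) with
    0-based half-open coordinates into the inputs; score 0 means no
    positive-scoring local alignment (empty rows).
    """
    if not a or not b:
        raise ValueError("cannot locally align an empty sequence")
    ops, score, (as_, ae), (bs, be) = align_path(
        residue_scores(a, b, matrix), gap_open, gap_extend, local=True)
    ra, rb = _ops_to_rows(a, b, ops, as_, bs)
    return ra, rb, score, (as_, ae), (bs, be)


def score_alignment(aligned_a: str, aligned_b: str, matrix: str = "BLOSUM62",
                    gap_open: float = 10.0, gap_extend: float = 0.2) -> float:
    """Re-score a pair of aligned rows under the declared gap convention."""
    alphabet, sub = load_matrix(matrix)
    total = 0.0
    in_gap_a = in_gap_b = False
    for ca, cb in zip(aligned_a, aligned_b):
        if ca == "-" and cb == "-":
            continue
        if ca == "-":
            total -= gap_extend + (0.0 if in_gap_a else gap_open)
            in_gap_a, in_gap_b = True, False
        elif cb == "-":
            total -= gap_extend + (0.0 if in_gap_b else gap_open)
            in_gap_b, in_gap_a = True, False
        else:
            total += sub[alphabet.index(ca), alphabet.index(cb)]
            in_gap_a = in_gap_b = False
    return total
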