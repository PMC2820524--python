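"""Affine-gap dynamic-programming alignment kernels (numba-compiled).

Gap convention throughout the package: a gap of length L scores
``gap_open + L * gap_extend`` (both passed as negative numbers), i.e. the
first gapped residue costs ``gap_open + gap_extend``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -1.0e30

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def encode(seq: str) -> np.ndarray:
    """Encode DNA to int8; any non-ACGT character becomes 4 (never matches)."""
    return np.array([_BASE_CODE.get(c, 4) for c in seq.upper()], dtype=np.int8)


@njit(cache=True)
def _sw_fill(a, b, match, mismatch, gap_open, gap_extend, H, E, F, ptr):  # pragma: no cover
    n, m = len(a), len(b)
    best = 0.0
    bi, bj = 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = max(E[i, j - 1] + gap_extend, H[i, j - 1] + gap_open + gap_extend)
            f = max(F[i - 1, j] + gap_extend, H[i - 1, j] + gap_open + gap_extend)
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] < 4) else mismatch
            d = H[i - 1, j - 1] + s
            h = d
            p = 1  # diagonal
            if e > h:
                h = e
                p = 2  # gap in a (consume b)
            if f > h:
                h = f
                p = 3  # gap in b (consume a)
            if h < 0.0:
                h = 0.0
                p = 0
            H[i, j] = h
            E[i, j] = e
            F[i, j] = f
            ptr[i, j] = p
            if h > best:
                best = h
                bi, bj = i, j
    return best, bi, bj


def smith_waterman(
    a: np.ndarray,
    b: np.ndarray,
    match: float = 1.0,
    mismatch: float = -2.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
):
    """Optimal local alignment of encoded sequences.

    Returns ``(score, a_start, a_end, b_start, b_end, cigar)`` with half-open
    coordinates, or ``None`` if the best score is 0.  CIGAR operations are
    M (column with both residues), D (gap in b / residue of a only),
    I (gap in a / residue of b only), from a's perspective.
    """
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1), dtype=np.float32)
    E = np.full((n + 1, m + 1), NEG_INF, dtype=np.float32)
    F = np.full((n + 1, m + 1), NEG_INF, dtype=np.float32)
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)
    best, bi, bj = _sw_fill(a, b, match, mismatch, gap_open, gap_extend, H, E, F, ptr)
    if best <= 0.0:
        return None
    ops = []
    i, j = bi, bj
    while i > 0 and j > 0 and ptr[i, j] != 0:
        p = ptr[i, j]
        if p == 1:
            ops.append("M")
            i -= 1
            j -= 1
        elif p == 2:
            # gap run in a: walk back along E
            while j > 0 and E[i, j] == E[i, j - 1] + gap_extend and H[i, j - 1] + gap_open + gap_extend < E[i, j]:
                ops.append("I")
                j -= 1
            ops.append("I")
            j -= 1
        else:
            while i > 0 and F[i, j] == F[i - 1, j] + gap_extend and H[i - 1, j] + gap_open + gap_extend < F[i, j]:
                ops.append("D")
                i -= 1
            ops.append("D")
            i -= 1
    ops.reverse()
    cigar = _run_length(ops)
    return best, i, bi, j, bj, cigar


def _run_length(ops: list[str]) -> str:
    out = []
    k = 0
    while k < len(ops):
        j = k
        while j < len(ops) and ops[j] == ops[k]:
            j += 1
        out.append(f"{j - k}{ops[k]}")
        k = j
    return "".join(out)


@njit(cache=True)
def _nw_score(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n, m = len(a), len(b)
    H = np.empty((2, m + 1))
    E = np.empty((2, m + 1))
    F = np.empty((2, m + 1))
    H[0, 0] = 0.0
    E[0, 0] = NEG_INF
    F[0, 0] = NEG_INF
    for j in range(1, m + 1):
        E[0, j] = gap_open + j * gap_extend
        H[0, j] = E[0, j]
        F[0, j] = NEG_INF
    for i in range(1, n + 1):
        cur, prev = i % 2, (i - 1) % 2
        F[cur, 0] = gap_open + i * gap_extend
        H[cur, 0] = F[cur, 0]
        E[cur, 0] = NEG_INF
        for j in range(1, m + 1):
            e = max(E[cur, j - 1] + gap_extend, H[cur, j - 1] + gap_open + gap_extend)
            f = max(F[prev, j] + gap_extend, H[prev, j] + gap_open + gap_extend)
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] < 4) else mismatch
            h = max(H[prev, j - 1] + s, e, f)
            H[cur, j] = h
            E[cur, j] = e
            F[cur, j] = f
    return H[n % 2, m]


def needleman_wunsch_score(
    a: np.ndarray,
    b: np.ndarray,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -4.0,
    gap_extend: float = -0.5,
) -> float:
    """Global affine-gap alignment score (linear space, score only)."""
    return float(_nw_score(a, b, match, mismatch, gap_open, gap_extend))
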