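"""Affine-gap local alignment kernels and k-mer seeding.

Two Smith-Waterman implementations share one scoring and tie-breaking
contract (match +1, mismatch -1, a gap of length L costs open + L*extend
with open -5, extend -1; local alignments never drop below score zero):

``sw_full``
    Exhaustive dynamic programming over the complete (m+1) x (n+1) matrix.
    Quadratic memory; the reference implementation used as the ``exact``
    backend and as the oracle in tests.

``sw_banded``
    The same recurrences restricted to a diagonal band ``dlo <= j - i <= dhi``
    located from exact k-mer seed matches. Linear-ish memory in the band
    width. Equal to ``sw_full`` whenever the optimal path stays inside the
    band, which holds for the high-identity fragment/subject pairs this
    package aligns (chance seeds on unrelated pairs produce alignments that
    the downstream retention rule rejects).

Tie-breaking, identical in both kernels: a cell's score prefers the diagonal
move, then a gap consuming a subject base, then a gap consuming a query
base, then local termination; gap-run states prefer opening over extending;
the reported optimum is the first best-scoring cell in row-major scan order.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from numpy.lib.stride_tricks import sliding_window_view

NEG = -(1 << 28)

_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _LUT[ord(_c)] = _i
    _LUT[ord(_c.lower())] = _i

_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A,C,G,T -> 0..3, other -> 4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _LUT[raw]


def decode(arr: np.ndarray) -> str:
    """Inverse of :func:`encode` (code 4 renders as ``N``)."""
    return _BASES[arr].tobytes().decode("ascii")


def kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Pack every length-``k`` window of an encoded sequence into a uint64.

    Windows containing an ambiguous base (code 4) still produce a code; on
    the A/C/G/T alphabet codes are injective for k <= 31.
    """
    if arr.shape[0] < k:
        return np.empty(0, dtype=np.uint64)
    win = sliding_window_view(arr, k).astype(np.uint64)
    pows = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    return (win * pows).sum(axis=1)


@njit(cache=True)
def sw_full(q, s, match, mismatch, gap_open, gap_extend):
    """Exhaustive affine local alignment.

    Returns ``(score, matches, align_len, q_start, q_end, s_start, s_end)``
    with half-open 0-based coordinate spans; all zeros when no positive-score
    alignment exists.
    """
    m = q.shape[0]
    n = s.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    tbH = np.zeros((m + 1, n + 1), dtype=np.uint8)  # 0 stop, 1 diag, 2 E, 3 F
    tbE = np.zeros((m + 1, n + 1), dtype=np.uint8)  # 1 opened from H
    tbF = np.zeros((m + 1, n + 1), dtype=np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            e_open = H[i, j - 1] + gap_open + gap_extend
            e_ext = E[i, j - 1] + gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
                tbE[i, j] = 1
            else:
                E[i, j] = e_ext
            f_open = H[i - 1, j] + gap_open + gap_extend
            f_ext = F[i - 1, j] + gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
                tbF[i, j] = 1
            else:
                F[i, j] = f_ext
            if qi == s[j - 1]:
                d = H[i - 1, j - 1] + match
            else:
                d = H[i - 1, j - 1] + mismatch
            h = 0
            t = 0
            if d > h:
                h = d
                t = 1
            if E[i, j] > h:
                h = E[i, j]
                t = 2
            if F[i, j] > h:
                h = F[i, j]
                t = 3
            H[i, j] = h
            tbH[i, j] = t
            if h > best:
                best = h
                bi = i
                bj = j
    if best <= 0:
        return 0, 0, 0, 0, 0, 0, 0
    matches = 0
    alen = 0
    i = bi
    j = bj
    while tbH[i, j] != 0:
        t = tbH[i, j]
        if t == 1:
            alen += 1
            if q[i - 1] == s[j - 1]:
                matches += 1
            i -= 1
            j -= 1
        elif t == 2:
            while True:
                alen += 1
                opened = tbE[i, j]
                j -= 1
                if opened == 1:
                    break
        else:
            while True:
                alen += 1
                opened = tbF[i, j]
                i -= 1
                if opened == 1:
                    break
    return best, matches, alen, i, bi, j, bj


@njit(cache=True)
def sw_banded(q, s, dlo, dhi, match, mismatch, gap_open, gap_extend):
    """Banded affine local alignment over diagonals ``dlo <= j - i <= dhi``.

    Same return convention, scoring and tie-breaking as :func:`sw_full`.
    Cells outside the band are unavailable (they can neither start nor relay
    an alignment).
    """
    m = q.shape[0]
    n = s.shape[0]
    if dlo < -m:
        dlo = -m
    if dhi > n:
        dhi = n
    if dhi < dlo:
        return 0, 0, 0, 0, 0, 0, 0
    W = dhi - dlo + 1
    # band column k = j - i - dlo + 1 in [1, W]; columns 0 and W+1 are NEG pads
    H = np.full((m + 1, W + 2), NEG, dtype=np.int32)
    E = np.full((m + 1, W + 2), NEG, dtype=np.int32)
    F = np.full((m + 1, W + 2), NEG, dtype=np.int32)
    tbH = np.zeros((m + 1, W + 2), dtype=np.uint8)
    tbE = np.zeros((m + 1, W + 2), dtype=np.uint8)
    tbF = np.zeros((m + 1, W + 2), dtype=np.uint8)
    for i in range(0, m + 1):
        jlo = i + dlo
        if jlo < 0:
            jlo = 0
        jhi = i + dhi
        if jhi > n:
            jhi = n
        for j in range(jlo, jhi + 1):
            k = j - i - dlo + 1
            if i == 0 or j == 0:
                H[i, k] = 0
    best = 0
    bi = 0
    bk = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        jlo = i + dlo
        if jlo < 1:
            jlo = 1
        jhi = i + dhi
        if jhi > n:
            jhi = n
        for j in range(jlo, jhi + 1):
            k = j - i - dlo + 1
            # (i, j-1) is band column k-1; (i-1, j) is k+1; (i-1, j-1) is k
            e_open = H[i, k - 1] + gap_open + gap_extend
            e_ext = E[i, k - 1] + gap_extend
            if e_open >= e_ext:
                E[i, k] = e_open
                tbE[i, k] = 1
            else:
                E[i, k] = e_ext
            f_open = H[i - 1, k + 1] + gap_open + gap_extend
            f_ext = F[i - 1, k + 1] + gap_extend
            if f_open >= f_ext:
                F[i, k] = f_open
                tbF[i, k] = 1
            else:
                F[i, k] = f_ext
            if qi == s[j - 1]:
                d = H[i - 1, k] + match
            else:
                d = H[i - 1, k] + mismatch
            h = 0
            t = 0
            if d > h:
                h = d
                t = 1
            if E[i, k] > h:
                h = E[i, k]
                t = 2
            if F[i, k] > h:
                h = F[i, k]
                t = 3
            H[i, k] = h
            tbH[i, k] = t
            if h > best:
                best = h
                bi = i
                bk = k
    if best <= 0:
        return 0, 0, 0, 0, 0, 0, 0
    matches = 0
    alen = 0
    i = bi
    k = bk
    while tbH[i, k] != 0:
        t = tbH[i, k]
        if t == 1:
            alen += 1
            j = i + k + dlo - 1
            if q[i - 1] == s[j - 1]:
                matches += 1
            i -= 1
            # k unchanged on a diagonal move
        elif t == 2:
            while True:
                alen += 1
                opened = tbE[i, k]
                k -= 1
                if opened == 1:
                    break
        else:
            while True:
                alen += 1
                opened = tbF[i, k]
                i -= 1
                k += 1
                if opened == 1:
                    break
    qs = i
    ss = i + k + dlo - 1
    bj = bi + bk + dlo - 1
    return best, matches, alen, qs, bi, ss, bj
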