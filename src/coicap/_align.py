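"""Numba-accelerated pairwise alignment kernels.

Two dynamic-programming kernels back the public modules:

* a free-end-gap (semi-global) Needleman-Wunsch with linear gap costs, used
  for barcode-vs-barcode and probe-vs-barcode distance alignments, and
* a Gotoh affine-gap Smith-Waterman, used for read-vs-reference search.

Sequences are encoded as int8 arrays with A,C,G,T -> 0..3 and every other
IUPAC code -> 4.  Code 4 never scores as a match.  Both kernels implement the
deterministic tie-breaks documented on their public wrappers.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# byte -> code lookup; ambiguity codes and anything unexpected collapse to 4
_CODE_TABLE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_TABLE[_b] = _i
    _CODE_TABLE[_b + 32] = _i  # lower case

GAP = -1  # sentinel in alignment index arrays


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string into the int8 alphabet used by the kernels."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE_TABLE[raw]


# pointer codes shared by both kernels
_DIAG, _LEFT, _UP, _STOP = 0, 1, 2, 3


@njit(cache=True)
def _nw_fill(a, b, match, mismatch, gap):  # pragma: no cover - numba
    n, m = a.shape[0], b.shape[0]
    score = np.zeros((n + 1, m + 1), dtype=np.int64)
    ptr = np.full((n + 1, m + 1), _STOP, dtype=np.uint8)
    # free leading end gaps: first row/column stay at 0
    for i in range(1, n + 1):
        ptr[i, 0] = _UP
    for j in range(1, m + 1):
        ptr[0, j] = _LEFT
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if (ai == b[j - 1] and ai < 4) else mismatch
            d = score[i - 1, j - 1] + s
            l = score[i, j - 1] + gap  # gap in a, consumes b
            u = score[i - 1, j] + gap  # gap in b, consumes a
            # tie-break: substitution over gap, then gap-in-a over gap-in-b
            best = d
            p = _DIAG
            if l > best:
                best = l
                p = _LEFT
            if u > best:
                best = u
                p = _UP
            score[i, j] = best
            ptr[i, j] = p
    # free trailing end gaps: best cell on the last row or last column;
    # scanned column-first so ties resolve toward the bottom-right corner
    bi, bj = n, m
    best = score[n, m]
    for i in range(n + 1):
        if score[i, m] > best:
            best = score[i, m]
            bi, bj = i, m
    for j in range(m + 1):
        if score[n, j] > best:
            best = score[n, j]
            bi, bj = n, j
    return score, ptr, best, bi, bj


@njit(cache=True)
def _nw_traceback(ptr, n, m, bi, bj):  # pragma: no cover - numba
    # columns emitted right-to-left, then reversed by the caller
    cap = n + m
    a_idx = np.empty(cap, dtype=np.int32)
    b_idx = np.empty(cap, dtype=np.int32)
    k = 0
    # trailing overhang outside the scored path
    for j in range(m - 1, bj - 1, -1):
        a_idx[k] = GAP
        b_idx[k] = j
        k += 1
    for i in range(n - 1, bi - 1, -1):
        a_idx[k] = i
        b_idx[k] = GAP
        k += 1
    i, j = bi, bj
    while i > 0 or j > 0:
        p = ptr[i, j]
        if p == _DIAG:
            i -= 1
            j -= 1
            a_idx[k] = i
            b_idx[k] = j
        elif p == _LEFT:
            j -= 1
            a_idx[k] = GAP
            b_idx[k] = j
        else:
            i -= 1
            a_idx[k] = i
            b_idx[k] = GAP
        k += 1
    return a_idx[:k][::-1].copy(), b_idx[:k][::-1].copy()


def nw_align(a: np.ndarray, b: np.ndarray, match: int, mismatch: int, gap: int):
    """Global alignment with free end gaps.

    Returns ``(score, a_idx, b_idx)`` where the index arrays give, per
    alignment column, the 0-based position in each sequence or ``GAP``.
    """
    _, ptr, best, bi, bj = _nw_fill(a, b, match, mismatch, gap)
    a_idx, b_idx = _nw_traceback(ptr, a.shape[0], b.shape[0], bi, bj)
    return int(best), a_idx, b_idx


@njit(cache=True)
def _sw_fill(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    """Gotoh affine local alignment.

    A gap of length k costs gap_open + k * gap_extend (positive costs).
    H-state tie-break: diagonal, then up (gap in b), then left (gap in a).
    The best cell is the first strictly-greater score scanning rows then
    columns, i.e. ties resolve to the smallest read end, then the smallest
    subject end.
    """
    n, m = a.shape[0], b.shape[0]
    NEG = np.int64(-10**12)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap in a (left)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap in b (up)
    ph = np.full((n + 1, m + 1), _STOP, dtype=np.uint8)
    pe = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 1 = extend, 0 = open
    pf = np.zeros((n + 1, m + 1), dtype=np.uint8)
    go = gap_open + gap_extend
    best = np.int64(0)
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            e_open = H[i, j - 1] - go
            e_ext = E[i, j - 1] - gap_extend
            if e_ext > e_open:
                E[i, j] = e_ext
                pe[i, j] = 1
            else:
                E[i, j] = e_open
                pe[i, j] = 0
            f_open = H[i - 1, j] - go
            f_ext = F[i - 1, j] - gap_extend
            if f_ext > f_open:
                F[i, j] = f_ext
                pf[i, j] = 1
            else:
                F[i, j] = f_open
                pf[i, j] = 0
            s = match if (ai == b[j - 1] and ai < 4) else mismatch
            d = H[i - 1, j - 1] + s
            h = np.int64(0)
            p = _STOP
            if d > h:
                h = d
                p = _DIAG
            if F[i, j] > h:
                h = F[i, j]
                p = _UP
            if E[i, j] > h:
                h = E[i, j]
                p = _LEFT
            H[i, j] = h
            ph[i, j] = p
            if h > best:
                best = h
                bi, bj = i, j
    return H, E, F, ph, pe, pf, best, bi, bj


@njit(cache=True)
def _sw_traceback(ph, pe, pf, bi, bj):  # pragma: no cover - numba
    cap = bi + bj
    a_idx = np.empty(cap, dtype=np.int32)
    b_idx = np.empty(cap, dtype=np.int32)
    k = 0
    i, j = bi, bj
    state = 0  # 0 = H, 1 = E (left), 2 = F (up)
    while True:
        if state == 0:
            p = ph[i, j]
            if p == _STOP:
                break
            if p == _DIAG:
                i -= 1
                j -= 1
                a_idx[k] = i
                b_idx[k] = j
                k += 1
            elif p == _LEFT:
                state = 1
            else:
                state = 2
        elif state == 1:
            ext = pe[i, j]
            j -= 1
            a_idx[k] = GAP
            b_idx[k] = j
            k += 1
            if ext == 0:
                state = 0
        else:
            ext = pf[i, j]
            i -= 1
            a_idx[k] = i
            b_idx[k] = GAP
            k += 1
            if ext == 0:
                state = 0
    return a_idx[:k][::-1].copy(), b_idx[:k][::-1].copy()


def sw_align(a: np.ndarray, b: np.ndarray, match: int, mismatch: int,
             gap_open: int, gap_extend: int):
    """Optimal local alignment of ``a`` against ``b``.

    Returns ``(raw_score, a_idx, b_idx)``; empty index arrays when the best
    local score is 0 (nothing aligns above the baseline).
    """
    _, _, _, ph, pe, pf, best, bi, bj = _sw_fill(
        a, b, match, mismatch, gap_open, gap_extend
    )
    if best <= 0:
        return 0, np.empty(0, dtype=np.int32), np.empty(0, dtype=np.int32)
    a_idx, b_idx = _sw_traceback(ph, pe, pf, bi, bj)
    return int(best), a_idx, b_idx
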