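"""Affine-gap dynamic programming kernels (numba).

One engine serves sequence-sequence and profile-profile alignment: callers
supply a precomputed column-vs-column score matrix ``S`` (for sequences a
substitution-matrix lookup table, for profiles a frequency-weighted average
computed by BLAS), and the kernels run a three-state affine-gap DP over it.

Gap cost convention: the first position of a gap costs ``gap_open``, every
further position ``gap_extend`` (both positive penalties), i.e. a gap of
length k costs ``gap_open + (k-1) * gap_extend``.

Traceback is deterministic: on score ties the diagonal (match) state wins
over the vertical (gap in b) state, which wins over the horizontal state.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = np.float32(-1e30)

# state codes
_M, _X, _Y = 0, 1, 2
_START = 3  # local-alignment restart marker (M-state only)


@njit(cache=True)
def _fill(S, gap_open, gap_extend, local):
    """Fill the three-state DP; return (traceback, score, end_i, end_j, end_state).

    traceback packs per cell the predecessor state of M (bits 0-1), X (bits
    2-3) and Y (bits 4-5).  X consumes a row of S (gap in b), Y a column.
    """
    la, lb = S.shape
    tb = np.zeros((la + 1, lb + 1), dtype=np.uint8)
    m_prev = np.empty(lb + 1, dtype=np.float32)
    x_prev = np.empty(lb + 1, dtype=np.float32)
    y_prev = np.empty(lb + 1, dtype=np.float32)
    m_cur = np.empty(lb + 1, dtype=np.float32)
    x_cur = np.empty(lb + 1, dtype=np.float32)
    y_cur = np.empty(lb + 1, dtype=np.float32)

    m_prev[0] = np.float32(0.0)
    x_prev[0] = NEG
    y_prev[0] = NEG
    best = NEG
    bi = 0
    bj = 0
    bs = _M
    for j in range(1, lb + 1):
        if local:
            m_prev[j] = np.float32(0.0)
            tb[0, j] |= _START
            y_prev[j] = NEG
        else:
            m_prev[j] = NEG
            y_prev[j] = -(gap_open + np.float32(j - 1) * gap_extend)
            tb[0, j] |= (_Y if j > 1 else _M) << 4
        x_prev[j] = NEG

    for i in range(1, la + 1):
        if local:
            m_cur[0] = np.float32(0.0)
            tb[i, 0] |= _START
            x_cur[0] = NEG
        else:
            m_cur[0] = NEG
            x_cur[0] = -(gap_open + np.float32(i - 1) * gap_extend)
            tb[i, 0] |= (_X if i > 1 else _M) << 2
        y_cur[0] = NEG
        for j in range(1, lb + 1):
            # M: diagonal move ending at (i, j)
            v = m_prev[j - 1]
            p = _M
            if x_prev[j - 1] > v:
                v = x_prev[j - 1]
                p = _X
            if y_prev[j - 1] > v:
                v = y_prev[j - 1]
                p = _Y
            m = v + S[i - 1, j - 1]
            if local and m < np.float32(0.0):
                m = np.float32(0.0)
                p = _START
            m_cur[j] = m
            code = p

            # X: vertical move (consume a-column i, gap in b)
            v = m_prev[j] - gap_open
            p = _M
            t = x_prev[j] - gap_extend
            if t > v:
                v = t
                p = _X
            t = y_prev[j] - gap_open
            if t > v:
                v = t
                p = _Y
            x_cur[j] = v
            code |= p << 2

            # Y: horizontal move (consume b-column j, gap in a)
            v = m_cur[j - 1] - gap_open
            p = _M
            t = x_cur[j - 1] - gap_open
            if t > v:
                v = t
                p = _X
            t = y_cur[j - 1] - gap_extend
            if t > v:
                v = t
                p = _Y
            y_cur[j] = v
            code |= p << 4

            tb[i, j] = code
            if local and m > best:
                best = m
                bi = i
                bj = j
        m_prev, m_cur = m_cur, m_prev
        x_prev, x_cur = x_cur, x_prev
        y_prev, y_cur = y_cur, y_prev

    if not local:
        # final state preference: diagonal > up > left
        best = m_prev[lb]
        bs = _M
        if x_prev[lb] > best:
            best = x_prev[lb]
            bs = _X
        if y_prev[lb] > best:
            best = y_prev[lb]
            bs = _Y
        bi = la
        bj = lb
    return tb, best, bi, bj, bs


@njit(cache=True)
def _traceback(tb, ei, ej, state, local):
    """Walk the packed traceback; return aligned index arrays (-1 = gap)."""
    n = ei + ej
    ai = np.empty(n, dtype=np.int32)
    bj = np.empty(n, dtype=np.int32)
    k = 0
    i, j, s = ei, ej, state
    while i > 0 or j > 0:
        code = tb[i, j]
        if s == _M:
            p = code & 3
            if local and p == _START:
                break
            ai[k] = i - 1
            bj[k] = j - 1
            i -= 1
            j -= 1
        elif s == _X:
            p = (code >> 2) & 3
            ai[k] = i - 1
            bj[k] = -1
            i -= 1
        else:
            p = (code >> 4) & 3
            ai[k] = -1
            bj[k] = j - 1
            j -= 1
        k += 1
        s = p
    return ai[:k][::-1].copy(), bj[:k][::-1].copy(), i, j


@njit(cache=True)
def _fill_seq(ca, cb, M, gap_open, gap_extend, local):
    """Sequence-sequence specialisation of :func:`_fill`.

    Identical recurrences, but substitution scores are looked up as
    ``M[ca[i-1], cb[j-1]]`` instead of reading a dense precomputed score
    matrix; this skips a large allocation on the all-pairs distance path.
    """
    la = ca.shape[0]
    lb = cb.shape[0]
    tb = np.zeros((la + 1, lb + 1), dtype=np.uint8)
    m_prev = np.empty(lb + 1, dtype=np.float32)
    x_prev = np.empty(lb + 1, dtype=np.float32)
    y_prev = np.empty(lb + 1, dtype=np.float32)
    m_cur = np.empty(lb + 1, dtype=np.float32)
    x_cur = np.empty(lb + 1, dtype=np.float32)
    y_cur = np.empty(lb + 1, dtype=np.float32)

    m_prev[0] = np.float32(0.0)
    x_prev[0] = NEG
    y_prev[0] = NEG
    best = NEG
    bi = 0
    bj = 0
    bs = _M
    for j in range(1, lb + 1):
        if local:
            m_prev[j] = np.float32(0.0)
            tb[0, j] |= _START
            y_prev[j] = NEG
        else:
            m_prev[j] = NEG
            y_prev[j] = -(gap_open + np.float32(j - 1) * gap_extend)
            tb[0, j] |= (_Y if j > 1 else _M) << 4
        x_prev[j] = NEG

    for i in range(1, la + 1):
        if local:
            m_cur[0] = np.float32(0.0)
            tb[i, 0] |= _START
            x_cur[0] = NEG
        else:
            m_cur[0] = NEG
            x_cur[0] = -(gap_open + np.float32(i - 1) * gap_extend)
            tb[i, 0] |= (_X if i > 1 else _M) << 2
        y_cur[0] = NEG
        Mrow = M[ca[i - 1]]
        for j in range(1, lb + 1):
            v = m_prev[j - 1]
            p = _M
            if x_prev[j - 1] > v:
                v = x_prev[j - 1]
                p = _X
            if y_prev[j - 1] > v:
                v = y_prev[j - 1]
                p = _Y
            m = v + Mrow[cb[j - 1]]
            if local and m < np.float32(0.0):
                m = np.float32(0.0)
                p = _START
            m_cur[j] = m
            code = p

            v = m_prev[j] - gap_open
            p = _M
            t = x_prev[j] - gap_extend
            if t > v:
                v = t
                p = _X
            t = y_prev[j] - gap_open
            if t > v:
                v = t
                p = _Y
            x_cur[j] = v
            code |= p << 2

            v = m_cur[j - 1] - gap_open
            p = _M
            t = x_cur[j - 1] - gap_open
            if t > v:
                v = t
                p = _X
            t = y_cur[j - 1] - gap_extend
            if t > v:
                v = t
                p = _Y
            y_cur[j] = v
            code |= p << 4

            tb[i, j] = code
            if local and m > best:
                best = m
                bi = i
                bj = j
        m_prev, m_cur = m_cur, m_prev
        x_prev, x_cur = x_cur, x_prev
        y_prev, y_cur = y_cur, y_prev

    if not local:
        best = m_prev[lb]
        bs = _M
        if x_prev[lb] > best:
            best = x_prev[lb]
            bs = _X
        if y_prev[lb] > best:
            best = y_prev[lb]
            bs = _Y
        bi = la
        bj = lb
    return tb, best, bi, bj, bs


def align_encoded(ca, cb, matrix, gap_open=10.0, gap_extend=0.5, local=False):
    """Align two encoded sequences; same return contract as align_score_matrix."""
    tb, score, ei, ej, state = _fill_seq(
        np.ascontiguousarray(ca),
        np.ascontiguousarray(cb),
        np.ascontiguousarray(matrix, dtype=np.float32),
        np.float32(gap_open),
        np.float32(gap_extend),
        local,
    )
    a_idx, b_idx, si, sj = _traceback(tb, ei, ej, state, local)
    return float(score), a_idx, b_idx, (si, sj)


def align_score_matrix(S, gap_open=10.0, gap_extend=0.5, local=False):
    """Optimal affine-gap alignment over an arbitrary score matrix.

    Returns ``(score, a_idx, b_idx, (start_a, start_b))`` where the index
    arrays give, per alignment column, the consumed row/column of ``S`` or
    -1 for a gap.  For local alignments the indices cover only the aligned
    segment, whose start offsets are returned as well.
    """
    S = np.ascontiguousarray(S, dtype=np.float32)
    tb, score, ei, ej, state = _fill(
        S, np.float32(gap_open), np.float32(gap_extend), local
    )
    a_idx, b_idx, si, sj = _traceback(tb, ei, ej, state, local)
    return float(score), a_idx, b_idx, (si, sj)
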