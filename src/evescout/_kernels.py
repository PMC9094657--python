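"""Numba dynamic-programming kernels for local and global affine alignment.

All kernels work on integer-coded target sequences and a per-query-position
score profile (shape (L, A)), so one code path serves plain substitution
queries, PSSM scans, and nucleotide repeat detection. Affine convention: a
gap of length k costs open + (k-1)*extend.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = np.float32(-1.0e30)


@njit(cache=True)
def sw_fill(prof, target, gap_open, gap_extend):
    """Smith-Waterman (Gotoh) fill. Returns H, E, F of shape (L+1, n+1).

    E: best score ending with a gap in the query (target residue aligned
    to '-'); F: gap in the target.
    """
    L = prof.shape[0]
    n = target.shape[0]
    H = np.zeros((L + 1, n + 1), dtype=np.float32)
    E = np.full((L + 1, n + 1), NEG, dtype=np.float32)
    F = np.full((L + 1, n + 1), NEG, dtype=np.float32)
    for i in range(1, L + 1):
        for j in range(1, n + 1):
            e = H[i, j - 1] - gap_open
            e2 = E[i, j - 1] - gap_extend
            if e2 > e:
                e = e2
            E[i, j] = e
            f = H[i - 1, j] - gap_open
            f2 = F[i - 1, j] - gap_extend
            if f2 > f:
                f = f2
            F[i, j] = f
            h = H[i - 1, j - 1] + prof[i - 1, target[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            H[i, j] = h
    return H, E, F


@njit(cache=True)
def sw_traceback(H, E, F, prof, target, gap_open, gap_extend, i0, j0):
    """Trace one optimal local path ending at (i0, j0).

    Returns (q_idx, t_idx, length): parallel arrays of 0-based indices with
    -1 marking a gap, in alignment order.
    """
    L = prof.shape[0]
    n = target.shape[0]
    maxlen = L + n
    q_idx = np.empty(maxlen, dtype=np.int64)
    t_idx = np.empty(maxlen, dtype=np.int64)
    pos = 0
    i = i0
    j = j0
    state = 0  # 0=M, 1=E (gap in query), 2=F (gap in target)
    while i > 0 and j > 0:
        if state == 0:
            h = H[i, j]
            if h == 0.0:
                break
            diag = H[i - 1, j - 1] + prof[i - 1, target[j - 1]]
            if h == diag:
                q_idx[pos] = i - 1
                t_idx[pos] = j - 1
                pos += 1
                i -= 1
                j -= 1
            elif h == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            q_idx[pos] = -1
            t_idx[pos] = j - 1
            pos += 1
            if E[i, j] == H[i, j - 1] - gap_open:
                state = 0
            j -= 1
        else:
            q_idx[pos] = i - 1
            t_idx[pos] = -1
            pos += 1
            if F[i, j] == H[i - 1, j] - gap_open:
                state = 0
            i -= 1
    # reverse in place to alignment order
    for k in range(pos // 2):
        q_idx[k], q_idx[pos - 1 - k] = q_idx[pos - 1 - k], q_idx[k]
        t_idx[k], t_idx[pos - 1 - k] = t_idx[pos - 1 - k], t_idx[k]
    return q_idx[:pos], t_idx[:pos], pos


@njit(cache=True)
def nw_fill(C, gap_open, gap_extend):
    """Global (Needleman-Wunsch/Gotoh) fill on a precomputed column-score
    matrix C of shape (L1, L2). Returns M, X, Y DP matrices.

    X: alignment ends with a gap in sequence 1 (consumes seq2);
    Y: gap in sequence 2.
    """
    L1, L2 = C.shape
    M = np.full((L1 + 1, L2 + 1), NEG, dtype=np.float32)
    X = np.full((L1 + 1, L2 + 1), NEG, dtype=np.float32)
    Y = np.full((L1 + 1, L2 + 1), NEG, dtype=np.float32)
    M[0, 0] = 0.0
    for j in range(1, L2 + 1):
        X[0, j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, L1 + 1):
        Y[i, 0] = -gap_open - (i - 1) * gap_extend
    for i in range(1, L1 + 1):
        for j in range(1, L2 + 1):
            best_prev = M[i - 1, j - 1]
            if X[i - 1, j - 1] > best_prev:
                best_prev = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > best_prev:
                best_prev = Y[i - 1, j - 1]
            M[i, j] = best_prev + C[i - 1, j - 1]

            a = M[i, j - 1] - gap_open
            b = X[i, j - 1] - gap_extend
            c = Y[i, j - 1] - gap_open
            x = a
            if b > x:
                x = b
            if c > x:
                x = c
            X[i, j] = x

            a = M[i - 1, j] - gap_open
            b = Y[i - 1, j] - gap_extend
            c = X[i - 1, j] - gap_open
            y = a
            if b > y:
                y = b
            if c > y:
                y = c
            Y[i, j] = y
    return M, X, Y


@njit(cache=True)
def nw_traceback(M, X, Y, C, gap_open, gap_extend):
    """Trace one optimal global path. Returns (idx1, idx2, length) with -1
    marking a gap, in alignment order."""
    L1 = C.shape[0]
    L2 = C.shape[1]
    maxlen = L1 + L2
    a_idx = np.empty(maxlen, dtype=np.int64)
    b_idx = np.empty(maxlen, dtype=np.int64)
    pos = 0
    i = L1
    j = L2
    # start in the best terminal state
    state = 0
    best = M[i, j]
    if X[i, j] > best:
        best = X[i, j]
        state = 1
    if Y[i, j] > best:
        best = Y[i, j]
        state = 2
    while i > 0 or j > 0:
        if state == 0:
            # diagonal step into (i-1, j-1); pick predecessor state
            a_idx[pos] = i - 1
            b_idx[pos] = j - 1
            pos += 1
            prev = M[i, j] - C[i - 1, j - 1]
            i -= 1
            j -= 1
            if i == 0 and j == 0:
                break
            if prev == M[i, j]:
                state = 0
            elif prev == X[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            a_idx[pos] = -1
            b_idx[pos] = j - 1
            pos += 1
            val = X[i, j]
            if val == X[i, j - 1] - gap_extend:
                state = 1
            elif val == M[i, j - 1] - gap_open:
                state = 0
            else:
                state = 2
            j -= 1
        else:
            a_idx[pos] = i - 1
            b_idx[pos] = -1
            pos += 1
            val = Y[i, j]
            if val == Y[i - 1, j] - gap_extend:
                state = 2
            elif val == M[i - 1, j] - gap_open:
                state = 0
            else:
                state = 1
            i -= 1
        if i == 0 and j == 0:
            break
    # drain any remaining leading gaps
    while j > 0:
        a_idx[pos] = -1
        b_idx[pos] = j - 1
        pos += 1
        j -= 1
    while i > 0:
        a_idx[pos] = i - 1
        b_idx[pos] = -1
        pos += 1
        i -= 1
    for k in range(pos // 2):
        a_idx[k], a_idx[pos - 1 - k] = a_idx[pos - 1 - k], a_idx[k]
        b_idx[k], b_idx[pos - 1 - k] = b_idx[pos - 1 - k], b_idx[k]
    return a_idx[:pos], b_idx[:pos], pos
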