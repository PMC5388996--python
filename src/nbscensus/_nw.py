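"""Needleman-Wunsch global alignment with affine gaps (numba kernel).

Gap costs follow the usual convention: the first column of a gap run costs
``gap_open`` and every further column ``gap_extend``. Transitions between a
gap in one sequence and a gap in the other re-open (both are charged
``gap_open``). Ties prefer match over gap-in-B over gap-in-A, which makes
the traceback deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1e30

# op codes emitted by the traceback
OP_MATCH = 0  # both sequences consume a residue
OP_GAP_B = 1  # residue of A against a gap in B
OP_GAP_A = 2  # residue of B against a gap in A


@njit(cache=True)
def nw_affine(a, b, S, gap_open, gap_ext):  # pragma: no cover - exercised via wrapper
    n = a.shape[0]
    m = b.shape[0]
    M = np.full((n + 1, m + 1), NEG, np.float64)
    X = np.full((n + 1, m + 1), NEG, np.float64)  # gap in B
    Y = np.full((n + 1, m + 1), NEG, np.float64)  # gap in A
    pM = np.zeros((n + 1, m + 1), np.int8)
    pX = np.zeros((n + 1, m + 1), np.int8)
    pY = np.zeros((n + 1, m + 1), np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        if i == 1:
            X[i, 0] = -gap_open
            pX[i, 0] = 0
        else:
            X[i, 0] = X[i - 1, 0] - gap_ext
            pX[i, 0] = 1
    for j in range(1, m + 1):
        if j == 1:
            Y[0, j] = -gap_open
            pY[0, j] = 0
        else:
            Y[0, j] = Y[0, j - 1] - gap_ext
            pY[0, j] = 2
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = S[ai, b[j - 1]]
            best = M[i - 1, j - 1]
            p = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                p = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                p = 2
            M[i, j] = best + s
            pM[i, j] = p

            best = M[i - 1, j] - gap_open
            p = 0
            v = X[i - 1, j] - gap_ext
            if v > best:
                best = v
                p = 1
            v = Y[i - 1, j] - gap_open
            if v > best:
                best = v
                p = 2
            X[i, j] = best
            pX[i, j] = p

            best = M[i, j - 1] - gap_open
            p = 0
            v = X[i, j - 1] - gap_open
            if v > best:
                best = v
                p = 1
            v = Y[i, j - 1] - gap_ext
            if v > best:
                best = v
                p = 2
            Y[i, j] = best
            pY[i, j] = p

    score = M[n, m]
    state = 0
    if X[n, m] > score:
        score = X[n, m]
        state = 1
    if Y[n, m] > score:
        score = Y[n, m]
        state = 2

    ops = np.empty(n + m, np.int8)
    k = 0
    i = n
    j = m
    while i > 0 or j > 0:
        if state == 0:
            ops[k] = 0
            state = pM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            ops[k] = 1
            state = pX[i, j]
            i -= 1
        else:
            ops[k] = 2
            state = pY[i, j]
            j -= 1
        k += 1
    return score, ops[:k][::-1].copy()
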