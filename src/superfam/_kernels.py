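"""Affine-gap alignment kernels (numba-compiled).

Three-state Gotoh dynamic programming for local (Smith–Waterman) and global
(Needleman–Wunsch) alignment with an affine gap model: a gap of length L
costs ``gap_open + (L - 1) * gap_extend``.

Tracebacks are deterministic: on ties the move preference is diagonal,
then up (gap in sequence b), then left (gap in sequence a); within gap
states, opening is preferred over extending.

Sequences are passed as uint8 code arrays indexing into a square
substitution-score grid.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = np.int32(-(10**8))

# traceback ops
DIAG, UP, LEFT = 1, 2, 3
# state ids
S_M, S_X, S_Y = 0, 1, 2


@njit(cache=True)
def _local_dp(a, b, sub, gap_open, gap_extend):
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG_INF, dtype=np.int32)
    X = np.full((n + 1, m + 1), NEG_INF, dtype=np.int32)
    Y = np.full((n + 1, m + 1), NEG_INF, dtype=np.int32)
    pM = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 start, 1 M, 2 X, 3 Y
    pX = np.zeros((n + 1, m + 1), dtype=np.int8)  # 1 from M (open), 2 from X
    pY = np.zeros((n + 1, m + 1), dtype=np.int8)  # 1 from M (open), 3 from Y
    best = np.int32(0)
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub[a[i - 1], b[j - 1]]
            # M state: preference M > X > Y > fresh start
            vm = M[i - 1, j - 1]
            vx = X[i - 1, j - 1]
            vy = Y[i - 1, j - 1]
            v = vm
            p = 1
            if vx > v:
                v = vx
                p = 2
            if vy > v:
                v = vy
                p = 3
            if 0 > v:
                v = np.int32(0)
                p = 0
            M[i, j] = v + s
            pM[i, j] = p
            # X: gap in b (consume a) — "up"
            vopen = M[i - 1, j] - gap_open
            vext = X[i - 1, j] - gap_extend
            if vopen >= vext:
                X[i, j] = vopen
                pX[i, j] = 1
            else:
                X[i, j] = vext
                pX[i, j] = 2
            # Y: gap in a (consume b) — "left"
            vopen = M[i, j - 1] - gap_open
            vext = Y[i, j - 1] - gap_extend
            if vopen >= vext:
                Y[i, j] = vopen
                pY[i, j] = 1
            else:
                Y[i, j] = vext
                pY[i, j] = 3
            if M[i, j] > best:
                best = M[i, j]
                bi = i
                bj = j
    return best, bi, bj, pM, pX, pY


@njit(cache=True)
def _local_traceback(bi, bj, pM, pX, pY):
    ops = np.empty(bi + bj, dtype=np.int8)
    k = 0
    i, j = bi, bj
    state = S_M
    while i > 0 and j > 0:
        if state == S_M:
            p = pM[i, j]
            ops[k] = DIAG
            k += 1
            i -= 1
            j -= 1
            if p == 0:
                break
            state = S_M if p == 1 else (S_X if p == 2 else S_Y)
        elif state == S_X:
            p = pX[i, j]
            ops[k] = UP
            k += 1
            i -= 1
            state = S_M if p == 1 else S_X
        else:
            p = pY[i, j]
            ops[k] = LEFT
            k += 1
            j -= 1
            state = S_M if p == 1 else S_Y
    return ops[:k][::-1], i, j


@njit(cache=True)
def _global_dp(a, b, sub, gap_open, gap_extend):
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG_INF, dtype=np.int32)
    X = np.full((n + 1, m + 1), NEG_INF, dtype=np.int32)
    Y = np.full((n + 1, m + 1), NEG_INF, dtype=np.int32)
    pM = np.zeros((n + 1, m + 1), dtype=np.int8)
    pX = np.zeros((n + 1, m + 1), dtype=np.int8)
    pY = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0
    for i in range(1, n + 1):
        X[i, 0] = -gap_open - (i - 1) * gap_extend
        pX[i, 0] = 1 if i == 1 else 2
    for j in range(1, m + 1):
        Y[0, j] = -gap_open - (j - 1) * gap_extend
        pY[0, j] = 1 if j == 1 else 3
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub[a[i - 1], b[j - 1]]
            vm = M[i - 1, j - 1]
            vx = X[i - 1, j - 1]
            vy = Y[i - 1, j - 1]
            v = vm
            p = 1
            if vx > v:
                v = vx
                p = 2
            if vy > v:
                v = vy
                p = 3
            M[i, j] = v + s if v > NEG_INF // 2 else NEG_INF
            pM[i, j] = p
            vopen = M[i - 1, j] - gap_open
            vext = X[i - 1, j] - gap_extend
            if vopen >= vext:
                X[i, j] = vopen
                pX[i, j] = 1
            else:
                X[i, j] = vext
                pX[i, j] = 2
            vopen = M[i, j - 1] - gap_open
            vext = Y[i, j - 1] - gap_extend
            if vopen >= vext:
                Y[i, j] = vopen
                pY[i, j] = 1
            else:
                Y[i, j] = vext
                pY[i, j] = 3
    return M, X, Y, pM, pX, pY


@njit(cache=True)
def _global_traceback(M, X, Y, pM, pX, pY):
    n = M.shape[0] - 1
    m = M.shape[1] - 1
    # final state: preference M > X > Y
    state = S_M
    best = M[n, m]
    if X[n, m] > best:
        best = X[n, m]
        state = S_X
    if Y[n, m] > best:
        best = Y[n, m]
        state = S_Y
    ops = np.empty(n + m, dtype=np.int8)
    k = 0
    i, j = n, m
    while i > 0 or j > 0:
        if state == S_M:
            p = pM[i, j]
            ops[k] = DIAG
            k += 1
            i -= 1
            j -= 1
            state = S_M if p == 1 else (S_X if p == 2 else S_Y)
        elif state == S_X:
            p = pX[i, j]
            ops[k] = UP
            k += 1
            i -= 1
            state = S_M if p == 1 else S_X
        else:
            p = pY[i, j]
            ops[k] = LEFT
            k += 1
            j -= 1
            state = S_M if p == 1 else S_Y
    return best, ops[:k][::-1]


def local_align_coded(a, b, sub, gap_open, gap_extend):
    """(score, start_a, end_a, start_b, end_b, ops) for the optimal local
    alignment; ops is an int8 array of DIAG/UP/LEFT moves."""
    score, bi, bj, pM, pX, pY = _local_dp(a, b, sub, gap_open, gap_extend)
    if score <= 0:
        return 0, 0, 0, 0, 0, np.empty(0, dtype=np.int8)
    ops, si, sj = _local_traceback(bi, bj, pM, pX, pY)
    return int(score), si, bi, sj, bj, ops


def global_align_coded(a, b, sub, gap_open, gap_extend):
    """(score, ops) for the optimal end-to-end alignment."""
    M, X, Y, pM, pX, pY = _global_dp(a, b, sub, gap_open, gap_extend)
    score, ops = _global_traceback(M, X, Y, pM, pX, pY)
    return int(score), ops


@njit(cache=True)
def global_score_coded(a, b, sub, gap_open, gap_extend):
    """Score-only global alignment, two rolling rows (the shuffle hot loop).

    NEG_INF is chosen so that adding a substitution score cannot overflow
    int32, which keeps the inner loop branch-free.
    """
    n, m = len(a), len(b)
    prevM = np.full(m + 1, NEG_INF, dtype=np.int32)
    prevX = np.full(m + 1, NEG_INF, dtype=np.int32)
    prevY = np.full(m + 1, NEG_INF, dtype=np.int32)
    curM = np.full(m + 1, NEG_INF, dtype=np.int32)
    curX = np.full(m + 1, NEG_INF, dtype=np.int32)
    curY = np.full(m + 1, NEG_INF, dtype=np.int32)
    prevM[0] = 0
    for j in range(1, m + 1):
        prevY[j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n + 1):
        curM[0] = NEG_INF
        curX[0] = -gap_open - (i - 1) * gap_extend
        curY[0] = NEG_INF
        sub_ai = sub[a[i - 1]]
        mdiag = prevM[0]
        xdiag = prevX[0]
        ydiag = prevY[0]
        ycur = curY[0]
        mleft = curM[0]
        for j in range(1, m + 1):
            v = max(mdiag, xdiag, ydiag)
            mdiag = prevM[j]
            xdiag = prevX[j]
            ydiag = prevY[j]
            mcur = v + sub_ai[b[j - 1]]
            curM[j] = mcur
            curX[j] = max(mdiag - gap_open, xdiag - gap_extend)
            ycur = max(mleft - gap_open, ycur - gap_extend)
            curY[j] = ycur
            mleft = mcur
        prevM, curM = curM, prevM
        prevX, curX = curX, prevX
        prevY, curY = curY, prevY
    return max(prevM[m], prevX[m], prevY[m])


@njit(cache=True)
def local_score_coded(a, b, sub, gap_open, gap_extend):
    """Score-only local alignment, rolling rows."""
    n, m = len(a), len(b)
    prevM = np.zeros(m + 1, dtype=np.int32)
    prevX = np.full(m + 1, NEG_INF, dtype=np.int32)
    prevY = np.full(m + 1, NEG_INF, dtype=np.int32)
    curM = np.zeros(m + 1, dtype=np.int32)
    curX = np.full(m + 1, NEG_INF, dtype=np.int32)
    curY = np.full(m + 1, NEG_INF, dtype=np.int32)
    best = np.int32(0)
    for i in range(1, n + 1):
        ai = a[i - 1]
        curM[0] = 0
        curX[0] = NEG_INF
        curY[0] = NEG_INF
        for j in range(1, m + 1):
            v = prevM[j - 1]
            if prevX[j - 1] > v:
                v = prevX[j - 1]
            if prevY[j - 1] > v:
                v = prevY[j - 1]
            if v < 0:
                v = 0
            curM[j] = v + sub[ai, b[j - 1]]
            vopen = prevM[j] - gap_open
            vext = prevX[j] - gap_extend
            curX[j] = vopen if vopen >= vext else vext
            vopen = curM[j - 1] - gap_open
            vext = curY[j - 1] - gap_extend
            curY[j] = vopen if vopen >= vext else vext
            if curM[j] > best:
                best = curM[j]
        prevM, curM = curM, prevM
        prevX, curX = curX, prevX
        prevY, curY = curY, prevY
    return best
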