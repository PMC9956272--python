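"""Affine-gap dynamic-programming kernels (numba).

Three kernels back the whole package:

* ``banded_affine`` — pairwise alignment of two encoded sequences with affine
  gaps, either *fitting* (terminal gaps free along the longer sequence; used
  for the clustering identity) or *global*.  A diagonal band restricts the
  search space; callers pass a band wide enough to contain the optimum
  (the full matrix for small inputs).
* ``local_affine`` — Smith–Waterman with affine gaps, reporting the optimal
  segment's coordinates, identical-column count and aligned-column count.
* ``profile_local`` — Smith–Waterman of a position-specific score matrix
  against an encoded protein, used by the RuvC-domain scan.

Gap cost convention everywhere: the first gap column of a run costs
``gap_open`` and every further column ``gap_extend`` (both passed positive).

All kernels are deterministic: ties are resolved in the fixed move order
match/mismatch > gap-in-b > gap-in-a.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1e18


@njit(cache=True)
def banded_affine(a, b, lo, hi, match, mismatch, gap_open, gap_extend, fit):
    """Align a (rows) to b (cols) within diagonals j - i in [lo, hi].

    fit=True frees terminal gaps in b (a is consumed entirely, b may dangle
    at either end); fit=False is a plain global alignment.  Returns
    (score, matches, cols) where cols counts aligned columns excluding
    terminal gap runs and matches counts identical columns among them.
    """
    m = a.shape[0]
    n = b.shape[0]
    W = hi - lo + 1
    # rolling score rows, full pointer matrices
    M0 = np.full(W, NEG)
    X0 = np.full(W, NEG)
    Y0 = np.full(W, NEG)
    M1 = np.full(W, NEG)
    X1 = np.full(W, NEG)
    Y1 = np.full(W, NEG)
    pM = np.zeros((m + 1, W), dtype=np.uint8)
    pX = np.zeros((m + 1, W), dtype=np.uint8)
    pY = np.zeros((m + 1, W), dtype=np.uint8)

    # row 0
    for k in range(W):
        j = 0 + lo + k
        if j < 0 or j > n:
            continue
        if fit:
            M0[k] = 0.0
        else:
            if j == 0:
                M0[k] = 0.0
            else:
                Y0[k] = -(gap_open + (j - 1) * gap_extend)
                pY[0, k] = 3 if j > 1 else 1

    for i in range(1, m + 1):
        for k in range(W):
            M1[k] = NEG
            X1[k] = NEG
            Y1[k] = NEG
        for k in range(W):
            j = i + lo + k
            if j < 0 or j > n:
                continue
            if j == 0:
                # leading gap in b (consume a)
                prev_m = M0[k + 1] if k + 1 < W else NEG
                prev_x = X0[k + 1] if k + 1 < W else NEG
                if prev_m - gap_open >= prev_x - gap_extend:
                    X1[k] = prev_m - gap_open
                    pX[i, k] = 1
                else:
                    X1[k] = prev_x - gap_extend
                    pX[i, k] = 2
                continue
            # M state: diagonal from (i-1, j-1) -> same k
            s = match if a[i - 1] == b[j - 1] else mismatch
            bm = M0[k]
            bp = 1
            if X0[k] > bm:
                bm = X0[k]
                bp = 2
            if Y0[k] > bm:
                bm = Y0[k]
                bp = 3
            if bm > NEG / 2:
                M1[k] = bm + s
                pM[i, k] = bp
            # X state: from (i-1, j) -> k+1
            pm = M0[k + 1] if k + 1 < W else NEG
            px = X0[k + 1] if k + 1 < W else NEG
            py = Y0[k + 1] if k + 1 < W else NEG
            bx = pm - gap_open
            bxp = 1
            if px - gap_extend > bx:
                bx = px - gap_extend
                bxp = 2
            if py - gap_open > bx:
                bx = py - gap_open
                bxp = 3
            if bx > NEG / 2:
                X1[k] = bx
                pX[i, k] = bxp
            # Y state: from (i, j-1) -> k-1 in current row
            if k - 1 >= 0:
                pm = M1[k - 1]
                px = X1[k - 1]
                py = Y1[k - 1]
                by = pm - gap_open
                byp = 1
                if py - gap_extend > by:
                    by = py - gap_extend
                    byp = 3
                if px - gap_open > by:
                    by = px - gap_open
                    byp = 2
                if by > NEG / 2:
                    Y1[k] = by
                    pY[i, k] = byp
        for k in range(W):
            M0[k] = M1[k]
            X0[k] = X1[k]
            Y0[k] = Y1[k]

    # pick endpoint
    best = NEG
    bk = -1
    bstate = 1
    if fit:
        for k in range(W):
            j = m + lo + k
            if j < 0 or j > n:
                continue
            if M0[k] > best:
                best = M0[k]
                bk = k
                bstate = 1
            if X0[k] > best:
                best = X0[k]
                bk = k
                bstate = 2
    else:
        k = n - m - lo
        if 0 <= k < W:
            if M0[k] > best:
                best = M0[k]
                bk = k
                bstate = 1
            if X0[k] > best:
                best = X0[k]
                bk = k
                bstate = 2
            if Y0[k] > best:
                best = Y0[k]
                bk = k
                bstate = 3
    if bk < 0:
        return NEG, 0, 0

    # traceback, recording column types (1 aligned-match, 2 aligned-mismatch,
    # 3 gap) to strip terminal gap runs afterwards
    path = np.empty(m + n + 2, dtype=np.uint8)
    plen = 0
    i = m
    k = bk
    state = bstate
    while True:
        j = i + lo + k
        if state == 1:
            if i == 0:
                break  # start cell
            ptr = pM[i, k]
            path[plen] = 1 if a[i - 1] == b[j - 1] else 2
            plen += 1
            i -= 1
            state = ptr
            if state == 0:
                break
        elif state == 2:
            ptr = pX[i, k]
            path[plen] = 3
            plen += 1
            i -= 1
            k += 1
            state = ptr
            if state == 0:
                break
        else:
            ptr = pY[i, k]
            path[plen] = 3
            plen += 1
            k -= 1
            state = ptr
            if state == 0:
                break
        if i == 0 and state == 1:
            break

    # strip terminal gap runs (path is end->start; both ends checked)
    s0 = 0
    e0 = plen
    while s0 < e0 and path[s0] == 3:
        s0 += 1
    while e0 > s0 and path[e0 - 1] == 3:
        e0 -= 1
    matches = 0
    cols = 0
    for t in range(s0, e0):
        cols += 1
        if path[t] == 1:
            matches += 1
    return best, matches, cols


@njit(cache=True)
def local_affine(a, b, match, mismatch, gap_open, gap_extend):
    """Smith–Waterman with affine gaps on encoded sequences.

    Returns (score, matches, cols, a_start, a_end, b_start, b_end) for the
    single best local alignment (deterministic tie-break: first cell in
    row-major order, moves preferred diagonal > gap-in-b > gap-in-a).
    """
    m = a.shape[0]
    n = b.shape[0]
    M = np.zeros((m + 1, n + 1))
    X = np.full((m + 1, n + 1), NEG)
    Y = np.full((m + 1, n + 1), NEG)
    pM = np.zeros((m + 1, n + 1), dtype=np.uint8)
    pX = np.zeros((m + 1, n + 1), dtype=np.uint8)
    pY = np.zeros((m + 1, n + 1), dtype=np.uint8)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            bm = M[i - 1, j - 1]
            bp = 1
            if X[i - 1, j - 1] > bm:
                bm = X[i - 1, j - 1]
                bp = 2
            if Y[i - 1, j - 1] > bm:
                bm = Y[i - 1, j - 1]
                bp = 3
            v = bm + s
            if v < 0.0:
                v = 0.0
                bp = 0
            M[i, j] = v
            pM[i, j] = bp
            bx = M[i - 1, j] - gap_open
            bxp = 1
            if X[i - 1, j] - gap_extend > bx:
                bx = X[i - 1, j] - gap_extend
                bxp = 2
            X[i, j] = bx
            pX[i, j] = bxp
            by = M[i, j - 1] - gap_open
            byp = 1
            if Y[i, j - 1] - gap_extend > by:
                by = Y[i, j - 1] - gap_extend
                byp = 3
            Y[i, j] = by
            pY[i, j] = byp
            if M[i, j] > best:
                best = M[i, j]
                bi = i
                bj = j
    if best <= 0.0:
        return 0.0, 0, 0, 0, 0, 0, 0
    # traceback from (bi, bj), state M; a local path starts and ends aligned
    i = bi
    j = bj
    state = 1
    matches = 0
    cols = 0
    while True:
        if state == 1:
            cols += 1
            if a[i - 1] == b[j - 1]:
                matches += 1
            prev = pM[i, j]
            i -= 1
            j -= 1
            if prev == 0:
                break
            if prev == 1:
                if M[i, j] == 0.0:
                    break
                state = 1
            else:
                state = prev
        elif state == 2:
            cols += 1
            prev = pX[i, j]
            i -= 1
            state = prev
        else:
            cols += 1
            prev = pY[i, j]
            j -= 1
            state = prev
    return best, matches, cols, i, bi, j, bj


@njit(cache=True)
def profile_local(S, x, gap_open, gap_extend):
    """Local alignment of a PSSM (rows = profile columns) to an encoded
    protein x.  S has one row per profile column and one entry per residue
    code.  Returns (score, q_start, q_end, t_start, t_end): profile-column
    and target-residue half-open intervals of the best local path.
    """
    m = S.shape[0]
    n = x.shape[0]
    M = np.zeros((m + 1, n + 1))
    X = np.full((m + 1, n + 1), NEG)
    Y = np.full((m + 1, n + 1), NEG)
    pM = np.zeros((m + 1, n + 1), dtype=np.uint8)
    pX = np.zeros((m + 1, n + 1), dtype=np.uint8)
    pY = np.zeros((m + 1, n + 1), dtype=np.uint8)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = S[i - 1, x[j - 1]]
            bm = M[i - 1, j - 1]
            bp = 1
            if X[i - 1, j - 1] > bm:
                bm = X[i - 1, j - 1]
                bp = 2
            if Y[i - 1, j - 1] > bm:
                bm = Y[i - 1, j - 1]
                bp = 3
            v = bm + s
            if v < 0.0:
                v = 0.0
                bp = 0
            M[i, j] = v
            pM[i, j] = bp
            # X: skip profile column (deletion in target)
            bx = M[i - 1, j] - gap_open
            bxp = 1
            if X[i - 1, j] - gap_extend > bx:
                bx = X[i - 1, j] - gap_extend
                bxp = 2
            X[i, j] = bx
            pX[i, j] = bxp
            # Y: consume target residue outside profile (insertion)
            by = M[i, j - 1] - gap_open
            byp = 1
            if Y[i, j - 1] - gap_extend > by:
                by = Y[i, j - 1] - gap_extend
                byp = 3
            Y[i, j] = by
            pY[i, j] = byp
            if M[i, j] > best:
                best = M[i, j]
                bi = i
                bj = j
    if best <= 0.0:
        return 0.0, 0, 0, 0, 0
    i = bi
    j = bj
    state = 1
    while True:
        if state == 1:
            prev = pM[i, j]
            i -= 1
            j -= 1
            if prev == 0:
                break
            if prev == 1:
                if M[i, j] == 0.0:
                    break
                state = 1
            else:
                state = prev
        elif state == 2:
            prev = pX[i, j]
            i -= 1
            state = prev
        else:
            prev = pY[i, j]
            j -= 1
            state = prev
    return best, i, bi, j, bj


@njit(cache=True)
def global_affine_path(a, b, match, mismatch, gap_open, gap_extend, free_ends):
    """End-to-end alignment of a and b returning the full move path.

    free_ends=True makes terminal gap runs in either sequence cost nothing
    (end-gap-free global alignment, the flavour used when stacking sequences
    into a multiple alignment).  Returns (score, moves) with moves a uint8
    array in alignment order: 1 = aligned column, 2 = gap in b (consume a),
    3 = gap in a (consume b).
    """
    m = a.shape[0]
    n = b.shape[0]
    M = np.full((m + 1, n + 1), NEG)
    X = np.full((m + 1, n + 1), NEG)
    Y = np.full((m + 1, n + 1), NEG)
    pM = np.zeros((m + 1, n + 1), dtype=np.uint8)
    pX = np.zeros((m + 1, n + 1), dtype=np.uint8)
    pY = np.zeros((m + 1, n + 1), dtype=np.uint8)
    M[0, 0] = 0.0
    for i in range(1, m + 1):
        if free_ends:
            X[i, 0] = 0.0
        else:
            X[i, 0] = -(gap_open + (i - 1) * gap_extend)
        pX[i, 0] = 2 if i > 1 else 1
    for j in range(1, n + 1):
        if free_ends:
            Y[0, j] = 0.0
        else:
            Y[0, j] = -(gap_open + (j - 1) * gap_extend)
        pY[0, j] = 3 if j > 1 else 1
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            bm = M[i - 1, j - 1]
            bp = 1
            if X[i - 1, j - 1] > bm:
                bm = X[i - 1, j - 1]
                bp = 2
            if Y[i - 1, j - 1] > bm:
                bm = Y[i - 1, j - 1]
                bp = 3
            M[i, j] = bm + s
            pM[i, j] = bp
            go_x = gap_extend if (free_ends and j == n) else gap_extend
            # gap costs; trailing runs free when free_ends and at the far edge
            if free_ends and j == n:
                bx = M[i - 1, j]
                bxp = 1
                if X[i - 1, j] > bx:
                    bx = X[i - 1, j]
                    bxp = 2
            else:
                bx = M[i - 1, j] - gap_open
                bxp = 1
                if X[i - 1, j] - gap_extend > bx:
                    bx = X[i - 1, j] - gap_extend
                    bxp = 2
            X[i, j] = bx
            pX[i, j] = bxp
            if free_ends and i == m:
                by = M[i, j - 1]
                byp = 1
                if Y[i, j - 1] > by:
                    by = Y[i, j - 1]
                    byp = 3
            else:
                by = M[i, j - 1] - gap_open
                byp = 1
                if Y[i, j - 1] - gap_extend > by:
                    by = Y[i, j - 1] - gap_extend
                    byp = 3
            Y[i, j] = by
            pY[i, j] = byp
    # endpoint (m, n), best state
    best = M[m, n]
    state = 1
    if X[m, n] > best:
        best = X[m, n]
        state = 2
    if Y[m, n] > best:
        best = Y[m, n]
        state = 3
    moves = np.empty(m + n, dtype=np.uint8)
    t = 0
    i = m
    j = n
    while i > 0 or j > 0:
        if state == 1:
            moves[t] = 1
            t += 1
            prev = pM[i, j]
            i -= 1
            j -= 1
            state = prev
        elif state == 2:
            moves[t] = 2
            t += 1
            prev = pX[i, j]
            i -= 1
            state = prev
        else:
            moves[t] = 3
            t += 1
            prev = pY[i, j]
            j -= 1
            state = prev
    return best, moves[:t][::-1].copy()
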