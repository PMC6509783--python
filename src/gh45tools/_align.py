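"""Gotoh global alignment with affine gaps (numba-accelerated kernel).

The dynamic program keeps three state matrices (substitution, gap in the
second sequence, gap in the first sequence).  A gap run of length L costs
``gap_open + L * gap_extend``.  Traceback ties are resolved in the fixed
order substitution > gap-in-b > gap-in-a so that reported alignments are
bit-reproducible across runs and platforms.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1e18

# state codes used in the pointer matrices
_M, _X, _Y = 0, 1, 2


@njit(cache=False)
def _gotoh_fill(a, b, sub, gap_open, gap_extend):  # pragma: no cover - jitted
    n = a.shape[0]
    m = b.shape[0]
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b: consumes a[i]
    Y = np.full((n + 1, m + 1), NEG)  # gap in a: consumes b[j]
    PM = np.zeros((n + 1, m + 1), dtype=np.int8)
    PX = np.zeros((n + 1, m + 1), dtype=np.int8)
    PY = np.zeros((n + 1, m + 1), dtype=np.int8)

    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(gap_open + i * gap_extend)
        PX[i, 0] = _M if i == 1 else _X
    for j in range(1, m + 1):
        Y[0, j] = -(gap_open + j * gap_extend)
        PY[0, j] = _M if j == 1 else _Y

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub[a[i - 1], b[j - 1]]
            # substitution: best predecessor of (i-1, j-1)
            best = M[i - 1, j - 1]
            ptr = _M
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                ptr = _X
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                ptr = _Y
            M[i, j] = best + s
            PM[i, j] = ptr

            # gap in b (vertical move)
            open_sc = M[i - 1, j] - gap_open - gap_extend
            ext_sc = X[i - 1, j] - gap_extend
            alt_sc = Y[i - 1, j] - gap_open - gap_extend
            best = open_sc
            ptr = _M
            if ext_sc > best:
                best = ext_sc
                ptr = _X
            if alt_sc > best:
                best = alt_sc
                ptr = _Y
            X[i, j] = best
            PX[i, j] = ptr

            # gap in a (horizontal move)
            open_sc = M[i, j - 1] - gap_open - gap_extend
            ext_sc = Y[i, j - 1] - gap_extend
            alt_sc = X[i, j - 1] - gap_open - gap_extend
            best = open_sc
            ptr = _M
            if ext_sc > best:
                best = ext_sc
                ptr = _Y
            if alt_sc > best:
                best = alt_sc
                ptr = _X
            Y[i, j] = best
            PY[i, j] = ptr

    return M, X, Y, PM, PX, PY


def gotoh_align(a: np.ndarray, b: np.ndarray, sub: np.ndarray,
                gap_open: float, gap_extend: float):
    """Align two index-encoded sequences; return (score, column list).

    Columns are (i, j) pairs of 0-based residue indices, with -1 marking a
    gap on that side.
    """
    M, X, Y, PM, PX, PY = _gotoh_fill(a, b, sub, gap_open, gap_extend)
    n, m = len(a), len(b)
    # final state: tie order substitution > gap-in-b > gap-in-a
    state = _M
    score = M[n, m]
    if X[n, m] > score:
        score, state = X[n, m], _X
    if Y[n, m] > score:
        score, state = Y[n, m], _Y

    cols = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == _M:
            prev = PM[i, j]
            cols.append((i - 1, j - 1))
            i -= 1
            j -= 1
        elif state == _X:
            prev = PX[i, j]
            cols.append((i - 1, -1))
            i -= 1
        else:
            prev = PY[i, j]
            cols.append((-1, j - 1))
            j -= 1
        state = prev
    cols.reverse()
    return float(score), cols
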