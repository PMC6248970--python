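"""Compiled random forest used inside the wrapper feature search.

The forward wrapper search evaluates on the order of 10^4-10^5 small forest
fits per selection run (every candidate subset, twice per inner 2-fold CV,
for every outer leave-one-out fold).  This module provides a minimal
CART/gini random forest — bootstrap per tree, sqrt-sized random feature
subsets at each split, trees grown to purity — compiled with numba so a fit
on a few dozen rows costs microseconds rather than milliseconds.  The final
classifier of the pipeline is scikit-learn's RandomForestClassifier; this
forest exists only as the wrapper's objective and is cross-checked against
scikit-learn in the test suite.

Labels are {0, 1}; predictions are per-tree majority votes, reported as the
fraction of trees voting 1.  Fully deterministic given the seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_MASK = np.uint64(0xFFFFFFFFFFFFFFFF)


@njit(cache=True, inline="always")
def _rand(state):
    # 64-bit LCG (Knuth constants), output = high 32 bits
    state[0] = (state[0] * np.uint64(6364136223846793005)
                + np.uint64(1442695040888963407)) & _MASK
    return np.int64(state[0] >> np.uint64(33))


@njit(cache=True, inline="always")
def _randbelow(state, n):
    return _rand(state) % n


@njit(cache=True)
def _forest_votes(Xtr, ytr, Xte, n_trees, max_features, seed):
    """Fraction of trees voting class 1 for each row of Xte."""
    n, p = Xtr.shape
    nte = Xte.shape[0]
    votes = np.zeros(nte, dtype=np.float64)
    state = np.empty(1, dtype=np.uint64)
    state[0] = np.uint64(2 * seed + 1)
    for _ in range(5):
        _rand(state)

    mtry = max_features
    if mtry < 1:
        mtry = 1
    if mtry > p:
        mtry = p

    max_nodes = 4 * n + 8
    feat = np.empty(max_nodes, dtype=np.int64)
    thr = np.empty(max_nodes, dtype=np.float64)
    left = np.empty(max_nodes, dtype=np.int64)
    right = np.empty(max_nodes, dtype=np.int64)
    pred = np.empty(max_nodes, dtype=np.int64)
    idx = np.empty(n, dtype=np.int64)
    tmp = np.empty(n, dtype=np.int64)
    stack = np.empty((n + 8, 3), dtype=np.int64)
    featbuf = np.empty(p, dtype=np.int64)
    vals = np.empty(n, dtype=np.float64)
    labs = np.empty(n, dtype=np.int64)
    rows = np.empty(n, dtype=np.int64)

    for _t in range(n_trees):
        for i in range(n):
            rows[i] = _randbelow(state, n)
            idx[i] = i
        n_nodes = 1
        top = 0
        stack[0, 0] = 0
        stack[0, 1] = 0
        stack[0, 2] = n
        while top >= 0:
            node = stack[top, 0]
            s = stack[top, 1]
            e = stack[top, 2]
            top -= 1
            nn = e - s
            c1 = 0
            for i in range(s, e):
                c1 += ytr[rows[idx[i]]]
            if c1 == 0 or c1 == nn or nn < 2:
                feat[node] = -1
                pred[node] = 1 if 2 * c1 > nn else 0
                continue
            for j in range(p):
                featbuf[j] = j
            best_w = 1e300
            best_f = -1
            best_thr = 0.0
            for km in range(mtry):
                r = km + _randbelow(state, p - km)
                f = featbuf[r]
                featbuf[r] = featbuf[km]
                featbuf[km] = f
                for i in range(nn):
                    vals[i] = Xtr[rows[idx[s + i]], f]
                    labs[i] = ytr[rows[idx[s + i]]]
                # insertion sort by value, labels co-sorted
                for i in range(1, nn):
                    v = vals[i]
                    lb = labs[i]
                    j2 = i - 1
                    while j2 >= 0 and vals[j2] > v:
                        vals[j2 + 1] = vals[j2]
                        labs[j2 + 1] = labs[j2]
                        j2 -= 1
                    vals[j2 + 1] = v
                    labs[j2 + 1] = lb
                c1L = 0
                for i in range(nn - 1):
                    c1L += labs[i]
                    if vals[i + 1] > vals[i]:
                        nL = i + 1
                        nR = nn - nL
                        c1R = c1 - c1L
                        giniL = 1.0 - (c1L * c1L + (nL - c1L) * (nL - c1L)) / (nL * nL)
                        giniR = 1.0 - (c1R * c1R + (nR - c1R) * (nR - c1R)) / (nR * nR)
                        w = (nL * giniL + nR * giniR) / nn
                        if w < best_w - 1e-12:
                            best_w = w
                            best_f = f
                            best_thr = 0.5 * (vals[i] + vals[i + 1])
            if best_f < 0:
                # no candidate feature admits a split: majority leaf
                feat[node] = -1
                pred[node] = 1 if 2 * c1 > nn else 0
                continue
            # partition idx[s:e] by threshold (stable)
            k_lo = 0
            k_hi = 0
            for i in range(s, e):
                if Xtr[rows[idx[i]], best_f] <= best_thr:
                    tmp[k_lo] = idx[i]
                    k_lo += 1
            for i in range(s, e):
                if Xtr[rows[idx[i]], best_f] > best_thr:
                    tmp[k_lo + k_hi] = idx[i]
                    k_hi += 1
            for i in range(nn):
                idx[s + i] = tmp[i]
            lch = n_nodes
            rch = n_nodes + 1
            n_nodes += 2
            feat[node] = best_f
            thr[node] = best_thr
            left[node] = lch
            right[node] = rch
            top += 1
            stack[top, 0] = lch
            stack[top, 1] = s
            stack[top, 2] = s + k_lo
            top += 1
            stack[top, 0] = rch
            stack[top, 1] = s + k_lo
            stack[top, 2] = e
        # predict test rows with this tree
        for i in range(nte):
            node = 0
            while feat[node] >= 0:
                if Xte[i, feat[node]] <= thr[node]:
                    node = left[node]
                else:
                    node = right[node]
            votes[i] += pred[node]
    return votes / n_trees


def forest_votes(Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray,
                 n_trees: int = 100, max_features: int | None = None,
                 seed: int = 0) -> np.ndarray:
    """Train a compiled forest on (Xtr, ytr in {0,1}) and vote on Xte."""
    Xtr = np.ascontiguousarray(Xtr, dtype=np.float64)
    Xte = np.ascontiguousarray(Xte, dtype=np.float64)
    ytr = np.ascontiguousarray(ytr, dtype=np.int64)
    p = Xtr.shape[1]
    if max_features is None:
        max_features = max(1, int(np.floor(np.sqrt(p))))
    return _forest_votes(Xtr, ytr, Xte, int(n_trees), int(max_features),
                         int(seed) % (2 ** 31))
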