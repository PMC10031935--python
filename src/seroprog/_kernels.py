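"""Compiled inner loop for the survival-tree split search.

The log-rank statistic for every candidate threshold of a feature can be
maintained incrementally while samples move from the right to the left
group: moving a sample at event-time index ti updates O - E and the variance
for the event times it is at risk for. The numba kernel below does exactly
what :func:`seroprog.survival._best_split_numpy` does, in O(n * m) simple
flops per feature; the numpy version doubles as its correctness oracle.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def best_split_kernel(Xnode, ti, di, Y, D, candidates, min_leaf):  # pragma: no cover
    """Return (feature, threshold, statistic) of the best log-rank split.

    Parameters
    ----------
    Xnode : (n, p) float64 node feature matrix
    ti : (n,) int64, index of the last node event time each sample is at
        risk for (-1 if at risk for none)
    di : (n,) bool, True when the sample dies at its event time
    Y, D : (m,) float64, at-risk and death counts at each node event time
    candidates : sorted int64 candidate feature indices
    min_leaf : minimum samples per child
    """
    n = Xnode.shape[0]
    m = Y.shape[0]
    best_feat = -1
    best_thr = 0.0
    best_stat = 0.0
    w = np.empty(m)
    u = np.empty(m)
    for j in range(m):
        w[j] = D[j] / Y[j]
        if Y[j] > 1.0:
            u[j] = D[j] * (Y[j] - D[j]) / ((Y[j] - 1.0) * Y[j] * Y[j])
        else:
            u[j] = 0.0
    Y1 = np.empty(m)
    x = np.empty(n)
    for c in range(candidates.shape[0]):
        f = candidates[c]
        for i in range(n):
            x[i] = Xnode[i, f]
        order = np.argsort(x, kind="mergesort")
        for j in range(m):
            Y1[j] = 0.0
        OE = 0.0
        V = 0.0
        for kk in range(n - 1):
            i = order[kk]
            t_idx = ti[i]
            if di[i]:
                OE += 1.0
            for j in range(t_idx + 1):
                OE -= w[j]
                V += u[j] * (Y[j] - 2.0 * Y1[j] - 1.0)
                Y1[j] += 1.0
            k = kk + 1
            if k < min_leaf or n - k < min_leaf:
                continue
            x_lo = x[order[kk]]
            x_hi = x[order[kk + 1]]
            if x_hi <= x_lo:
                continue
            if V > 1e-300:
                stat = OE * OE / V
                if stat > best_stat:
                    best_stat = stat
                    best_feat = f
                    best_thr = 0.5 * (x_lo + x_hi)
    return best_feat, best_thr, best_stat


@njit(cache=True)
def tree_sum_mortality(X, feat, thr, left, right, mort, roots, sel):  # pragma: no cover
    """Sum of leaf mortalities over the selected trees for each row of X."""
    n = X.shape[0]
    out = np.zeros(n)
    for s in range(sel.shape[0]):
        root = roots[sel[s]]
        for i in range(n):
            node = root
            while feat[node] >= 0:
                if X[i, feat[node]] <= thr[node]:
                    node = left[node]
                else:
                    node = right[node]
            out[i] += mort[node]
    return out


@njit(cache=True)
def per_tree_mortality(X, feat, thr, left, right, mort, roots, sel):  # pragma: no cover
    """(len(sel), n) matrix of leaf mortalities, one row per selected tree."""
    n = X.shape[0]
    out = np.empty((sel.shape[0], n))
    for s in range(sel.shape[0]):
        root = roots[sel[s]]
        for i in range(n):
            node = root
            while feat[node] >= 0:
                if X[i, feat[node]] <= thr[node]:
                    node = left[node]
                else:
                    node = right[node]
            out[s, i] = mort[node]
    return out
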