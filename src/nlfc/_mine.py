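"""Grid-search kernels for the maximal information coefficient.

The characteristic matrix entry ``m[p][q]`` records, for a grid with ``p``
column bins and ``q`` row bins subject to the resolution budget
``p * q <= B(n)``, the largest mutual information achievable by an
axis-aligned grid of that shape, normalised by ``log2 min(p, q)``.

The exact maximisation is combinatorial, so the search approximates it in
the usual way: rows are fixed first, and the column axis is then optimised
exactly by dynamic programming over "clump" boundaries — maximal runs of
consecutive points sharing a row bin, with equal-valued points never
separated, and at most ``cmax`` times the column budget of clumps kept (by
merging adjacent ones) to bound the DP cost.  Row partitions are chosen in
one of two ways: when few enough are possible (small samples or coarse
grids) every legal row partition is enumerated, making the search exact for
that shape; otherwise the single (near) equal-frequency partition is used,
the standard large-sample heuristic.  Both axis orientations are evaluated
and merged cell-wise.

Entries the search never reaches are left at -1 and masked by the caller.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1.0e18

#: Enumerate all row partitions for a shape when their count is at most
#: this; beyond it, fall back to the equal-frequency partition.
ENUM_CAP = 32


@njit(cache=False)
def _optimize_columns(xs, rows, q_eff, pmax, cmax, n, M):
    """Exact DP over column cuts for a fixed row assignment.

    Updates ``M[p, q_eff]`` in place for p = 2..pmax with the normalised
    maximal mutual information over grids with at most p columns.
    """
    # clumps along x: cuts are legal only between distinct x values, and a
    # clump extends while consecutive points share a row bin
    clump_id = np.empty(n, np.int64)
    T = 0
    clump_id[0] = 0
    curr_row = rows[0]
    curr_pure = True
    for t in range(1, n):
        if xs[t] == xs[t - 1]:
            clump_id[t] = T
            if rows[t] != curr_row:
                curr_pure = False
        elif curr_pure and rows[t] == curr_row:
            clump_id[t] = T
        else:
            T += 1
            clump_id[t] = T
            curr_row = rows[t]
            curr_pure = True
    nclumps = T + 1

    # cap the DP size: merge adjacent clumps into <= cmax*pmax superclumps
    kmax = cmax * pmax
    if kmax < 2:
        kmax = 2
    if nclumps > kmax:
        size = np.zeros(nclumps, np.int64)
        for t in range(n):
            size[clump_id[t]] += 1
        group = np.empty(nclumps, np.int64)
        before = 0
        g_prev = 0
        for c in range(nclumps):
            g = int(before * kmax / n)
            if g >= kmax:
                g = kmax - 1
            if g < g_prev:
                g = g_prev
            group[c] = g
            g_prev = g
            before += size[c]
        for t in range(n):
            clump_id[t] = group[clump_id[t]]
        nclumps = group[nclumps - 1] + 1

    T = nclumps
    cum = np.zeros((T + 1, q_eff), np.int64)
    for t in range(n):
        cum[clump_id[t] + 1, rows[t]] += 1
    for c in range(1, T + 1):
        for r in range(q_eff):
            cum[c, r] += cum[c - 1, r]
    cumtot = np.zeros(T + 1, np.int64)
    for c in range(1, T + 1):
        s = 0
        for r in range(q_eff):
            s += cum[c, r]
        cumtot[c] = s

    HQ = 0.0
    for r in range(q_eff):
        p_r = cum[T, r] / n
        if p_r > 0.0:
            HQ -= p_r * np.log2(p_r)

    # column contribution of clump interval (s, t]; I(P;Q) = H(Q) + sum of
    # per-column terms, so the objective is additive over columns
    C = np.zeros((T + 1, T + 1))
    for s in range(T):
        for t in range(s + 1, T + 1):
            tot = cumtot[t] - cumtot[s]
            if tot == 0:
                continue
            val = -(tot / n) * np.log2(tot / n)
            for r in range(q_eff):
                cell = cum[t, r] - cum[s, r]
                if cell > 0:
                    val += (cell / n) * np.log2(cell / n)
            C[s, t] = val

    F = np.full((T + 1, pmax + 1), NEG)
    for t in range(1, T + 1):
        F[t, 1] = C[0, t]
    for l in range(2, pmax + 1):
        for t in range(l, T + 1):
            best = NEG
            for s in range(l - 1, t):
                v = F[s, l - 1] + C[s, t]
                if v > best:
                    best = v
            F[t, l] = best

    best_I = 0.0  # the trivial 1-column grid carries no information
    for p in range(2, pmax + 1):
        if p <= T and F[T, p] > NEG / 2.0:
            I = HQ + F[T, p]
            if I > best_I:
                best_I = I
        denom = np.log2(min(p, q_eff))
        m = best_I / denom
        if m > M[p, q_eff]:
            M[p, q_eff] = m


@njit(cache=False)
def _oriented_char_matrix(xs, ys, y_order, B, cmax):
    """One orientation of the search: columns optimised on the ``xs`` axis,
    rows partitioned on the ``ys`` axis.  Points arrive sorted by ``xs``;
    ``y_order`` is the argsort of ``ys``."""
    n = xs.shape[0]
    M = np.full((B + 1, B + 1), -1.0)

    # distinct-value group index of each point along y
    grp = np.empty(n, np.int64)
    du = 0
    grp[y_order[0]] = 0
    for k in range(1, n):
        if ys[y_order[k]] != ys[y_order[k - 1]]:
            du += 1
        grp[y_order[k]] = du
    du += 1

    rows = np.empty(n, np.int64)
    maxq = B // 2
    for q in range(2, maxq + 1):
        pmax = B // q
        if pmax < 2:
            break
        ncuts = du - 1
        k = q - 1
        if k > ncuts:
            continue

        # number of legal row partitions: C(ncuts, k)
        ncomb = 1
        for i in range(k):
            ncomb = ncomb * (ncuts - i) // (i + 1)
            if ncomb > ENUM_CAP:
                break

        if ncomb <= ENUM_CAP:
            # exact: enumerate every choice of k cuts between y groups
            cut = np.arange(k)
            while True:
                for t in range(n):
                    r = 0
                    for c in range(k):
                        if cut[c] < grp[t]:
                            r += 1
                    rows[t] = r
                _optimize_columns(xs, rows, q, pmax, cmax, n, M)
                i = k - 1
                while i >= 0 and cut[i] == ncuts - k + i:
                    i -= 1
                if i < 0:
                    break
                cut[i] += 1
                for j in range(i + 1, k):
                    cut[j] = cut[j - 1] + 1
        else:
            # heuristic: single near-equal-frequency partition, ties kept
            curr = 0
            in_curr = 0
            i = 0
            target = n / q
            while i < n:
                j = i
                v = ys[y_order[i]]
                while j < n and ys[y_order[j]] == v:
                    j += 1
                s = j - i
                if (
                    in_curr > 0
                    and curr < q - 1
                    and abs(in_curr + s - target) >= abs(in_curr - target)
                ):
                    curr += 1
                    in_curr = 0
                    target = (n - i) / (q - curr)
                for t in range(i, j):
                    rows[y_order[t]] = curr
                in_curr += s
                i = j
            q_eff = curr + 1
            if q_eff >= 2:
                _optimize_columns(xs, rows, q_eff, pmax, cmax, n, M)
    return M


def char_matrix_search(x: np.ndarray, y: np.ndarray, B: int, cmax: int) -> np.ndarray:
    """Run the search in both orientations and merge cell-wise."""
    ox = np.argsort(x, kind="mergesort")
    xs, ys = x[ox], y[ox]
    m1 = _oriented_char_matrix(xs, ys, np.argsort(ys, kind="mergesort"), B, cmax)
    oy = np.argsort(y, kind="mergesort")
    xs2, ys2 = y[oy], x[oy]
    m2 = _oriented_char_matrix(xs2, ys2, np.argsort(ys2, kind="mergesort"), B, cmax)
    return np.maximum(m1, m2.T)
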