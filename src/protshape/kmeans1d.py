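"""Seeded 1-D K-means: Lloyd iterations plus interval-based merge-split refinement.

One-dimensional K-means has special structure: every optimal (and every
Lloyd-stationary) clustering partitions the sorted values into contiguous
intervals.  Plain Lloyd from random initial centers routinely stalls 10-50 %
above the optimal within-cluster sum of squares (WCSS) once K grows past a
handful, because fixing a misallocation of centers between modes requires a
coordinated move of many boundaries.  The solver here therefore descends in
the interval representation with exact merge-split moves (delete the cheapest
boundary, re-insert the most profitable one), which teleports centers across
the data in one step, and finishes with a short iterated-local-search phase
whose kick moves escape merge-split-stationary configurations.  Initial
centers are data points: uniform draws and D^2-weighted (k-means++ style)
draws, all from one seed, so the result is deterministic.

All state flows through explicit ``numpy`` generators; WCSS never increases
along accepted moves.
"""

from __future__ import annotations

import numpy as np


def _lloyd(x: np.ndarray, centers: np.ndarray, max_iter: int, tol: float) -> np.ndarray:
    """Classic Lloyd on scalars; ties go to the lower-indexed center and empty
    clusters are re-seeded with the point farthest from its current center."""
    K = len(centers)
    centers = centers.copy()
    for _ in range(max_iter):
        labels = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
        new = centers.copy()
        for k in range(K):
            pts = x[labels == k]
            if len(pts):
                new[k] = pts.mean()
            else:
                far = int(np.argmax(np.abs(x - new[labels])))
                new[k] = x[far]
                labels[far] = k
        shift = np.abs(new - centers).max()
        centers = new
        if shift < tol:
            break
    return centers


class _Prefix:
    """Prefix sums over the sorted values; O(1) interval WCSS."""

    def __init__(self, xs: np.ndarray):
        self.xs = xs
        self.s = np.concatenate([[0.0], np.cumsum(xs)])
        self.s2 = np.concatenate([[0.0], np.cumsum(xs * xs)])

    def cost(self, i: int, j: int) -> float:
        if j - i < 2:
            return 0.0
        t = self.s[j] - self.s[i]
        return (self.s2[j] - self.s2[i]) - t * t / (j - i)

    def mean(self, i: int, j: int) -> float:
        if j <= i:
            return float(self.xs[min(i, len(self.xs) - 1)])
        return (self.s[j] - self.s[i]) / (j - i)


def _interval_lloyd(P: _Prefix, b: np.ndarray, K: int, iters: int = 100) -> np.ndarray:
    """Alternate center update / boundary update until the partition is stable."""
    xs = P.xs
    for _ in range(iters):
        centers = np.sort([P.mean(b[k], b[k + 1]) for k in range(K)])
        nb = np.concatenate([[0], np.searchsorted(xs, (centers[:-1] + centers[1:]) / 2),
                             [len(xs)]])
        if np.array_equal(nb, b):
            break
        b = nb
    return b


def _move_tables(P: _Prefix, b: np.ndarray, K: int):
    """Exact cost of merging each adjacent pair and best split of each interval."""
    costs = np.array([P.cost(b[k], b[k + 1]) for k in range(K)])
    merge_inc = np.array([P.cost(b[k], b[k + 2]) - costs[k] - costs[k + 1]
                          for k in range(K - 1)])
    split_dec = np.full(K, -np.inf)
    split_at = np.zeros(K, dtype=np.int64)
    for k in range(K):
        i, j = b[k], b[k + 1]
        if j - i < 2:
            continue
        m = np.arange(i + 1, j)
        two = ((P.s2[m] - P.s2[i]) - (P.s[m] - P.s[i]) ** 2 / (m - i)
               + (P.s2[j] - P.s2[m]) - (P.s[j] - P.s[m]) ** 2 / (j - m))
        best = int(np.argmin(two))
        split_dec[k] = costs[k] - two[best]
        split_at[k] = m[best]
    return merge_inc, split_dec, split_at


def _descend(P: _Prefix, b: np.ndarray, K: int, max_moves: int = 300) -> np.ndarray:
    """Greedy best merge-split moves until no move lowers the WCSS."""
    b = _interval_lloyd(P, b, K)
    for _ in range(max_moves):
        merge_inc, split_dec, split_at = _move_tables(P, b, K)
        best_gain, best = 1e-15, None
        for bm in range(K - 1):
            for bs in range(K):
                if bs == bm or bs == bm + 1:
                    continue
                gain = split_dec[bs] - merge_inc[bm]
                if gain > best_gain:
                    best_gain, best = gain, (bm, bs)
        if best is None:
            break
        bm, bs = best
        nb = np.sort(np.insert(np.delete(b, bm + 1), 0, split_at[bs]))
        b = _interval_lloyd(P, nb, K)
    return b


def _kick(P: _Prefix, b: np.ndarray, K: int, rank: int) -> np.ndarray:
    """Apply the rank-th best merge-split pair regardless of sign (ILS kick)."""
    merge_inc, split_dec, split_at = _move_tables(P, b, K)
    pairs = [(bm, bs) for bm in range(K - 1) for bs in range(K)
             if bs != bm and bs != bm + 1 and np.isfinite(split_dec[bs])]
    if not pairs:
        return b
    pairs.sort(key=lambda p: -(split_dec[p[1]] - merge_inc[p[0]]))
    bm, bs = pairs[min(rank, len(pairs) - 1)]
    return np.sort(np.insert(np.delete(b, bm + 1), 0, split_at[bs]))


def _init_uniform(x: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    return x[rng.choice(len(x), size=K, replace=False)].copy()


def _init_dsquared(x: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++-style D^2 sampling of data points."""
    centers = [x[rng.integers(len(x))]]
    d2 = (x - centers[0]) ** 2
    for _ in range(K - 1):
        tot = d2.sum()
        p = d2 / tot if tot > 0 else None
        centers.append(x[rng.choice(len(x), p=p)])
        d2 = np.minimum(d2, (x - centers[-1]) ** 2)
    return np.asarray(centers)


def _total(P: _Prefix, b: np.ndarray, K: int) -> float:
    return float(sum(P.cost(b[k], b[k + 1]) for k in range(K)))


def solve(values, K: int, seed: int, max_iter: int = 100, tol: float = 1e-8,
          n_init: int = 3, ils_rounds: int = 8) -> np.ndarray:
    """K cluster means of 1-D data, ascending; deterministic under ``seed``.

    Runs ``n_init`` uniform-data-point and ``n_init`` D^2-weighted starts, each
    polished by Lloyd plus merge-split descent, then ``ils_rounds`` kick/descend
    cycles from the incumbent; returns the best solution's interval means.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    n = len(x)
    if n < K:
        raise ValueError(f"{n} values cannot support K={K} clusters; use a smaller K")
    xs = np.sort(x)
    P = _Prefix(xs)
    streams = [np.random.default_rng(int(s.generate_state(1)[0] % 2**31))
               for s in np.random.SeedSequence(seed).spawn(2 * n_init)]
    inits = [_init_uniform(x, K, r) for r in streams[:n_init]]
    inits += [_init_dsquared(x, K, r) for r in streams[n_init:]]
    best_b, best_w = None, np.inf
    for c0 in inits:
        c = np.sort(_lloyd(x, c0, max_iter, tol))
        b0 = np.concatenate([[0], np.searchsorted(xs, (c[:-1] + c[1:]) / 2), [n]])
        b = _descend(P, b0, K)
        w = _total(P, b, K)
        if w < best_w:
            best_w, best_b = w, b
    cur = best_b
    for r in range(ils_rounds):
        b = _descend(P, _kick(P, cur, K, rank=r), K)
        w = _total(P, b, K)
        if w < best_w - 1e-15:
            best_w, best_b = w, b
        cur = b  # walk on even without improvement; incumbent is kept separately
    return np.array([P.mean(best_b[k], best_b[k + 1]) for k in range(K)])
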