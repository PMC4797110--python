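"""Independent brute-force oracles the production code is checked against."""

import numpy as np


def grey_relation_naive(X, Y):
    """Literal double-loop transcription of the grey relation degree formulas."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    m, n = X.shape

    def eps(s, t):
        return (1 + abs(s) + abs(t)) / (1 + abs(s) + abs(t) + abs(s - t))

    row_eps = []
    for k in range(m):
        s = sum(X[k, q] - X[k, 0] for q in range(n))
        t = sum(Y[k, q] - Y[k, 0] for q in range(n))
        row_eps.append(eps(s, t))
    col_eps = []
    for k in range(n):
        s = sum(X[q, k] - X[0, k] for q in range(m))
        t = sum(Y[q, k] - Y[0, k] for q in range(m))
        col_eps.append(eps(s, t))
    return 0.5 * (sum(row_eps) / m + sum(col_eps) / n)


def kmeans_1d_optimal_wcss(values, K):
    """Exact optimal within-cluster sum of squares for 1-D K-means.

    Dynamic programming over the sorted values: optimal clusters are
    contiguous runs, so D[k][j] = min_i D[k-1][i] + cost(i, j).
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    ps = np.concatenate([[0.0], np.cumsum(x)])
    ps2 = np.concatenate([[0.0], np.cumsum(x * x)])
    D = np.full((K + 1, n + 1), np.inf)
    D[0, 0] = 0.0
    for k in range(1, K + 1):
        for j in range(k, n + 1):
            i = np.arange(k - 1, j)
            cost = (ps2[j] - ps2[i]) - (ps[j] - ps[i]) ** 2 / (j - i)
            D[k, j] = (D[k - 1, i] + cost).min()
    return float(D[K, n])


def wcss(values, centers):
    """WCSS of assigning each value to its nearest center."""
    x = np.asarray(values, dtype=float)
    c = np.asarray(centers, dtype=float)
    nearest = c[np.argmin(np.abs(x[:, None] - c[None, :]), axis=1)]
    return float(((x - nearest) ** 2).sum())
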