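"""Matrix-extended grey relation degree: the similarity score between descriptors.

Grey relational analysis compares sequences through their cumulative deviation
from a zero-start image (each line minus its first element), which makes the
degree blind to additive offsets.  Extended to matrices, the degree averages a
row-wise and a column-wise relation coefficient:

    eps(k) = (1 + |s(k)| + |t(k)|) / (1 + |s(k)| + |t(k)| + |s(k) - t(k)|)

with s(k), t(k) the summed zero-start images of line k of X and Y, and

    eta = 1/2 * (mean_k eps_rows(k) + mean_k eps_cols(k))  in (0, 1].

eta = 1 iff every line's cumulative deviations coincide (in particular for
X = Y); the measure is symmetric in its arguments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class GreyRelationResult:
    eta: float
    row_degrees: np.ndarray
    col_degrees: np.ndarray


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.size == 0:
        raise ValueError("expected a non-empty 2-D matrix")
    return X


def zero_start_rows(X) -> np.ndarray:
    """Subtract each row's first element from the row: x'(k, q) = x(k, q) - x(k, 1)."""
    X = _as_matrix(X)
    return X - X[:, :1]


def directional_degrees(X, Y, axis: str = "rows") -> np.ndarray:
    """Grey relation coefficient eps(k) per row (or per column) of X vs Y.

    Every coefficient lies in (0, 1], reaching 1 exactly when the two lines'
    summed zero-start images agree.
    """
    X, Y = _as_matrix(X), _as_matrix(Y)
    if X.shape != Y.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {Y.shape}")
    if axis == "columns":
        X, Y = X.T, Y.T
    elif axis != "rows":
        raise ValueError("axis must be 'rows' or 'columns'")
    s = zero_start_rows(X).sum(axis=1)
    t = zero_start_rows(Y).sum(axis=1)
    base = 1.0 + np.abs(s) + np.abs(t)
    return base / (base + np.abs(s - t))


def matrix_grey_relation(X, Y) -> GreyRelationResult:
    """Grey relation degree eta of two equal-shaped matrices.

    eta = 1/2 (mean of row coefficients + mean of column coefficients); equals
    1 for X = Y and is invariant to adding a scalar constant to either matrix.
    """
    rows = directional_degrees(X, Y, "rows")
    cols = directional_degrees(X, Y, "columns")
    eta = 0.5 * (rows.mean() + cols.mean())
    return GreyRelationResult(float(eta), rows, cols)
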