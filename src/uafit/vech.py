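"""Fixed ordering of the non-redundant correlations of a p x p matrix.

Every vector of correlations in this package (sample estimates, model-implied
values, rows/columns of Gamma and of the GLS weight matrix) uses one single
ordering: the strict lower triangle, column-major, 0-based.  For p = 4 that is
(1,0), (2,0), (3,0), (2,1), (3,1), (3,2).
"""

from __future__ import annotations

import numpy as np


def n_pairs(p: int) -> int:
    return p * (p - 1) // 2


def pair_indices(p: int) -> tuple[np.ndarray, np.ndarray]:
    """Row and column index arrays (i > j) in the canonical ordering."""
    rows = []
    cols = []
    for j in range(p):
        for i in range(j + 1, p):
            rows.append(i)
            cols.append(j)
    return np.asarray(rows, dtype=np.intp), np.asarray(cols, dtype=np.intp)


def vech_off(M: np.ndarray) -> np.ndarray:
    """Extract the strict lower triangle of a symmetric matrix as a vector."""
    M = np.asarray(M, dtype=float)
    p = M.shape[0]
    rows, cols = pair_indices(p)
    return M[rows, cols].copy()


def unvech_off(v: np.ndarray, p: int) -> np.ndarray:
    """Embed a correlation vector into a symmetric matrix with unit diagonal."""
    v = np.asarray(v, dtype=float)
    if v.shape != (n_pairs(p),):
        raise ValueError(
            f"correlation vector has length {v.size}, expected {n_pairs(p)} for p={p}"
        )
    M = np.eye(p)
    rows, cols = pair_indices(p)
    M[rows, cols] = v
    M[cols, rows] = v
    return M
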