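"""Half-vectorization (vech) basis shared by every moment matrix.

All p* x p* matrices in this package (Gamma-hat, the normal-theory weight
matrix, the residual matrix U) and the p* x q Jacobian live in the same
vech basis: the lower triangle of a symmetric p x p matrix, ordered
column-major, so element a of the basis corresponds to the pair
(row_index[a], col_index[a]) with row >= col.  Keeping a single source of
truth here avoids duplication-matrix mismatches between modules.
"""

from __future__ import annotations

import numpy as np

__all__ = ["vech_indices", "vech", "unvech", "p_star"]


def p_star(p: int) -> int:
    """Number of unique elements of a symmetric p x p matrix, p(p+1)/2."""
    return p * (p + 1) // 2


def vech_indices(p: int) -> tuple[np.ndarray, np.ndarray]:
    """Row and column index arrays of the vech basis for dimension ``p``.

    Lower triangle, column-major: (0,0), (1,0), ..., (p-1,0), (1,1), ...
    """
    cols, rows = np.triu_indices(p)  # upper triangle row-major == lower col-major
    return rows, cols


def vech(mat: np.ndarray) -> np.ndarray:
    """Half-vectorize a symmetric matrix into the shared basis."""
    rows, cols = vech_indices(mat.shape[0])
    return np.asarray(mat)[rows, cols]


def unvech(v: np.ndarray) -> np.ndarray:
    """Inverse of :func:`vech`: rebuild the symmetric matrix."""
    n = v.shape[0]
    p = int((np.sqrt(8 * n + 1) - 1) / 2)
    if p_star(p) != n:
        raise ValueError(f"length {n} is not a triangular number")
    rows, cols = vech_indices(p)
    out = np.zeros((p, p), dtype=float)
    out[rows, cols] = v
    out[cols, rows] = v
    return out
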