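"""Matrix permanent of non-negative matrices, in log space.

The normalising constant of the assignment posterior is a sum over all
bijections of products of likelihoods — algebraically the permanent of the
likelihood matrix.  We compute it exactly with Ryser's inclusion–exclusion
formula using Gray-code subset updates, O(2^n · n).  Rows are rescaled by
their maxima (accumulated in log space) before the alternating sum, so the
computation stays finite for likelihoods spanning hundreds of orders of
magnitude.

The permanent is returned as ``(log_permanent, sign)`` where sign 1 means a
strictly positive permanent and sign 0 a structurally or numerically zero one
(log value -inf); a zero permanent means no feasible assignment.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import UsageError

#: Hard cap on exact permanent computation (2^n subsets).
N_PERM_MAX = 22


def permanent_scaled(M: np.ndarray, n_perm_max: int = N_PERM_MAX) -> tuple[float, int]:
    """Log permanent of a non-negative square matrix via scaled Ryser.

    Parameters
    ----------
    M : ndarray, shape (n, n)
        Non-negative entries; zeros allowed.
    n_perm_max : int
        Refuse matrices larger than this (worst-case 2^n work).

    Returns
    -------
    (log_perm, sign) : tuple
        ``sign`` is 1 for a positive permanent, 0 for a zero permanent
        (``log_perm`` is then ``-inf``).
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise UsageError(f"permanent requires a square matrix, got shape {M.shape}")
    n = M.shape[0]
    if n > n_perm_max:
        raise UsageError(
            f"matrix size {n} exceeds the exact-permanent limit n <= {n_perm_max}"
        )
    if np.any(M < 0) or not np.all(np.isfinite(M)):
        raise UsageError("permanent requires finite non-negative entries")
    if n == 0:
        return 0.0, 1  # empty product convention

    row_max = M.max(axis=1)
    col_max = M.max(axis=0)
    if np.any(row_max == 0.0) or np.any(col_max == 0.0):
        return -math.inf, 0  # an all-zero row or column kills every permutation

    S = M / row_max[:, None]
    log_scale = float(np.log(row_max).sum())

    total = 0.0
    rowsum = np.zeros(n)
    cols = [S[:, j].copy() for j in range(n)]
    prev_gray = 0
    for k in range(1, 1 << n):
        gray = k ^ (k >> 1)
        diff = gray ^ prev_gray
        j = diff.bit_length() - 1
        if gray & diff:
            rowsum += cols[j]
        else:
            rowsum -= cols[j]
        prev_gray = gray
        prod = float(rowsum.prod())
        # sign of the Ryser term: (-1)^(n - |S|)
        if (n - gray.bit_count()) & 1:
            total -= prod
        else:
            total += prod
    if total <= 0.0:
        # Alternating-sum cancellation can leave a tiny negative residue for a
        # permanent that is structurally zero; report it as zero.
        return -math.inf, 0
    return math.log(total) + log_scale, 1
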