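"""Small numerical helpers shared across analysis stages."""

from __future__ import annotations

import numpy as np

__all__ = ["nan_pearson"]


def nan_pearson(A: np.ndarray, B: np.ndarray | None = None, min_overlap: int = 2) -> np.ndarray:
    """Pairwise-complete Pearson correlation between the rows of ``A`` and ``B``.

    For each pair of rows only the columns that are non-missing in *both* rows
    enter the correlation. Pairs with fewer than ``min_overlap`` shared columns,
    or with zero variance on the shared columns, yield NaN.

    Implemented with masked matrix products so the full pairwise computation is
    a handful of BLAS calls rather than a Python loop over row pairs.

    Parameters
    ----------
    A : (n, p) array with NaN marking missing entries.
    B : (m, p) array, optional. Defaults to ``A`` (symmetric case).
    min_overlap : minimum number of jointly observed columns.

    Returns
    -------
    (n, m) array of correlations.
    """
    A = np.asarray(A, dtype=float)
    B = A if B is None else np.asarray(B, dtype=float)
    if A.ndim != 2 or B.ndim != 2 or A.shape[1] != B.shape[1]:
        raise ValueError("A and B must be 2-D with matching column counts")

    Ma = np.isfinite(A).astype(float)
    Mb = np.isfinite(B).astype(float)
    A0 = np.where(Ma > 0, A, 0.0)
    B0 = np.where(Mb > 0, B, 0.0)

    n = Ma @ Mb.T
    sx = A0 @ Mb.T
    sy = Ma @ B0.T
    sxx = (A0 * A0) @ Mb.T
    syy = Ma @ (B0 * B0).T
    sxy = A0 @ B0.T

    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        vx = sxx - sx * sx / n
        vy = syy - sy * sy / n
        # guard tiny negative round-off
        vx = np.where(vx < 0, 0.0, vx)
        vy = np.where(vy < 0, 0.0, vy)
        r = cov / np.sqrt(vx * vy)

    bad = (n < max(min_overlap, 2)) | ~np.isfinite(r)
    r = np.where(bad, np.nan, r)
    return np.clip(r, -1.0, 1.0, out=r)
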