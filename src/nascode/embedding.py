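"""Spectral embedding of the trial-by-trial sequence correlation matrix.

Each trial's sequence vector (per-unit peak firing times, missing entries
allowed) is compared with every other trial's by Pearson correlation over the
jointly observed units, giving a symmetric T x T matrix X. Trials are embedded
by projecting X onto its leading eigenvectors: with Q = [v1 .. vk] ordered by
eigenvalue modulus, the coordinates are P = X Q. Condition centroids in this
space, and the Euclidean distances between them, summarize how discriminable
the sequences of different remembered targets are.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from ._stats import nan_pearson

__all__ = [
    "Projection",
    "sequence_correlation_matrix",
    "spectral_projection",
    "condition_centroids",
    "embed",
]


@dataclass
class Projection:
    """Eigen-projection of a trial correlation matrix.

    Attributes
    ----------
    X : T x T correlation matrix (DataFrame, trial-id indexed).
    eigenvalues : all T eigenvalues ordered by decreasing modulus.
    Q : T x k matrix of the leading eigenvectors (columns follow the ordering).
    P : T x k coordinates, P = X Q (DataFrame, trial-id indexed).
    """

    X: pd.DataFrame
    eigenvalues: np.ndarray
    Q: np.ndarray
    P: pd.DataFrame


def sequence_correlation_matrix(seqs: pd.DataFrame, min_overlap: int = 10) -> pd.DataFrame:
    """Pearson correlation between every pair of trial sequence vectors.

    Correlations use pairwise-complete units (entries non-missing in both
    trials). Pairs with fewer than ``min_overlap`` shared units, or with no
    variance across shared units, are assigned 0 (neutral similarity). The
    diagonal is forced to 1 and the matrix exactly symmetrized.
    """
    if seqs.shape[0] < 2:
        raise ValueError("need at least two trials")
    counts = seqs.notna().sum(axis=1)
    starved = counts[counts < min_overlap]
    for tid, c in starved.items():
        warnings.warn(
            f"trial {tid} has only {int(c)} non-missing entries (< min_overlap={min_overlap})",
            stacklevel=2,
        )
    R = nan_pearson(seqs.to_numpy(dtype=float), min_overlap=min_overlap)
    R = np.nan_to_num(R, nan=0.0)
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    return pd.DataFrame(R, index=seqs.index, columns=seqs.index)


def spectral_projection(X: pd.DataFrame | np.ndarray, k: int = 3) -> Projection:
    """Project X onto its k leading eigenvectors (by eigenvalue modulus).

    X must be symmetric, so the spectrum is real. Ordering is by decreasing
    |lambda| with ties broken by ascending eigenvector index; each eigenvector's
    sign is fixed by making its largest-magnitude entry positive (all
    downstream distances are sign-invariant).
    """
    if isinstance(X, pd.DataFrame):
        idx = X.index
        M = X.to_numpy(dtype=float)
    else:
        M = np.asarray(X, dtype=float)
        idx = pd.RangeIndex(M.shape[0])
    if M.shape[0] != M.shape[1]:
        raise ValueError("X must be square")
    if not np.allclose(M, M.T, atol=1e-8):
        raise ValueError("X must be symmetric")
    T = M.shape[0]
    if k > T:
        raise ValueError(f"k={k} exceeds the number of trials T={T}")
    vals, vecs = np.linalg.eigh(M)
    order = np.argsort(-np.abs(vals), kind="stable")
    vals = vals[order]
    Q = vecs[:, order[:k]].copy()
    for j in range(k):
        i = int(np.argmax(np.abs(Q[:, j])))
        if Q[i, j] < 0:
            Q[:, j] = -Q[:, j]
    P = M @ Q
    Pdf = pd.DataFrame(P, index=idx, columns=[f"pc{j + 1}" for j in range(k)])
    Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(M)
    return Projection(X=Xdf, eigenvalues=vals, Q=Q, P=Pdf)


def condition_centroids(
    P: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    expected: list | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-condition centroid coordinates and their normalized distance matrix.

    ``labels`` gives one condition label per trial (aligned with P's rows).
    Returns ``(centroids, D)`` where D is the Euclidean distance matrix between
    centroids divided by its maximum entry (so max(D) == 1 exactly). If
    ``expected`` lists conditions and some have no trials, their rows/columns
    are present but NaN, with a warning.
    """
    lab = pd.Series(np.asarray(labels), index=P.index, name="condition")
    centroids = P.groupby(lab).mean()
    centroids = centroids.sort_index()
    if expected is not None:
        missing = [c for c in expected if c not in centroids.index]
        if missing:
            warnings.warn(f"conditions with no trials: {missing}", stacklevel=2)
        centroids = centroids.reindex(expected)
    pts = centroids.to_numpy(dtype=float)
    finite = np.isfinite(pts).all(axis=1)
    D = np.full((len(centroids), len(centroids)), np.nan)
    sub = cdist(pts[finite], pts[finite])
    if sub.size and np.nanmax(sub) > 0:
        sub = sub / sub.max()
    ij = np.where(finite)[0]
    D[np.ix_(ij, ij)] = sub
    Ddf = pd.DataFrame(D, index=centroids.index, columns=centroids.index)
    return centroids, Ddf


def embed(
    seqs: pd.DataFrame,
    labels: pd.Series | np.ndarray | None = None,
    k: int = 3,
    min_overlap: int = 10,
) -> tuple[Projection, pd.DataFrame | None, pd.DataFrame | None]:
    """Convenience wrapper: correlation matrix -> projection -> centroids.

    Returns ``(projection, centroids, centroid_D)``; the latter two are None
    when no labels are supplied.
    """
    X = sequence_correlation_matrix(seqs, min_overlap=min_overlap)
    proj = spectral_projection(X, k=k)
    if labels is None:
        return proj, None, None
    centroids, D = condition_centroids(proj.P, labels)
    return proj, centroids, D
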