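"""Trajectory analysis and the sequence-behavior link.

Movement paths recorded in 3-D world coordinates are mapped to the subject's
2-D screen view with a pinhole perspective camera, averaged per target, and
compared pairwise with the discrete Frechet distance. The resulting 9x9
trajectory-distance matrix is rank-correlated (Spearman) with the 9x9
sequence-centroid distance matrix from :mod:`nascode.embedding`; a label-shuffle
null and a unit-ablation curve quantify the strength and robustness of that
link.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import spearmanr

from .embedding import condition_centroids, sequence_correlation_matrix, spectral_projection

__all__ = [
    "Camera",
    "project_points",
    "project_trajectory",
    "resample_path",
    "average_trajectory",
    "average_trajectories_by_target",
    "discrete_frechet",
    "frechet_matrix",
    "link_correlation",
    "shuffle_link",
    "ablation_curve",
    "target_distance_matrix",
    "straight_line_paths",
]


@dataclass(frozen=True)
class Camera:
    """Pinhole camera looking down the +y (depth) axis.

    ``eye`` is the optical center in world units. The horizontal field of view
    sets the focal length in pixels; square pixels are assumed. Points closer
    than ``near`` (world units in front of the eye) are dropped on projection.
    """

    eye: tuple[float, float, float] = (0.0, 0.0, 100.0)
    hfov_deg: float = 90.0
    width: int = 1024
    height: int = 768
    near: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.hfov_deg < 180.0:
            raise ValueError("horizontal field of view must be in (0, 180) degrees")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("screen dimensions must be positive")

    @property
    def focal_px(self) -> float:
        return (self.width / 2.0) / np.tan(np.deg2rad(self.hfov_deg) / 2.0)


def project_points(points: np.ndarray, camera: Camera) -> np.ndarray:
    """Perspective-project world points (N, 3) to screen pixels (N, 2).

    World axes: x right, y forward (depth), z up. Screen origin top-left,
    x right, y down. Points behind the near plane are dropped with a warning.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ValueError("empty point set")
    rel = pts - np.asarray(camera.eye, dtype=float)
    depth = rel[:, 1]
    keep = depth >= camera.near
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} point(s) behind the near plane", stacklevel=2
        )
    rel = rel[keep]
    if rel.shape[0] == 0:
        raise ValueError("no points in front of the camera")
    f = camera.focal_px
    sx = camera.width / 2.0 + f * rel[:, 0] / rel[:, 1]
    sy = camera.height / 2.0 - f * rel[:, 2] / rel[:, 1]
    return np.column_stack([sx, sy])


def project_trajectory(path3d: np.ndarray, camera: Camera) -> np.ndarray:
    """Project an ordered 3-D path to an ordered 2-D screen trajectory."""
    return project_points(path3d, camera)


def resample_path(path: np.ndarray, n_points: int = 50) -> np.ndarray:
    """Resample an ordered path to ``n_points`` equally spaced by arc length."""
    p = np.atleast_2d(np.asarray(path, dtype=float))
    if p.shape[0] == 1:
        return np.repeat(p, n_points, axis=0)
    seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0.0:
        return np.repeat(p[:1], n_points, axis=0)
    t = np.linspace(0.0, s[-1], n_points)
    return np.column_stack([np.interp(t, s, p[:, k]) for k in range(p.shape[1])])


def discrete_frechet(A: np.ndarray, B: np.ndarray) -> float:
    """Discrete Frechet distance between two ordered point lists.

    Dynamic program over the coupling lattice with Euclidean ground metric:
    ``dp[i, j]`` is the minimal leash length for walking prefixes ``A[:i+1]``
    and ``B[:j+1]`` with monotone, stepwise advances.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[0] == 0 or B.shape[0] == 0:
        raise ValueError("both trajectories must be non-empty")
    d = cdist(A, B).tolist()
    n, m = len(d), len(d[0])
    prev = [0.0] * m
    row = d[0]
    prev[0] = row[0]
    for j in range(1, m):
        prev[j] = prev[j - 1] if prev[j - 1] > row[j] else row[j]
    for i in range(1, n):
        cur = [0.0] * m
        row = d[i]
        cur[0] = prev[0] if prev[0] > row[0] else row[0]
        for j in range(1, m):
            best = prev[j]
            if prev[j - 1] < best:
                best = prev[j - 1]
            if cur[j - 1] < best:
                best = cur[j - 1]
            cur[j] = row[j] if row[j] > best else best
        prev = cur
    return prev[m - 1]


def average_trajectory(
    paths: list[np.ndarray], n_points: int = 50, outlier_z: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean of arc-length-resampled trajectories with outlier removal.

    Each path is resampled to ``n_points``; a path whose mean Frechet distance
    to the other paths exceeds ``outlier_z`` standard deviations above the
    group mean is excluded. If the rule would exclude every path, no exclusion
    is applied (with a warning).

    Returns ``(mean_path, outlier_flags)``.
    """
    if len(paths) == 0:
        raise ValueError("need at least one trajectory")
    rs = np.stack([resample_path(p, n_points) for p in paths])
    k = rs.shape[0]
    outl = np.zeros(k, dtype=bool)
    if k >= 3:
        D = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                D[i, j] = D[j, i] = discrete_frechet(rs[i], rs[j])
        mean_d = D.sum(axis=1) / (k - 1)
        sd = mean_d.std(ddof=0)
        if sd > 0:
            outl = (mean_d - mean_d.mean()) / sd > outlier_z
    if outl.all():
        warnings.warn("all trajectories flagged as outliers; keeping all", stacklevel=2)
        outl = np.zeros(k, dtype=bool)
    return rs[~outl].mean(axis=0), outl


def _paths_by_trial(trajectories: pd.DataFrame) -> dict[int, np.ndarray]:
    cols = [c for c in ("x", "y", "z") if c in trajectories.columns]
    out: dict[int, np.ndarray] = {}
    for tid, g in trajectories.sort_values("t_s").groupby("trial_id"):
        out[int(tid)] = g[cols].to_numpy(dtype=float)
    return out


def average_trajectories_by_target(
    trajectories: pd.DataFrame,
    trials: pd.DataFrame,
    camera: Camera | None = None,
    n_points: int = 50,
    correct_only: bool = True,
    view: str = "screen",
) -> dict[str, np.ndarray]:
    """Per-target average trajectory in the requested view.

    ``view="screen"`` applies the perspective projection before averaging
    (the subject's visuospatial view); ``view="world"`` averages the raw 3-D
    paths (bird's-eye comparison).
    """
    if view == "screen" and camera is None:
        camera = Camera()
    use = trials[trials["correct"]] if correct_only else trials
    paths3d = _paths_by_trial(trajectories)
    out: dict[str, np.ndarray] = {}
    for label, g in use.groupby(use.apply(lambda r: f"r{int(r.target_row)}c{int(r.target_col)}", axis=1)):
        ps = []
        for tid in g["trial_id"]:
            p = paths3d.get(int(tid))
            if p is None:
                continue
            ps.append(project_trajectory(p, camera) if view == "screen" else p)
        if ps:
            out[str(label)], _ = average_trajectory(ps, n_points=n_points)
    return out


def frechet_matrix(
    avg_paths: dict[str, np.ndarray], normalize: bool = True
) -> pd.DataFrame:
    """Pairwise discrete Frechet distances between average trajectories.

    Labels are sorted; the matrix is symmetric with zero diagonal and, when
    ``normalize`` is set, divided by its maximum entry (max becomes exactly 1).
    """
    labels = sorted(avg_paths)
    k = len(labels)
    D = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            D[i, j] = D[j, i] = discrete_frechet(avg_paths[labels[i]], avg_paths[labels[j]])
    if normalize and D.max() > 0:
        D = D / D.max()
    return pd.DataFrame(D, index=labels, columns=labels)


def link_correlation(centroid_D: pd.DataFrame, other_D: pd.DataFrame) -> float:
    """Spearman rank correlation between two condition distance matrices.

    Computed over the strict upper triangle (36 entries for 9 conditions),
    with the second matrix aligned to the first's label order. A constant
    matrix yields 0 with a warning (rank correlation undefined).
    """
    labels = list(centroid_D.index)
    other = other_D.loc[labels, labels]
    iu = np.triu_indices(len(labels), k=1)
    a = centroid_D.to_numpy()[iu]
    b = other.to_numpy()[iu]
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        warnings.warn("constant distance matrix; Spearman correlation undefined, returning 0")
        return 0.0
    rho = spearmanr(a, b).statistic
    return 0.0 if not np.isfinite(rho) else float(rho)


def shuffle_link(
    P: pd.DataFrame,
    labels: pd.Series,
    other_D: pd.DataFrame,
    n_shuffles: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Null distribution of the link correlation under target-label shuffles.

    Target labels are permuted across trials; condition centroids, their
    distance matrix and the Spearman link are recomputed per shuffle. The
    embedding coordinates ``P`` are fixed (label-only randomization).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    lab = np.asarray(labels)
    rhos = np.empty(n_shuffles)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in range(n_shuffles):
            perm = pd.Series(rng.permutation(lab), index=P.index)
            _, Dn = condition_centroids(P, perm)
            rhos[s] = link_correlation(Dn, other_D)
    return rhos


def ablation_curve(
    seqs: pd.DataFrame,
    labels: pd.Series,
    other_D: pd.DataFrame,
    fractions: np.ndarray | None = None,
    iters: int = 100,
    seed: int = 0,
    k: int = 3,
    min_overlap: int = 10,
) -> pd.DataFrame:
    """Mean link correlation after randomly ablating a fraction of units.

    At each fraction, that share of unit columns is set to missing, the whole
    correlation-matrix / projection / centroid / Spearman pipeline is re-run,
    and the correlation is averaged over ``iters`` random unit subsets.
    Fraction 0 is the unablated value (computed through the same code path).
    """
    if fractions is None:
        fractions = np.arange(0.0, 1.0, 0.1)
    fractions = np.asarray(fractions, dtype=float)
    if (fractions >= 1.0).any() or (fractions < 0).any():
        raise ValueError("ablation fractions must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n_units = seqs.shape[1]
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for frac in fractions:
            n_drop = int(round(frac * n_units))
            reps = 1 if n_drop == 0 else iters
            rhos = np.empty(reps)
            for it in range(reps):
                ab = seqs.copy()
                if n_drop:
                    drop = rng.choice(n_units, size=n_drop, replace=False)
                    ab.iloc[:, drop] = np.nan
                X = sequence_correlation_matrix(ab, min_overlap=min_overlap)
                proj = spectral_projection(X, k=k)
                _, Dn = condition_centroids(proj.P, labels)
                rhos[it] = link_correlation(Dn, other_D)
            rows.append({"fraction": frac, "mean_rho": rhos.mean(), "sd_rho": rhos.std(ddof=0)})
    return pd.DataFrame(rows)


def target_distance_matrix(target_coords: dict[str, np.ndarray], normalize: bool = True) -> pd.DataFrame:
    """Euclidean distance matrix between target locations (label-keyed)."""
    labels = sorted(target_coords)
    pts = np.stack([np.asarray(target_coords[l], dtype=float) for l in labels])
    D = cdist(pts, pts)
    if normalize and D.max() > 0:
        D = D / D.max()
    return pd.DataFrame(D, index=labels, columns=labels)


def straight_line_paths(
    start: np.ndarray, target_coords: dict[str, np.ndarray], n_points: int = 50
) -> dict[str, np.ndarray]:
    """Optimal (shortest) paths: straight lines from the start to each target."""
    start = np.asarray(start, dtype=float)
    out = {}
    for label, tgt in target_coords.items():
        tgt = np.asarray(tgt, dtype=float)
        t = np.linspace(0.0, 1.0, n_points)[:, None]
        out[label] = start[None, :] * (1 - t) + tgt[None, :] * t
    return out
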