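"""Trial-to-trial temporal consistency of peak firing times.

For every unit and target condition with enough trials, the sample standard
deviation of the unit's peak firing time across that condition's trials
measures how precisely the unit keeps its place in the sequence. A shuffle
null — permuting, within each trial, the assignment of peak times to units —
destroys unit identity while preserving each trial's time marginal; the
difference between the shuffled and real distribution means (in ms) is the
session-level consistency statistic. Degraded sessions (error trials,
NMDA-antagonist-like jitter inflation) show a smaller difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConsistencyResult",
    "peak_sd",
    "best_condition_sd",
    "shuffle_null",
    "summarize",
    "consistency_analysis",
]

DEFAULT_SD_THRESHOLDS_MS = (1000.0, 1500.0)


@dataclass
class ConsistencyResult:
    sd: pd.DataFrame                      # units x conditions, seconds
    best_sd: pd.Series                    # per-unit minimum across conditions, seconds
    real_pooled: np.ndarray               # all (unit, condition) SDs, seconds
    shuffled_pooled: np.ndarray
    shuffled_repeat_means: np.ndarray     # mean pooled SD per shuffle repeat, seconds
    mean_difference_ms: float             # shuffled mean - real mean
    fraction_below: dict[float, float]    # threshold (ms) -> fraction of units


def peak_sd(
    seqs: pd.DataFrame, conditions: pd.Series | np.ndarray, min_trials: int = 5
) -> pd.DataFrame:
    """Sample SD (n-1 denominator) of peak times per (unit, condition).

    Conditions with fewer than ``min_trials`` trials are excluded entirely;
    a (unit, condition) cell with fewer than two non-missing peaks is NaN.
    Returns a units x conditions DataFrame in seconds.
    """
    cond = pd.Series(np.asarray(conditions), index=seqs.index)
    keep = cond.value_counts()
    keep = keep.index[keep >= min_trials]
    cols = {}
    for c in sorted(keep):
        block = seqs.loc[cond[cond == c].index]
        sd = block.std(ddof=1)
        sd[block.notna().sum() < 2] = np.nan
        cols[c] = sd
    if not cols:
        raise ValueError(f"no condition has at least {min_trials} trials")
    return pd.DataFrame(cols)


def best_condition_sd(sd: pd.DataFrame) -> pd.Series:
    """Per-unit SD in the condition where the unit fires most consistently."""
    return sd.min(axis=1)


def _shuffle_within_trials(seqs: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Permute, within each trial, the peak times across units.

    Missing entries stay missing: only the non-missing values of a trial are
    permuted among the non-missing positions.
    """
    vals = seqs.to_numpy(dtype=float).copy()
    for i in range(vals.shape[0]):
        idx = np.flatnonzero(np.isfinite(vals[i]))
        if idx.size > 1:
            vals[i, idx] = vals[i, rng.permutation(idx)]
    return pd.DataFrame(vals, index=seqs.index, columns=seqs.columns)


def _shuffle_across_trials(seqs: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Alternative scheme: permute each unit's peak times across trials."""
    vals = seqs.to_numpy(dtype=float).copy()
    for j in range(vals.shape[1]):
        idx = np.flatnonzero(np.isfinite(vals[:, j]))
        if idx.size > 1:
            vals[idx, j] = vals[rng.permutation(idx), j]
    return pd.DataFrame(vals, index=seqs.index, columns=seqs.columns)


def shuffle_null(
    seqs: pd.DataFrame,
    conditions: pd.Series | np.ndarray,
    n_repeats: int = 100,
    seed: int = 0,
    min_trials: int = 5,
    scheme: str = "within_trial",
) -> tuple[np.ndarray, np.ndarray]:
    """Shuffled peak-time SD distribution, pooled over repeats.

    Returns ``(pooled_sds, repeat_means)`` in seconds, where ``repeat_means``
    holds one pooled-distribution mean per repeat (used for confidence bands
    on the mean-difference statistic).
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if scheme == "within_trial":
        shuffler = _shuffle_within_trials
    elif scheme == "across_trial":
        shuffler = _shuffle_across_trials
    else:
        raise ValueError("scheme must be 'within_trial' or 'across_trial'")
    rng = np.random.default_rng(seed)
    pooled, means = [], []
    for _ in range(n_repeats):
        sh = shuffler(seqs, rng)
        sds = peak_sd(sh, conditions, min_trials=min_trials).to_numpy().ravel()
        sds = sds[np.isfinite(sds)]
        pooled.append(sds)
        means.append(sds.mean() if sds.size else np.nan)
    return np.concatenate(pooled), np.asarray(means)


def summarize(
    sd: pd.DataFrame,
    shuffled_pooled: np.ndarray,
    thresholds_ms: tuple[float, ...] = DEFAULT_SD_THRESHOLDS_MS,
) -> dict:
    """Mean difference (ms) between shuffled and real SD distributions,
    plus the fraction of units whose best-condition SD falls below each
    threshold."""
    real = sd.to_numpy().ravel()
    real = real[np.isfinite(real)]
    if real.size == 0 or np.asarray(shuffled_pooled).size == 0:
        raise ValueError("empty SD distribution")
    best = best_condition_sd(sd).dropna()
    return {
        "mean_difference_ms": float((np.mean(shuffled_pooled) - real.mean()) * 1000.0),
        "fraction_below": {
            float(thr): float((best * 1000.0 < thr).mean()) for thr in thresholds_ms
        },
    }


def consistency_analysis(
    seqs: pd.DataFrame,
    conditions: pd.Series | np.ndarray,
    min_trials: int = 5,
    n_repeats: int = 100,
    seed: int = 0,
    thresholds_ms: tuple[float, ...] = DEFAULT_SD_THRESHOLDS_MS,
    scheme: str = "within_trial",
) -> ConsistencyResult:
    sd = peak_sd(seqs, conditions, min_trials=min_trials)
    pooled, repeat_means = shuffle_null(
        seqs, conditions, n_repeats=n_repeats, seed=seed, min_trials=min_trials, scheme=scheme
    )
    summary = summarize(sd, pooled, thresholds_ms)
    real = sd.to_numpy().ravel()
    real = real[np.isfinite(real)]
    return ConsistencyResult(
        sd=sd,
        best_sd=best_condition_sd(sd),
        real_pooled=real,
        shuffled_pooled=pooled,
        shuffled_repeat_means=repeat_means,
        mean_difference_ms=summary["mean_difference_ms"],
        fraction_below=summary["fraction_below"],
    )
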