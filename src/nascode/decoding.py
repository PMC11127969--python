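"""Decoding remembered targets and trial epochs from sequence vectors.

The workhorse is an unsupervised nearest-centroid classifier operating on the
spectral-embedding coordinates: train-fold trials define condition centroids,
and each test trial takes the label of the nearest centroid (Euclidean
distance, stratified cross-validation). On top of it sit the epoch decoder
(cue / delay / navigation from epoch-masked sequences), target decoding from
the full population, row/column decoding from spike-time-selective
subpopulations combined into a target prediction, and the comparison between
the sequence code and the classical persistent delay-rate code via matched
linear maximum-margin (SVM) decoders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import f_oneway, ttest_ind
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from ._stats import nan_pearson
from .sequences import mask_epoch
from .embedding import sequence_correlation_matrix, spectral_projection
from .synth import Session, target_label

__all__ = [
    "DecoderReport",
    "PersistentCellSet",
    "nearest_centroid_cv",
    "epoch_windows",
    "epoch_decode",
    "cohens_d",
    "selectivity_scores",
    "select_units",
    "tune_selectivity_percentile",
    "combined_target_decode",
    "find_persistent_cells",
    "compare_codes",
    "same_trial_replay_test",
]

DEFAULT_PERCENTILE_GRID = (50.0, 60.0, 70.0, 80.0, 90.0, 95.0)


@dataclass
class DecoderReport:
    task: str
    fold_accuracies: list[float]
    mean_accuracy: float
    chance: float
    n_classes: int
    seed: int
    predictions: pd.Series | None = None  # out-of-fold prediction per sample

    def above_chance(self) -> float:
        return self.mean_accuracy - self.chance


@dataclass
class PersistentCellSet:
    p_threshold: float
    unit_ids: np.ndarray
    preferred_target: pd.Series   # per-member preferred target label
    delay_rate_hz: pd.Series      # per-member mean delay rate on preferred-target trials
    baseline_rate_hz: pd.Series   # per-member mean inter-trial-interval rate


def _embed_coords(seqs: pd.DataFrame, k: int = 3, min_overlap: int = 10) -> pd.DataFrame:
    X = sequence_correlation_matrix(seqs, min_overlap=min_overlap)
    return spectral_projection(X, k=k).P


def nearest_centroid_cv(
    P: pd.DataFrame | np.ndarray,
    labels: pd.Series | np.ndarray,
    k_folds: int = 5,
    seed: int = 0,
    task: str = "nearest_centroid",
) -> DecoderReport:
    """Stratified cross-validated nearest-centroid decoding.

    Folds are stratified by class; centroids are the per-class coordinate
    means of the training fold; distance ties resolve to the lowest class
    index (classes in sorted order). A class absent from a training fold is a
    configuration error, reported by name.
    """
    coords = P.to_numpy(dtype=float) if isinstance(P, pd.DataFrame) else np.asarray(P, dtype=float)
    idx = P.index if isinstance(P, pd.DataFrame) else pd.RangeIndex(coords.shape[0])
    y = np.asarray(labels)
    classes = np.array(sorted(set(y.tolist())))
    counts = pd.Series(y).value_counts()
    if (counts < k_folds).any():
        short = counts[counts < k_folds].index.tolist()
        raise ValueError(f"classes with fewer trials than folds: {short}")
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    accs: list[float] = []
    preds = pd.Series(index=idx, dtype=object)
    for tr, te in skf.split(coords, y):
        cents = np.empty((len(classes), coords.shape[1]))
        for ci, c in enumerate(classes):
            m = y[tr] == c
            if not m.any():
                raise ValueError(f"class {c!r} absent from a training fold")
            cents[ci] = coords[tr][m].mean(axis=0)
        d = np.linalg.norm(coords[te][:, None, :] - cents[None, :, :], axis=2)
        p = classes[np.argmin(d, axis=1)]  # argmin takes the first (lowest) class on ties
        accs.append(float(np.mean(p == y[te])))
        preds.iloc[te] = p
    return DecoderReport(
        task=task,
        fold_accuracies=accs,
        mean_accuracy=float(np.mean(accs)),
        chance=1.0 / len(classes),
        n_classes=len(classes),
        seed=seed,
        predictions=preds,
    )


def epoch_windows(
    trials: pd.DataFrame,
    pre_delay_t: float | None = None,
    pre_nav_t: float | None = None,
) -> dict[str, tuple[float, float]]:
    """Cue/delay/navigation windows from neural boundaries, task fallback.

    When both neural boundaries are available they parcel the trial; otherwise
    the task event times do, with a warning.
    """
    t_end = float(trials["t_end"].iloc[0])
    if pre_delay_t is not None and pre_nav_t is not None:
        b1, b2 = float(pre_delay_t), float(pre_nav_t)
    else:
        warnings.warn("neural boundaries unavailable; using task boundaries", stacklevel=2)
        b1 = float(trials["t_delay_on"].iloc[0])
        b2 = float(trials["t_nav_on"].iloc[0])
    return {"cue": (0.0, b1), "delay": (b1, b2), "nav": (b2, t_end)}


def epoch_decode(
    seqs: pd.DataFrame,
    trials: pd.DataFrame,
    pre_delay_t: float | None = None,
    pre_nav_t: float | None = None,
    k: int = 3,
    min_overlap: int = 10,
    k_folds: int = 5,
    seed: int = 0,
) -> DecoderReport:
    """Decode trial epoch from epoch-masked sequences (3 classes, chance 1/3).

    Every trial contributes one masked sequence per epoch; the pooled set is
    embedded and classified by nearest centroid.
    """
    windows = epoch_windows(trials, pre_delay_t, pre_nav_t)
    frames, labels = [], []
    for name, win in windows.items():
        m = mask_epoch(seqs, win)
        m.index = pd.MultiIndex.from_product([[name], seqs.index], names=["epoch", "trial_id"])
        frames.append(m)
        labels.extend([name] * len(seqs))
    stacked = pd.concat(frames)
    P = _embed_coords(stacked, k=k, min_overlap=min_overlap)
    return nearest_centroid_cv(P, np.array(labels), k_folds=k_folds, seed=seed, task="epoch")


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Cohen's d with pooled SD; infinite when the pooled SD is zero but the
    means differ, zero when both distributions are identical constants."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        return float("nan")
    pooled = np.sqrt(((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2))
    diff = x.mean() - y.mean()
    if pooled == 0.0:
        if diff == 0.0:
            return 0.0
        warnings.warn("zero pooled SD with unequal means; effect size set to inf", stacklevel=2)
        return float("inf")
    return float(diff / pooled)


def selectivity_scores(
    seqs: pd.DataFrame, grouping: pd.Series | np.ndarray, min_trials: int = 5
) -> pd.Series:
    """Per-unit selectivity for a grouping (row / column / target).

    For each unit the absolute Cohen's d between its spike-time distributions
    is computed for every pair of grouping values; the score is the maximum
    across pairs, so a unit separating any two groups counts as selective even
    if other groups overlap.
    """
    g = pd.Series(np.asarray(grouping), index=seqs.index)
    values = sorted(g.unique().tolist())
    if len(values) < 2:
        raise ValueError("need at least two grouping values")
    groups = {v: seqs.loc[g[g == v].index] for v in values}
    scores = {}
    for u in seqs.columns:
        best = 0.0
        for i in range(len(values)):
            xi = groups[values[i]][u].dropna().to_numpy()
            if xi.size < min_trials:
                continue
            for j in range(i + 1, len(values)):
                yj = groups[values[j]][u].dropna().to_numpy()
                if yj.size < min_trials:
                    continue
                d = abs(cohens_d(xi, yj))
                if np.isfinite(d) and d > best:
                    best = d
                elif np.isinf(d):
                    best = np.inf
        scores[u] = best
    return pd.Series(scores, name="selectivity")


def select_units(scores: pd.Series, percentile: float) -> np.ndarray:
    """Units with selectivity strictly above the given score percentile."""
    finite = scores.replace(np.inf, scores[np.isfinite(scores)].max() if np.isfinite(scores).any() else 0.0)
    thr = np.percentile(finite.to_numpy(), percentile)
    return scores.index[scores > thr].to_numpy()


def tune_selectivity_percentile(
    seqs: pd.DataFrame,
    grouping: pd.Series,
    scores: pd.Series,
    grid: tuple[float, ...] = DEFAULT_PERCENTILE_GRID,
    k: int = 3,
    min_overlap: int = 10,
    k_folds: int = 5,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Choose the percentile threshold maximizing cross-validated decoding of
    the grouping from the selected subpopulation's subsequences."""
    best = (-1.0, None, None)
    for pct in grid:
        units = select_units(scores, pct)
        if len(units) == 0:
            continue
        sub = seqs.copy()
        sub.loc[:, [u for u in sub.columns if u not in set(units)]] = np.nan
        try:
            P = _embed_coords(sub, k=k, min_overlap=min_overlap)
            rep = nearest_centroid_cv(P, grouping, k_folds=k_folds, seed=seed)
        except ValueError:
            continue
        if rep.mean_accuracy > best[0]:
            best = (rep.mean_accuracy, pct, units)
    if best[1] is None:
        warnings.warn("selectivity tuning failed; falling back to all units", stacklevel=2)
        return 0.0, scores.index.to_numpy()
    return best[1], best[2]


def _masked_to(seqs: pd.DataFrame, units: np.ndarray) -> pd.DataFrame:
    out = seqs.copy()
    keep = set(units.tolist())
    out.loc[:, [u for u in out.columns if u not in keep]] = np.nan
    return out


def combined_target_decode(
    seqs: pd.DataFrame,
    trials: pd.DataFrame,
    k: int = 3,
    min_overlap: int = 10,
    k_folds: int = 5,
    seed: int = 0,
    percentile_grid: tuple[float, ...] = DEFAULT_PERCENTILE_GRID,
) -> dict[str, DecoderReport]:
    """Target decoding: full population vs combined row x column prediction.

    Row and column are decoded separately from the subsequences of row- and
    column-selective units (selectivity percentile tuned by cross-validated
    decoding); the (row, column) pair uniquely determines one of the nine
    targets. Reported alongside direct 9-class decoding from all cells.
    """
    tr = trials.set_index("trial_id").loc[seqs.index]
    target = tr.apply(lambda r: target_label(r.target_row, r.target_col), axis=1)
    row_lab = tr["target_row"].astype(int)
    col_lab = tr["target_col"].astype(int)

    P_all = _embed_coords(seqs, k=k, min_overlap=min_overlap)
    all_cell = nearest_centroid_cv(P_all, target, k_folds=k_folds, seed=seed, task="all_cell_target")

    reports: dict[str, DecoderReport] = {"all_cell_target": all_cell}
    axis_preds = {}
    for axis, lab in (("row", row_lab), ("column", col_lab)):
        scores = selectivity_scores(seqs, lab)
        _, units = tune_selectivity_percentile(
            seqs, lab, scores, grid=percentile_grid, k=k, min_overlap=min_overlap,
            k_folds=k_folds, seed=seed,
        )
        if len(units) == 0:
            warnings.warn(f"empty {axis}-selective set; using all units", stacklevel=2)
            units = np.asarray(seqs.columns)
        sub = _masked_to(seqs, units)
        P_sub = _embed_coords(sub, k=k, min_overlap=min_overlap)
        rep = nearest_centroid_cv(P_sub, lab, k_folds=k_folds, seed=seed, task=axis)
        reports[axis] = rep
        axis_preds[axis] = rep.predictions

    combined = pd.Series(
        [
            target_label(axis_preds["row"].loc[i], axis_preds["column"].loc[i])
            for i in seqs.index
        ],
        index=seqs.index,
    )
    acc = float((combined == target).mean())
    reports["combined_target"] = DecoderReport(
        task="combined_target",
        fold_accuracies=[acc],
        mean_accuracy=acc,
        chance=1.0 / 9.0,
        n_classes=9,
        seed=seed,
        predictions=combined,
    )
    return reports


def _rates_in_window(
    session: Session, start_col: str, end_col: str
) -> pd.DataFrame:
    """Mean firing rate per (trial, unit) inside a per-trial window (Hz)."""
    trials = session.trials
    spk = session.spikes
    win = trials.set_index("trial_id")[[start_col, end_col]]
    s = spk.join(win, on="trial_id")
    inside = (s["t_s"] >= s[start_col]) & (s["t_s"] < s[end_col])
    counts = (
        s[inside].groupby(["trial_id", "unit_id"]).size().unstack(fill_value=0)
    )
    counts = counts.reindex(index=trials["trial_id"], columns=session.units["unit_id"], fill_value=0)
    dur = (win[end_col] - win[start_col]).reindex(trials["trial_id"])
    return counts.div(dur, axis=0)


def find_persistent_cells(session: Session, p_threshold: float = 0.05) -> PersistentCellSet:
    """Units with classical persistent delay activity.

    Two criteria, both at ``p < p_threshold``: (1) one-way ANOVA of the
    delay-period firing rate across the nine targets (target-selective
    tuning), and (2) a one-sided Welch t-test that the delay rate on
    preferred-target trials exceeds the inter-trial-interval baseline rate.
    Relaxing the threshold grows the set monotonically.
    """
    trials = session.trials
    if "iti_start" not in trials.columns or "iti_end" not in trials.columns:
        raise ValueError("session trials lack inter-trial-interval columns")
    delay = _rates_in_window(session, "t_delay_on", "t_nav_on")
    base = _rates_in_window(session, "iti_start", "iti_end")
    target = trials.set_index("trial_id").apply(
        lambda r: target_label(r.target_row, r.target_col), axis=1
    )
    members, pref, drate, brate = [], {}, {}, {}
    labels = sorted(target.unique().tolist())
    groups_idx = {lab: target[target == lab].index for lab in labels}
    for u in delay.columns:
        groups = [delay.loc[groups_idx[lab], u].to_numpy() for lab in labels]
        if len(groups) < 2 or any(g.size < 2 for g in groups):
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p_tuning = f_oneway(*groups).pvalue
        if not np.isfinite(p_tuning) or p_tuning >= p_threshold:
            continue
        means = {lab: g.mean() for lab, g in zip(labels, groups)}
        best = max(means, key=means.get)
        x = delay.loc[groups_idx[best], u].to_numpy()
        y = base[u].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p_elev = ttest_ind(x, y, equal_var=False, alternative="greater").pvalue
        if np.isfinite(p_elev) and p_elev < p_threshold:
            members.append(u)
            pref[u] = best
            drate[u] = float(x.mean())
            brate[u] = float(y.mean())
    return PersistentCellSet(
        p_threshold=p_threshold,
        unit_ids=np.asarray(members),
        preferred_target=pd.Series(pref, dtype=object),
        delay_rate_hz=pd.Series(drate, dtype=float),
        baseline_rate_hz=pd.Series(brate, dtype=float),
    )


def _svm_cv(
    features: pd.DataFrame, labels: pd.Series, folds: int, seed: int, task: str
) -> DecoderReport:
    y = np.asarray(labels)
    counts = pd.Series(y).value_counts()
    if (counts < folds).any():
        raise ValueError(f"classes with fewer trials than folds: {counts[counts < folds].index.tolist()}")
    X = features.to_numpy(dtype=float)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(X, y):
        clf = make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0))
        clf.fit(X[tr], y[tr])
        accs.append(float(clf.score(X[te], y[te])))
    k = len(set(y.tolist()))
    return DecoderReport(
        task=task,
        fold_accuracies=accs,
        mean_accuracy=float(np.mean(accs)),
        chance=1.0 / k,
        n_classes=k,
        seed=seed,
    )


def compare_codes(
    session: Session,
    seqs: pd.DataFrame,
    delay_window: tuple[float, float] | None = None,
    p_threshold: float = 0.05,
    folds: int = 10,
    seed: int = 0,
    k: int = 3,
    min_overlap: int = 10,
) -> tuple[DecoderReport | None, DecoderReport]:
    """Persistent-rate vs sequence-code target decoding with matched SVMs.

    The persistent decoder uses mean delay rates of the persistent-cell set;
    the sequence decoder uses the spectral-projection coordinates of
    delay-epoch sequences. Both are linear SVMs with stratified ``folds``-fold
    cross-validation. Returns ``(persistent_report, sequence_report)``;
    the persistent report is None when no unit passes the criteria.
    """
    trials = session.trials.set_index("trial_id").loc[seqs.index]
    target = trials.apply(lambda r: target_label(r.target_row, r.target_col), axis=1)

    if delay_window is None:
        delay_window = (float(trials["t_delay_on"].iloc[0]), float(trials["t_nav_on"].iloc[0]))
    delay_seqs = mask_epoch(seqs, delay_window)
    P = _embed_coords(delay_seqs, k=k, min_overlap=min_overlap)
    seq_rep = _svm_cv(P, target, folds=folds, seed=seed, task="sequence_svm")

    pers = find_persistent_cells(session, p_threshold=p_threshold)
    if pers.unit_ids.size == 0:
        warnings.warn("no persistent cells at this threshold", stacklevel=2)
        return None, seq_rep
    delay_rates = _rates_in_window(session, "t_delay_on", "t_nav_on")
    feats = delay_rates.loc[seqs.index, pers.unit_ids]
    pers_rep = _svm_cv(feats, target, folds=folds, seed=seed, task="persistent_svm")
    return pers_rep, seq_rep


def same_trial_replay_test(
    delay_seqs: pd.DataFrame,
    nav_seqs: pd.DataFrame,
    min_overlap: int = 10,
    top_frac: float = 0.05,
) -> float:
    """Fraction of trials whose delay sequence is exceptionally correlated with
    its own navigation sequence.

    For each trial, the correlation between its delay-epoch sequence and every
    trial's navigation-epoch sequence is ranked; the trial counts as a
    'replay' trial when its own-navigation correlation sits in the top
    ``top_frac`` of that distribution. Under no replay the fraction is ~0.05.
    """
    if len(delay_seqs) < 2:
        raise ValueError("need at least two trials")
    if not delay_seqs.index.equals(nav_seqs.index):
        raise ValueError("delay and navigation sequences must cover the same trials")
    R = nan_pearson(
        delay_seqs.to_numpy(dtype=float), nav_seqs.to_numpy(dtype=float), min_overlap=min_overlap
    )
    T = R.shape[0]
    hits = 0
    valid = 0
    for i in range(T):
        row = R[i]
        own = row[i]
        if not np.isfinite(own):
            continue
        finite = row[np.isfinite(row)]
        if finite.size < 2:
            continue
        valid += 1
        rank = (finite < own).sum() / finite.size
        if rank >= 1.0 - top_frac:
            hits += 1
    if valid == 0:
        raise ValueError("no trial had enough overlapping units for the replay test")
    return hits / valid
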