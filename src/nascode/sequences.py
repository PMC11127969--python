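"""Spike-density functions and per-trial sequence vectors.

A unit's spike train on one trial is smoothed with a Gaussian kernel
(SD 100 ms by default) into a spike-density function on a 1 ms grid; the grid
time of its global maximum is the unit's peak firing time t_n for that trial.
Collecting t_n across the simultaneously recorded population turns every trial
into a sequence vector S with S_n = t_n, the object all downstream stages
operate on. Sequence vectors are stored as a wide trials x units DataFrame
with NaN marking units that did not fire (or were masked out of an epoch).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .synth import Session

__all__ = [
    "gaussian_kernel",
    "spike_density",
    "peak_time",
    "included_units",
    "build_sequences",
    "mask_epoch",
]

DEFAULT_KERNEL_SD = 0.1
DEFAULT_DT = 0.001
KERNEL_TRUNCATE_SD = 5.0


def gaussian_kernel(kernel_sd: float, dt: float, truncate: float = KERNEL_TRUNCATE_SD) -> np.ndarray:
    """Discrete Gaussian kernel sampled at step ``dt``, truncated at ±truncate·SD.

    Values are the continuous density times ``dt`` (sum ≈ 1 up to truncation);
    the truncated tail mass is not redistributed.
    """
    if kernel_sd <= 0 or dt <= 0:
        raise ValueError("kernel_sd and dt must be positive")
    half = int(np.ceil(truncate * kernel_sd / dt))
    x = np.arange(-half, half + 1) * dt
    return np.exp(-0.5 * (x / kernel_sd) ** 2) * dt / (kernel_sd * np.sqrt(2.0 * np.pi))


def spike_density(
    spike_times: np.ndarray,
    window: tuple[float, float],
    kernel_sd: float = DEFAULT_KERNEL_SD,
    dt: float = DEFAULT_DT,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel rate estimate of one spike train on a uniform grid.

    Returns ``(grid, values)`` with values in spikes/s; the integral over the
    window equals the spike count up to kernel truncation at the edges (no
    boundary renormalization). Spike times must be sorted and inside the
    half-open window.
    """
    t0, t1 = float(window[0]), float(window[1])
    if not t1 > t0:
        raise ValueError("window must have positive length")
    st = np.asarray(spike_times, dtype=float)
    if st.size and np.any(np.diff(st) < 0):
        raise ValueError("spike times must be sorted ascending")
    if st.size and (st.min() < t0 or st.max() >= t1):
        raise ValueError("spike times must lie within the half-open window")
    n_bins = int(round((t1 - t0) / dt))
    grid = t0 + np.arange(n_bins) * dt
    counts = np.zeros(n_bins)
    if st.size:
        idx = np.clip(np.rint((st - t0) / dt).astype(int), 0, n_bins - 1)
        np.add.at(counts, idx, 1.0)
    kernel = gaussian_kernel(kernel_sd, dt)
    values = fftconvolve(counts, kernel, mode="same") / dt
    np.clip(values, 0.0, None, out=values)
    return grid, values


def peak_time(grid: np.ndarray, values: np.ndarray) -> float:
    """Grid time of the global density maximum; ties go to the earliest time.

    An identically zero density (no spikes) returns NaN — the missing marker —
    rather than raising.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0 or values.max() <= 0.0:
        return float("nan")
    return float(grid[int(np.argmax(values))])


def included_units(session: Session, min_rate_hz: float = 0.5) -> np.ndarray:
    """Units whose whole-session mean firing rate exceeds ``min_rate_hz``.

    The rate is total session spikes divided by total recorded time (trial
    plus inter-trial interval, summed over trials).
    """
    total_time = float(session.trials["iti_end"].sum())
    counts = (
        session.spikes.groupby("unit_id")
        .size()
        .reindex(session.units["unit_id"], fill_value=0)
    )
    rates = counts / total_time
    keep = rates.index[rates > min_rate_hz].to_numpy()
    if keep.size == 0:
        raise ValueError(
            f"no unit passes the firing-rate criterion (> {min_rate_hz} Hz over the session)"
        )
    return keep


def build_sequences(
    session: Session,
    min_rate_hz: float = 0.5,
    kernel_sd: float = DEFAULT_KERNEL_SD,
    dt: float = DEFAULT_DT,
    window: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Per-trial sequence vectors for all rate-criterion units.

    Returns a trials x units DataFrame of peak times in seconds from cue
    onset. The unit order (columns) is fixed across trials; a unit with no
    spikes in a trial's analysis window gets NaN for that trial but keeps its
    column. By default densities are computed over the whole trial window
    [0, t_end) — epoch restriction is then applied afterwards by
    :func:`mask_epoch` — but an explicit ``window`` computes epoch-specific
    sequences (each unit's density argmax within that window), which the
    same-trial replay comparison needs.
    """
    units = included_units(session, min_rate_hz)
    unit_pos = {u: i for i, u in enumerate(units)}
    trials = session.trials
    kernel = gaussian_kernel(kernel_sd, dt)

    spk = session.spikes
    spk = spk[spk["unit_id"].isin(unit_pos)]
    by_trial = dict(tuple(spk.groupby("trial_id")))

    out = np.full((len(trials), len(units)), np.nan)
    for ti, trial in enumerate(trials.itertuples()):
        t0, t1 = (0.0, float(trial.t_end)) if window is None else window
        if not t1 > t0:
            raise ValueError("window must have positive length")
        n_bins = int(round((t1 - t0) / dt))
        g = by_trial.get(trial.trial_id)
        if g is None:
            continue
        tt = g["t_s"].to_numpy()
        in_win = (tt >= t0) & (tt < t1)
        if not in_win.any():
            continue
        uu = g["unit_id"].map(unit_pos).to_numpy()[in_win]
        bidx = np.clip(np.rint((tt[in_win] - t0) / dt).astype(int), 0, n_bins - 1)
        counts = np.zeros((len(units), n_bins))
        np.add.at(counts, (uu, bidx), 1.0)
        dens = fftconvolve(counts, kernel[None, :], mode="same", axes=1)
        fired = counts.sum(axis=1) > 0
        pk = t0 + np.argmax(dens, axis=1).astype(float) * dt
        out[ti, fired] = pk[fired]
    return pd.DataFrame(out, index=trials["trial_id"].to_numpy(), columns=units)


def mask_epoch(seqs: pd.DataFrame | pd.Series, window: tuple[float, float]):
    """Restrict sequence entries to one epoch: times outside [start, end) -> NaN.

    The window is half-open, so an entry exactly at the start is retained and
    one exactly at the end is masked. A zero-length window masks everything;
    an inverted window is an error.
    """
    start, end = float(window[0]), float(window[1])
    if end < start:
        raise ValueError("inverted epoch window")
    return seqs.where((seqs >= start) & (seqs < end))
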