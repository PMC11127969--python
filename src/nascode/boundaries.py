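"""Time-boundary cells and neural epoch boundaries.

A time-selective (boundary) unit peaks at the same trial time regardless of
the remembered target, so its peak-time distribution pooled across *all*
trials is narrow. Selectivity is quantified by the full width at half maximum
(FWHM) of a fixed-bandwidth Gaussian kernel density estimate of that
distribution: the width of the contiguous region around the global mode that
stays above half the mode's height (a far-away second mode therefore does not
widen the measure). Units below a width threshold are time-selective; the
histogram of their pooled peak times shows two peaks anticipating the delay
and navigation onsets, which define the session's neural epoch boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BoundaryResult",
    "unit_fwhm",
    "find_time_selective",
    "neural_boundaries",
    "boundary_analysis",
]


@dataclass
class BoundaryResult:
    fwhm: pd.Series                 # per-unit FWHM (s); NaN when undefined
    selective_units: np.ndarray     # unit ids below the threshold
    fraction_selective: float
    hist_edges: np.ndarray
    hist_counts: np.ndarray
    pre_delay_t: float | None       # neural boundary before delay onset (s)
    pre_nav_t: float | None         # neural boundary between delay and nav onset (s)


def unit_fwhm(
    peak_times: np.ndarray,
    bandwidth_s: float = 0.1,
    grid_dt: float = 0.002,
) -> float:
    """FWHM of the Gaussian-KDE of a unit's across-trial peak-time distribution.

    Uses a fixed (configurable) bandwidth rather than a data-driven rule so the
    degenerate case is exact: all peaks identical gives the kernel's own width,
    2*sqrt(2 ln 2)*bandwidth. Fewer than two finite peaks -> NaN (missing).
    """
    pt = np.asarray(peak_times, dtype=float)
    pt = pt[np.isfinite(pt)]
    if pt.size < 2:
        return float("nan")
    lo = pt.min() - 5.0 * bandwidth_s
    hi = pt.max() + 5.0 * bandwidth_s
    grid = np.arange(lo, hi + grid_dt, grid_dt)
    dens = np.exp(-0.5 * ((grid[:, None] - pt[None, :]) / bandwidth_s) ** 2).mean(axis=1)
    mode = int(np.argmax(dens))
    half = dens[mode] / 2.0
    left = mode
    while left > 0 and dens[left - 1] >= half:
        left -= 1
    right = mode
    while right < dens.size - 1 and dens[right + 1] >= half:
        right += 1
    return float((right - left) * grid_dt)


def find_time_selective(fwhm: pd.Series, threshold_s: float = 1.0) -> np.ndarray:
    """Unit ids whose FWHM falls strictly below the threshold."""
    ok = fwhm.dropna()
    return ok.index[ok < threshold_s].to_numpy()


def neural_boundaries(
    pooled_peaks: np.ndarray,
    delay_on: float,
    nav_on: float,
    t_end: float,
    bin_s: float = 0.1,
) -> tuple[float | None, float | None, np.ndarray, np.ndarray]:
    """Two neural boundaries from the pooled selective-unit peak histogram.

    The pre-delay boundary is the center of the highest-count bin before delay
    onset; the pre-navigation boundary the highest bin between delay and
    navigation onset. An empty region yields None for that boundary, with a
    warning — the signature of a perception-control session, where no units
    anticipate the (never hidden) memory period.

    Returns ``(pre_delay_t, pre_nav_t, bin_edges, counts)``.
    """
    pk = np.asarray(pooled_peaks, dtype=float)
    pk = pk[np.isfinite(pk)]
    edges = np.arange(0.0, t_end + bin_s, bin_s)
    counts, edges = np.histogram(pk, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0

    def _best(mask: np.ndarray) -> float | None:
        if not mask.any() or counts[mask].max() == 0:
            return None
        sub = np.where(mask)[0]
        return float(centers[sub[np.argmax(counts[sub])]])

    pre_delay = _best(centers < delay_on)
    pre_nav = _best((centers >= delay_on) & (centers < nav_on))
    if pre_delay is None or pre_nav is None:
        warnings.warn("no neural boundary found in one or both epochs", stacklevel=2)
    return pre_delay, pre_nav, edges, counts


def boundary_analysis(
    seqs: pd.DataFrame,
    delay_on: float,
    nav_on: float,
    t_end: float,
    fwhm_threshold_s: float = 1.0,
    bandwidth_s: float = 0.1,
    bin_s: float = 0.1,
) -> BoundaryResult:
    """Full boundary stage on a set of sequence vectors (trials x units)."""
    fwhm = pd.Series(
        {u: unit_fwhm(seqs[u].to_numpy(), bandwidth_s=bandwidth_s) for u in seqs.columns},
        name="fwhm_s",
    )
    selective = find_time_selective(fwhm, fwhm_threshold_s)
    frac = len(selective) / max(len(seqs.columns), 1)
    if len(selective):
        pooled = seqs[selective].to_numpy().ravel()
    else:
        pooled = np.empty(0)
    pre_delay, pre_nav, edges, counts = neural_boundaries(
        pooled, delay_on, nav_on, t_end, bin_s=bin_s
    )
    return BoundaryResult(
        fwhm=fwhm,
        selective_units=selective,
        fraction_selective=frac,
        hist_edges=edges,
        hist_counts=counts,
        pre_delay_t=pre_delay,
        pre_nav_t=pre_nav,
    )
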