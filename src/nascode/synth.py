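"""Synthetic recording sessions with planted sequence structure.

The generator emulates a prefrontal population recorded while a subject
performs a cued visuospatial working-memory task in a virtual arena: a 3 s cue
epoch, a 2 s memory delay, and a navigation epoch (1.5 s analyzed) toward one
of nine targets arranged in a 3x3 grid spaced 290 world units apart. Units fire
background Poisson spikes plus a transient Gaussian rate bump whose center (the
planted peak time) tiles the trial across the population and, for
target-coding units, shifts with the remembered target. A small subset of
time-boundary units peaks at fixed times anticipating the delay and navigation
onsets on every trial. Alternative modes plant a persistent delay-rate code
(the classical working-memory signature probed by oculomotor delayed-response
tasks), no condition structure at all, or a perception-control session without
boundary units.

All randomness flows from a single session seed through one generator, with
draws in a fixed, documented order (unit parameters, then trial order and
correctness, then per-trial peak jitter, spikes and trajectories), so the same
configuration and seed reproduce a byte-identical session.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .behavior import Camera, project_points

__all__ = [
    "SynthConfig",
    "Session",
    "generate_session",
    "generate_trajectories",
    "target_label",
    "target_world_coords",
    "target_screen_coords",
    "TARGET_LABELS",
]

MODES = ("sequence", "persistent", "unstructured", "perception_control")

TARGET_LABELS = [f"r{r}c{c}" for r in range(3) for c in range(3)]


def target_label(row: int, col: int) -> str:
    return f"r{int(row)}c{int(col)}"


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of a synthetic session. Durations in seconds, rates in Hz.

    ``bump_width80_s`` is the duration over which a unit's firing bump exceeds
    80% of its maximum (the printed bump statistic, ~220 ms); the Gaussian rate
    profile's SD is derived from it. ``peak_jitter_sd_s`` is the trial-to-trial
    SD of the realized peak around the planted, target-specific peak time.
    """

    n_units: int = 200
    n_trials_per_target: int = 20
    cue_s: float = 3.0
    delay_s: float = 2.0
    nav_s: float = 1.5
    iti_s: float = 0.5
    background_rate_hz: float = 2.0
    bump_amplitude_hz: float = 25.0
    bump_width80_s: float = 0.22
    # trial-to-trial multiplicative rate variability (lognormal sigma); the
    # timing code is robust to it, a windowed rate code is not
    rate_variability_sd: float = 0.8
    peak_jitter_sd_s: float = 0.3
    frac_boundary_cells: float = 0.05
    boundary_offsets_s: tuple[float, float] = (0.75, 0.5)
    boundary_jitter_sd_s: float = 0.05
    frac_row_selective: float = 0.15
    frac_col_selective: float = 0.15
    incorrect_frac: float = 0.15
    incorrect_jitter_multiplier: float = 2.0
    mode: str = "sequence"
    frac_persistent: float = 0.5
    persistent_tuned_rate_hz: float = 10.0
    persistent_baseline_hz: float = 2.0
    # target-dependent timing structure (seconds of peak shift); see docs/methods.md
    screen_loading_x: tuple[float, float] = (1.0, 1.5)
    screen_loading_y: tuple[float, float] = (0.25, 0.5)
    row_col_step_s: float = 0.6
    cross_axis_range_s: tuple[float, float] = (0.2, 0.28)
    idiosyncratic_sd_s: float = 0.25
    idiosyncratic_rowcol_sd_s: float = 0.15
    peak_span_range_s: tuple[float, float] = (1.2, 1.6)
    # arena / movement
    grid_spacing: float = 290.0
    front_row_depth: float = 580.0
    move_speed: float = 580.0
    trajectory_noise_sd: float = 15.0
    traj_sample_hz: float = 50.0
    eye_height: float = 100.0
    camera_setback: float = 150.0
    seed: int = 0

    # -- derived quantities -------------------------------------------------
    @property
    def t_delay_on(self) -> float:
        return self.cue_s

    @property
    def t_nav_on(self) -> float:
        return self.cue_s + self.delay_s

    @property
    def t_end(self) -> float:
        return self.cue_s + self.delay_s + self.nav_s

    @property
    def bump_sigma_s(self) -> float:
        # width at 80% of max of exp(-t^2/2s^2) is 2*s*sqrt(2*ln(1/0.8))
        return self.bump_width80_s / (2.0 * np.sqrt(2.0 * np.log(1.0 / 0.8)))

    def validate(self) -> None:
        for name in ("cue_s", "delay_s", "nav_s", "iti_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("background_rate_hz", "bump_amplitude_hz", "persistent_tuned_rate_hz",
                     "persistent_baseline_hz"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        fracs = {
            "frac_boundary_cells": self.frac_boundary_cells,
            "frac_row_selective": self.frac_row_selective,
            "frac_col_selective": self.frac_col_selective,
            "incorrect_frac": self.incorrect_frac,
            "frac_persistent": self.frac_persistent,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.frac_boundary_cells + self.frac_row_selective + self.frac_col_selective > 1.0:
            raise ValueError("role fractions (boundary + row + column) sum to more than 1")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.n_units < 1 or self.n_trials_per_target < 1:
            raise ValueError("n_units and n_trials_per_target must be positive")
        if self.seed < 0:
            raise ValueError("seed must be a non-negative integer")

    def camera(self) -> Camera:
        # eye slightly behind the start position so the path's first sample
        # has positive depth under the projection
        return Camera(eye=(0.0, -self.camera_setback, self.eye_height))


@dataclass
class Session:
    """One recording day: unit roster, trial metadata, spikes and trajectories.

    ``ground_truth`` carries the planted parameters (roles, per-target peak
    times, boundary times, preferred targets) for recovery tests; it is written
    as a sidecar by :mod:`nascode.session_io` and absent for real data.
    """

    units: pd.DataFrame
    trials: pd.DataFrame
    spikes: pd.DataFrame
    trajectories: pd.DataFrame
    ground_truth: dict | None = None
    config: SynthConfig | None = None


def target_world_coords(cfg: SynthConfig) -> dict[str, np.ndarray]:
    """World (x, y, z) coordinates of the nine targets; start is the origin.

    Columns span lateral x, rows recede in depth y; adjacent targets differ by
    ``grid_spacing`` along exactly one axis.
    """
    out = {}
    for r in range(3):
        for c in range(3):
            out[target_label(r, c)] = np.array(
                [(c - 1) * cfg.grid_spacing, cfg.front_row_depth + r * cfg.grid_spacing, 0.0]
            )
    return out


def target_screen_coords(cfg: SynthConfig) -> dict[str, np.ndarray]:
    """Screen-pixel positions of the nine targets under the session camera."""
    cam = cfg.camera()
    world = target_world_coords(cfg)
    labels = list(world)
    pts = project_points(np.stack([world[l] for l in labels]), cam)
    return {l: pts[i] for i, l in enumerate(labels)}


def _normalized_screen(cfg: SynthConfig) -> dict[str, np.ndarray]:
    """Target screen coordinates standardized per axis to span [-0.5, 0.5].

    The raw pixel spans are wildly anisotropic (the lateral dimension of the
    3x3 grid covers most of the screen while the depth dimension compresses
    to a narrow vertical band); standardizing per axis lets the timing
    loadings control the anisotropy explicitly while keeping each target's
    ordering along both screen axes.
    """
    scr = target_screen_coords(cfg)
    arr = np.stack([scr[l] for l in TARGET_LABELS])
    for ax in (0, 1):
        span = arr[:, ax].max() - arr[:, ax].min()
        mid = (arr[:, ax].max() + arr[:, ax].min()) / 2.0
        arr[:, ax] = (arr[:, ax] - mid) / span if span > 0 else 0.0
    return {l: arr[i] for i, l in enumerate(TARGET_LABELS)}


def _assign_roles(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    n = cfg.n_units
    roles = np.array(["sequence"] * n, dtype=object)
    if cfg.mode == "unstructured":
        roles[:] = "unstructured"
        return roles
    if cfg.mode == "persistent":
        roles[:] = "background"
        n_p = int(round(cfg.frac_persistent * n))
        roles[:n_p] = "persistent"
        return roles
    n_b = 0 if cfg.mode == "perception_control" else int(round(cfg.frac_boundary_cells * n))
    n_r = int(round(cfg.frac_row_selective * n))
    n_c = int(round(cfg.frac_col_selective * n))
    roles[:n_b] = "boundary"
    roles[n_b : n_b + n_r] = "row_selective"
    roles[n_b + n_r : n_b + n_r + n_c] = "col_selective"
    return roles


def _plant_peaks(cfg: SynthConfig, roles: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    """Planted peak time per (unit, target); columns follow TARGET_LABELS.

    Non-boundary units get a base time tiling the trial plus a target-dependent
    offset: row/column-selective units shift by ``row_col_step_s`` per grid step
    along their axis (plus a small cross-axis term), generic sequence units
    shift linearly in the target's normalized screen coordinates. Boundary
    units peak at the configured anticipatory offsets on every target.
    """
    n = cfg.n_units
    scr = _normalized_screen(cfg)
    lo, hi = 0.15, cfg.t_end - 0.15
    base = rng.uniform(lo, hi, size=n)
    sx = np.array([scr[l][0] for l in TARGET_LABELS])
    sy = np.array([scr[l][1] for l in TARGET_LABELS])
    rows = np.array([int(l[1]) for l in TARGET_LABELS])
    cols = np.array([int(l[3]) for l in TARGET_LABELS])

    peaks = np.zeros((n, 9))
    b1 = cfg.t_delay_on - cfg.boundary_offsets_s[0]
    b2 = cfg.t_nav_on - cfg.boundary_offsets_s[1]
    n_boundary_seen = 0
    for u in range(n):
        role = roles[u]
        if role == "boundary":
            peaks[u, :] = b1 if n_boundary_seen % 2 == 0 else b2
            n_boundary_seen += 1
            continue
        if role in ("unstructured", "persistent", "background"):
            peaks[u, :] = base[u]  # unused for spiking in these roles
            continue
        if role == "row_selective":
            sign = rng.choice([-1.0, 1.0])
            cross = rng.choice([-1.0, 1.0]) * rng.uniform(*cfg.cross_axis_range_s)
            off = sign * cfg.row_col_step_s * (rows - 1) + cross * (cols - 1)
            idio = cfg.idiosyncratic_rowcol_sd_s
        elif role == "col_selective":
            sign = rng.choice([-1.0, 1.0])
            cross = rng.choice([-1.0, 1.0]) * rng.uniform(*cfg.cross_axis_range_s)
            off = sign * cfg.row_col_step_s * (cols - 1) + cross * (rows - 1)
            idio = cfg.idiosyncratic_rowcol_sd_s
        else:  # generic sequence unit: timing tied to the screen view of the target
            ax = rng.choice([-1.0, 1.0]) * rng.uniform(*cfg.screen_loading_x)
            ay = rng.choice([-1.0, 1.0]) * rng.uniform(*cfg.screen_loading_y)
            off = ax * sx + ay * sy
            idio = cfg.idiosyncratic_sd_s
        # Idiosyncratic per-target term: consistent across trials for this
        # unit but uncorrelated across units, so it perturbs each unit's
        # target ordering without biasing the population-level geometry of
        # target similarity, which averages over units.
        off = off + rng.normal(0.0, idio, size=off.size)
        if role == "sequence":
            # Respace generic units' nine offsets onto an even grid spanning
            # peak_span_range: the target ordering (the structure rank
            # statistics use) is preserved while the across-target peak
            # distribution merges into one broad band, wide relative to the
            # time-selectivity threshold — target-selective units spread
            # their peaks over seconds. Row/column-selective units keep their
            # raw block structure (three overlapping lobes already span
            # well over a second).
            span = rng.uniform(*cfg.peak_span_range_s)
            ranks = np.argsort(np.argsort(off, kind="stable"), kind="stable")
            off = (ranks / (off.size - 1.0) - 0.5) * span
        else:
            off = off - off.mean()
        # Rescale the base time so base + offset stays inside the trial for
        # every target: clipping would pile several targets' peaks onto one
        # point (faking time-selectivity) and wrapping would make single
        # units peak both early and late (blurring epoch identity).
        max_off = float(np.abs(off).max())
        lo2, hi2 = lo + max_off, hi - max_off
        b = lo2 + (base[u] - lo) / (hi - lo) * (hi2 - lo2) if hi2 > lo2 else 0.5 * (lo + hi)
        peaks[u, :] = b + off
    return pd.DataFrame(peaks, columns=TARGET_LABELS)


def _make_trials(cfg: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    reps = np.repeat(np.arange(9), cfg.n_trials_per_target)
    order = rng.permutation(reps)
    correct = rng.random(order.size) >= cfg.incorrect_frac
    rows = order // 3
    cols = order % 3
    return pd.DataFrame(
        {
            "trial_id": np.arange(order.size),
            "target_row": rows,
            "target_col": cols,
            "t_cue_on": 0.0,
            "t_delay_on": cfg.t_delay_on,
            "t_nav_on": cfg.t_nav_on,
            "t_end": cfg.t_end,
            "iti_start": cfg.t_end,
            "iti_end": cfg.t_end + cfg.iti_s,
            "correct": correct,
        }
    )


def _trial_rate_peaks(
    cfg: SynthConfig, roles: np.ndarray, peaks: pd.DataFrame, trial: pd.Series,
    rng: np.random.Generator,
) -> np.ndarray:
    """Realized (jittered) bump centers for one trial; NaN = no bump."""
    n = cfg.n_units
    lab = target_label(trial.target_row, trial.target_col)
    mult = 1.0 if trial.correct else cfg.incorrect_jitter_multiplier
    out = np.full(n, np.nan)
    planted = peaks[lab].to_numpy()
    jit = rng.normal(0.0, 1.0, size=n)
    for u in range(n):
        role = roles[u]
        if role in ("persistent", "background"):
            continue
        if role == "boundary":
            # boundary units anticipate epoch onsets regardless of target or outcome
            out[u] = planted[u] + jit[u] * cfg.boundary_jitter_sd_s
        elif role == "unstructured":
            out[u] = rng.uniform(0.1, cfg.t_end - 0.1)
        else:
            out[u] = planted[u] + jit[u] * cfg.peak_jitter_sd_s * mult
    return out


def _draw_spikes_for_trial(
    cfg: SynthConfig,
    roles: np.ndarray,
    bump_centers: np.ndarray,
    trial: pd.Series,
    preferred: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Thinning of an inhomogeneous Poisson process, vectorized over units.

    The rate is background plus (within the trial window) a Gaussian bump at
    the realized peak, or, for persistent units on preferred-target trials, a
    sustained elevation throughout the delay. The inter-trial interval carries
    background (or baseline) rate only.
    """
    n = cfg.n_units
    t_total = float(trial.iti_end)
    lab = target_label(trial.target_row, trial.target_col)

    lam_bg = np.full(n, cfg.background_rate_hz)
    is_pers = roles == "persistent"
    lam_bg[is_pers] = cfg.persistent_baseline_hz
    # unit-and-trial-specific multiplicative rate gain (mean 1)
    sd = cfg.rate_variability_sd
    gain = np.exp(rng.normal(0.0, sd, size=n) - 0.5 * sd * sd) if sd > 0 else np.ones(n)
    amp = cfg.bump_amplitude_hz * gain
    tuned_rate = cfg.persistent_baseline_hz + (
        cfg.persistent_tuned_rate_hz - cfg.persistent_baseline_hz
    ) * gain
    lam_max = lam_bg + np.where(np.isfinite(bump_centers), amp, 0.0)
    if is_pers.any():
        lam_max[is_pers] = np.maximum(cfg.persistent_baseline_hz, tuned_rate[is_pers])

    counts = rng.poisson(lam_max * t_total)
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=int), np.empty(0)
    uidx = np.repeat(np.arange(n), counts)
    times = rng.uniform(0.0, t_total, size=total)
    u_accept = rng.random(total)

    rate = lam_bg[uidx].astype(float)
    centers = bump_centers[uidx]
    in_trial = times < trial.t_end
    has_bump = np.isfinite(centers) & in_trial
    if has_bump.any():
        sig = cfg.bump_sigma_s
        rate[has_bump] += amp[uidx[has_bump]] * np.exp(
            -0.5 * ((times[has_bump] - centers[has_bump]) / sig) ** 2
        )
    if is_pers.any():
        tuned = is_pers[uidx] & (preferred[uidx] == lab)
        in_delay = (times >= trial.t_delay_on) & (times < trial.t_nav_on)
        boost = tuned & in_delay
        rate[boost] = tuned_rate[uidx[boost]]

    keep = u_accept * lam_max[uidx] < rate
    uidx, times = uidx[keep], times[keep]
    order = np.lexsort((times, uidx))
    return uidx[order], times[order]


def generate_trajectories(
    cfg: SynthConfig, trials: pd.DataFrame, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """3-D movement paths: start -> target at fixed speed with lateral noise.

    Correct trials end exactly on target (up to noise, which tapers to zero at
    both endpoints so the zero-noise endpoint equals the target coordinate);
    incorrect trials aim at a point displaced from the target by roughly a
    grid step. Times are absolute trial times starting at navigation onset.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    world = target_world_coords(cfg)
    recs = []
    for trial in trials.itertuples():
        tgt = world[target_label(trial.target_row, trial.target_col)].copy()
        if not trial.correct:
            ang = rng.uniform(0, 2 * np.pi)
            mag = rng.uniform(0.5, 1.5) * cfg.grid_spacing
            tgt = tgt + np.array([np.cos(ang) * mag, np.sin(ang) * mag, 0.0])
        start = np.zeros(3)
        dist = float(np.linalg.norm(tgt - start))
        dur = dist / cfg.move_speed
        nt = max(int(np.ceil(dur * cfg.traj_sample_hz)) + 1, 2)
        t_rel = np.linspace(0.0, dur, nt)
        frac = t_rel / dur if dur > 0 else np.zeros(nt)
        pos = start[None, :] + frac[:, None] * (tgt - start)[None, :]
        if cfg.trajectory_noise_sd > 0 and dist > 0:
            direction = (tgt - start) / dist
            perp = np.array([-direction[1], direction[0], 0.0])
            taper = np.sin(np.pi * frac)
            pos = pos + perp[None, :] * (rng.normal(0, cfg.trajectory_noise_sd, nt) * taper)[:, None]
        recs.append(
            pd.DataFrame(
                {
                    "trial_id": trial.trial_id,
                    "t_s": trial.t_nav_on + t_rel,
                    "x": pos[:, 0],
                    "y": pos[:, 1],
                    "z": pos[:, 2],
                }
            )
        )
    return pd.concat(recs, ignore_index=True)


def generate_session(cfg: SynthConfig) -> Session:
    """Draw a complete synthetic session from a validated configuration."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    roles = _assign_roles(cfg, rng)
    peaks = _plant_peaks(cfg, roles, rng)
    preferred = np.array(
        [TARGET_LABELS[rng.integers(9)] if roles[u] == "persistent" else "" for u in range(cfg.n_units)],
        dtype=object,
    )
    trials = _make_trials(cfg, rng)

    spike_frames = []
    for _, trial in trials.iterrows():
        centers = _trial_rate_peaks(cfg, roles, peaks, trial, rng)
        uidx, times = _draw_spikes_for_trial(cfg, roles, centers, trial, preferred, rng)
        if uidx.size:
            spike_frames.append(
                pd.DataFrame(
                    {"unit_id": uidx, "trial_id": int(trial.trial_id), "t_s": times}
                )
            )
    spikes = (
        pd.concat(spike_frames, ignore_index=True)
        if spike_frames
        else pd.DataFrame(columns=["unit_id", "trial_id", "t_s"])
    )
    spikes = spikes.sort_values(["trial_id", "unit_id", "t_s"], kind="stable").reset_index(drop=True)

    trajectories = generate_trajectories(cfg, trials, rng)

    units = pd.DataFrame({"unit_id": np.arange(cfg.n_units), "role": roles})
    ground_truth = {
        "mode": cfg.mode,
        "roles": {int(u): str(r) for u, r in zip(units.unit_id, units.role)},
        "planted_peaks": {int(u): peaks.iloc[u].to_dict() for u in range(cfg.n_units)},
        "boundary_times": {
            "pre_delay": float(cfg.t_delay_on - cfg.boundary_offsets_s[0]),
            "pre_nav": float(cfg.t_nav_on - cfg.boundary_offsets_s[1]),
        },
        "preferred_target": {int(u): str(p) for u, p in enumerate(preferred) if p},
        "config": asdict(cfg),
    }
    return Session(
        units=units,
        trials=trials,
        spikes=spikes,
        trajectories=trajectories,
        ground_truth=ground_truth,
        config=cfg,
    )
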