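"""Spike-density estimation and sequence-vector construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nascode.sequences import (
    build_sequences,
    included_units,
    mask_epoch,
    peak_time,
    spike_density,
)


class TestSpikeDensity:
    def test_empty_train_gives_zero_density(self):
        grid, values = spike_density([], (0.0, 5.0))
        assert np.all(values == 0.0)

    def test_single_spike_peak_location_and_height(self):
        # closed form: a unit-mass Gaussian of SD 0.1 s peaks at 1/(0.1*sqrt(2*pi))
        grid, values = spike_density([2.0], (0.0, 5.0), kernel_sd=0.1)
        assert peak_time(grid, values) == pytest.approx(2.0, abs=1e-9)
        assert values.max() == pytest.approx(1.0 / (0.1 * np.sqrt(2 * np.pi)), rel=1e-3)

    def test_two_far_spikes_give_equal_maxima(self):
        grid, values = spike_density([1.0, 3.0], (0.0, 5.0), kernel_sd=0.1)
        i1 = np.argmin(np.abs(grid - 1.0))
        i3 = np.argmin(np.abs(grid - 3.0))
        assert values[i1] == pytest.approx(values[i3], rel=1e-9)
        # both are local maxima of the same height as the global max
        assert values[i1] == pytest.approx(values.max(), rel=1e-6)

    def test_density_integrates_to_spike_count(self):
        spikes = [1.0, 2.0, 2.5, 4.0]
        grid, values = spike_density(spikes, (0.0, 6.0), kernel_sd=0.1, dt=0.001)
        assert np.trapezoid(values, grid) == pytest.approx(len(spikes), rel=1e-3)

    def test_unsorted_and_out_of_window_rejected(self):
        with pytest.raises(ValueError):
            spike_density([2.0, 1.0], (0.0, 5.0))
        with pytest.raises(ValueError):
            spike_density([6.0], (0.0, 5.0))
        with pytest.raises(ValueError):
            spike_density([1.0], (3.0, 3.0))

    @given(
        shift=st.floats(min_value=-0.9, max_value=0.9),
        spikes=st.lists(st.floats(min_value=1.0, max_value=4.0), min_size=1, max_size=12),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_shift_equivariance(self, shift, spikes):
        """Translating every spike by a grid-aligned delta translates the
        density (and hence, up to exact ties, every peak time)."""
        dt = 0.001
        shift = round(shift / dt) * dt
        nshift = int(round(shift / dt))
        spikes = sorted(round(s / dt) * dt for s in spikes)
        g0, v0 = spike_density(spikes, (0.0, 6.0), dt=dt)
        g1, v1 = spike_density([s + shift for s in spikes], (0.0, 6.0), dt=dt)
        # compare on the overlap region, away from the window edges
        lo, hi = 1000, 5000
        assert np.allclose(v1[lo + nshift : hi + nshift], v0[lo:hi], atol=1e-8)

    @pytest.mark.parametrize("kernel_sd", [0.02, 0.1, 0.4])
    def test_single_spike_peak_invariant_to_kernel_scale(self, kernel_sd):
        grid, values = spike_density([2.5], (0.0, 6.0), kernel_sd=kernel_sd)
        assert peak_time(grid, values) == pytest.approx(2.5, abs=1e-9)


class TestPeakTime:
    def test_unique_maximum(self):
        grid = np.arange(0, 4, 0.001)
        values = np.exp(-((grid - 2.0) ** 2))
        assert peak_time(grid, values) == pytest.approx(2.0, abs=1e-3)

    def test_all_zero_is_missing(self):
        grid = np.arange(0, 4, 0.001)
        assert np.isnan(peak_time(grid, np.zeros_like(grid)))

    def test_plateau_tie_breaks_to_earliest(self):
        grid = np.arange(0, 2, 0.001)
        values = np.where((grid >= 1.0) & (grid <= 1.2), 5.0, 1.0)
        assert peak_time(grid, values) == pytest.approx(1.0, abs=1e-9)


class TestMaskEpoch:
    def setup_method(self):
        self.seqs = pd.DataFrame(
            [[0.5, 2.0, 4.0], [1.0, 3.0, 5.0]], index=[0, 1], columns=["a", "b", "c"]
        )

    def test_full_trial_window_is_identity(self):
        out = mask_epoch(self.seqs, (0.0, 10.0))
        pd.testing.assert_frame_equal(out, self.seqs)

    def test_zero_length_window_masks_everything(self):
        out = mask_epoch(self.seqs, (2.0, 2.0))
        assert out.isna().all().all()

    def test_half_open_convention(self):
        out = mask_epoch(self.seqs, (2.0, 5.0))
        assert out.loc[0, "b"] == 2.0          # exactly at start: kept
        assert np.isnan(out.loc[1, "c"])       # exactly at end: masked
        assert np.isnan(out.loc[0, "a"])

    def test_inverted_window_rejected(self):
        with pytest.raises(ValueError):
            mask_epoch(self.seqs, (3.0, 1.0))


class TestBuildSequences:
    def test_zero_spike_unit_excluded(self, small_session):
        session = small_session
        # remove one unit's spikes entirely
        import copy
        s2 = copy.copy(session)
        victim = session.units["unit_id"].iloc[0]
        s2.spikes = session.spikes[session.spikes["unit_id"] != victim]
        seqs = build_sequences(s2)
        assert victim not in seqs.columns

    def test_rate_criterion_error_when_no_unit_passes(self, small_session):
        import copy
        s2 = copy.copy(small_session)
        s2.spikes = small_session.spikes.iloc[:0]
        with pytest.raises(ValueError, match="firing-rate criterion"):
            included_units(s2)

    def test_identical_trials_give_identical_vectors(self, small_session):
        """Two trials with byte-identical spike tables map to equal vectors."""
        import copy
        s2 = copy.copy(small_session)
        spk = small_session.spikes
        t0, t1 = small_session.trials["trial_id"].iloc[:2]
        cloned = spk[spk.trial_id == t0].assign(trial_id=t1)
        s2.spikes = pd.concat([spk[~spk.trial_id.isin([t1])], cloned], ignore_index=True)
        seqs = build_sequences(s2)
        pd.testing.assert_series_equal(
            seqs.loc[t0], seqs.loc[t1], check_names=False
        )

    def test_unit_order_fixed_across_trials(self, small_seqs):
        assert small_seqs.columns.is_monotonic_increasing

    def test_noiseless_recovery_of_planted_peaks(self):
        """With no jitter, no background and a strong bump, recovered peak
        times sit within a kernel SD of the planted times."""
        from nascode.synth import SynthConfig, generate_session, target_label
        cfg = SynthConfig(
            n_units=30, n_trials_per_target=3, peak_jitter_sd_s=0.0,
            background_rate_hz=0.0, bump_amplitude_hz=120.0,
            incorrect_frac=0.0, frac_boundary_cells=0.0, seed=7,
        )
        session = generate_session(cfg)
        seqs = build_sequences(session, min_rate_hz=0.0)
        planted = session.ground_truth["planted_peaks"]
        tr = session.trials.set_index("trial_id")
        errs = []
        for tid in seqs.index:
            lab = target_label(tr.loc[tid, "target_row"], tr.loc[tid, "target_col"])
            for u in seqs.columns:
                got = seqs.loc[tid, u]
                if np.isfinite(got):
                    errs.append(abs(got - planted[u][lab]))
        assert np.mean(errs) < 0.1  # mean abs error below the kernel SD

    def test_sorted_raster_reproduces_planted_order(self):
        """Ordering units by recovered peak time on one trial reproduces the
        planted ordering (the monotone band of a sorted population raster)."""
        from scipy.stats import spearmanr
        from nascode.synth import SynthConfig, generate_session, target_label
        cfg = SynthConfig(
            n_units=40, n_trials_per_target=2, peak_jitter_sd_s=0.02,
            background_rate_hz=0.5, bump_amplitude_hz=80.0,
            incorrect_frac=0.0, frac_boundary_cells=0.0, seed=3,
        )
        session = generate_session(cfg)
        seqs = build_sequences(session, min_rate_hz=0.0)
        tr = session.trials.set_index("trial_id")
        tid = seqs.index[0]
        lab = target_label(tr.loc[tid, "target_row"], tr.loc[tid, "target_col"])
        row = seqs.loc[tid].dropna()
        planted = np.array([session.ground_truth["planted_peaks"][u][lab] for u in row.index])
        rho = spearmanr(row.to_numpy(), planted).statistic
        assert rho > 0.95
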