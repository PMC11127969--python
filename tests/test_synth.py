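"""Synthetic-session generator: determinism, statistics, geometry."""

import numpy as np
import pandas as pd
import pytest

from nascode.synth import (
    SynthConfig,
    generate_session,
    generate_trajectories,
    target_label,
    target_world_coords,
)


class TestConfigValidation:
    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError, match="strictly positive"):
            SynthConfig(cue_s=-1.0).validate()

    def test_role_fractions_over_one_rejected(self):
        with pytest.raises(ValueError, match="sum to more than 1"):
            SynthConfig(
                frac_boundary_cells=0.5, frac_row_selective=0.4, frac_col_selective=0.3
            ).validate()

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            SynthConfig(mode="telepathy").validate()

    def test_negative_seed_rejected(self):
        with pytest.raises(ValueError, match="seed"):
            SynthConfig(seed=-1).validate()

    def test_bump_sigma_matches_printed_width(self):
        # the duration at 80% of the bump maximum is the printed statistic
        cfg = SynthConfig()
        sig = cfg.bump_sigma_s
        width80 = 2.0 * sig * np.sqrt(2.0 * np.log(1.0 / 0.8))
        assert width80 == pytest.approx(0.22, abs=1e-12)


class TestDeterminism:
    def test_same_seed_same_session(self):
        cfg = SynthConfig(n_units=20, n_trials_per_target=3, seed=42)
        s1 = generate_session(cfg)
        s2 = generate_session(cfg)
        pd.testing.assert_frame_equal(s1.spikes, s2.spikes)
        pd.testing.assert_frame_equal(s1.trials, s2.trials)
        pd.testing.assert_frame_equal(s1.trajectories, s2.trajectories)

    def test_different_seed_different_spikes(self):
        a = generate_session(SynthConfig(n_units=20, n_trials_per_target=3, seed=1))
        b = generate_session(SynthConfig(n_units=20, n_trials_per_target=3, seed=2))
        assert not a.spikes.equals(b.spikes)


class TestSessionInvariants:
    def test_spikes_sorted_and_within_recording(self, small_session):
        s = small_session
        end = s.trials.set_index("trial_id")["iti_end"]
        joined = s.spikes.join(end, on="trial_id")
        assert (joined["t_s"] >= 0).all()
        assert (joined["t_s"] < joined["iti_end"]).all()
        for (_, _), g in s.spikes.groupby(["unit_id", "trial_id"]):
            assert g["t_s"].is_monotonic_increasing

    def test_epoch_onsets_strictly_increasing(self, small_session):
        t = small_session.trials
        assert ((t.t_cue_on < t.t_delay_on) & (t.t_delay_on < t.t_nav_on)
                & (t.t_nav_on < t.t_end)).all()

    def test_every_trial_has_one_target(self, small_session):
        t = small_session.trials
        assert t.target_row.isin([0, 1, 2]).all()
        assert t.target_col.isin([0, 1, 2]).all()
        counts = t.groupby(["target_row", "target_col"]).size()
        assert len(counts) == 9

    def test_boundary_cell_fraction_as_configured(self):
        cfg = SynthConfig(n_units=100, n_trials_per_target=2, frac_boundary_cells=0.1, seed=0)
        s = generate_session(cfg)
        assert (s.units["role"] == "boundary").sum() == 10


class TestSpikeStatistics:
    def test_background_poisson_expectation(self):
        """1000 trials of pure background at 5 Hz over a 6.5 s trial: the mean
        count per trial should sit within 3 standard errors of rate*duration."""
        cfg = SynthConfig(
            n_units=1, n_trials_per_target=112, mode="unstructured",
            background_rate_hz=5.0, bump_amplitude_hz=0.0, iti_s=0.5,
            incorrect_frac=0.0, seed=13,
        )
        s = generate_session(cfg)
        in_trial = s.spikes[s.spikes["t_s"] < 6.5]
        n_trials = len(s.trials)
        counts = in_trial.groupby("trial_id").size().reindex(s.trials.trial_id, fill_value=0)
        expected = 5.0 * 6.5
        se = np.sqrt(expected / n_trials)
        assert abs(counts.mean() - expected) < 3 * se

    def test_noiseless_limit_recovers_planted_peaks_tightly(self):
        """Zero jitter and zero background: downstream per-condition peak-time
        SD collapses to the spike-sampling floor, far below the kernel SD."""
        from nascode.sequences import build_sequences
        from nascode.consistency import peak_sd

        cfg = SynthConfig(
            n_units=20, n_trials_per_target=6, peak_jitter_sd_s=0.0,
            background_rate_hz=0.0, bump_amplitude_hz=150.0,
            frac_boundary_cells=0.0, incorrect_frac=0.0, seed=2,
        )
        s = generate_session(cfg)
        seqs = build_sequences(s, min_rate_hz=0.0)
        tr = s.trials.set_index("trial_id")
        labels = tr.apply(lambda r: target_label(r.target_row, r.target_col), axis=1)
        sd = peak_sd(seqs, labels.loc[seqs.index], min_trials=5)
        assert np.nanmean(sd.to_numpy()) < 0.1  # well below the kernel SD


class TestTrajectories:
    def test_adjacent_targets_spaced_290_units(self):
        cfg = SynthConfig()
        w = target_world_coords(cfg)
        d_col = np.linalg.norm(w["r0c0"] - w["r0c1"])
        d_row = np.linalg.norm(w["r0c0"] - w["r1c0"])
        assert d_col == pytest.approx(290.0)
        assert d_row == pytest.approx(290.0)

    def test_travel_time_between_adjacent_targets_half_second(self):
        cfg = SynthConfig()
        assert cfg.grid_spacing / cfg.move_speed == pytest.approx(0.5)

    def test_zero_noise_endpoint_is_target(self):
        cfg = SynthConfig(n_units=5, n_trials_per_target=1, trajectory_noise_sd=0.0,
                          incorrect_frac=0.0, seed=4)
        s = generate_session(cfg)
        w = target_world_coords(cfg)
        for tid, g in s.trajectories.groupby("trial_id"):
            row = s.trials.set_index("trial_id").loc[tid]
            tgt = w[target_label(row.target_row, row.target_col)]
            assert np.allclose(g[["x", "y", "z"]].iloc[-1].to_numpy(), tgt, atol=1e-9)

    def test_incorrect_trials_end_off_target(self):
        cfg = SynthConfig(n_units=5, n_trials_per_target=4, incorrect_frac=0.99,
                          trajectory_noise_sd=0.0, seed=6)
        s = generate_session(cfg)
        w = target_world_coords(cfg)
        wrong = 0
        for tid, g in s.trajectories.groupby("trial_id"):
            row = s.trials.set_index("trial_id").loc[tid]
            if row.correct:
                continue
            tgt = w[target_label(row.target_row, row.target_col)]
            endpoint = g[["x", "y", "z"]].iloc[-1].to_numpy()
            if np.linalg.norm(endpoint - tgt) > 100.0:
                wrong += 1
        assert wrong > 0
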