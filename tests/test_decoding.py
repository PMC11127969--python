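"""Nearest-centroid and SVM decoding, selectivity, persistence, replay."""

import numpy as np
import pandas as pd
import pytest

from nascode.decoding import (
    cohens_d,
    find_persistent_cells,
    nearest_centroid_cv,
    same_trial_replay_test,
    select_units,
    selectivity_scores,
)
from tests.conftest import make_seqs


class TestNearestCentroid:
    def test_well_separated_clusters_decode_perfectly(self):
        rng = np.random.default_rng(0)
        centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        X = np.vstack([c + rng.normal(0, 0.1, size=(20, 2)) for c in centers])
        y = np.repeat(["a", "b", "c"], 20)
        rep = nearest_centroid_cv(pd.DataFrame(X), y, k_folds=5, seed=0)
        assert rep.mean_accuracy == 1.0
        assert rep.chance == pytest.approx(1.0 / 3.0)

    def test_point_on_centroid_takes_its_label(self):
        X = np.array([[0.0, 0.0]] * 10 + [[5.0, 5.0]] * 10)
        y = np.array(["a"] * 10 + ["b"] * 10)
        rep = nearest_centroid_cv(pd.DataFrame(X), y, k_folds=2, seed=1)
        assert rep.mean_accuracy == 1.0

    def test_distance_tie_breaks_to_lowest_class(self):
        # symmetric configuration: test point equidistant from both centroids
        X = np.array([[-1.0, 0.0]] * 5 + [[1.0, 0.0]] * 5 + [[0.0, 0.0]])
        y = np.array(["a"] * 5 + ["b"] * 5 + ["a"])
        rep = nearest_centroid_cv(pd.DataFrame(X), y, k_folds=2, seed=0)
        tied = rep.predictions.iloc[10]
        assert tied == "a"

    def test_permuted_labels_decode_at_chance(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(1080, 3))
        y = rng.permutation(np.repeat([f"c{i}" for i in range(9)], 120))
        rep = nearest_centroid_cv(pd.DataFrame(X), y, k_folds=5, seed=0)
        p = 1.0 / 9.0
        se = np.sqrt(p * (1 - p) / len(y))
        assert abs(rep.mean_accuracy - p) < 3 * se

    def test_rigid_rotation_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 3)) + np.repeat(np.eye(3) * 5, 20, axis=0)
        y = np.repeat(["a", "b", "c"], 20)
        rep1 = nearest_centroid_cv(pd.DataFrame(X), y, k_folds=5, seed=0)
        theta = 0.7
        R = np.array([
            [np.cos(theta), -np.sin(theta), 0.0],
            [np.sin(theta), np.cos(theta), 0.0],
            [0.0, 0.0, 1.0],
        ])
        rep2 = nearest_centroid_cv(pd.DataFrame(X @ R.T), y, k_folds=5, seed=0)
        assert rep1.fold_accuracies == pytest.approx(rep2.fold_accuracies)

    def test_class_smaller_than_fold_count_rejected(self):
        X = np.zeros((7, 2))
        y = np.array(["a"] * 5 + ["b"] * 2)
        with pytest.raises(ValueError, match="fewer trials than folds"):
            nearest_centroid_cv(pd.DataFrame(X), y, k_folds=5)


class TestSelectivity:
    def test_identical_distributions_score_zero(self):
        d = cohens_d(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]))
        assert d == 0.0

    def test_cohens_d_direct_formula(self):
        # means 1.0 and 2.0 s, common SD 0.5 s -> d = 2.0
        rng = np.random.default_rng(0)
        x = rng.normal(1.0, 0.5, 4000)
        y = rng.normal(2.0, 0.5, 4000)
        assert cohens_d(y, x) == pytest.approx(2.0, rel=0.05)

    def test_zero_pooled_sd_with_unequal_means_is_infinite(self):
        with pytest.warns(UserWarning, match="zero pooled SD"):
            assert np.isinf(cohens_d(np.ones(5), np.full(5, 2.0)))

    def test_selected_sets_shrink_with_percentile(self):
        rng = np.random.default_rng(2)
        scores = pd.Series(rng.random(100))
        s50 = select_units(scores, 50.0)
        s90 = select_units(scores, 90.0)
        assert set(s90) <= set(s50)
        assert len(s90) < len(s50)

    def test_planted_row_selective_units_score_highest(self, small_session, small_seqs):
        tr = small_session.trials.set_index("trial_id")
        rows = tr.loc[small_seqs.index, "target_row"].astype(int)
        scores = selectivity_scores(small_seqs, rows)
        roles = small_session.units.set_index("unit_id")["role"]
        row_units = [u for u in small_seqs.columns if roles[u] == "row_selective"]
        other = [u for u in small_seqs.columns if roles[u] == "sequence"]
        assert scores[row_units].mean() > scores[other].mean()


class TestPersistentCells:
    def test_planted_persistent_units_detected(self):
        from nascode.synth import SynthConfig, generate_session
        cfg = SynthConfig(
            n_units=40, n_trials_per_target=20, mode="persistent",
            persistent_tuned_rate_hz=10.0, persistent_baseline_hz=2.0,
            incorrect_frac=0.0, seed=5,
        )
        s = generate_session(cfg)
        res = find_persistent_cells(s, p_threshold=0.05)
        roles = s.units.set_index("unit_id")["role"]
        planted = set(roles[roles == "persistent"].index)
        detected = set(res.unit_ids.tolist())
        assert len(detected & planted) / len(planted) > 0.9

    def test_homogeneous_units_detected_at_nominal_rate(self):
        """Pure background units should pass the two-criterion screen at a
        rate no higher than roughly the nominal alpha."""
        from nascode.synth import SynthConfig, generate_session
        hits, total = 0, 0
        for seed in range(3):
            cfg = SynthConfig(
                n_units=60, n_trials_per_target=10, mode="persistent",
                frac_persistent=0.0, incorrect_frac=0.0, seed=seed,
            )
            s = generate_session(cfg)
            res = find_persistent_cells(s, p_threshold=0.05)
            hits += res.unit_ids.size
            total += cfg.n_units
        # two independent criteria at alpha=0.05 each: expected rate << 0.05
        assert hits / total < 0.05

    def test_membership_monotone_in_threshold(self):
        from nascode.synth import SynthConfig, generate_session
        cfg = SynthConfig(
            n_units=40, n_trials_per_target=12, mode="persistent",
            incorrect_frac=0.0, seed=9,
        )
        s = generate_session(cfg)
        sizes = [
            find_persistent_cells(s, p_threshold=p).unit_ids.size
            for p in (0.001, 0.01, 0.05)
        ]
        assert sizes == sorted(sizes)


class TestReplay:
    def test_constructed_replay_detected_in_every_trial(self):
        rng = np.random.default_rng(0)
        delay = rng.random((20, 30)) * 5
        # navigation sequences identical to delay per trial, distinct across
        nav = delay.copy()
        frac = same_trial_replay_test(make_seqs(delay), make_seqs(nav), min_overlap=5)
        assert frac == 1.0

    def test_independent_epochs_near_nominal_rate(self):
        rng = np.random.default_rng(1)
        delay = rng.random((200, 30)) * 5
        nav = rng.random((200, 30)) * 5
        frac = same_trial_replay_test(make_seqs(delay), make_seqs(nav), min_overlap=5)
        assert abs(frac - 0.05) < 0.05

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError):
            same_trial_replay_test(make_seqs([[1.0]]), make_seqs([[1.0]]))
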