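"""Perspective projection, trajectory averaging, Frechet distances and the
sequence-behavior link."""

import itertools

import numpy as np
import pandas as pd
import pytest

from nascode.behavior import (
    Camera,
    average_trajectory,
    discrete_frechet,
    frechet_matrix,
    link_correlation,
    project_points,
    resample_path,
)


def brute_force_frechet(A, B):
    """Exhaustive minimax over all monotone couplings (oracle for short paths)."""
    A = np.asarray(A, float)
    B = np.asarray(B, float)

    def rec(i, j):
        d = float(np.linalg.norm(A[i] - B[j]))
        if i == 0 and j == 0:
            return d
        opts = []
        if i > 0:
            opts.append(rec(i - 1, j))
        if j > 0:
            opts.append(rec(i, j - 1))
        if i > 0 and j > 0:
            opts.append(rec(i - 1, j - 1))
        return max(d, min(opts))

    return rec(len(A) - 1, len(B) - 1)


class TestProjection:
    def setup_method(self):
        self.cam = Camera(eye=(0.0, 0.0, 100.0))

    def test_point_on_optical_axis_hits_screen_center(self):
        pt = np.array([[0.0, 500.0, 100.0]])  # straight ahead of the eye
        s = project_points(pt, self.cam)
        assert s[0, 0] == pytest.approx(self.cam.width / 2)
        assert s[0, 1] == pytest.approx(self.cam.height / 2)

    def test_left_right_mirror_symmetry(self):
        pts = np.array([[-50.0, 400.0, 100.0], [50.0, 400.0, 100.0]])
        s = project_points(pts, self.cam)
        cx = self.cam.width / 2
        assert s[0, 0] - cx == pytest.approx(-(s[1, 0] - cx))
        assert s[0, 1] == pytest.approx(s[1, 1])

    def test_doubling_depth_halves_screen_offset(self):
        # similar triangles: lateral offset x at depth d projects to f*x/d
        near = project_points(np.array([[60.0, 300.0, 100.0]]), self.cam)
        far = project_points(np.array([[60.0, 600.0, 100.0]]), self.cam)
        cx = self.cam.width / 2
        assert (near[0, 0] - cx) == pytest.approx(2.0 * (far[0, 0] - cx))

    def test_points_behind_near_plane_dropped_with_warning(self):
        pts = np.array([[0.0, -5.0, 100.0], [0.0, 400.0, 100.0]])
        with pytest.warns(UserWarning, match="near plane"):
            s = project_points(pts, self.cam)
        assert s.shape == (1, 2)

    def test_empty_path_rejected(self):
        with pytest.raises(ValueError):
            project_points(np.empty((0, 3)), self.cam)


class TestAverageTrajectory:
    def test_identical_paths_average_to_themselves(self):
        p = np.column_stack([np.linspace(0, 10, 7), np.linspace(0, 3, 7)])
        mean, outl = average_trajectory([p, p, p], n_points=20)
        assert not outl.any()
        assert np.allclose(mean, resample_path(p, 20))

    def test_gross_deviant_excluded_by_zscore_rule(self):
        base = np.column_stack([np.linspace(0, 10, 10), np.zeros(10)])
        deviant = base + np.array([0.0, 50.0])
        paths = [base.copy() for _ in range(9)] + [deviant]
        mean, outl = average_trajectory(paths, n_points=20)
        assert outl.sum() == 1 and outl[-1]
        assert np.allclose(mean, resample_path(base, 20))

    def test_two_straight_segments_average_to_midline(self):
        a = np.array([[0.0, 0.0], [10.0, 0.0]])
        b = np.array([[0.0, 4.0], [10.0, 4.0]])
        mean, _ = average_trajectory([a, b], n_points=5)
        assert np.allclose(mean[:, 1], 2.0)


class TestDiscreteFrechet:
    def test_identical_paths_distance_zero(self):
        p = np.array([[0.0, 0.0], [1.0, 2.0], [4.0, 4.0]])
        assert discrete_frechet(p, p) == 0.0

    def test_single_point_pair(self):
        assert discrete_frechet([[0.0, 0.0]], [[3.0, 4.0]]) == pytest.approx(5.0)

    def test_parallel_segments(self):
        A = [[0.0, 0.0], [4.0, 0.0]]
        B = [[0.0, 3.0], [4.0, 3.0]]
        assert discrete_frechet(A, B) == pytest.approx(3.0)

    def test_matches_brute_force_on_short_random_paths(self):
        rng = np.random.default_rng(12)
        for _ in range(60):
            A = rng.normal(size=(rng.integers(1, 7), 2))
            B = rng.normal(size=(rng.integers(1, 7), 2))
            assert discrete_frechet(A, B) == pytest.approx(brute_force_frechet(A, B), abs=1e-12)

    def test_metric_properties_on_random_triples(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            A, B, C = (rng.normal(size=(6, 2)) for _ in range(3))
            dab = discrete_frechet(A, B)
            dba = discrete_frechet(B, A)
            assert dab == pytest.approx(dba, abs=1e-12)
            assert dab <= discrete_frechet(A, C) + discrete_frechet(C, B) + 1e-12


class TestLinkCorrelation:
    def _matrix(self, values):
        labels = [f"c{i}" for i in range(values.shape[0])]
        return pd.DataFrame(values, index=labels, columns=labels)

    def test_identical_matrices_correlate_perfectly(self):
        rng = np.random.default_rng(2)
        M = rng.random((9, 9))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0)
        D = self._matrix(M)
        assert link_correlation(D, D) == pytest.approx(1.0)

    def test_decreasing_transform_gives_minus_one(self):
        rng = np.random.default_rng(3)
        M = rng.random((9, 9))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0)
        D1 = self._matrix(M)
        D2 = self._matrix(10.0 - M)
        assert link_correlation(D1, D2) == pytest.approx(-1.0)

    def test_constant_matrix_warns_and_returns_zero(self):
        D1 = self._matrix(np.ones((4, 4)) - np.eye(4))
        rng = np.random.default_rng(4)
        M = rng.random((4, 4))
        M = (M + M.T) / 2
        with pytest.warns(UserWarning, match="constant"):
            assert link_correlation(D1, self._matrix(M)) == 0.0

    def test_frechet_matrix_normalized(self):
        paths = {
            "a": np.array([[0.0, 0.0], [1.0, 0.0]]),
            "b": np.array([[0.0, 2.0], [1.0, 2.0]]),
            "c": np.array([[0.0, 7.0], [1.0, 7.0]]),
        }
        D = frechet_matrix(paths)
        assert D.to_numpy().max() == 1.0
        assert np.allclose(np.diag(D.to_numpy()), 0.0)
        assert D.loc["a", "b"] == pytest.approx(2.0 / 7.0)
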