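import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import neurodyn as nd
from neurodyn.recurrence import (EmbeddedTrajectory, RecurrenceMatrix,
                                 line_histograms, recurrence_matrix,
                                 rqa_measures, select_delay,
                                 select_embedding_dim)

from _oracles import rqa_from_matrix


def _rm_from_binary(mat, theiler=0):
    mat = np.asarray(mat, dtype=np.uint8)
    return RecurrenceMatrix(matrix=mat, epsilon=1.0, target_rr=None,
                            metric="euclidean", theiler=theiler)


class TestDelaySelection:
    def test_sine_quarter_period(self):
        t = np.arange(1000) / 100.0
        x = np.sin(2 * np.pi * 5 * t)  # period 20 samples
        assert select_delay(x, "autocorr_zero") == 5

    def test_white_noise_delay_one(self):
        x = np.random.default_rng(0).standard_normal(5000)
        assert select_delay(x, "autocorr_zero") == 1
        assert select_delay(x, "autocorr_1_over_e") == 1

    def test_mutual_info_minimum_reasonable_for_sine(self):
        t = np.arange(2000) / 100.0
        x = np.sin(2 * np.pi * 5 * t)
        tau = select_delay(x, "mutual_info_min")
        assert 3 <= tau <= 10  # near the quarter period

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            select_delay(np.ones(100), "autocorr_zero")


class TestEmbeddingDim:
    def test_sine_embeds_in_plane(self):
        t = np.arange(1500) / 100.0
        x = np.sin(2 * np.pi * 5 * t)
        res = select_embedding_dim(x, tau=5, max_m=6)
        assert res.converged and res.m == 2

    def test_lorenz_low_dimensional(self, lorenz_x):
        res = select_embedding_dim(lorenz_x[:1200], tau=11, max_m=6)
        assert res.converged and res.m <= 4

    def test_noise_never_saturates(self):
        x = np.random.default_rng(1).standard_normal(800)
        with pytest.warns(UserWarning):
            res = select_embedding_dim(x, tau=1, max_m=6, threshold=0.02)
        assert res.m == 6 and not res.converged


class TestDelayEmbed:
    def test_point_count(self):
        traj = nd.delay_embed(np.arange(10.0), m=3, tau=2)
        assert traj.points.shape == (6, 3)

    def test_m_one_is_identity(self):
        x = np.arange(5.0)
        np.testing.assert_array_equal(nd.delay_embed(x, 1, 1).points.ravel(), x)

    def test_rows_by_construction(self):
        traj = nd.delay_embed([1.0, 2.0, 3.0, 4.0], m=2, tau=1)
        np.testing.assert_array_equal(traj.points, [[1, 2], [2, 3], [3, 4]])

    @settings(deadline=None, max_examples=30)
    @given(st.integers(2, 5), st.integers(1, 4), st.integers(0, 30))
    def test_shape_invariant(self, m, tau, extra):
        n = (m - 1) * tau + 2 + extra
        traj = nd.delay_embed(np.arange(float(n)), m, tau)
        assert traj.points.shape == (n - (m - 1) * tau, m)
        # each row is the lagged coordinate vector
        np.testing.assert_array_equal(
            traj.points[0], np.arange(0, m * tau, tau, dtype=float))

    def test_insufficient_length_rejected(self):
        with pytest.raises(ValueError):
            nd.delay_embed(np.arange(4.0), m=3, tau=2)


class TestRecurrenceMatrix:
    def test_fixed_rr_achieves_target_on_lorenz(self, lorenz_x):
        tau = select_delay(lorenz_x[:2000], "autocorr_zero")
        traj = nd.delay_embed(lorenz_x[:2000], 3, tau)
        R = recurrence_matrix(traj, target_rr=0.05, theiler=tau)
        assert abs(R.recurrence_rate() - 0.05) <= 0.005

    def test_epsilon_zero_identity_only(self):
        pts = np.arange(12.0).reshape(-1, 1)
        R = recurrence_matrix(pts, epsilon=0.0)
        np.testing.assert_array_equal(R.matrix, np.eye(12, dtype=np.uint8))

    def test_identical_points_all_ones_with_warning(self):
        pts = np.zeros((15, 2))
        with pytest.warns(UserWarning):
            R = recurrence_matrix(pts, target_rr=0.1)
        assert R.matrix.all() and R.degenerate

    def test_symmetric_unit_diagonal(self, lorenz_x):
        traj = nd.delay_embed(lorenz_x[:400], 3, 11)
        R = recurrence_matrix(traj, target_rr=0.08, theiler=11)
        np.testing.assert_array_equal(R.matrix, R.matrix.T)
        assert R.matrix.diagonal().all()

    def test_raising_epsilon_never_decreases_density(self, lorenz_x):
        traj = nd.delay_embed(lorenz_x[:300], 3, 11)
        rrs = [recurrence_matrix(traj, epsilon=e, theiler=11).recurrence_rate()
               for e in (1.0, 3.0, 8.0, 20.0)]
        assert all(b >= a for a, b in zip(rrs, rrs[1:]))

    def test_argument_validation(self):
        pts = np.random.default_rng(2).standard_normal((50, 2))
        with pytest.raises(ValueError):
            recurrence_matrix(pts)
        with pytest.raises(ValueError):
            recurrence_matrix(pts, target_rr=0.05, epsilon=1.0)
        with pytest.raises(ValueError):
            recurrence_matrix(pts[:5], target_rr=0.05)


class TestLineHistogramsAgainstOracle:
    def test_all_ones_matrix(self):
        R = _rm_from_binary(np.ones((5, 5)), theiler=1)
        diag, vert, white = line_histograms(R, 2)
        # offsets 2,3,4 give maximal runs of length 3,2,1, each counted twice
        assert dict(diag.counts) == {3: 2, 2: 2, 1: 2}
        assert white.counts == {}

    def test_checkerboard_verticals_are_all_singletons(self):
        # a checkerboard alternates down every column, so vertical (and
        # interior white-vertical) runs all have length 1; its diagonals are
        # constant by parity, giving one full line per recurrent offset
        mat = np.indices((8, 8)).sum(axis=0) % 2
        R = _rm_from_binary(mat, theiler=0)
        diag, vert, white = line_histograms(R, 2)
        assert vert.max_length() == 1
        assert white.max_length() == 1
        assert dict(diag.counts) == {7: 2, 5: 2, 3: 2, 1: 2}

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("theiler", [0, 1, 2])
    def test_random_matrices_match_brute_force(self, seed, theiler):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 9))
        mat = (rng.random((n, n)) < 0.45).astype(np.uint8)
        mat = np.triu(mat) | np.triu(mat).T  # symmetrize
        np.fill_diagonal(mat, 1)
        R = _rm_from_binary(mat, theiler=theiler)
        got = rqa_measures(R, lmin=2)
        expected = rqa_from_matrix(mat.tolist(), theiler=theiler, lmin=2)
        for key, val in expected.items():
            assert got[key] == pytest.approx(val, abs=1e-12), key


class TestRQAMeasures:
    def test_sine_is_fully_deterministic(self, sine_2000):
        tau = select_delay(sine_2000, "autocorr_zero")
        traj = nd.delay_embed(sine_2000, 3, tau)
        R = recurrence_matrix(traj, target_rr=0.05, theiler=tau)
        m = rqa_measures(R, lmin=2)
        assert m["det"] == pytest.approx(1.0, abs=0.02)

    def test_noise_has_low_determinism(self):
        x = np.random.default_rng(3).standard_normal(2000)
        traj = nd.delay_embed(x, 3, 2)
        R = recurrence_matrix(traj, target_rr=0.05, theiler=2)
        m = rqa_measures(R, lmin=2)
        assert m["det"] < 0.3
        assert m["det"] >= 0.0

    def test_bounds_and_flags(self, lorenz_x):
        traj = nd.delay_embed(lorenz_x[:600], 3, 11)
        R = recurrence_matrix(traj, target_rr=0.05, theiler=11)
        m = rqa_measures(R, lmin=2)
        assert 0.0 <= m["det"] <= 1.0
        assert 0.0 <= m["lam"] <= 1.0
        assert m["lmax"] <= R.n_points - 1
        assert m["lentr"] >= 0 and m["vert_ent"] >= 0
        assert m["white_vert_ent"] >= 0

    def test_lmin_validation(self, sine_2000):
        traj = nd.delay_embed(sine_2000[:200], 2, 6)
        R = recurrence_matrix(traj, target_rr=0.1, theiler=6)
        with pytest.raises(ValueError):
            rqa_measures(R, lmin=1)


def test_recurrence_plot_export_csv(tmp_path, sine_2000):
    from neurodyn.recurrence import export_recurrence_plot
    traj = nd.delay_embed(sine_2000[:300], 2, 6)
    R = recurrence_matrix(traj, target_rr=0.1, theiler=6)
    p = tmp_path / "rp.csv"
    export_recurrence_plot(R, p)
    back = np.loadtxt(p, delimiter=",", dtype=int)
    np.testing.assert_array_equal(back, R.matrix)
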