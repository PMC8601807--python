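"""PWLS cost, OS gradients, continuation schedule, OS-LALM(-OGM)."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oslalm.geometry import Image, Sinogram, make_geometry, partition_subsets
from oslalm.projector import dense_system_matrix
from oslalm.regularization import RegularizerSpec, reg_value
from oslalm.simulate import NOISELESS, NoiseModel, simulate_sinogram
from oslalm.solvers import (
    ALL,
    SolverConfig,
    data_gradient,
    majorizer_diag,
    ogm_momentum_coeff,
    pwls_cost,
    rho_schedule,
    run_oslalm,
    run_oslalm_ogm,
)

ZERO_REG = RegularizerSpec(strengths=(0.0, 0.0, 0.0, 0.0))


def quadratic_spec(lam):
    return RegularizerSpec(potential="quadratic", strength=lam, delta=1.0)


def dense_regularizer_hessian(n, spec):
    """Dense  sum_i lam_i B_i' B_i  for the quadratic potential."""
    N = n * n
    H = np.zeros((N, N))
    for (dr, dc), lam in zip(spec.directions, spec.strengths):
        for r in range(n):
            for c in range(n):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < n and 0 <= c2 < n:
                    i, j = r * n + c, r2 * n + c2
                    H[i, i] += lam
                    H[j, j] += lam
                    H[i, j] -= lam
                    H[j, i] -= lam
    return H


class TestRhoSchedule:
    def test_starts_at_one(self):
        assert rho_schedule(0, 1e-3) == 1.0

    def test_first_step_closed_form(self):
        expected = (math.pi / 2) * math.sqrt(1 - (math.pi / 4) ** 2)
        assert rho_schedule(1, 1e-3) == pytest.approx(expected, abs=1e-12)
        assert rho_schedule(1, 1e-3) == pytest.approx(0.97231, abs=1e-5)

    def test_clamp_engages_for_large_g(self):
        assert rho_schedule(10**6, 1e-3) == 1e-3

    def test_strictly_decreasing_until_clamp(self):
        vals = [rho_schedule(g, 1e-3) for g in range(0, 5000)]
        unclamped = [v for v in vals if v > 1e-3]
        assert all(a > b for a, b in zip(unclamped, unclamped[1:]))
        assert vals[-1] == pytest.approx(1e-3)  # pi/5000 < 1e-3: clamp active

    def test_negative_g_rejected(self):
        with pytest.raises(ValueError):
            rho_schedule(-1, 1e-3)


class TestMomentumCoeff:
    def test_first_step_values(self):
        assert ogm_momentum_coeff(1.0) == pytest.approx((1 + math.sqrt(5)) / 2, abs=1e-12)
        assert ogm_momentum_coeff(1.0, is_last=True) == pytest.approx(2.0, abs=1e-12)

    def test_sequence_grows_at_least_linearly(self):
        theta = 1.0
        for k in range(100):
            theta = ogm_momentum_coeff(theta)
            assert theta >= (k + 3) / 2  # theta_k >= (k+2)/2 after k updates
        prev = 1.0
        for _ in range(50):
            nxt = ogm_momentum_coeff(prev)
            assert nxt > prev
            prev = nxt

    def test_below_one_rejected(self):
        with pytest.raises(ValueError):
            ogm_momentum_coeff(0.5)

    def test_momentum_beats_gradient_descent_on_quadratic(self):
        """OGM-coefficient momentum vs plain GD, same 1/L step, dense 20-dim."""
        rng = np.random.default_rng(8)
        A = rng.normal(size=(30, 20))
        Q = A.T @ A
        b = rng.normal(size=20)
        L = np.linalg.eigvalsh(Q).max()
        xstar = np.linalg.solve(Q, b)

        def f(x):
            return 0.5 * x @ Q @ x - b @ x

        x_gd = np.zeros(20)
        for _ in range(30):
            x_gd = x_gd - (Q @ x_gd - b) / L
        x = np.zeros(20)
        z_prev = x.copy()
        theta = 1.0
        for k in range(30):
            z = x - (Q @ x - b) / L
            tn = ogm_momentum_coeff(theta, is_last=(k == 29))
            x = z + ((theta - 1) / tn) * (z - z_prev) + (theta / tn) * (z - x)
            theta, z_prev = tn, z
        assert f(x) - f(xstar) < f(x_gd) - f(xstar)


class TestPWLSCost:
    def test_zero_everything_gives_zero(self, tiny_geom):
        y = Sinogram(np.zeros(tiny_geom.shape), tiny_geom)
        w = Sinogram(np.ones(tiny_geom.shape), tiny_geom)
        assert pwls_cost(np.zeros((8, 8)), y, w, ZERO_REG) == 0.0

    def test_exact_fit_unregularized_is_zero(self, tiny_geom):
        rng = np.random.default_rng(1)
        x = Image(rng.random((8, 8)) * 0.03)
        ybar, w = simulate_sinogram(x, tiny_geom, NoiseModel(NOISELESS))
        assert pwls_cost(x, ybar, w, ZERO_REG) == pytest.approx(0.0, abs=1e-18)

    def test_matches_dense_evaluation(self, tiny_geom, tiny_noisy_data):
        truth, ybar, w = tiny_noisy_data
        rng = np.random.default_rng(2)
        x = rng.random((8, 8)) * 0.05
        spec = RegularizerSpec(strength=3.0, delta=0.01)
        M = dense_system_matrix(tiny_geom)
        r = ybar.values.ravel() - M @ x.ravel()
        expected = 0.5 * r @ (w.values.ravel() * r) + reg_value(x, spec)
        assert pwls_cost(x, ybar, w, spec) == pytest.approx(expected, rel=1e-10)


class TestDataGradient:
    def test_single_subset_equals_full(self, tiny_geom, tiny_noisy_data):
        _, ybar, w = tiny_noisy_data
        rng = np.random.default_rng(3)
        x = rng.random((8, 8))
        part = partition_subsets(tiny_geom, 1)
        full = data_gradient(x, ybar, w, tiny_geom, k=ALL)
        sub = data_gradient(x, ybar, w, tiny_geom, part, k=0)
        assert np.allclose(full, sub, rtol=1e-12)

    def test_zero_at_weighted_least_squares_minimizer(self, tiny_geom, tiny_noisy_data):
        _, ybar, w = tiny_noisy_data
        M = dense_system_matrix(tiny_geom)
        wv = w.values.ravel()
        xls = np.linalg.solve(M.T @ (wv[:, None] * M), M.T @ (wv * ybar.values.ravel()))
        g = data_gradient(xls.reshape(8, 8), ybar, w, tiny_geom, k=ALL)
        assert np.linalg.norm(g) < 1e-8

    def test_subset_gradients_average_to_full(self, tiny_geom, tiny_noisy_data):
        _, ybar, w = tiny_noisy_data
        rng = np.random.default_rng(4)
        x = rng.random((8, 8))
        W = 4
        part = partition_subsets(tiny_geom, W, scheme="strided")
        mean = np.mean(
            [data_gradient(x, ybar, w, tiny_geom, part, k=k) for k in range(W)], axis=0
        )
        full = data_gradient(x, ybar, w, tiny_geom, k=ALL)
        assert np.allclose(mean, full, rtol=1e-10, atol=1e-14)

    def test_invalid_subset_index_rejected(self, tiny_geom, tiny_noisy_data):
        _, ybar, w = tiny_noisy_data
        part = partition_subsets(tiny_geom, 3)
        with pytest.raises(ValueError):
            data_gradient(np.zeros((8, 8)), ybar, w, tiny_geom, part, k=3)


class TestMajorizer:
    def test_all_entries_positive(self, tiny_geom, tiny_noisy_data):
        _, _, w = tiny_noisy_data
        D = majorizer_diag(tiny_geom, w)
        assert np.all(D > 0)

    def test_dominates_data_hessian(self, tiny_geom, tiny_noisy_data):
        _, _, w = tiny_noisy_data
        M = dense_system_matrix(tiny_geom)
        wv = w.values.ravel()
        H = M.T @ (wv[:, None] * M)
        D = majorizer_diag(tiny_geom, w).ravel()
        rng = np.random.default_rng(6)
        for _ in range(100):
            x = rng.normal(size=D.size)
            assert x @ (D * x) - x @ H @ x >= -1e-9

    def test_linear_in_weights(self, tiny_geom, tiny_noisy_data):
        _, _, w = tiny_noisy_data
        D1 = majorizer_diag(tiny_geom, w)
        D2 = majorizer_diag(tiny_geom, Sinogram(2.0 * w.values, tiny_geom))
        assert np.allclose(D2, 2.0 * D1, rtol=1e-12)


class TestOSLALM:
    def test_unregularized_reaches_wls_solution(self, tiny_geom):
        rng = np.random.default_rng(3)
        truth = Image(rng.random((8, 8)) * 0.04)
        ybar, w = simulate_sinogram(truth, tiny_geom, NoiseModel(NOISELESS))
        cfg = SolverConfig(
            n_iter=2000, subsets=1, nonneg=False, rho_min=0.02, track_omega=False
        )
        res = run_oslalm(ybar, w, tiny_geom, ZERO_REG, cfg)
        M = dense_system_matrix(tiny_geom)
        wv = w.values.ravel()
        xls = np.linalg.solve(M.T @ (wv[:, None] * M), M.T @ (wv * ybar.values.ravel()))
        rel = np.linalg.norm(res.final.values.ravel() - xls) / np.linalg.norm(xls)
        assert rel < 1e-6

    def test_quadratic_regularizer_matches_dense_solve(self, tiny_geom, tiny_noisy_data):
        _, ybar, w = tiny_noisy_data
        spec = quadratic_spec(1e3)
        cfg = SolverConfig(n_iter=2000, subsets=1, nonneg=False, track_omega=False)
        res = run_oslalm(ybar, w, tiny_geom, spec, cfg)
        M = dense_system_matrix(tiny_geom)
        wv = w.values.ravel()
        H = M.T @ (wv[:, None] * M) + dense_regularizer_hessian(8, spec)
        xq = np.linalg.solve(H, M.T @ (wv * ybar.values.ravel()))
        rel = np.linalg.norm(res.final.values.ravel() - xq) / np.linalg.norm(xq)
        assert rel < 1e-5

    def test_subset_counts_agree_at_convergence(self, tiny_geom, tiny_noisy_data):
        """W=2 converges near (not onto) the W=1 minimizer.

        Ordered-subsets iterations settle on a fixed point with a small,
        iteration-independent bias relative to the exact minimizer (the OS
        limit-cycle effect); on this instance it measures ~0.4% relative.
        """
        _, ybar, w = tiny_noisy_data
        spec = quadratic_spec(1e3)
        final = {}
        for W in (1, 2):
            cfg = SolverConfig(
                n_iter=500, subsets=W, rho_min=0.02, track_omega=False
            )
            final[W] = run_oslalm(ybar, w, tiny_geom, spec, cfg).final.values
        rel = np.linalg.norm(final[1] - final[2]) / np.linalg.norm(final[1])
        assert rel < 5e-3

    def test_rho_trace_nonincreasing_and_bounded(self, tiny_geom, tiny_noisy_data):
        _, ybar, w = tiny_noisy_data
        cfg = SolverConfig(n_iter=30, subsets=4, track_omega=False)
        res = run_oslalm(ybar, w, tiny_geom, quadratic_spec(10.0), cfg)
        rho = res.trace["rho"].to_numpy()
        assert np.all(np.diff(rho) <= 1e-15)
        assert np.all((rho >= cfg.rho_min - 1e-15) & (rho <= 1.0))

    def test_nonnegativity_of_snapshots(self, tiny_geom, tiny_noisy_data):
        _, ybar, w = tiny_noisy_data
        cfg = SolverConfig(n_iter=20, subsets=4, checkpoints=(5, 10, 20), nonneg=True)
        res = run_oslalm(ybar, w, tiny_geom, quadratic_spec(10.0), cfg)
        assert set(res.snapshots) == {5, 10, 20}
        for snap in res.snapshots.values():
            assert snap.values.min() >= 0.0

    def test_determinism(self, tiny_geom, tiny_noisy_data):
        _, ybar, w = tiny_noisy_data
        cfg = SolverConfig(n_iter=15, subsets=4, checkpoints=(15,))
        a = run_oslalm(ybar, w, tiny_geom, quadratic_spec(5.0), cfg)
        b = run_oslalm(ybar, w, tiny_geom, quadratic_spec(5.0), cfg)
        assert a.final.values.tobytes() == b.final.values.tobytes()
        assert np.array_equal(a.trace["cost"], b.trace["cost"])

    def test_all_zero_sinogram_returns_zero_image(self, tiny_geom):
        y = Sinogram(np.zeros(tiny_geom.shape), tiny_geom)
        w = Sinogram(np.ones(tiny_geom.shape), tiny_geom)
        res = run_oslalm(y, w, tiny_geom, ZERO_REG, SolverConfig(n_iter=3, subsets=2))
        assert np.all(res.final.values == 0.0)

    def test_omega_diagnostic_recorded(self, tiny_geom, tiny_noisy_data):
        _, ybar, w = tiny_noisy_data
        cfg = SolverConfig(n_iter=10, subsets=2, track_omega=True)
        res = run_oslalm(ybar, w, tiny_geom, quadratic_spec(10.0), cfg)
        assert len(res.trace) == 10
        assert np.all(np.isfinite(res.trace["omega"].to_numpy()[1:]))


class TestOGMVariant:
    def test_forced_unit_theta_reproduces_plain_solver(self, tiny_geom, tiny_noisy_data):
        _, ybar, w = tiny_noisy_data
        spec = quadratic_spec(100.0)
        kw = dict(n_iter=25, subsets=4, checkpoints=(5, 25), track_omega=False)
        plain = run_oslalm(ybar, w, tiny_geom, spec, SolverConfig(**kw))
        pinned = run_oslalm_ogm(
            ybar, w, tiny_geom, spec, SolverConfig(force_theta=1.0, **kw)
        )
        assert plain.final.values.tobytes() == pinned.final.values.tobytes()
        for it in (5, 25):
            assert (
                plain.snapshots[it].values.tobytes()
                == pinned.snapshots[it].values.tobytes()
            )

    def test_momentum_accelerates_early_iterations(self, tiny_geom, tiny_noisy_data):
        _, ybar, w = tiny_noisy_data
        spec = quadratic_spec(1e3)
        ref_cfg = SolverConfig(n_iter=800, subsets=1, rho_min=0.02, track_omega=False)
        x_star = run_oslalm(ybar, w, tiny_geom, spec, ref_cfg).final.values
        kw = dict(n_iter=5, subsets=4, track_omega=False)
        plain = run_oslalm(ybar, w, tiny_geom, spec, SolverConfig(**kw))
        ogm = run_oslalm_ogm(ybar, w, tiny_geom, spec, SolverConfig(use_ogm=True, **kw))
        d_plain = np.linalg.norm(plain.final.values - x_star)
        d_ogm = np.linalg.norm(ogm.final.values - x_star)
        assert d_ogm < d_plain


class TestSolverConfig:
    def test_checkpoint_bounds_validated(self):
        with pytest.raises(ValueError):
            SolverConfig(n_iter=10, checkpoints=(11,))

    def test_rho_min_bounds_validated(self):
        with pytest.raises(ValueError):
            SolverConfig(rho_min=0.0)

    def test_roundtrip_through_dict(self):
        cfg = SolverConfig(n_iter=7, subsets=3, checkpoints=(2, 7), use_ogm=True)
        assert SolverConfig.from_dict(cfg.to_dict()) == cfg

    @settings(deadline=None, max_examples=30)
    @given(
        g=st.integers(min_value=0, max_value=10**6),
        rho_min=st.floats(min_value=1e-6, max_value=1.0),
    )
    def test_rho_schedule_always_in_range(self, g, rho_min):
        rho = rho_schedule(g, rho_min)
        assert rho_min - 1e-15 <= rho <= 1.0
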