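import numpy as np
import pytest

from saccadekit.denoise import (
    DenoiseConfig,
    diff_operator,
    mm_solve,
    mm_step,
    objective,
)
from oracles import admm_solve, tv_exact


def random_signal(rng, n=100):
    """Random walk plus white noise — generic rough input."""
    return np.cumsum(rng.normal(0, 1, n)) + rng.normal(0, 0.5, n)


class TestDiffOperator:
    def test_first_difference_annihilates_constants(self):
        D1 = diff_operator(1, 10)
        assert np.allclose(D1 @ np.full(10, 3.7), 0.0)

    def test_third_difference_annihilates_quadratics(self, rng):
        t = np.arange(20, dtype=float)
        poly = 1.3 + 0.7 * t - 0.2 * t**2
        assert np.allclose(diff_operator(3, 20) @ poly, 0.0, atol=1e-9)

    def test_third_difference_impulse_response(self):
        e = np.zeros(7)
        e[3] = 1.0
        out = diff_operator(3, 7) @ e
        assert np.allclose(out, [1.0, -3.0, 3.0, -1.0])

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            diff_operator(3, 3)


class TestObjective:
    def test_zero_at_perfect_constant_fit(self):
        y = np.full(10, 2.0)
        assert objective(y, y, DenoiseConfig(alpha=1.0, beta=1.0)) == 0.0

    def test_pure_fidelity_when_unregularized(self, rng):
        y = rng.normal(size=50)
        x = rng.normal(size=50)
        cfg = DenoiseConfig(alpha=0.0, beta=0.0)
        assert objective(y, x, cfg) == pytest.approx(0.5 * np.sum((y - x) ** 2))

    def test_hand_computed_short_vector(self):
        # n=2: the third-difference term is vacuous
        val = objective(np.array([0.0, 1.0]), np.array([0.0, 0.0]),
                        DenoiseConfig(alpha=1.0, beta=5.0))
        assert val == pytest.approx(0.5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            objective(np.zeros(5), np.zeros(6), DenoiseConfig(alpha=1.0, beta=1.0))


class TestMMStep:
    def test_identity_when_unregularized(self, rng):
        y = random_signal(rng, 50)
        out = mm_step(y, y, DenoiseConfig(alpha=0.0, beta=0.0))
        assert np.allclose(out, y, atol=1e-12)

    def test_descent_on_random_input(self, rng):
        for _ in range(20):
            y = random_signal(rng, 80)
            cfg = DenoiseConfig(alpha=float(rng.uniform(0.1, 5)),
                                beta=float(rng.uniform(0.1, 20)))
            x = y + rng.normal(0, 0.1, 80)
            assert objective(y, mm_step(y, x, cfg), cfg) <= objective(y, x, cfg)

    def test_matches_dense_solve(self, rng):
        # single MM step from x0 = y against an explicit dense linear solve
        y = random_signal(rng, 60)
        cfg = DenoiseConfig(alpha=2.0, beta=7.0)
        D1 = diff_operator(1, 60).toarray()
        D3 = diff_operator(3, 60).toarray()
        L1 = np.diag(1.0 / (np.abs(D1 @ y) + cfg.epsilon))
        L3 = np.diag(1.0 / (np.abs(D3 @ y) + cfg.epsilon))
        M = np.eye(60) + cfg.alpha * D1.T @ L1 @ D1 + cfg.beta * D3.T @ L3 @ D3
        assert np.allclose(mm_step(y, y, cfg), np.linalg.solve(M, y), atol=1e-8)


class TestMMSolve:
    def test_near_identity_on_clean_signal_with_small_weights(self, five_saccade_truth):
        g, _ = five_saccade_truth
        res = mm_solve(g.x, DenoiseConfig(alpha=1e-6, beta=1e-6))
        assert np.sqrt(np.mean((res.x_hat - g.x) ** 2)) < 1e-4

    def test_objective_trace_non_increasing(self, rng):
        y = random_signal(rng, 300)
        res = mm_solve(y, DenoiseConfig(alpha=1.0, beta=10.0, max_iter=200, tol=0.0))
        assert np.all(np.diff(res.objective_trace) <= 0.0)

    def test_fixed_point_stays_put(self, rng):
        # IRLS weights converge slowly where differences vanish, so the
        # per-step movement decays gradually; after many iterations one
        # further step must move the iterate far less than the first did.
        y = random_signal(rng, 150)
        cfg = DenoiseConfig(alpha=1.0, beta=5.0, max_iter=20000, tol=0.0)
        x_star = mm_solve(y, cfg).x_hat
        first_move = np.max(np.abs(mm_step(y, y, cfg) - y))
        final_move = np.max(np.abs(mm_step(y, x_star, cfg) - x_star))
        assert final_move < 1e-3
        assert final_move < 1e-2 * first_move

    def test_tv_limit_matches_exact_oracle_at_smoothing_floor(self, rng):
        # With beta=0 the objective is exact TV denoising.  The MM fixed
        # point solves an eps-smoothed surrogate, which bounds agreement
        # with the exact solution at roughly sqrt(n alpha eps) RMSE.
        for _ in range(10):
            y = random_signal(rng, 100)
            lam = float(rng.uniform(0.1, 5))
            res = mm_solve(y, DenoiseConfig(alpha=lam, beta=0.0,
                                            max_iter=3000, tol=0.0))
            rmse = np.sqrt(np.mean((res.x_hat - tv_exact(y, lam)) ** 2))
            assert rmse < 5e-4

    def test_objective_matches_admm_optimum(self, rng):
        y = random_signal(rng, 200)
        cfg = DenoiseConfig(alpha=2.0, beta=8.0, max_iter=500, tol=0.0)
        res = mm_solve(y, cfg)
        j_star = objective(y, admm_solve(y, cfg.alpha, cfg.beta), cfg)
        assert objective(y, res.x_hat, cfg) <= j_star * (1 + 1e-4)

    def test_large_alpha_drives_to_mean(self, rng):
        y = random_signal(rng, 100)
        res = mm_solve(y, DenoiseConfig(alpha=1e3, beta=0.0, max_iter=500, tol=0.0))
        assert np.allclose(res.x_hat, y.mean(), atol=1e-2)

    def test_large_beta_drives_to_quadratic_fit(self, rng):
        # a milder smoothing eps keeps the huge-weight system well
        # conditioned in this degenerate limit
        y = random_signal(rng, 100)
        res = mm_solve(y, DenoiseConfig(alpha=0.0, beta=1e5, epsilon=1e-6,
                                        max_iter=2000, tol=0.0))
        t = np.arange(100, dtype=float)
        coef = np.polynomial.polynomial.polyfit(t, y, 2)
        fit = np.polynomial.polynomial.polyval(t, coef)
        assert np.sqrt(np.mean((res.x_hat - fit) ** 2)) < 1e-2

    def test_velocity_silenced_between_saccades(self, five_saccade_truth):
        # the combined first+third-difference penalty should leave the
        # denoised velocity near zero away from saccades — small residual
        # ripple remains, but with a wide margin below both detection
        # thresholds, which is what makes plain velocity thresholding
        # work afterwards
        from saccadekit.autoparams import auto_config
        from saccadekit.detect import central_velocity
        from saccadekit.simulate import add_noise

        g, truth = five_saccade_truth
        noisy = add_noise(g, 0.4, seed=17)
        cfg, _ = auto_config(noisy)
        x_hat = mm_solve(noisy.x, cfg).x_hat
        v = np.abs(central_velocity(x_hat, g.sampling_rate))
        # fixation samples: where the noise-free velocity is exactly zero
        v_clean = np.abs(central_velocity(g.x, g.sampling_rate))
        saccadic = np.zeros(len(v), dtype=bool)
        for i in np.flatnonzero(v_clean > 0):
            saccadic[max(0, i - 3):i + 4] = True
        inter = v[~saccadic]
        # raw-velocity noise at this sigma is ~280 deg/s RMS; after
        # denoising the fixation velocity must stay below the 10 deg/s
        # event-closing threshold and mostly below 1 deg/s
        assert inter.max() < 10.0
        assert np.mean(inter > 1.0) < 0.05

    def test_nan_input_names_index(self):
        y = np.zeros(10)
        y[4] = np.nan
        with pytest.raises(ValueError, match="index 4"):
            mm_solve(y, DenoiseConfig(alpha=1.0, beta=1.0))

    def test_rejects_too_short_series(self):
        with pytest.raises(ValueError):
            mm_solve(np.zeros(4), DenoiseConfig(alpha=1.0, beta=1.0))
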