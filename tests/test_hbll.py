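"""Bayesian last layer: log posterior, MAP, Hessian, HMC, prediction, tuning."""

import numpy as np
import pytest

from chemuq.hbll import (BLRProblem, BayesianLastLayer, HMCConfig,
                         _precondition_from_hessian, fit_hbll, hbll_predict,
                         hessian_at, hmc_sample, leapfrog, log_posterior,
                         map_fit, tune_prior_precision)
from chemuq.mlp import MLPConfig, MLPModel
from chemuq.utils import sigmoid


def small_problem(rng, n=40, h=3, tau=1.0):
    H = rng.normal(size=(n, h))
    w_true = rng.normal(size=h + 1)
    z = np.hstack([H, np.ones((n, 1))]) @ w_true
    y = (rng.random(n) < sigmoid(z)).astype(int)
    return BLRProblem(H=H, y=y, prior_precision=tau)


FAST_HMC = dict(n_burnin=100, n_samples=400, leapfrog_steps=25, step_size=0.2)


class TestLogPosterior:
    def test_value_at_zero(self, rng):
        prob = small_problem(rng)
        val, _ = log_posterior(np.zeros(prob.n_params), prob)
        assert val == pytest.approx(len(prob.y) * np.log(0.5), rel=1e-12)

    def test_gradient_matches_finite_differences(self, rng):
        prob = small_problem(rng)
        eps = 1e-6
        for _ in range(200):
            w = rng.normal(scale=2.0, size=prob.n_params)
            _, g = log_posterior(w, prob)
            g_fd = np.empty_like(g)
            for j in range(len(w)):
                e = np.zeros_like(w); e[j] = eps
                vp, _ = log_posterior(w + e, prob)
                vm, _ = log_posterior(w - e, prob)
                g_fd[j] = (vp - vm) / (2 * eps)
            assert np.linalg.norm(g - g_fd) / max(np.linalg.norm(g), 1.0) < 1e-5

    def test_nonfinite_rejected(self, rng):
        prob = small_problem(rng)
        with pytest.raises(ValueError):
            log_posterior(np.full(prob.n_params, np.inf), prob)


class TestMAP:
    def test_ridge_shrinkage_limit(self, rng):
        prob = small_problem(rng, tau=1e6)
        assert np.linalg.norm(map_fit(prob)) < 1e-2

    def test_symmetric_one_feature_problem_zero_bias(self):
        H = np.array([[-1.0], [1.0], [-2.0], [2.0]])
        y = np.array([0, 1, 0, 1])
        w = map_fit(BLRProblem(H=H, y=y, prior_precision=1.0))
        assert w[1] == pytest.approx(0.0, abs=1e-8)

    def test_matches_dense_grid_oracle(self, rng):
        # 2-parameter problem (one feature + bias), grid over [-5, 5]^2
        prob = small_problem(rng, n=30, h=1, tau=0.5)
        w_hat = map_fit(prob)
        g = np.arange(-5.0, 5.0 + 1e-9, 0.02)
        W = np.stack(np.meshgrid(g, g), axis=-1).reshape(-1, 2)
        Z = prob.design @ W.T
        lp = (prob.y @ np.log(sigmoid(Z) + 1e-300)
              + (1 - prob.y) @ np.log(1 - sigmoid(Z) + 1e-300)
              - 0.5 * prob.prior_precision * (W ** 2).sum(axis=1))
        w_grid = W[np.argmax(lp)]
        assert np.linalg.norm(w_hat - w_grid) < 0.05

    def test_deterministic(self, rng):
        prob = small_problem(rng)
        assert np.array_equal(map_fit(prob), map_fit(prob))


class TestHessian:
    def test_prior_only_curvature(self):
        prob = BLRProblem(H=np.empty((0, 2)), y=np.empty(0, dtype=int),
                          prior_precision=3.0)
        assert np.allclose(hessian_at(np.zeros(3), prob), 3.0 * np.eye(3))

    def test_symmetric_and_spd(self, rng):
        prob = small_problem(rng)
        A = hessian_at(rng.normal(size=prob.n_params), prob)
        assert np.allclose(A, A.T, atol=1e-14)
        assert np.linalg.eigvalsh(A).min() > 0

    def test_matches_finite_difference_hessian(self, rng):
        prob = small_problem(rng, n=25, h=2)
        eps = 1e-5
        for _ in range(10):
            w = rng.normal(size=prob.n_params)
            A = hessian_at(w, prob)
            d = len(w)
            A_fd = np.empty((d, d))
            for j in range(d):
                e = np.zeros(d); e[j] = eps
                _, gp = log_posterior(w + e, prob)
                _, gm = log_posterior(w - e, prob)
                A_fd[:, j] = -(gp - gm) / (2 * eps)  # negative Hessian
            assert np.abs(A - A_fd).max() / np.abs(A).max() < 1e-4


class TestHMC:
    def test_leapfrog_time_reversibility(self, rng):
        prob = small_problem(rng)
        grad = lambda w: log_posterior(w, prob)[1]
        w0 = rng.normal(size=prob.n_params)
        p0 = rng.normal(size=prob.n_params)
        w1, p1 = leapfrog(grad, w0, p0, 0.05, 30, None)
        w2, p2 = leapfrog(grad, w1, -p1, 0.05, 30, None)
        assert np.abs(w2 - w0).max() < 1e-8
        assert np.abs(-p2 - p0).max() < 1e-8

    def test_acceptance_approaches_one_as_step_vanishes(self, rng):
        prob = small_problem(rng)
        target = lambda w: log_posterior(w, prob)
        cfg = HMCConfig(n_burnin=20, n_samples=200, leapfrog_steps=10,
                        step_size=1e-3, seed=0)
        assert hmc_sample(target, map_fit(prob), cfg).acceptance_rate > 0.99

    def test_standard_normal_moments(self):
        target = lambda w: (-0.5 * float(w @ w), -w)
        cfg = HMCConfig(n_burnin=500, n_samples=20_000, leapfrog_steps=20,
                        step_size=0.05, seed=1)
        s = hmc_sample(target, np.zeros(1), cfg)
        assert abs(s.mean()[0]) < 0.03
        assert abs(s.var()[0] - 1.0) < 0.05

    def test_2d_gaussian_nonidentity_mass_covariance(self):
        # detailed-balance proxy: sample covariance matches analytic target
        P = np.array([[2.0, 0.6], [0.6, 1.0]])
        cov = np.linalg.inv(P)
        target = lambda w: (-0.5 * float(w @ P @ w), -(P @ w))
        cfg = HMCConfig(n_burnin=500, n_samples=20_000, leapfrog_steps=15,
                        step_size=0.15, seed=2, inverse_mass_matrix=cov)
        s = hmc_sample(target, np.zeros(2), cfg)
        emp = np.cov(s.samples.T)
        se = 3.0 * np.abs(cov) * np.sqrt(10.0 / s.n_samples)  # 3 sigma, ESS>=N/10
        assert (np.abs(emp - cov) < se + 0.02).all()

    def test_seeded_determinism(self, rng):
        prob = small_problem(rng)
        target = lambda w: log_posterior(w, prob)
        cfg = HMCConfig(seed=5, **FAST_HMC)
        s1 = hmc_sample(target, map_fit(prob), cfg)
        s2 = hmc_sample(target, map_fit(prob), cfg)
        assert np.array_equal(s1.samples, s2.samples)
        assert s1.acceptance_rate == s2.acceptance_rate

    def test_preconditioning_reduces_autocorrelation(self):
        # ill-conditioned Gaussian (condition number 100)
        P = np.diag([1.0, 100.0])
        target = lambda w: (-0.5 * float(w @ P @ w), -(P @ w))

        def max_abs_lag1(s):
            x = s.samples - s.samples.mean(axis=0)
            return max(abs(float(np.corrcoef(x[:-1, i], x[1:, i])[0, 1]))
                       for i in range(x.shape[1]))

        base = dict(n_burnin=200, n_samples=4000, leapfrog_steps=15,
                    step_size=0.1, seed=3)
        s_id = hmc_sample(target, np.zeros(2), HMCConfig(**base))
        s_pre = hmc_sample(target, np.zeros(2), HMCConfig(
            **base, inverse_mass_matrix=_precondition_from_hessian(P)))
        assert max_abs_lag1(s_pre) < max_abs_lag1(s_id)


class TestPosteriorOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_hmc_moments_match_dense_quadrature(self, seed):
        # <=3-parameter Bayesian logistic regression vs grid quadrature
        rng = np.random.default_rng(seed)
        prob = small_problem(rng, n=60, h=2, tau=1.0)
        w_map = map_fit(prob)
        A = hessian_at(w_map, prob)
        sd = np.sqrt(np.diag(np.linalg.inv(A)))

        axes = [np.linspace(w_map[j] - 6 * sd[j], w_map[j] + 6 * sd[j], 61)
                for j in range(3)]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        Z = prob.design @ grid.T
        logp = (prob.y @ Z - np.logaddexp(0.0, Z).sum(axis=0)
                - 0.5 * prob.prior_precision * (grid ** 2).sum(axis=1))
        wts = np.exp(logp - logp.max())
        wts /= wts.sum()
        mean_q = wts @ grid
        var_q = wts @ (grid - mean_q) ** 2

        cfg = HMCConfig(n_burnin=300, n_samples=4000, leapfrog_steps=25,
                        step_size=0.2, seed=seed + 10,
                        inverse_mass_matrix=_precondition_from_hessian(A))
        s = hmc_sample(lambda w: log_posterior(w, prob), w_map, cfg)
        assert s.acceptance_rate > 0.6
        mc_se = 3.0 * np.sqrt(var_q) * np.sqrt(10.0 / s.n_samples)
        assert (np.abs(s.mean() - mean_q) < mc_se).all()
        assert (np.abs(s.var() - var_q) < 3.0 * var_q * np.sqrt(20.0 / s.n_samples) + 1e-4).all()


class TestHBLLEndToEnd:
    def test_fit_predict_and_jensen_gap(self, small_synthetic, split, trained_mlp):
        data, _, _ = small_synthetic
        model = trained_mlp.params
        cfg = HMCConfig(seed=0, **FAST_HMC)
        samples = fit_hbll(model, data, split, prior_precision=1.0, cfg=cfg)
        assert samples.acceptance_rate > 0.5
        X_te = data.features.data[data.fold_indices(split.test_fold)]
        probs = hbll_predict(samples, model, X_te)
        assert ((probs > 0) & (probs < 1)).all()
        # posterior averaging never more extreme than the MAP plug-in
        from chemuq.hbll import build_blr_problem
        prob = build_blr_problem(model, data, split, 1.0)
        w_map = map_fit(prob)
        H = model.hidden_features(X_te)
        map_probs = sigmoid(np.hstack([H, np.ones((H.shape[0], 1))]) @ w_map)
        assert (np.abs(probs - 0.5) <= np.abs(map_probs - 0.5) + 0.02).all()

    def test_huge_prior_precision_pins_predictions_at_half(self, small_synthetic,
                                                           split, trained_mlp):
        data, _, _ = small_synthetic
        cfg = HMCConfig(seed=1, **FAST_HMC)
        res = BayesianLastLayer(trained_mlp.params, data, split,
                                prior_precision=1e8, hmc_config=cfg).fit()
        X_te = data.features.data[data.fold_indices(split.test_fold)]
        assert np.allclose(res.predict_proba(X_te), 0.5, atol=1e-2)

    def test_fixed_seed_identical_samples(self, small_synthetic, split, trained_mlp):
        data, _, _ = small_synthetic
        cfg = HMCConfig(seed=2, **FAST_HMC)
        s1 = fit_hbll(trained_mlp.params, data, split, 1.0, cfg)
        s2 = fit_hbll(trained_mlp.params, data, split, 1.0, cfg)
        assert np.array_equal(s1.samples, s2.samples)

    def test_summary_mentions_acceptance(self, small_synthetic, split, trained_mlp):
        data, _, _ = small_synthetic
        res = BayesianLastLayer(trained_mlp.params, data, split, 1.0,
                                HMCConfig(seed=0, n_burnin=20, n_samples=50,
                                          leapfrog_steps=10, step_size=0.2)).fit()
        assert "acceptance rate" in res.summary()


class TestPriorTuning:
    def test_singleton_grid(self, small_synthetic, split, trained_mlp):
        data, _, _ = small_synthetic
        cfg = HMCConfig(seed=0, n_burnin=20, n_samples=80, leapfrog_steps=10,
                        step_size=0.2)
        tau, report = tune_prior_precision(trained_mlp.params, data, split,
                                           tau_grid=[2.5], cfg=cfg)
        assert tau == 2.5 and len(report) == 1

    def test_report_covers_grid_and_best_beats_extremes(self, small_synthetic,
                                                        split, trained_mlp):
        data, _, _ = small_synthetic
        grid = [0.01, 1.0, 100.0]
        cfg = HMCConfig(seed=0, n_burnin=30, n_samples=100, leapfrog_steps=10,
                        step_size=0.2)
        tau, report = tune_prior_precision(trained_mlp.params, data, split,
                                           tau_grid=grid, cfg=cfg, criterion="bce")
        assert [r["tau"] for r in report] == grid
        best_score = min(r["score"] for r in report)
        extreme_scores = [r["score"] for r in report if r["tau"] in (0.01, 100.0)]
        assert best_score <= min(extreme_scores) + 1e-12

    def test_empty_grid_rejected(self, small_synthetic, split, trained_mlp):
        data, _, _ = small_synthetic
        with pytest.raises(ValueError):
            tune_prior_precision(trained_mlp.params, data, split, tau_grid=[])
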