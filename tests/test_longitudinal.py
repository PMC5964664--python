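import numpy as np
import pytest
from scipy.optimize import minimize

from augbin import TrialDataset, fit_gee, fit_gls, generate_trial, mbn_correct
from augbin.longitudinal import FitError


def make_dataset(y, arm, threshold=20.0):
    n = len(arm)
    T = y.shape[1]
    return TrialDataset(
        patient_id=np.array([f"q{i}" for i in range(n)], dtype=object),
        arm=np.asarray(arm),
        baseline=np.full(n, 50.0),
        y=y,
        d=np.zeros((n, T), dtype=int),
        threshold=threshold,
    )


@pytest.fixture
def complete_data():
    rng = np.random.default_rng(42)
    n = 40
    arm = np.repeat([0, 1], n // 2)
    mu = np.array([[5.0, 10.0], [12.0, 20.0]])
    L = np.linalg.cholesky(np.array([[900.0, 540.0], [540.0, 900.0]]))
    y = mu[arm] + rng.standard_normal((n, 2)) @ L.T
    return make_dataset(y, arm)


class TestGls:
    def test_saturated_means_on_complete_data(self, complete_data):
        fit = fit_gls(complete_data)
        y, arm = complete_data.y, complete_data.arm
        for t in range(2):
            assert fit.beta[t] == pytest.approx(y[arm == 0, t].mean())
            assert fit.beta[2 + t] == pytest.approx(
                y[arm == 1, t].mean() - y[arm == 0, t].mean()
            )
        assert np.all(np.linalg.eigvalsh(fit.Sigma) > 0)

    def test_single_visit_reduces_to_ols(self):
        rng = np.random.default_rng(0)
        arm = np.repeat([0, 1], 10)
        y = (5.0 + 3.0 * arm + rng.normal(0, 2, 20)).reshape(-1, 1)
        fit = fit_gls(make_dataset(y, arm))
        assert fit.beta[0] == pytest.approx(y[arm == 0].mean())
        assert fit.beta[1] == pytest.approx(y[arm == 1].mean() - y[arm == 0].mean())
        # ML variance of residuals (denominator n)
        resid = y.ravel() - np.where(arm == 1, fit.beta.sum(), fit.beta[0])
        assert fit.Sigma[0, 0] == pytest.approx(np.mean(resid**2))

    def test_missing_data_matches_joint_optimizer_oracle(self):
        """Direct joint maximization of the observed-data normal likelihood."""
        rng = np.random.default_rng(7)
        n = 14
        arm = np.repeat([0, 1], n // 2)
        mu = np.array([[0.0, 2.0], [1.0, 5.0]])
        L = np.linalg.cholesky(np.array([[4.0, 2.0], [2.0, 5.0]]))
        y = mu[arm] + rng.standard_normal((n, 2)) @ L.T
        y[1, 0] = np.nan
        y[9, 1] = np.nan
        data = make_dataset(y, arm)
        fit = fit_gls(data)

        mask = np.isfinite(y)

        def nll(params):
            beta = params[:4]
            l11, l21, l22 = params[4:]
            Lm = np.array([[np.exp(l11), 0.0], [l21, np.exp(l22)]])
            Sigma = Lm @ Lm.T
            total = 0.0
            for i in range(n):
                obs = np.flatnonzero(mask[i])
                mu_i = np.array(
                    [beta[t] + beta[2 + t] * arm[i] for t in range(2)]
                )[obs]
                sub = Sigma[np.ix_(obs, obs)]
                r = y[i, obs] - mu_i
                total += 0.5 * (
                    np.linalg.slogdet(sub)[1]
                    + r @ np.linalg.solve(sub, r)
                    + len(obs) * np.log(2 * np.pi)
                )
            return total

        start = np.r_[fit.beta * 0.9, np.log(2.0), 0.5, np.log(2.0)]
        res = minimize(nll, start, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        np.testing.assert_allclose(fit.beta, res.x[:4], atol=1e-3)
        assert -fit.loglik == pytest.approx(res.fun, abs=1e-6)

    def test_parameter_recovery(self, alt_params):
        hits = total = 0
        for seed in range(200):
            data = generate_trial(alt_params.replace(n_per_arm=200), seed=seed)
            fit = fit_gls(data)
            # layout: [int_1, int_2, arm_1, arm_2]
            truth = np.r_[alt_params.mu[0], alt_params.mu[1] - alt_params.mu[0]]
            se = np.sqrt(np.diag(fit.cov_model))
            hits += int(np.all(np.abs(fit.beta - truth) <= 3 * se))
            total += 1
        assert hits / total >= 0.99

    def test_too_few_patients(self):
        y = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(Exception):
            fit_gls(make_dataset(y, np.array([0, 1])))


class TestGee:
    def test_independence_matches_gls_on_complete_data(self, complete_data):
        gls = fit_gls(complete_data)
        gee = fit_gee(complete_data, working_corr="independence")
        np.testing.assert_allclose(gee.beta, gls.beta, atol=1e-6)

    def test_exchangeable_matches_means_on_complete_data(self, complete_data):
        gee = fit_gee(complete_data, working_corr="exchangeable")
        gls = fit_gls(complete_data)
        np.testing.assert_allclose(gee.beta, gls.beta, atol=1e-6)

    def test_single_cluster_per_arm_errors(self):
        y = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(Exception):
            fit_gee(make_dataset(y, np.array([0, 1])))

    def test_sandwich_tracks_empirical_variance(self, alt_params):
        """Sandwich consistency at n=400 over repeated simulation."""
        n_seeds = 300
        arm_final = []
        robust_var = []
        for seed in range(n_seeds):
            data = generate_trial(alt_params.replace(n_per_arm=200), seed=1000 + seed)
            fit = fit_gee(data)
            arm_final.append(fit.beta[3])
            robust_var.append(fit.cov_robust[3, 3])
        emp = np.var(arm_final, ddof=1)
        assert np.mean(robust_var) == pytest.approx(emp, rel=0.20)

    def test_invalid_working_corr(self, complete_data):
        with pytest.raises(ValueError):
            fit_gee(complete_data, working_corr="toeplitz")

    def test_gls_gee_estimates_converge_with_n(self, alt_params):
        """With final visits missing at random the likelihood fit adjusts
        through the interim outcome while GEE does not; the gap between the
        two arm-effect estimates shrinks as the sample grows."""

        def gap(n_per_arm, seed):
            data = generate_trial(alt_params.replace(n_per_arm=n_per_arm), seed=seed)
            rng = np.random.default_rng(10_000 + seed)
            y = data.y.copy()
            drop = rng.random(len(y)) < 0.2
            drop[:4] = False  # keep a few complete rows in each arm
            y[drop, 1] = np.nan
            data = TrialDataset(
                patient_id=data.patient_id, arm=data.arm, baseline=data.baseline,
                y=y, d=data.d, threshold=data.threshold,
            )
            return abs(fit_gls(data).beta[3] - fit_gee(data).beta[3])

        small = np.mean([gap(60, s) for s in range(8)])
        large = np.mean([gap(1500, s) for s in range(8)])
        assert large < small


class TestMbn:
    def test_diagonal_inflation(self, alt_params):
        for seed in range(5):
            data = generate_trial(alt_params.replace(n_per_arm=12), seed=seed)
            fit = mbn_correct(fit_gee(data))
            assert np.all(np.diag(fit.cov_mbn) >= np.diag(fit.cov_robust) - 1e-12)

    def test_correction_vanishes_at_large_k(self, alt_params):
        data = generate_trial(alt_params.replace(n_per_arm=500), seed=3)
        fit = mbn_correct(fit_gee(data))
        rel = np.abs(fit.cov_mbn - fit.cov_robust) / np.abs(fit.cov_robust)
        assert rel.max() < 0.02

    def test_matches_independent_formula(self, alt_params):
        data = generate_trial(alt_params.replace(n_per_arm=10), seed=11)
        fit = fit_gee(data)
        corrected = mbn_correct(fit)
        # independent evaluation of the same algebra
        A, B = fit.cov_robust, fit.cov_model
        K, p, N = fit.n_clusters, fit.p, fit.n_obs_total
        f = (N - 1) / (N - p) * K / (K - 1)
        delta = min(0.5, p / (K - p))
        xi = max(1.0, np.trace(np.linalg.inv(B) @ A) / p)
        expected = f * A + delta * xi * B
        np.testing.assert_allclose(corrected.cov_mbn, 0.5 * (expected + expected.T),
                                   atol=1e-10)

    def test_requires_gee(self, complete_data):
        with pytest.raises(FitError):
            mbn_correct(fit_gls(complete_data))

    def test_k_leq_p_errors(self):
        from augbin.longitudinal import LongitudinalFit

        fit = LongitudinalFit(
            beta=np.zeros(4), Sigma=np.eye(2), cov_model=np.eye(4),
            fitter="GEE", n_clusters=4, p=4, n_obs_total=8, n_visits=2,
            baseline_adjust=False, cov_robust=np.eye(4),
        )
        with pytest.raises(FitError, match="K="):
            mbn_correct(fit)

    def test_mbn_wald_rejects_no_more_than_robust(self, null_params):
        """Corrected Wald tests are never more liberal than sandwich tests."""
        z = 1.959963984540054
        rej_robust = rej_mbn = 0
        for seed in range(100):
            data = generate_trial(null_params.replace(n_per_arm=20), seed=seed)
            fit = mbn_correct(fit_gee(data))
            stat_rob = abs(fit.beta[3]) / np.sqrt(fit.cov_robust[3, 3])
            stat_mbn = abs(fit.beta[3]) / np.sqrt(fit.cov_mbn[3, 3])
            assert stat_mbn <= stat_rob + 1e-12
            rej_robust += stat_rob > z
            rej_mbn += stat_mbn > z
        assert rej_mbn <= rej_robust
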