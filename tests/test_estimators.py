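"""t-test and MMRM: closed-form oracles, likelihood checks, recovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import mmrmsim as m
from mmrmsim.estimators import EstimationError

from conftest import make_trial


def dataset_from_arrays(values, arm, observed=None):
    values = np.asarray(values, dtype=float)
    if observed is None:
        observed = np.ones_like(values, dtype=bool)
    return m.LongDataset(values, observed, np.asarray(arm), np.arange(1, len(arm) + 1))


def scale_to(x, mean, sd):
    """Affinely map a sample to an exact mean and SD (ddof=1)."""
    x = np.asarray(x, dtype=float)
    return mean + (x - x.mean()) / x.std(ddof=1) * sd


class TestCompleteCaseTTest:
    def test_identical_arms_null(self):
        y = np.arange(10, dtype=float).reshape(5, 2)
        data = dataset_from_arrays(np.vstack([y, y]), [0] * 5 + [1] * 5)
        res = m.complete_case_ttest(data, 2)
        assert res.estimate == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_textbook_formula_oracle(self):
        # arm means 50 / 54.18, pooled SD 10.4881, 100 per arm
        rng = np.random.default_rng(0)
        y0 = scale_to(rng.normal(size=100), 50.0, 10.4881)
        y1 = scale_to(rng.normal(size=100), 54.18, 10.4881)
        values = np.column_stack([np.full(200, 50.0), np.concatenate([y0, y1])])
        data = dataset_from_arrays(values, [0] * 100 + [1] * 100)
        res = m.complete_case_ttest(data, 2)
        t_oracle = 4.18 / (10.4881 * np.sqrt(2.0 / 100))
        assert res.statistic == pytest.approx(t_oracle, abs=1e-6)
        assert res.statistic == pytest.approx(2.818, abs=0.001)
        assert res.p_value == pytest.approx(2 * stats.t.sf(t_oracle, 198), abs=1e-9)
        assert res.p_value == pytest.approx(0.0053, abs=0.0002)
        assert res.df == 198
        assert res.n_used == (100, 100)

    def test_agrees_with_scipy(self, mcar_trial):
        res = m.complete_case_ttest(mcar_trial, 4)
        mask = mcar_trial.observed[:, 3]
        y0 = mcar_trial.values[mask & (mcar_trial.arm == 0), 3]
        y1 = mcar_trial.values[mask & (mcar_trial.arm == 1), 3]
        ref = stats.ttest_ind(y1, y0, equal_var=True)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_welch_variant(self, mcar_trial):
        res = m.complete_case_ttest(mcar_trial, 4, equal_var=False)
        mask = mcar_trial.observed[:, 3]
        y0 = mcar_trial.values[mask & (mcar_trial.arm == 0), 3]
        y1 = mcar_trial.values[mask & (mcar_trial.arm == 1), 3]
        ref = stats.ttest_ind(y1, y0, equal_var=False)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_too_few_subjects(self):
        data = dataset_from_arrays([[1.0, 2.0], [2.0, 3.0], [3.0, 4.0]], [0, 0, 1])
        with pytest.raises(EstimationError):
            m.complete_case_ttest(data, 2)

    def test_zero_variance_degenerate(self):
        data = dataset_from_arrays(np.ones((8, 2)), [0] * 4 + [1] * 4)
        with pytest.raises(EstimationError):
            m.complete_case_ttest(data, 2)


class TestMMRMFitStructure:
    def test_complete_balanced_cell_means_are_sample_means(self, complete_trial):
        for structure in ("CS", "UN"):
            fit = m.fit_mmrm(complete_trial, structure)
            for g in (0, 1):
                sample = complete_trial.values[complete_trial.arm == g].mean(axis=0)
                assert np.allclose(fit.cell_means[g], sample, atol=1e-7)

    def test_un_cov_matches_reml_moment_estimator(self, complete_trial):
        # complete data: REML Sigma-hat is the pooled within-cell covariance
        # with divisor N - 2 (one mean per arm profiled out)
        fit = m.fit_mmrm(complete_trial, "UN")
        resid = complete_trial.values.copy()
        for g in (0, 1):
            in_arm = complete_trial.arm == g
            resid[in_arm] -= resid[in_arm].mean(axis=0)
        n = complete_trial.n_subjects
        direct = resid.T @ resid / (n - 2)
        assert np.allclose(fit.sigma, direct, rtol=1e-4)

    def test_param_counts(self, mcar_trial):
        assert m.fit_mmrm(mcar_trial, "CS").cov_params.shape == (2,)
        assert m.fit_mmrm(mcar_trial, "UN").cov_params.shape == (10,)

    def test_sigma_positive_definite(self, mcar_trial):
        for structure in ("CS", "UN"):
            fit = m.fit_mmrm(mcar_trial, structure)
            assert np.allclose(fit.sigma, fit.sigma.T)
            assert np.linalg.eigvalsh(fit.sigma).min() > 0

    def test_cs_parameter_recovery(self):
        # rho = 0.7, total 110, 2,000 per arm; the total-variance estimate
        # has MC SE ~1.8 per trial, so average a few independent trials
        totals, rhos = [], []
        for seed in range(31, 37):
            fit = m.fit_mmrm(make_trial(n_per_arm=2000, rho=0.7, seed=seed), "CS")
            totals.append(fit.cov_params[0])
            rhos.append(fit.cov_params[1])
        assert np.mean(rhos) == pytest.approx(0.7, abs=0.02)
        assert np.mean(totals) == pytest.approx(110.0, abs=3.0)

    def test_cs_recovery_improves_with_n(self):
        errs = []
        for n in (100, 1000):
            err = []
            for seed in range(5):
                fit = m.fit_mmrm(make_trial(n_per_arm=n, rho=0.5, seed=700 + seed), "CS")
                err.append(abs(fit.cov_params[1] - 0.5))
            errs.append(np.mean(err))
        assert errs[1] < errs[0]

    def test_ml_close_to_reml_at_this_size(self, mcar_trial):
        reml = m.fit_mmrm(mcar_trial, "CS", method="REML")
        ml = m.fit_mmrm(mcar_trial, "CS", method="ML")
        assert ml.cov_params[0] == pytest.approx(reml.cov_params[0], rel=0.03)
        c_reml = m.final_time_contrast(reml)
        c_ml = m.final_time_contrast(ml)
        assert c_ml.estimate == pytest.approx(c_reml.estimate, abs=0.05)

    def test_non_estimable_cell_named(self):
        data = make_trial(n_per_arm=10, seed=1)
        obs = data.observed.copy()
        obs[data.arm == 1, 3] = False
        broken = m.LongDataset(data.values, obs, data.arm, data.subject_id)
        with pytest.raises(EstimationError, match="arm=1, occasion=4"):
            m.fit_mmrm(broken, "CS")

    def test_cross_validation_against_statsmodels_mixedlm(self, mcar_trial):
        # random-intercept MixedLM is exactly the CS model (rho >= 0)
        pd = pytest.importorskip("pandas")
        from statsmodels.regression.mixed_linear_model import MixedLM

        fit = m.fit_mmrm(mcar_trial, "CS")
        df = mcar_trial.to_frame()
        df = df[df.observed == 1]
        df["cell"] = df.arm.astype(str) + "_" + df.time_index.astype(str)
        X = pd.get_dummies(df["cell"]).astype(float)
        res = MixedLM(
            df["value"].to_numpy(), X.to_numpy(), groups=df["subject_id"].to_numpy()
        ).fit(reml=True)
        sb = float(np.atleast_2d(res.cov_re)[0, 0])
        se = float(res.scale)
        assert sb + se == pytest.approx(fit.cov_params[0], rel=1e-3)
        assert sb / (sb + se) == pytest.approx(fit.cov_params[1], abs=1e-3)
        beta = dict(zip(X.columns, res.fe_params))
        est = beta["1_4"] - beta["0_4"]
        mine = m.final_time_contrast(fit)
        assert mine.estimate == pytest.approx(est, abs=1e-4)


class TestLoglik:
    def test_univariate_density_at_mean(self):
        data = dataset_from_arrays(
            [[5.0, 0.0]], [0], observed=np.array([[True, False]])
        )
        means = np.array([[5.0, 0.0], [5.0, 0.0]])
        total, rho = 3.0, 0.4
        ll = m.mmrm_loglik(np.array([total, rho]), means, data, "CS")
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi * total), abs=1e-12)

    def test_brute_force_density_sum(self):
        data = make_trial(n_per_arm=3, seed=2)
        out = m.apply_mcar(
            make_trial(n_per_arm=3, seed=2),
            m.DropoutSpec("MCAR", "none", (0.5, 0.5), 0.0),
            3,
        )
        means = m.make_linear_trajectory(50.0, 4.18, 4).mu
        sigma = m.variance_components(100.0, 0.6).covariance(4)
        params = sigma[np.tril_indices(4)]
        ll = m.mmrm_loglik(params, means, out, "UN")
        brute = 0.0
        for i in range(out.n_subjects):
            idx = np.flatnonzero(out.observed[i])
            brute += stats.multivariate_normal.logpdf(
                out.values[i, idx], means[out.arm[i], idx], sigma[np.ix_(idx, idx)]
            )
        assert ll == pytest.approx(brute, abs=1e-10)

    def test_duplication_doubles(self):
        data = make_trial(n_per_arm=2, seed=4)
        doubled = m.LongDataset(
            np.vstack([data.values, data.values]),
            np.vstack([data.observed, data.observed]),
            np.concatenate([data.arm, data.arm]),
            np.arange(1, 2 * data.n_subjects + 1),
        )
        means = m.make_linear_trajectory(50.0, 4.18, 4).mu
        params = np.array([110.0, 0.5])
        assert m.mmrm_loglik(params, means, doubled, "CS") == pytest.approx(
            2 * m.mmrm_loglik(params, means, data, "CS"), abs=1e-9
        )

    def test_non_spd_rejected(self):
        data = make_trial(n_per_arm=2, seed=4)
        means = m.make_linear_trajectory(50.0, 4.18, 4).mu
        with pytest.raises(EstimationError):
            m.mmrm_loglik(np.array([110.0, 1.2]), means, data, "CS")

    def test_fitted_cs_params_maximize_loglik_nearby(self, mcar_trial):
        # ML fit: the likelihood at the optimum beats nearby perturbations
        fit = m.fit_mmrm(mcar_trial, "CS", method="ML")
        ll_hat = m.mmrm_loglik(fit.cov_params, fit.cell_means, mcar_trial, "CS")
        for d_total, d_rho in ((5.0, 0.0), (-5.0, 0.0), (0.0, 0.05), (0.0, -0.05)):
            pert = fit.cov_params + np.array([d_total, d_rho])
            assert m.mmrm_loglik(pert, fit.cell_means, mcar_trial, "CS") < ll_hat


class TestContrast:
    def test_complete_data_equivalence_with_ttest(self, complete_trial):
        tt = m.complete_case_ttest(complete_trial, 4)
        for structure in ("CS", "UN"):
            c = m.final_time_contrast(m.fit_mmrm(complete_trial, structure), 4)
            assert c.estimate == pytest.approx(tt.estimate, abs=1e-8)
        c_un = m.final_time_contrast(m.fit_mmrm(complete_trial, "UN"), 4)
        assert c_un.p_value == pytest.approx(tt.p_value, abs=1e-3)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), rho=st.sampled_from([0.3, 0.5, 0.7]))
    def test_equivalence_property_over_random_complete_trials(self, seed, rho):
        data = make_trial(n_per_arm=15, rho=rho, seed=seed)
        tt = m.complete_case_ttest(data, 4)
        c = m.final_time_contrast(m.fit_mmrm(data, "UN"), 4)
        assert c.estimate == pytest.approx(tt.estimate, abs=1e-8)

    @settings(max_examples=8, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_un_loglik_dominates_cs(self, seed):
        data = make_trial(n_per_arm=40, rho=0.5, seed=seed)
        data = m.apply_mcar(data, m.SCENARIOS["mcar_equal"], seed + 1)
        cs = m.fit_mmrm(data, "CS")
        un = m.fit_mmrm(data, "UN")
        assert un.loglik >= cs.loglik - 1e-6

    def test_shift_invariance(self, mcar_trial):
        shifted = mcar_trial.copy()
        shifted.values = shifted.values + 17.3
        for structure in ("CS", "UN"):
            a = m.fit_mmrm(mcar_trial, structure)
            b = m.fit_mmrm(shifted, structure)
            assert np.allclose(b.cell_means, a.cell_means + 17.3, atol=1e-6)
            assert np.allclose(b.cov_params, a.cov_params, atol=1e-5)
            ca, cb = m.final_time_contrast(a), m.final_time_contrast(b)
            assert cb.estimate == pytest.approx(ca.estimate, abs=1e-6)
            assert cb.std_error == pytest.approx(ca.std_error, abs=1e-6)
            assert cb.p_value == pytest.approx(ca.p_value, abs=1e-8)

    def test_time_index_out_of_range(self, complete_trial):
        fit = m.fit_mmrm(complete_trial, "CS")
        with pytest.raises(EstimationError):
            m.final_time_contrast(fit, 5)

    def test_df_rule(self, mcar_trial):
        c = m.final_time_contrast(m.fit_mmrm(mcar_trial, "CS"))
        assert c.df == mcar_trial.n_subjects - 2
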