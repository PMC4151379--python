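"""GEE solver, cluster-robust inference, QIC and td-term selection."""

import numpy as np
import pandas as pd
import pytest

from pseudosurv import (
    ModelSpec,
    SplineBasis,
    SurvivalSample,
    backward_select_td,
    build_design,
    default_knots,
    fit_gee,
    kaplan_meier,
    marginal_survival_check,
    pseudo_values,
    qic,
    qicu,
    select_pseudo_times,
    wald_test,
)


def _pv(sample, m):
    return pseudo_values(sample, select_pseudo_times(sample, m))


def _indicator_spec(pv, covs=(), td=()):
    return ModelSpec(
        link="identity",
        baseline=SplineBasis.indicator(pv.pseudo_times),
        covariate_terms=list(covs),
        td_terms=list(td),
    )


class TestIdentityOracles:
    def test_indicator_fit_recovers_km_exactly_without_censoring(self, rng):
        n = 70
        t = rng.exponential(8, n)
        s = SurvivalSample(np.arange(n), t, np.ones(n, int))
        pv = _pv(s, 6)
        fit = fit_gee(pv, _indicator_spec(pv))
        km = kaplan_meier(s)(pv.pseudo_times)
        coef = fit.coefficients.to_numpy()
        pred = coef[0] + np.concatenate([[0.0], coef[1:]])
        np.testing.assert_allclose(pred, km, atol=1e-10)

    def test_identity_equals_ols_and_dense_sandwich(self, censored_sample):
        pv = _pv(censored_sample, 6)
        spec = _indicator_spec(pv, covs=["z"])
        fit = fit_gee(pv, spec)
        X, y, cl = build_design(pv, spec)
        Xm = X.to_numpy()
        beta = np.linalg.lstsq(Xm, y, rcond=None)[0]
        np.testing.assert_allclose(fit.coefficients.to_numpy(), beta, atol=1e-8)
        # dense cluster sandwich: A^-1 B A^-1 with per-subject score outer products
        resid = y - Xm @ beta
        A = Xm.T @ Xm
        B = np.zeros((Xm.shape[1], Xm.shape[1]))
        for g in np.unique(cl):
            idx = cl == g
            s_g = Xm[idx].T @ resid[idx]
            B += np.outer(s_g, s_g)
        dense = np.linalg.inv(A) @ B @ np.linalg.inv(A)
        np.testing.assert_allclose(fit.robust_vcov.to_numpy(), dense, atol=1e-10)

    def test_matches_statsmodels_gee(self, censored_sample):
        import statsmodels.api as sm

        pv = _pv(censored_sample, 5)
        spec = _indicator_spec(pv, covs=["z"])
        fit = fit_gee(pv, spec)
        X, y, cl = build_design(pv, spec)
        res = sm.GEE(y, X.to_numpy(), groups=cl, family=sm.families.Gaussian()).fit()
        np.testing.assert_allclose(
            fit.coefficients.to_numpy(), res.params, atol=1e-8
        )
        np.testing.assert_allclose(
            fit.robust_vcov.to_numpy(), res.cov_params(), atol=1e-8
        )

    def test_saturated_group_model_recovers_stratified_survival(self, rng):
        # saturated time x group design, no censoring: group-difference
        # coefficients equal differences of group-wise empirical survival
        n = 80
        z = np.repeat([0.0, 1.0], n // 2)
        t = rng.exponential(np.where(z == 1, 5.0, 10.0))
        s = SurvivalSample(
            np.arange(n), t, np.ones(n, int), pd.DataFrame({"z": z})
        )
        pv = _pv(s, 4)
        spec = _indicator_spec(pv, covs=["z"], td=["z"])
        fit = fit_gee(pv, spec)
        km0 = kaplan_meier(
            SurvivalSample(np.arange(n // 2), t[z == 0], np.ones(n // 2, int))
        )(pv.pseudo_times)
        km1 = kaplan_meier(
            SurvivalSample(np.arange(n // 2), t[z == 1], np.ones(n // 2, int))
        )(pv.pseudo_times)
        coef = fit.coefficients
        diff = coef["z"] + np.concatenate(
            [[0.0], [coef[f"z:b{j}"] for j in range(1, pv.M)]]
        )
        np.testing.assert_allclose(diff, km1 - km0, atol=1e-10)


class TestInvariances:
    def test_subject_relabeling_invariance(self, censored_sample):
        pv = _pv(censored_sample, 5)
        spec = _indicator_spec(pv, covs=["z"])
        fit1 = fit_gee(pv, spec)
        perm = np.random.default_rng(5).permutation(censored_sample.n)
        s2 = SurvivalSample(
            np.arange(censored_sample.n),
            censored_sample.time[perm],
            censored_sample.event[perm],
            censored_sample.covariates.iloc[perm].reset_index(drop=True),
        )
        pv2 = pseudo_values(s2, pv.pseudo_times)
        fit2 = fit_gee(pv2, spec)
        np.testing.assert_allclose(
            fit1.coefficients.to_numpy(), fit2.coefficients.to_numpy(), atol=1e-8
        )
        np.testing.assert_allclose(
            fit1.robust_vcov.to_numpy(), fit2.robust_vcov.to_numpy(), atol=1e-8
        )

    def test_singular_design_names_collinear_column(self, censored_sample):
        pv = _pv(censored_sample, 5)
        pv.covariates["z2"] = pv.covariates["z"]
        spec = _indicator_spec(pv, covs=["z", "z2"])
        with pytest.raises(ValueError, match="collinear"):
            fit_gee(pv, spec)


class TestNonIdentityLinks:
    def test_cloglog_recovers_log_hazard_ratio_under_ph(self):
        # under proportional hazards the cloglog-link coefficient is the log
        # cumulative-hazard ratio = log HR; average over a few replicates
        truth = np.log(1.8)
        ests, ses = [], []
        for seed in range(5):
            r = np.random.default_rng(100 + seed)
            n = 500
            z = r.integers(0, 2, n).astype(float)
            lam = 0.05 * np.exp(truth * z)
            t_ev = r.exponential(1 / lam)
            c = r.exponential(100.0, n)
            s = SurvivalSample(
                np.arange(n),
                np.minimum(t_ev, c),
                (t_ev <= c).astype(int),
                pd.DataFrame({"z": z}),
            )
            pv = _pv(s, 10)
            spec = ModelSpec(
                link="cloglog",
                baseline=SplineBasis.rcs(
                    default_knots(s.distinct_event_times, 3)
                ),
                covariate_terms=["z"],
            )
            fit = fit_gee(pv, spec)
            ests.append(fit.coefficients["z"])
            ses.append(fit.robust_se()["z"])
        mean_est = np.mean(ests)
        mc_se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(mean_est - truth) < 2 * max(mc_se, np.mean(ses) / np.sqrt(5))

    @pytest.mark.parametrize("link", ["log", "logit", "cloglog"])
    def test_nonidentity_links_converge_and_fit_survival_scale(
        self, censored_sample, link
    ):
        pv = _pv(censored_sample, 5)
        spec = ModelSpec(
            link=link,
            baseline=SplineBasis.indicator(pv.pseudo_times),
            covariate_terms=["z"],
        )
        fit = fit_gee(pv, spec)
        assert fit.converged
        if link in ("logit", "cloglog"):
            assert np.all(fit.fitted_means > 0) and np.all(fit.fitted_means < 1)


class TestWald:
    def test_single_term_is_squared_z(self, censored_sample):
        pv = _pv(censored_sample, 5)
        fit = fit_gee(pv, _indicator_spec(pv, covs=["z"]))
        res = wald_test(fit, ["z"])
        z = fit.coefficients["z"] / fit.robust_se()["z"]
        assert res.statistic == pytest.approx(z**2, rel=1e-10)
        assert res.df == 1

    def test_joint_equals_dense_quadratic_form(self, censored_sample):
        pv = _pv(censored_sample, 5)
        fit = fit_gee(pv, _indicator_spec(pv, covs=["z"], td=["z"]))
        terms = [c for c in fit.coefficients.index if c.startswith("z:")]
        res = wald_test(fit, terms)
        c = fit.coefficients.loc[terms].to_numpy()
        V = fit.robust_vcov.loc[terms, terms].to_numpy()
        assert res.statistic == pytest.approx(
            float(c @ np.linalg.inv(V) @ c), rel=1e-10
        )
        assert res.df == len(terms)

    def test_empty_terms_rejected(self, censored_sample):
        pv = _pv(censored_sample, 5)
        fit = fit_gee(pv, _indicator_spec(pv))
        with pytest.raises(ValueError, match="no terms"):
            wald_test(fit, [])


class TestQic:
    def test_penalty_reduces_to_2p_when_robust_equals_naive(self, censored_sample):
        pv = _pv(censored_sample, 5)
        fit = fit_gee(pv, _indicator_spec(pv, covs=["z"]))
        fit.robust_vcov = fit.naive_vcov
        assert qic(fit) == pytest.approx(qicu(fit), rel=1e-10)

    def test_noise_columns_increase_qic_in_expectation(self):
        diffs = []
        for seed in range(40):
            r = np.random.default_rng(300 + seed)
            n = 60
            t = r.exponential(10, n)
            e = (r.random(n) < 0.8).astype(int)
            if e.sum() < 6:
                continue
            cov = pd.DataFrame(
                {"z": r.integers(0, 2, n).astype(float), "u": r.normal(size=n)}
            )
            s = SurvivalSample(np.arange(n), t, e, cov)
            pv = _pv(s, 4)
            small = fit_gee(pv, _indicator_spec(pv, covs=["z"]))
            big = fit_gee(pv, _indicator_spec(pv, covs=["z", "u"], td=["u"]))
            diffs.append(qic(big) - qic(small))
        assert np.mean(diffs) > 0


class TestBackwardSelection:
    def test_alpha_one_returns_full_model(self, censored_sample):
        pv = _pv(censored_sample, 5)
        full = _indicator_spec(pv, covs=["z"], td=["z"])
        out = backward_select_td(pv, full, alpha=1.0)
        assert out.td_terms == ["z"]

    def test_null_td_usually_removed_and_true_td_retained(self):
        # exposure with a strongly time-varying survival difference is kept;
        # a pure-noise covariate's td block is dropped at alpha = 0.05
        r = np.random.default_rng(11)
        n = 400
        z = np.repeat([0.0, 1.0], n // 2)
        u = r.normal(size=n)
        # crossing hazards: z harmful early, protective late
        t0 = r.exponential(10.0, n)
        t1 = 4.0 + r.exponential(14.0, n)
        t = np.where(z == 1, t1, t0)
        s = SurvivalSample(
            np.arange(n), t, np.ones(n, int), pd.DataFrame({"z": z, "u": u})
        )
        pv = _pv(s, 8)
        full = ModelSpec(
            link="identity",
            baseline=SplineBasis.rcs(default_knots(s.distinct_event_times, 3)),
            covariate_terms=["z", "u"],
            td_terms=["z", "u"],
        )
        out = backward_select_td(pv, full, alpha=0.05)
        assert "z" in out.td_terms
        assert "u" not in out.td_terms
        assert set(out.covariate_terms) == {"z", "u"}  # main effects retained


class TestMarginalCheck:
    def test_indicator_basis_is_saturated(self, censored_sample):
        chk = marginal_survival_check(
            censored_sample,
            5,
            SplineBasis.indicator(
                select_pseudo_times(censored_sample, 5)
            ),
        )
        assert chk.max_abs_discrepancy < 1e-8

    def test_rcs_tracks_km_closely_on_simulated_data(self, scenario1_sample):
        import warnings

        times = select_pseudo_times(scenario1_sample, 15)
        knots = default_knots(scenario1_sample.distinct_event_times, 5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            chk = marginal_survival_check(
                scenario1_sample, 15, SplineBasis.rcs(knots)
            )
        assert chk.max_abs_discrepancy < 0.02
        assert chk.monotone
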