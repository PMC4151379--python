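"""Association measures, CI transformation and NNT interval arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pseudosurv import (
    EffectCurve,
    ModelSpec,
    SplineBasis,
    constant_effect,
    default_knots,
    fit_gee,
    nnt_display,
    nnt_from_rd,
    pseudo_values,
    select_pseudo_times,
    time_varying_effect,
)
from pseudosurv.gee import TransformationModelFit


def _manual_fit(link, names, coefs, vcov, pseudo_times, spec=None):
    """Assemble a fit object directly from coefficients and covariance."""
    if spec is None:
        spec = ModelSpec(
            link=link,
            baseline=SplineBasis.indicator(pseudo_times),
            covariate_terms=[n for n in names if n not in ("intercept",)
                             and not n.startswith("b")],
        )
    idx = pd.Index(names)
    return TransformationModelFit(
        spec=spec,
        coefficients=pd.Series(coefs, index=idx),
        robust_vcov=pd.DataFrame(vcov, index=idx, columns=idx),
        naive_vcov=pd.DataFrame(vcov, index=idx, columns=idx),
        n_subjects=100,
        n_rows=100 * len(pseudo_times),
        converged=True,
        fitted_means=np.full(100 * len(pseudo_times), 0.5),
        scale=1.0,
        pseudo_times=np.asarray(pseudo_times, dtype=float),
    )


def _flat_fit(link, alpha, se):
    pt = np.array([10.0, 20.0, 30.0])
    names = ["intercept", "b1", "b2", "z"]
    coefs = [0.0, 0.0, 0.0, alpha]
    vcov = np.zeros((4, 4))
    vcov[3, 3] = se**2
    return _manual_fit(link, names, coefs, vcov, pt)


class TestConstantEffect:
    @pytest.mark.parametrize("link,null_value", [
        ("identity", 0.0), ("log", 1.0), ("logit", 1.0), ("cloglog", 1.0),
    ])
    def test_null_coefficient_maps_to_null_measure(self, link, null_value):
        curve = constant_effect(_flat_fit(link, 0.0, 0.05), "z")
        np.testing.assert_allclose(curve.estimate, null_value)

    def test_prostate_constant_rd_worked_numbers(self):
        # identity-link alpha 0.022, robust se 0.0291: RD 2.2% with the
        # 1.96-Wald interval (-3.5%, 7.9%)
        curve = constant_effect(_flat_fit("identity", 0.022, 0.0291), "z")
        assert curve.estimate[0] == pytest.approx(0.022)
        assert curve.lower[0] == pytest.approx(0.022 - 1.96 * 0.0291)
        assert curve.upper[0] == pytest.approx(0.022 + 1.96 * 0.0291)
        assert curve.lower[0] == pytest.approx(-0.035, abs=5e-4)
        assert curve.upper[0] == pytest.approx(0.079, abs=5e-4)

    def test_delta_scaling_linear_on_link_scale(self):
        fit_id = _flat_fit("identity", 0.03, 0.01)
        rd1 = constant_effect(fit_id, "z", delta=1.0)
        rd2 = constant_effect(fit_id, "z", delta=2.0)
        assert rd2.estimate[0] == pytest.approx(2 * rd1.estimate[0])
        fit_log = _flat_fit("log", 0.3, 0.05)
        rr1 = constant_effect(fit_log, "z", delta=1.0)
        rr2 = constant_effect(fit_log, "z", delta=2.0)
        assert rr2.estimate[0] == pytest.approx(rr1.estimate[0] ** 2)

    def test_monotone_ci_transform_for_ratio_measures(self):
        curve = constant_effect(_flat_fit("cloglog", 0.4, 0.1), "z")
        assert curve.lower[0] == pytest.approx(np.exp(0.4 - 1.96 * 0.1))
        assert curve.upper[0] == pytest.approx(np.exp(0.4 + 1.96 * 0.1))
        assert curve.lower[0] < curve.estimate[0] < curve.upper[0]

    def test_td_covariate_redirected(self):
        pt = np.array([10.0, 20.0, 30.0])
        spec = ModelSpec(
            link="identity",
            baseline=SplineBasis.indicator(pt),
            covariate_terms=["z"],
            td_terms=["z"],
        )
        names = ["intercept", "b1", "b2", "z", "z:b1", "z:b2"]
        fit = _manual_fit("identity", names, np.zeros(6), np.eye(6), pt, spec)
        with pytest.raises(ValueError, match="time_varying_effect"):
            constant_effect(fit, "z")


class TestTimeVaryingEffect:
    def _td_fit(self, gamma1=0.0, gamma2=0.0, vsub=None):
        pt = np.array([5.0, 15.0, 40.0, 80.0])
        knots = np.array([10.0, 30.0, 70.0])
        spec = ModelSpec(
            link="identity",
            baseline=SplineBasis.rcs(knots),
            covariate_terms=["z"],
            td_terms=["z"],
        )
        names = ["intercept", "b1", "b2", "z", "z:b1", "z:b2"]
        coefs = [0.5, -0.001, 0.0, 0.04, gamma1, gamma2]
        vcov = np.zeros((6, 6))
        if vsub is None:
            vsub = np.diag([0.02**2, 1e-8, 1e-10])
        vcov[3:, 3:] = vsub
        return _manual_fit("identity", names, coefs, vcov, pt, spec), spec

    def test_zero_td_coefficients_reduce_to_constant(self):
        fit, _ = self._td_fit(0.0, 0.0)
        tv = time_varying_effect(fit, "z", np.array([10.0, 50.0]))
        np.testing.assert_allclose(tv.estimate, 0.04, atol=1e-12)

    def test_variance_equals_dense_quadratic_form(self):
        vsub = np.array(
            [[4e-4, 1e-6, -2e-8], [1e-6, 1e-8, 1e-10], [-2e-8, 1e-10, 1e-11]]
        )
        fit, spec = self._td_fit(0.002, -1e-5, vsub=vsub)
        t = np.array([25.0])
        tv = time_varying_effect(fit, "z", t)
        B = spec.baseline.evaluate(t)
        b = np.concatenate([[1.0], B[0]])
        var = float(b @ vsub @ b)
        half = (tv.upper[0] - tv.lower[0]) / 2
        assert half == pytest.approx(1.96 * np.sqrt(var), rel=1e-10)
        est = float(b @ np.array([0.04, 0.002, -1e-5]))
        assert tv.estimate[0] == pytest.approx(est, rel=1e-12)

    def test_times_outside_pseudo_range_rejected(self):
        fit, _ = self._td_fit()
        with pytest.raises(ValueError, match="pseudo-time range"):
            time_varying_effect(fit, "z", np.array([100.0]))

    def test_constant_contrast_agrees_with_constant_effect(self, censored_sample):
        pv = pseudo_values(
            censored_sample, select_pseudo_times(censored_sample, 5)
        )
        spec = ModelSpec(
            link="identity",
            baseline=SplineBasis.indicator(pv.pseudo_times),
            covariate_terms=["z"],
        )
        fit = fit_gee(pv, spec)
        const = constant_effect(fit, "z")
        tv = time_varying_effect(fit, "z", pv.pseudo_times)
        np.testing.assert_allclose(tv.estimate, const.estimate, atol=1e-12)
        np.testing.assert_allclose(tv.lower, const.lower, atol=1e-12)


class TestNNT:
    def _rd(self, est, lo, hi):
        return EffectCurve(
            measure="RD",
            times=np.array([1.0]),
            estimate=np.array([est]),
            lower=np.array([lo]),
            upper=np.array([hi]),
        )

    def test_prostate_worked_example_two_piece_interval(self):
        # RD 2.2% with CI (-3.5%, 7.9%): NNT 45.45..., confidence set
        # (-inf, -28.57] U [12.66, +inf)
        nnt = nnt_from_rd(self._rd(0.022, -0.035, 0.079))
        assert nnt.estimate[0] == pytest.approx(1 / 0.022)
        assert nnt.lower[0] == -np.inf
        assert nnt.upper[0] == pytest.approx(1 / -0.035)
        assert nnt.lower2[0] == pytest.approx(1 / 0.079)
        assert nnt.upper2[0] == np.inf
        # display rounding gives the conventional "about 45", -28 and 13
        assert nnt_display(nnt.estimate[0]) == "45"
        assert nnt_display(nnt.upper[0], endpoint=True) == "-28"
        assert nnt_display(nnt.lower2[0], endpoint=True) == "13"

    def test_significant_rd_gives_exact_reciprocal_single_piece(self):
        nnt = nnt_from_rd(self._rd(0.5, 0.25, 1.0))
        assert nnt.estimate[0] == pytest.approx(2.0)
        assert nnt.lower[0] == pytest.approx(1.0)
        assert nnt.upper[0] == pytest.approx(4.0)
        assert np.isnan(nnt.lower2[0])

    def test_null_rd_maps_to_infinite_nnt(self):
        nnt = nnt_from_rd(self._rd(0.0, -0.1, 0.1))
        assert np.isinf(nnt.estimate[0])

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        rd=st.floats(-0.9, 0.9),
        half=st.floats(0.001, 0.5),
    )
    def test_piece_structure_iff_interval_excludes_zero(self, rd, half):
        lo, hi = rd - half, rd + half
        nnt = nnt_from_rd(self._rd(rd, lo, hi))
        single = not np.isnan(nnt.lower2[0])
        excludes_zero = lo > 0 or hi < 0
        assert single == (not excludes_zero)
        if excludes_zero:
            assert nnt.lower[0] == pytest.approx(1 / hi)
            assert nnt.upper[0] == pytest.approx(1 / lo)
            assert nnt.lower[0] <= nnt.estimate[0] <= nnt.upper[0]

    def test_frame_serialization_with_infinities(self):
        nnt = nnt_from_rd(self._rd(0.022, -0.035, 0.079))
        df = nnt.to_frame()
        assert set(df.columns) >= {"time", "estimate", "lower", "upper",
                                   "lower2", "upper2"}
        assert np.isneginf(df["lower"].iloc[0])

    def test_rejects_non_rd_curve(self):
        curve = EffectCurve(
            measure="RR",
            times=np.array([1.0]),
            estimate=np.array([1.2]),
            lower=np.array([0.9]),
            upper=np.array([1.5]),
        )
        with pytest.raises(ValueError, match="RD"):
            nnt_from_rd(curve)
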