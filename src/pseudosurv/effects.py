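"""Association measures and pointwise confidence intervals from a fitted
transformation model.

The link used at fit time fixes the measure obtained by back-transforming a
covariate contrast: identity -> survival/risk difference RD(t), log ->
relative risk RR(t), logit -> survival odds ratio, cloglog -> cumulative
hazard ratio (the hazard ratio under proportional hazards).  For a
time-dependent effect the contrast at time t is the linear combination
alpha + sum_k gamma_k B_k(t); its variance is the quadratic form
b(t)' V b(t) over the cluster-robust sub-covariance of (alpha, gamma_1, ...).

NNT(t) = 1 / RD(t).  When the RD interval contains 0 the NNT confidence set
is the disjoint union (-inf, 1/l_lower] U [1/l_upper, +inf): crossing "no
effect" corresponds to NNT passing through +-infinity, 1 is the largest
possible beneficial effect and -1 the largest harmful one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gee import TransformationModelFit
from .design import get_link

__all__ = [
    "EffectCurve",
    "constant_effect",
    "time_varying_effect",
    "nnt_from_rd",
    "nnt_display",
]

_MEASURE_BY_LINK = {
    "identity": "RD",
    "log": "RR",
    "logit": "OR_surv",
    "cloglog": "cumHR",
}


@dataclass
class EffectCurve:
    """Point estimates and pointwise CIs of one association measure on a
    time grid.  For NNT a disjoint two-piece interval per time is carried in
    (lower, upper) and (lower2, upper2); lower2/upper2 are NaN when the
    interval is a single piece."""

    measure: str
    times: np.ndarray
    estimate: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    lower2: np.ndarray | None = None
    upper2: np.ndarray | None = None
    link_used: str = "identity"
    covariate: str = ""
    description: str = ""
    direction: str = "survival_difference"  # treated minus control on S(t)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        for name in ("estimate", "lower", "upper"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.measure == "RD" and (
            np.any(self.estimate < -1 - 1e-12) or np.any(self.estimate > 1 + 1e-12)
        ):
            import warnings

            warnings.warn("RD estimates outside [-1, 1]", stacklevel=2)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "time": self.times,
                "estimate": self.estimate,
                "lower": self.lower,
                "upper": self.upper,
            }
        )
        if self.lower2 is not None:
            out["lower2"] = self.lower2
            out["upper2"] = self.upper2
        return out

    def plot(self, ax=None, **kwargs):
        """Effect-versus-time display with a shaded pointwise CI band."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.times, self.estimate, **kwargs)
        finite = np.isfinite(self.lower) & np.isfinite(self.upper)
        ax.fill_between(
            self.times[finite], self.lower[finite], self.upper[finite], alpha=0.25
        )
        ref = 0.0 if self.measure == "RD" else 1.0
        ax.axhline(ref, color="grey", lw=0.8, ls=":")
        ax.set_xlabel("time")
        ax.set_ylabel(f"{self.measure}(t)")
        return ax


def _z(level: float) -> float:
    # the conventional 1.96 at 95%; exact normal quantile otherwise
    return 1.96 if abs(level - 0.95) < 1e-12 else float(stats.norm.ppf(0.5 + level / 2))


def _transform(link_name: str, est, lo, hi):
    if link_name == "identity":
        return est, lo, hi
    return np.exp(est), np.exp(lo), np.exp(hi)


def constant_effect(
    fit: TransformationModelFit,
    covariate: str,
    delta: float = 1.0,
    level: float = 0.95,
) -> EffectCurve:
    """Flat effect curve for a covariate with no time-dependent terms.

    On the link scale the estimate is delta * alpha_hat with Wald interval
    alpha_hat +- z * se; RR/OR/cumHR are obtained by exponentiating the
    endpoints (a monotone transform), RD needs no transformation.
    """
    if covariate in fit.spec.td_terms:
        raise ValueError(
            f"{covariate!r} has time-dependent terms; use time_varying_effect"
        )
    if covariate not in fit.coefficients.index:
        raise ValueError(f"unknown covariate {covariate!r}")
    link = get_link(fit.spec.link)
    alpha = float(fit.coefficients[covariate]) * delta
    se = math.sqrt(float(fit.robust_vcov.loc[covariate, covariate])) * abs(delta)
    z = _z(level)
    est, lo, hi = _transform(link.name, alpha, alpha - z * se, alpha + z * se)
    times = fit.pseudo_times
    ones = np.ones_like(times)
    return EffectCurve(
        measure=_MEASURE_BY_LINK[link.name],
        times=times,
        estimate=est * ones,
        lower=lo * ones,
        upper=hi * ones,
        link_used=link.name,
        covariate=covariate,
        description=f"constant effect of {covariate} (delta={delta:g})",
    )


def time_varying_effect(
    fit: TransformationModelFit,
    covariate: str,
    times: np.ndarray,
    delta: float = 1.0,
    level: float = 0.95,
) -> EffectCurve:
    """Time-varying effect alpha + sum_k gamma_k B_k(t) with quadratic-form
    variance b(t)' V_sub b(t) over the cluster-robust sub-covariance.

    ``times`` must lie within the pseudo-time range (no extrapolation).
    Covariates without td terms degenerate to the constant effect.
    """
    times = np.asarray(times, dtype=float)
    lo_t, hi_t = fit.pseudo_times[0], fit.pseudo_times[-1]
    if np.any(times < lo_t - 1e-9) or np.any(times > hi_t + 1e-9):
        raise ValueError(
            f"times must lie within the pseudo-time range [{lo_t:g}, {hi_t:g}]"
        )
    if covariate not in fit.coefficients.index:
        raise ValueError(f"unknown covariate {covariate!r}")
    link = get_link(fit.spec.link)
    terms = [covariate] + fit.spec.td_column_names(covariate)
    theta = fit.coefficients.loc[terms].to_numpy()
    V = fit.robust_vcov.loc[terms, terms].to_numpy()
    if len(terms) == 1:
        b = np.ones((times.size, 1))
    else:
        B = fit.spec.baseline.evaluate(times)
        b = np.column_stack([np.ones(times.size), B])
    est = delta * (b @ theta)
    var = delta**2 * np.einsum("tp,pq,tq->t", b, V, b)
    se = np.sqrt(var)
    z = _z(level)
    est_m, lo, hi = _transform(link.name, est, est - z * se, est + z * se)
    return EffectCurve(
        measure=_MEASURE_BY_LINK[link.name],
        times=times,
        estimate=est_m,
        lower=lo,
        upper=hi,
        link_used=link.name,
        covariate=covariate,
        description=f"time-varying effect of {covariate} (delta={delta:g})",
    )


def nnt_from_rd(rd_curve: EffectCurve) -> EffectCurve:
    """NNT(t) = 1 / RD(t) with the reciprocal interval arithmetic.

    If the RD interval excludes 0 the NNT interval is the single piece
    [1/upper, 1/lower]; if it includes 0 the confidence set is the disjoint
    union (-inf, 1/lower] U [1/upper, +inf).  RD = 0 maps to an infinite
    point estimate.  Stored values are exact reals; see :func:`nnt_display`
    for the whole-patients display rounding.
    """
    if rd_curve.measure != "RD":
        raise ValueError("nnt_from_rd needs an RD curve")
    rd = rd_curve.estimate
    with np.errstate(divide="ignore"):
        est = np.where(rd == 0, np.inf, 1.0 / np.where(rd == 0, 1.0, rd))
    n = rd.size
    lower = np.empty(n)
    upper = np.empty(n)
    lower2 = np.full(n, np.nan)
    upper2 = np.full(n, np.nan)
    for i in range(n):
        lo_rd, hi_rd = rd_curve.lower[i], rd_curve.upper[i]
        if lo_rd > 0 or hi_rd < 0:  # interval excludes 0: single piece
            lower[i] = 1.0 / hi_rd
            upper[i] = 1.0 / lo_rd
        else:  # includes 0: piece through +-infinity
            lower[i] = -np.inf
            upper[i] = -np.inf if lo_rd == 0 else 1.0 / lo_rd
            lower2[i] = np.inf if hi_rd == 0 else 1.0 / hi_rd
            upper2[i] = np.inf
    return EffectCurve(
        measure="NNT",
        times=rd_curve.times,
        estimate=est,
        lower=lower,
        upper=upper,
        lower2=lower2,
        upper2=upper2,
        link_used=rd_curve.link_used,
        covariate=rd_curve.covariate,
        description=f"NNT from {rd_curve.description}",
        direction=rd_curve.direction,
    )


def nnt_display(value: float, endpoint: bool = False) -> str:
    """Whole-patients display of an NNT value.

    Point estimates are truncated toward zero (45.45 -> "45"); interval
    endpoints take the signed ceiling, counting the beneficial side up
    conservatively (12.66 -> 13) and the harmful side toward zero
    (-28.57 -> -28).  Display only: stored values stay exact.
    """
    if not np.isfinite(value):
        return "inf" if value > 0 else "-inf"
    rounded = math.ceil(value) if endpoint else math.trunc(value)
    return str(int(rounded))
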