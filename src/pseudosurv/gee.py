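"""GEE estimation of transformation models on pseudo-value data.

The model ``g(E[theta_i(t)]) = eta = X beta`` is fitted by solving the
estimating equations

    sum_i D_i' V_i^{-1} (theta_i - mu_i) = 0

with an independence working correlation and working variance identically 1
(a homoskedastic Gaussian working model).  The constant working variance is
deliberate: pseudo-values can fall outside [0, 1], so a binomial-type
variance function would be undefined.  Inference uses the cluster-robust
sandwich covariance A^{-1} B A^{-1} clustered by subject, the standard choice
for pseudo-observation regression.

With the identity link the solver reduces to ordinary least squares on the
long data, which the test suite exploits as a closed-form oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .design import LinkFunction, ModelSpec, SplineBasis, build_design, get_link
from .surv_core import (
    PseudoValueData,
    SurvivalSample,
    kaplan_meier,
    pseudo_values,
    select_pseudo_times,
)

__all__ = [
    "TransformationModelFit",
    "WaldResult",
    "ConvergenceError",
    "fit_gee",
    "wald_test",
    "qic",
    "backward_select_td",
    "marginal_survival_check",
    "MarginalCheck",
]

_CLAMP = 1e-10


class ConvergenceError(RuntimeError):
    """GEE iterations failed to converge; carries the step-size trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


@dataclass
class TransformationModelFit:
    """A fitted transformation model with cluster-robust inference."""

    spec: ModelSpec
    coefficients: pd.Series
    robust_vcov: pd.DataFrame
    naive_vcov: pd.DataFrame
    n_subjects: int
    n_rows: int
    converged: bool
    fitted_means: np.ndarray
    scale: float  # Pearson-type moment estimate of the working dispersion
    pseudo_times: np.ndarray
    _bread: np.ndarray = field(repr=False, default=None)  # A = sum D_i' D_i
    _response: np.ndarray = field(repr=False, default=None)

    @property
    def link(self) -> LinkFunction:
        return get_link(self.spec.link)

    def robust_se(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.robust_vcov.to_numpy())),
            index=self.coefficients.index,
        )

    def summary(self) -> pd.DataFrame:
        se = self.robust_se()
        z = self.coefficients / se
        return pd.DataFrame(
            {
                "estimate": self.coefficients,
                "robust_se": se,
                "z": z,
                "p": 2 * stats.norm.sf(np.abs(z)),
            }
        )


@dataclass(frozen=True)
class WaldResult:
    statistic: float
    df: int
    p_value: float
    terms: tuple[str, ...]


def _check_collinearity(X: np.ndarray, names: list[str]) -> None:
    q, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps * 10
    bad = diag < tol
    if bad.any():
        cols = [names[piv[i]] for i in np.where(bad)[0]]
        raise ValueError(f"singular design; collinear columns: {cols}")


def fit_gee(
    pv: PseudoValueData,
    spec: ModelSpec,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> TransformationModelFit:
    """Fit the transformation model on the long pseudo-value data.

    Iteratively reweighted least squares on the estimating equations; start
    values come from an identity-link least-squares fit mapped through g.
    For log/logit/cloglog links fitted means are clamped away from {0, 1}
    inside the inverse link during iteration; a terminal fit whose unclamped
    means leave (0, 1) raises a warning (identity/log links do not guarantee
    in-range probabilities).
    """
    Xdf, y, clusters = build_design(pv, spec)
    names = list(Xdf.columns)
    X = Xdf.to_numpy()
    N, p = X.shape
    n_sub = pv.n
    if n_sub < p:
        raise ValueError(
            f"more design columns ({p}) than subjects ({n_sub}); model not identifiable"
        )
    _check_collinearity(X, names)
    link = get_link(spec.link)

    def inv_mu(eta: np.ndarray) -> np.ndarray:
        mu = link.ginv(eta)
        if link.name != "identity":
            mu = np.clip(mu, _CLAMP, 1.0 - _CLAMP)
        return mu

    # start: identity LS, means clamped into the link domain, mapped through g
    beta_ls, *_ = np.linalg.lstsq(X, y, rcond=None)
    if link.name == "identity":
        beta = beta_ls
    else:
        m0 = np.clip(X @ beta_ls, 1e-4, 1.0 - 1e-4)
        beta, *_ = np.linalg.lstsq(X, link.g(m0), rcond=None)

    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = inv_mu(eta)
        dmu = link.dinv(eta)  # d mu / d eta
        D = X * dmu[:, None]
        U = D.T @ (y - mu)
        A = D.T @ D
        try:
            delta = np.linalg.solve(A, U)
        except np.linalg.LinAlgError as err:
            raise ConvergenceError(f"normal equations singular: {err}", trace) from err
        beta = beta + delta
        step = float(np.max(np.abs(delta)))
        trace.append(step)
        if step < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"GEE did not converge in {max_iter} iterations "
            f"(last step {trace[-1]:.3e})",
            trace,
        )

    eta = X @ beta
    mu_unclamped = link.ginv(eta)
    mu = inv_mu(eta)
    if link.name in ("identity", "log") and (
        np.any(mu_unclamped < 0) or np.any(mu_unclamped > 1)
    ):
        warnings.warn(
            f"{link.name}-link fitted means leave (0, 1); "
            "interpret survival probabilities with care",
            stacklevel=2,
        )
    dmu = link.dinv(eta)
    D = X * dmu[:, None]
    resid = y - mu
    A = D.T @ D
    A_inv = np.linalg.inv(A)
    # cluster score sums; data are balanced and ordered by (subject, time)
    M = pv.M
    S = (D * resid[:, None]).reshape(n_sub, M, p).sum(axis=1)
    B = S.T @ S
    robust = A_inv @ B @ A_inv
    phi = float(resid @ resid) / (N - p)
    naive = phi * A_inv

    return TransformationModelFit(
        spec=spec,
        coefficients=pd.Series(beta, index=names),
        robust_vcov=pd.DataFrame(robust, index=names, columns=names),
        naive_vcov=pd.DataFrame(naive, index=names, columns=names),
        n_subjects=n_sub,
        n_rows=N,
        converged=converged,
        fitted_means=mu_unclamped,
        scale=phi,
        pseudo_times=pv.pseudo_times.copy(),
        _bread=A,
        _response=y,
    )


def wald_test(fit: TransformationModelFit, terms: list[str]) -> WaldResult:
    """Joint Wald chi-square test that the named coefficients are zero,
    using the cluster-robust covariance."""
    if not terms:
        raise ValueError("no terms to test")
    missing = [t for t in terms if t not in fit.coefficients.index]
    if missing:
        raise ValueError(f"unknown terms: {missing}")
    c = fit.coefficients.loc[terms].to_numpy()
    V = fit.robust_vcov.loc[terms, terms].to_numpy()
    stat = float(c @ np.linalg.solve(V, c))
    df = len(terms)
    return WaldResult(stat, df, float(stats.chi2.sf(stat, df)), tuple(terms))


def qic(fit: TransformationModelFit) -> float:
    """Quasi-likelihood information criterion under the Gaussian working model.

    QIC = -2 Q(mu_hat) + 2 trace(Omega_I V_robust), with quasi-likelihood
    Q = -(1/2) sum (theta - mu)^2 / phi_hat and Omega_I the naive (model-based)
    information A / phi_hat.  Lower is better.  When the robust covariance
    equals the naive one the penalty reduces to 2p (the QICu limit).
    """
    resid = fit._response - fit.fitted_means
    Q = -0.5 * float(resid @ resid) / fit.scale
    omega = fit._bread / fit.scale
    penalty = float(np.trace(omega @ fit.robust_vcov.to_numpy()))
    return -2.0 * Q + 2.0 * penalty


def qicu(fit: TransformationModelFit) -> float:
    """QICu = -2 Q + 2 p (penalty by parameter count)."""
    resid = fit._response - fit.fitted_means
    Q = -0.5 * float(resid @ resid) / fit.scale
    return -2.0 * Q + 2.0 * len(fit.coefficients)


def backward_select_td(
    pv: PseudoValueData,
    full_spec: ModelSpec,
    alpha: float = 0.05,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> ModelSpec:
    """Backward elimination of time-dependent blocks by joint Wald tests.

    Repeatedly removes the covariate whose whole interaction block has the
    largest joint-Wald p-value above ``alpha`` and refits; main effects are
    never removed.  Deterministic given the data.  alpha = 1 returns the full
    spec unchanged.
    """
    spec = ModelSpec(
        link=full_spec.link,
        baseline=full_spec.baseline,
        covariate_terms=list(full_spec.covariate_terms),
        td_terms=list(full_spec.td_terms),
    )
    if alpha >= 1:
        return spec
    while spec.td_terms:
        fit = fit_gee(pv, spec, tol=tol, max_iter=max_iter)
        pvals = {
            cov: wald_test(fit, spec.td_column_names(cov)).p_value
            for cov in spec.td_terms
        }
        worst = max(pvals, key=lambda c: pvals[c])
        if pvals[worst] <= alpha:
            break
        spec = ModelSpec(
            link=spec.link,
            baseline=spec.baseline,
            covariate_terms=list(spec.covariate_terms),
            td_terms=[c for c in spec.td_terms if c != worst],
        )
    return spec


@dataclass
class MarginalCheck:
    """KM vs covariate-free transformation-model marginal survival."""

    times: np.ndarray
    km: np.ndarray
    model: np.ndarray
    max_abs_discrepancy: float
    monotone: bool


def marginal_survival_check(
    sample: SurvivalSample,
    M: int,
    baseline: SplineBasis,
    link: str = "identity",
) -> MarginalCheck:
    """Fit the intercept + baseline model (no covariates) and compare its
    marginal survival with the Kaplan-Meier estimate on the pseudo-time grid.

    A non-monotone fitted baseline raises the ``monotone=False`` flag; the
    estimate is not constrained.
    """
    times = select_pseudo_times(sample, M)
    pv = pseudo_values(sample, times)
    spec = ModelSpec(link=link, baseline=baseline)
    fit = fit_gee(pv, spec)
    B = baseline.evaluate(times)
    eta = fit.coefficients.iloc[0] + B @ fit.coefficients.iloc[1:].to_numpy()
    model_surv = get_link(link).ginv(eta)
    km = kaplan_meier(sample)(times)
    return MarginalCheck(
        times=times,
        km=km,
        model=model_surv,
        max_abs_discrepancy=float(np.max(np.abs(model_surv - km))),
        monotone=bool(np.all(np.diff(model_surv) <= 1e-10)),
    )
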