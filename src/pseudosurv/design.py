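"""Link functions, spline bases and regression-design assembly.

The transformation model regresses a monotone transform g of the conditional
survival probability on covariates,

    g(S(t | x)) = g(S0(t)) + x' beta,

with the transformed baseline g(S0(t)) represented parametrically by spline
(or indicator) bases of the pseudo-time.  The link chosen fixes the scale of
the covariate coefficients: identity -> survival/risk difference (RD), log ->
relative risk, logit -> survival odds ratio, cloglog (log(-log s)) ->
cumulative-hazard ratio (equal to the hazard ratio under proportional
hazards).  Time-dependent covariate effects enter as interactions between a
covariate and every baseline basis column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.special import expit

from .surv_core import PseudoValueData, SurvivalSample

__all__ = [
    "LinkFunction",
    "LINKS",
    "get_link",
    "SplineBasis",
    "ModelSpec",
    "rcs_basis",
    "default_knots",
    "build_design",
]


@dataclass(frozen=True)
class LinkFunction:
    """A monotone transform g with inverse and derivative dg/ds."""

    name: str
    g: Callable[[np.ndarray], np.ndarray]
    ginv: Callable[[np.ndarray], np.ndarray]
    dg: Callable[[np.ndarray], np.ndarray]
    # derivative of the inverse link, d mu / d eta, used by the GEE solver
    dinv: Callable[[np.ndarray], np.ndarray]
    domain: tuple[float, float] = (0.0, 1.0)


def _cloglog_inv(eta):
    return np.exp(-np.exp(eta))


LINKS: dict[str, LinkFunction] = {
    "identity": LinkFunction(
        "identity",
        g=lambda s: np.asarray(s, dtype=float),
        ginv=lambda e: np.asarray(e, dtype=float),
        dg=lambda s: np.ones_like(np.asarray(s, dtype=float)),
        dinv=lambda e: np.ones_like(np.asarray(e, dtype=float)),
        domain=(-np.inf, np.inf),
    ),
    "log": LinkFunction(
        "log",
        g=np.log,
        ginv=np.exp,
        dg=lambda s: 1.0 / s,
        dinv=np.exp,
    ),
    "logit": LinkFunction(
        "logit",
        g=lambda s: np.log(s / (1.0 - s)),
        ginv=expit,
        dg=lambda s: 1.0 / (s * (1.0 - s)),
        dinv=lambda e: expit(e) * (1.0 - expit(e)),
    ),
    "cloglog": LinkFunction(
        "cloglog",
        g=lambda s: np.log(-np.log(s)),
        ginv=_cloglog_inv,
        dg=lambda s: 1.0 / (s * np.log(s)),
        dinv=lambda e: -np.exp(e) * np.exp(-np.exp(e)),
    ),
}


def get_link(link: "str | LinkFunction") -> LinkFunction:
    if isinstance(link, LinkFunction):
        return link
    try:
        return LINKS[link]
    except KeyError:
        raise ValueError(
            f"unknown link {link!r}; choose from {sorted(LINKS)}"
        ) from None


def _trunc_cube(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, 0.0) ** 3


def rcs_basis(t: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted cubic spline basis (linear-tail truncated power basis).

    For K knots k_1 < ... < k_K returns K-1 columns: the first is t itself,
    and for j = 1..K-2

        B_{j+1}(t) = (t-k_j)+^3
                     - (t-k_{K-1})+^3 * (k_K - k_j) / (k_K - k_{K-1})
                     + (t-k_K)+^3   * (k_{K-1} - k_j) / (k_K - k_{K-1})

    which is cubic between the boundary knots and exactly linear outside
    them.  No scaling or orthogonalisation is applied, so coefficients stay
    in raw time units.
    """
    t = np.asarray(t, dtype=float)
    knots = np.asarray(knots, dtype=float)
    if knots.ndim != 1 or knots.size < 3:
        raise ValueError("rcs needs at least 3 knots")
    if np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing (no duplicates)")
    K = knots.size
    cols = [t]
    kK, kK1 = knots[-1], knots[-2]
    for j in range(K - 2):
        kj = knots[j]
        col = (
            _trunc_cube(t - kj)
            - _trunc_cube(t - kK1) * (kK - kj) / (kK - kK1)
            + _trunc_cube(t - kK) * (kK1 - kj) / (kK - kK1)
        )
        cols.append(col)
    return np.column_stack(cols)


def default_knots(event_times: np.ndarray, K: int = 3) -> np.ndarray:
    """Knots at quantiles of the distinct event-time distribution.

    K=3 uses the conventional {0.1, 0.5, 0.9}; K=5 uses
    {0.05, 0.25, 0.5, 0.75, 0.95}; any other K >= 3 places K equally spaced
    quantiles on [0.05, 0.95].
    """
    distinct = np.unique(np.asarray(event_times, dtype=float))
    if distinct.size < max(K, 2):
        raise ValueError("not enough distinct event times for the requested knots")
    if distinct[0] == distinct[-1]:
        raise ValueError("event times are constant; knots are undefined")
    if K == 3:
        probs = np.array([0.1, 0.5, 0.9])
    elif K == 5:
        probs = np.array([0.05, 0.25, 0.5, 0.75, 0.95])
    elif K >= 3:
        probs = np.linspace(0.05, 0.95, K)
    else:
        raise ValueError("K must be >= 3")
    knots = np.quantile(distinct, probs, method="linear")
    if np.any(np.diff(knots) <= 0):
        raise ValueError("quantile knots are not distinct; reduce K")
    return knots


@dataclass
class SplineBasis:
    """Baseline time basis: restricted cubic spline, cubic B-spline or
    pseudo-time indicators.  ``n_basis`` excludes the intercept."""

    kind: str  # rcs | bspline | indicator
    knots: np.ndarray = field(default_factory=lambda: np.array([]))
    boundary: tuple[float, float] | None = None  # bspline only
    reference_times: np.ndarray | None = None  # indicator only

    def __post_init__(self) -> None:
        if self.kind not in ("rcs", "bspline", "indicator"):
            raise ValueError("kind must be one of rcs, bspline, indicator")
        self.knots = np.asarray(self.knots, dtype=float)
        if self.knots.size and np.any(np.diff(self.knots) <= 0):
            raise ValueError("duplicate or unsorted knots")

    @classmethod
    def rcs(cls, knots: np.ndarray) -> "SplineBasis":
        return cls("rcs", np.asarray(knots, dtype=float))

    @classmethod
    def bspline(
        cls, interior_knots: np.ndarray, boundary: tuple[float, float]
    ) -> "SplineBasis":
        return cls("bspline", np.asarray(interior_knots, dtype=float), boundary=boundary)

    @classmethod
    def indicator(cls, pseudo_times: np.ndarray) -> "SplineBasis":
        return cls(
            "indicator", reference_times=np.asarray(pseudo_times, dtype=float)
        )

    @classmethod
    def from_sample(
        cls, sample: SurvivalSample, kind: str = "rcs", n_knots: int = 3
    ) -> "SplineBasis":
        """Data-driven default: knots at quantiles of distinct event times."""
        if kind == "rcs":
            return cls.rcs(default_knots(sample.distinct_event_times, n_knots))
        raise ValueError("from_sample supports kind='rcs' only")

    @property
    def n_basis(self) -> int:
        if self.kind == "rcs":
            return self.knots.size - 1
        if self.kind == "bspline":
            # cubic: interior + 4 B-spline functions, first dropped for the
            # model intercept
            return self.knots.size + 3
        return self.reference_times.size - 1

    def column_names(self) -> list[str]:
        return [f"b{j + 1}" for j in range(self.n_basis)]

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.kind == "rcs":
            return rcs_basis(t, self.knots)
        if self.kind == "bspline":
            if self.boundary is None:
                raise ValueError("bspline basis needs boundary knots")
            lo, hi = self.boundary
            if self.knots.size and (
                np.any(self.knots <= lo) or np.any(self.knots >= hi)
            ):
                raise ValueError("interior knots must lie inside the boundary")
            full = np.concatenate([[lo] * 4, self.knots, [hi] * 4])
            tc = np.clip(t, lo, hi)
            dm = BSpline.design_matrix(tc, full, 3).toarray()
            return dm[:, 1:]  # drop first basis; the model keeps an intercept
        # indicator: dummies against the first pseudo-time as reference
        ref = self.reference_times
        out = np.zeros((t.size, ref.size - 1))
        for j, tm in enumerate(ref[1:]):
            out[:, j] = np.isclose(t, tm)
        return out


@dataclass
class ModelSpec:
    """Specification of one transformation model.

    ``td_terms`` lists covariates whose effect interacts with every baseline
    basis column (time-dependent effect); it must be a subset of
    ``covariate_terms``.  Design column order is fixed: intercept, baseline
    bases, covariates, interactions.
    """

    link: str = "identity"
    baseline: SplineBasis | None = None
    covariate_terms: list[str] = field(default_factory=list)
    td_terms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        get_link(self.link if isinstance(self.link, str) else self.link.name)
        extra = set(self.td_terms) - set(self.covariate_terms)
        if extra:
            raise ValueError(
                f"td_terms must be a subset of covariate_terms; extra: {sorted(extra)}"
            )

    def column_names(self) -> list[str]:
        names = ["intercept"] + self.baseline.column_names()
        names += list(self.covariate_terms)
        for cov in self.td_terms:
            names += [f"{cov}:{b}" for b in self.baseline.column_names()]
        return names

    def td_column_names(self, covariate: str) -> list[str]:
        if covariate not in self.td_terms:
            return []
        return [f"{covariate}:{b}" for b in self.baseline.column_names()]

    def to_dict(self) -> dict:
        d: dict = {
            "link": self.link if isinstance(self.link, str) else self.link.name,
            "basis": self.baseline.kind,
            "covariates": list(self.covariate_terms),
            "td": list(self.td_terms),
        }
        if self.baseline.kind == "indicator":
            d["pseudo_times"] = self.baseline.reference_times.tolist()
        else:
            d["knots"] = self.baseline.knots.tolist()
            if self.baseline.boundary is not None:
                d["boundary"] = list(self.baseline.boundary)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        kind = d.get("basis", "rcs")
        if kind == "indicator":
            basis = SplineBasis.indicator(np.asarray(d["pseudo_times"], dtype=float))
        elif kind == "bspline":
            basis = SplineBasis.bspline(
                np.asarray(d.get("knots", []), dtype=float),
                tuple(d["boundary"]),
            )
        else:
            basis = SplineBasis.rcs(np.asarray(d["knots"], dtype=float))
        return cls(
            link=d.get("link", "identity"),
            baseline=basis,
            covariate_terms=list(d.get("covariates", [])),
            td_terms=list(d.get("td", [])),
        )


def build_design(
    pv: PseudoValueData, spec: ModelSpec
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Assemble (design matrix, response theta, cluster ids) for the long data.

    Columns in fixed order: intercept, baseline basis columns evaluated at the
    pseudo-time, covariates, then covariate x basis interactions for each
    time-dependent term.
    """
    missing = [c for c in spec.covariate_terms if c not in pv.covariates.columns]
    if missing:
        raise ValueError(f"missing covariates in pseudo-value data: {missing}")
    if spec.baseline is None:
        raise ValueError("model spec has no baseline basis")
    if spec.baseline.kind != "indicator":
        lo, hi = pv.pseudo_times[0], pv.pseudo_times[-1]
        k = spec.baseline.knots
        if k.size and (k[0] < lo - 1e-9 or k[-1] > hi + 1e-9):
            warnings.warn(
                "baseline knots lie outside the pseudo-time range", stacklevel=2
            )

    long = pv.theta.ravel()
    n, M = pv.n, pv.M
    t_long = np.tile(pv.pseudo_times, n)
    B = spec.baseline.evaluate(t_long)  # (N, n_basis)
    cols = [np.ones(n * M), *B.T]
    for c in spec.covariate_terms:
        cols.append(np.repeat(pv.covariates[c].to_numpy(dtype=float), M))
    for c in spec.td_terms:
        x = np.repeat(pv.covariates[c].to_numpy(dtype=float), M)
        for j in range(B.shape[1]):
            cols.append(x * B[:, j])
    X = pd.DataFrame(
        np.column_stack(cols), columns=spec.column_names()
    )
    clusters = np.repeat(np.arange(n), M)
    return X, long, clusters
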