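# Methods

## Pseudo-value transformation models

The package estimates covariate effects on the conditional survival
function through transformation models

    g(S(t | x)) = g(S0(t)) + x' beta,

with g one of identity / log / logit / cloglog.  The transformed baseline
g(S0(t)) is represented parametrically by spline bases of the pseudo-time
(restricted cubic splines, cubic B-splines, or pseudo-time indicators), and
time-dependent covariate effects enter as interactions between a covariate
and every baseline basis column.

Since S(t | x) is not observable per subject under censoring, the response
is the jackknife pseudo-observation

    theta_i(t) = n * S_KM(t) - (n - 1) * S_KM^(-i)(t),

which is defined for every subject (censored or not) at every time, equals
the event-free indicator 1{T_i > t} exactly when no censoring is present,
and has the right conditional expectation under independent censoring.
Pseudo-values may fall outside [0, 1]; this is expected and harmless for
estimation.  Computation uses a closed-form leave-one-out update of the
full-sample death/risk counts, O(n·J) for J distinct event times, verified
in the test suite against naive O(n²) re-estimation at 1e-12.

**Scale convention.** Pseudo-values and all model equations are on the
survival-probability scale (theta estimates S(t)); the complementary event
scale (1 − theta) is available via `scale="event"`.  Reported risk
differences default to the survival difference of the treated/exposed minus
control/unexposed; the classical risk-difference orientation F1 − F2 is the
same quantity with opposite sign and is available through the curve's
`direction` metadata.

**Pseudo-times.** M pseudo-times sit at equally spaced probability
quantiles (type-7) of the *distinct* failure times, never at 0.  The default
M targets roughly 10 events between consecutive pseudo-times, capped at the
number of distinct event times.  Inference is pointwise within the
pseudo-time range; no extrapolation is allowed.

## GEE estimation

The estimating equations sum_i D_i' V_i^{-1} (theta_i − mu_i) = 0 are solved
with an independence working correlation and working variance identically 1
— a homoskedastic Gaussian working model.  A variance function tied to the
Bernoulli mean would be undefined for pseudo-values outside [0, 1], which is
why the constant choice is standard in pseudo-observation regression.
Consequences:

- with the identity link the solver is exactly ordinary least squares on
  the long (subject × pseudo-time) data — a closed-form oracle used by the
  tests;
- inference always uses the cluster-robust sandwich A^{-1} B A^{-1}
  clustered by subject (A = sum D_i'D_i, B = sum of per-subject score outer
  products); the naive covariance phi·A^{-1} is kept for QIC.

Numerical choices: Fisher-scoring (IRLS) updates; start values from an
identity-link least-squares fit clamped into the link domain and mapped
through g; convergence when the largest coefficient update drops below 1e-8,
cap 100 iterations with an error carrying the step trace; for log / logit /
cloglog the inverse link clamps means to [1e-10, 1 − 1e-10] during
iteration.  Identity and log links do not constrain fitted survival to
(0, 1); a terminal fit violating the range raises a warning, and the
baseline monotonicity check (below) flags non-monotone fits — neither is
enforced by constrained estimation.

Model comparison uses QIC = −2Q + 2·trace(Omega_I · V_robust) with the
Gaussian working quasi-likelihood Q = −(1/2) sum (theta − mu)²/phi and the
naive information Omega_I; phi is the Pearson-type moment estimate with
N − p denominator.  The quasi-likelihood inside QIC is itself a modelling
choice (nothing canonical exists for pseudo-values); QICu = −2Q + 2p is also
exposed, and the two coincide when robust and naive covariances agree.

Backward selection of time-dependent effects removes whole interaction
blocks (never single columns, never main effects) by joint Wald tests on the
robust covariance, dropping the block with the largest p-value above alpha
(default 0.05; 0.01 is the conservative option) and refitting until all
remaining blocks are significant.  The procedure is deterministic given the
data.

A graphical model check compares the Kaplan-Meier curve with the marginal
survival from the covariate-free model on the pseudo-time grid and reports
the maximum discrepancy plus a monotonicity flag for the fitted baseline.

## Effect curves and intervals

A constant effect uses alpha_hat ± 1.96·se on the link scale (the 1.96
multiplier is fixed at the conventional value for 95%; other levels use the
exact normal quantile); ratio measures exponentiate the endpoints (monotone,
so ordering is preserved).  A time-varying effect evaluates
b(t) = (1, B_1(t), ..., B_K(t)) against the coefficient subvector, with
variance b(t)' V_sub b(t) over the robust sub-covariance.

NNT(t) = 1/RD(t).  If the RD interval excludes 0 the NNT interval is
[1/upper, 1/lower]; otherwise the confidence set passes through infinity:
(−inf, 1/lower] U [1/upper, +inf).  RD = 0 maps to an infinite point
estimate; 1 and −1 are the largest beneficial and harmful NNT values.
Stored values are exact; for whole-patients display the point estimate is
truncated toward zero and interval endpoints take the signed ceiling (this
pair of rules reproduces the conventional "about 45", −28 and 13 from
RD 2.2% with CI (−3.5%, 7.9%)).

## The CGPM comparator

The corrected group prognosis method predicts each subject's survival from a
multivariable Cox model with the treatment forced to 1 and then to 0,
averages within a chosen set and differences the averages.  Averaging over
everyone gives the adjusted RD(t); over the unexposed only, the NNE
contrast; over the exposed only, the EIN contrast — and the all-subjects
curve is exactly the group-proportion-weighted mix of the two (tested to
1e-12).  The average covariate method (plug in covariate means) is provided
for comparison only; it describes a hypothetical average subject, not a
population average.

Baseline survival uses the exponentiated Breslow cumulative hazard.
Time-dependent covariate effects are supported as covariate × f(t)
interactions with f in {log t, restricted cubic spline, cubic B-spline};
the partial likelihood evaluates the interaction columns at every risk-set
event time, which is identical to the usual start-stop episode-split
augmentation (verified against an independent episode-split fit in the
tests), and survival prediction accumulates h0_e·exp(x(tau_e)'beta)
stepwise over the event-time grid.

Fitting uses an in-package vectorised Newton solver for the Breslow partial
likelihood (step-halving, tolerance 1e-9).  A single fit takes milliseconds,
which is what makes percentile-bootstrap confidence intervals practical:
subjects (not augmented rows) are resampled with replacement, the whole
CGPM pipeline is recomputed per resample (200 resamples inside simulations,
1000 for single-dataset analyses), and pointwise bounds are mirrored
empirical quantiles — so a degenerate B = 2 yields the min/max of the two
replicates, and the interval widens weakly with the confidence level.
Resamples whose fit fails are dropped and counted, with a warning above 1%.

## The simulation designs

Both designs draw 100 exposed and 100 unexposed subjects with confounder
X ~ N(45, 8) / N(40, 8) respectively, event times from

- design 1: hazard lam·exp(log(1.01)·X + log(1.80)·Z) (proportional), and
- design 2: hazard lam·exp(log(1.01)·X)·t^(cZ) with c = −log(0.95), a
  time-growing exposure effect generated by closed-form inversion of the
  cumulative hazard,

and censoring from the same covariate-dependent family with baseline rate
lam_c.  With that construction P(censored) = lam_c/(lam_c + lam) exactly,
so lam_c = lam/9 hits the 10% censoring target; a covariate-free censoring
switch with numeric calibration is also available.  The baseline rate lam
is chosen so the marginal median event time for an unexposed subject at
X = 40 equals 400, the middle evaluation time — this keeps 200/400/600
inside the event-time support in every replicate.  With this calibration
the true RD(t) magnitude peaks near t ≈ 410; the constant-RD arm's
misspecification is therefore mildest at t = 200 and strongest at
t = 400–600, so its undercoverage concentrates at the later evaluation
times.  A different (smaller-median) baseline rate would move the peak
before t = 200 and shift the undercoverage earlier; only this timing, not
the qualitative conclusion, depends on the choice.

The exact adjusted RD(t) integrates the conditional survival difference over
the two confounder densities by Gauss-Hermite quadrature (80 nodes, doubled
once as a convergence check; cross-validated against 10^6-draw Monte-Carlo
integration).

The harness runs, per replicate: simulate, fit each estimator arm with a
nominal 95% interval — pseudo-value arms use the identity link, a
restricted cubic spline baseline with 5 knots at the 5/25/50/75/95%
quantiles of the distinct failure times, covariates Z and X, and Z either
constant or fully time-interacted; CGPM arms use the Cox model with Z
proportional, Z × log t, or Z × rcs(t, 3 knots), each with 200 bootstrap
resamples — then aggregates bias, RMSE, mean CI width and empirical
coverage with Monte-Carlo standard errors.  Replicate streams are spawned
from a single seed sequence, so results are reproducible bit-for-bit.
Problem sizes in the shipped tests and acceptance script: 500 replicates
for the pseudo-value arms, 300 (design 1) / 150 (design 2) for the
bootstrap-based CGPM arms; Monte-Carlo standard errors accompany every
cell.

**What the generator does and does not emulate.** It reproduces the
designs' confounding structure (a normally shifted confounder), exponential
/ Weibull-type event times, and proportional covariate-dependent censoring.
It does not emulate covariate measurement error, ties from coarse time
recording, non-proportional censoring, competing risks, or categorical
covariate patterns — so passing simulation checks demonstrates correctness
of the estimators under the stated designs, not robustness on arbitrary
real data.

## Known limitations

- Identity/log-link fitted survival can leave (0, 1) and the fitted
  baseline need not be monotone; both are flagged, not constrained.
- Confidence intervals are pointwise; no simultaneous bands.
- Competing risks, restricted-mean pseudo-values and additive hazard models
  are out of scope.
- The cloglog pseudo-value estimate of a hazard ratio attenuates slightly
  relative to Cox partial likelihood for strong effects; the tests allow
  for this mild attenuation.
- The prostate reproduction depends on a user-supplied public file; its
  pipeline skips (never fails) when the file is absent.
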