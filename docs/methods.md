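# Methods

## Model and estimands

`ivhr` targets the marginal structural Cox model for potential outcomes,

S_x(t) = S₀(t)^{exp β_X(t;θ)·x}, equivalently λ₁(t) = exp{β_X(t;θ)}·λ₀(t),

with a single (typically binary) exposure X fixed at baseline.  "Marginal"
means the model describes the population law of the potential outcomes — it
never parameterizes the effect of the omitted covariate U, and by the
non-collapsibility of the Cox model it is *not* the same estimand as the
U-conditional hazard ratio.  Three parameterizations of the log hazard ratio
are provided:

| kind      | β_X(t;θ)                  | K | weight functions φ_k = ∂β/∂θ_k |
|-----------|---------------------------|---|---------------------------------|
| constant  | θ₁                        | 1 | φ₁ ≡ 1                          |
| loglinear | θ₀ + θ₁·t                 | 2 | φ₁ ≡ 1, φ₂(t) = t               |
| piecewise | θ_k on [τ_{k−1}, τ_k)     | K | window indicators               |

Piecewise windows are half-open and the final window extends to +∞, so
β_X is total on t ≥ 0 (the nominal upper integration limit τ is taken as the
largest observed time, and the last window simply absorbs it).  The loglinear
ordering is (intercept, slope); θ₁ is per unit of the input's time scale.

## Estimation

The IV estimating function is

G_k(θ) = Σ_v φ_k(v) · Σ_{events i at v} [W_i − W̄(v;θ)],

with W̄ the exp{β_X(v;θ)X_j}-weighted mean of the instrument over the risk
set at v; the partial-likelihood comparator replaces W by X.  The baseline
cumulative hazard never appears: substituting the Breslow increments
dΛ̂₀(v) = ΣdN(v) / ΣR(v)e^{βX} eliminates it, which is also why the equations
reduce exactly to the Cox partial-likelihood score when W ≡ X.  The estimator
is *not* claimed to be consistent in general — it inherits the heuristic of
substituting the Breslow estimator — and the simulations quantify the residual
bias rather than assume it away.

Numerical choices:

- **Ties.** Breslow convention throughout: events tied at a time share one
  risk set, subjects censored at an event time remain at risk there.
- **Solver.** Damped Newton on G(θ): central finite-difference Jacobian
  (relative step 1e-5), step halved up to 20 times whenever ‖G‖∞ fails to
  decrease, start θ = 0 (hazard ratio 1), tolerance 1e-8 on ‖G‖∞, at most 100
  iterations.  A singular Jacobian or a stalled line search yields a result
  flagged `converged=False` rather than an exception, so simulation studies
  can tally failures.
- **Conditioning.** For the loglinear model the slope equation carries weights
  φ₂(v) = v; times are internally rescaled by their maximum and the slope
  unscaled afterwards, with the internal tolerance tightened so the reported
  residual (on the original scale) still meets the requested tolerance.
- **Overflow.** Risk-set weights are computed with a per-risk-set
  max-subtraction on the exponent, so the weighted means are finite for any
  β·X; at θ = 0 the Breslow increments reduce *exactly* to the Nelson–Aalen
  increments dN(v)/R(v).
- **Complexity.** Risk sets are suffixes of the time-sorted sample.  For
  constant and piecewise models the subject weights are constant across the
  event times of a window, so each evaluation of G is a reverse cumulative
  sum, O(n) after one sort; the loglinear model uses a chunked event-time ×
  subject matrix.
- **Piecewise fitting.** One constant solve per window on the truncated
  sub-sample (drop subjects who left risk before the window, censor events at
  or after its end).  This equals the joint K-dimensional solve because the
  indicator-weight system decouples; a window without events is reported as a
  per-window error while the other windows are still returned.
- **Degenerate inputs.** No events, constant exposure, or (for the IV method)
  constant instrument raise a degenerate-data error before any iteration.

## Confidence intervals

The variance of the estimating equations is not derived here (no sandwich or
martingale formula is implemented); intervals are nonparametric subject-level
**percentile bootstrap**: resample n subjects with replacement B times
(default 500), refit, take the (1−level)/2 and 1−(1−level)/2 percentiles per
parameter.  Non-convergent refits are dropped and counted; more than 50%
failures aborts the interval.  Percentile bootstrap is an assumption-light
default, not a reproduction of any particular variance estimator, and it
undercovers somewhat at small n.

## The data generator

The simulator produces observational data whose treatment assignment is
confounded by an unmeasured variable while the marginal potential-outcome
laws follow the structural model exactly:

1. (Y₀, Y₁) ~ copula(ρ) with uniform marginals.  ρ is interpreted as
   **Kendall's τ for every family** and mapped to the family parameter by the
   standard inversions — Gaussian correlation sin(πτ/2), Clayton 2τ/(1−τ),
   Gumbel 1/(1−τ) — so the dependence level is comparable across families.
   Clayton and Gumbel are sampled by Marshall–Olkin mixing, carried in log
   space because at τ = 0.99 the mixing variables (Gamma with shape ≈ 1/200,
   positive stable with index ≈ 1/100) put appreciable mass outside the
   representable range of double precision.
2. U = Φ⁻¹(Y₀): the omitted covariate is a standard-normal, monotone
   transform of the untreated potential outcome.
3. W ~ N(0,1), independent of (Y₀, Y₁) — a valid instrument by construction.
4. X ~ Bernoulli(logistic(α_UX·U + α_WX·W)); the zero intercept gives ~50%
   treated.  α_UX is the confounding dial (0 = exogenous treatment), α_WX the
   instrument strength.
5. T(0) = −log Y₀ (unit exponential); T(1) = Λ₁⁻¹(−log Y₁) with
   Λ₁(t) = ∫₀ᵗ e^{β_X(v;θ)}dv, inverted in closed form per model kind.
   Both potential outcomes are coupled through their *survival coordinates*
   (S₀(T(0)) = Y₀ and S₁(T(1)) = Y₁), so the latent frailty is concordant
   across arms: a subject short-lived untreated is short-lived treated.  The
   copula affects only this joint law; each marginal is exact by
   construction.
6. C ~ Uniform(0, c) with c calibrated on the realized pre-censoring times of
   the dataset being generated: the expected censored fraction
   (1/n)Σ min(T_i/c, 1) is driven to the target by bracketed root finding
   (Brent, tolerance 1e-10).  Target 0 returns an infinite scale (no
   censoring).

One seed sequence drives four documented streams (copula → instrument →
treatment → censoring), so each step is individually reproducible.

Defective treated laws: a loglinear model with negative slope has finite
total hazard Λ₁(∞) = e^{θ₀}/|θ₁|, so a fraction exp(−Λ₁(∞)) of the treated
mass never fails.  The generator realizes those draws as T(1) = +∞ — subjects
censored with certainty — which keeps S₁(t) = exp(−Λ₁(t)) exact at every
finite t.  Calibration refuses censoring targets at or below the
never-failing fraction.  The public quantile function keeps a strict
contract (requests beyond the mass raise a defective-distribution error)
and the generator opts into the +∞ behavior explicitly.

What the generator does **not** emulate: covariate-dependent or informative
censoring, time-varying exposure, competing risks, delayed entry, measured
covariates, or non-logistic selection.  Passing tests therefore show the
estimator's behavior under clean instrument validity and independent uniform
censoring — not robustness to violations of those assumptions.

## The Monte Carlo study

`run_study` draws, per replicate: α_UX ~ U[−log 10, log 10],
α_WX ~ U[log 2, log 50], copula family and ρ ∈ {0.5, 0.99} uniformly, and a
true model — stepwise with three period values drawn from a 25-point grid on
[−ln 3, ln 3], or loglinear with intercept from {−1, −0.8, …, 1} and slope
from {−0.5, −0.4, …, 0.5}.  (The stepwise grid is specified by its endpoints;
25 equally spaced points give step log(9)/24.)  Each replicate generates
n = 1000 subjects at 50% target censoring, fits the requested estimators, and
records θ̂ − θ_true.  Medians are aggregated within strata: confounding
positive/negative when α_UX ≷ ±log 5 (else none), instrument strong when
exp(α_WX) > 5.  Stepwise period boundaries sit where untreated survival
crosses 90% and 75%, i.e. −log 0.90 and −log 0.75 on the unit-exponential
scale — one defensible reading of "early/mid/late" follow-up.

Replicates are independent with per-replicate seeds spawned from the master
seed, so results are order-independent and could be parallelized.  Replicates
where an estimator fails to converge are excluded from that estimator's
median and reported in `n_failed`.

Default replication is 200 datasets per condition — enough to separate the
partial likelihood's confounding bias (order 1 on the log-HR scale under
strong confounding) from the IV estimator's residual bias (order 0.1) with
median Monte Carlo errors around 0.02–0.05.  The acceptance-level study in
the test suite uses this size; larger runs are a `reps` argument away.

## Known limitations

- The IV estimator is biased away from the null for hazard ratios far from 1,
  and the loglinear slope estimate retains visible bias under very strong
  confounding; the bias advantage over the partial likelihood is the claim,
  not unbiasedness.
- No asymptotic variance; bootstrap only.
- Exposure fixed at baseline; single exposure; no covariate adjustment.
- The estimating equations assume the instrument's exclusion restriction and
  randomization; nothing in the data can verify these.
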