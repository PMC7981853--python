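"""Copula-based potential-outcomes simulator with a specified marginal hazard ratio.

The generator produces right-censored observational data in which treatment
assignment depends on an omitted covariate, yet the *marginal* laws of the
potential outcomes are exactly those of a structural Cox model:

1. Draw (Y₀, Y₁) from a bivariate copula with uniform marginals and
   dependence ρ (interpreted as Kendall's τ; see :func:`sample_copula`).
2. The omitted covariate is U = Φ⁻¹(Y₀) — a standard-normal, monotone
   transform of the untreated potential outcome.
3. Draw the instrument W ~ N(0, 1), independent of everything so far.
4. Assign treatment X ~ Bernoulli(logistic(α_UX·U + α_WX·W)); the zero
   intercept yields roughly equal arm sizes.
5. Potential outcomes: T(0) = −log(Y₀), unit exponential, so Y₀ is the
   *survival coordinate* of T(0): S₀(T(0)) = Y₀.  T(1) enters through the
   same coordinate, S₁(T(1)) = Y₁, i.e. T(1) = Λ₁⁻¹(−log Y₁) where
   Λ₁(t) = ∫₀ᵗ exp{β_X(v;θ)} dv is the treated cumulative hazard against the
   unit-exponential baseline.  Coupling both arms through their survival
   coordinates makes the latent frailty concordant: a subject short-lived
   untreated is short-lived treated, which is what lets α_UX generate genuine
   confounding of one sign.
6. Censor with C ~ Uniform(0, c), with c calibrated so the expected censored
   fraction of this dataset equals the target rate.

Because the marginals of the copula are uniform no matter the dependence, the
marginal distributions of T(0) and T(1) are exact by construction; the copula
and the α_UX selection only create the confounding, never a distortion of the
structural model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, ndtr, ndtri

from .data_model import SurvivalSample
from .exceptions import CalibrationError, DefectiveDistributionError
from .hazard_models import HazardRatioModel

COPULA_FAMILIES = ("gaussian", "clayton", "gumbel")


@dataclass(frozen=True)
class SimulationConfig:
    """Settings of one generated dataset (all parameters constant within it)."""

    true_model: HazardRatioModel
    alpha_ux: float
    alpha_wx: float
    copula_family: str = "gaussian"
    rho: float = 0.5
    n: int = 1000
    censor_rate: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.copula_family not in COPULA_FAMILIES:
            raise ValueError(f"unsupported copula family {self.copula_family!r}")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        if self.n < 2:
            raise ValueError("n must be at least 2")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must lie in [0, 1)")


@dataclass(frozen=True)
class SimulatedDataset:
    """Observed sample plus the full latent structure for diagnostics."""

    sample: SurvivalSample
    y0: np.ndarray = field(repr=False)
    y1: np.ndarray = field(repr=False)
    u: np.ndarray = field(repr=False)
    t0: np.ndarray = field(repr=False)
    t1: np.ndarray = field(repr=False)
    censor_times: np.ndarray = field(repr=False)
    censor_scale: float = np.inf
    config: SimulationConfig | None = None

    def latent_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"Y0": self.y0, "Y1": self.y1, "U": self.u,
             "T0": self.t0, "T1": self.t1, "C": self.censor_times}
        )


# ---------------------------------------------------------------------------
# copulas
# ---------------------------------------------------------------------------


def kendall_tau_to_parameter(family: str, tau: float) -> float:
    """Map Kendall's τ to the family's natural parameter.

    Gaussian: correlation sin(πτ/2); Clayton: 2τ/(1−τ); Gumbel: 1/(1−τ).
    """
    if not 0.0 <= tau < 1.0:
        raise ValueError("tau must lie in [0, 1)")
    if family == "gaussian":
        return float(np.sin(np.pi * tau / 2.0))
    if family == "clayton":
        return 2.0 * tau / (1.0 - tau)
    if family == "gumbel":
        return 1.0 / (1.0 - tau)
    raise ValueError(f"unsupported copula family {family!r}")


def _log_positive_stable(alpha: float, size: int, rng: np.random.Generator) -> np.ndarray:
    # Chambers–Mallows–Stuck sampler for the positive stable law S(alpha, 1),
    # the mixing variable of the Gumbel copula (0 < alpha < 1).  Returns log V:
    # at strong dependence alpha is tiny and sin(u)^(1/alpha) under/overflows,
    # so everything is carried in log space.
    u = rng.uniform(0.0, np.pi, size)
    e = rng.standard_exponential(size)
    return (
        np.log(np.sin(alpha * u))
        - np.log(np.sin(u)) / alpha
        + (1.0 - alpha) / alpha * (np.log(np.sin((1.0 - alpha) * u)) - np.log(e))
    )


def sample_copula(family: str, rho: float, n: int, seed=None):
    """Draw n pairs (Y₀, Y₁) with uniform marginals and Kendall's τ = rho.

    ``rho`` is interpreted as Kendall's τ for every family so the dependence
    level is comparable across families; it is mapped to the family parameter
    by :func:`kendall_tau_to_parameter`.  ``seed`` may be an int, a
    SeedSequence, or a Generator.  rho = 0 yields independent uniforms (used
    as an internal testing limit).
    """
    if family not in COPULA_FAMILIES:
        raise ValueError(f"unsupported copula family {family!r}")
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    if rho == 0.0:
        return rng.uniform(size=n), rng.uniform(size=n)

    param = kendall_tau_to_parameter(family, rho)
    if family == "gaussian":
        z0 = rng.standard_normal(n)
        z1 = param * z0 + np.sqrt(1.0 - param**2) * rng.standard_normal(n)
        return ndtr(z0), ndtr(z1)
    if family == "clayton":
        # Marshall–Olkin: V ~ Gamma(1/param), Y_i = (1 + E_i/V)^(-1/param).
        # Gamma(a) with a = 1/param << 1 puts non-trivial mass below realmin,
        # so V is sampled in log space via Gamma(a) =d Gamma(a+1)·U^(1/a).
        a = 1.0 / param
        logv = np.log(rng.gamma(a + 1.0, size=n)) + np.log(rng.uniform(size=n)) / a
        loge0 = np.log(rng.standard_exponential(n))
        loge1 = np.log(rng.standard_exponential(n))
        y0 = np.exp(-np.logaddexp(0.0, loge0 - logv) / param)
        y1 = np.exp(-np.logaddexp(0.0, loge1 - logv) / param)
        return y0, y1
    # Gumbel via Marshall–Olkin with positive stable mixing, generator exp(-t^(1/param))
    alpha = 1.0 / param
    logv = _log_positive_stable(alpha, n, rng)
    loge0 = np.log(rng.standard_exponential(n))
    loge1 = np.log(rng.standard_exponential(n))
    y0 = np.exp(-np.exp(alpha * (loge0 - logv)))
    y1 = np.exp(-np.exp(alpha * (loge1 - logv)))
    return y0, y1


# ---------------------------------------------------------------------------
# treated marginal
# ---------------------------------------------------------------------------


def treated_cumulative_hazard(t, model: HazardRatioModel):
    """Λ₁(t) = ∫₀ᵗ exp{β_X(v;θ)} dv against the unit-exponential baseline."""
    t = np.asarray(t, dtype=float)
    th = np.asarray(model.theta)
    if model.kind == "constant":
        return np.exp(th[0]) * t
    if model.kind == "loglinear":
        if th[1] == 0.0:
            return np.exp(th[0]) * t
        return np.exp(th[0]) * np.expm1(th[1] * t) / th[1]
    rates = np.exp(th)
    cp = np.asarray(model.cutpoints)  # last entry is +inf
    cum = np.concatenate([[0.0], np.cumsum(rates[:-1] * np.diff(cp[:-1]))])
    idx = model.window_index(t)
    return cum[idx] + rates[idx] * (t - cp[idx])


def inverse_treated_cdf(u, model: HazardRatioModel, defective: str = "raise"):
    """F₁⁻¹(u): the t with Λ₁(t) = −log(1−u), in closed form per model kind.

    A loglinear model with negative slope has finite total hazard, so the
    distribution is defective: quantiles beyond its total mass do not exist.
    With ``defective="raise"`` (default) such a request raises
    :class:`DefectiveDistributionError`; with ``defective="inf"`` it returns
    +inf — the subject never fails — which is how the data generator realizes
    a defective treated law while keeping S₁(t) = exp(−Λ₁(t)) exact at every
    finite t.
    """
    if defective not in ("raise", "inf"):
        raise ValueError("defective must be 'raise' or 'inf'")
    u = np.asarray(u, dtype=float)
    if np.any((u <= 0.0) | (u >= 1.0)):
        raise ValueError("u must lie strictly inside (0, 1)")
    s = -np.log1p(-u)  # target cumulative hazard
    th = np.asarray(model.theta)

    if model.kind == "constant":
        out = s * np.exp(-th[0])
    elif model.kind == "loglinear":
        if th[1] == 0.0:
            out = s * np.exp(-th[0])
        else:
            arg = 1.0 + th[1] * s * np.exp(-th[0])
            if np.any(arg <= 0.0):
                if defective == "raise":
                    total = np.exp(th[0]) / (-th[1])
                    raise DefectiveDistributionError(
                        f"total hazard is finite ({total:.6g}); requested quantile "
                        "exceeds the distribution's mass"
                    )
                with np.errstate(invalid="ignore", divide="ignore"):
                    out = np.where(arg > 0.0, np.log(np.maximum(arg, 1e-300)) / th[1], np.inf)
            else:
                out = np.log(arg) / th[1]
    else:
        rates = np.exp(th)
        cp = np.asarray(model.cutpoints)  # last entry is +inf
        cum = np.concatenate([[0.0], np.cumsum(rates[:-1] * np.diff(cp[:-1]))])
        # window whose hazard budget s falls into; the last window is unbounded
        idx = np.minimum(np.searchsorted(cum, s, side="right") - 1, model.K - 1)
        out = cp[idx] + (s - cum[idx]) / rates[idx]
    return out if out.shape else float(out)


def is_defective(model: HazardRatioModel) -> bool:
    """True when the treated distribution has finite total hazard (loglinear
    with negative slope); a fraction exp(−Λ₁(∞)) of treated subjects then
    never fail."""
    return model.kind == "loglinear" and model.theta[1] < 0.0


# ---------------------------------------------------------------------------
# treatment assignment and censoring
# ---------------------------------------------------------------------------


def assign_treatment(u, w, alpha_ux: float, alpha_wx: float, seed=None) -> np.ndarray:
    """X_i ~ Bernoulli(logistic(α_UX·U_i + α_WX·W_i)), zero intercept."""
    u = np.asarray(u, dtype=float)
    w = np.asarray(w, dtype=float)
    if u.shape != w.shape:
        raise ValueError("U and W must have the same length")
    rng = np.random.default_rng(seed)
    p = expit(alpha_ux * u + alpha_wx * w)
    return (rng.uniform(size=u.shape) < p).astype(float)


def calibrate_censor_scale(event_times, target_rate: float) -> float:
    """Scale c of C ~ Uniform(0, c) whose expected censored fraction is target_rate.

    The expected censored fraction given the realized times is
    (1/n)·Σ min(T_i/c, 1); the unique root in c is found by bracketed
    bisection (Brent) to 1e-10.  target_rate = 0 returns +inf (no censoring).
    """
    times = np.asarray(event_times, dtype=float)
    if np.any(times <= 0.0):
        raise ValueError("event times must be positive")
    if not 0.0 <= target_rate < 1.0:
        raise CalibrationError("target censoring rate must lie in [0, 1)")
    if target_rate == 0.0:
        if np.any(np.isinf(times)):
            raise CalibrationError(
                "subjects with infinite event times require a positive censoring rate"
            )
        return np.inf

    # subjects that never fail (infinite time) are censored with certainty
    never_fail = float(np.mean(np.isinf(times)))
    if never_fail >= target_rate:
        raise CalibrationError(
            f"cannot attain censoring rate {target_rate}: {never_fail:.3f} of "
            "subjects never fail and are censored regardless of the scale"
        )

    def expected_censored(c: float) -> float:
        return float(np.mean(np.minimum(times / c, 1.0))) - target_rate

    finite = times[np.isfinite(times)]
    lo = float(finite.min()) * 1e-12
    hi = float(finite.max())
    while expected_censored(hi) > 0.0:
        hi *= 2.0
        if hi > 1e300:
            raise CalibrationError(f"cannot attain censoring rate {target_rate}")
    return float(brentq(expected_censored, lo, hi, xtol=1e-10, rtol=1e-12))


# ---------------------------------------------------------------------------
# full generator
# ---------------------------------------------------------------------------


def generate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run simulation steps 1–6 with one seeded generator per stream.

    Stream order is fixed (copula → instrument → treatment → censoring) so
    each step is individually reproducible from the config seed.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_copula, rng_w, rng_x, rng_c = [np.random.default_rng(s) for s in ss.spawn(4)]

    y0, y1 = sample_copula(config.copula_family, config.rho, config.n, rng_copula)
    # guard against floating-point saturation at the open interval's ends
    y0 = np.clip(y0, 1e-16, 1.0 - 1e-16)
    y1 = np.clip(y1, 1e-16, 1.0 - 1e-16)
    u = ndtri(y0)
    w = rng_w.standard_normal(config.n)
    x = assign_treatment(u, w, config.alpha_ux, config.alpha_wx, rng_x)
    t0 = -np.log(y0)
    # Y1 enters through the survival coordinate, mirroring T0 = -log(Y0):
    # S1(T1) = Y1, hence the quantile passed to the CDF inverse is 1 - Y1.
    # A defective treated law (negative loglinear slope) maps quantiles beyond
    # its total mass to subjects that never fail; censoring keeps them finite.
    t1 = inverse_treated_cdf(1.0 - y1, config.true_model, defective="inf")
    t_assigned = np.where(x == 1.0, t1, t0)

    scale = calibrate_censor_scale(t_assigned, config.censor_rate)
    if np.isinf(scale):
        c = np.full(config.n, np.inf)
    else:
        c = rng_c.uniform(0.0, scale, config.n)
    time = np.minimum(t_assigned, c)
    event = (t_assigned <= c).astype(float)

    sample = SurvivalSample(time=time, event=event, exposure=x, instrument=w)
    return SimulatedDataset(
        sample=sample, y0=y0, y1=y1, u=u, t0=t0, t1=t1,
        censor_times=c, censor_scale=scale, config=config,
    )
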