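"""Estimating equations for time-dependent hazard ratios, IV and partial likelihood.

The target is the marginal structural Cox model λ₁(t) = exp{β_X(t;θ)}·λ₀(t)
for potential outcomes, with β_X parameterized by a
:class:`~ivhr.hazard_models.HazardRatioModel`.  The instrumental-variable
estimator solves, for k = 1..K,

    0 = Σ_i ∫₀^τ φ_k(v) · [ W_i − W̄(v;θ) ] dN_i(v),

where W̄(v;θ) is the exp{β_X(v;θ)·X_j}-weighted mean of the instrument over
the risk set at v, φ_k = ∂β_X/∂θ_k, and τ is the largest observed time.
Replacing W by X gives the score equations of the partial likelihood for a
time-dependent coefficient, which serves as the (confounding-prone)
comparator.  The baseline cumulative hazard is profiled out by the Breslow
estimator dΛ̂₀(v) = ΣdN_i(v) / ΣR_i(v)exp{β_X(v;θ)X_i}.

Ties are handled in the Breslow convention throughout: events tied at a time
share one risk set, and subjects censored at an event time remain at risk
there.

The equations are solved by damped Newton iteration with a central
finite-difference Jacobian; non-convergence is reported as a flagged result,
not an exception, so simulation studies can tally failures.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import logging

import numpy as np

from .data_model import SurvivalSample
from .exceptions import CIFailureError, DegenerateDataError, NumericalError
from .hazard_models import HazardRatioModel

logger = logging.getLogger(__name__)

DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 100
_FD_STEP = 1e-5
_MAX_HALVINGS = 20


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WindowResult:
    """Per-window outcome of a piecewise fit."""

    index: int
    lower: float
    upper: float
    theta: float
    converged: bool
    residual_norm: float
    iterations: int
    n_events: int
    error: Optional[str] = None


@dataclass(frozen=True)
class EstimationResult:
    """Solved parameters plus convergence diagnostics and optional bootstrap CIs."""

    theta_hat: np.ndarray
    residual_norm: float
    converged: bool
    iterations: int
    method: str
    model: HazardRatioModel
    ci_lower: Optional[np.ndarray] = None
    ci_upper: Optional[np.ndarray] = None
    ci_level: Optional[float] = None
    n_boot_used: Optional[int] = None
    n_boot_failed: Optional[int] = None
    window_results: Optional[tuple] = None

    @property
    def hazard_ratio(self) -> np.ndarray:
        """exp(θ̂) — the HR scale of each parameter (for the loglinear slope this
        is the multiplicative change in the HR per unit time)."""
        return np.exp(self.theta_hat)

    def to_dict(self) -> dict:
        out = {
            "method": self.method,
            "model": self.model.kind,
            "theta_hat": list(np.asarray(self.theta_hat, float)),
            "hazard_ratio": list(np.exp(np.asarray(self.theta_hat, float))),
            "converged": bool(self.converged),
            "iterations": int(self.iterations),
            "residual_norm": float(self.residual_norm),
        }
        if self.model.kind == "piecewise":
            out["cutpoints"] = list(self.model.cutpoints)
        if self.ci_lower is not None:
            out["ci_level"] = self.ci_level
            out["ci_lower"] = list(np.asarray(self.ci_lower, float))
            out["ci_upper"] = list(np.asarray(self.ci_upper, float))
            out["n_boot_used"] = self.n_boot_used
            out["n_boot_failed"] = self.n_boot_failed
        return out


@dataclass(frozen=True)
class BaselineHazard:
    """Breslow baseline cumulative-hazard increments at the distinct event times."""

    event_times: np.ndarray
    increments: np.ndarray

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.increments)

    def cumulative_at(self, t):
        """Λ̂₀(t) — right-continuous step function through the increments."""
        idx = np.searchsorted(self.event_times, np.asarray(t, float), side="right")
        cum = np.concatenate([[0.0], self.cumulative])
        return cum[idx]


# ---------------------------------------------------------------------------
# estimating-function workspace
# ---------------------------------------------------------------------------


class _Workspace:
    """Precomputed risk-set structure for fast repeated evaluation of G(θ).

    Sorting once by follow-up time makes every risk set a suffix of the sorted
    arrays.  For constant and piecewise models the subject weights
    exp{β_X(v)·X_j} are constant across the event times of a window, so the
    risk-set sums reduce to reverse cumulative sums (O(n) per evaluation).
    For the loglinear model the weights vary with v and a chunked event-time ×
    subject matrix is used instead.
    """

    _CHUNK = 256

    def __init__(self, sample: SurvivalSample, model: HazardRatioModel, z: np.ndarray):
        sample.require_events()
        self.model = model
        order = np.argsort(sample.time, kind="stable")
        self.t_sorted = sample.time[order]
        self.x_sorted = sample.exposure[order]
        self.z_sorted = z[order]
        self.n = sample.n

        is_event = sample.event[order] == 1
        ev_times = self.t_sorted[is_event]
        ev_z = self.z_sorted[is_event]
        self.event_times, inverse, self.d = np.unique(
            ev_times, return_inverse=True, return_counts=True
        )
        self.m = self.event_times.shape[0]
        self.z_event_sum = np.bincount(inverse, weights=ev_z, minlength=self.m)
        # first index of the suffix at risk at each event time
        self.risk_start = np.searchsorted(self.t_sorted, self.event_times, side="left")
        self.phi = model.gradient(self.event_times)  # (m, K)

        if model.kind == "piecewise":
            self.group_of_event = model.window_index(self.event_times)
            self.n_groups = model.K
        elif model.kind == "constant":
            self.group_of_event = np.zeros(self.m, dtype=int)
            self.n_groups = 1
        else:
            self.group_of_event = None
            self.n_groups = None

    def risk_weighted_mean(self, beta_v: np.ndarray) -> np.ndarray:
        """Z̄(v;θ): exp{β_X(v)X_j}-weighted mean of z over the risk set at each v."""
        if self.group_of_event is not None:
            return self._suffix_path(beta_v)
        return self._matrix_path(beta_v)

    def _suffix_path(self, beta_v: np.ndarray) -> np.ndarray:
        zbar = np.empty(self.m)
        for g in range(self.n_groups):
            idx = np.flatnonzero(self.group_of_event == g)
            if idx.size == 0:
                continue
            b = beta_v[idx[0]]
            a = b * self.x_sorted
            e = np.exp(a - a.max())
            den = np.cumsum(e[::-1])[::-1]
            num = np.cumsum((e * self.z_sorted)[::-1])[::-1]
            starts = self.risk_start[idx]
            if np.any(den[starts] <= 0.0):
                t_bad = self.event_times[idx[np.argmax(den[starts] <= 0.0)]]
                raise NumericalError(f"risk-set weight sum underflowed at event time {t_bad}")
            zbar[idx] = num[starts] / den[starts]
        return zbar

    def _matrix_path(self, beta_v: np.ndarray) -> np.ndarray:
        zbar = np.empty(self.m)
        col = np.arange(self.n)
        for lo in range(0, self.m, self._CHUNK):
            hi = min(lo + self._CHUNK, self.m)
            a = beta_v[lo:hi, None] * self.x_sorted[None, :]
            mask = col[None, :] >= self.risk_start[lo:hi, None]
            a = np.where(mask, a, -np.inf)
            amax = a.max(axis=1, keepdims=True)
            e = np.exp(a - amax)
            e[~mask] = 0.0
            den = e.sum(axis=1)
            if np.any(den <= 0.0):
                t_bad = self.event_times[lo + int(np.argmax(den <= 0.0))]
                raise NumericalError(f"risk-set weight sum underflowed at event time {t_bad}")
            zbar[lo:hi] = (e @ self.z_sorted) / den
        return zbar

    def estimating_function(self, theta) -> np.ndarray:
        model = self.model.with_theta(theta)
        beta_v = np.atleast_1d(model.log_hazard_ratio(self.event_times))
        resid = self.z_event_sum - self.d * self.risk_weighted_mean(beta_v)
        return self.phi.T @ resid


def iv_estimating_function(
    theta, sample: SurvivalSample, model: HazardRatioModel
) -> np.ndarray:
    """Evaluate the K IV estimating equations G(θ) on a sample.

    G_k(θ) = Σ over event times v of φ_k(v) · Σ_{events i at v} [W_i − W̄(v;θ)].
    """
    return _Workspace(sample, model, sample.instrument).estimating_function(theta)


def pl_estimating_function(
    theta, sample: SurvivalSample, model: HazardRatioModel
) -> np.ndarray:
    """Partial-likelihood score for a time-dependent coefficient: G with W ≡ X."""
    return _Workspace(sample, model, sample.exposure).estimating_function(theta)


# ---------------------------------------------------------------------------
# Breslow baseline
# ---------------------------------------------------------------------------


def breslow_baseline(theta, sample: SurvivalSample, model: HazardRatioModel) -> BaselineHazard:
    """Breslow increments dΛ̂₀(v) = ΣdN_i(v) / ΣR_i(v)·exp{β_X(v;θ)·X_i}.

    At θ = 0 (or X ≡ 0) the increments reduce to the Nelson–Aalen estimator
    dN(v)/R(v).
    """
    ws = _Workspace(sample, model, sample.instrument)
    model = model.with_theta(theta)
    beta_v = np.atleast_1d(model.log_hazard_ratio(ws.event_times))
    increments = np.empty(ws.m)
    for k in range(ws.m):
        a = beta_v[k] * ws.x_sorted[ws.risk_start[k]:]
        m = a.max()  # max-subtraction: at θ=0 this reduces exactly to d/R
        increments[k] = ws.d[k] * np.exp(-m) / np.exp(a - m).sum()
    return BaselineHazard(event_times=ws.event_times, increments=increments)


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------


def _newton(func, x0, tol, max_iter):
    """Damped Newton with central finite-difference Jacobian.

    Halves the step up to _MAX_HALVINGS times whenever ‖G‖∞ fails to decrease;
    a singular Jacobian or a stalled line search yields converged=False.
    """
    x = np.array(x0, dtype=float)
    k = x.size
    g = func(x)
    gnorm = np.max(np.abs(g))
    iterations = 0
    for iterations in range(1, max_iter + 1):
        logger.debug("newton iter %d: |G|_inf = %.6g", iterations - 1, gnorm)
        if gnorm <= tol:
            return x, g, iterations - 1, True
        jac = np.empty((k, k))
        for j in range(k):
            h = _FD_STEP * max(1.0, abs(x[j]))
            e = np.zeros(k)
            e[j] = h
            jac[:, j] = (func(x + e) - func(x - e)) / (2.0 * h)
        try:
            delta = np.linalg.solve(jac, -g)
        except np.linalg.LinAlgError:
            return x, g, iterations, False
        if not np.all(np.isfinite(delta)):
            return x, g, iterations, False
        step = 1.0
        for _ in range(_MAX_HALVINGS + 1):
            x_new = x + step * delta
            g_new = func(x_new)
            gnorm_new = np.max(np.abs(g_new))
            if np.isfinite(gnorm_new) and gnorm_new < gnorm:
                break
            step *= 0.5
        else:
            return x, g, iterations, False
        x, g, gnorm = x_new, g_new, gnorm_new
    return x, g, max_iter, bool(gnorm <= tol)


def _check_nonconstant(arr: np.ndarray, label: str) -> None:
    if np.all(arr == arr[0]):
        raise DegenerateDataError(
            f"{label} is constant; the estimating equations are degenerate"
        )


def _solve(
    sample: SurvivalSample,
    model: HazardRatioModel,
    z: np.ndarray,
    method: str,
    init=None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> EstimationResult:
    sample.require_events()
    _check_nonconstant(sample.exposure, "exposure")
    if method == "iv":
        _check_nonconstant(z, "instrument")

    if init is None:
        init = np.zeros(model.K)
    init = np.atleast_1d(np.asarray(init, dtype=float))

    # For the loglinear model the slope equation carries weights φ₂(v)=v, so the
    # Newton system conditions poorly when times are large; solve on times
    # rescaled by their maximum and unscale the slope afterwards.  The scaled
    # tolerance is tightened so the reported (unscaled) residual still meets tol.
    scale = 1.0
    work_sample = sample
    work_init = init
    work_tol = tol
    if model.kind == "loglinear":
        scale = float(sample.time.max())
        if scale <= 0.0:
            scale = 1.0
        work_sample = SurvivalSample(
            time=sample.time / scale,
            event=sample.event,
            exposure=sample.exposure,
            instrument=sample.instrument,
        )
        work_init = np.array([init[0], init[1] * scale])
        work_tol = tol / max(1.0, scale)

    ws = _Workspace(work_sample, model, z)
    theta, _, iterations, converged = _newton(ws.estimating_function, work_init, work_tol, max_iter)
    if model.kind == "loglinear":
        theta = np.array([theta[0], theta[1] / scale])

    residual = _Workspace(sample, model, z).estimating_function(theta)
    residual_norm = float(np.max(np.abs(residual)))
    if converged and residual_norm > tol:
        converged = False
    logger.debug(
        "%s %s solve: converged=%s after %d iteration(s), |G|_inf = %.3g",
        method, model.kind, converged, iterations, residual_norm,
    )
    return EstimationResult(
        theta_hat=theta,
        residual_norm=residual_norm,
        converged=converged,
        iterations=iterations,
        method=method,
        model=model.with_theta(theta),
    )


def solve_iv(
    sample: SurvivalSample,
    model: HazardRatioModel,
    init=None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> EstimationResult:
    """Solve the IV estimating equations G(θ̂) = 0.

    Returns a result with ``converged=False`` (never raises) when Newton
    iteration stalls; raises :class:`DegenerateDataError` when the sample has
    no events or a constant exposure or instrument.
    """
    return _solve(sample, model, sample.instrument, "iv", init, tol, max_iter)


def solve_partial_likelihood(
    sample: SurvivalSample,
    model: HazardRatioModel,
    init=None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> EstimationResult:
    """Maximum partial likelihood for a time-dependent coefficient (W ≡ X)."""
    return _solve(sample, model, sample.exposure, "partial_likelihood", init, tol, max_iter)


_SOLVERS = {"iv": solve_iv, "partial_likelihood": solve_partial_likelihood, "pl": solve_partial_likelihood}


def solve(sample, model, method: str = "iv", **kwargs) -> EstimationResult:
    """Dispatch to :func:`solve_iv` or :func:`solve_partial_likelihood` by name."""
    try:
        solver = _SOLVERS[method]
    except KeyError:
        raise ValueError(f"unknown method {method!r}; expected 'iv' or 'partial_likelihood'") from None
    return solver(sample, model, **kwargs)


# ---------------------------------------------------------------------------
# piecewise fitting via window truncation
# ---------------------------------------------------------------------------


def _window_subsample(sample: SurvivalSample, lower: float, upper: float) -> SurvivalSample:
    """Truncation rule for the window [lower, upper): drop subjects who left
    risk before ``lower``; censor events at or after ``upper`` at ``upper``."""
    keep = sample.time >= lower
    time = sample.time[keep]
    event = sample.event[keep]
    if np.isfinite(upper):
        event = np.where(time < upper, event, 0.0)
        time = np.minimum(time, upper)
    return SurvivalSample(
        time=time,
        event=event,
        exposure=sample.exposure[keep],
        instrument=sample.instrument[keep],
    )


def fit_piecewise(
    sample: SurvivalSample,
    cutpoints,
    method: str = "iv",
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> EstimationResult:
    """One constant log hazard ratio per window [τ_{k-1}, τ_k).

    Equivalent to the joint K-dimensional solve with indicator weights — the
    system decouples across windows — but fitted window by window on the
    truncated sub-samples, which is how the piecewise estimator is used in
    practice.  Windows without events (or with an otherwise degenerate
    sub-sample) are reported per-window with ``theta = nan`` while the other
    windows are still returned.
    """
    model = HazardRatioModel.piecewise(cutpoints)
    if method not in _SOLVERS:
        raise ValueError(f"unknown method {method!r}")
    solver = _SOLVERS[method]

    windows = []
    thetas = np.full(model.K, np.nan)
    any_error = False
    for k, (lo, hi) in enumerate(model.windows):
        sub = _window_subsample(sample, lo, hi)
        n_events = sub.n_events
        if n_events == 0:
            windows.append(
                WindowResult(k, lo, hi, np.nan, False, np.nan, 0, 0,
                             error=f"window {k} [{lo}, {hi}) contains no events")
            )
            any_error = True
            continue
        try:
            res = solver(sub, HazardRatioModel.constant(0.0), tol=tol, max_iter=max_iter)
        except DegenerateDataError as exc:
            windows.append(
                WindowResult(k, lo, hi, np.nan, False, np.nan, 0, n_events,
                             error=f"window {k} [{lo}, {hi}): {exc}")
            )
            any_error = True
            continue
        thetas[k] = res.theta_hat[0]
        windows.append(
            WindowResult(k, lo, hi, float(res.theta_hat[0]), res.converged,
                         res.residual_norm, res.iterations, n_events)
        )

    ok = [w for w in windows if w.error is None]
    converged = bool(ok) and not any_error and all(w.converged for w in ok)
    residual_norm = max((w.residual_norm for w in ok), default=np.nan)
    iterations = max((w.iterations for w in ok), default=0)
    return EstimationResult(
        theta_hat=thetas,
        residual_norm=residual_norm,
        converged=converged,
        iterations=iterations,
        method=method if method != "pl" else "partial_likelihood",
        model=model.with_theta(thetas),
        window_results=tuple(windows),
    )


# ---------------------------------------------------------------------------
# bootstrap confidence intervals
# ---------------------------------------------------------------------------


def bootstrap_ci(
    sample: SurvivalSample,
    model: HazardRatioModel,
    method: str = "iv",
    B: int = 500,
    level: float = 0.95,
    seed=None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> EstimationResult:
    """Nonparametric subject-level percentile bootstrap.

    Resamples n subjects with replacement B times, refits, and takes the
    percentile interval at (1−level)/2 and 1−(1−level)/2 per parameter.
    Replicates that fail to converge (or are degenerate after resampling) are
    dropped and counted; more than 50% failures raises :class:`CIFailureError`.
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    solver = _SOLVERS[method]
    point = solver(sample, model, tol=tol, max_iter=max_iter)

    rng = np.random.default_rng(seed)
    estimates = []
    n_failed = 0
    for _ in range(B):
        idx = rng.integers(0, sample.n, sample.n)
        boot = SurvivalSample(
            time=sample.time[idx],
            event=sample.event[idx],
            exposure=sample.exposure[idx],
            instrument=sample.instrument[idx],
        )
        try:
            res = solver(boot, model, tol=tol, max_iter=max_iter)
        except DegenerateDataError:
            n_failed += 1
            continue
        if res.converged:
            estimates.append(res.theta_hat)
        else:
            n_failed += 1
    if n_failed > B / 2:
        raise CIFailureError(
            f"{n_failed} of {B} bootstrap replicates failed to converge"
        )
    est = np.asarray(estimates)
    alpha = (1.0 - level) / 2.0
    lower = np.percentile(est, 100.0 * alpha, axis=0)
    upper = np.percentile(est, 100.0 * (1.0 - alpha), axis=0)
    return replace(
        point,
        ci_lower=lower,
        ci_upper=upper,
        ci_level=level,
        n_boot_used=len(estimates),
        n_boot_failed=n_failed,
    )
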