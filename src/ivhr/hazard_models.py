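"""Parameterizations of the time-dependent log hazard ratio β_X(t; θ).

Three families are supported:

``constant``
    β_X(t) = θ₁ — the proportional-hazards case, K = 1.
``loglinear``
    β_X(t) = θ₀ + θ₁·t — hazard ratio exp(θ₀) at inception, multiplied by
    exp(θ₁) per unit time, K = 2 with (intercept, slope) ordering.
``piecewise``
    β_X(t) = θ_k on the window [τ_{k-1}, τ_k), with 0 = τ₀ < τ₁ < … ;
    the final window extends to +∞ so the model is total on t >= 0.

The θ-gradient of β_X doubles as the weight functions φ_k(t) = ∂β_X/∂θ_k of
the estimating equations, so both the value and the gradient are first-class
operations here.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

VALID_KINDS = ("constant", "loglinear", "piecewise")


@dataclass(frozen=True)
class HazardRatioModel:
    """A parameterization of the log hazard ratio with value and θ-gradient.

    Use the constructors :meth:`constant`, :meth:`loglinear` and
    :meth:`piecewise` rather than the raw dataclass.
    """

    kind: str
    theta: tuple
    cutpoints: tuple | None = None

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}; expected one of {VALID_KINDS}")
        object.__setattr__(self, "theta", tuple(float(v) for v in self.theta))
        if self.kind == "constant" and len(self.theta) != 1:
            raise ValueError("constant model has exactly one parameter")
        if self.kind == "loglinear" and len(self.theta) != 2:
            raise ValueError("loglinear model has exactly two parameters (intercept, slope)")
        if self.kind == "piecewise":
            if self.cutpoints is None:
                raise ValueError("piecewise model requires cutpoints")
            cp = tuple(float(v) for v in self.cutpoints)
            if len(cp) < 2 or cp[0] != 0.0 or not np.isinf(cp[-1]):
                raise ValueError(
                    "canonical piecewise cutpoints run 0 = τ₀ < τ₁ < … < τ_K = +inf; "
                    "use HazardRatioModel.piecewise() to normalize other spellings"
                )
            if any(b <= a for a, b in zip(cp, cp[1:])):
                raise ValueError("piecewise cutpoints must be strictly increasing")
            object.__setattr__(self, "cutpoints", cp)
            if len(self.theta) != len(cp) - 1:
                raise ValueError(
                    f"piecewise model with {len(cp) - 1} window(s) needs "
                    f"{len(cp) - 1} parameter(s), got {len(self.theta)}"
                )
        elif self.cutpoints is not None:
            raise ValueError(f"cutpoints are only meaningful for piecewise models, not {self.kind}")

    # -- constructors -------------------------------------------------------

    @classmethod
    def constant(cls, theta: float = 0.0) -> "HazardRatioModel":
        return cls("constant", (theta,))

    @classmethod
    def loglinear(cls, intercept: float = 0.0, slope: float = 0.0) -> "HazardRatioModel":
        return cls("loglinear", (intercept, slope))

    @classmethod
    def piecewise(cls, cutpoints, theta=None) -> "HazardRatioModel":
        """Piecewise-constant model on windows [τ_{k-1}, τ_k), last window open-ended.

        ``cutpoints`` may omit the leading 0 and the trailing +inf; interior
        cut times alone (e.g. ``(30, 180)`` for three windows) are enough.
        A finite last cutpoint is kept as an upper bound only when ``theta``
        has one parameter fewer than there are cutpoint gaps; the final window
        always extends to +∞ regardless.
        """
        cp = [float(v) for v in cutpoints]
        if not cp or cp[0] != 0.0:
            cp = [0.0] + cp
        if not np.isinf(cp[-1]):
            if theta is not None and len(theta) == len(cp) - 1:
                cp[-1] = np.inf  # last value was the (now open-ended) upper bound
            else:
                cp.append(np.inf)
        if theta is None:
            theta = (0.0,) * (len(cp) - 1)
        return cls("piecewise", tuple(theta), tuple(cp))

    # -- basic properties ---------------------------------------------------

    @property
    def K(self) -> int:
        """Parameter dimension (number of weight functions φ_k)."""
        return len(self.theta)

    @property
    def windows(self) -> list:
        """Piecewise windows as (lower, upper) pairs; the last upper is +inf."""
        if self.kind != "piecewise":
            raise ValueError("windows are defined only for piecewise models")
        return list(zip(self.cutpoints[:-1], self.cutpoints[1:]))

    def with_theta(self, theta) -> "HazardRatioModel":
        """Same parameterization, new parameter vector."""
        theta = tuple(float(v) for v in np.atleast_1d(theta))
        if len(theta) != self.K:
            raise ValueError(f"expected {self.K} parameter(s), got {len(theta)}")
        return replace(self, theta=theta)

    # -- evaluation ---------------------------------------------------------

    def window_index(self, t):
        """Index k of the window [τ_{k-1}, τ_k) containing each t (piecewise only)."""
        breaks = np.asarray(self.cutpoints[1:-1])
        return np.searchsorted(breaks, np.asarray(t, dtype=float), side="right")

    def log_hazard_ratio(self, t):
        """β_X(t; θ), vectorized over t >= 0."""
        t = np.asarray(t, dtype=float)
        th = np.asarray(self.theta)
        if self.kind == "constant":
            out = np.broadcast_to(th[0], t.shape).copy()
        elif self.kind == "loglinear":
            out = th[0] + th[1] * t
        else:
            out = th[self.window_index(t)]
        return out if out.shape else float(out)

    def gradient(self, t):
        """φ(t) = ∂β_X(t; θ)/∂θ, shape (..., K); φ does not depend on θ itself."""
        t = np.asarray(t, dtype=float)
        shape = t.shape + (self.K,)
        if self.kind == "constant":
            return np.ones(shape)
        if self.kind == "loglinear":
            g = np.empty(shape)
            g[..., 0] = 1.0
            g[..., 1] = t
            return g
        g = np.zeros(shape)
        idx = self.window_index(t)
        if t.shape:
            g[np.arange(t.size).reshape(t.shape), idx] = 1.0
        else:
            g[int(idx)] = 1.0
        return g


def evaluate_log_hr(model: HazardRatioModel, t):
    """Functional alias for :meth:`HazardRatioModel.log_hazard_ratio`."""
    return model.log_hazard_ratio(t)


def gradient_log_hr(model: HazardRatioModel, t):
    """Functional alias for :meth:`HazardRatioModel.gradient`."""
    return model.gradient(t)
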