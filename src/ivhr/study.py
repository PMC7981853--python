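"""Monte Carlo bias study: IV estimating equations vs partial likelihood.

Each replicate draws a parameter configuration, generates one confounded
dataset, fits the requested estimators, and records the per-parameter bias
θ̂ − θ_true.  Medians are then aggregated within strata defined by the
confounding direction (positive when α_UX > log 5, negative when
α_UX < −log 5, none otherwise) and the instrument strength (strong when
exp(α_WX) > 5).

Two true-model scenarios are supported:

``stepwise``
    A three-piece constant log hazard ratio with period boundaries at the
    times where untreated (unit-exponential) survival crosses 90% and 75%,
    i.e. −log(0.90) and −log(0.75): "early", "mid" and "late" follow-up.
``loglinear``
    β_X(t) = θ₀ + θ₁·t with intercept and slope drawn from regular grids.

Replicates are independent, with per-replicate seeds spawned from the master
seed, so results do not depend on execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimators import fit_piecewise, solve
from .hazard_models import HazardRatioModel
from .simulator import SimulationConfig, generate_dataset

# Period boundaries where the untreated survival curve crosses 90% and 75%.
EARLY_MID_CUT = -np.log(0.90)
MID_LATE_CUT = -np.log(0.75)
STEPWISE_CUTPOINTS = (0.0, EARLY_MID_CUT, MID_LATE_CUT)

CONFOUNDING_THRESHOLD = np.log(5.0)  # |alpha_UX| above this is directional confounding
STRONG_INSTRUMENT_OR = 5.0  # exp(alpha_WX) above this is a strong instrument


def _grid(lo: float, hi: float, num: int) -> tuple:
    return tuple(np.linspace(lo, hi, num))


@dataclass(frozen=True)
class StudyGrid:
    """Per-dataset parameter draws; the defaults are the study's design grids.

    ``alpha_ux_range`` / ``alpha_wx_range`` are uniform-draw intervals; set both
    endpoints equal to pin a value (e.g. a fixed strong instrument).
    """

    alpha_ux_range: tuple = (-np.log(10.0), np.log(10.0))
    alpha_wx_range: tuple = (np.log(2.0), np.log(50.0))
    copula_families: tuple = ("gaussian", "clayton", "gumbel")
    rhos: tuple = (0.5, 0.99)
    # 25-point grid from -ln 3 to ln 3 in steps of log(6)/24 for each period
    stepwise_values: tuple = field(default_factory=lambda: _grid(-np.log(3.0), np.log(3.0), 25))
    loglinear_intercepts: tuple = field(default_factory=lambda: _grid(-1.0, 1.0, 11))
    loglinear_slopes: tuple = field(default_factory=lambda: _grid(-0.5, 0.5, 11))
    n: int = 1000
    censor_rate: float = 0.5

    def draw(self, scenario: str, rng: np.random.Generator) -> dict:
        """Draw one replicate's parameter configuration."""
        params = {
            "alpha_ux": float(rng.uniform(*self.alpha_ux_range)),
            "alpha_wx": float(rng.uniform(*self.alpha_wx_range)),
            "copula_family": str(rng.choice(self.copula_families)),
            "rho": float(rng.choice(self.rhos)),
        }
        if scenario == "stepwise":
            theta = rng.choice(self.stepwise_values, size=3, replace=True)
            params["true_model"] = HazardRatioModel.piecewise(STEPWISE_CUTPOINTS, theta)
        elif scenario == "loglinear":
            intercept = float(rng.choice(self.loglinear_intercepts))
            # negative slopes make the treated law defective; the generator
            # realizes the never-failing mass as always-censored subjects
            slope = float(rng.choice(self.loglinear_slopes))
            params["true_model"] = HazardRatioModel.loglinear(intercept, slope)
        else:
            raise ValueError(f"unknown scenario {scenario!r}")
        return params


def _true_values(scenario: str, model: HazardRatioModel) -> dict:
    if scenario == "stepwise":
        return {f"period_{k + 1}": model.theta[k] for k in range(model.K)}
    return {"intercept": model.theta[0], "slope": model.theta[1]}


def _fit(scenario: str, method: str, sample) -> np.ndarray | None:
    """Fit one estimator; returns the parameter vector or None on failure."""
    if scenario == "stepwise":
        res = fit_piecewise(sample, STEPWISE_CUTPOINTS, method=method)
    else:
        res = solve(sample, HazardRatioModel.loglinear(), method=method)
    return res.theta_hat if res.converged else None


def run_study(
    grid: StudyGrid,
    scenario: str = "stepwise",
    methods: tuple = ("iv", "partial_likelihood"),
    reps: int = 200,
    seed: int = 0,
) -> "StudyResult":
    """Generate ``reps`` datasets, fit each estimator, and record biases."""
    if reps < 1:
        raise ValueError("reps must be at least 1")
    records = []
    children = np.random.SeedSequence(seed).spawn(reps)
    for rep, child in enumerate(children):
        rng = np.random.default_rng(child)
        params = grid.draw(scenario, rng)
        data_seed = int(child.generate_state(1, np.uint32)[0] % (2**31))
        config = SimulationConfig(
            true_model=params["true_model"],
            alpha_ux=params["alpha_ux"],
            alpha_wx=params["alpha_wx"],
            copula_family=params["copula_family"],
            rho=params["rho"],
            n=grid.n,
            censor_rate=grid.censor_rate,
            seed=data_seed,
        )
        dataset = generate_dataset(config)
        truths = _true_values(scenario, params["true_model"])
        for method in methods:
            theta = _fit(scenario, method, dataset.sample)
            for k, (pname, true_val) in enumerate(truths.items()):
                est = np.nan if theta is None else float(theta[k])
                records.append(
                    {
                        "rep": rep,
                        "scenario": scenario,
                        "estimator": "partial_likelihood" if method == "pl" else method,
                        "parameter": pname,
                        "true_value": true_val,
                        "estimate": est,
                        "bias": est - true_val,
                        "converged": theta is not None and np.isfinite(est),
                        "alpha_ux": params["alpha_ux"],
                        "alpha_wx": params["alpha_wx"],
                        "copula_family": params["copula_family"],
                        "rho": params["rho"],
                    }
                )
    records = pd.DataFrame.from_records(records)
    return StudyResult(records=records, table=summarize(records))


def classify_confounding(alpha_ux) -> np.ndarray:
    """positive / negative / none by α_UX against ±log 5."""
    alpha_ux = np.asarray(alpha_ux, dtype=float)
    out = np.where(
        alpha_ux > CONFOUNDING_THRESHOLD,
        "positive",
        np.where(alpha_ux < -CONFOUNDING_THRESHOLD, "negative", "none"),
    )
    return out


def classify_instrument(alpha_wx) -> np.ndarray:
    """strong / weak by the treatment-instrument odds ratio against 5."""
    alpha_wx = np.asarray(alpha_wx, dtype=float)
    return np.where(np.exp(alpha_wx) > STRONG_INSTRUMENT_OR, "strong", "weak")


def summarize(records: pd.DataFrame) -> pd.DataFrame:
    """Median estimate and bias per (stratum, estimator, parameter) cell.

    Non-convergent replicates are excluded from the medians but counted in
    ``n_failed``; a cell where every replicate failed has NaN medians.
    """
    df = records.copy()
    df["confounding"] = classify_confounding(df["alpha_ux"])
    df["instrument"] = classify_instrument(df["alpha_wx"])
    keys = ["scenario", "confounding", "instrument", "estimator", "parameter"]

    def _agg(group: pd.DataFrame) -> pd.Series:
        ok = group[group["converged"]]
        return pd.Series(
            {
                "median_estimate": ok["estimate"].median(),
                "median_bias": ok["bias"].median(),
                "median_true_value": group["true_value"].median(),
                "n_used": int(len(ok)),
                "n_failed": int((~group["converged"]).sum()),
            }
        )

    table = df.groupby(keys, sort=True).apply(_agg, include_groups=False).reset_index()
    return table


@dataclass(frozen=True)
class StudyResult:
    """Raw replicate records plus the stratified median-bias table."""

    records: pd.DataFrame
    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def plot_bias(records: pd.DataFrame, path=None):
    """Median bias vs true value, one panel per parameter, colored by estimator."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    params = sorted(records["parameter"].unique())
    fig, axes = plt.subplots(1, len(params), figsize=(4 * len(params), 3.5), squeeze=False)
    colors = {"iv": "black", "partial_likelihood": "red"}
    for ax, pname in zip(axes[0], params):
        sub = records[(records["parameter"] == pname) & records["converged"]]
        for est, grp in sub.groupby("estimator"):
            med = grp.groupby("true_value")["bias"].median()
            ax.plot(med.index, med.values, "o", ms=4, color=colors.get(est), label=est)
        ax.axhline(0.0, lw=0.5, color="grey")
        ax.set_title(pname)
        ax.set_xlabel("true value")
        ax.set_ylabel("median bias")
        ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
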