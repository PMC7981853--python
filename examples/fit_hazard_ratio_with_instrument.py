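"""Fit a time-dependent hazard ratio with and without the instrument.

Generates confounded datasets (treatment selection depends on an unmeasured
frailty) and estimates the log-linear log hazard ratio β_X(t) = θ₀ + θ₁·t two
ways: the IV estimating equations, which use the instrument W, and the
ordinary partial likelihood, which uses the exposure alone and inherits the
confounding.  A single dataset's IV estimate is noisy, so the bias pattern is
shown as the median over a small batch of replicates.
"""

import numpy as np

from ivhr import (
    HazardRatioModel,
    SimulationConfig,
    generate_dataset,
    solve_iv,
    solve_partial_likelihood,
)

true_model = HazardRatioModel.loglinear(intercept=0.4, slope=0.2)
reps = 50

iv_estimates, pl_estimates = [], []
for seed in range(reps):
    sample = generate_dataset(SimulationConfig(
        true_model=true_model,
        alpha_ux=np.log(10.0),   # strong unmeasured confounding
        alpha_wx=np.log(10.0),   # strong instrument
        n=1000,
        censor_rate=0.5,
        seed=seed,
    )).sample
    iv = solve_iv(sample, HazardRatioModel.loglinear())
    pl = solve_partial_likelihood(sample, HazardRatioModel.loglinear())
    if iv.converged:
        iv_estimates.append(iv.theta_hat)
    if pl.converged:
        pl_estimates.append(pl.theta_hat)

iv_med = np.median(iv_estimates, axis=0)
pl_med = np.median(pl_estimates, axis=0)
print(f"true (intercept, slope):                     ({true_model.theta[0]:.3f}, {true_model.theta[1]:.3f})")
print(f"IV estimating equations, median of {len(iv_estimates)}:      ({iv_med[0]:.3f}, {iv_med[1]:.3f})")
print(f"partial likelihood, median of {len(pl_estimates)}:           ({pl_med[0]:.3f}, {pl_med[1]:.3f})")
print()
print("The partial-likelihood fit is pulled far from the truth by the omitted")
print("frailty. The IV fit is not exactly unbiased under confounding this")
print("strong, but its bias is several times smaller on both parameters")
print("because the instrument is independent of the frailty.")
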