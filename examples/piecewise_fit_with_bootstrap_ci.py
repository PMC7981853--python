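"""Piecewise hazard-ratio estimation with bootstrap confidence intervals.

Fits one constant log hazard ratio per follow-up window via the truncation
rule (drop subjects who left risk before the window, censor events after it)
and attaches subject-level percentile bootstrap intervals.
"""

import numpy as np

from ivhr import (
    HazardRatioModel,
    SimulationConfig,
    bootstrap_ci,
    fit_piecewise,
    generate_dataset,
)

cuts = (0.1, 0.3)  # three windows: [0, 0.1), [0.1, 0.3), [0.3, inf)
true_model = HazardRatioModel.piecewise(cuts, (np.log(2.0), 0.0, -np.log(2.0)))
sample = generate_dataset(SimulationConfig(
    true_model=true_model, alpha_ux=np.log(10.0), alpha_wx=np.log(10.0),
    n=2000, censor_rate=0.4, seed=99,
)).sample

fit = fit_piecewise(sample, cuts, method="iv")
print("per-window IV fits (log HR):")
for w, true_theta in zip(fit.window_results, true_model.theta):
    print(f"  [{w.lower:.2f}, {w.upper:.2f}): theta = {w.theta:+.3f}"
          f"  (true {true_theta:+.3f}, {w.n_events} events)")

ci = bootstrap_ci(sample, HazardRatioModel.piecewise(cuts), method="iv",
                  B=200, level=0.95, seed=1)
print("\n95% percentile bootstrap intervals (hazard-ratio scale):")
for k in range(3):
    print(f"  window {k}: HR {np.exp(ci.theta_hat[k]):.2f}"
          f"  ({np.exp(ci.ci_lower[k]):.2f} to {np.exp(ci.ci_upper[k]):.2f})")
print(f"  ({ci.n_boot_failed} of 200 bootstrap refits dropped for non-convergence)")
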