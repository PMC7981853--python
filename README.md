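# ivhr — instrumental-variable estimation of time-dependent hazard ratios

`ivhr` estimates how a treatment's hazard ratio changes over follow-up when
treatment selection may depend on *unmeasured* confounders, using an
instrumental variable (IV): a variable associated with the exposure,
independent of the confounders, and affecting the outcome only through the
exposure.  Typical instruments are clinician or center preference, geographic
access, or a randomization indicator.  The package is aimed at
biostatisticians and epidemiologists running comparative-effectiveness
analyses of right-censored time-to-event data.

## The model and the estimating equations

The target is the **marginal structural Cox model** for potential outcomes:

    λ₁(t) = exp{β_X(t; θ)} · λ₀(t),

where λ_x is the hazard the population would have if everyone received
exposure level x, and β_X(t; θ) is a parameterized log hazard ratio —
constant (θ), log-linear in time (θ₀ + θ₁·t), or piecewise constant on
follow-up windows.  The model is *marginal*: it never parameterizes how the
omitted covariate U affects the outcome.

With observed data {W_i, X_i, Δ_i, T_i} (instrument, exposure, event
indicator, follow-up time), counting processes N_i and at-risk indicators
R_i, the IV estimator solves, for k = 1..K,

    0 = Σᵢ ∫₀^τ φ_k(v) · [ W_i − W̄(v; θ) ] dN_i(v),

where W̄(v; θ) = Σⱼ W_j R_j(v) e^{β_X(v;θ)X_j} / Σⱼ R_j(v) e^{β_X(v;θ)X_j}
is the risk-set-weighted mean of the instrument, φ_k(t) = ∂β_X(t;θ)/∂θ_k,
and τ is the largest observed time.  The baseline hazard is profiled out by
the Breslow estimator dΛ̂₀(v) = ΣdN_i(v) / ΣR_i(v)e^{β_X(v;θ)X_i}.
Replacing W by X recovers the score equations of the ordinary partial
likelihood for a time-dependent coefficient, which `ivhr` also provides as
the (confounding-prone) comparator.

The package additionally ships the copula-based potential-outcomes simulator
used to probe the estimator's bias: (Y₀, Y₁) from a Gaussian, Clayton or
Gumbel copula at Kendall's τ = ρ give T(0) = −log Y₀ (unit exponential) and
T(1) = Λ₁⁻¹(−log Y₁), the omitted covariate U = Φ⁻¹(Y₀), logistic treatment
assignment Pr[X=1] = logistic(α_UX·U + α_WX·W), and uniform censoring
calibrated to a target rate — so the marginals obey the structural model
exactly while α_UX controls the confounding.

## Worked example

`examples/fit_hazard_ratio_with_instrument.py` simulates 50 confounded
datasets (n = 1000, 50% censoring, strong instrument and strong positive
confounding, both odds ratios 10) with true log-linear log hazard ratio
β_X(t) = 0.4 + 0.2·t, and fits each with and without the instrument:

```
true (intercept, slope):                     (0.400, 0.200)
IV estimating equations, median of 50:      (0.578, -0.339)
partial likelihood, median of 50:           (2.121, -1.401)
```

The partial likelihood, blind to the unmeasured frailty, overstates the
inception hazard ratio by a factor of exp(2.121 − 0.4) ≈ 5.6 and badly
distorts the time trend.  The IV estimating equations are not exactly
unbiased under confounding this strong, but their error is several times
smaller on both parameters.  The other examples cover the simulator's latent
structure, piecewise fits with bootstrap confidence intervals, and the
stratified Monte Carlo bias study (`examples/bias_study.py`).

A thin CLI mirrors the library:

```sh
ivhr simulate --config sim.yaml --out data.csv
ivhr fit --data data.csv --model piecewise --cuts 0.1,0.3 --method iv --boot 500
ivhr study --scenario stepwise --reps 200 --seed 1 --out summary.csv
```

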