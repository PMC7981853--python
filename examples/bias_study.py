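"""Desk-scale Monte Carlo bias study: IV estimating equations vs partial likelihood.

Replicates the bias-comparison design at reduced replication: parameters are
drawn per dataset (confounding strength, instrument strength, copula family
and dependence, true hazard ratios), a dataset of n = 1000 with 50% censoring
is generated, both estimators are fitted, and median biases are stratified by
confounding direction and instrument strength.
"""

from ivhr import StudyGrid, run_study

result = run_study(StudyGrid(), scenario="stepwise", reps=100, seed=42)

cols = ["confounding", "instrument", "estimator", "parameter",
        "median_bias", "n_used", "n_failed"]
print(result.table[cols].to_string(index=False))
print()
print("Under directional confounding the partial-likelihood rows show median")
print("bias of the confounding's sign (largest early, shrinking with follow-up),")
print("while the IV rows stay near zero; with 'none' both are unbiased.")
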