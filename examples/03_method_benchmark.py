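"""Replicate comparison of FNC+Lasso against SIS+Lasso and plain Lasso.

Runs a small number of fresh simulation replicates at medium base/target
overlap and prints the mean predictive R^2, mean AIC and median model size
per method — the transfer-learning methods should dominate plain Lasso,
with FNC+Lasso the most accurate and most parsimonious.
"""

from fnclasso import SimScheme, run_experiment, summarize_experiment

scheme = SimScheme(m=1000, n0=4000, n=1000, delta=0.5, seed=5)
results = run_experiment(
    scheme, ["fnc", "sis", "lasso"], n_replicates=5, cv_folds=5
)
print(summarize_experiment(results).to_string(index=False))
print(
    "\nEach row aggregates 5 replicates (fresh data, 1:1 train/test split).\n"
    "r2_mean: phenotype variance explained on held-out samples; q_median:\n"
    "SNPs retained in the final model (parsimony); lower AIC is better."
)
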