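"""End-to-end transfer-learning PRS on one simulated base/target pair.

Simulates the nested scheme (target causal variants are a subset of the
base signal variants), fits FNC+Lasso on the training half of the target
sample, and evaluates predictive R^2, AIC and model size on the held-out
half.
"""

import numpy as np

from fnclasso import SimScheme, evaluate, fnc_lasso, simulate_nested

scheme = SimScheme(m=1000, n0=4000, n=1000, delta=0.5, seed=11)
ds = simulate_nested(scheme)
print(f"simulated dataset: m={scheme.m} SNPs, realized h2={ds.realized_h2:.3f}")

train, test = ds.target.split(np.random.default_rng(12))
model = fnc_lasso(ds.sumstats, train, cv_folds=5, seed=11)
print(
    f"winning screening level eps = {model.eps_level}, "
    f"candidate set |D| = {len(model.snp_ids)}, "
    f"nonzero effects q = {model.q}"
)

report = evaluate(model, test)
print(f"held-out predictive R^2 = {report.r2:.3f}, AIC = {report.aic:.1f}")
truth = {f"snp{i:05d}" for i in ds.truth["S"]}
found = truth & set(model.support)
print(
    f"{len(found)} of {len(truth)} true causal SNPs are in the final model;\n"
    "R^2 is the phenotype variance the genetic score explains on unseen\n"
    "samples, and AIC trades that fit against the retained SNP count."
)
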