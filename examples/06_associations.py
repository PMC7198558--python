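"""Covariate-adjusted association testing of gene mutation status.

Fits multivariable logistic models of planted driver-gene mutations against
histology and platinum response, runs backward stepwise elimination, and
compares the planted log-odds with the recovered coefficients.
"""

import numpy as np
import pandas as pd

from tgctk.cohort import CohortConfig, generate_cohort
from tgctk.stats import ModelSpec, fit_glm, likelihood_ratio_test, stepwise_backward

cfg = CohortConfig(n_cases=400, seed=17, samples_per_case={1: 1.0})
samples, variants, _, truth = generate_cohort(cfg)

mutated = {}
for v in variants:
    mutated.setdefault(v.gene, set()).add(v.case_id)

rows = [
    {
        "kit": int(s.case_id in mutated.get("KIT", set())),
        "tp53": int(s.case_id in mutated.get("TP53", set())),
        "seminoma": int(s.histology == "seminoma"),
        "resistant": int(s.platinum_response == "resistant"),
        "extragonadal": int(s.site == "extragonadal"),
    }
    for s in samples
]
data = pd.DataFrame(rows)

print("planted effects:")
print(truth.gene_effects.to_string(index=False))

spec = ModelSpec("kit", "binary", ["seminoma", "resistant", "extragonadal"])
fit = stepwise_backward(spec, data, alpha=0.05, protected=["resistant"])
print("\nKIT model after backward elimination "
      f"(removed: {fit.elimination_trace or 'none'}):")
for term in fit.coefficients.index:
    if term == "Intercept":
        continue
    print(f"  {term:<14} log-OR {fit.coefficients[term]:+.2f} "
          f"(p = {fit.p_values[term]:.2g})")

reduced = fit_glm(ModelSpec("kit", "binary",
                            [c for c in fit.spec.covariates if c != "resistant"]), data)
full = fit_glm(ModelSpec("kit", "binary", fit.spec.covariates), data)
stat, df, p = likelihood_ratio_test(full, reduced)
print(f"\nlikelihood-ratio test for keeping 'resistant': "
      f"chi2 = {stat:.2f}, df = {df}, p = {p:.3g}")
# the planted KIT effects are +1.8 (seminoma) and -1.2 (resistance); the
# adjusted fit recovers both signs at this cohort size.
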