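"""Multitrait versus univariate BLUP with exact reliabilities.

Evaluates one simulated replicate with the full 5-trait animal model and
with single-trait models.  The multitrait model borrows information across
correlated traits, which lifts the reliability of the low-heritability
fertility trait (NRR, h² = 0.02) well above its univariate value.
"""

import numpy as np

from meritsim import GeneticParams, SchemeConfig, simulate_breeding_scheme
from meritsim.mme import multitrait_evaluation, univariate_evaluation
from meritsim.params import TRAITS

params = GeneticParams()
config = SchemeConfig(n_herds=6, cows_per_herd=15, n_years=12,
                      n_proven_sires=4, n_young_sires=4, min_proven_daughters=2,
                      base_years=(5, 7), analysis_years=(3, 12))
sim = simulate_breeding_scheme(params, config, seed=7)
records = sim.records_for(params)

multi = multitrait_evaluation(records, sim.pedigree, params)
cows = np.unique(records.animal[records.trait == 0])

print("trait  h2     mean r2 univariate   mean r2 multitrait   corr(EBV, TBV)")
for t, name in enumerate(TRAITS):
    uni = univariate_evaluation(records, sim.pedigree, t, params)
    acc = np.corrcoef(multi.ebv[cows, t], sim.tbv[cows, t])[0, 1]
    print(f"{name:5s}  {params.h2[t]:.2f}        {uni.rel[cows, 0].mean():.3f}"
          f"                {multi.rel[cows, t].mean():.3f}            {acc:.3f}")
print("\nthe multitrait gain is largest for the lowest-heritability trait")
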