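"""Compare all three estimators on a simulated two-breed composite.

Simulates two distant reference breeds and 100 crossbred animals at
true admixture (0.625, 0.375) under Hardy-Weinberg sampling, then runs
adjusted linear regression, the admixture likelihood, and path analysis
on each animal and prints per-breed means and SDs.
"""

import numpy as np

from gbckit import (
    estimate_admixture_gbc,
    estimate_linreg_gbc,
    estimate_path_gbc,
    make_scenarios,
    summarize_gbc,
)

scenario = make_scenarios(seed=1)["brangus_like"]
F, G = scenario.frequencies, scenario.genotypes
print(f"true proportions: {dict(zip(F.breeds, scenario.true_W.tolist()))}")

estimators = {
    "linear regression": lambda y, i: estimate_linreg_gbc(y, F, animal_id=i),
    "admixture": lambda y, i: estimate_admixture_gbc(y, F, animal_id=i),
    "path D-GBC": lambda y, i: estimate_path_gbc(y, F, mode="direct", id=i),
    "path C-GBC": lambda y, i: estimate_path_gbc(y, F, mode="combined", id=i),
}
for name, fn in estimators.items():
    ests = [fn(G.dosage[i], str(i)) for i in range(G.n_animals)]
    summary = summarize_gbc(ests)
    cells = "  ".join(
        f"{row.breed} {row.mean:.3f} (SD {row.sd:.3f})" for row in summary.itertuples()
    )
    print(f"{name:<18} {cells}")

# Linear regression and the admixture likelihood estimate the admixture
# proportions themselves (means near 0.625/0.375). The path measures
# quantify relative genomic *determination*: with distant breeds D-GBC
# and C-GBC agree with each other (the ratio of squared standardized
# effects, here near 0.73/0.27), and the D-vs-C gap stays small.
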