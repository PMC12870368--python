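"""Structural-equation model selection over an explicit candidate space.

Candidates share treatment -> component edges and differ in the orientation
of component-component edges; each is ML-fitted with a mean-scaled robust
test statistic, filtered by the absolute-fit ledger (chi-square p > 0.05,
robust CFI/TLI > 0.95, RMSEA < 0.07, SRMR < 0.08, GFI/AGFI > 0.95,
|standardized residual| < 2.58), then ranked by GFI-AGFI gap and AIC.
"""

import numpy as np

from microsem import (
    PathModel,
    bootstrap_se,
    enumerate_and_select,
    generate_sem_sample,
)
from microsem.simulate import default_structural_model

# data straight from the generating structural model, n = 600
model = default_structural_model()
cmp_col = (np.arange(600) % 2).astype(float)
data = generate_sem_sample(model, 600, seed=7, exogenous={"Cmp": cmp_col})

fixed = {"Cmp": float(data["Cmp"].var(ddof=1))}
truth = PathModel(model.variables, tuple(model.edges.keys()), (), fixed, name="truth")
no_cross = PathModel(
    model.variables,
    tuple((p, c) for p, c in model.edges if p == "Cmp"),
    (), fixed, name="treatment-only",
)
rewired = dict(model.edges)
rewired.pop(("Bty", "Ace"))
rewired[("Rmb", "Ace")] = 1.0
wrong = PathModel(model.variables, tuple(rewired.keys()), (), fixed, name="rewired")

result = enumerate_and_select([truth, no_cross, wrong], data)
cols = ["p_sc", "cfi_robust", "rmsea", "srmr", "gfi", "agfi", "aic", "stage1", "selected"]
print(result.table[cols].round(3).to_string())

fit = result.selected
print(f"\nselected: {fit.model.name}")
boot = bootstrap_se(fit.model, data, n_boot=200, seed=1)
table = fit.estimates.round(3).to_frame("estimate")
table["boot_se"] = boot["se"].round(3)
print(table.head(6).to_string())
# The generating model passes every ledger criterion and wins on AIC; its
# path estimates sit within a bootstrap SE or two of the planted values.
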