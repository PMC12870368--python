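"""Exploratory factor analysis of the selected components.

Runs on the Spearman correlation matrix of the ML-selected components plus
the treatment indicator: VSS picks the factor count, minres extracts, and
the rotation is promax or varimax depending on how correlated the
components are (oblique when any |rho| > 0.4).
"""

import pandas as pd

from microsem import (
    clr_transform,
    fit_efa,
    generate_study,
    log_transform,
    spearman_matrix,
    vss_curve,
)

study = generate_study(seed=42)
frame = pd.concat(
    [clr_transform(study.counts).data, log_transform(study.metabolites).data], axis=1
)
meta = study.metadata.data
keep = meta["arm"].isin(["HS-Comp", "HS-CON"]).to_numpy()
frame = frame[keep]

components = list(study.truth.planted_taxa) + list(study.truth.planted_metabolites)
data = frame[components].copy()
data["Compost_ex"] = (
    (meta[keep]["arm"] == "HS-Comp") & (meta[keep]["phase"] == "post")
).astype(float).to_numpy()

rho, _ = spearman_matrix(data)
curve, nfactors = vss_curve(rho, max_nfactors=3)
print(f"VSS curve: { {k: round(v, 3) for k, v in curve.items()} } -> {nfactors} factors")

fit = fit_efa(rho, nfactors, rotation="auto")
print(f"rotation chosen: {fit.rotation}")
print()
print(fit.to_frame().round(3).to_string())
# h2 = communality (variance a component shares with the factors),
# u2 = 1 - h2, com = Hofmann row complexity (1 = loads on one factor).
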