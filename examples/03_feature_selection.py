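"""Consensus feature selection: association rules + two tree ensembles + AUC.

The combined CLR/log dataset is median-binarized; rules with the treatment
item as consequent propose candidates; a bagged-tree and a boosted-tree
ensemble score them under supervision; per-feature ROC AUC adds a
model-free axis.  The consensus rank averages the three.
"""

import pandas as pd

from microsem import (
    binarize_by_median,
    clr_transform,
    consensus_select,
    generate_study,
    log_transform,
    mine_association_rules,
    score_candidates,
)

study = generate_study(seed=42)
clr = clr_transform(study.counts)
logmet = log_transform(study.metabolites)
frame = pd.concat([clr.data, logmet.data], axis=1)

meta = study.metadata.data
keep = meta["arm"].isin(["HS-Comp", "HS-CON"]).to_numpy()
frame = frame[keep]
label = ((meta[keep]["arm"] == "HS-Comp") & (meta[keep]["phase"] == "post")).astype(int)

binary = binarize_by_median(frame)
bm = binary.data.copy()
for col in binary.data.columns:          # low items catch depleted features
    bm[f"{col}__low"] = 1 - binary.data[col]
bm["Compost_ex"] = label.to_numpy()
binary.data = bm

rules = mine_association_rules(binary, "Compost_ex", max_candidates=40)
candidates = []
for item in rules.candidates:
    base = item.removesuffix("__low")
    if base not in candidates:
        candidates.append(base)
candidates = candidates[:20]
print(f"{len(rules.rules)} rules mined; first candidates: {candidates[:6]}")

scores = score_candidates(frame[candidates], label.to_numpy(), seed=42)
top8 = consensus_select(scores, 8)
print()
print(scores.frame.loc[top8, ["gini", "gain", "auc", "consensus"]].round(3).to_string())
# gini = bagged-tree impurity importance, gain = boosting gain, auc = ROC
# area against administration (0.5 = uninformative; |auc-0.5| is ranked so
# depleted features score too).  The top-8 set feeds the factor analysis.
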