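"""Difference-in-differences (DID) screen for treatment-associated features.

The DID effect for a feature is the arm x phase interaction coefficient of
an ordinary linear model on CLR/log values with farm fixed effects; shared
baseline and temporal shifts cancel by construction.  Two p values are
reported per feature: the parametric t-based p of the interaction, and a
farm-level permutation p obtained by reassigning the farm-to-arm map
(exact enumeration when the assignment space is small), which respects the
farm-clustered design.  The significance flag and the Benjamini-Hochberg
FDR use the parametric p — with a handful of farms the permutation p is
quantised at 1/#assignments, too coarse to threshold or to feed a step-up
procedure — while the permutation p serves as a design-level robustness
check.

This estimator is a transparent reimplementation choice: the label
"difference-in-differences" is taken literally as the interaction of a
two-group/two-phase linear model, not as a reproduction of any particular
count-model package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb, log

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .tables import FeatureTable, SampleMetadata


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValidationError("bh_fdr expects a 1-d array")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


@dataclass
class DidResult:
    """Per-feature DID screen output for one contrast."""

    frame: pd.DataFrame  # feature, contrast, logFC, p_perm, p_param, fdr, significant
    contrast: str
    alpha: float
    fdr_cut: float
    n_assignments: int

    def to_frame(self) -> pd.DataFrame:
        return self.frame

    def to_dict(self) -> dict:
        return {
            "contrast": self.contrast,
            "alpha": self.alpha,
            "fdr_cut": self.fdr_cut,
            "n_assignments": self.n_assignments,
            "results": self.frame.reset_index().to_dict(orient="records"),
        }

    @property
    def significant_features(self) -> list:
        return self.frame.index[self.frame["significant"]].tolist()


def _design(meta: pd.DataFrame, treated: str, phases: tuple) -> tuple[np.ndarray, np.ndarray]:
    """Farm dummies + post indicator; interaction column returned separately."""
    farms = sorted(meta["farm"].unique())
    n = len(meta)
    x = np.zeros((n, len(farms) + 1))
    for k, f in enumerate(farms):
        x[:, k] = (meta["farm"] == f).to_numpy(dtype=float)
    post = (meta["phase"] == phases[1]).to_numpy(dtype=float)
    x[:, -1] = post
    inter = post * (meta["arm"] == treated).to_numpy(dtype=float)
    return x, inter


def _interaction_stats(base: np.ndarray, inter: np.ndarray, y: np.ndarray):
    """OLS interaction estimates for all features at once.

    Returns (beta3, se, df_resid).  ``y`` is samples x features.
    """
    x = np.column_stack([base, inter])
    # pinv handles the collinearity of farm dummies with an implicit intercept
    pinv = np.linalg.pinv(x)
    beta = pinv @ y
    resid = y - x @ beta
    rank = np.linalg.matrix_rank(x)
    dfres = y.shape[0] - rank
    if dfres <= 0:
        raise ValidationError("no residual degrees of freedom in DID design")
    sigma2 = (resid**2).sum(axis=0) / dfres
    xtx_inv_last = (pinv @ pinv.T)[-1, -1]
    se = np.sqrt(np.maximum(sigma2 * xtx_inv_last, 0.0))
    return beta[-1], se, dfres


def did_test(
    table: FeatureTable,
    metadata: SampleMetadata,
    contrast: tuple = ("HS-Comp", "HS-CON"),
    phases: tuple = ("pre", "post"),
    alpha: float = 0.05,
    fdr_cut: float = 0.1,
    n_perm: int = 10000,
    seed: int = 0,
) -> DidResult:
    """DID screen of every feature for the given arm contrast.

    ``contrast[0]`` is the treated arm.  Farms are the exchangeable units of
    the permutation test; all C(n_farms, n_treated) farm-to-arm assignments
    are enumerated when feasible, otherwise ``n_perm`` assignments are
    sampled with the add-one rule (b+1)/(B+1).
    """
    if table.scale not in ("clr", "log"):
        raise ValidationError("did_test expects a clr or log table")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives very coarse permutation p values")
    treated, control = contrast
    metadata.require_samples(table.sample_ids)
    meta = metadata.data.loc[table.sample_ids]
    keep = meta["arm"].isin(contrast) & meta["phase"].isin(phases)
    meta = meta[keep]
    if meta.empty:
        raise ValidationError(f"no samples for contrast {contrast}")
    y = table.data.loc[meta.index].to_numpy(dtype=float)

    for arm in contrast:
        for ph in phases:
            cell = ((meta["arm"] == arm) & (meta["phase"] == ph)).sum()
            if cell < 2:
                raise ValidationError(f"design cell ({arm}, {ph}) has {cell} samples (<2)")

    base, inter_obs = _design(meta, treated, phases)
    beta3, se, dfres = _interaction_stats(base, inter_obs, y)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, beta3 / se, 0.0)
    p_param = 2.0 * stats.t.sf(np.abs(tval), dfres)

    # farm-level permutation of the arm assignment
    farm_arm = meta.groupby("farm")["arm"].first()
    farms = list(farm_arm.index)
    n_treated_farms = int((farm_arm == treated).sum())
    post = (meta["phase"] == phases[1]).to_numpy(dtype=float)
    farm_col = meta["farm"].to_numpy()

    n_total = comb(len(farms), n_treated_farms)
    rng = np.random.default_rng(seed)
    obs_abs = np.abs(beta3)
    if n_total <= n_perm:
        exceed = np.zeros(y.shape[1])
        for chosen in combinations(range(len(farms)), n_treated_farms):
            treated_farms = {farms[i] for i in chosen}
            inter = post * np.isin(farm_col, list(treated_farms)).astype(float)
            b3, _, _ = _interaction_stats(base, inter, y)
            exceed += np.abs(b3) >= obs_abs - 1e-12
        p_perm = exceed / n_total
        n_assign = n_total
    else:
        exceed = np.zeros(y.shape[1])
        for _ in range(n_perm):
            chosen = rng.choice(len(farms), n_treated_farms, replace=False)
            treated_farms = {farms[i] for i in chosen}
            inter = post * np.isin(farm_col, list(treated_farms)).astype(float)
            b3, _, _ = _interaction_stats(base, inter, y)
            exceed += np.abs(b3) >= obs_abs - 1e-12
        p_perm = (exceed + 1.0) / (n_perm + 1.0)
        n_assign = n_perm

    fdr = bh_fdr(p_param)
    significant = (p_param < alpha) & (fdr < fdr_cut)
    frame = pd.DataFrame(
        {
            "contrast": f"{treated}-vs-{control}",
            "logFC": beta3 / log(2.0),
            "p_perm": p_perm,
            "p_param": p_param,
            "fdr": fdr,
            "significant": significant,
        },
        index=pd.Index(table.feature_ids, name="feature"),
    )
    frame = frame.sort_values(["p_param", "p_perm"], kind="stable")
    return DidResult(frame, f"{treated}-vs-{control}", alpha, fdr_cut, n_assign)
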