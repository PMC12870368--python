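"""Scale transforms and descriptive statistics that gate later stages.

Compositional counts go through the centred log-ratio (CLR) transform so
that ordinary linear methods apply; metabolite concentrations are
log-transformed; the binarized matrix feeds association-rule mining; and
Shapiro-Wilk / Jarque-Bera normality flags decide between parametric and
robust estimators downstream.  Natural logarithms are used throughout;
base-2 appears only in DID reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .tables import FeatureTable


def clr_transform(table: FeatureTable, pseudocount: float = 0.5) -> FeatureTable:
    """Centred log-ratio transform of a counts or relative table.

    Per sample: add ``pseudocount`` (counts scale), close to proportions and
    return ln(p_i / geometric mean p).  Rows of the result sum to zero, and
    the transform is invariant to per-sample scaling of the input.
    """
    if table.scale not in ("counts", "relative"):
        raise ValidationError(f"clr_transform expects counts or relative, got {table.scale}")
    x = table.values.copy()
    if (x.sum(axis=1) == 0).any():
        bad = table.data.index[x.sum(axis=1) == 0].tolist()
        raise ValidationError(f"all-zero samples cannot be transformed: {bad[:5]}")
    if (x == 0).any():
        if pseudocount <= 0:
            raise ValidationError("zeros present: pseudocount must be > 0")
        x = x + pseudocount
    logp = np.log(x / x.sum(axis=1, keepdims=True))
    clr = logp - logp.mean(axis=1, keepdims=True)
    frame = pd.DataFrame(clr, index=table.data.index, columns=table.data.columns)
    return FeatureTable(frame, scale="clr", feature_kind=table.feature_kind)


def log_transform(table: FeatureTable, offset: float = 0.5) -> FeatureTable:
    """Elementwise natural log of (value + offset) for concentration tables."""
    x = table.values
    if (x < 0).any():
        raise ValidationError("negative concentrations cannot be log-transformed")
    if (x == 0).any() and offset <= 0:
        raise ValidationError("zeros present: offset must be > 0")
    frame = pd.DataFrame(
        np.log(x + offset), index=table.data.index, columns=table.data.columns
    )
    return FeatureTable(frame, scale="log", feature_kind=table.feature_kind)


@dataclass
class BinaryMatrix:
    """Median-binarized dataset for association-rule mining.

    Ties at the median map to 1 (rule ">= M -> 1"); constant features are
    dropped and listed in ``dropped``.  ``thresholds`` records the median
    used per retained item.
    """

    data: pd.DataFrame
    thresholds: dict
    dropped: list = field(default_factory=list)

    def __post_init__(self) -> None:
        vals = self.data.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError("binary matrix entries must be 0/1")


def binarize_by_median(frame: pd.DataFrame) -> BinaryMatrix:
    """Binarize each feature at its sample median (>= median -> 1)."""
    out = {}
    thresholds = {}
    dropped = []
    for col in frame.columns:
        v = frame[col].to_numpy(dtype=float)
        if np.unique(v).size < 2:
            dropped.append(col)
            continue
        m = float(np.median(v))
        thresholds[col] = m
        out[col] = (v >= m).astype(int)
    if not out:
        raise ValidationError("all features are constant; nothing to binarize")
    return BinaryMatrix(pd.DataFrame(out, index=frame.index), thresholds, dropped)


@dataclass
class DiversityResult:
    """Per-sample alpha diversity: observed features, Shannon (nats), Gini-Simpson."""

    frame: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return self.frame


def alpha_diversity(table: FeatureTable) -> DiversityResult:
    """Observed features, Shannon entropy H = -sum p ln p, Simpson 1 - sum p^2."""
    if table.scale not in ("counts", "relative"):
        raise ValidationError("alpha_diversity expects counts or relative scale")
    x = table.values
    totals = x.sum(axis=1)
    if (totals == 0).any():
        raise ValidationError("all-zero sample has undefined diversity")
    p = x / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    shannon = -plogp.sum(axis=1)
    simpson = 1.0 - (p**2).sum(axis=1)
    observed = (x > 0).sum(axis=1)
    frame = pd.DataFrame(
        {"observed": observed, "shannon": shannon, "simpson": simpson},
        index=table.data.index,
    )
    return DiversityResult(frame)


def spearman_matrix(frame: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rank correlation matrix (mid-ranks for ties) with p values.

    Zero-variance columns yield NaN correlations and are reported rather
    than raising, mirroring how correlation heat maps flag degenerate rows.
    """
    if len(frame) < 3:
        raise ValidationError("spearman_matrix needs at least 3 samples")
    cols = frame.columns
    k = len(cols)
    rho = np.eye(k)
    pval = np.zeros((k, k))
    x = frame.to_numpy(dtype=float)
    constant = x.std(axis=0) == 0
    for i in range(k):
        for j in range(i + 1, k):
            if constant[i] or constant[j]:
                r, p = np.nan, np.nan
            else:
                r, p = stats.spearmanr(x[:, i], x[:, j])
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    if constant.any():
        for idx in np.flatnonzero(constant):
            rho[idx, idx] = np.nan
    return (
        pd.DataFrame(rho, index=cols, columns=cols),
        pd.DataFrame(pval, index=cols, columns=cols),
    )


def normality_test(vector, method: str = "shapiro") -> dict:
    """Shapiro-Wilk or Jarque-Bera normality test.

    Returns ``{"statistic", "p", "gaussian"}`` where ``gaussian`` is the
    alpha=0.05 flag the pipeline records to choose between plain and robust
    estimators.
    """
    v = np.asarray(vector, dtype=float)
    if np.unique(v).size < 2:
        raise ValidationError("normality test undefined for a constant vector")
    if method == "shapiro":
        if v.size < 3:
            raise ValidationError("Shapiro-Wilk needs n >= 3")
        stat, p = stats.shapiro(v)
    elif method == "jarque_bera":
        if v.size < 8:
            raise ValidationError("Jarque-Bera needs n >= 8 for its asymptotics")
        res = stats.jarque_bera(v)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValidationError(f"unknown normality test {method!r}")
    return {"statistic": float(stat), "p": float(p), "gaussian": bool(p >= 0.05)}
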