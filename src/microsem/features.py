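"""Candidate mining and consensus feature ranking.

Mirrors a three-pronged selection strategy: association-rule mining on the
median-binarized dataset proposes up to 20 candidates associated with the
treatment item; a bagged-tree ensemble (Gini importance) and a
gradient-boosted tree ensemble (gain importance) score them under
supervision; per-feature ROC AUC against the treatment label adds a
model-free axis.  The consensus rank averages the three per-method ranks,
using |AUC - 0.5| so that depleted features rank as highly as enriched
ones.

The level-wise (apriori) itemset search is implemented here directly on the
boolean matrix; rule statistics are plain contingency counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from xgboost import XGBClassifier

from .errors import ValidationError
from .preprocess import BinaryMatrix


@dataclass
class Rule:
    antecedent: tuple
    consequent: str
    support: float
    confidence: float
    lift: float


@dataclass
class RuleSet:
    """Mined rules with consequent = treatment item, plus candidate features."""

    rules: list = field(default_factory=list)
    candidates: list = field(default_factory=list)
    target_item: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "antecedent": " & ".join(r.antecedent),
                    "consequent": r.consequent,
                    "support": r.support,
                    "confidence": r.confidence,
                    "lift": r.lift,
                }
                for r in self.rules
            ]
        )


def _frequent_itemsets(mat: np.ndarray, min_count: int, max_len: int) -> dict:
    """Level-wise frequent itemset search; keys are sorted column-index tuples."""
    n_items = mat.shape[1]
    counts = {}
    current = []
    for j in range(n_items):
        c = int(mat[:, j].sum())
        if c >= min_count:
            counts[(j,)] = c
            current.append((j,))
    length = 1
    while current and length < max_len:
        nxt = []
        seen = set()
        frequent = set(current)
        for a, b in combinations(current, 2):
            if a[:-1] != b[:-1]:
                continue
            cand = tuple(sorted(set(a) | set(b)))
            if cand in seen or len(cand) != length + 1:
                continue
            seen.add(cand)
            # apriori pruning: every (k-1)-subset must be frequent
            if any(cand[:i] + cand[i + 1 :] not in frequent for i in range(len(cand))):
                continue
            col = np.logical_and.reduce(mat[:, list(cand)], axis=1)
            c = int(col.sum())
            if c >= min_count:
                counts[cand] = c
                nxt.append(cand)
        current = sorted(nxt)
        length += 1
    return counts


def mine_association_rules(
    binary: BinaryMatrix,
    target_item: str,
    min_support: float = 0.2,
    min_confidence: float = 0.6,
    max_candidates: int = 20,
    max_len: int = 3,
) -> RuleSet:
    """Mine rules ``antecedent => target_item`` from the binarized dataset.

    Rules are ranked by lift, ties broken by confidence then support then
    antecedent name; candidate features are the unique antecedent items
    accumulated in rank order until ``max_candidates``.
    """
    if not (0 < min_support < 1 and 0 < min_confidence < 1):
        raise ValidationError("min_support and min_confidence must lie in (0, 1)")
    frame = binary.data
    if target_item not in frame.columns:
        raise ValidationError(f"target item {target_item!r} not in binary matrix")
    tcol = frame[target_item].to_numpy()
    if np.unique(tcol).size < 2:
        raise ValidationError("target item is constant; rules are undefined")
    mat = frame.to_numpy(dtype=bool)
    n = mat.shape[0]
    cols = list(frame.columns)
    tidx = cols.index(target_item)
    p_target = tcol.mean()

    min_count = int(np.ceil(min_support * n))
    itemsets = _frequent_itemsets(mat, min_count, max_len)
    rules = []
    for iset, cnt in itemsets.items():
        if tidx not in iset or len(iset) < 2:
            continue
        ante = tuple(j for j in iset if j != tidx)
        ante_cnt = itemsets.get(ante)
        if ante_cnt is None:  # antecedent infrequent (cannot happen by apriori)
            continue
        conf = cnt / ante_cnt
        if conf < min_confidence:
            continue
        rules.append(
            Rule(
                antecedent=tuple(cols[j] for j in ante),
                consequent=target_item,
                support=cnt / n,
                confidence=conf,
                lift=conf / p_target,
            )
        )
    rules.sort(key=lambda r: (-r.lift, -r.confidence, -r.support, r.antecedent))
    if not rules:
        warnings.warn("no association rules met the support/confidence thresholds")
    candidates: list = []
    for r in rules:
        for item in r.antecedent:
            if item not in candidates:
                candidates.append(item)
            if len(candidates) >= max_candidates:
                break
        if len(candidates) >= max_candidates:
            break
    return RuleSet(rules=rules, candidates=candidates, target_item=target_item)


def _check_labels(labels: np.ndarray) -> None:
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size != 2:
        raise ValidationError("labels must contain exactly two classes")
    if counts.min() < 2:
        raise ValidationError("need at least 2 samples per class")


def importance_scores(
    candidates: pd.DataFrame,
    labels,
    seed: int = 0,
    n_trees: int = 1000,
    n_rounds: int = 100,
    max_depth: int = 3,
    learning_rate: float = 0.3,
) -> pd.DataFrame:
    """Gini (bagged-tree) and gain (gradient-boosting) importances.

    Deterministic given ``seed``; returns a frame indexed like the candidate
    columns with columns ``gini`` and ``gain``.
    """
    y = np.asarray(labels)
    _check_labels(y)
    x = candidates.to_numpy(dtype=float)
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    rf.fit(x, y)
    gini = rf.feature_importances_

    xgb = XGBClassifier(
        n_estimators=n_rounds,
        max_depth=max_depth,
        learning_rate=learning_rate,
        objective="binary:logistic",
        random_state=seed,
        n_jobs=1,
        verbosity=0,
        base_score=0.5,
    )
    xgb.fit(x, (y == np.max(y)).astype(int))
    booster = xgb.get_booster()
    gain_map = booster.get_score(importance_type="gain")
    gain = np.array([gain_map.get(f"f{j}", 0.0) for j in range(x.shape[1])])
    return pd.DataFrame({"gini": gini, "gain": gain}, index=candidates.columns)


def roc_auc(values, labels) -> float:
    """AUC via the Mann-Whitney mid-rank identity; positive class is 1."""
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValidationError("roc_auc needs both classes present")
    pos = y == classes.max()
    n1 = int(pos.sum())
    n0 = int((~pos).sum())
    ranks = pd.Series(v).rank(method="average").to_numpy()
    r1 = ranks[pos].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n0 * n1))


@dataclass
class FeatureScores:
    """Per-candidate scores, per-method ranks and the consensus ranking."""

    frame: pd.DataFrame  # gini, gain, auc, rank_gini, rank_gain, rank_auc, consensus

    def to_frame(self) -> pd.DataFrame:
        return self.frame

    def top(self, k: int) -> list:
        return self.frame.sort_values(["consensus", "feature"], kind="stable").index[
            :k
        ].tolist()


def _ordinal_rank(series: pd.Series) -> pd.Series:
    """Descending ordinal rank with lexicographic tie-break (a permutation)."""
    order = sorted(series.index, key=lambda f: (-series[f], str(f)))
    return pd.Series({f: i + 1 for i, f in enumerate(order)})


def score_candidates(
    candidate_values: pd.DataFrame, labels, seed: int = 0, **learner_params
) -> FeatureScores:
    """Combine ensemble importances and ROC AUC into one score table."""
    imp = importance_scores(candidate_values, labels, seed=seed, **learner_params)
    auc = pd.Series(
        {c: roc_auc(candidate_values[c], labels) for c in candidate_values.columns}
    )
    frame = imp.copy()
    frame["auc"] = auc
    frame["rank_gini"] = _ordinal_rank(frame["gini"])
    frame["rank_gain"] = _ordinal_rank(frame["gain"])
    frame["rank_auc"] = _ordinal_rank((frame["auc"] - 0.5).abs())
    frame["consensus"] = frame[["rank_gini", "rank_gain", "rank_auc"]].mean(axis=1)
    frame.index.name = "feature"
    return FeatureScores(frame.sort_values(["consensus", "feature"], kind="stable"))


def consensus_select(scores: FeatureScores, k: int = 8) -> list:
    """Top-k candidates by mean rank across the three methods."""
    if k > len(scores.frame):
        raise ValidationError(f"k={k} exceeds the {len(scores.frame)} candidates")
    return scores.top(k)
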