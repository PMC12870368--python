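"""Association-rule mining, ensemble importances, AUC and consensus."""

import numpy as np
import pandas as pd
import pytest

from microsem.errors import ValidationError
from microsem.features import (
    FeatureScores,
    consensus_select,
    importance_scores,
    mine_association_rules,
    roc_auc,
    score_candidates,
)
from microsem.preprocess import BinaryMatrix

FAST_LEARNERS = dict(n_trees=50, n_rounds=30)


def _binary(frame: pd.DataFrame) -> BinaryMatrix:
    return BinaryMatrix(frame, {c: 0.5 for c in frame.columns})


class TestAssociationRules:
    def test_identical_item_closed_form(self):
        target = np.tile([0, 1], 50)
        frame = pd.DataFrame({"X": target, "noise": np.tile([0, 0, 1, 1], 25), "T": target})
        rules = mine_association_rules(_binary(frame), "T", 0.2, 0.6, 20)
        rx = [r for r in rules.rules if r.antecedent == ("X",)][0]
        assert rx.confidence == 1.0
        assert rx.lift == pytest.approx(2.0)
        assert rx.support == pytest.approx(0.5)

    def test_independent_item_lift_near_one(self, rng):
        n = 2000
        target = rng.integers(0, 2, n)
        item = rng.integers(0, 2, n)
        frame = pd.DataFrame({"X": item, "T": target})
        rules = mine_association_rules(_binary(frame), "T", 0.1, 0.1, 20)
        rx = [r for r in rules.rules if r.antecedent == ("X",)][0]
        assert 0.9 <= rx.lift <= 1.1

    def test_unreachable_support_gives_empty_set(self):
        frame = pd.DataFrame({"X": [0, 1, 0, 1], "T": [0, 0, 1, 1]})
        with pytest.warns(UserWarning, match="no association rules"):
            rules = mine_association_rules(_binary(frame), "T", 0.9, 0.6, 20)
        assert rules.rules == [] and rules.candidates == []

    def test_constant_target_rejected(self):
        frame = pd.DataFrame({"X": [0, 1, 0, 1], "T": [1, 1, 1, 1]})
        with pytest.raises(ValidationError, match="constant"):
            mine_association_rules(_binary(frame), "T")

    def test_statistics_match_contingency_counts(self, rng):
        """Support/confidence/lift equal direct counting on random matrices."""
        for rep in range(20):
            r = np.random.default_rng(rep)
            frame = pd.DataFrame(
                r.integers(0, 2, (60, 5)), columns=list("ABCDE")
            )
            frame["T"] = r.integers(0, 2, 60)
            if frame["T"].nunique() < 2:
                continue
            rules = mine_association_rules(_binary(frame), "T", 0.05, 0.05, 50)
            for rule in rules.rules:
                ante = frame[list(rule.antecedent)].all(axis=1)
                both = (ante & (frame["T"] == 1)).sum()
                assert rule.support == pytest.approx(both / len(frame))
                assert rule.confidence == pytest.approx(both / ante.sum())
                assert rule.lift == pytest.approx(
                    (both / ante.sum()) / frame["T"].mean()
                )


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0

    def test_full_ties_give_half(self):
        assert roc_auc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_interleaved(self):
        assert roc_auc([1, 2, 3, 4], [0, 1, 0, 1]) == 0.75

    def test_matches_pair_counting_with_ties(self):
        """Mann-Whitney identity vs exhaustive concordant-pair counting."""
        for rep in range(200):
            r = np.random.default_rng(rep)
            n = int(r.integers(4, 15))
            vals = r.integers(0, 5, n).astype(float)  # heavy ties
            labs = r.integers(0, 2, n)
            if labs.min() == labs.max():
                continue
            auc = roc_auc(vals, labs)
            pos = vals[labs == 1]
            neg = vals[labs == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert auc == pytest.approx(wins / (len(pos) * len(neg)))

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestImportances:
    def test_label_defining_feature_ranks_first(self):
        top_both = 0
        for rep in range(100):
            r = np.random.default_rng(rep)
            n = 200
            y = r.integers(0, 2, n)
            x = pd.DataFrame(
                r.normal(size=(n, 9)), columns=[f"n{j}" for j in range(9)]
            )
            x["signal"] = y.astype(float)
            imp = importance_scores(x, y, seed=rep, **FAST_LEARNERS)
            top_both += (
                imp["gini"].idxmax() == "signal" and imp["gain"].idxmax() == "signal"
            )
        assert top_both >= 95

    def test_deterministic_given_seed(self, rng):
        y = rng.integers(0, 2, 80)
        x = pd.DataFrame(rng.normal(size=(80, 5)))
        x.columns = [f"f{j}" for j in range(5)]
        a = importance_scores(x, y, seed=4, **FAST_LEARNERS)
        b = importance_scores(x, y, seed=4, **FAST_LEARNERS)
        pd.testing.assert_frame_equal(a, b)

    def test_no_positional_bias_on_pure_noise(self):
        first_wins = 0
        for rep in range(100):
            r = np.random.default_rng(500 + rep)
            y = r.integers(0, 2, 100)
            x = pd.DataFrame(
                r.normal(size=(100, 8)), columns=[f"f{j}" for j in range(8)]
            )
            imp = importance_scores(x, y, seed=rep, **FAST_LEARNERS)
            first_wins += imp["gini"].idxmax() == "f0"
        assert first_wins <= 30

    def test_single_class_rejected(self):
        x = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 2)))
        with pytest.raises(ValidationError):
            importance_scores(x, np.ones(10, dtype=int), seed=0)


class TestConsensus:
    def _scores(self, frame):
        return FeatureScores(frame)

    def test_unanimous_winner(self, rng):
        y = np.tile([0, 1], 40)
        x = pd.DataFrame(rng.normal(size=(80, 4)), columns=list("abcd"))
        x["win"] = y + rng.normal(0, 0.05, 80)
        scores = score_candidates(x, y, seed=1, **FAST_LEARNERS)
        assert consensus_select(scores, 1) == ["win"]
        assert scores.frame.loc["win", "consensus"] == 1.0

    def test_k_equal_candidate_count_is_permutation(self, rng):
        y = rng.integers(0, 2, 60)
        x = pd.DataFrame(rng.normal(size=(60, 5)), columns=list("abcde"))
        scores = score_candidates(x, y, seed=2, **FAST_LEARNERS)
        assert sorted(consensus_select(scores, 5)) == list("abcde")

    def test_k_too_large_rejected(self, rng):
        y = rng.integers(0, 2, 60)
        x = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
        scores = score_candidates(x, y, seed=3, **FAST_LEARNERS)
        with pytest.raises(ValidationError):
            consensus_select(scores, 4)

    def test_column_order_invariance(self, rng):
        y = rng.integers(0, 2, 80)
        x = pd.DataFrame(rng.normal(size=(80, 5)), columns=list("abcde"))
        x["sig"] = y + rng.normal(0, 0.3, 80)
        a = score_candidates(x, y, seed=5, **FAST_LEARNERS)
        # AUC and the rank bookkeeping must not depend on column order;
        # tree ensembles are checked on the winning feature only, since the
        # learners' internal tie-breaking is positional
        shuffled = x[list(x.columns[::-1])]
        b = score_candidates(shuffled, y, seed=5, **FAST_LEARNERS)
        pd.testing.assert_series_equal(
            a.frame["auc"].sort_index(), b.frame["auc"].sort_index()
        )
        assert a.frame["rank_auc"].sort_index().equals(b.frame["rank_auc"].sort_index())
        assert a.top(1) == b.top(1)
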