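"""Confusion matrices, diagnostic metrics, ROC/AUC, grouped evaluation."""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from hrvlit import (
    ConfusionMatrix,
    auc_from_points,
    confusion,
    evaluate_by_group,
    metrics,
    metrics_rounded,
    roc_curve,
    round_half_up,
)
from hrvlit.evaluation import UndefinedAUCError
from hrvlit.fixtures import REFERENCE_CONFUSION_MATRICES
from hrvlit.stratification import ReferenceStats


def concordance_auc(scores, truths):
    """Brute-force pairwise concordance: P(score_pos > score_neg) + ties/2."""
    pos = scores[truths]
    neg = scores[~truths]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_agreement(self):
        truth = [True] * 10 + [False] * 20
        cm = confusion(truth, truth)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (10, 0, 0, 20)

    def test_all_negative_predictions(self):
        truth = [True] * 16 + [False] * 98
        cm = confusion([False] * 114, truth)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (0, 0, 16, 98)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion([True], [True, False])

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=-1, fp=0, fn=0, tn=0)


class TestMetrics:
    # the self-consistent published one-decimal values per candidate parameter
    @pytest.mark.parametrize(
        "param,metric,expected",
        [
            ("LF", "sensitivity", 81.3),
            ("TP", "accuracy", 82.5),
            ("TP", "sensitivity", 62.5),
            ("TP", "specificity", 85.7),
            ("HF", "accuracy", 79.8),
            ("LF/HF", "accuracy", 78.9),
            ("LF/HF", "sensitivity", 25.0),
            ("LF/HF", "specificity", 87.8),
            ("VLF", "accuracy", 78.9),
            ("VLF", "sensitivity", 37.5),
            ("VLF", "specificity", 85.7),
        ],
    )
    def test_reference_matrices_reproduce_printed_percentages(
        self, param, metric, expected
    ):
        cm = REFERENCE_CONFUSION_MATRICES[param]
        assert metrics_rounded(cm)[metric] == expected

    def test_formulas_on_lf_matrix(self):
        cm = REFERENCE_CONFUSION_MATRICES["LF"]
        m = metrics(cm)
        assert m["sensitivity"] == pytest.approx(100 * 13 / 16)
        assert m["specificity"] == pytest.approx(100 * 85 / 98)
        assert m["accuracy"] == pytest.approx(100 * 98 / 114)

    def test_accuracy_times_n_is_exact(self):
        for cm in REFERENCE_CONFUSION_MATRICES.values():
            assert metrics(cm)["accuracy"] * cm.n / 100 == pytest.approx(cm.tp + cm.tn)

    def test_zero_denominators_are_undefined_not_zero(self):
        m = metrics(ConfusionMatrix(tp=0, fp=0, fn=0, tn=10))
        assert math.isnan(m["sensitivity"])
        assert m["specificity"] == 100.0

    def test_half_up_rounding(self):
        assert round_half_up(82.45) == 82.5
        assert round_half_up(81.25) == 81.3
        assert round_half_up(86.0 - 1e-12) == 86.0


class TestROC:
    def test_perfect_separation_auc_one(self):
        values = np.r_[np.full(5, 3.0), np.full(10, 6.0)]  # events lower
        truth = np.r_[np.ones(5, bool), np.zeros(10, bool)]
        roc = roc_curve(values, truth, "negative")
        assert roc.auc == pytest.approx(1.0)
        assert roc.points[0] == (0.0, 0.0) and roc.points[-1] == (1.0, 1.0)

    def test_direction_flip_mirrors_auc(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = int(rng.integers(10, 50))
            values = rng.normal(size=n)
            truth = rng.random(n) < 0.4
            if truth.all() or not truth.any():
                continue
            a = roc_curve(values, truth, "negative").auc
            b = roc_curve(values, truth, "positive").auc
            assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_matches_concordance_oracle_on_random_instances(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            n = int(rng.integers(5, 51))
            values = np.round(rng.normal(size=n), 1)  # ties occur
            truth = rng.random(n) < 0.5
            if truth.all() or not truth.any():
                continue
            roc = roc_curve(values, truth, "negative")
            assert roc.auc == pytest.approx(
                concordance_auc(-values, truth), abs=1e-9
            )

    def test_matches_sklearn(self):
        rng = np.random.default_rng(17)
        values = rng.normal(size=200)
        truth = rng.random(200) < 0.3
        roc = roc_curve(values, truth, "negative")
        assert roc.auc == pytest.approx(roc_auc_score(truth, -values), abs=1e-12)

    def test_single_class_truth_is_error(self):
        with pytest.raises(UndefinedAUCError):
            roc_curve(np.arange(5.0), np.ones(5, bool), "negative")

    def test_k_grid_mode_staircase(self):
        rng = np.random.default_rng(6)
        values = rng.normal(5.0, 1.0, size=200)
        truth = values < 4.0  # events in the low tail
        ref = ReferenceStats(5.0, 1.0, "all_subjects", 200)
        roc = roc_curve(values, truth, "negative",
                        k_grid=np.linspace(0.1, 3.0, 30), ref=ref)
        fpr = [p[0] for p in roc.points]
        tpr = [p[1] for p in roc.points]
        assert fpr == sorted(fpr) and tpr == sorted(tpr)
        assert roc.auc > 0.9


class TestAUC:
    def test_trivial_point_sets(self):
        assert auc_from_points([(0, 0), (0, 1), (1, 1)]) == 1.0
        assert auc_from_points([(0, 0), (1, 1)]) == 0.5

    def test_unsorted_points_rejected(self):
        with pytest.raises(ValueError):
            auc_from_points([(0.5, 0.5), (0.1, 0.1)])


class TestGroupedEvaluation:
    @staticmethod
    def make(n=40, seed=0, sexes=("male", "female")):
        rng = np.random.default_rng(seed)
        cohort = pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(n)],
            "sex": rng.choice(sexes, size=n),
            "event": rng.random(n) < 0.3,
        })
        preds = pd.DataFrame({
            "subject_id": cohort.subject_id,
            "prediction": rng.random(n) < 0.3,
            "event": cohort.event,
        })
        return cohort, preds

    def test_single_group_equals_overall(self):
        cohort, preds = self.make(sexes=("male",))
        table = evaluate_by_group(cohort, preds, "sex")
        overall = table[table.group == "overall"].iloc[0]
        male = table[table.group == "male"].iloc[0]
        for col in ("tp", "fp", "fn", "tn", "accuracy"):
            assert overall[col] == male[col]

    def test_group_without_events_has_undefined_sensitivity(self):
        cohort, preds = self.make(seed=3)
        cohort.loc[cohort.sex == "female", "event"] = False
        preds["event"] = cohort["event"]
        table = evaluate_by_group(cohort, preds, "sex")
        female = table[table.group == "female"].iloc[0]
        assert math.isnan(female["sensitivity"])

    def test_equal_effect_gives_similar_group_sensitivity(self):
        # identical low-tail effect in both sexes: large-sample sensitivities agree
        rng = np.random.default_rng(12)
        n = 4000
        sex = np.where(rng.random(n) < 0.5, "male", "female")
        values = rng.normal(5.0, 1.0, n)
        event = values < 3.8
        preds = values < 4.0
        cohort = pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(n)], "sex": sex, "event": event,
        })
        pred_df = pd.DataFrame({
            "subject_id": cohort.subject_id, "prediction": preds, "event": event,
        })
        table = evaluate_by_group(cohort, pred_df, "sex").set_index("group")
        assert table.loc["male", "sensitivity"] == pytest.approx(
            table.loc["female", "sensitivity"], abs=5.0
        )

    def test_missing_group_column(self):
        cohort, preds = self.make()
        with pytest.raises(KeyError):
            evaluate_by_group(cohort, preds, "hospital")
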