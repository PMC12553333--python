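"""Metric kernels against brute-force oracles and scikit-learn."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import (
    average_precision_score,
    f1_score,
    roc_auc_score,
)

from oracles import (
    confusion_brute,
    macro_f1_brute,
    pr_auc_brute,
    random_binary_instance,
    regression_brute,
    roc_auc_brute,
)
from protbench import ProteinRecord, TaskSpec
from protbench.errors import (
    NoPositives,
    SingleClass,
    TooFewReplicates,
    ZeroVariance,
)
from protbench.evaluation import (
    accuracy,
    compare_methods,
    compute_metrics,
    confusion_counts,
    macro_f1,
    pr_auc,
    precision_recall,
    regression_metrics,
    roc_auc,
)


class TestConfusionCounts:
    def test_enumeration_example(self):
        assert confusion_counts([1, 1, 0, 0], [1, 0, 1, 0]) == (1, 1, 1, 1)

    def test_perfect_prediction(self):
        y = [1, 1, 1, 0, 0]
        assert confusion_counts(y, y) == (3, 0, 2, 0)

    def test_random_instances_match_loop_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            y = rng.integers(0, 2, 50)
            p = rng.integers(0, 2, 50)
            assert confusion_counts(y, p) == confusion_brute(y, p)

    def test_counts_sum_to_n(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 33)
        p = rng.integers(0, 2, 33)
        assert sum(confusion_counts(y, p)) == 33


class TestPrecisionRecall:
    def test_balanced_counts(self):
        pr = precision_recall((1, 1, 1, 1))
        assert (pr.precision, pr.recall) == (0.5, 0.5)

    def test_perfect_predictor(self):
        pr = precision_recall((5, 0, 5, 0))
        assert (pr.precision, pr.recall) == (1.0, 1.0)

    def test_zero_denominator_flagged(self):
        pr = precision_recall((0, 0, 4, 2))
        assert pr.precision == 0.0 and not pr.precision_defined
        assert pr.recall_defined


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 1, 0, 0], [0.9, 0.8, 0.3, 0.2]) == 1.0

    def test_pair_enumeration_example(self):
        # 4 pos-neg pairs: 3 wins, 1 loss -> 0.75
        assert roc_auc([1, 0, 1, 0], [0.9, 0.8, 0.3, 0.2]) == 0.75

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        y, s = random_binary_instance(rng, tie_prob=0.0)
        assert np.isclose(roc_auc(y, s), roc_auc(y, np.exp(5 * s)))

    def test_single_class_raises(self):
        with pytest.raises(SingleClass):
            roc_auc([1, 1], [0.2, 0.3])

    def test_complement_symmetry_without_ties(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 20)
        y[0], y[1] = 0, 1
        s = rng.permutation(np.linspace(0, 1, 20))
        assert np.isclose(roc_auc(y, s) + roc_auc(y, -s), 1.0)


class TestPrAuc:
    def test_perfect(self):
        assert pr_auc([1, 0], [0.9, 0.1]) == 1.0

    def test_threshold_enumeration_example(self):
        # precisions 1 and 2/3 at recall steps of 1/2 each -> 5/6
        assert np.isclose(pr_auc([1, 0, 1], [0.9, 0.8, 0.7]), 5.0 / 6.0)

    def test_no_positives_raises(self):
        with pytest.raises(NoPositives):
            pr_auc([0, 0], [0.1, 0.2])

    def test_random_scores_approach_prevalence(self):
        rng = np.random.default_rng(4)
        vals = []
        for _ in range(10):
            y = (rng.random(4000) < 0.3).astype(int)
            s = rng.random(4000)
            vals.append(pr_auc(y, s))
        assert abs(np.mean(vals) - 0.3) < 0.02


class TestKernelOracleEquivalence:
    """200 random instances (N <= 50, ties included) against brute force."""

    def test_auc_kernels(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            y, s = random_binary_instance(rng)
            assert abs(roc_auc(y, s) - roc_auc_brute(y, s)) <= 1e-9
            assert abs(pr_auc(y, s) - pr_auc_brute(y, s)) <= 1e-9

    def test_sklearn_cross_check(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            y, s = random_binary_instance(rng)
            assert abs(roc_auc(y, s) - roc_auc_score(y, s)) <= 1e-9
            assert abs(pr_auc(y, s) - average_precision_score(y, s)) <= 1e-9

    def test_macro_f1_against_loop_and_sklearn(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            y = rng.integers(0, 10, 200)
            p = rng.integers(0, 10, 200)
            ours = macro_f1(y, p, 10)
            assert abs(ours - macro_f1_brute(y, p, 10)) <= 1e-9
            assert abs(ours - f1_score(y, p, average="macro",
                                       labels=range(10),
                                       zero_division=0)) <= 1e-9

    def test_regression_metrics_against_brute(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            n = int(rng.integers(3, 50))
            t = rng.standard_normal(n)
            p = t + 0.3 * rng.standard_normal(n)
            ours = regression_metrics(t, p)
            brute = regression_brute(t, p)
            np.testing.assert_allclose(ours, brute, atol=1e-9)

    def test_accuracy_reproduces_fraction_correct(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, 40)
        p = rng.integers(0, 2, 40)
        tp, fp, tn, fn = confusion_counts(y, p)
        assert accuracy(y, p) == (tp + tn) / 40


class TestRegressionMetrics:
    def test_perfect_prediction(self):
        mse, mae, rho, r2 = regression_metrics([1, 2, 3], [1, 2, 3])
        assert (mse, mae, rho, r2) == (0.0, 0.0, 1.0, 1.0)

    def test_mean_prediction_gives_zero_r2(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        _, _, _, r2 = regression_metrics(y, np.full(4, y.mean()))
        assert np.isclose(r2, 0.0)

    def test_reversed_ranks(self):
        _, _, rho, _ = regression_metrics([1, 2, 3], [3, 2, 1])
        assert rho == -1.0

    def test_constant_truth_raises(self):
        with pytest.raises(ZeroVariance):
            regression_metrics([2, 2, 2], [1, 2, 3])

    def test_spearman_monotone_invariance(self):
        rng = np.random.default_rng(10)
        t = rng.standard_normal(30)
        p = rng.standard_normal(30)
        _, _, rho1, _ = regression_metrics(t, p)
        _, _, rho2, _ = regression_metrics(t, np.exp(p))
        assert np.isclose(rho1, rho2)


class TestMacroF1:
    def test_perfect_three_class(self):
        assert macro_f1([0, 1, 2, 1], [0, 1, 2, 1], 3) == 1.0

    def test_balanced_binary_half(self):
        # counts (TP,FP,TN,FN) = (1,1,1,1): F1 = 0.5 for both classes
        assert macro_f1([1, 1, 0, 0], [1, 0, 1, 0], 2) == 0.5

    def test_absent_class_contributes_zero(self):
        assert macro_f1([0, 0], [0, 0], 2) == 0.5


class TestComputeMetrics:
    def test_regression_report_keys(self, regression_task):
        truth = [ProteinRecord(id=f"r{i}", sequence="ACD", label=float(i))
                 for i in range(6)]
        preds = pd.DataFrame({"id": [r.id for r in truth],
                              "pred": [r.label + 0.1 for r in truth]})
        report = compute_metrics(regression_task, preds, truth)
        assert set(report.values) == {"mse", "mae", "spearman", "r2"}

    def test_binary_report_in_unit_interval(self, binary_task):
        rng = np.random.default_rng(11)
        truth = [ProteinRecord(id=f"r{i}", sequence="ACD",
                               label=int(rng.integers(0, 2)))
                 for i in range(20)]
        truth[0].label, truth[1].label = 0, 1
        preds = pd.DataFrame({
            "id": [r.id for r in truth],
            "prob_1": rng.random(20),
        })
        preds["pred"] = (preds["prob_1"] >= 0.5).astype(int)
        report = compute_metrics(binary_task, preds, truth)
        assert all(0.0 <= v <= 1.0 for v in report.values.values())

    def test_residue_metrics_pool_across_sequences(self, residue_task):
        from protbench import ResidueRecord
        truth = [
            ResidueRecord(id="a", sequence="ACD", residue_labels=[0, 1, 0]),
            ResidueRecord(id="b", sequence="ACDEF",
                          residue_labels=[1, 0, 0, 1, 0]),
        ]
        rows = []
        for rec in truth:
            for t, lab in enumerate(rec.residue_labels):
                rows.append({"id": rec.id, "position": t, "pred": lab,
                             "prob_1": 0.9 if lab else 0.1})
        report = compute_metrics(residue_task, pd.DataFrame(rows), truth)
        assert report.n_samples == 8
        assert report["roc_auc"] == 1.0


class TestCompareMethods:
    def test_identical_replicates(self):
        res = compare_methods([0.8, 0.8, 0.8], [0.8, 0.8, 0.8], alpha=0.01)
        assert res.t_statistic == 0.0
        assert res.p_value == 1.0
        assert res.verdict == "not_significant"

    def test_separated_methods_significant(self):
        res = compare_methods([0.9, 0.91, 0.92], [0.5, 0.51, 0.52],
                              alpha=0.01)
        assert res.verdict == "significant"
        # hand-computed Student's t oracle
        a, b = np.array([0.9, 0.91, 0.92]), np.array([0.5, 0.51, 0.52])
        sp = np.sqrt(((a.var(ddof=1) * 2) + (b.var(ddof=1) * 2)) / 4)
        t_hand = (a.mean() - b.mean()) / (sp * np.sqrt(1 / 3 + 1 / 3))
        p_hand = 2 * stats.t.sf(abs(t_hand), df=4)
        assert abs(res.t_statistic - t_hand) <= 1e-9
        assert abs(res.p_value - p_hand) <= 1e-6

    def test_single_replicate_raises(self):
        with pytest.raises(TooFewReplicates):
            compare_methods([0.9], [0.8])

    def test_welch_flag_changes_df(self):
        a = [0.1, 0.2, 0.3, 0.35]
        b = [0.8, 0.80001, 0.80002]
        student = compare_methods(a, b)
        welch = compare_methods(a, b, welch=True)
        assert student.p_value != welch.p_value
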