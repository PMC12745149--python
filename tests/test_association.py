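"""Risk labels, balanced accuracy, and the paired model-comparison CV."""

import numpy as np
import pandas as pd
import pytest

from lvatlas.association import (CVSettings, balanced_accuracy, cv_compare,
                                 derive_risk_labels)


def cov_rows(sid, exam, **kw):
    base = dict(subject_id=sid, exam=exam, age=60.0, sex="female",
                race_ethnicity="white", bmi=25.0, sbp=120.0, dbp=75.0,
                total_cholesterol=180.0, ldl=100.0, hdl=55.0,
                triglycerides=120.0, smoker=False, htn_diagnosis=False,
                htn_medication=False, statins=False, diabetes_status="none",
                bsa=1.8)
    base.update(kw)
    return base


def make_table(rows):
    return pd.DataFrame(rows)


class TestDeriveRiskLabels:
    def test_obesity_threshold_and_longitudinal_scheme(self):
        table = make_table([
            cov_rows("A", "baseline", bmi=28.0),
            cov_rows("A", "followup", bmi=31.0),   # incident -> positive
            cov_rows("B", "baseline", bmi=28.0),
            cov_rows("B", "followup", bmi=28.0),   # never -> negative
            cov_rows("C", "baseline", bmi=31.0),
            cov_rows("C", "followup", bmi=28.0),   # remitted -> excluded
        ])
        lab = derive_risk_labels(table)
        assert lab.loc["A", "obesity"] == "positive"
        assert lab.loc["B", "obesity"] == "negative"
        assert lab.loc["C", "obesity"] == "excluded"

    def test_hypertension_rule_truth_table(self):
        # enumerate the conjunction/disjunction variants of the BP rule
        cases = [
            # (sbp, dbp, diagnosis) -> (label under "and", label under "or")
            ((150.0, 95.0, False), ("positive", "positive")),
            ((150.0, 80.0, False), ("negative", "positive")),  # divergent
            ((120.0, 95.0, False), ("negative", "positive")),  # divergent
            ((120.0, 80.0, False), ("negative", "negative")),
            ((120.0, 80.0, True), ("positive", "positive")),
        ]
        for (sbp, dbp, diag), (want_and, want_or) in cases:
            table = make_table([
                cov_rows("X", "baseline"),
                cov_rows("X", "followup", sbp=sbp, dbp=dbp,
                         htn_diagnosis=diag)])
            got_and = derive_risk_labels(table, bp_rule="and") \
                .loc["X", "hypertension"]
            got_or = derive_risk_labels(table, bp_rule="or") \
                .loc["X", "hypertension"]
            assert got_and == want_and
            assert got_or == want_or

    def test_cholesterol_rule_variants(self):
        high_one = cov_rows("Y", "followup", triglycerides=200.0)
        table = make_table([cov_rows("Y", "baseline"), high_one])
        assert derive_risk_labels(table, chol_rule="any") \
            .loc["Y", "high_cholesterol"] == "positive"
        assert derive_risk_labels(table, chol_rule="all") \
            .loc["Y", "high_cholesterol"] == "negative"

    def test_smoking_from_followup_status(self):
        table = make_table([
            cov_rows("Q", "baseline", smoker=True),
            cov_rows("Q", "followup", smoker=False),   # quit -> excluded
            cov_rows("R", "baseline", smoker=False),
            cov_rows("R", "followup", smoker=True)])   # smokes at FU
        lab = derive_risk_labels(table)
        assert lab.loc["Q", "smoking"] == "excluded"
        assert lab.loc["R", "smoking"] == "positive"

    def test_diabetes_includes_impaired_fasting_glucose(self):
        table = make_table([
            cov_rows("Z", "baseline"),
            cov_rows("Z", "followup", diabetes_status="ifg")])
        assert derive_risk_labels(table).loc["Z", "diabetes"] == "positive"

    def test_missing_field_excludes_subject_for_factor(self):
        rows = [cov_rows("M", "baseline"), cov_rows("M", "followup")]
        rows[1]["bmi"] = np.nan
        lab = derive_risk_labels(make_table(rows))
        assert lab.loc["M", "obesity"] == "excluded"
        assert lab.loc["M", "smoking"] == "negative"

    def test_invalid_rules_rejected(self):
        table = make_table([cov_rows("A", "baseline"),
                            cov_rows("A", "followup")])
        with pytest.raises(ValueError):
            derive_risk_labels(table, chol_rule="sometimes")


class TestBalancedAccuracy:
    def test_perfect_and_chance(self):
        y = np.array([1, 1, 1, 0, 0])
        assert balanced_accuracy(y, y) == 1.0
        assert balanced_accuracy(y, np.ones(5)) == 0.5

    def test_confusion_table_oracle(self):
        # TP=3 FN=1 TN=2 FP=2 -> (3/4 + 2/4)/2 = 0.625
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        p = np.array([1, 1, 1, 0, 1, 1, 0, 0])
        assert balanced_accuracy(y, p) == pytest.approx(0.625)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import balanced_accuracy_score
        for _ in range(20):
            y = rng.integers(0, 2, 30)
            p = rng.integers(0, 2, 30)
            if len(np.unique(y)) < 2:
                continue
            assert balanced_accuracy(y, p) == pytest.approx(
                balanced_accuracy_score(y, p))

    def test_relabeling_invariance(self, rng):
        y = rng.integers(0, 2, 40)
        p = rng.integers(0, 2, 40)
        assert balanced_accuracy(y, p) == pytest.approx(
            balanced_accuracy(1 - y, 1 - p))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            balanced_accuracy(np.ones(5), np.ones(5))


@pytest.fixture(scope="module")
def small_cv_problem():
    """Tiny synthetic feature/label set for CV plumbing tests."""
    rng = np.random.default_rng(42)
    n = 120
    sids = [f"S{i:04d}" for i in range(n)]
    y = rng.random(n) < 0.35
    scores = pd.DataFrame(
        rng.normal(size=(n, 5)) + np.outer(y, [1.2, 0, 0, 0, 0]),
        index=pd.Index(sids, name="subject_id"),
        columns=[f"score_{j+1}" for j in range(5)])
    mv = pd.DataFrame(rng.normal(size=(n, 4)),
                      index=scores.index,
                      columns=["delta_EDV", "delta_ESV", "delta_mass",
                               "delta_EF"])
    labels = pd.DataFrame(
        {"obesity": np.where(y, "positive", "negative")},
        index=scores.index)
    cov = pd.concat([
        pd.DataFrame({"subject_id": sids, "exam": "baseline",
                      "age": rng.normal(60, 9, n),
                      "sex": rng.choice(["male", "female"], n)}),
        pd.DataFrame({"subject_id": sids, "exam": "followup",
                      "age": 70.0, "sex": "female"})], ignore_index=True)
    return scores, mv, labels, cov


FAST = CVSettings(n_splits=4, n_iter=6, inner_folds=3, min_labeled=30,
                  min_class=5)


class TestCvCompare:
    def test_deterministic_given_seed(self, small_cv_problem):
        scores, mv, labels, cov = small_cv_problem
        a = cv_compare(scores, mv, labels, cov, seed=7, settings=FAST,
                       include_sex_response=False)
        b = cv_compare(scores, mv, labels, cov, seed=7, settings=FAST,
                       include_sex_response=False)
        pd.testing.assert_frame_equal(a.folds, b.folds)
        pd.testing.assert_frame_equal(a.summary, b.summary)

    def test_informative_scores_beat_uninformative_mv(self, small_cv_problem):
        scores, mv, labels, cov = small_cv_problem
        res = cv_compare(scores, mv, labels, cov, seed=7, settings=FAST,
                         include_sex_response=False)
        row = res.summary.iloc[0]
        assert row["atlas_mean"] > row["mv_mean"]
        assert (res.folds["balanced_accuracy"].between(0, 1)).all()

    def test_small_class_skipped_with_reason(self, small_cv_problem):
        scores, mv, labels, cov = small_cv_problem
        rare = labels.copy()
        rare["obesity"] = "negative"
        rare.iloc[:3, 0] = "positive"
        res = cv_compare(scores, mv, rare, cov, seed=1, settings=FAST,
                         include_sex_response=False)
        assert "obesity" in res.skipped
        assert res.summary.empty

    def test_stratified_splits_preserve_proportions(self):
        from sklearn.model_selection import StratifiedShuffleSplit
        y = np.array([1] * 30 + [0] * 90)
        sss = StratifiedShuffleSplit(n_splits=5, test_size=0.2,
                                     random_state=0)
        for tr, te in sss.split(np.zeros_like(y), y):
            assert abs(y[te].mean() - 0.25) <= 1.0 / len(te)

    def test_bonferroni_scales_with_responses(self, small_cv_problem):
        scores, mv, labels, cov = small_cv_problem
        res = cv_compare(scores, mv, labels, cov, seed=7, settings=FAST,
                         responses=["obesity"])
        row = res.summary.iloc[0]
        assert row["p_bonferroni"] == pytest.approx(
            min(1.0, row["p_raw"] * 1))
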