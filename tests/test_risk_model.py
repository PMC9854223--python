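"""Logistic stack: fitting, selection, metrics and the CV pipeline."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

import radiomethyl as rm
from radiomethyl.risk_model import _intercept_only, encode_features


def make_xy(n=500, beta=(1.0,), intercept=-0.5, seed=0, scale=1.0):
    gen = np.random.default_rng(seed)
    X = pd.DataFrame({f"x{i}": gen.normal(0, scale, n) for i in range(len(beta))})
    eta = intercept + X.to_numpy() @ np.asarray(beta)
    y = (gen.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    return X, y


class TestFitLogistic:
    def test_constant_feature_dropped_intercept_is_logit_prevalence(self):
        gen = np.random.default_rng(1)
        y = (gen.random(400) < 0.25).astype(int)
        X = pd.DataFrame({"zero": np.zeros(400)})
        m = rm.fit_logistic(X, y)
        assert m.dropped == ["zero"] and m.variables == []
        prev = y.mean()
        assert m.intercept == pytest.approx(math.log(prev / (1 - prev)), abs=1e-6)

    def test_single_class_labels_rejected(self):
        X, _ = make_xy(50)
        with pytest.raises(ValueError, match="both classes"):
            rm.fit_logistic(X, np.ones(50))

    def test_binary_predictor_reproduces_closed_form_log_odds_ratio(self):
        # 2x2 table: exposure x outcome; slope = log(ad/bc)
        a, b, c, d = 40, 60, 25, 75  # exposed y1, exposed y0, unexp y1, unexp y0
        x = np.array([1] * (a + b) + [0] * (c + d))
        y = np.array([1] * a + [0] * b + [1] * c + [0] * d)
        m = rm.fit_logistic(pd.DataFrame({"x": x}), y)
        log_or = math.log((a * d) / (b * c))
        assert m.coef("x") == pytest.approx(log_or, abs=1e-8)

    def test_complete_separation_is_flagged(self):
        x = np.concatenate([np.full(30, -1.0), np.full(30, 1.0)])
        y = (x > 0).astype(int)
        m = rm.fit_logistic(pd.DataFrame({"x": x}), y)
        assert m.separated

    def test_wald_ci_covers_planted_effect(self):
        # 40 refits at n=2000: the planted slope should be inside its own
        # 95% CI in the large majority of runs
        hits = 0
        for seed in range(40):
            X, y = make_xy(n=2_000, beta=(0.4,), seed=seed)
            m = rm.fit_logistic(X, y)
            lo, hi = m.params.loc["x0", ["ci_low", "ci_high"]]
            hits += lo <= 0.4 <= hi
        assert hits >= 34


class TestSelectVariables:
    def test_noise_variable_dropped_strong_kept(self):
        gen = np.random.default_rng(7)
        X, y = make_xy(n=2_000, beta=(0.8,), seed=7)
        X["noise"] = gen.normal(size=len(X))
        sel, model = rm.select_variables(X, y)
        assert sel == ["x0"]

    def test_single_candidate_below_threshold_retained(self):
        X, y = make_xy(n=3_000, beta=(0.3,), seed=3)
        sel, _ = rm.select_variables(X, y, retention_p=0.1)
        assert sel == ["x0"]

    def test_all_noise_usually_intercept_only(self):
        empty = 0
        for seed in range(10):
            gen = np.random.default_rng(100 + seed)
            X = pd.DataFrame({"a": gen.normal(size=300), "b": gen.normal(size=300)})
            y = (gen.random(300) < 0.5).astype(int)
            sel, _ = rm.select_variables(X, y)
            empty += not sel
        assert empty >= 7

    def test_forward_agrees_on_obvious_signal(self):
        X, y = make_xy(n=2_000, beta=(0.9, 0.0), seed=5)
        sel, _ = rm.select_variables(X, y, direction="forward")
        assert sel == ["x0"]


class TestEvaluate:
    def test_perfect_separation_scores_one(self):
        scores_x = np.concatenate([np.full(10, -3.0), np.full(10, 3.0)])
        y = (scores_x > 0).astype(int)
        m = _intercept_only(np.array([0, 1]))
        m.params.loc["intercept", "coef"] = 0.0
        m.params.loc["x", "coef"] = 5.0
        m.variables = ["x"]
        rep = rm.evaluate(m, pd.DataFrame({"x": scores_x}), y)
        assert rep.accuracy == rep.sensitivity_no_stenosis == 1.0
        assert rep.specificity_stenosis == rep.auc == 1.0

    def test_constant_score_auc_half_by_midranks(self):
        assert rm.auc_mann_whitney(np.ones(10), [0, 1] * 5) == pytest.approx(0.5)

    def test_hand_ranked_six_patient_auc(self):
        # stenosis scores {0.9, 0.8, 0.4}, no-stenosis {0.7, 0.3, 0.2}
        # pairwise wins: 3 + 3 + 2 = 8 of 9 -> AUC 8/9
        scores = [0.9, 0.8, 0.4, 0.7, 0.3, 0.2]
        labels = [1, 1, 1, 0, 0, 0]
        assert rm.auc_mann_whitney(scores, labels) == pytest.approx(8 / 9)

    def test_auc_matches_sklearn_on_random_scores(self):
        gen = np.random.default_rng(8)
        scores = gen.normal(size=200)
        labels = (gen.random(200) < 0.4).astype(int)
        assert rm.auc_mann_whitney(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_auc_invariant_under_monotone_transform(self, seed):
        gen = np.random.default_rng(seed)
        scores = gen.normal(size=60)
        labels = np.r_[np.zeros(20), np.ones(40)].astype(int)
        gen.shuffle(labels)
        base = rm.auc_mann_whitney(scores, labels)
        assert rm.auc_mann_whitney(np.exp(2 * scores), labels) == pytest.approx(base)

    def test_accuracy_is_prevalence_weighted_mean_of_rates(self):
        X, y = make_xy(n=400, beta=(1.0,), seed=9)
        m = rm.fit_logistic(X, y)
        rep = rm.evaluate(m, X, y)
        blended = (rep.sensitivity_no_stenosis * rep.n_no_stenosis
                   + rep.specificity_stenosis * rep.n_stenosis) / len(y)
        assert rep.accuracy == pytest.approx(blended)


class TestImportanceScores:
    def test_single_variable_anchored_at_100(self):
        X, y = make_xy(n=500, beta=(0.8,), seed=2)
        m = rm.fit_logistic(X, y)
        imp = rm.importance_scores([m], ["x0"])
        assert imp.score.iloc[0] == pytest.approx(100.0)

    def test_linear_rescale_of_fold_mean_z(self):
        X, y = make_xy(n=800, beta=(0.9, 0.0), seed=4)
        m = rm.fit_logistic(X, y)
        m.params.loc["x0", "z"] = 4.0
        m.params.loc["x1", "z"] = 2.0
        imp = rm.importance_scores([m], ["x0", "x1"]).set_index("variable")
        assert imp.loc["x0", "score"] == pytest.approx(100.0)
        assert imp.loc["x1", "score"] == pytest.approx(50.0)

    def test_unselected_variable_contributes_zero(self):
        X, y = make_xy(n=800, beta=(0.9,), seed=4)
        m = rm.fit_logistic(X, y)
        imp = rm.importance_scores([m], ["x0", "ghost"]).set_index("variable")
        assert imp.loc["ghost", "score"] == 0.0


class TestSplitAndCrossvalidate:
    def test_same_seed_reproduces_everything(self):
        co = rm.finalize_cohort(rm.generate_cohort(rm.reference_cohort_spec(seed=31)))
        cand = ["age", "hypertension", "MTNR1B", "lipoprotein_a", "creatinine"]
        y = (co.group == "stenosis").astype(int)
        r1 = rm.split_and_crossvalidate(co, y, cand, rm.SplitPlan(seed=31))
        r2 = rm.split_and_crossvalidate(co, y, cand, rm.SplitPlan(seed=31))
        pd.testing.assert_frame_equal(r1.importance, r2.importance)
        assert r1.performance == r2.performance
        r3 = rm.split_and_crossvalidate(co, y, cand, rm.SplitPlan(seed=32))
        assert not np.array_equal(r1.test_index, r3.test_index)

    def test_tiny_cohort_fold_failure_raises(self):
        gen = np.random.default_rng(0)
        df = pd.DataFrame({"x": gen.normal(size=12)})
        y = np.r_[np.zeros(3), np.ones(9)].astype(int)
        with pytest.raises(ValueError):
            rm.split_and_crossvalidate(df, y, ["x"], rm.SplitPlan(folds=5, seed=0))

    def test_invalid_plan_rejected(self):
        with pytest.raises(ValueError):
            rm.SplitPlan(train_fraction=1.0).validate()

    def test_encode_features_maps_yes_no(self):
        df = pd.DataFrame({"flag": ["yes", "no"], "v": [1.5, 2.5]})
        X = encode_features(df, ["flag", "v"])
        assert list(X["flag"]) == [1.0, 0.0]
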