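"""Unit-level differential tests, logistic model, stepwise, LOOCV, ROC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import roc_curve

from simpo import (
    CRCModel,
    SimpoError,
    backward_stepwise,
    classification_summary,
    fit_logistic,
    loocv_predict,
    odds_ratio,
    roc_auc,
    simulate_epityper,
    unit_group_test,
    unit_shifts_for_auc,
)


class TestUnitGroupTest:
    def test_planted_shift_detected_with_negative_direction(self):
        flagged = []
        for seed in range(10):
            shift = np.zeros(15)
            shift[:6] = -0.15
            units, truth = simulate_epityper(
                n_case=100, n_control=50, case_shift=shift, seed=seed
            )
            res = unit_group_test(units, contrast="ctrl-vs-early")
            res = res.set_index("unit")
            planted = truth.units.loc[truth.units["case_shift"] < 0, "unit"]
            ok = [
                res.loc[u, "p_value"] <= 0.05 and res.loc[u, "difference"] < 0
                for u in planted
            ]
            flagged.append(np.mean(ok))
        assert np.mean(flagged) >= 0.9

    def test_null_calibration(self):
        rates = []
        for seed in range(10):
            units, _ = simulate_epityper(n_case=100, n_control=50, seed=seed)
            res = unit_group_test(units, contrast="all")
            rates.append((res["p_value"] < 0.05).mean())
        assert np.mean(rates) == pytest.approx(0.05, abs=0.03)

    def test_female_only_effect_found_in_female_stratum(self):
        hits_f, hits_m, hits_pooled = [], [], []
        for seed in range(10):
            shift = np.zeros(15)
            shift[0] = -0.12
            mod = np.ones(15)
            mod[0] = 0.0  # zero the effect in males
            units, _ = simulate_epityper(
                n_case=100, n_control=50, case_shift=shift, sex_modulation=mod,
                seed=seed,
            )
            strat = unit_group_test(units, contrast="all", stratify_by_sex=True)
            strat = strat.set_index(["unit", "stratum"])
            pooled = unit_group_test(units, contrast="all").set_index("unit")
            hits_f.append(strat.loc[("CpG_1", "female"), "p_value"] <= 0.05)
            hits_m.append(strat.loc[("CpG_1", "male"), "p_value"] <= 0.05)
            tf = abs(strat.loc[("CpG_1", "female"), "t"])
            tp = abs(pooled.loc["CpG_1", "t"])
            hits_pooled.append(tp < tf)
        assert np.mean(hits_f) >= 0.9
        assert np.mean(hits_m) <= 0.3
        assert np.mean(hits_pooled) >= 0.7  # pooling attenuates the female effect


class TestLogistic:
    def test_intercept_only_closed_form(self):
        y = pd.Series([1] * 30 + [0] * 70)
        X = pd.DataFrame(index=y.index)
        coefs = fit_logistic(X, y)
        assert coefs["intercept"] == pytest.approx(np.log(0.3 / 0.7), abs=1e-6)

    def test_uninformative_feature_slope_near_zero(self):
        rng = np.random.default_rng(0)
        y = pd.Series(rng.integers(0, 2, 400))
        X = pd.DataFrame({"f": rng.normal(size=400)})
        coefs = fit_logistic(X, y)
        assert abs(coefs["f"]) < 3 * (1 / np.sqrt(400 * 0.25))

    def test_known_coefficients_recovered(self):
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 500
            X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
            lin = -0.3 + 0.8 * X["a"] - 0.5 * X["b"]
            y = pd.Series((rng.random(n) < 1 / (1 + np.exp(-lin))).astype(int))
            coefs = fit_logistic(X, y)
            errs.append([coefs["a"] - 0.8, coefs["b"] + 0.5])
        mean_err = np.abs(np.mean(errs, axis=0))
        assert (mean_err < 0.15).all()

    def test_complete_separation_names_feature(self):
        X = pd.DataFrame({"sep": [0.0, 0.1, 0.2, 0.8, 0.9, 1.0]})
        y = pd.Series([0, 0, 0, 1, 1, 1])
        with pytest.raises(SimpoError, match="sep"):
            fit_logistic(X, y)


class TestBackwardStepwise:
    def test_informative_feature_retained_over_noise(self):
        kept = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 300
            X = pd.DataFrame(
                {"signal": rng.normal(size=n)}
                | {f"noise{i}": rng.normal(size=n) for i in range(5)}
            )
            lin = 2.0 * X["signal"]
            y = pd.Series((rng.random(n) < 1 / (1 + np.exp(-lin))).astype(int))
            kept += "signal" in backward_stepwise(X, y)
        assert kept >= 18

    def test_all_noise_shrinks_toward_minimal_model(self):
        sizes = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X = pd.DataFrame({f"n{i}": rng.normal(size=200) for i in range(6)})
            y = pd.Series(rng.integers(0, 2, 200))
            sizes.append(len(backward_stepwise(X, y)))
        assert np.mean(sizes) < 3  # descriptive: most noise features removed

    def test_single_feature_kept_iff_it_beats_intercept_only(self):
        rng = np.random.default_rng(3)
        n = 300
        x = rng.normal(size=n)
        y_info = pd.Series((rng.random(n) < 1 / (1 + np.exp(-2 * x))).astype(int))
        y_null = pd.Series(rng.integers(0, 2, n))
        X = pd.DataFrame({"x": x})
        assert backward_stepwise(X, y_info) == ["x"]
        assert backward_stepwise(X, y_null) == []

    def test_column_order_invariance(self):
        rng = np.random.default_rng(4)
        n = 200
        X = pd.DataFrame({c: rng.normal(size=n) for c in "abcd"})
        lin = 1.5 * X["b"] - 1.0 * X["d"]
        y = pd.Series((rng.random(n) < 1 / (1 + np.exp(-lin))).astype(int))
        sel1 = backward_stepwise(X, y)
        sel2 = backward_stepwise(X[list("dcba")], y)
        assert sorted(sel1) == sorted(sel2)


class TestLoocv:
    def test_shared_pattern_gets_similar_probabilities(self):
        X = pd.DataFrame({"x": [0.0] * 10 + [1.0] * 10})
        y = pd.Series([0] * 10 + [1] * 10)
        # add jitter to avoid separation
        rng = np.random.default_rng(0)
        X["x"] += rng.normal(0, 0.4, 20)
        probs = loocv_predict(X, y, ["x"])
        assert probs.notna().all()
        assert (probs.between(0, 1)).all()

    def test_null_features_auc_never_optimistic(self):
        """Under the null, pooled leave-one-out probabilities are known to be
        pessimistically biased (each fold's training set is depleted of the
        left-out sample's class), so the AUC sits below 0.5 on average and
        must never look like signal. Band frozen from an independent sklearn
        LeaveOneOut oracle run of the same design (mean ~0.36)."""
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame({"x": rng.normal(size=100)})
            y = pd.Series(rng.integers(0, 2, 100))
            probs = loocv_predict(X, y, ["x"])
            _, auc = roc_auc(probs, y)
            aucs.append(auc)
        assert np.mean(aucs) < 0.5  # no optimistic leakage
        assert np.mean(aucs) == pytest.approx(0.36, abs=0.1)

    def test_binormal_effect_recovers_closed_form_auc(self):
        """Single binormal feature with d' chosen for AUC 0.85 = Phi(d'/sqrt 2)."""
        d_prime = np.sqrt(2) * stats.norm.ppf(0.85)
        aucs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n_pos, n_neg = 75, 75
            x = np.r_[rng.normal(d_prime, 1, n_pos), rng.normal(0, 1, n_neg)]
            y = pd.Series(np.r_[np.ones(n_pos), np.zeros(n_neg)].astype(int))
            X = pd.DataFrame({"x": x})
            probs = loocv_predict(X, y, ["x"])
            _, auc = roc_auc(probs, y)
            aucs.append(auc)
        assert np.mean(aucs) == pytest.approx(0.85, abs=0.07)


class TestRocAuc:
    def test_perfect_separation_auc_one(self):
        p = pd.Series([0.9, 0.8, 0.2, 0.1])
        y = pd.Series([1, 1, 0, 0])
        _, auc = roc_auc(p, y)
        assert auc == 1.0

    def test_four_sample_worked_example_brute_force(self):
        p = pd.Series([0.9, 0.8, 0.4, 0.1])
        y = pd.Series([1, 0, 1, 0])
        _, auc = roc_auc(p, y)
        # brute force over all positive-negative pairs: (0.9,0.8)+, (0.9,0.1)+,
        # (0.4,0.8)-, (0.4,0.1)+ -> 3/4
        pairs = [(pi, pj) for pi, yi in zip(p, y) if yi == 1 for pj, yj in zip(p, y) if yj == 0]
        brute = np.mean([1.0 if a > b else 0.5 if a == b else 0.0 for a, b in pairs])
        assert auc == pytest.approx(brute) == pytest.approx(0.75)

    def test_mann_whitney_equals_trapezoidal_integration(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(10, 60))
            p = pd.Series(np.round(rng.random(n), 2))  # rounding forces ties
            y = pd.Series(rng.integers(0, 2, n))
            if y.nunique() < 2:
                continue
            _, auc = roc_auc(p, y)
            fpr, tpr, _ = roc_curve(y, p, drop_intermediate=False)
            assert auc == pytest.approx(np.trapezoid(tpr, fpr), abs=1e-10)

    def test_complement_identity(self):
        rng = np.random.default_rng(1)
        p = pd.Series(rng.random(50))
        y = pd.Series(rng.integers(0, 2, 50))
        _, a = roc_auc(p, y)
        _, b = roc_auc(1 - p, y)
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(SimpoError):
            roc_auc(pd.Series([0.1, 0.9]), pd.Series([1, 1]))


class TestClassificationSummary:
    def test_confusion_arithmetic_worked_example(self):
        assert odds_ratio(38, 10, 40, 12) == pytest.approx((38 * 40) / (10 * 12))
        assert odds_ratio(38, 10, 40, 12) == pytest.approx(12.67, abs=0.01)

    def test_haldane_correction_on_zero_cells(self):
        assert np.isfinite(odds_ratio(10, 0, 10, 0))
        assert odds_ratio(10, 0, 10, 0) == pytest.approx((10.5 * 10.5) / (0.5 * 0.5))

    def test_perfect_classifier_summary(self):
        # outcome coding: cancer=0 scored by low probability-of-normal
        probs = pd.Series([0.1] * 10 + [0.9] * 10)
        y = pd.Series([0] * 10 + [1] * 10)
        rep = classification_summary(probs, y)
        assert rep["sensitivity"] == 1.0
        assert rep["specificity"] == 1.0
        assert np.isfinite(rep["odds_ratio"])
        assert sum(rep["confusion"].values()) == 20

    def test_fixed_threshold_null_symmetry(self):
        sens_spec = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            probs = pd.Series(rng.random(200))
            y = pd.Series(rng.integers(0, 2, 200))
            rep = classification_summary(probs, y, threshold_rule="fixed",
                                         fixed_threshold=0.5)
            sens_spec.append(rep["sensitivity"] - (1 - rep["specificity"]))
        assert np.mean(sens_spec) == pytest.approx(0.0, abs=0.05)


class TestCRCModel:
    def test_end_to_end_early_stage_pipeline(self):
        shifts = unit_shifts_for_auc(0.83, 6)
        case_shift = np.zeros(15)
        case_shift[:6] = shifts
        units, _ = simulate_epityper(
            n_case=100, n_control=50, case_shift=case_shift, seed=0
        )
        report = CRCModel(units).fit(contrast="early")
        n_early_design = len(CRCModel(units).design("early")[0])
        assert n_early_design == 103  # 53 early-stage cases + 50 controls
        assert 0.5 < report.auc <= 1.0
        assert report.confusion["tp"] + report.confusion["fn"] == 53
        assert 0 <= report.sensitivity <= 1 and 0 <= report.specificity <= 1
        assert report.auc_refit >= report.auc - 0.05  # apparent AUC is optimistic
        text = report.summary()
        assert "LOOCV AUC" in text and "odds ratio" in text

    def test_label_shuffle_null_auc_not_optimistic(self):
        """Shuffled labels must not yield apparent signal; the mean sits at or
        below 0.5 (LOOCV's pessimistic null bias, see the methods note)."""
        units, _ = simulate_epityper(n_case=60, n_control=40, n_units=5, seed=1)
        X, y = CRCModel(units).design("all")
        rng = np.random.default_rng(2)
        aucs = []
        for _ in range(10):
            y_shuf = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
            probs = loocv_predict(X, y_shuf, list(X.columns[:2]))
            _, auc = roc_auc(probs, y_shuf)
            aucs.append(auc)
        assert np.mean(aucs) < 0.55
        assert np.mean(aucs) > 0.15

    def test_complete_case_restriction(self):
        units, _ = simulate_epityper(
            n_case=40, n_control=20, missing_rate=0.1, seed=3
        )
        X, y = CRCModel(units).design("all")
        assert X.drop(columns=["sex"]).notna().all().all()
        assert len(X) < 60
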