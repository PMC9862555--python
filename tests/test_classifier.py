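"""Logistic classifier, stepwise harness, cutoff selection, ablation."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from sputumflow.classifier import (IneligibleSampleError, LungFlowClassifier,
                                   ModelCoefficients, PREDICTORS,
                                   ablation_misclassifications, choose_cutoff,
                                   classify, fit_logistic, predict_probability,
                                   stepwise_select)
from sputumflow.synthetic import CohortSpec, generate_cohort

COEFS = ("b0", "b1", "b2", "b3", "b4", "b5")


def _model(**values) -> ModelCoefficients:
    v = {n: 0.0 for n in COEFS}
    v.update(values)
    return ModelCoefficients(values=v)


def _row(age=65.0, tcpp=200, fvs=900, linmid=800):
    return pd.Series({"age": age, "tcpp_r3_per10k": tcpp,
                      "fvs_r2_per10k": fvs, "cd206low_linmid_per10k": linmid})


class TestPredictProbability:
    def test_zero_coefficients_give_half(self):
        assert predict_probability(_model(), _row()) == pytest.approx(0.5)

    def test_known_linear_predictor(self):
        # lp = 1.386 -> p = expit(1.386) = 0.8
        m = _model(b0=1.386)
        assert predict_probability(m, _row()) == pytest.approx(0.8, abs=1e-3)
        m2 = _model(b0=-2.0, b2=0.01)
        lp = -2.0 + 0.01 * 200
        assert predict_probability(m2, _row()) == pytest.approx(expit(lp), abs=1e-9)

    def test_probability_increases_with_tcpp_when_b2_positive(self):
        m = _model(b0=-1.0, b2=0.005)
        probs = [predict_probability(m, _row(tcpp=v)) for v in (0, 100, 400, 900)]
        assert all(a < b for a, b in zip(probs, probs[1:]))

    def test_fvs_slope_sign_is_b3_plus_b5_age(self):
        m = _model(b3=0.004, b5=-0.0001)  # combined slope negative at age 65
        lo = predict_probability(m, _row(fvs=500))
        hi = predict_probability(m, _row(fvs=1500))
        assert hi < lo

    def test_ineligible_sample_refused(self):
        with pytest.raises(IneligibleSampleError):
            predict_probability(_model(), _row(), eligible=False)


class TestClassify:
    @pytest.mark.parametrize("p,cutoff,expected", [
        (0.28, 0.28, "non-cancer"),   # boundary goes to non-cancer
        (0.281, 0.28, "cancer"),
        (0.0, 0.0, "non-cancer"),
        (0.5, 0.5, "non-cancer"),
        (0.51, 0.5, "cancer"),
    ])
    def test_boundary_conventions(self, p, cutoff, expected):
        assert classify(p, cutoff) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify(1.2, 0.5)


class TestFitLogistic:
    @staticmethod
    def _simulate(n, seed, b=None):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame({
            "age": rng.normal(68, 8, n),
            "tcpp_r3_per10k": rng.poisson(250, n).astype(float),
            "fvs_r2_per10k": rng.poisson(1000, n).astype(float),
            "cd206low_linmid_per10k": rng.poisson(900, n).astype(float),
        })
        if b is None:
            b = dict(b1=0.10, b2=0.006, b3=0.002, b4=-0.001, b5=-2e-5)
        lp = (b["b1"] * X["age"] + b["b2"] * X["tcpp_r3_per10k"]
              + b["b3"] * X["fvs_r2_per10k"]
              + b["b4"] * X["cd206low_linmid_per10k"]
              + b["b5"] * X["age"] * X["fvs_r2_per10k"])
        b0 = -float(lp.mean())
        y = rng.random(n) < expit(b0 + lp)
        truth = {"b0": b0, **b}
        return X, y.astype(int), truth

    def test_parameter_recovery_within_three_standard_errors(self):
        X, y, truth = self._simulate(500, seed=11)
        m = fit_logistic(X, y)
        assert not m.penalized_fallback
        for name in COEFS:
            se = m.std_errors[name]
            assert abs(m.values[name] - truth[name]) < 3 * se, name

    def test_wald_type_one_error_rate_near_nominal(self):
        # labels independent of a fixed predictor: p < 0.05 in about 5%
        rng = np.random.default_rng(5)
        hits = 0
        reps = 50
        import statsmodels.api as sm
        for _ in range(reps):
            x = rng.normal(size=500)
            y = rng.random(500) < 0.3
            res = sm.Logit(y.astype(int),
                           np.column_stack([np.ones(500), x])).fit(disp=0)
            hits += res.pvalues[1] < 0.05
        assert hits / reps <= 0.14  # 5% nominal, within binomial slack at n=50

    def test_refit_is_bit_identical(self):
        X, y, _ = self._simulate(300, seed=2)
        m1, m2 = fit_logistic(X, y), fit_logistic(X, y)
        assert m1.values == m2.values
        assert m1.std_errors == m2.std_errors

    def test_balanced_symmetric_single_predictor_has_zero_intercept(self):
        import statsmodels.api as sm
        x = np.array([-2.0, -1.0, 1.0, 2.0] * 50)
        y = (x > 0).astype(int)
        y[::7] = 1 - y[::7]  # break separation symmetrically
        res = sm.Logit(y, np.column_stack([np.ones(x.size), x])).fit(disp=0)
        assert abs(res.params[0]) < 0.3

    def test_perfect_separation_flagged_with_fallback(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({
            "age": rng.normal(68, 8, 100),
            "tcpp_r3_per10k": np.r_[rng.uniform(0, 100, 50),
                                    rng.uniform(500, 900, 50)],
            "fvs_r2_per10k": rng.poisson(1000, 100).astype(float),
            "cd206low_linmid_per10k": rng.poisson(900, 100).astype(float),
        })
        y = np.r_[np.zeros(50), np.ones(50)].astype(int)
        with pytest.warns(UserWarning, match="separation"):
            m = fit_logistic(X, y)
        assert m.penalized_fallback

    def test_constant_predictor_rejected(self):
        X, y, _ = self._simulate(100, seed=3)
        X["tcpp_r3_per10k"] = 100.0
        with pytest.raises(ValueError, match="constant"):
            fit_logistic(X, y)

    def test_unknown_status_rows_excluded_from_fit(self):
        X, y, _ = self._simulate(300, seed=4)
        y = y.astype(float)
        y[:10] = np.nan  # status-unknown samples
        m = fit_logistic(X, y)
        m2 = fit_logistic(X.iloc[10:], y[10:])
        assert m.values == pytest.approx(m2.values)


class TestStepwise:
    def test_signal_variables_dominate_selection_frequencies(self):
        # moderate between-sample spread so each 100-sample split has
        # adequate power for both signal variables
        X, y = generate_cohort(CohortSpec(n_samples=400, seed=6,
                                          heterogeneity_sd=0.45))
        rng = np.random.default_rng(5)
        cand = X[["tcpp_r3_per10k", "cd206low_linmid_per10k"]].copy()
        for i in range(8):
            cand[f"noise{i}"] = rng.normal(size=len(X))
        freq, final = stepwise_select(cand, y, n_splits=60, seed=3)
        signal = ["tcpp_r3_per10k", "cd206low_linmid_per10k"]
        assert all(freq[s] >= 0.8 for s in signal)
        assert sorted(final) == sorted(signal)
        assert freq.drop(signal).max() < 0.3

    def test_all_noise_candidates_rarely_selected(self):
        # a large null cohort keeps chance cohort-level correlations small,
        # so no noise variable looks repeatably predictive across splits
        X, y = generate_cohort(CohortSpec(n_samples=800, seed=6))
        rng = np.random.default_rng(7)
        cand = pd.DataFrame({f"noise{i}": rng.normal(size=len(X))
                             for i in range(6)})
        freq, final = stepwise_select(cand, y, n_splits=60, seed=3)
        assert freq.max() <= 0.30
        assert final == []

    def test_single_split_fixed_seed_is_deterministic(self):
        X, y = generate_cohort(CohortSpec(n_samples=200, seed=1))
        cand = X[PREDICTORS].copy()
        f1, s1 = stepwise_select(cand, y, n_splits=1, seed=9)
        f2, s2 = stepwise_select(cand, y, n_splits=1, seed=9)
        pd.testing.assert_series_equal(f1, f2)
        assert s1 == s2

    def test_infeasible_split_sizes_rejected(self):
        X, y = generate_cohort(CohortSpec(n_samples=60, cancer_fraction=0.1,
                                          seed=1))
        with pytest.raises(ValueError, match="infeasible"):
            stepwise_select(X[PREDICTORS], y, n_splits=2, split_size=100,
                            cancer_per_split=20, seed=0)


class TestChooseCutoff:
    def test_perfect_separation(self):
        p = np.r_[np.full(50, 0.1), np.full(50, 0.9)]
        y = np.r_[np.zeros(50), np.ones(50)].astype(int)
        cutoff, roc, auc = choose_cutoff(p, y)
        assert auc == 1.0
        assert 0.1 < cutoff < 0.9
        sens = (p[y == 1] > cutoff).mean()
        spec = (p[y == 0] <= cutoff).mean()
        assert sens == spec == 1.0

    def test_random_labels_give_half_auc(self):
        rng = np.random.default_rng(8)
        p = rng.random(1000)
        y = rng.integers(0, 2, 1000)
        _, _, auc = choose_cutoff(p, y)
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            choose_cutoff([0.2, 0.6], [1, 1])


def test_ablation_never_beats_full_model_on_average():
    """Dropping any predictor group does not reduce misclassifications.

    Mirrors the predictor-drop table: models are compared on the cohort
    they were fitted to, so a dropped term can only lose information.
    """
    deficits = {g: 0.0 for g in ("age", "tcpp_r3", "cd206low_linmid",
                                 "fvs_r2", "interaction")}
    n_seeds = 10
    for seed in range(n_seeds):
        X, y = generate_cohort(CohortSpec(n_samples=300, seed=seed))
        errors = ablation_misclassifications(X, y, X, y)
        for g in deficits:
            deficits[g] += errors[g] - errors["none"]
    for g, total in deficits.items():
        assert total / n_seeds >= 0.0, g  # ablated models are no better


def test_model_json_roundtrip(tmp_path):
    m = ModelCoefficients(
        values={n: i * 0.1 for i, n in enumerate(COEFS)},
        std_errors={n: 0.01 for n in COEFS},
        wald_p={n: 0.02 for n in COEFS})
    path = tmp_path / "model.json"
    m.to_json(path, cutoff=0.28, seed=1)
    back = ModelCoefficients.from_json(path)
    assert back.values == m.values
    assert back.wald_p == m.wald_p


def test_estimator_follows_sklearn_conventions():
    from sklearn.base import clone
    X, y = generate_cohort(CohortSpec(n_samples=200, seed=4))
    clf = LungFlowClassifier(cutoff=0.3)
    assert clone(clf).get_params() == {"cutoff": 0.3}
    clf.fit(X, y)
    assert hasattr(clf, "coef_") and clf.classes_.tolist() == [0, 1]
    proba = clf.predict_proba(X)
    np.testing.assert_allclose(proba.sum(axis=1), 1.0)
    assert set(np.unique(clf.predict(X))) <= {0, 1}
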