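"""Final model fitting, confusion-matrix metrics, regression tables."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcrtsig.evaluate import (
    EvaluationReport,
    FittedSignatureModel,
    evaluate,
    fit_final_model,
    multivariate_table,
    univariate_table,
)
from conftest import make_matrix


def strong_gene_matrix(seed=0, n=40, effect=2.0):
    rng = np.random.default_rng(seed)
    y = np.array([True] * (n // 2) + [False] * (n // 2))
    data = rng.normal(6, 1, size=(3, n))
    data[0, y] += effect  # gene G0 up in responders
    m = make_matrix(data)
    labels = {s: bool(v) for s, v in zip(m.sample_ids, y)}
    return m, labels


def test_confusion_metrics_arithmetic():
    r = EvaluationReport(tp=9, fn=1, tn=8, fp=2)
    assert r.accuracy == pytest.approx(0.85)
    assert r.sensitivity == pytest.approx(0.90)
    assert r.specificity == pytest.approx(0.80)
    assert r.ppv == pytest.approx(9 / 11)
    assert r.npv == pytest.approx(8 / 9)


def test_degenerate_predictions_give_undefined_not_nan():
    r = EvaluationReport(tp=10, fn=0, tn=0, fp=5)  # everyone predicted positive
    assert r.specificity == 0.0
    assert r.npv is None
    assert not any(
        isinstance(v, float) and math.isnan(v) for v in r.as_dict().values() if v is not None
    )


@settings(derandomize=True, max_examples=200)
@given(
    tp=st.integers(0, 200), fp=st.integers(0, 200),
    tn=st.integers(0, 200), fn=st.integers(0, 200),
)
def test_confusion_identities_hold_for_all_matrices(tp, fp, tn, fn):
    r = EvaluationReport(tp=tp, fp=fp, tn=tn, fn=fn)
    if r.total:
        assert r.accuracy == pytest.approx((tp + tn) / (tp + fp + tn + fn))
    for value, num, den in [
        (r.sensitivity, tp, tp + fn),
        (r.specificity, tn, tn + fp),
        (r.ppv, tp, tp + fp),
        (r.npv, tn, tn + fn),
    ]:
        if den:
            assert value == pytest.approx(num / den)
            assert 0.0 <= value <= 1.0
        else:
            assert value is None


def test_fit_final_model_deterministic_and_sign_correct():
    m, labels = strong_gene_matrix()
    f1 = fit_final_model(["G0"], m, labels)
    f2 = fit_final_model(["G0"], m, labels)
    np.testing.assert_array_equal(f1.params, f2.params)
    assert f1.params[1] > 0  # up-in-responder gene gets a positive coefficient
    # probabilities are monotone in the linear predictor
    lp = f1.linear_predictor(m)
    prob = f1.predict_proba(m)
    assert np.all(np.diff(prob[np.argsort(lp)]) >= 0)


def test_model_dichotomy_splits_training_at_median():
    m, labels = strong_gene_matrix()
    f = fit_final_model(["G0"], m, labels)
    high = f.dichotomize(m)
    assert abs(int(high.sum()) - m.n_samples // 2) <= 1


def test_coefficient_count_validated():
    with pytest.raises(ValueError, match="coefficient count"):
        FittedSignatureModel(("a", "b"), np.zeros(2), score_threshold=0.0)


def test_evaluate_matches_manual_confusion():
    m, labels = strong_gene_matrix(effect=5.0)
    f = fit_final_model(["G0"], m, labels)
    r = evaluate(f, m, labels)
    assert r.total == m.n_samples
    assert r.accuracy == pytest.approx(1.0)


def closed_form_binary_logit(table):
    """Log-odds-ratio and SE from a 2x2 table: the analytic oracle for a
    single binary covariate logistic regression."""
    a, b, c, d = table  # exposed-pos, exposed-neg, unexposed-pos, unexposed-neg
    coef = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return coef, se


def test_binary_covariate_fit_equals_two_by_two_closed_form():
    a, b, c, d = 15, 9, 7, 19
    x = np.array([1.0] * (a + b) + [0.0] * (c + d))
    y = pd.Series([1.0] * a + [0.0] * b + [1.0] * c + [0.0] * d)
    tab = univariate_table(pd.DataFrame({"exposure": x}), y)
    coef, se = closed_form_binary_logit((a, b, c, d))
    assert tab.loc[0, "coef"] == pytest.approx(coef, abs=1e-6)
    assert tab.loc[0, "se"] == pytest.approx(se, abs=1e-6)


def test_wald_and_ci_identities():
    rng = np.random.default_rng(2)
    x = rng.normal(size=120)
    y = pd.Series((rng.random(120) < 1 / (1 + np.exp(-0.7 * x))).astype(float))
    tab = univariate_table(pd.DataFrame({"x": x}), y)
    row = tab.iloc[0]
    assert row["z"] == pytest.approx(row["coef"] / row["se"], abs=1e-9)
    assert row["ci95_low"] == pytest.approx(
        math.exp(row["coef"] - 1.959963984540054 * row["se"]), abs=1e-6
    )
    assert row["ci95_high"] == pytest.approx(
        math.exp(row["coef"] + 1.959963984540054 * row["se"]), abs=1e-6
    )
    from scipy.stats import norm

    assert row["p"] == pytest.approx(2 * norm.sf(abs(row["z"])), abs=1e-9)


def test_quasi_separated_covariate_reported_with_flag():
    # one category almost determines the outcome -> huge coef and SE
    x = np.array([0.0] * 58 + [1.0] * 2)
    y = pd.Series(np.array([0.45] * 58 > np.random.default_rng(3).random(58)).tolist()
                  + [True, True], dtype=float)
    tab = univariate_table(pd.DataFrame({"m_stage": x}), y)
    assert bool(tab.loc[0, "separation_flag"])
    assert np.isfinite(tab.loc[0, "coef"])


def test_single_feature_multivariate_equals_univariate():
    rng = np.random.default_rng(4)
    x = rng.normal(size=100)
    y = pd.Series((rng.random(100) < 1 / (1 + np.exp(-x))).astype(float))
    feats = pd.DataFrame({"x": x})
    uni = univariate_table(feats, y)
    multi = multivariate_table(feats, y)
    assert multi.loc[0, "coef"] == pytest.approx(uni.loc[0, "coef"], abs=1e-8)
    assert multi.loc[0, "se"] == pytest.approx(uni.loc[0, "se"], abs=1e-8)


def test_rank_deficiency_names_collinear_columns():
    rng = np.random.default_rng(5)
    x = rng.normal(size=50)
    feats = pd.DataFrame({"a": x, "b": 2 * x})
    y = pd.Series((rng.random(50) < 0.5).astype(float))
    with pytest.raises(ValueError, match="collinear"):
        multivariate_table(feats, y)


def test_no_confounding_multivariate_matches_univariate():
    """With independent covariates the adjusted OR equals the crude OR."""
    rng = np.random.default_rng(6)
    n = 4000
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    y = pd.Series((rng.random(n) < 1 / (1 + np.exp(-(0.8 * x1)))).astype(float))
    feats = pd.DataFrame({"x1": x1, "x2": x2})
    uni = univariate_table(feats[["x1"]], y)
    multi = multivariate_table(feats, y)
    assert multi.loc[0, "odds_ratio"] == pytest.approx(
        uni.loc[0, "odds_ratio"], rel=0.05
    )
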