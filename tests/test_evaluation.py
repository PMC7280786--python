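"""Bias correction, brain-PAD, metrics and the univariate age screen."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import pandas as pd

from brainage import (
    BiasModel,
    PhenotypeTable,
    brain_pad,
    brain_pad_table,
    correct,
    fit_bias,
    metrics,
    univariate_age_screen,
)
from brainage.evaluation import bonferroni_threshold


def test_identity_predictions_give_unit_bias_line():
    ages = np.array([50.0, 55.0, 60.0, 70.0])
    b = fit_bias(ages, ages)
    assert b.slope == pytest.approx(1.0)
    assert b.intercept == pytest.approx(0.0, abs=1e-10)


def test_exact_affine_predictions_recovered():
    ages = np.linspace(45, 80, 20)
    b = fit_bias(ages, 0.5 * ages + 10.0)
    assert b.slope == pytest.approx(0.5)
    assert b.intercept == pytest.approx(10.0)


def test_five_point_toy_matches_normal_equations():
    ages = np.array([48.0, 52.0, 61.0, 70.0, 77.0])
    preds = np.array([55.0, 50.0, 63.0, 66.0, 71.0])
    b = fit_bias(ages, preds)
    sxx = np.sum((ages - ages.mean()) ** 2)
    sxy = np.sum((ages - ages.mean()) * (preds - preds.mean()))
    assert b.slope == pytest.approx(sxy / sxx)
    assert b.intercept == pytest.approx(preds.mean() - (sxy / sxx) * ages.mean())


def test_correction_inverts_published_bias_line():
    """Slope 0.59, intercept 24.7: raw 59.8 corrects to (59.8-24.7)/0.59."""
    b = BiasModel(slope=0.59, intercept=24.7, fit_n=100)
    assert correct(b, np.array([59.8]))[0] == pytest.approx((59.8 - 24.7) / 0.59)


def test_identity_bias_is_noop_and_correct_is_exact_inverse():
    b = BiasModel(slope=1.0, intercept=0.0, fit_n=10)
    raw = np.array([50.0, 60.0])
    assert np.allclose(correct(b, raw), raw)
    b2 = BiasModel(slope=0.7, intercept=12.0, fit_n=10)
    roundtrip = b2.intercept + b2.slope * correct(b2, raw)
    assert np.allclose(roundtrip, raw, atol=1e-10)


def test_near_zero_slope_rejected():
    with pytest.raises(ValueError, match="slope"):
        BiasModel(slope=1e-9, intercept=0.0, fit_n=10)


def test_brain_pad_definition():
    assert brain_pad(np.array([60.0]), np.array([65.0]))[0] == pytest.approx(5.0)
    assert brain_pad(np.array([60.0]), np.array([60.0]))[0] == 0.0
    with pytest.raises(ValueError):
        brain_pad(np.array([60.0]), np.array([60.0, 61.0]))


def test_pad_uncorrelated_with_age_on_fitting_cohort(rng):
    """OLS residual orthogonality: corr(age, brain-PAD) = 0 on the bias cohort."""
    ages = rng.uniform(45, 80, 400)
    raw = 25 + 0.6 * ages + rng.normal(0, 4, 400)
    b = fit_bias(ages, raw)
    tab = brain_pad_table(pd.Series(ages), pd.Series(raw), b)
    assert abs(np.corrcoef(ages, tab["brain_pad"])[0, 1]) < 1e-10
    assert np.allclose(tab["brain_pad"], tab["corrected_pred"] - tab["age"])


def test_metrics_hand_example():
    m = metrics(np.array([60.0, 62.0, 64.0]), np.array([61.0, 62.0, 63.0]))
    assert m.mae == pytest.approx(2.0 / 3.0)
    assert m.age_bias == pytest.approx(-1.0)
    assert m.r == pytest.approx(1.0)


def test_perfect_predictions_degenerate_bias():
    ages = np.array([50.0, 60.0, 70.0])
    m = metrics(ages, ages)
    assert m.r == pytest.approx(1.0) and m.mae == 0.0
    assert m.age_bias == 0.0 and m.degenerate


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_metrics_match_brute_force_formulas(seed):
    rng = np.random.default_rng(seed)
    ages = rng.uniform(45, 80, 30)
    preds = rng.uniform(40, 90, 30)
    m = metrics(ages, preds)
    assert m.r == pytest.approx(stats.pearsonr(ages, preds).statistic, abs=1e-12)
    assert m.r2 == pytest.approx(m.r**2)
    assert m.mae == pytest.approx(np.mean(np.abs(preds - ages)))
    assert m.age_bias == pytest.approx(
        stats.pearsonr(ages, preds - ages).statistic, abs=1e-12
    )


def test_bonferroni_threshold_for_1079_tests():
    thr = bonferroni_threshold(0.05, 1079)
    assert thr == pytest.approx(4.6e-5, rel=0.01)


def test_univariate_screen_matches_t_closed_form(rng):
    n = 10
    ages = rng.uniform(45, 80, n)
    df = pd.DataFrame(
        {
            "strong": ages + rng.normal(0, 1, n),
            "noise": rng.normal(size=n),
            "const": np.ones(n),
        },
        index=[f"s{i}" for i in range(n)],
    )
    tab = PhenotypeTable(df, {c: "T1" for c in df.columns})
    out = univariate_age_screen(tab, ages)
    for name in ("strong", "noise"):
        r, p = stats.pearsonr(df[name], ages)
        assert out.loc[name, "r"] == pytest.approx(r, abs=1e-10)
        assert out.loc[name, "p"] == pytest.approx(p, rel=1e-8)
    assert out.loc["const", "p"] == 1.0
    assert out.loc["const", "constant"]


def test_perfectly_correlated_phenotype_significant(rng):
    ages = rng.uniform(45, 80, 50)
    df = pd.DataFrame({"exact": 2.0 * ages - 10.0}, index=[f"s{i}" for i in range(50)])
    tab = PhenotypeTable(df, {"exact": "T1"})
    out = univariate_age_screen(tab, ages)
    assert out.loc["exact", "p"] < 1e-30
    assert out.loc["exact", "bonferroni_significant"]
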