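"""Penalized age model: KKT boundary, brute-force oracle, CV one-SE rule."""

import numpy as np
import pandas as pd
import pytest

from brainage import fit_lasso, fit_lasso_cv, predict_raw
from brainage.lasso import lambda_max, lasso_objective, make_lambda_grid
from brainage.normalization import apply_normalizer, fit_normalizer
from brainage.tables import PhenotypeTable


def _toy(n=50, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 2))
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    y = 60 + 2.0 * X[:, 0] - 1.0 * X[:, 1] + rng.normal(0, 0.5, n)
    return X, y


def test_lambda_at_or_above_lambda_max_zeroes_everything():
    X, y = _toy()
    lam = lambda_max(X, y)
    for factor in (1.0, 1.5):
        model = fit_lasso(X, y, lam * factor)
        assert model.n_nonzero == 0
        assert model.intercept == pytest.approx(np.mean(y))


def brute_force_lasso_2d(X, y, lam, span=3.0, iters=4, grid=101):
    """Grid minimization of the penalized objective over (b1, b2)."""
    ybar = y.mean()
    center = np.zeros(2)
    width = span
    for _ in range(iters):
        b1 = np.linspace(center[0] - width, center[0] + width, grid)
        b2 = np.linspace(center[1] - width, center[1] + width, grid)
        B1, B2 = np.meshgrid(b1, b2, indexing="ij")
        betas = np.stack([B1.ravel(), B2.ravel()], axis=1)
        resid = y[:, None] - ybar - X @ betas.T
        obj = 0.5 * np.mean(resid**2, axis=0) + lam * np.abs(betas).sum(axis=1)
        center = betas[np.argmin(obj)]
        width = 2.5 * width / (grid - 1)
    return center


@pytest.mark.parametrize("lam_frac", [0.05, 0.3, 0.7])
def test_two_predictor_fit_matches_grid_oracle(lam_frac):
    X, y = _toy()
    lam = lam_frac * lambda_max(X, y)
    model = fit_lasso(X, y, lam)
    oracle = brute_force_lasso_2d(X, y, lam)
    assert np.max(np.abs(model.coefficients.to_numpy() - oracle)) < 1e-4


def test_solver_objective_not_above_oracle_objective():
    X, y = _toy(seed=3)
    lam = 0.2 * lambda_max(X, y)
    model = fit_lasso(X, y, lam)
    oracle = brute_force_lasso_2d(X, y, lam)
    f_model = lasso_objective(X, y, model.intercept, model.coefficients.to_numpy(), lam)
    f_oracle = lasso_objective(X, y, y.mean(), oracle, lam)
    assert f_model <= f_oracle + 1e-6


def test_noiseless_single_predictor_interpolates():
    rng = np.random.default_rng(1)
    x = rng.normal(size=(80, 1))
    y = 55.0 + 3.0 * x[:, 0]
    model = fit_lasso(x, y, 1e-10)
    preds = model.intercept + x @ model.coefficients.to_numpy()
    assert np.max(np.abs(preds - y)) < 1e-8


def test_cv_one_se_rule_invariant():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(120, 8))
    y = 60 + X[:, 0] * 2 + rng.normal(0, 1, 120)
    cv, model = fit_lasso_cv(X, y, k_folds=5, seed=0, n_lambdas=40)
    assert cv.lambda_1se >= cv.lambda_min
    i_min = int(np.argmin(cv.cv_mean_error))
    thr = cv.cv_mean_error[i_min] + cv.cv_se[i_min]
    larger = cv.lambda_grid > cv.lambda_1se
    # lambda_1se is the LARGEST grid value under the threshold
    assert cv.cv_mean_error[np.nonzero(cv.lambda_grid == cv.lambda_1se)[0][0]] <= thr
    assert np.all(cv.cv_mean_error[larger] > thr)
    assert model.lambda_ == cv.lambda_1se


def test_cv_deterministic_under_seed():
    X, y = _toy(n=80, seed=5)
    cv1, m1 = fit_lasso_cv(X, y, k_folds=5, seed=3, n_lambdas=30)
    cv2, m2 = fit_lasso_cv(X, y, k_folds=5, seed=3, n_lambdas=30)
    assert np.array_equal(cv1.cv_mean_error, cv2.cv_mean_error)
    assert m1.coefficients.equals(m2.coefficients)


def test_k_folds_exceeding_n_errors():
    X, y = _toy(n=5)
    with pytest.raises(ValueError):
        fit_lasso_cv(X, y, k_folds=10)


def test_non_finite_inputs_rejected():
    X, y = _toy()
    X[0, 0] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        fit_lasso_cv(X, y, k_folds=5)


def test_prediction_invariant_to_column_order(small_cohort):
    pheno, cohort, _ = small_cohort
    ids = pheno.subject_ids[:200]
    params = fit_normalizer(pheno, ids)
    Xn = apply_normalizer(params, pheno, ids)
    y = cohort.ages(ids)
    lam = 0.3 * lambda_max(Xn.values.to_numpy(), y)
    model = fit_lasso(Xn.values, y, lam)
    model.normalization = params
    preds = predict_raw(model, pheno, ids[:20])
    shuffled_cols = list(reversed(pheno.phenotype_names))
    pheno_shuffled = pheno.subset(columns=shuffled_cols)
    preds2 = predict_raw(model, pheno_shuffled, ids[:20])
    assert np.allclose(preds.to_numpy(), preds2.to_numpy(), atol=1e-10)


def test_all_zero_features_predict_intercept():
    model = fit_lasso(np.random.default_rng(0).normal(size=(30, 3)), np.full(30, 61.0), 0.5)
    df = pd.DataFrame(np.zeros((2, 3)), columns=["x0", "x1", "x2"], index=["a", "b"])
    tab = PhenotypeTable(df, {c: "T1" for c in df.columns})
    preds = predict_raw(model, tab)
    assert np.allclose(preds, model.intercept)


def test_grid_is_descending_from_lambda_max():
    X, y = _toy()
    grid = make_lambda_grid(X, y, n_lambdas=20)
    assert grid[0] == pytest.approx(lambda_max(X, y))
    assert np.all(np.diff(grid) < 0)
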