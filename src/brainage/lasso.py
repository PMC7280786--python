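"""L1-penalized age prediction with cross-validated penalty (one-SE rule).

The model minimizes

    (1 / 2n) * sum_i (y_i - b0 - x_i' b)^2  +  lambda * sum_j |b_j|

over a descending log-spaced lambda grid anchored at lambda_max (the
smallest penalty that zeroes every coefficient, ``max_j |x_j'(y - ybar)| / n``).
Ten-fold cross-validation selects ``lambda.1se``: the largest grid value
whose mean CV error is within one standard error of the minimum.  The final
model is refit on all rows at that penalty.  Coordinate descent is
delegated to scikit-learn, whose objective is exactly the one above.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, lasso_path

from .normalization import NormalizationParams, apply_normalizer, fit_normalizer
from .tables import CohortTable, PhenotypeTable

_TOL = 1e-8        # duality-gap tolerance for single-penalty (final/bootstrap) fits
_TOL_PATH = 1e-4   # CV fold paths only rank penalties; a looser gap suffices
_MAX_ITER = 200_000


@dataclass
class CVResult:
    lambda_grid: np.ndarray  # descending
    cv_mean_error: np.ndarray  # mean squared prediction error per lambda
    cv_se: np.ndarray  # SE across the k fold-level errors
    lambda_min: float
    lambda_1se: float
    k_folds: int
    seed: int

    def __post_init__(self) -> None:
        assert self.lambda_1se >= self.lambda_min


@dataclass
class AgeModel:
    intercept: float
    coefficients: pd.Series  # normalized-phenotype scale
    lambda_: float
    normalization: NormalizationParams | None = None
    seed: int | None = None

    @property
    def n_nonzero(self) -> int:
        return int((self.coefficients != 0.0).sum())

    def nonzero(self) -> pd.Series:
        return self.coefficients[self.coefficients != 0.0]

    def to_json(self, path: str | Path, cv: CVResult | None = None) -> None:
        obj = {
            "intercept": float(self.intercept),
            "lambda": float(self.lambda_),
            "seed": self.seed,
            "n_nonzero": self.n_nonzero,
            "coefficients": {k: float(v) for k, v in self.nonzero().items()},
            "phenotype_order": self.coefficients.index.tolist(),
            "normalization": None
            if self.normalization is None
            else self.normalization.to_jsonable(),
        }
        if cv is not None:
            obj["cv"] = {
                "lambda_min": float(cv.lambda_min),
                "lambda_1se": float(cv.lambda_1se),
                "k_folds": cv.k_folds,
                "lambda_grid": [float(v) for v in cv.lambda_grid],
                "cv_mean_error": [float(v) for v in cv.cv_mean_error],
                "cv_se": [float(v) for v in cv.cv_se],
            }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "AgeModel":
        with open(path) as fh:
            obj = json.load(fh)
        order = obj["phenotype_order"]
        coef = pd.Series(0.0, index=order)
        for k, v in obj["coefficients"].items():
            coef[k] = v
        norm = None
        if obj["normalization"] is not None:
            nz = obj["normalization"]
            norm = NormalizationParams(
                means=pd.Series(nz["means"])[order],
                sds=pd.Series(nz["sds"])[order],
                dropped_phenotypes=nz["dropped_phenotypes"],
            )
        return cls(
            intercept=obj["intercept"],
            coefficients=coef,
            lambda_=obj["lambda"],
            normalization=norm,
            seed=obj.get("seed"),
        )


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which every LASSO coefficient is exactly zero (KKT)."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    return float(np.max(np.abs(Xc.T @ yc)) / len(y))


def make_lambda_grid(
    X: np.ndarray, y: np.ndarray, n_lambdas: int = 100, min_ratio: float = 1e-3
) -> np.ndarray:
    lam_max = lambda_max(X, y)
    if lam_max <= 0:
        raise ValueError("degenerate design: lambda_max is zero")
    return np.geomspace(lam_max, min_ratio * lam_max, n_lambdas)


def _fold_assignment(n: int, k: int, seed: int) -> np.ndarray:
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, k)):
        folds[chunk] = f
    return folds


def _path_coefs(X: np.ndarray, y: np.ndarray, lambdas: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Coefficients along the grid with explicit centering (no intercept in path)."""
    mu = X.mean(axis=0)
    ybar = y.mean()
    _, coefs, _ = lasso_path(
        X - mu, y - ybar, alphas=lambdas, tol=_TOL_PATH, max_iter=_MAX_ITER
    )
    return coefs, mu, ybar


def fit_lasso_cv(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    k_folds: int = 10,
    seed: int = 0,
    lambdas: np.ndarray | None = None,
    n_lambdas: int = 100,
    min_ratio: float = 1e-3,
) -> tuple[CVResult, AgeModel]:
    """Cross-validate the penalty, pick lambda.1se, refit on all rows."""
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [f"x{j}" for j in range(np.shape(X)[1])]
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float)
    n = len(ya)
    if not (np.all(np.isfinite(Xa)) and np.all(np.isfinite(ya))):
        raise ValueError("non-finite values in X or y")
    if k_folds > n:
        raise ValueError("k_folds cannot exceed the number of rows")
    if lambdas is None:
        lambdas = make_lambda_grid(Xa, ya, n_lambdas=n_lambdas, min_ratio=min_ratio)
    lambdas = np.sort(np.asarray(lambdas, dtype=float))[::-1]

    folds = _fold_assignment(n, k_folds, seed)
    fold_err = np.empty((k_folds, len(lambdas)))
    for f in range(k_folds):
        tr, va = folds != f, folds == f
        coefs, mu, ybar = _path_coefs(Xa[tr], ya[tr], lambdas)
        preds = (Xa[va] - mu) @ coefs + ybar  # (n_va, n_lambdas)
        fold_err[f] = np.mean((preds - ya[va][:, None]) ** 2, axis=0)
    cv_mean = fold_err.mean(axis=0)
    cv_se = fold_err.std(axis=0, ddof=1) / np.sqrt(k_folds)

    i_min = int(np.argmin(cv_mean))
    threshold = cv_mean[i_min] + cv_se[i_min]
    i_1se = int(np.nonzero(cv_mean <= threshold)[0][0])  # grid descending: first = largest lambda
    cv = CVResult(
        lambda_grid=lambdas,
        cv_mean_error=cv_mean,
        cv_se=cv_se,
        lambda_min=float(lambdas[i_min]),
        lambda_1se=float(lambdas[i_1se]),
        k_folds=k_folds,
        seed=seed,
    )
    model = fit_lasso(Xa, ya, cv.lambda_1se, names=names, seed=seed)
    return cv, model


def fit_lasso(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    lambda_: float,
    names: Sequence[str] | None = None,
    seed: int | None = None,
) -> AgeModel:
    """Single LASSO fit at a fixed penalty (with intercept)."""
    if names is None:
        names = list(X.columns) if isinstance(X, pd.DataFrame) else [f"x{j}" for j in range(np.shape(X)[1])]
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float)
    est = Lasso(alpha=lambda_, fit_intercept=True, tol=_TOL, max_iter=_MAX_ITER)
    est.fit(Xa, ya)
    coef = pd.Series(est.coef_, index=list(names))
    return AgeModel(intercept=float(est.intercept_), coefficients=coef, lambda_=float(lambda_), seed=seed)


def lasso_objective(X: np.ndarray, y: np.ndarray, intercept: float, beta: np.ndarray, lambda_: float) -> float:
    """Penalized objective value; exposed for convergence checks and oracles."""
    resid = y - intercept - X @ beta
    return float(0.5 * np.mean(resid**2) + lambda_ * np.sum(np.abs(beta)))


def predict_raw(
    model: AgeModel, pheno: PhenotypeTable, ids: Sequence[str] | None = None
) -> pd.Series:
    """Raw (uncorrected) predicted age in years, applying the frozen normalization."""
    if model.normalization is not None:
        normed = apply_normalizer(model.normalization, pheno, ids)
        df = normed.values
    else:
        df = pheno.values if ids is None else pheno.values.loc[list(ids)]
        absent = [c for c in model.coefficients.index if c not in df.columns]
        if absent:
            raise ValueError(f"phenotype(s) required by model absent: {absent[:5]}")
        df = df[model.coefficients.index]
    pred = model.intercept + df.to_numpy() @ model.coefficients.to_numpy()
    return pd.Series(pred, index=df.index, name="raw_pred")


def train_age_model(
    pheno: PhenotypeTable,
    cohort: CohortTable,
    train_ids: Sequence[str],
    seed: int = 0,
    k_folds: int = 10,
    lambdas: np.ndarray | None = None,
    n_lambdas: int = 100,
    min_ratio: float = 1e-3,
    columns: Sequence[str] | None = None,
) -> tuple[CVResult, AgeModel]:
    """Normalize on the training ids, cross-validate and fit the age model."""
    sub = pheno if columns is None else pheno.subset(columns=columns)
    params = fit_normalizer(sub, train_ids)
    Xn = apply_normalizer(params, sub, train_ids)
    y = cohort.ages(list(train_ids))
    cv, model = fit_lasso_cv(
        Xn.values, y, k_folds=k_folds, seed=seed, lambdas=lambdas,
        n_lambdas=n_lambdas, min_ratio=min_ratio,
    )
    model.normalization = params
    return cv, model
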