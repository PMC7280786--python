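"""Bootstrap confidence intervals for the penalized coefficients.

LASSO under collinear predictors can place weight on an arbitrary member of
a correlated group; resampling with replacement and refitting at the fixed
penalty yields a per-phenotype coefficient distribution that exposes this
instability.  A phenotype is *informative* when its 95% basic-bootstrap
interval excludes zero.

The basic bootstrap interval around the full-data estimate theta_hat is

    [2*theta_hat - q_{0.975},  2*theta_hat - q_{0.025}]

with q the resample quantiles (type-7 linear interpolation).  Resamples in
which the phenotype's coefficient is shrunk to zero contribute genuine
zeros to the distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso

from .lasso import _MAX_ITER, _TOL


def basic_ci(
    theta_hat: float | np.ndarray, samples: np.ndarray, level: float = 0.95
) -> tuple[np.ndarray, np.ndarray]:
    """Basic-bootstrap interval(s); ``samples`` has resamples along axis 0."""
    alpha = 1.0 - level
    q_lo = np.quantile(samples, alpha / 2.0, axis=0, method="linear")
    q_hi = np.quantile(samples, 1.0 - alpha / 2.0, axis=0, method="linear")
    return 2.0 * np.asarray(theta_hat) - q_hi, 2.0 * np.asarray(theta_hat) - q_lo


@dataclass
class BootstrapSummary:
    table: pd.DataFrame  # index: phenotype; columns: mean_coef, ci_low, ci_high, informative
    n_boot: int
    seed: int
    lambda_: float
    n_degenerate_redraws: int = 0

    @property
    def informative_set(self) -> frozenset[str]:
        return frozenset(self.table.index[self.table["informative"]])


def bootstrap_lasso(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    lambda_: float,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    refit_lambda: bool = False,
    k_folds: int = 10,
) -> BootstrapSummary:
    """Resample rows with replacement, refit at the fixed penalty, form CIs.

    ``refit_lambda=True`` re-runs the full cross-validated penalty selection
    inside every resample instead of holding the main fit's penalty fixed;
    roughly 10x the cost, so off by default.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [f"x{j}" for j in range(np.shape(X)[1])]
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float)
    n = len(ya)

    est = Lasso(alpha=lambda_, fit_intercept=True, tol=_TOL, max_iter=_MAX_ITER)
    est.fit(Xa, ya)
    theta_hat = est.coef_.copy()

    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    boot = np.empty((n_boot, Xa.shape[1]))
    refit = Lasso(
        alpha=lambda_, fit_intercept=True, tol=_TOL, max_iter=_MAX_ITER, warm_start=True
    )
    n_redraw = 0
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        while np.all(idx == idx[0]):  # degenerate resample: every row identical
            n_redraw += 1
            idx = rng.integers(0, n, n)
        if refit_lambda:
            from .lasso import fit_lasso_cv

            _, bmodel = fit_lasso_cv(
                Xa[idx], ya[idx], k_folds=k_folds, seed=int(rng.integers(2**31))
            )
            boot[b] = bmodel.coefficients.to_numpy()
        else:
            refit.fit(Xa[idx], ya[idx])
            boot[b] = refit.coef_

    ci_low, ci_high = basic_ci(theta_hat, boot, level=level)
    table = pd.DataFrame(
        {
            "mean_coef": boot.mean(axis=0),
            "ci_low": ci_low,
            "ci_high": ci_high,
        },
        index=pd.Index(names, name="phenotype"),
    )
    table["informative"] = (table["ci_low"] > 0.0) | (table["ci_high"] < 0.0)
    return BootstrapSummary(
        table=table, n_boot=n_boot, seed=seed, lambda_=lambda_, n_degenerate_redraws=n_redraw
    )


def rank_informative(
    summary: BootstrapSummary, modality_of: dict[str, str] | None = None
) -> pd.DataFrame:
    """Informative phenotypes sorted by |mean coefficient|, report-table shape."""
    tab = summary.table[summary.table["informative"]].copy()
    tab = tab.reindex(tab["mean_coef"].abs().sort_values(ascending=False).index)
    if modality_of is not None:
        tab.insert(0, "modality", [modality_of.get(p, "") for p in tab.index])
    return tab.reset_index()
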