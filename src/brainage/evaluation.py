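"""Age-bias correction, brain-PAD, performance metrics and ablation runners.

Raw brain-age predictions regress to the mean: young subjects are predicted
old and vice versa, so predicted-minus-chronological age correlates
negatively with age.  The correction fits, on the training cohort, the OLS
line of raw prediction on age and inverts it:

    corrected = (raw - intercept) / slope

On the bias-fitting cohort itself, corr(age, corrected - age) is exactly
zero (OLS residuals are orthogonal to the predictor), which is asserted as
this module's central check.  Brain-PAD = corrected prediction - age;
positive values mean an older-appearing brain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .lasso import predict_raw, train_age_model
from .tables import CohortTable, PhenotypeTable

_SLOPE_FLOOR = 1e-8


@dataclass
class BiasModel:
    slope: float
    intercept: float
    fit_n: int
    fit_cohort: str = "training"

    def __post_init__(self) -> None:
        if abs(self.slope) < _SLOPE_FLOOR:
            raise ValueError("bias-correction slope is (near) zero; correction undefined")


@dataclass
class PerformanceMetrics:
    r: float
    r2: float
    mae: float
    age_bias: float
    n: int
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "r": self.r,
            "r2": self.r2,
            "mae": self.mae,
            "age_bias": self.age_bias,
            "n": self.n,
            "degenerate": self.degenerate,
        }


def fit_bias(ages: np.ndarray, raw_preds: np.ndarray, fit_cohort: str = "training") -> BiasModel:
    """OLS of raw predicted age (outcome) on chronological age (predictor)."""
    ages = np.asarray(ages, dtype=float)
    raw_preds = np.asarray(raw_preds, dtype=float)
    if len(ages) < 3:
        raise ValueError("need at least 3 subjects to fit the bias line")
    if np.var(ages) == 0:
        raise ValueError("zero age variance; bias line undefined")
    slope, intercept = np.polyfit(ages, raw_preds, 1)
    return BiasModel(slope=float(slope), intercept=float(intercept), fit_n=len(ages), fit_cohort=fit_cohort)


def correct(bias: BiasModel, raw_preds: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Invert the bias line: subtract the intercept, divide by the slope."""
    return (raw_preds - bias.intercept) / bias.slope


def brain_pad(
    ages: np.ndarray | pd.Series, corrected_preds: np.ndarray | pd.Series
) -> np.ndarray | pd.Series:
    ages = np.asarray(ages, dtype=float) if not isinstance(ages, pd.Series) else ages
    if len(ages) != len(corrected_preds):
        raise ValueError("ages and predictions have different lengths")
    return corrected_preds - ages


def brain_pad_table(
    ages: pd.Series, raw_preds: pd.Series, bias: BiasModel
) -> pd.DataFrame:
    """Per-subject raw, corrected and brain-PAD values (years)."""
    corrected = correct(bias, raw_preds)
    return pd.DataFrame(
        {
            "age": ages,
            "raw_pred": raw_preds,
            "corrected_pred": corrected,
            "brain_pad": corrected - ages,
        }
    )


def _safe_corr(a: np.ndarray, b: np.ndarray) -> tuple[float, bool]:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0, True
    return float(np.corrcoef(a, b)[0, 1]), False


def metrics(ages: np.ndarray, preds: np.ndarray) -> PerformanceMetrics:
    """Pearson r, squared-correlation R², MAE (years) and age bias."""
    ages = np.asarray(ages, dtype=float)
    preds = np.asarray(preds, dtype=float)
    if len(ages) < 3:
        raise ValueError("need at least 3 subjects")
    r, deg_r = _safe_corr(ages, preds)
    bias, deg_b = _safe_corr(ages, preds - ages)
    return PerformanceMetrics(
        r=r,
        r2=r * r,
        mae=float(np.mean(np.abs(preds - ages))),
        age_bias=bias,
        n=len(ages),
        degenerate=deg_r or deg_b,
    )


def univariate_age_screen(
    pheno: PhenotypeTable, ages: np.ndarray, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-phenotype Pearson correlation with age and Bonferroni screen.

    p-values use the exact t transform t = r*sqrt(n-2)/sqrt(1-r^2); constant
    phenotypes are flagged with r=0, p=1.
    """
    ages = np.asarray(ages, dtype=float)
    n = len(ages)
    if n < 3:
        raise ValueError("need at least 3 subjects")
    X = pheno.values.to_numpy(dtype=float)
    xc = X - X.mean(axis=0)
    yc = ages - ages.mean()
    sx = X.std(axis=0)
    sy = ages.std()
    constant = sx == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc.T @ yc) / (n * sx * sy)
    r = np.clip(np.where(constant, 0.0, r), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    p = np.where(np.abs(r) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), df=n - 2))
    p = np.where(constant, 1.0, p)
    threshold = alpha / pheno.values.shape[1]
    return pd.DataFrame(
        {
            "r": r,
            "p": p,
            "bonferroni_significant": p < threshold,
            "constant": constant,
        },
        index=pheno.values.columns,
    )


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    return alpha / n_tests


def _evaluate_model(model, pheno, cohort, val_ids) -> PerformanceMetrics:
    preds = predict_raw(model, pheno, val_ids)
    return metrics(cohort.ages(list(val_ids)), preds.to_numpy())


def run_single_modality(
    pheno: PhenotypeTable,
    cohort: CohortTable,
    train_ids: Sequence[str],
    val_ids: Sequence[str],
    seed: int = 0,
    k_folds: int = 10,
    n_lambdas: int = 60,
    min_ratio: float = 1e-2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit one model per modality; evaluate each on the validation ids.

    Returns the per-modality performance table and the correlation matrix of
    chronological age with each modality's predicted ages on the validation
    set (the cross-modality "ages" analysis).
    """
    modalities = pheno.modalities
    if len(modalities) < 2:
        raise ValueError("need at least 2 modalities")
    child_seeds = np.random.SeedSequence(seed).generate_state(len(modalities)) % (2**31)
    rows = []
    preds_by_modality: dict[str, np.ndarray] = {}
    for mod, s in zip(modalities, child_seeds):
        cols = pheno.columns_for(mod)
        if not cols:
            raise ValueError(f"modality {mod!r} has no phenotype columns")
        _, model = train_age_model(
            pheno, cohort, train_ids, seed=int(s), k_folds=k_folds,
            n_lambdas=n_lambdas, min_ratio=min_ratio, columns=cols,
        )
        preds = predict_raw(model, pheno, val_ids)
        preds_by_modality[mod] = preds.to_numpy()
        m = metrics(cohort.ages(list(val_ids)), preds.to_numpy())
        rows.append(
            {"modality": mod, "n_entered": len(cols), "n_nonzero": model.n_nonzero, **m.as_dict()}
        )
    table = pd.DataFrame(rows).set_index("modality")
    mat = pd.DataFrame({"age": cohort.ages(list(val_ids)), **preds_by_modality})
    corr = mat.corr()
    # a modality whose model kept no phenotypes predicts a constant; report
    # its undefined correlations as 0 (degenerate convention), diagonal as 1
    vals = corr.fillna(0.0).to_numpy()
    np.fill_diagonal(vals, 1.0)
    corr = pd.DataFrame(vals, index=corr.index, columns=corr.columns)
    return table, corr


def run_leave_one_out(
    pheno: PhenotypeTable,
    cohort: CohortTable,
    train_ids: Sequence[str],
    val_ids: Sequence[str],
    seed: int = 0,
    k_folds: int = 10,
    n_lambdas: int = 60,
    min_ratio: float = 1e-2,
) -> pd.DataFrame:
    """Refit excluding each modality in turn, plus the all-modality reference row."""
    modalities = pheno.modalities
    if len(modalities) < 2:
        raise ValueError("need at least 2 modalities")
    child_seeds = np.random.SeedSequence(seed).generate_state(len(modalities) + 1) % (2**31)
    rows = []
    _, full_model = train_age_model(
        pheno, cohort, train_ids, seed=int(child_seeds[0]), k_folds=k_folds,
        n_lambdas=n_lambdas, min_ratio=min_ratio,
    )
    m = _evaluate_model(full_model, pheno, cohort, val_ids)
    rows.append(
        {
            "excluded_modality": "none",
            "n_entered": len(pheno.phenotype_names),
            "n_nonzero": full_model.n_nonzero,
            **m.as_dict(),
        }
    )
    for mod, s in zip(modalities, child_seeds[1:]):
        cols = [c for c in pheno.phenotype_names if pheno.modality_of[c] != mod]
        if not cols:
            raise ValueError("excluding a modality left no phenotypes")
        _, model = train_age_model(
            pheno, cohort, train_ids, seed=int(s), k_folds=k_folds,
            n_lambdas=n_lambdas, min_ratio=min_ratio, columns=cols,
        )
        m = _evaluate_model(model, pheno, cohort, val_ids)
        rows.append(
            {
                "excluded_modality": mod,
                "n_entered": len(cols),
                "n_nonzero": model.n_nonzero,
                **m.as_dict(),
            }
        )
    return pd.DataFrame(rows).set_index("excluded_modality")
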