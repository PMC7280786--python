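"""Covariate-adjusted association tests between brain-PAD and outcome variables.

Each variable is tested in its own ordinary-least-squares model,

    brain_pad ~ variable + age_c + age_c^2 + sex + height + vol_scaling + head_motion

with age centered before squaring (conditioning only; the fit is unchanged).
Binary variables are entered 0/1 so the estimate is the adjusted group
difference in years; ordinal lifestyle codes (smoking status, alcohol
intake frequency) enter as single integer predictors.  "Prefer not to
answer" codes and missing values are removed per variable (complete-case),
with the n actually used reported.  p-values across the panel are adjusted
with Benjamini–Hochberg FDR, and the per-term effect size is partial
eta-squared, t² / (t² + residual df).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

DEFAULT_COVARIATES = ("age", "age_sq", "sex", "height", "vol_scaling", "head_motion")

_COND_LIMIT = 1e10


@dataclass(frozen=True)
class PanelVariable:
    name: str
    kind: str = "continuous"  # continuous | binary | ordinal
    missing_codes: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary", "ordinal"):
            raise ValueError(f"unknown variable kind {self.kind!r}")


def default_panel() -> tuple[PanelVariable, ...]:
    """The standard 18-variable biomedical / lifestyle / cognitive panel."""
    return (
        PanelVariable("diastolic_bp"),
        PanelVariable("systolic_bp"),
        PanelVariable("bmi"),
        PanelVariable("weight"),
        PanelVariable("hip_circumference"),
        PanelVariable("diabetes", kind="binary"),
        PanelVariable("stroke", kind="binary"),
        PanelVariable("facial_aging", kind="ordinal"),
        PanelVariable("smoking_status", kind="ordinal"),
        PanelVariable("alcohol_freq", kind="ordinal", missing_codes=(-3,)),
        PanelVariable("moderate_activity"),
        PanelVariable("vigorous_activity"),
        PanelVariable("fluid_intelligence"),
        PanelVariable("trail1_duration"),
        PanelVariable("trail2_duration"),
        PanelVariable("matrix_correct"),
        PanelVariable("matrix_duration"),
        PanelVariable("tower_correct"),
    )


@dataclass
class AssociationResult:
    variable: str
    estimate: float
    std_error: float
    t_value: float
    p_value: float
    partial_eta_sq: float
    n_used: int
    fdr_p: float | None = None

    def as_dict(self) -> dict:
        return {
            "variable": self.variable,
            "estimate": self.estimate,
            "std_error": self.std_error,
            "t_value": self.t_value,
            "p_value": self.p_value,
            "fdr_p": self.fdr_p,
            "partial_eta_sq": self.partial_eta_sq,
            "n_used": self.n_used,
        }


def partial_eta_squared(t_value: float, df_residual: float) -> float:
    t2 = t_value * t_value
    return t2 / (t2 + df_residual)


def _design_frame(
    pad: pd.Series, cohort_df: pd.DataFrame, var: PanelVariable, covariates: Sequence[str]
) -> pd.DataFrame:
    cols = {"brain_pad": pad}
    v = cohort_df.loc[pad.index, var.name]
    v = pd.to_numeric(v, errors="coerce")
    for code in var.missing_codes:
        v = v.mask(v == code)
    cols[var.name] = v
    for c in covariates:
        if c == "age_sq":
            continue
        col = cohort_df.loc[pad.index, c]
        if c == "sex":
            col = col.map({"F": 0.0, "M": 1.0}) if col.dtype == object else col
        cols[c] = pd.to_numeric(col, errors="coerce")
    frame = pd.DataFrame(cols).dropna()
    if "age" in covariates and "age_sq" in covariates:
        age_c = frame["age"] - frame["age"].mean()
        frame["age_sq"] = age_c**2
    return frame


def fit_association(
    pad: pd.Series,
    cohort_df: pd.DataFrame,
    variable: PanelVariable | str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> AssociationResult:
    """OLS of brain-PAD on one variable plus the covariate set (complete case)."""
    var = PanelVariable(variable) if isinstance(variable, str) else variable
    if var.name not in cohort_df.columns:
        raise KeyError(f"variable {var.name!r} not in cohort table")
    missing_cov = [c for c in covariates if c != "age_sq" and c not in cohort_df.columns]
    if missing_cov:
        raise KeyError(f"covariate(s) missing from cohort table: {missing_cov}")
    frame = _design_frame(pad, cohort_df, var, covariates)
    if len(frame) < 20:
        raise ValueError(f"only {len(frame)} complete cases for {var.name!r}; need >= 20")
    if frame[var.name].nunique() < 2:
        raise ValueError(f"variable {var.name!r} is constant after filtering")
    X = sm.add_constant(frame[[var.name, *covariates]])
    if np.linalg.cond(X.to_numpy()) > _COND_LIMIT:
        raise ValueError(f"collinear design for {var.name!r} (condition number > {_COND_LIMIT:g})")
    fit = sm.OLS(frame["brain_pad"], X).fit()
    t = float(fit.tvalues[var.name])
    return AssociationResult(
        variable=var.name,
        estimate=float(fit.params[var.name]),
        std_error=float(fit.bse[var.name]),
        t_value=t,
        p_value=float(fit.pvalues[var.name]),
        partial_eta_sq=partial_eta_squared(t, float(fit.df_resid)),
        n_used=int(fit.nobs),
    )


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted


def run_panel(
    pad: pd.Series,
    cohort_df: pd.DataFrame,
    panel: Sequence[PanelVariable] | None = None,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Run every panel variable and FDR-adjust across the panel."""
    if panel is None:
        panel = default_panel()
    results = [fit_association(pad, cohort_df, var, covariates) for var in panel]
    adj = fdr_adjust([r.p_value for r in results])
    for r, a in zip(results, adj):
        r.fdr_p = float(a)
    out = pd.DataFrame([r.as_dict() for r in results]).set_index("variable")
    return out[["estimate", "std_error", "t_value", "p_value", "fdr_p", "partial_eta_sq", "n_used"]]
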