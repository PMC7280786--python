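"""Reference end-to-end study on the default synthetic cohort.

Runs the complete analysis at the package's default study conditions —
n = 3000 subjects, the 1079-phenotype inventory, 200 bootstrap resamples,
and a fresh n = 5000 cohort for the association panel — and returns the
measured quantities (validation accuracy, selection sensitivity/precision
against the generator's ground truth, ablation deltas, injected-effect
recovery).  Used by the acceptance machinery and convenient for quick
sanity runs; every quantity is recomputed from scratch under the given
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .associations import default_panel, run_panel
from .bootstrap import bootstrap_lasso, rank_informative
from .evaluation import (
    brain_pad_table,
    fit_bias,
    metrics,
    run_leave_one_out,
    run_single_modality,
    univariate_age_screen,
)
from .lasso import predict_raw, train_age_model
from .normalization import apply_normalizer
from .screening import SplitSpec, screen_healthy, split
from .simulate import SimulationConfig, generate_cohort
from .tables import CohortTable, PhenotypeTable

_STREAMS = ("simulate", "split", "cv", "bootstrap", "single", "loo", "assoc_sim")


@dataclass
class StudyResult:
    seed: int
    n_train: int
    n_validation: int
    lambda_1se: float
    n_nonzero: int
    validation: dict
    bias_slope: float
    bias_intercept: float
    train_corr_age_pad: float
    n_informative: int
    selection_sensitivity: float
    selection_precision: float
    univariate_n_bonferroni: int
    single_modality: pd.DataFrame
    modality_corr: pd.DataFrame
    leave_one_out: pd.DataFrame
    associations: pd.DataFrame
    association_n: int
    informative_table: pd.DataFrame = field(repr=False, default=None)


def study_seeds(seed: int) -> dict[str, int]:
    state = np.random.SeedSequence(seed).generate_state(len(_STREAMS)) % (2**31)
    return {name: int(s) for name, s in zip(_STREAMS, state)}


def run_reference_study(
    seed: int,
    n_subjects: int = 3000,
    n_boot: int = 200,
    association_n: int = 5000,
    run_ablations: bool = True,
) -> StudyResult:
    seeds = study_seeds(seed)

    sim = SimulationConfig(n_subjects=n_subjects, seed=seeds["simulate"])
    pheno, cohort, truth = generate_cohort(sim)
    healthy, _ = screen_healthy(cohort)
    train_ids, val_ids = split(healthy, SplitSpec(train_fraction=0.8, seed=seeds["split"]))

    cv, model = train_age_model(pheno, cohort, train_ids, seed=seeds["cv"])

    train_raw = predict_raw(model, pheno, train_ids)
    bias = fit_bias(cohort.ages(train_ids), train_raw.to_numpy())
    train_pad = brain_pad_table(cohort.data.loc[train_ids, "age"], train_raw, bias)
    corr_train = float(np.corrcoef(train_pad["age"], train_pad["brain_pad"])[0, 1])

    val_raw = predict_raw(model, pheno, val_ids)
    val_metrics = metrics(cohort.ages(val_ids), val_raw.to_numpy())

    Xn = apply_normalizer(model.normalization, pheno, train_ids)
    summary = bootstrap_lasso(
        Xn.values, cohort.ages(train_ids), model.lambda_, n_boot=n_boot, seed=seeds["bootstrap"]
    )
    selected = summary.informative_set
    true_set = truth.informative_set
    tp = len(selected & true_set)
    sensitivity = tp / len(true_set)
    precision = tp / len(selected) if selected else 0.0

    screen_tab = univariate_age_screen(pheno.subset(train_ids), cohort.ages(train_ids))

    single = corr = loo = None
    if run_ablations:
        single, corr = run_single_modality(
            pheno, cohort, train_ids, val_ids, seed=seeds["single"]
        )
        loo = run_leave_one_out(pheno, cohort, train_ids, val_ids, seed=seeds["loo"])

    assoc_sim = SimulationConfig(n_subjects=association_n, seed=seeds["assoc_sim"])
    a_pheno, a_cohort, _ = generate_cohort(assoc_sim)
    a_raw = predict_raw(model, a_pheno)
    a_pad = brain_pad_table(a_cohort.data["age"], a_raw, bias)
    panel = run_panel(a_pad["brain_pad"], a_cohort.data, default_panel())

    return StudyResult(
        seed=seed,
        n_train=len(train_ids),
        n_validation=len(val_ids),
        lambda_1se=model.lambda_,
        n_nonzero=model.n_nonzero,
        validation=val_metrics.as_dict(),
        bias_slope=bias.slope,
        bias_intercept=bias.intercept,
        train_corr_age_pad=corr_train,
        n_informative=len(selected),
        selection_sensitivity=sensitivity,
        selection_precision=precision,
        univariate_n_bonferroni=int(screen_tab["bonferroni_significant"].sum()),
        single_modality=single,
        modality_corr=corr,
        leave_one_out=loo,
        associations=panel,
        association_n=association_n,
        informative_table=rank_informative(summary, pheno.modality_of),
    )
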