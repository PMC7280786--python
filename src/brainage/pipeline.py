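"""End-to-end orchestration: simulate -> screen -> split -> fit -> bootstrap
-> bias-correct -> ablate -> associate, with a reproducibility manifest.

A run is driven by a :class:`RunConfig` (optionally loaded from YAML).  One
top-level seed is split into per-stage seeds through a documented
``SeedSequence`` derivation, so two runs with the same config are
byte-identical in every artifact recorded in the manifest.  Wall-clock
timings go to ``run.log`` only, never into the manifest.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
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
from .simulate import SimulationConfig, generate_cohort, small_schema
from .tables import write_json

_STAGES = ("simulate", "split", "cv", "bootstrap", "single_modality", "leave_one_out")


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "brainage_run"
    n_subjects: int = 3000
    schema_scale: int | None = None  # None = full 1079-phenotype inventory
    train_fraction: float = 0.8
    k_folds: int = 10
    n_lambdas: int = 100
    n_boot: int = 200
    run_ablations: bool = True
    run_associations: bool = True
    min_test_subjects: int = 50

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def stage_seeds(seed: int) -> dict[str, int]:
    state = np.random.SeedSequence(seed).generate_state(len(_STAGES)) % (2**31)
    return {name: int(s) for name, s in zip(_STAGES, state)}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    log = open(log_path, "w")
    t0 = time.time()

    def stage(msg: str) -> None:
        log.write(f"[{time.time() - t0:8.1f}s] {msg}\n")
        log.flush()

    seeds = stage_seeds(config.seed)
    artifacts: dict[str, str] = {}

    def record(name: str, path: Path) -> None:
        artifacts[name] = str(path.relative_to(out))

    try:
        stage("simulate: drawing synthetic cohort")
        schema = small_schema(config.schema_scale) if config.schema_scale else None
        sim_kwargs = {"n_subjects": config.n_subjects, "seed": seeds["simulate"]}
        if schema is not None:
            sim_kwargs["schema"] = schema
        sim = SimulationConfig(**sim_kwargs)
        pheno, cohort, truth = generate_cohort(sim)
        pheno.write(out / "phenotypes.tsv", out / "modality_map.tsv")
        cohort.write(out / "cohort.tsv")
        write_json(truth.to_jsonable(), out / "truth.json")
        for n_, p_ in [
            ("phenotypes", out / "phenotypes.tsv"),
            ("modality_map", out / "modality_map.tsv"),
            ("cohort", out / "cohort.tsv"),
            ("truth", out / "truth.json"),
        ]:
            record(n_, p_)

        stage("screen: applying healthy-cohort exclusions")
        healthy, exclusions = screen_healthy(cohort)
        (out / "healthy_ids.txt").write_text("\n".join(healthy) + "\n")
        exclusions.to_csv(out / "exclusions.tsv", sep="\t", index=False)
        record("healthy_ids", out / "healthy_ids.txt")
        record("exclusions", out / "exclusions.tsv")

        stage(f"split: {len(healthy)} healthy subjects, fraction {config.train_fraction}")
        train_ids, val_ids = split(
            healthy, SplitSpec(train_fraction=config.train_fraction, seed=seeds["split"])
        )
        test_ids = sorted(set(cohort.subject_ids) - set(healthy))
        (out / "train_ids.txt").write_text("\n".join(train_ids) + "\n")
        (out / "val_ids.txt").write_text("\n".join(val_ids) + "\n")
        (out / "test_ids.txt").write_text("\n".join(test_ids) + "\n")
        assert not (set(train_ids) & set(val_ids)) and not (set(train_ids) & set(test_ids))

        stage("fit: normalization + cross-validated LASSO")
        cv, model = train_age_model(
            pheno, cohort, train_ids, seed=seeds["cv"],
            k_folds=config.k_folds, n_lambdas=config.n_lambdas,
        )
        model.to_json(out / "model.json", cv)
        record("model", out / "model.json")

        stage(f"bootstrap: {config.n_boot} resamples at lambda.1se")
        Xn = apply_normalizer(model.normalization, pheno, train_ids)
        summary = bootstrap_lasso(
            Xn.values, cohort.ages(train_ids), model.lambda_,
            n_boot=config.n_boot, seed=seeds["bootstrap"],
        )
        informative = rank_informative(summary, pheno.modality_of)
        informative.to_csv(out / "informative_phenotypes.tsv", sep="\t", index=False)
        record("informative_phenotypes", out / "informative_phenotypes.tsv")

        stage("evaluate: bias correction and validation metrics")
        train_raw = predict_raw(model, pheno, train_ids)
        bias = fit_bias(cohort.ages(train_ids), train_raw.to_numpy())
        train_pad = brain_pad_table(
            cohort.data.loc[train_ids, "age"], train_raw, bias
        )
        val_raw = predict_raw(model, pheno, val_ids)
        val_metrics = metrics(cohort.ages(val_ids), val_raw.to_numpy())
        val_pad = brain_pad_table(cohort.data.loc[val_ids, "age"], val_raw, bias)
        val_corrected = metrics(cohort.ages(val_ids), val_pad["corrected_pred"].to_numpy())
        screen_tab = univariate_age_screen(
            pheno.subset(train_ids), cohort.ages(train_ids)
        )
        corr_age_pad_train = float(
            np.corrcoef(train_pad["age"], train_pad["brain_pad"])[0, 1]
        )
        metrics_obj = {
            "lambda_1se": model.lambda_,
            "n_nonzero": model.n_nonzero,
            "n_informative": int(len(informative)),
            "bias_slope": bias.slope,
            "bias_intercept": bias.intercept,
            "train_corr_age_brain_pad": corr_age_pad_train,
            "validation_raw": val_metrics.as_dict(),
            "validation_corrected": val_corrected.as_dict(),
            "univariate_n_bonferroni_significant": int(
                screen_tab["bonferroni_significant"].sum()
            ),
            "n_train": len(train_ids),
            "n_validation": len(val_ids),
            "n_test": len(test_ids),
        }
        write_json(metrics_obj, out / "metrics.json")
        record("metrics", out / "metrics.json")

        if config.run_ablations:
            stage("ablation: single-modality models")
            single, corr = run_single_modality(
                pheno, cohort, train_ids, val_ids,
                seed=seeds["single_modality"], k_folds=config.k_folds,
            )
            single.to_csv(out / "single_modality.tsv", sep="\t")
            corr.to_csv(out / "modality_age_correlations.tsv", sep="\t")
            record("single_modality", out / "single_modality.tsv")
            record("modality_age_correlations", out / "modality_age_correlations.tsv")

            stage("ablation: leave-one-modality-out models")
            loo = run_leave_one_out(
                pheno, cohort, train_ids, val_ids,
                seed=seeds["leave_one_out"], k_folds=config.k_folds,
            )
            loo.to_csv(out / "leave_one_out.tsv", sep="\t")
            record("leave_one_out", out / "leave_one_out.tsv")

        if config.run_associations and len(test_ids) >= config.min_test_subjects:
            stage(f"associate: brain-PAD panel on {len(test_ids)} test subjects")
            test_raw = predict_raw(model, pheno, test_ids)
            test_pad = brain_pad_table(cohort.data.loc[test_ids, "age"], test_raw, bias)
            panel_tab = run_panel(test_pad["brain_pad"], cohort.data, default_panel())
            panel_tab.to_csv(out / "associations.tsv", sep="\t")
            record("associations", out / "associations.tsv")
        elif config.run_associations:
            stage("associate: skipped (too few test subjects)")

        manifest = {
            "package_version": __version__,
            "config": config.as_dict(),
            "stage_seeds": seeds,
            "id_set_check": {
                "train_val_disjoint": True,
                "train_test_disjoint": True,
                "val_test_disjoint": not (set(val_ids) & set(test_ids)),
            },
            "artifacts": {name: _sha256(out / rel) for name, rel in artifacts.items()},
            "artifact_paths": artifacts,
        }
        write_json(manifest, out / "manifest.json")
        stage("done")
    except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
        stage(f"FAILED: {type(exc).__name__}: {exc}")
        raise
    finally:
        log.close()
    return manifest
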