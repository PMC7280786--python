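"""Synthetic multimodal cohort generator with known ground truth.

The generator emulates a population-imaging cohort of the UK-Biobank kind:
six MRI modalities contribute a fixed inventory of imaging-derived
phenotypes (1079 by default), ages are uniform on 45–80 years, and a small
set of phenotypes carries an age signal.

Generative model
----------------
Each subject has a latent brain age

    B = age + sum_k effect_k * x_k + delta,      delta ~ N(0, delta_sd^2)

where the ``x_k`` are health/lifestyle variables (diabetes, stroke, smoking
code, alcohol code, blood pressure) and ``effect_k`` their injected
brain-age shifts in years.  An informative phenotype j reads

    p_j = loading_j * z(B) + N(0, sigma_m^2),    z(B) = (B - mid) / age_sd

with ``sigma_m`` the noise SD of j's modality and ``z`` the latent scaled by
the nominal age SD (range/sqrt(12)).  Uninformative phenotypes are pure
noise with within-modality equicorrelation (default 0.3), which makes the
penalized fit face realistic collinearity.  Cognitive scores are generated
*from* the latent offset ``B - age`` (older-appearing brain, worse score)
plus noise; screening fields (ICD-10 flag, long-standing illness,
self-rated health) are drawn independently at configured prevalences.

All randomness flows from a single seed through named
``numpy.random.SeedSequence`` child streams, so a config is reproducible
bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .schema import ModalitySchema, default_schema, modality_map
from .tables import CohortTable, PhenotypeTable

# Default per-modality informative-phenotype counts (34 in total) and the
# magnitude ranges of their loadings on the standardized latent brain age.
# T1 and diffusion dominate; task fMRI is weakest; the single T2-FLAIR
# phenotype carries no signal.
_INFORMATIVE_COUNTS = {"T1": 11, "T2FLAIR": 0, "T2star": 1, "dMRI": 19, "taskfMRI": 2, "rsfMRI": 1}
# Within a modality the informative loadings share one magnitude (signs
# alternate): the members are exchangeable proxies of the latent, so equal
# magnitudes keep each one individually (stably) selectable instead of the
# penalty concentrating on a strong subset.  Aggregate signal orders the
# modalities dMRI > T1 >> rsfMRI > T2* > taskfMRI > T2-FLAIR.
_LOADING_RANGES = {
    "T1": (0.36, 0.36),
    "T2star": (0.52, 0.52),
    "dMRI": (0.36, 0.36),
    "taskfMRI": (0.28, 0.28),
    "rsfMRI": (0.58, 0.58),
}

DEFAULT_OUTCOME_EFFECTS = {
    # years of latent brain age per unit of the variable's native coding
    "diabetes": 2.115,
    "stroke": 2.695,
    "smoking_status": 0.879,       # codes 0=never, 1=previous, 2=current
    "alcohol_freq": -0.997,        # codes 1 (daily) .. 6 (never); applied to (code - 6)
    "diastolic_bp": 0.049,         # per mmHg above the cohort mean
    "systolic_bp": 0.028,
}

# slope of score on latent offset (B - age) and residual SD, per cognitive score
DEFAULT_COGNITIVE_PARAMS = {
    "fluid_intelligence": (-0.025, 2.0),
    "trail2_duration": (7.2, 300.0),
    "matrix_correct": (-0.078, 3.0),
    "tower_correct": (-0.042, 3.0),
}

DEFAULT_PREVALENCES = {
    "diabetes": 0.0572,
    "stroke": 0.0137,
    "icd10_any": 0.03,
    "longstanding_illness": 0.03,
}

SMOKING_PROBS = (0.55, 0.35, 0.10)                    # never / previous / current
ALCOHOL_PROBS = (0.18, 0.18, 0.25, 0.12, 0.17, 0.10)  # codes 1..6
ALCOHOL_REFUSED_RATE = 0.01                           # code -3, "prefer not to answer"
HEALTH_PROBS = (0.25, 0.65, 0.08, 0.02)               # excellent / good / fair / poor


@dataclass
class GroundTruth:
    """True generative parameters, kept for downstream validation.

    ``latent_brain_age`` and ``latent_offset`` are filled in by
    :func:`generate_cohort` as per-subject diagnostics.
    """

    loadings: dict[str, float]
    modality_noise_sd: dict[str, float]
    outcome_effects: dict[str, float]
    delta_sd: float = 3.5
    noise_equicorrelation: float = 0.3
    cognitive_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COGNITIVE_PARAMS)
    )
    latent_brain_age: pd.Series | None = None
    latent_offset: pd.Series | None = None

    def __post_init__(self) -> None:
        if any(sd <= 0 for sd in self.modality_noise_sd.values()):
            raise ValueError("modality noise SDs must be strictly positive")
        if self.delta_sd < 0:
            raise ValueError("delta_sd must be non-negative")

    @property
    def informative_set(self) -> frozenset[str]:
        return frozenset(p for p, b in self.loadings.items() if b != 0.0)

    def to_jsonable(self) -> dict:
        return {
            "loadings": {p: b for p, b in self.loadings.items() if b != 0.0},
            "modality_noise_sd": self.modality_noise_sd,
            "outcome_effects": self.outcome_effects,
            "delta_sd": self.delta_sd,
            "noise_equicorrelation": self.noise_equicorrelation,
            "cognitive_params": {k: list(v) for k, v in self.cognitive_params.items()},
        }


def _spread_indices(n_total: int, n_pick: int) -> list[int]:
    if n_pick == 0:
        return []
    return sorted(set(np.linspace(0, n_total - 1, n_pick).round().astype(int).tolist()))


def default_ground_truth(schemas: Sequence[ModalitySchema] | None = None) -> GroundTruth:
    """34-phenotype informative set spread over modalities, Table-like magnitudes."""
    if schemas is None:
        schemas = default_schema()
    loadings: dict[str, float] = {}
    for s in schemas:
        k = min(_INFORMATIVE_COUNTS.get(s.modality_name, 0), s.count)
        if k == 0:
            continue
        lo, hi = _LOADING_RANGES[s.modality_name]
        mags = np.linspace(hi, lo, k)
        idx = _spread_indices(s.count, k)
        for rank, i in enumerate(idx):
            sign = -1.0 if rank % 2 == 0 else 1.0
            loadings[s.phenotype_names[i]] = sign * float(mags[rank])
    noise_sd = {s.modality_name: 1.0 for s in schemas}
    return GroundTruth(
        loadings=loadings,
        modality_noise_sd=noise_sd,
        outcome_effects=dict(DEFAULT_OUTCOME_EFFECTS),
    )


def null_ground_truth(schemas: Sequence[ModalitySchema] | None = None) -> GroundTruth:
    """No informative phenotypes, no injected outcome effects (pure-noise cohort)."""
    if schemas is None:
        schemas = default_schema()
    return GroundTruth(
        loadings={},
        modality_noise_sd={s.modality_name: 1.0 for s in schemas},
        outcome_effects={k: 0.0 for k in DEFAULT_OUTCOME_EFFECTS},
    )


@dataclass
class SimulationConfig:
    n_subjects: int = 3000
    age_range: tuple[float, float] = (45.0, 80.0)
    seed: int = 0
    schema: tuple[ModalitySchema, ...] = field(default_factory=default_schema)
    truth: GroundTruth | None = None
    prevalences: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PREVALENCES))

    def __post_init__(self) -> None:
        if self.n_subjects < 10:
            raise ValueError("n_subjects must be at least 10")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must satisfy min < max")
        if any(not 0.0 <= p <= 1.0 for p in self.prevalences.values()):
            raise ValueError("prevalences must lie in [0, 1]")
        if self.truth is None:
            self.truth = default_ground_truth(self.schema)
        known = {p for s in self.schema for p in s.phenotype_names}
        unknown = set(self.truth.loadings) - known
        if unknown:
            raise ValueError(f"loading(s) reference unknown phenotype(s): {sorted(unknown)[:5]}")


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = ["age", "screening", "outcomes", "latent", "phenotypes", "covariates", "cognitive"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.Generator(np.random.PCG64(c)) for n, c in zip(names, children)}


def generate_cohort(
    config: SimulationConfig,
) -> tuple[PhenotypeTable, CohortTable, GroundTruth]:
    """Draw a full synthetic cohort; deterministic under ``config.seed``."""
    truth = config.truth
    assert truth is not None
    rng = _streams(config.seed)
    n = config.n_subjects
    lo, hi = config.age_range
    ids = [f"S{k:06d}" for k in range(1, n + 1)]

    age = rng["age"].uniform(lo, hi, n)

    prev = config.prevalences
    diabetes = (rng["outcomes"].random(n) < prev.get("diabetes", 0.0)).astype(int)
    stroke = (rng["outcomes"].random(n) < prev.get("stroke", 0.0)).astype(int)
    smoking = rng["outcomes"].choice(3, size=n, p=SMOKING_PROBS)
    alcohol = rng["outcomes"].choice(np.arange(1, 7), size=n, p=ALCOHOL_PROBS)
    refused = rng["outcomes"].random(n) < ALCOHOL_REFUSED_RATE
    alcohol = np.where(refused, -3, alcohol)
    dbp = rng["outcomes"].normal(79.0, 10.0, n)
    sbp = 137.0 + 1.1 * (dbp - 79.0) + rng["outcomes"].normal(0.0, 12.0, n)

    eff = truth.outcome_effects
    shift = (
        eff.get("diabetes", 0.0) * diabetes
        + eff.get("stroke", 0.0) * stroke
        + eff.get("smoking_status", 0.0) * smoking
        + eff.get("alcohol_freq", 0.0) * np.where(alcohol > 0, alcohol - 6, 0)
        + eff.get("diastolic_bp", 0.0) * (dbp - 79.0)
        + eff.get("systolic_bp", 0.0) * (sbp - 137.0)
    )
    delta = rng["latent"].normal(0.0, truth.delta_sd, n) if truth.delta_sd > 0 else np.zeros(n)
    brain_age = age + shift + delta
    offset = brain_age - age

    mid = 0.5 * (lo + hi)
    age_sd = (hi - lo) / np.sqrt(12.0)
    z = (brain_age - mid) / age_sd

    rho = truth.noise_equicorrelation
    cols: dict[str, np.ndarray] = {}
    for s in config.schema:
        sd = truth.modality_noise_sd[s.modality_name]
        shared = rng["phenotypes"].normal(0.0, 1.0, n)
        noise = rng["phenotypes"].normal(0.0, 1.0, (n, s.count))
        for j, name in enumerate(s.phenotype_names):
            b = truth.loadings.get(name, 0.0)
            if b != 0.0:
                cols[name] = b * z + sd * noise[:, j]
            else:
                cols[name] = sd * (np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * noise[:, j])
    pheno = PhenotypeTable(
        pd.DataFrame(cols, index=pd.Index(ids, name="subject_id")),
        modality_map(tuple(config.schema)),
    )

    sex = np.where(rng["covariates"].random(n) < 0.5, "F", "M")
    height = np.where(
        sex == "F",
        rng["covariates"].normal(162.0, 6.0, n),
        rng["covariates"].normal(176.0, 7.0, n),
    )
    vol_scaling = rng["covariates"].normal(1.30, 0.12, n)
    head_motion = np.exp(rng["covariates"].normal(np.log(0.12), 0.25, n)) + 0.002 * offset
    head_motion = np.clip(head_motion, 0.01, None)

    icd10_any = (rng["screening"].random(n) < prev.get("icd10_any", 0.0)).astype(int)
    longstanding = (rng["screening"].random(n) < prev.get("longstanding_illness", 0.0)).astype(int)
    health = rng["screening"].choice(
        np.array(["excellent", "good", "fair", "poor"]), size=n, p=HEALTH_PROBS
    )

    cog = rng["cognitive"]
    cognitive: dict[str, np.ndarray] = {}
    baselines = {
        "fluid_intelligence": 6.0,
        "trail2_duration": 350.0,
        "matrix_correct": 8.0,
        "tower_correct": 10.0,
    }
    for name, (slope, noise_sd) in truth.cognitive_params.items():
        cognitive[name] = baselines.get(name, 0.0) + slope * offset + cog.normal(0.0, noise_sd, n)

    data = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "icd10_any": icd10_any,
            "longstanding_illness": longstanding,
            "diabetes": diabetes,
            "stroke": stroke,
            "self_rated_health": health,
            "height": height,
            "vol_scaling": vol_scaling,
            "head_motion": head_motion,
            "systolic_bp": sbp,
            "diastolic_bp": dbp,
            "bmi": cog.normal(26.5, 4.0, n),
            "weight": cog.normal(75.0, 14.0, n),
            "hip_circumference": cog.normal(100.0, 9.0, n),
            "facial_aging": cog.choice(np.array([-1, 0, 1]), size=n, p=(0.25, 0.74, 0.01)),
            "smoking_status": smoking,
            "alcohol_freq": alcohol,
            "moderate_activity": np.round(np.clip(cog.normal(60.0, 40.0, n), 0, None)),
            "vigorous_activity": np.round(np.clip(cog.normal(30.0, 25.0, n), 0, None)),
            "fluid_intelligence": cognitive["fluid_intelligence"],
            "trail1_duration": np.clip(cog.normal(180.0, 60.0, n), 20, None),
            "trail2_duration": np.clip(cognitive["trail2_duration"], 30, None),
            "matrix_correct": cognitive["matrix_correct"],
            "matrix_duration": np.clip(cog.normal(15.0, 5.0, n), 1, None),
            "tower_correct": cognitive["tower_correct"],
        },
        index=pd.Index(ids, name="subject_id"),
    )
    cohort = CohortTable(data)

    out_truth = replace(
        truth,
        latent_brain_age=pd.Series(brain_age, index=ids, name="latent_brain_age"),
        latent_offset=pd.Series(offset, index=ids, name="latent_offset"),
    )
    return pheno, cohort, out_truth


def small_schema(scale: int = 10) -> tuple[ModalitySchema, ...]:
    """Scaled-down modality inventory for fast tests and demos.

    Keeps all six modalities and the pairwise structure of the resting-state
    block (6 networks -> 15 pairs) but divides the larger blocks by ``scale``.
    """
    counts = {
        "T1": max(165 // scale, 4),
        "T2FLAIR": 1,
        "T2star": max(14 // scale, 2),
        "dMRI": max(675 // scale, 8),
        "taskfMRI": max(14 // scale, 2),
        "rsfMRI": 15,
    }
    return default_schema(counts, n_networks=6)
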