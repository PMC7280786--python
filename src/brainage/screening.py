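"""Healthy-cohort screening and train/holdout splitting.

A subject enters the healthy model-building cohort only if none of the
exclusion criteria fire: any ICD-10 diagnosis, self-reported long-standing
illness, diabetes, stroke history, or self-rated health worse than good.
Exclusion reasons are reported in that fixed order (first match wins).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import CohortTable

EXCLUSION_ORDER = (
    ("icd10_any", "icd10_diagnosis"),
    ("longstanding_illness", "longstanding_illness"),
    ("diabetes", "diabetes"),
    ("stroke", "stroke"),
    ("self_rated_health", "self_rated_health_not_good_or_excellent"),
)
GOOD_HEALTH = {"good", "excellent"}


def screen_healthy(cohort: CohortTable) -> tuple[list[str], pd.DataFrame]:
    """Return (healthy ids, exclusion report with one reason per excluded id)."""
    df = cohort.data
    for fld, _ in EXCLUSION_ORDER:
        if fld not in df.columns:
            raise ValueError(f"cohort table is missing exclusion field {fld!r}")
    healthy: list[str] = []
    excluded: list[tuple[str, str]] = []
    flags = {f: df[f] for f, _ in EXCLUSION_ORDER}
    for sid in df.index:
        reason = None
        for fld, label in EXCLUSION_ORDER:
            v = flags[fld].loc[sid]
            if fld == "self_rated_health":
                fired = v not in GOOD_HEALTH
            else:
                fired = bool(v)
            if fired:
                reason = label
                break
        if reason is None:
            healthy.append(sid)
        else:
            excluded.append((sid, reason))
    report = pd.DataFrame(excluded, columns=["subject_id", "reason"])
    return healthy, report


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly between 0 and 1")


def split(ids: list[str], spec: SplitSpec) -> tuple[list[str], list[str]]:
    """Seeded random partition into train/holdout with round-half-up sizing."""
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 ids to split")
    n_train = int(np.floor(spec.train_fraction * n + 0.5))
    n_train = min(max(n_train, 1), n - 1)  # both sides non-empty
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(spec.seed)))
    perm = rng.permutation(n)
    train = sorted(ids[i] for i in perm[:n_train])
    holdout = sorted(ids[i] for i in perm[n_train:])
    return train, holdout
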