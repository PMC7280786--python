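"""Per-phenotype standardization (zero mean, unit SD) fitted on training subjects.

Statistics are estimated on the training split only and frozen; applying the
normalizer to held-out subjects never re-fits, which keeps the downstream
penalized regression leakage-free.  Zero-variance phenotypes are dropped and
recorded.  Missing values are mean-imputed (exactly 0 after scaling), with
the imputed count tracked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .tables import PhenotypeTable


@dataclass
class NormalizationParams:
    means: pd.Series
    sds: pd.Series  # sample SD, ddof=1
    dropped_phenotypes: list[str] = field(default_factory=list)
    n_imputed_fit: int = 0

    @property
    def retained(self) -> list[str]:
        return self.means.index.tolist()

    def to_jsonable(self) -> dict:
        return {
            "means": {k: float(v) for k, v in self.means.items()},
            "sds": {k: float(v) for k, v in self.sds.items()},
            "dropped_phenotypes": list(self.dropped_phenotypes),
        }


def fit_normalizer(pheno: PhenotypeTable, ids: Sequence[str]) -> NormalizationParams:
    ids = list(ids)
    if not ids:
        raise ValueError("ids must be non-empty")
    block = pheno.values.loc[ids]
    means = block.mean(axis=0, skipna=True)
    sds = block.std(axis=0, ddof=1, skipna=True)
    zero_var = sds.index[(sds == 0) | sds.isna()].tolist()
    if len(zero_var) == len(sds):
        raise ValueError("all phenotypes have zero variance on the fitting ids")
    keep = [c for c in block.columns if c not in set(zero_var)]
    return NormalizationParams(
        means=means[keep],
        sds=sds[keep],
        dropped_phenotypes=zero_var,
        n_imputed_fit=int(block.isna().sum().sum()),
    )


def apply_normalizer(
    params: NormalizationParams, pheno: PhenotypeTable, ids: Sequence[str] | None = None
) -> PhenotypeTable:
    """Scale by the frozen training statistics; missing values map to 0."""
    df = pheno.values if ids is None else pheno.values.loc[list(ids)]
    absent = [c for c in params.retained if c not in df.columns]
    if absent:
        raise ValueError(f"phenotype(s) in normalizer absent from table: {absent[:5]}")
    scaled = (df[params.retained] - params.means) / params.sds
    scaled = scaled.fillna(0.0)
    return PhenotypeTable(scaled, {c: pheno.modality_of[c] for c in params.retained})
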