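"""Core tabular containers and TSV/CSV IO.

Two containers cross every stage of the pipeline:

* :class:`PhenotypeTable` — subjects × imaging-derived phenotypes, each
  phenotype column tagged with its modality;
* :class:`CohortTable` — per-subject demographics, health/exclusion flags,
  model covariates and outcome variables.

Subject identifiers are opaque strings (arithmetic on them is meaningless).
Missing numeric values are NaN internally and empty cells or ``NA`` on disk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

HEALTH_LEVELS = ("excellent", "good", "fair", "poor")
ALCOHOL_CODES = frozenset({1, 2, 3, 4, 5, 6, -3})

EXCLUSION_FIELDS = ("icd10_any", "longstanding_illness", "diabetes", "stroke", "self_rated_health")
COVARIATE_FIELDS = ("height", "vol_scaling", "head_motion")


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


@dataclass
class PhenotypeTable:
    """Subjects × phenotypes matrix with a modality tag per column."""

    values: pd.DataFrame  # index: subject id (str), columns: phenotype names
    modality_of: dict[str, str]

    def __post_init__(self) -> None:
        self.values.index = self.values.index.astype(str)
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate subject ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate phenotype names")
        missing = [c for c in self.values.columns if c not in self.modality_of]
        if missing:
            raise ValueError(f"phenotype(s) missing a modality tag: {missing[:5]}")

    @property
    def subject_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def phenotype_names(self) -> list[str]:
        return self.values.columns.tolist()

    def columns_for(self, modality: str) -> list[str]:
        return [c for c in self.values.columns if self.modality_of[c] == modality]

    @property
    def modalities(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.values.columns:
            seen.setdefault(self.modality_of[c], None)
        return list(seen)

    def n_missing(self) -> int:
        return int(self.values.isna().sum().sum())

    def subset(self, ids: Sequence[str] | None = None, columns: Sequence[str] | None = None) -> "PhenotypeTable":
        df = self.values
        if ids is not None:
            df = df.loc[list(ids)]
        if columns is not None:
            df = df[list(columns)]
        return PhenotypeTable(df.copy(), {c: self.modality_of[c] for c in df.columns})

    def write(self, path: str | Path, modality_map_path: str | Path | None = None) -> None:
        path = Path(path)
        sep = "\t" if path.suffix != ".csv" else ","
        self.values.to_csv(path, sep=sep, index_label="subject_id", na_rep="NA")
        if modality_map_path is not None:
            write_modality_map(self.modality_of, modality_map_path, order=self.phenotype_names)


@dataclass
class CohortTable:
    """Per-subject demographics, exclusion fields, covariates and outcomes."""

    data: pd.DataFrame  # index: subject id (str)

    def __post_init__(self) -> None:
        self.data.index = self.data.index.astype(str)
        if self.data.index.has_duplicates:
            raise ValueError("duplicate subject ids in cohort table")
        self.validate()

    def validate(self) -> None:
        df = self.data
        if "age" in df:
            ages = df["age"].dropna()
            if ((ages < 30) | (ages > 100)).any():
                raise ValueError("age outside the plausible [30, 100] year range")
        if "self_rated_health" in df:
            bad = set(df["self_rated_health"].dropna()) - set(HEALTH_LEVELS)
            if bad:
                raise ValueError(f"invalid self_rated_health level(s): {sorted(bad)}")
        if "alcohol_freq" in df:
            codes = set(df["alcohol_freq"].dropna().astype(int))
            if codes - ALCOHOL_CODES:
                raise ValueError(f"invalid alcohol_freq code(s): {sorted(codes - ALCOHOL_CODES)}")

    @property
    def subject_ids(self) -> list[str]:
        return self.data.index.tolist()

    def ages(self, ids: Sequence[str] | None = None) -> np.ndarray:
        df = self.data if ids is None else self.data.loc[list(ids)]
        return df["age"].to_numpy(dtype=float)

    def subset(self, ids: Sequence[str]) -> "CohortTable":
        return CohortTable(self.data.loc[list(ids)].copy())

    def write(self, path: str | Path) -> None:
        path = Path(path)
        sep = "\t" if path.suffix != ".csv" else ","
        self.data.to_csv(path, sep=sep, index_label="subject_id", na_rep="NA")


def read_modality_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep=_detect_sep(Path(path)), dtype=str)
    if df.shape[1] < 2:
        raise ValueError("modality map must have (phenotype, modality) columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_modality_map(
    modality_of: Mapping[str, str], path: str | Path, order: Iterable[str] | None = None
) -> None:
    names = list(order) if order is not None else list(modality_of)
    pd.DataFrame(
        {"phenotype": names, "modality": [modality_of[n] for n in names]}
    ).to_csv(path, sep="\t", index=False)


def read_phenotype_table(path: str | Path, modality_map_path: str | Path) -> PhenotypeTable:
    """Read a phenotype matrix plus its modality map, with dialect auto-detection.

    Empty cells and ``NA`` become missing values; any other non-numeric cell is
    reported with its row and column.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=_detect_sep(path), dtype=str, keep_default_na=False)
    id_col = raw.columns[0]
    raw = raw.set_index(id_col)
    raw = raw.replace({"": np.nan, "NA": np.nan})
    numeric_cols = {}
    for col in raw.columns:
        numeric = pd.to_numeric(raw[col], errors="coerce")
        bad = numeric.isna() & raw[col].notna()
        if bad.any():
            row = raw.index[bad.to_numpy().argmax()]
            raise ValueError(
                f"non-numeric phenotype value {raw.loc[row, col]!r} at row {row!r}, column {col!r}"
            )
        numeric_cols[col] = numeric
    values = pd.DataFrame(numeric_cols, index=raw.index)
    modality_of = read_modality_map(modality_map_path)
    untagged = [c for c in values.columns if c not in modality_of]
    if untagged:
        raise ValueError(f"column(s) absent from modality map: {untagged}")
    return PhenotypeTable(values, {c: modality_of[c] for c in values.columns})


def read_cohort_table(path: str | Path) -> CohortTable:
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), na_values=["NA", ""])
    df[df.columns[0]] = df[df.columns[0]].astype(str)
    df = df.set_index(df.columns[0])
    return CohortTable(df)


@dataclass
class AlignReport:
    dropped_from_phenotypes: list[str] = field(default_factory=list)
    dropped_from_cohort: list[str] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped_from_phenotypes) + len(self.dropped_from_cohort)


def align(pheno: PhenotypeTable, cohort: CohortTable) -> tuple[PhenotypeTable, CohortTable, AlignReport]:
    """Restrict both tables to their common subjects, in the phenotype table's order."""
    pheno_ids = pheno.subject_ids
    cohort_ids = set(cohort.subject_ids)
    common = [s for s in pheno_ids if s in cohort_ids]
    if not common:
        raise ValueError("no overlapping subject ids between phenotype and cohort tables")
    report = AlignReport(
        dropped_from_phenotypes=[s for s in pheno_ids if s not in cohort_ids],
        dropped_from_cohort=[s for s in cohort.subject_ids if s not in set(pheno_ids)],
    )
    return pheno.subset(common), cohort.subset(common), report


def write_json(obj: object, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
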