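"""Modality registry and phenotype naming for multimodal imaging-derived phenotypes.

The default inventory mirrors the UK-Biobank-style six-modality layout:
165 T1-weighted, 1 T2-FLAIR (white-matter hyperintensity volume), 14 T2*,
675 diffusion-MRI, 14 task fMRI and 210 resting-state fMRI phenotypes
(1079 in total).  The resting-state block is the vectorized upper triangle
of a between-network partial-correlation matrix: with ``n_networks = 21``
there are 21·20/2 = 210 pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

MODALITIES: tuple[str, ...] = ("T1", "T2FLAIR", "T2star", "dMRI", "taskfMRI", "rsfMRI")

DEFAULT_COUNTS: dict[str, int] = {
    "T1": 165,
    "T2FLAIR": 1,
    "T2star": 14,
    "dMRI": 675,
    "taskfMRI": 14,
    "rsfMRI": 210,
}

DEFAULT_N_NETWORKS = 21


def rsfmri_pair_count(n_networks: int) -> int:
    """Number of distinct network pairs in a symmetric connectivity matrix."""
    if n_networks < 2:
        raise ValueError("need at least 2 networks for pairwise correlations")
    return n_networks * (n_networks - 1) // 2


@dataclass(frozen=True)
class ModalitySchema:
    """One imaging modality and the ordered phenotype names it contributes."""

    modality_name: str
    phenotype_names: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.modality_name not in MODALITIES:
            raise ValueError(
                f"unknown modality {self.modality_name!r}; expected one of {MODALITIES}"
            )
        if len(set(self.phenotype_names)) != len(self.phenotype_names):
            raise ValueError(f"duplicate phenotype names in modality {self.modality_name}")

    @property
    def count(self) -> int:
        return len(self.phenotype_names)


_PREFIX = {
    "T1": "t1",
    "T2FLAIR": "flair",
    "T2star": "t2star",
    "dMRI": "dmri",
    "taskfMRI": "taskfmri",
}


def _names_for(modality: str, count: int, n_networks: int) -> tuple[str, ...]:
    if modality == "rsfMRI":
        pairs = [
            f"rsfmri_conn_{i:02d}_{j:02d}"
            for i in range(1, n_networks + 1)
            for j in range(i + 1, n_networks + 1)
        ]
        if count != len(pairs):
            raise ValueError(
                f"rsfMRI count {count} inconsistent with n_networks={n_networks} "
                f"(expected {len(pairs)})"
            )
        return tuple(pairs)
    if modality == "T2FLAIR" and count == 1:
        return ("flair_wmh_volume",)
    prefix = _PREFIX[modality]
    return tuple(f"{prefix}_{k:04d}" for k in range(1, count + 1))


def default_schema(
    counts: dict[str, int] | None = None, n_networks: int = DEFAULT_N_NETWORKS
) -> tuple[ModalitySchema, ...]:
    """Build the modality schema list, by default the 1079-phenotype inventory.

    ``counts`` may override per-modality sizes (rsfMRI's size is derived from
    ``n_networks`` and must agree if given explicitly).
    """
    eff = dict(DEFAULT_COUNTS if counts is None else counts)
    for name in eff:
        if name not in MODALITIES:
            raise ValueError(f"unknown modality {name!r}")
    eff.setdefault("rsfMRI", rsfmri_pair_count(n_networks))
    if "rsfMRI" in eff and counts is not None and "rsfMRI" in counts:
        if eff["rsfMRI"] != rsfmri_pair_count(n_networks):
            raise ValueError("rsfMRI count must equal n_networks*(n_networks-1)/2")
    schemas = tuple(
        ModalitySchema(m, _names_for(m, eff[m], n_networks)) for m in MODALITIES if m in eff
    )
    all_names = [p for s in schemas for p in s.phenotype_names]
    if len(set(all_names)) != len(all_names):
        raise ValueError("phenotype names are not globally unique across modalities")
    return schemas


def modality_map(schemas: tuple[ModalitySchema, ...]) -> dict[str, str]:
    """Map phenotype name -> modality name."""
    return {p: s.modality_name for s in schemas for p in s.phenotype_names}


def total_phenotypes(schemas: tuple[ModalitySchema, ...]) -> int:
    return sum(s.count for s in schemas)
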