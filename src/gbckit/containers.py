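"""Core in-memory containers shared across gbckit modules.

Genotypes are stored as allele-A dosages in {0, 1, 2} with an explicit
missing mask; the 0–1 "allele frequency" coding used by the regression
estimator (AA=1, AB=0.5, BB=0) is dosage/2 and is produced at the point
of use rather than stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "AlleleFrequencyTable",
    "SNPMap",
    "BreedLabels",
    "CorrelationStructure",
    "GBCEstimate",
]


def _check_unique(ids, what: str) -> None:
    if len(set(ids)) != len(ids):
        dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dupes[:5]}")


@dataclass
class GenotypeMatrix:
    """Animals x SNPs allele-A dosage matrix with a missing mask.

    ``dosage`` holds values in {0, 1, 2} wherever ``missing_mask`` is
    False; masked entries may hold any placeholder (conventionally 0).
    """

    animal_ids: list[str]
    snp_ids: list[str]
    dosage: np.ndarray
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        self.animal_ids = [str(a) for a in self.animal_ids]
        self.snp_ids = [str(s) for s in self.snp_ids]
        self.dosage = np.asarray(self.dosage, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.dosage.shape != (len(self.animal_ids), len(self.snp_ids)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.animal_ids)} animals x {len(self.snp_ids)} SNPs"
            )
        if self.missing_mask.shape != self.dosage.shape:
            raise ValueError("missing_mask shape does not match dosage")
        _check_unique(self.animal_ids, "animal ids")
        _check_unique(self.snp_ids, "snp ids")
        observed = self.dosage[~self.missing_mask]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            bad = np.argwhere(~self.missing_mask & ~np.isin(self.dosage, (0.0, 1.0, 2.0)))
            i, j = bad[0]
            raise ValueError(
                f"dosage {self.dosage[i, j]} outside {{0,1,2}} at animal "
                f"{self.animal_ids[i]!r}, SNP {self.snp_ids[j]!r}"
            )

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def dosage_with_nan(self) -> np.ndarray:
        """Dosage matrix with missing entries replaced by NaN."""
        out = self.dosage.copy()
        out[self.missing_mask] = np.nan
        return out

    def subset_snps(self, snp_ids: list[str]) -> "GenotypeMatrix":
        idx = pd.Index(self.snp_ids).get_indexer(snp_ids)
        if (idx < 0).any():
            missing = [s for s, i in zip(snp_ids, idx) if i < 0]
            raise KeyError(f"SNPs not present: {missing[:5]}")
        return GenotypeMatrix(
            self.animal_ids, list(snp_ids), self.dosage[:, idx], self.missing_mask[:, idx]
        )

    def subset_animals(self, animal_ids: list[str]) -> "GenotypeMatrix":
        idx = pd.Index(self.animal_ids).get_indexer(animal_ids)
        if (idx < 0).any():
            missing = [a for a, i in zip(animal_ids, idx) if i < 0]
            raise KeyError(f"animals not present: {missing[:5]}")
        return GenotypeMatrix(
            list(animal_ids), self.snp_ids, self.dosage[idx, :], self.missing_mask[idx, :]
        )

    def animal_vector(self, animal_id: str) -> np.ndarray:
        """Dosage vector (NaN for missing) for one animal."""
        i = self.animal_ids.index(animal_id)
        row = self.dosage[i].copy()
        row[self.missing_mask[i]] = np.nan
        return row


@dataclass
class AlleleFrequencyTable:
    """SNPs x breeds allele-A frequencies with observation counts.

    ``freq`` holds values in [0, 1] or NaN for cells with no observed
    alleles; ``n_obs`` counts non-missing *alleles* (2 per genotyped
    animal) behind each cell.
    """

    snp_ids: list[str]
    breeds: list[str]
    freq: np.ndarray
    n_obs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.snp_ids = [str(s) for s in self.snp_ids]
        self.breeds = [str(b) for b in self.breeds]
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.shape != (len(self.snp_ids), len(self.breeds)):
            raise ValueError(
                f"freq shape {self.freq.shape} does not match "
                f"{len(self.snp_ids)} SNPs x {len(self.breeds)} breeds"
            )
        _check_unique(self.snp_ids, "snp ids")
        _check_unique(self.breeds, "breed names")
        finite = self.freq[np.isfinite(self.freq)]
        if finite.size and ((finite < 0).any() or (finite > 1).any()):
            raise ValueError("allele frequencies must lie in [0, 1]")
        if self.n_obs is None:
            self.n_obs = np.zeros_like(self.freq, dtype=int)
        else:
            self.n_obs = np.asarray(self.n_obs, dtype=int)
            if self.n_obs.shape != self.freq.shape:
                raise ValueError("n_obs shape does not match freq")
            if (self.n_obs < 0).any():
                raise ValueError("n_obs must be non-negative")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_breeds(self) -> int:
        return len(self.breeds)

    def column(self, breed: str) -> np.ndarray:
        return self.freq[:, self.breeds.index(breed)]

    def subset_snps(self, snp_ids: list[str]) -> "AlleleFrequencyTable":
        idx = pd.Index(self.snp_ids).get_indexer(snp_ids)
        if (idx < 0).any():
            missing = [s for s, i in zip(snp_ids, idx) if i < 0]
            raise KeyError(f"SNPs not present: {missing[:5]}")
        return AlleleFrequencyTable(
            list(snp_ids), self.breeds, self.freq[idx, :], self.n_obs[idx, :]
        )

    def subset_breeds(self, breeds: list[str]) -> "AlleleFrequencyTable":
        idx = [self.breeds.index(b) for b in breeds]
        return AlleleFrequencyTable(
            self.snp_ids, list(breeds), self.freq[:, idx], self.n_obs[:, idx]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.freq, index=self.snp_ids, columns=self.breeds)


@dataclass
class SNPMap:
    """Physical SNP map: id, chromosome label, 1-based bp position."""

    table: pd.DataFrame  # columns: snp_id, chrom, pos

    def __post_init__(self) -> None:
        required = {"snp_id", "chrom", "pos"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"SNP map needs columns {sorted(required)}")
        self.table = self.table.copy()
        self.table["snp_id"] = self.table["snp_id"].astype(str)
        self.table["chrom"] = self.table["chrom"].astype(str)
        self.table["pos"] = self.table["pos"].astype(np.int64)
        if (self.table["pos"] <= 0).any():
            raise ValueError("positions must be positive (1-based)")
        if self.table["snp_id"].duplicated().any():
            raise ValueError("duplicate snp_id in map")
        # canonical order: by chromosome then position
        self.table = self.table.sort_values(
            ["chrom", "pos"], kind="stable"
        ).reset_index(drop=True)

    @property
    def snp_ids(self) -> list[str]:
        return self.table["snp_id"].tolist()

    def __len__(self) -> int:
        return len(self.table)


#: recognised breed roles, mirroring composite/ancestral/non-ancestral panels
BREED_ROLES = ("ancestral", "non-ancestral", "composite")


@dataclass
class BreedLabels:
    """Mapping animal_id -> breed, with optional per-breed role flags."""

    assignments: dict[str, str]
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.assignments = {str(a): str(b) for a, b in self.assignments.items()}
        for breed, role in self.roles.items():
            if role not in BREED_ROLES:
                raise ValueError(f"unknown role {role!r} for breed {breed!r}")

    @property
    def breeds(self) -> list[str]:
        seen: list[str] = []
        for b in self.assignments.values():
            if b not in seen:
                seen.append(b)
        return seen

    def animals_of(self, breed: str) -> list[str]:
        return [a for a, b in self.assignments.items() if b == breed]

    def __len__(self) -> int:
        return len(self.assignments)


@dataclass
class CorrelationStructure:
    """Correlations of a target with each reference breed plus the
    breed-by-breed correlation matrix, the inputs to path analysis."""

    breeds: list[str]
    r_yx: np.ndarray
    R_xx: np.ndarray
    method: str
    n_loci: int

    def __post_init__(self) -> None:
        self.r_yx = np.asarray(self.r_yx, dtype=float)
        self.R_xx = np.asarray(self.R_xx, dtype=float)
        k = len(self.breeds)
        if self.r_yx.shape != (k,):
            raise ValueError("r_yx length must equal number of breeds")
        if self.R_xx.shape != (k, k):
            raise ValueError("R_xx must be breeds x breeds")
        if not np.allclose(self.R_xx, self.R_xx.T, atol=1e-12):
            raise ValueError("R_xx must be symmetric")
        if not np.allclose(np.diag(self.R_xx), 1.0, atol=1e-10):
            raise ValueError("R_xx diagonal must be 1")
        if (np.abs(self.r_yx) > 1 + 1e-12).any() or (np.abs(self.R_xx) > 1 + 1e-12).any():
            raise ValueError("correlations must lie in [-1, 1]")


@dataclass
class GBCEstimate:
    """Per-animal (or per-population) breed composition on the simplex."""

    id: str
    method: str
    breeds: list[str]
    composition: np.ndarray
    reliability: float | None = None
    n_loci: int | None = None
    clamped: bool = False

    def __post_init__(self) -> None:
        self.composition = np.asarray(self.composition, dtype=float)
        if self.composition.shape != (len(self.breeds),):
            raise ValueError("composition length must match breeds")
        if (self.composition < -1e-10).any():
            raise ValueError("composition entries must be non-negative")
        if abs(self.composition.sum() - 1.0) > 1e-8:
            raise ValueError("composition must sum to 1")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.breeds, self.composition.tolist()))
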