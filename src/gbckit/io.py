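"""Readers and writers for genotype, frequency, map and label tables.

Supported dialects: PLINK 1.9 ``.raw`` (recode A) and ``.map``, and plain
tab-separated tables with a header row (UTF-8). All writers round-trip
losslessly at 6-decimal precision.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import AlleleFrequencyTable, BreedLabels, GenotypeMatrix, SNPMap

logger = logging.getLogger("gbckit")

DEFAULT_MISSING_CODES = ("NA", "-9", "")

_PLINK_META_COLS = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


class FormatError(ValueError):
    """Raised when a file does not conform to its declared dialect."""


def read_genotypes(
    path: str | Path,
    format: str = "tsv",
    missing_codes: tuple[str, ...] = DEFAULT_MISSING_CODES,
) -> GenotypeMatrix:
    """Read a genotype matrix from a PLINK ``.raw`` export or a TSV.

    TSV layout: first column is the animal id, remaining columns are
    SNP ids, cells are dosages in {0,1,2} or a missing code.
    ``plink_raw`` layout: whitespace-separated with the six PLINK meta
    columns then one column per SNP named ``<snp_id>_<counted allele>``.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise FormatError(f"{path}: empty file")
    if format == "plink_raw":
        return _read_plink_raw(path, missing_codes)
    if format == "tsv":
        return _read_genotypes_tsv(path, missing_codes)
    raise ValueError(f"unknown genotype format {format!r}")


def _parse_dosages(df: pd.DataFrame, animal_ids: list[str], snp_ids: list[str],
                   missing_codes: tuple[str, ...]) -> GenotypeMatrix:
    raw = df.to_numpy(dtype=object)
    dosage = np.zeros(raw.shape, dtype=float)
    mask = np.zeros(raw.shape, dtype=bool)
    for (i, j), val in np.ndenumerate(raw):
        s = "" if val is None or (isinstance(val, float) and np.isnan(val)) else str(val).strip()
        if s in missing_codes:
            mask[i, j] = True
            continue
        try:
            d = float(s)
        except ValueError:
            raise FormatError(
                f"non-numeric dosage {s!r} at animal {animal_ids[i]!r}, SNP {snp_ids[j]!r}"
            ) from None
        if d not in (0.0, 1.0, 2.0):
            raise ValueError(
                f"dosage {d} outside {{0,1,2}} at animal {animal_ids[i]!r}, "
                f"SNP {snp_ids[j]!r}"
            )
        dosage[i, j] = d
    return GenotypeMatrix(animal_ids, snp_ids, dosage, mask)


def _read_genotypes_tsv(path: Path, missing_codes) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected an id column plus >=1 SNP column")
    animal_ids = df.iloc[:, 0].tolist()
    snp_ids = list(df.columns[1:])
    return _parse_dosages(df.iloc[:, 1:], animal_ids, snp_ids, missing_codes)


def _read_plink_raw(path: Path, missing_codes) -> GenotypeMatrix:
    df = pd.read_csv(path, sep=r"\s+", dtype=str, keep_default_na=False)
    if list(df.columns[:6]) != _PLINK_META_COLS:
        raise FormatError(
            f"{path}: malformed .raw header; expected leading columns "
            f"{_PLINK_META_COLS}, got {list(df.columns[:6])}"
        )
    if df.shape[1] == 6:
        raise FormatError(f"{path}: .raw file has no SNP columns")
    snp_cols = list(df.columns[6:])
    snp_ids = []
    for col in snp_cols:
        if "_" not in col:
            raise FormatError(f"{path}: SNP column {col!r} lacks the _<allele> suffix")
        snp_ids.append(col.rsplit("_", 1)[0])
    animal_ids = df["IID"].tolist()
    return _parse_dosages(df[snp_cols], animal_ids, snp_ids, missing_codes)


def counted_alleles(path: str | Path) -> dict[str, str]:
    """Map snp_id -> counted allele letter from a ``.raw`` header."""
    with open(path) as fh:
        header = fh.readline().split()
    out = {}
    for col in header[6:]:
        snp, _, allele = col.rpartition("_")
        out[snp] = allele
    return out


def write_genotypes(G: GenotypeMatrix, path: str | Path, missing_code: str = "NA") -> None:
    dos = G.dosage_with_nan()
    df = pd.DataFrame(dos, index=pd.Index(G.animal_ids, name="animal_id"),
                      columns=G.snp_ids)
    df = df.map(lambda v: missing_code if np.isnan(v) else str(int(v)))
    df.to_csv(path, sep="\t")


def read_frequency_table(path: str | Path) -> AlleleFrequencyTable:
    """Read a SNP x breed allele-A frequency TSV (snp_id column first)."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise FormatError(f"{path}: empty file")
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected snp_id column plus >=1 breed column")
    snp_ids = df.iloc[:, 0].astype(str)
    if snp_ids.duplicated().any():
        dupes = snp_ids[snp_ids.duplicated()].tolist()
        raise FormatError(f"{path}: duplicate snp_id {dupes[:5]}")
    freqs = df.iloc[:, 1:].apply(pd.to_numeric, errors="raise").to_numpy(dtype=float)
    finite = freqs[np.isfinite(freqs)]
    if finite.size and ((finite < 0).any() or (finite > 1).any()):
        bad = finite[(finite < 0) | (finite > 1)][0]
        raise ValueError(f"{path}: allele frequency {bad} outside [0, 1]")
    return AlleleFrequencyTable(snp_ids.tolist(), list(df.columns[1:]), freqs)


def write_frequency_table(F: AlleleFrequencyTable, path: str | Path) -> None:
    df = F.to_frame().round(6)
    df.index.name = "snp_id"
    df.to_csv(path, sep="\t", float_format="%.6f")


def read_snp_map(path: str | Path, format: str = "tsv") -> SNPMap:
    """Read a SNP map: PLINK ``.map`` (chrom, id, cM, pos) or a TSV with
    header snp_id/chrom/pos."""
    path = Path(path)
    if format == "plink_map":
        df = pd.read_csv(path, sep=r"\s+", header=None,
                         names=["chrom", "snp_id", "cm", "pos"], dtype=str)
        table = df[["snp_id", "chrom", "pos"]].copy()
        table["pos"] = table["pos"].astype(np.int64)
        return SNPMap(table)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
        return SNPMap(df[["snp_id", "chrom", "pos"]])
    raise ValueError(f"unknown map format {format!r}")


def write_snp_map(m: SNPMap, path: str | Path) -> None:
    m.table.to_csv(path, sep="\t", index=False)


def read_breed_labels(path: str | Path) -> BreedLabels:
    """Read animal_id/breed (and optional role) assignments from TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"animal_id", "breed"}.issubset(df.columns):
        raise FormatError(f"{path}: expected columns animal_id, breed")
    if df["animal_id"].duplicated().any():
        dupes = df.loc[df["animal_id"].duplicated(), "animal_id"].tolist()
        raise FormatError(f"{path}: animal labeled more than once: {dupes[:5]}")
    roles = {}
    if "role" in df.columns:
        roles = (
            df.dropna(subset=["role"]).drop_duplicates("breed")
            .set_index("breed")["role"].to_dict()
        )
    return BreedLabels(dict(zip(df["animal_id"], df["breed"])), roles)


def write_breed_labels(labels: BreedLabels, path: str | Path) -> None:
    rows = [
        {"animal_id": a, "breed": b, "role": labels.roles.get(b, "")}
        for a, b in labels.assignments.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def align_panels(
    G: GenotypeMatrix, F: AlleleFrequencyTable
) -> tuple[GenotypeMatrix, AlleleFrequencyTable]:
    """Restrict genotypes and frequencies to their common SNPs.

    The retained SNP order follows the frequency table, so the result is
    deterministic for a given input pair. Idempotent.
    """
    common = [s for s in F.snp_ids if s in set(G.snp_ids)]
    if not common:
        raise ValueError("no SNPs in common between genotype and frequency panels")
    dropped_g = G.n_snps - len(common)
    dropped_f = F.n_snps - len(common)
    if dropped_g or dropped_f:
        logger.info(
            "align_panels: retained %d common SNPs (dropped %d from genotypes, "
            "%d from frequencies)", len(common), dropped_g, dropped_f,
        )
    return G.subset_snps(common), F.subset_snps(common)
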