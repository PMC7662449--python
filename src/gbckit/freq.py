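"""Allele frequencies, standardization and correlation structures.

These primitives feed all three breed-composition estimators: per-breed
allele-A frequencies are the reference columns x_j; the correlation of a
target (an animal's genotypes on the 0–1 frequency scale, or a composite
breed's frequency vector) with each reference column, together with the
breed-by-breed correlation matrix, is the input to path analysis.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .containers import (
    AlleleFrequencyTable,
    BreedLabels,
    CorrelationStructure,
    GenotypeMatrix,
)

__all__ = [
    "allele_frequencies",
    "standardize",
    "correlation_structure",
    "target_frequency_vector",
]


def allele_frequencies(G: GenotypeMatrix, labels: BreedLabels) -> AlleleFrequencyTable:
    """Per-breed allele-A frequencies from labeled genotypes.

    freq(snp, breed) = sum of dosages / (2 x non-missing animals); cells
    with no observations are NaN. Every breed in ``labels`` must have at
    least one genotyped animal.
    """
    breeds = labels.breeds
    freq = np.full((G.n_snps, len(breeds)), np.nan)
    n_obs = np.zeros((G.n_snps, len(breeds)), dtype=int)
    present = set(G.animal_ids)
    for k, breed in enumerate(breeds):
        animals = [a for a in labels.animals_of(breed) if a in present]
        if not animals:
            raise ValueError(f"breed {breed!r} has no genotyped animals")
        sub = G.subset_animals(animals)
        obs = ~sub.missing_mask
        counts = obs.sum(axis=0)
        sums = np.where(obs, sub.dosage, 0.0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq[:, k] = np.where(counts > 0, sums / (2.0 * counts), np.nan)
        n_obs[:, k] = 2 * counts
    return AlleleFrequencyTable(G.snp_ids, breeds, freq, n_obs)


def standardize(v: np.ndarray) -> np.ndarray:
    """Center to mean 0 and scale to sample (n-1) standard deviation 1."""
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("standardize needs a 1-d vector of length >= 2")
    sd = v.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot standardize a vector with zero variance")
    return (v - v.mean()) / sd


def target_frequency_vector(y: np.ndarray) -> np.ndarray:
    """Coerce a target vector onto the allele-frequency (0–1) scale.

    Dosage vectors ({0,1,2}, possibly with NaN) are divided by 2; vectors
    already within [0, 1] are returned unchanged.
    """
    y = np.asarray(y, dtype=float)
    finite = y[np.isfinite(y)]
    if finite.size == 0:
        raise ValueError("target vector has no observed loci")
    if (finite < 0).any() or (finite > 2).any():
        raise ValueError("target values must lie in [0, 2]")
    if (finite > 1).any():
        return y / 2.0
    return y


def _pairwise_corr(a: np.ndarray, b: np.ndarray, method: str) -> tuple[float, int]:
    ok = np.isfinite(a) & np.isfinite(b)
    n = int(ok.sum())
    if n < 3:
        raise ValueError(f"fewer than 3 complete loci ({n}) for correlation")
    x, y = a[ok], b[ok]
    if method == "pearson":
        r = stats.pearsonr(x, y).statistic
    elif method == "spearman":
        r = stats.spearmanr(x, y).statistic  # average ranks for ties
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(r), n


def correlation_structure(
    y: np.ndarray, F: AlleleFrequencyTable, method: str = "pearson"
) -> CorrelationStructure:
    """Correlations of a target with each breed plus the breed matrix.

    ``y`` is aligned to ``F``'s SNPs and may be a per-animal dosage vector
    (rescaled to the frequency scale internally) or a composite-breed
    frequency vector. Correlations use pairwise-complete observations.
    """
    yf = target_frequency_vector(y)
    if yf.shape != (F.n_snps,):
        raise ValueError(
            f"target length {yf.shape[0]} does not match {F.n_snps} SNPs"
        )
    k = F.n_breeds
    r_yx = np.empty(k)
    n_min = F.n_snps
    for j in range(k):
        r_yx[j], n = _pairwise_corr(yf, F.freq[:, j], method)
        n_min = min(n_min, n)
    R_xx = np.eye(k)
    for j in range(k):
        for j2 in range(j + 1, k):
            r, n = _pairwise_corr(F.freq[:, j], F.freq[:, j2], method)
            R_xx[j, j2] = R_xx[j2, j] = r
            n_min = min(n_min, n)
    return CorrelationStructure(list(F.breeds), r_yx, R_xx, method, n_min)
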