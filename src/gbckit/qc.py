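"""Reference-panel quality control and uniform SNP-panel selection.

Reference animals claiming a breed are screened with a multinomial
purity score: under HWE and locus independence, each genotype has
probability f^2, 2f(1-f) or (1-f)^2 given the breed's allele frequency
f, and the score is -2 times the per-locus mean log10 genotype
probability. Animals scoring above the cutoff (default 2) are excluded.
Uniform panels place an even grid over each chromosome's span and pick
the nearest unused SNP to each grid point.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .containers import BreedLabels, GenotypeMatrix, SNPMap
from .freq import allele_frequencies

logger = logging.getLogger("gbckit")

__all__ = ["PurityScore", "purity_score", "filter_reference", "select_uniform_snps"]

DEFAULT_THRESHOLD = 2.0
FREQ_EPS = 1e-6


@dataclass
class PurityScore:
    animal_id: str
    breed: str
    score: float
    n_loci: int


def _genotype_log10_prob(y: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Per-locus log10 HWE genotype probability for dosages 0/1/2."""
    log_f = np.log10(f)
    log_q = np.log10(1.0 - f)
    het = np.log10(2.0) + log_f + log_q
    return np.where(y == 2, 2 * log_f, np.where(y == 1, het, 2 * log_q))


def purity_score(
    y: np.ndarray,
    f: np.ndarray,
    animal_id: str = "",
    breed: str = "",
    eps: float = FREQ_EPS,
    base: float = 10.0,
    normalize: bool = True,
) -> PurityScore:
    """Breed-membership outlier score for one animal.

    score = -2 * mean_i log10 P(y_i | f_i); smaller is purer. ``base``
    and ``normalize`` (per-locus averaging) are configurable; the
    defaults make the conventional cutoff of 2 panel-size independent.
    """
    y = np.asarray(y, dtype=float)
    f = np.asarray(f, dtype=float)
    if y.shape != f.shape:
        raise ValueError("dosage and frequency vectors must be aligned")
    ok = np.isfinite(y) & np.isfinite(f)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("zero usable loci for purity score")
    fc = np.clip(f[ok], eps, 1.0 - eps)
    lp = _genotype_log10_prob(y[ok], fc)
    if base != 10.0:
        lp = lp * np.log(10.0) / np.log(base)
    total = lp.mean() if normalize else lp.sum()
    return PurityScore(animal_id, breed, float(-2.0 * total), n)


def filter_reference(
    G: GenotypeMatrix,
    labels: BreedLabels,
    threshold: float = DEFAULT_THRESHOLD,
    leave_one_out: bool = False,
) -> tuple[GenotypeMatrix, list[PurityScore]]:
    """Remove within-breed outliers from a labeled reference panel.

    Scores every labeled, genotyped animal against its own breed's
    allele frequencies (optionally recomputed leaving that animal out)
    and drops those with score > threshold. Returns the retained matrix
    and the scores of the excluded animals.
    """
    F = allele_frequencies(G, labels)
    dosage = G.dosage_with_nan()
    a_index = {a: i for i, a in enumerate(G.animal_ids)}
    excluded: list[PurityScore] = []
    keep: list[str] = []
    for breed in labels.breeds:
        members = [a for a in labels.animals_of(breed) if a in a_index]
        col = F.freq[:, F.breeds.index(breed)]
        n_obs = F.n_obs[:, F.breeds.index(breed)].astype(float)
        kept_in_breed = 0
        for animal in members:
            y = dosage[a_index[animal]]
            if leave_one_out:
                obs = np.isfinite(y)
                n_loo = n_obs - np.where(obs, 2.0, 0.0)
                with np.errstate(invalid="ignore", divide="ignore"):
                    f = np.where(
                        n_loo > 0,
                        (col * n_obs - np.where(obs, y, 0.0)) / n_loo,
                        np.nan,
                    )
            else:
                f = col
            ps = purity_score(y, f, animal_id=animal, breed=breed)
            if ps.score > threshold:
                excluded.append(ps)
            else:
                keep.append(animal)
                kept_in_breed += 1
        if kept_in_breed == 0:
            warnings.warn(f"breed {breed!r} has no animals left after filtering")
    # unlabeled animals pass through untouched
    labeled = set(labels.assignments)
    keep.extend(a for a in G.animal_ids if a not in labeled)
    keep_ordered = [a for a in G.animal_ids if a in set(keep)]
    if excluded:
        logger.info(
            "filter_reference: excluded %d of %d labeled animals (threshold %.3g)",
            len(excluded), len(labeled), threshold,
        )
    return G.subset_animals(keep_ordered), excluded


def select_uniform_snps(snp_map: SNPMap, n: int) -> list[str]:
    """Pick ``n`` SNP ids spread uniformly across the genome.

    Chromosomes are allocated counts proportional to their bp span
    (largest-remainder rounding); an even grid is laid over each span
    and the nearest not-yet-taken SNP to each grid point is selected.
    Deterministic; output sorted by (chrom, pos).
    """
    total = len(snp_map)
    if n > total:
        raise ValueError(f"requested {n} SNPs but map has only {total}")
    if n == total:
        return snp_map.snp_ids
    if n < 1:
        raise ValueError("n must be >= 1")
    table = snp_map.table
    chroms = []
    for chrom, grp in table.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy()
        span = float(pos.max() - pos.min()) + 1.0
        chroms.append((chrom, grp, span))
    spans = np.array([c[2] for c in chroms])
    quota = n * spans / spans.sum()
    alloc = np.floor(quota).astype(int)
    sizes = np.array([len(c[1]) for c in chroms])
    alloc = np.minimum(alloc, sizes)
    # largest remainders get the leftover picks, capped by availability
    while alloc.sum() < n:
        remainder = np.where(alloc < sizes, quota - alloc, -np.inf)
        alloc[int(np.argmax(remainder))] += 1
    selected: list[tuple[str, int, str]] = []
    for (chrom, grp, _), k in zip(chroms, alloc):
        if k == 0:
            continue
        pos = grp["pos"].to_numpy()
        ids = grp["snp_id"].to_numpy()
        lo, hi = float(pos.min()), float(pos.max())
        grid = np.array([(lo + hi) / 2.0]) if k == 1 else np.linspace(lo, hi, k)
        taken = np.zeros(len(pos), dtype=bool)
        for g in grid:
            dist = np.where(taken, np.inf, np.abs(pos - g))
            i = int(np.argmin(dist))
            taken[i] = True
            selected.append((chrom, int(pos[i]), ids[i]))
    selected.sort(key=lambda t: (t[0], t[1]))
    return [s[2] for s in selected]
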