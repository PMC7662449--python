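"""Breed composition by adjusted linear regression.

An animal's genotypes, coded as within-individual allele-A frequencies
(AA=1, AB=0.5, BB=0, i.e. dosage/2), are regressed on the reference
breeds' allele-A frequencies with an intercept:

    y = mu + sum_j b_j x_j + e

The raw coefficients b_j are unbounded, so they are mapped onto the
probability simplex (negatives clamped to zero, remainder rescaled to
sum to one) to read as breed proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import AlleleFrequencyTable, GBCEstimate

__all__ = ["LinRegFit", "fit_linreg", "adjust_coefficients", "estimate_linreg_gbc"]


@dataclass
class LinRegFit:
    breeds: list[str]
    intercept: float
    b: np.ndarray
    residual_variance: float
    condition: float
    n_loci: int


def fit_linreg(y: np.ndarray, F: AlleleFrequencyTable) -> LinRegFit:
    """Ordinary least squares of a 0–1 coded genotype vector on the
    reference frequency columns, over loci complete in y and every breed.

    The condition diagnostic is the ratio of extreme singular values of
    the centered design.
    """
    y = np.asarray(y, dtype=float)
    if y.shape != (F.n_snps,):
        raise ValueError("target length does not match frequency table")
    X = F.freq
    ok = np.isfinite(y) & np.isfinite(X).all(axis=1)
    k = F.n_breeds
    n = int(ok.sum())
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} complete loci, have {n}")
    yc, Xc = y[ok], X[ok]
    design = np.column_stack([np.ones(n), Xc])
    rank = np.linalg.matrix_rank(design)
    if rank < k + 1:
        pairs = _collinear_breeds(Xc, F.breeds)
        raise ValueError(
            "rank-deficient design; exactly collinear breed columns: "
            + (", ".join(f"{a}~{b}" for a, b in pairs) if pairs else "(with intercept)")
        )
    coef, _, _, _ = np.linalg.lstsq(design, yc, rcond=None)
    resid = yc - design @ coef
    dof = max(n - (k + 1), 1)
    sv = np.linalg.svd(Xc - Xc.mean(axis=0), compute_uv=False)
    condition = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
    return LinRegFit(
        breeds=list(F.breeds),
        intercept=float(coef[0]),
        b=coef[1:],
        residual_variance=float(resid @ resid / dof),
        condition=condition,
        n_loci=n,
    )


def _collinear_breeds(X: np.ndarray, breeds: list[str]) -> list[tuple[str, str]]:
    pairs = []
    with np.errstate(invalid="ignore"):
        C = np.corrcoef(X, rowvar=False)
    for i in range(len(breeds)):
        for j in range(i + 1, len(breeds)):
            if np.isfinite(C[i, j]) and abs(C[i, j]) > 1 - 1e-10:
                pairs.append((breeds[i], breeds[j]))
    return pairs


def adjust_coefficients(b: np.ndarray) -> np.ndarray:
    """Map raw regression coefficients onto the probability simplex:
    clamp negatives to zero, then rescale so the sum is exactly 1."""
    b = np.atleast_1d(np.asarray(b, dtype=float))
    clamped = np.where(b > 0, b, 0.0)
    total = clamped.sum()
    if total <= 0:
        raise ValueError("all coefficients non-positive: no admissible composition")
    return clamped / total


def estimate_linreg_gbc(
    y_dosage: np.ndarray, F: AlleleFrequencyTable, animal_id: str = ""
) -> GBCEstimate:
    """Full pipeline: dosage vector -> 0–1 coding -> OLS -> simplex."""
    y = np.asarray(y_dosage, dtype=float) / 2.0
    fit = fit_linreg(y, F)
    w = adjust_coefficients(fit.b)
    return GBCEstimate(
        id=animal_id, method="linreg", breeds=fit.breeds,
        composition=w, n_loci=fit.n_loci,
        clamped=bool((fit.b < 0).any()),
    )
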