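"""Path analysis of genomic breed composition (the causal estimator).

Path analysis treats the reference breeds' allele frequencies as
exogenous causes of a composite animal's (standardized) genotypes.  The
path coefficients p_yx are the standardized regression coefficients,
obtained either from the correlation system

    R_xx p_yx = r_yx

or equivalently as b_j * sigma_xj / sigma_y from the unstandardized OLS
fit.  Each breed's influence decomposes into a *direct* determination
p_yx_j^2 and a *combined* determination

    d_j = p_j^2 + sum_{j' != j} p_j r_jj' p_j'

which adds the correlational (indirect) terms.  Breed composition is
then read as the relative ratio of direct determinations (D-GBC) or
combined determinations (C-GBC).  The unexplained share
R = 1 - sum_j d_j is the squared residual path coefficient (coefficient
of alienation p_ye); 1 - R is reported as a reliability measure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import AlleleFrequencyTable, CorrelationStructure, GBCEstimate
from .freq import correlation_structure, standardize
from .linreg import fit_linreg

__all__ = [
    "PathSolution",
    "solve_path_coefficients",
    "solve_bivariate",
    "path_from_regression",
    "combined_determination",
    "d_gbc",
    "c_gbc",
    "residual_determination",
    "estimate_path_gbc",
]

DEFAULT_CONDITION_CAP = 1e8


@dataclass
class PathSolution:
    """Solved path coefficients and their determination decomposition."""

    breeds: list[str]
    p_yx: np.ndarray
    r_yx: np.ndarray
    R_xx: np.ndarray
    direct_det: np.ndarray
    combined_det: np.ndarray  # raw signed values, kept for diagnostics
    residual_det: float  # R = 1 - sum(combined_det), may be negative
    p_ye: float  # sqrt(max(0, R))
    reliability: float  # 1 - R
    n_loci: int | None = None


def _finalize(breeds, p, r_yx, R_xx, n_loci=None) -> PathSolution:
    d_comb = combined_determination(p, R_xx)
    R, p_ye, reliability = residual_determination(p, R_xx)
    return PathSolution(
        breeds=list(breeds),
        p_yx=p,
        r_yx=np.asarray(r_yx, dtype=float),
        R_xx=np.asarray(R_xx, dtype=float),
        direct_det=p**2,
        combined_det=d_comb,
        residual_det=R,
        p_ye=p_ye,
        reliability=reliability,
        n_loci=n_loci,
    )


def solve_path_coefficients(
    cs: CorrelationStructure, condition_cap: float = DEFAULT_CONDITION_CAP
) -> PathSolution:
    """Solve R_xx p = r_yx for the path coefficients and decompose.

    Solves the linear system directly (no explicit inverse). Raises if
    the breed correlation matrix is ill-conditioned, naming the most
    correlated breed pair.
    """
    R_xx, r_yx = cs.R_xx, cs.r_yx
    cond = np.linalg.cond(R_xx)
    if not np.isfinite(cond) or cond > condition_cap:
        k = len(cs.breeds)
        off = np.abs(R_xx - np.eye(k))
        i, j = np.unravel_index(np.argmax(off), off.shape)
        raise np.linalg.LinAlgError(
            f"breed correlation matrix is singular or ill-conditioned "
            f"(condition number {cond:.3g} > {condition_cap:.3g}); most "
            f"correlated pair: {cs.breeds[i]} ~ {cs.breeds[j]} "
            f"(r = {R_xx[i, j]:.6f})"
        )
    p = np.linalg.solve(R_xx, r_yx)
    return _finalize(cs.breeds, p, r_yx, R_xx, cs.n_loci)


def solve_bivariate(r_y1: float, r_y2: float, r_12: float) -> tuple[float, float]:
    """Closed-form path coefficients for two exogenous variables; each is
    the semi-partial correlation of its variable with the target."""
    if abs(r_12) >= 1:
        raise np.linalg.LinAlgError(
            f"breed correlation r_12 = {r_12} leaves the system singular"
        )
    denom = 1.0 - r_12**2
    p1 = (r_y1 - r_12 * r_y2) / denom
    p2 = (r_y2 - r_12 * r_y1) / denom
    return p1, p2


def path_from_regression(
    y: np.ndarray, X: np.ndarray, breeds: list[str] | None = None
) -> PathSolution:
    """Path coefficients via standardized multiple regression.

    Fits OLS of the raw target on the raw breed columns and rescales each
    coefficient by sigma_xj / sigma_y. Numerically identical (to solver
    precision) to ``solve_path_coefficients`` on the same data's
    correlation structure.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise ValueError("X must be loci x breeds aligned with y")
    k = X.shape[1]
    if breeds is None:
        breeds = [f"x{j + 1}" for j in range(k)]
    ok = np.isfinite(y) & np.isfinite(X).all(axis=1)
    yv, Xv = y[ok], X[ok]
    n = len(yv)
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} complete loci, have {n}")
    design = np.column_stack([np.ones(n), Xv])
    coef, _, rank, _ = np.linalg.lstsq(design, yv, rcond=None)
    if rank < k + 1:
        raise ValueError("rank-deficient design in standardized regression")
    b = coef[1:]
    sd_y = yv.std(ddof=1)
    if sd_y == 0:
        raise ValueError("target has zero variance")
    p = b * Xv.std(axis=0, ddof=1) / sd_y
    ys = standardize(yv)
    Xs = np.column_stack([standardize(Xv[:, j]) for j in range(k)])
    r_yx = Xs.T @ ys / (n - 1)
    R_xx = Xs.T @ Xs / (n - 1)
    np.fill_diagonal(R_xx, 1.0)
    R_xx = (R_xx + R_xx.T) / 2.0
    return _finalize(breeds, p, r_yx, R_xx, n)


def combined_determination(p_yx: np.ndarray, R_xx: np.ndarray) -> np.ndarray:
    """Per-breed combined determination: the direct square plus the
    correlational cross terms p_j r_jj' p_j'. Sums (with the residual) to
    the total variance of the standardized target."""
    p = np.asarray(p_yx, dtype=float)
    R = np.asarray(R_xx, dtype=float)
    if R.shape != (p.size, p.size):
        raise ValueError("R_xx shape does not match coefficient vector")
    return p * (R @ p)  # diag contributes p_j^2, off-diag the cross terms


def d_gbc(p_yx: np.ndarray, breeds: list[str] | None = None, id: str = "") -> GBCEstimate:
    """Direct-effect breed composition: squared path coefficients,
    normalized to the simplex."""
    p = np.atleast_1d(np.asarray(p_yx, dtype=float))
    sq = p**2
    total = sq.sum()
    if total <= 0:
        raise ValueError("all path coefficients are zero: D-GBC undefined")
    if breeds is None:
        breeds = [f"x{j + 1}" for j in range(p.size)]
    return GBCEstimate(
        id=id, method="path_direct", breeds=list(breeds), composition=sq / total
    )


def c_gbc(
    p_yx: np.ndarray,
    R_xx: np.ndarray,
    breeds: list[str] | None = None,
    id: str = "",
) -> GBCEstimate:
    """Combined-effect breed composition: each breed's combined
    determination over the total. Negative components (possible when
    cross terms are negative) are clamped to zero and the remainder
    renormalized; the estimate is flagged when clamping occurred."""
    d = combined_determination(p_yx, R_xx)
    total = d.sum()
    if total <= 0:
        raise ValueError("total combined determination is non-positive: C-GBC undefined")
    comp = d / total
    clamped = bool((comp < 0).any())
    if clamped:
        comp = np.where(comp > 0, comp, 0.0)
        comp = comp / comp.sum()
    if breeds is None:
        breeds = [f"x{j + 1}" for j in range(len(d))]
    return GBCEstimate(
        id=id, method="path_combined", breeds=list(breeds),
        composition=comp, clamped=clamped,
    )


def residual_determination(
    p_yx: np.ndarray, R_xx: np.ndarray
) -> tuple[float, float, float]:
    """Residual share of variance R = 1 - sum(combined determinations),
    the residual path coefficient p_ye = sqrt(max(0, R)), and the
    reliability 1 - R. Warns when correlational terms push R below zero."""
    R = 1.0 - float(combined_determination(p_yx, R_xx).sum())
    if R < 0:
        warnings.warn(
            f"total determination exceeds 1 (residual {R:.6f} < 0); "
            "residual path coefficient clamped to 0"
        )
    p_ye = float(np.sqrt(max(0.0, R)))
    return R, p_ye, 1.0 - R


def estimate_path_gbc(
    target: np.ndarray,
    F: AlleleFrequencyTable,
    method: str = "pearson",
    mode: str = "direct",
    id: str = "",
    condition_cap: float = DEFAULT_CONDITION_CAP,
) -> GBCEstimate:
    """Full pipeline: correlations -> path coefficients -> D-GBC or C-GBC.

    ``target`` is a dosage vector (per-animal "genotype data" mode) or a
    composite-breed frequency vector ("correlation data" mode); the
    reliability 1 - R is attached to the estimate.
    """
    cs = correlation_structure(target, F, method=method)
    sol = solve_path_coefficients(cs, condition_cap=condition_cap)
    if mode == "direct":
        est = d_gbc(sol.p_yx, sol.breeds, id=id)
    elif mode == "combined":
        est = c_gbc(sol.p_yx, sol.R_xx, sol.breeds, id=id)
    else:
        raise ValueError(f"unknown mode {mode!r}; use 'direct' or 'combined'")
    est.reliability = sol.reliability
    est.n_loci = sol.n_loci
    return est
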