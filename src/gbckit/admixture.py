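"""Supervised admixture model: maximum-likelihood breed proportions.

Genotype dosages are modeled as Binomial(2, f_i) under Hardy–Weinberg
equilibrium, with f_i = sum_j x_ij w_j the mixture of known reference
allele frequencies weighted by the admixture proportions W. The
log-likelihood (up to a W-independent binomial constant, which is
dropped) is

    L(W) = sum_i [ y_i ln f_i + (2 - y_i) ln(1 - f_i) ]

maximized over the simplex by bound-constrained quasi-Newton (L-BFGS-B)
on non-negative raw weights, with the objective evaluated at w / sum(w)
and the result renormalized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .containers import AlleleFrequencyTable, GBCEstimate

__all__ = [
    "AdmixtureFit",
    "mixture_frequency",
    "genotype_loglik",
    "fit_admixture",
    "estimate_admixture_gbc",
]

DEFAULT_EPS = 1e-6  # frequency clipping bound, guards ln(0) at monomorphic SNPs


@dataclass
class AdmixtureFit:
    breeds: list[str]
    W: np.ndarray
    loglik: float  # value without the binomial constant
    n_iter: int
    converged: bool
    n_loci: int


def _check_simplex(W: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if (W < -tol).any() or abs(W.sum() - 1.0) > tol:
        raise ValueError(f"weights {W} are not on the probability simplex")
    return W


def mixture_frequency(
    W: np.ndarray, F: AlleleFrequencyTable, eps: float = DEFAULT_EPS
) -> np.ndarray:
    """Per-SNP mixed allele-A frequency f = X W, clipped to [eps, 1-eps]."""
    W = _check_simplex(W)
    if W.shape != (F.n_breeds,):
        raise ValueError("weight length does not match breed count")
    f = F.freq @ W
    return np.clip(f, eps, 1.0 - eps)


def genotype_loglik(y: np.ndarray, f: np.ndarray) -> float:
    """HWE binomial log-likelihood without the constant term; loci with
    missing dosage (NaN) are skipped."""
    y = np.asarray(y, dtype=float)
    f = np.asarray(f, dtype=float)
    if y.shape != f.shape:
        raise ValueError("y and f must be aligned")
    ok = np.isfinite(y)
    y, f = y[ok], f[ok]
    if ((f <= 0) | (f >= 1)).any():
        raise ValueError("mixture frequencies must lie strictly within (0, 1)")
    return float(y @ np.log(f) + (2.0 - y) @ np.log1p(-f))


def _neg_loglik_and_grad(w, X, y, eps):
    s = w.sum()
    v = w / s
    f = np.clip(X @ v, eps, 1.0 - eps)
    ll = y @ np.log(f) + (2.0 - y) @ np.log1p(-f)
    g_f = y / f - (2.0 - y) / (1.0 - f)
    g_v = X.T @ g_f
    g_w = (g_v - v @ g_v) / s  # chain rule through w -> w/sum(w)
    return -ll, -g_w


def fit_admixture(
    y: np.ndarray,
    F: AlleleFrequencyTable,
    init: np.ndarray | str = "uniform",
    tol: float = 1e-10,
    max_iter: int = 500,
    eps: float = DEFAULT_EPS,
    nonneg: bool = True,
) -> AdmixtureFit:
    """Maximize the admixture likelihood over breed proportions.

    ``nonneg=True`` (default) keeps raw weights box-constrained at zero;
    ``nonneg=False`` uses pure rescaling with unconstrained weights.
    Loci missing in ``y`` or incomplete in ``F`` are dropped.
    """
    k = F.n_breeds
    if k < 2:
        raise ValueError("need at least 2 reference breeds")
    y = np.asarray(y, dtype=float)
    if y.shape != (F.n_snps,):
        raise ValueError("target length does not match frequency table")
    ok = np.isfinite(y) & np.isfinite(F.freq).all(axis=1)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no complete loci")
    if n < 50:
        warnings.warn(f"only {n} complete loci; estimates may be unstable")
    X, yv = F.freq[ok], y[ok]
    col_sd = X.std(axis=0)
    if (col_sd.max() > 0) and np.allclose(X, X[:, [0]], atol=1e-12):
        warnings.warn("all reference columns identical; solution is non-unique")

    if isinstance(init, str):
        if init != "uniform":
            raise ValueError(f"unknown init {init!r}")
        w0 = np.full(k, 1.0 / k)
    else:
        w0 = _check_simplex(np.asarray(init, dtype=float))

    ll0 = genotype_loglik(yv, np.clip(X @ w0, eps, 1 - eps))
    bounds = [(1e-12, None)] * k if nonneg else [(None, None)] * k
    res = optimize.minimize(
        _neg_loglik_and_grad,
        w0,
        args=(X, yv, eps),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-8},
    )
    w = np.maximum(res.x, 0.0) if nonneg else res.x
    total = w.sum()
    if total <= 0:
        raise ValueError("optimizer returned non-positive total weight")
    W = w / total
    ll = genotype_loglik(yv, np.clip(X @ W, eps, 1 - eps))
    if ll < ll0:  # keep ascent guarantee even on optimizer failure
        W, ll = w0, ll0
    return AdmixtureFit(
        breeds=list(F.breeds),
        W=W,
        loglik=ll,
        n_iter=int(res.nit),
        converged=bool(res.success),
        n_loci=n,
    )


def estimate_admixture_gbc(
    y_dosage: np.ndarray, F: AlleleFrequencyTable, animal_id: str = "", **kwargs
) -> GBCEstimate:
    fit = fit_admixture(y_dosage, F, **kwargs)
    return GBCEstimate(
        id=animal_id, method="admixture", breeds=fit.breeds,
        composition=fit.W, n_loci=fit.n_loci,
    )
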