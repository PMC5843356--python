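"""Wald Z-scores and correlation matrices from individual-level data.

Every association is a simple (marginal) linear regression with intercept;
the Wald statistic is the effect estimate divided by its standard error.
Because genotypes, mark signals and expression are standardized internally,
each Wald statistic equals the correlation-based t statistic
``r * sqrt((n-2) / (1-r^2))``, which is how the scores are computed here
(vectorized over whole matrices).  An exact-fit pair (|r| = 1) has an
undefined standard error and is reported as signed infinity with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_model import RegionDataset, RegionSummary, ValidationError, standardize


@dataclass
class AssociationResult:
    """One marginal regression: effect, standard error, Wald z, correlation r."""

    beta_hat: float
    se: float
    z: float
    r: float


def _corr_to_z(r: np.ndarray, n: int) -> np.ndarray:
    """Wald/t statistic of a simple regression from the Pearson correlation."""
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = r * np.sqrt((n - 2) / (1.0 - r**2))
    exact = np.isclose(np.abs(r), 1.0)
    if np.any(exact):
        warnings.warn(
            "perfect correlation: Wald statistic reported as +/-inf",
            RuntimeWarning,
            stacklevel=2,
        )
        z = np.where(exact, np.sign(r) * np.inf, z)
    return z


def wald_z(x: np.ndarray, y: np.ndarray) -> AssociationResult:
    """Wald statistic for the simple linear regression of ``y`` on ``x``.

    Requires n >= 4 and non-constant ``x``.  beta_hat and se are on the raw
    (unstandardized) scale; z and r are scale-free.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.shape[0]
    if y.shape[0] != n:
        raise ValidationError("x and y lengths differ")
    if n < 4:
        raise ValidationError(f"need n >= 4 observations, got {n}")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = xc @ xc
    if sxx == 0:
        raise ValidationError("predictor is constant")
    beta = (xc @ yc) / sxx
    resid = yc - beta * xc
    syy = yc @ yc
    r = 0.0 if syy == 0 else float((xc @ yc) / np.sqrt(sxx * syy))
    dof = n - 2
    s2 = (resid @ resid) / dof
    if s2 == 0:
        warnings.warn(
            "perfect fit: Wald statistic reported as +/-inf", RuntimeWarning, stacklevel=2
        )
        return AssociationResult(float(beta), 0.0, np.sign(beta) * np.inf, r)
    se = float(np.sqrt(s2 / sxx))
    return AssociationResult(float(beta), se, float(beta / se), r)


def build_summary(d: RegionDataset, corr_floor: float = 1e-6) -> RegionSummary:
    """Compute the full summary-statistic view of a region.

    Zg[j, k] regresses mark k on SNP j; Zh[k] regresses expression on mark k;
    Zge[j] regresses expression on SNP j.  sigma_g / sigma_h are the Pearson
    correlation matrices of the genotype and mark columns, regularized to be
    positive definite.
    """
    n = d.n
    if n < 4:
        raise ValidationError("need n >= 4 individuals")
    G = standardize(d.genotypes)
    H = standardize(d.marks)
    e = standardize(d.expression)
    denom = n - 1
    Rg = (G.T @ H) / denom  # SNP-mark correlations
    Rh = (H.T @ e) / denom
    Rge = (G.T @ e) / denom
    with warnings.catch_warnings():
        warnings.simplefilter("always")
        Zg = _corr_to_z(np.clip(Rg, -1, 1), n)
        Zh = _corr_to_z(np.clip(Rh, -1, 1), n)
        Zge = _corr_to_z(np.clip(Rge, -1, 1), n)
    sigma_g = regularize_corr((G.T @ G) / denom, floor=corr_floor)
    sigma_h = regularize_corr((H.T @ H) / denom, floor=corr_floor)
    return RegionSummary(
        Zg=Zg,
        Zh=Zh,
        Zge=Zge,
        sigma_g=sigma_g,
        sigma_h=sigma_h,
        n=n,
        snp_ids=list(d.snp_ids),
        mark_ids=list(d.mark_ids),
    )


def regularize_corr(R: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Project a correlation matrix to the PD cone by eigenvalue clipping.

    Eigenvalues below ``floor`` are raised to it and the result is rescaled to
    unit diagonal; entries are clipped to [-1, 1].  A matrix that already
    satisfies the floor is returned unchanged (up to symmetrization).
    """
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValidationError("correlation matrix must be square")
    R = 0.5 * (R + R.T)
    np.fill_diagonal(R, 1.0)
    R = np.clip(R, -1.0, 1.0)
    # unit-diagonal rescaling after clipping can nudge the spectrum back below
    # the floor, so iterate to a fixed point (converges in a few passes)
    for _ in range(20):
        w, V = np.linalg.eigh(R)
        if w[0] >= floor * (1 - 1e-9):
            break
        w = np.maximum(w, floor)
        R2 = (V * w) @ V.T
        dinv = 1.0 / np.sqrt(np.diag(R2))
        R = np.clip(0.5 * (R2 + R2.T) * np.outer(dinv, dinv), -1.0, 1.0)
        np.fill_diagonal(R, 1.0)
    return R
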