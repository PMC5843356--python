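"""Likelihood and posterior engine for hierarchical path fine-mapping.

A causal *path* is the hypothesis that one SNP c perturbs one chromatin mark
d, which in turn drives expression of the region's gene.  For each of the
s*t candidate paths the engine evaluates

* the mark-expression likelihood: the vector of mark-expression Z-scores is
  multivariate normal with mean 0 and covariance
  ``sigma_h + sigma_h (w e_d e_d' + eps I) sigma_h``, obtained by integrating
  the causal mark's non-centrality parameter (NCP) against a N(0, w) prior
  (w = prior_ncp_var); inter-mark correlations propagate the signal to
  non-causal marks;

* the SNP-mark likelihood: the s x t matrix of SNP-mark Z-scores is
  matrix-variate normal with row covariance sigma_g (LD), column covariance
  sigma_h, and mean M[j, k] = sigma_g[j, c] * sigma_h[k, d] * Zg[c, d] — the
  causal pair's NCP, approximated by its observed (signed) Z-score,
  attenuated through both correlation structures.

Posteriors follow by Bayes' rule with a uniform (or user-supplied) prior
over paths, normalized by log-sum-exp over all s*t hypotheses.  The Cholesky
factors of sigma_g and sigma_h are computed once per region and shared by
every path: with unit-diagonal correlation matrices the matrix-normal
log-likelihood of path (c, d) reduces to ``const - (q - Zg[c,d]^2) / 2``
where q is a path-independent quadratic form, so the whole s x t likelihood
surface costs one pair of triangular solves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.special import logsumexp

from .data_model import ModelPrior, PathPosterior, RegionSummary, ValidationError


@dataclass(frozen=True)
class PathHypothesis:
    """Single-causal hypothesis: SNP ``snp_index`` -> mark ``mark_index`` -> expression."""

    snp_index: int
    mark_index: int


def _chol(mat: np.ndarray, what: str) -> np.ndarray:
    try:
        return linalg.cholesky(mat, lower=True)
    except linalg.LinAlgError as err:
        raise ValidationError(
            f"{what} is not positive definite; regularize it first "
            "(association.regularize_corr)"
        ) from err


def _mvn_logpdf_zero_mean(x: np.ndarray, cov: np.ndarray) -> float:
    """log N(x; 0, cov) via Cholesky."""
    L = _chol(cov, "covariance")
    alpha = linalg.solve_triangular(L, x, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    k = x.shape[0]
    return float(-0.5 * (k * np.log(2 * np.pi) + logdet + alpha @ alpha))


def mark_expression_loglik(
    Zh: np.ndarray,
    sigma_h: np.ndarray,
    d: int,
    prior: ModelPrior | None = None,
) -> float:
    """Log-likelihood of the mark-expression Z-scores given causal mark ``d``.

    Covariance: sigma_h + sigma_h @ (w * e_d e_d' + eps * I) @ sigma_h with
    w = prior.prior_ncp_var, eps = prior.diag_eps.
    """
    prior = prior or ModelPrior()
    Zh = np.asarray(Zh, dtype=float).ravel()
    sigma_h = np.asarray(sigma_h, dtype=float)
    t = Zh.shape[0]
    if not (0 <= d < t):
        raise ValidationError(f"mark index {d} out of range for t={t}")
    sd = sigma_h[:, d]
    cov = (
        sigma_h
        + prior.diag_eps * (sigma_h @ sigma_h)
        + prior.prior_ncp_var * np.outer(sd, sd)
    )
    return _mvn_logpdf_zero_mean(Zh, cov)


def snp_mark_loglik(
    Zg: np.ndarray,
    sigma_g: np.ndarray,
    sigma_h: np.ndarray,
    c: int,
    d: int,
) -> float:
    """Matrix-variate normal log-likelihood of the SNP-mark Z-score matrix.

    Zg ~ MN(M, sigma_g, sigma_h) with M[j, k] =
    sigma_g[j, c] * sigma_h[k, d] * Zg[c, d]; equivalent to the multivariate
    normal density of vec(Zg) with covariance kron(sigma_h, sigma_g).
    """
    Zg = np.asarray(Zg, dtype=float)
    s, t = Zg.shape
    if not (0 <= c < s and 0 <= d < t):
        raise ValidationError(f"path ({c}, {d}) out of range for ({s}, {t})")
    Lg = _chol(np.asarray(sigma_g, dtype=float), "sigma_g")
    Lh = _chol(np.asarray(sigma_h, dtype=float), "sigma_h")
    M = np.outer(sigma_g[:, c], sigma_h[:, d]) * Zg[c, d]
    resid = Zg - M
    A = linalg.solve_triangular(Lg, resid, lower=True)
    B = linalg.solve_triangular(Lh, A.T, lower=True)
    quad = float(np.sum(B * B))
    logdet_g = 2.0 * np.sum(np.log(np.diag(Lg)))
    logdet_h = 2.0 * np.sum(np.log(np.diag(Lh)))
    return float(
        -0.5 * (s * t * np.log(2 * np.pi) + t * logdet_g + s * logdet_h + quad)
    )


def _snp_mark_logliks_all(
    Zg: np.ndarray, sigma_g: np.ndarray, sigma_h: np.ndarray
) -> np.ndarray:
    """All s*t matrix-normal log-likelihoods at once.

    For unit-diagonal sigma_g/sigma_h the quadratic form of path (c, d)
    collapses to q0 - Zg[c, d]^2, with q0 = ||Lg^{-1} Zg Lh^{-T}||_F^2 shared
    by all paths (the whitened mean has squared norm Zg[c, d]^2 and its inner
    product with the whitened data is also Zg[c, d]^2).
    """
    Lg = _chol(sigma_g, "sigma_g")
    Lh = _chol(sigma_h, "sigma_h")
    s, t = Zg.shape
    A = linalg.solve_triangular(Lg, Zg, lower=True)
    B = linalg.solve_triangular(Lh, A.T, lower=True)
    q0 = float(np.sum(B * B))
    logdet_g = 2.0 * np.sum(np.log(np.diag(Lg)))
    logdet_h = 2.0 * np.sum(np.log(np.diag(Lh)))
    const = -0.5 * (s * t * np.log(2 * np.pi) + t * logdet_g + s * logdet_h)
    return const - 0.5 * (q0 - Zg**2)


def path_posteriors(
    summ: RegionSummary, prior: ModelPrior | None = None
) -> PathPosterior:
    """Posterior probability of every single-SNP/single-mark causal path.

    P(c, d | Z) is proportional to
    exp(mark_expression_loglik(d) + snp_mark_loglik(c, d)) * path_prior[c, d],
    normalized over all s*t paths; marginals are row/column sums.
    """
    prior = prior or ModelPrior()
    s, t = summ.s, summ.t
    if not np.all(np.isfinite(summ.Zg)) or not np.all(np.isfinite(summ.Zh)):
        raise ValidationError(
            "non-finite Z-scores (perfect-fit pairs) cannot enter the likelihood"
        )
    ll_h = np.array(
        [mark_expression_loglik(summ.Zh, summ.sigma_h, d, prior) for d in range(t)]
    )
    ll_g = _snp_mark_logliks_all(summ.Zg, summ.sigma_g, summ.sigma_h)
    log_prior = np.log(prior.path_prior_for(s, t))
    log_joint = ll_g + ll_h[np.newaxis, :] + log_prior
    if not np.any(np.isfinite(log_joint)):
        raise ValidationError("degenerate region: every path has zero likelihood")
    log_norm = float(logsumexp(log_joint))
    probs = np.exp(log_joint - log_norm)
    probs /= probs.sum()  # remove residual rounding
    return PathPosterior(
        path_probs=probs,
        log_evidence=log_norm,
        snp_ids=list(summ.snp_ids or []) or None,
        mark_ids=list(summ.mark_ids or []) or None,
    )


def credible_set(probs: np.ndarray, rho: float) -> list[int]:
    """Smallest set of top-probability candidates with cumulative mass >= rho.

    Candidates are ordered by descending probability, ties broken by
    ascending index (deterministic).
    """
    if not (0 < rho < 1):
        raise ValidationError(f"credible level must be in (0, 1), got {rho}")
    probs = np.asarray(probs, dtype=float).ravel()
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-6:
        raise ValidationError("probabilities must be non-negative and sum to 1")
    order = np.lexsort((np.arange(probs.size), -probs))
    csum = np.cumsum(probs[order])
    k = int(np.searchsorted(csum, rho - 1e-12) + 1)
    k = min(k, probs.size)
    return [int(i) for i in order[:k]]
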