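"""Comparator methods: independent two-level fine-mapping, naive association
ranking, and the classical hQTL + eQTL overlap analysis.

These are the standard approaches a molecular-QTL analyst would reach for
before modelling the SNP -> mark -> expression chain jointly; they serve as
benchmarks for the hierarchical engine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .data_model import (
    ModelPrior,
    PathPosterior,
    RegionDataset,
    RegionSummary,
    ValidationError,
    standardize,
)


# ---------------------------------------------------------------------------
# Independent two-level fine-mapping
# ---------------------------------------------------------------------------


def _log_abf(z: np.ndarray, W: float) -> np.ndarray:
    """Log approximate Bayes factor for a single-causal-variant model.

    BF(z) = sqrt(1/(1+W)) * exp(z^2 * W / (2 * (1+W))) with W the prior
    effect (NCP) variance.
    """
    z = np.asarray(z, dtype=float)
    return -0.5 * np.log1p(W) + z**2 * W / (2.0 * (1.0 + W))


def independent_finemap(
    summ: RegionSummary, prior_var: float = 5.0
) -> PathPosterior:
    """Fine-map the two levels separately and multiply the posteriors.

    Mark posteriors come from single-causal approximate Bayes factors on the
    mark-expression Z-scores; conditional SNP posteriors come from each
    candidate mark's column of SNP-mark Z-scores.  The path posterior is
    P(snp c | mark d) * P(mark d), which is normalized by construction.
    Ignores LD and mark correlations entirely.
    """
    log_bf_mark = _log_abf(summ.Zh, prior_var)
    log_bf_snp = _log_abf(summ.Zg, prior_var)  # s x t
    if np.allclose(summ.Zh, summ.Zh[0]) and np.allclose(summ.Zg, summ.Zg.ravel()[0]):
        warnings.warn("degenerate Z-scores: uniform path posterior", RuntimeWarning)
    log_p_mark = log_bf_mark - _logsumexp(log_bf_mark)
    log_p_snp = log_bf_snp - _logsumexp(log_bf_snp, axis=0, keepdims=True)
    log_path = log_p_snp + log_p_mark[np.newaxis, :]
    probs = np.exp(log_path - _logsumexp(log_path))
    probs /= probs.sum()
    return PathPosterior(
        path_probs=probs,
        log_evidence=float("nan"),
        snp_ids=list(summ.snp_ids or []) or None,
        mark_ids=list(summ.mark_ids or []) or None,
    )


def _logsumexp(a, axis=None, keepdims=False):
    from scipy.special import logsumexp

    return logsumexp(a, axis=axis, keepdims=keepdims)


# ---------------------------------------------------------------------------
# Naive association ranking
# ---------------------------------------------------------------------------


@dataclass
class NaiveRanking:
    """Rank orders (best first) from marginal association magnitudes."""

    snp_order: list[int]  # by |Zge| descending
    mark_order: list[int]  # by |Zh| descending
    path_order: list[tuple[int, int]]  # by |Zge[c]| * |Zh[d]| descending
    path_scores: np.ndarray  # s x t


def naive_ranking(summ: RegionSummary) -> NaiveRanking:
    """Rank SNPs by |SNP-expression Z|, marks by |mark-expression Z|, and
    paths by the product of the two; ties break by ascending index."""
    a_snp = np.abs(summ.Zge)
    a_mark = np.abs(summ.Zh)
    snp_order = np.lexsort((np.arange(summ.s), -a_snp))
    mark_order = np.lexsort((np.arange(summ.t), -a_mark))
    scores = np.outer(a_snp, a_mark)
    flat = np.lexsort((np.arange(scores.size), -scores.ravel()))
    path_order = [(int(i // summ.t), int(i % summ.t)) for i in flat]
    return NaiveRanking(
        snp_order=[int(i) for i in snp_order],
        mark_order=[int(i) for i in mark_order],
        path_order=path_order,
        path_scores=scores,
    )


# ---------------------------------------------------------------------------
# hQTL + eQTL overlap analysis
# ---------------------------------------------------------------------------


@dataclass
class OverlapResult:
    """Candidate sets from the classical top-SNP-per-phenotype overlap."""

    top_snp_per_mark: list[int]
    adjusted_p: np.ndarray  # length t, permutation-adjusted
    q_values: np.ndarray  # length t
    retained_marks: list[int]  # q <= fdr level
    top_eqtl_snp: int
    eqtl_adjusted_p: float
    candidate_paths: list[tuple[int, int]]  # (top hQTL SNP, mark) for retained marks


def overlap_analysis(
    d: RegionDataset,
    B: int = 999,
    fdr: float = 0.10,
    rng: np.random.Generator | None = None,
) -> OverlapResult:
    """Top-SNP-per-mark hQTL mapping with permutation-adjusted p-values.

    For every mark (and for expression) the strongest SNP association is
    recorded; its adjusted p-value is the permutation tail probability of the
    region-wide max |Z| under phenotype shuffling,
    p = (1 + #{b : max|Z|_b >= obs}) / (B + 1).  Mark-level q-values
    (Benjamini-Hochberg) gate the retained set at the given FDR.
    """
    if B < 100:
        raise ValidationError("need at least 100 permutations for a stable tail")
    rng = rng if rng is not None else np.random.default_rng(0)
    n = d.n
    G = standardize(d.genotypes)  # n x s
    Y = standardize(np.column_stack([d.marks, d.expression[:, None]]))  # n x (t+1)
    denom = n - 1
    # |Z| is monotone in |r| at fixed n, so the max-|Z| SNP is the max-|r| SNP
    R_obs = np.abs(G.T @ Y) / denom  # s x (t+1)
    top_snp = R_obs.argmax(axis=0)
    obs_max = R_obs.max(axis=0)

    perm_idx = np.argsort(rng.random((B, n)), axis=1)
    exceed = np.zeros(Y.shape[1], dtype=int)
    for b in range(B):
        Rp = np.abs(G.T @ Y[perm_idx[b]]) / denom
        exceed += Rp.max(axis=0) >= obs_max
    adj_p = (1.0 + exceed) / (B + 1.0)

    mark_p = adj_p[:-1]
    eqtl_p = float(adj_p[-1])
    _, qvals, _, _ = multipletests(mark_p, method="fdr_bh")
    retained = [int(k) for k in np.flatnonzero(qvals <= fdr)]
    paths = [(int(top_snp[k]), k) for k in retained]
    return OverlapResult(
        top_snp_per_mark=[int(j) for j in top_snp[:-1]],
        adjusted_p=mark_p,
        q_values=qvals,
        retained_marks=retained,
        top_eqtl_snp=int(top_snp[-1]),
        eqtl_adjusted_p=eqtl_p,
        candidate_paths=paths,
    )
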