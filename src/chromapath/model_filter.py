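"""Pre-filter and consistency diagnostics for the mediated causal model.

Before fine-mapping a region it is worth asking whether the data show any
evidence for the SNP -> mark -> expression chain at all.  The two-stage
regression filter (1) regresses expression on all marks jointly and
(2) regresses the chromatin-explained part of expression (the stage-1 fitted
values) on each SNP; a region is kept iff some SNP passes the Bonferroni
threshold 0.05 / n_snps.  Post-hoc diagnostics check whether top-ranked
paths behave like mediation: the SNP-expression effect should equal the
product of the SNP-mark and mark-expression effects, and the SNP should be
conditionally independent of expression given the mark (but not of the mark
given expression).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import wald_z
from .data_model import RegionDataset, ValidationError, standardize


@dataclass
class FilterReport:
    """Outcome of the two-stage regression filter for one region."""

    keep: bool
    min_p: float
    threshold: float
    n_snps: int
    best_snp: int


def two_stage_filter(d: RegionDataset, ridge_scale: float = 1e-3) -> FilterReport:
    """Two-stage regression filter for evidence of chromatin mediation.

    Stage 1 fits expression on all marks jointly (OLS; ridge with penalty
    ridge_scale * t on standardized marks when the mark matrix is
    rank-deficient or t >= n - 1).  Stage 2 regresses the fitted values on
    each SNP marginally; the region is kept iff min p < 0.05 / s.
    """
    H = standardize(d.marks)
    e = standardize(d.expression)
    n, t = H.shape
    X = np.column_stack([np.ones(n), H])
    use_ridge = n <= t + 1 or np.linalg.matrix_rank(H) < t
    if use_ridge:
        warnings.warn(
            "mark matrix is (near-)singular: stage-1 fit uses ridge",
            RuntimeWarning,
        )
        lam = ridge_scale * t
        coef = np.linalg.solve(H.T @ H + lam * np.eye(t), H.T @ e)
        fitted = H @ coef
    else:
        coef, *_ = np.linalg.lstsq(X, e, rcond=None)
        fitted = X @ coef
    pvals = np.empty(d.s)
    for j in range(d.s):
        res = wald_z(d.genotypes[:, j], fitted)
        pvals[j] = 2.0 * stats.t.sf(abs(res.z), d.n - 2) if np.isfinite(res.z) else 0.0
    threshold = 0.05 / d.s
    best = int(pvals.argmin())
    return FilterReport(
        keep=bool(pvals[best] < threshold),
        min_p=float(pvals[best]),
        threshold=threshold,
        n_snps=d.s,
        best_snp=best,
    )


def partial_corr(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> tuple[float, float]:
    """First-order partial correlation of x and y controlling for z.

    r_xy.z = (r_xy - r_xz * r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)), with a
    two-sided p-value from the t transform on n - 3 degrees of freedom.
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    z = np.asarray(z, float).ravel()
    n = x.size
    if y.size != n or z.size != n:
        raise ValidationError("x, y, z must share length")
    if n < 5:
        raise ValidationError("need n >= 5 for a partial correlation")
    r_xy = float(np.corrcoef(x, y)[0, 1])
    r_xz = float(np.corrcoef(x, z)[0, 1])
    r_yz = float(np.corrcoef(y, z)[0, 1])
    denom = (1 - r_xz**2) * (1 - r_yz**2)
    if denom <= 0:
        raise ValidationError("degenerate conditioning: |r| = 1 with the covariate")
    r = (r_xy - r_xz * r_yz) / np.sqrt(denom)
    r = float(np.clip(r, -1.0, 1.0))
    dof = n - 3
    if abs(r) == 1.0:
        return r, 0.0
    tstat = r * np.sqrt(dof / (1 - r**2))
    p = float(2.0 * stats.t.sf(abs(tstat), dof))
    return r, p


def weighted_pearson(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Pearson correlation with non-negative observation weights."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    w = w / w.sum()
    mx, my = w @ x, w @ y
    cov = w @ ((x - mx) * (y - my))
    vx = w @ (x - mx) ** 2
    vy = w @ (y - my) ** 2
    return float(cov / np.sqrt(vx * vy))


def mediation_consistency(
    top_paths: list[tuple[object, int, int, float]],
    data: dict[object, RegionDataset],
) -> pd.DataFrame:
    """Mediation diagnostics for a collection of top paths.

    ``top_paths`` holds (region_key, snp_index, mark_index, posterior); the
    matching RegionDataset is looked up in ``data``.  For each path the
    product of the standardized SNP->mark and mark->expression effects is
    compared with the total SNP->expression effect, and both conditional
    independencies are tested at the Bonferroni level 0.05 / n_paths.  The
    posterior-weighted Pearson correlation between product and total effects
    is stored in ``df.attrs['weighted_correlation']``.
    """
    if len(top_paths) < 3:
        raise ValidationError("need at least 3 top paths for the diagnostic")
    rows = []
    thr = 0.05 / len(top_paths)
    for key, c, d_idx, post in top_paths:
        reg = data[key]
        g = standardize(reg.genotypes[:, c])
        h = standardize(reg.marks[:, d_idx])
        e = standardize(reg.expression)
        b_gm = float(np.corrcoef(g, h)[0, 1])  # standardized effects = correlations
        b_me = float(np.corrcoef(h, e)[0, 1])
        b_ge = float(np.corrcoef(g, e)[0, 1])
        r_ge_h, p_ge_h = partial_corr(g, e, h)
        r_gh_e, p_gh_e = partial_corr(g, h, e)
        rows.append(
            {
                "region": key,
                "snp": c,
                "mark": d_idx,
                "posterior": post,
                "effect_product": b_gm * b_me,
                "snp_expression_effect": b_ge,
                "partial_snp_expr_given_mark": r_ge_h,
                "p_snp_expr_given_mark": p_ge_h,
                "snp_expr_given_mark_significant": p_ge_h < thr,
                "partial_snp_mark_given_expr": r_gh_e,
                "p_snp_mark_given_expr": p_gh_e,
                "snp_mark_given_expr_significant": p_gh_e < thr,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["weighted_correlation"] = weighted_pearson(
        df["effect_product"].to_numpy(),
        df["snp_expression_effect"].to_numpy(),
        df["posterior"].to_numpy(),
    )
    df.attrs["bonferroni_threshold"] = thr
    return df
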