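"""Region simulator with known causal architecture.

Generates individual-level genotype/mark/expression data under the mediated
causal model (SNP -> mark -> expression) and under a suite of deviations
from it: multi-causal variants and seven qualitative model violations.

Genotypes come from a latent-Gaussian model: a latent MVN draw with the
configured LD structure is thresholded into dosages {0, 1, 2} at the
quantiles implied by a per-SNP minor-allele frequency drawn Uniform(0.05,
0.5), then column-standardized.  This stands in for empirical reference-panel
LD while keeping the correlation strength tunable (blockwise-exchangeable or
AR(1) families).

Mark signals are drawn from an MVN around the means the causal mark induces
through the mark correlation matrix: the causal mark's genetic mean is
H_c = beta_g * G_c with beta_g ~ N(0, var_explained_g), every mark k gets
mean H_c * sigma_h[d, k], and the noise covariance is
(1 - var_explained_g) * sigma_h.  Expression is E = beta_h * H_d + eps with
beta_h = sqrt(var_explained_h) and eps ~ N(0, 1 - var_explained_h), so the
realized R^2 at each level matches its variance-explained target in
expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .data_model import CausalConfig, RegionDataset, ValidationError, standardize

_MAX_REJECTIONS = 100_000

# mark-type labels cycled over simulated peaks, mirroring the four assay
# types analysed jointly in LCL data
_MARK_TYPES = ("DHS", "H3K4me1", "H3K4me3", "H3K27ac")


@dataclass
class SimConfig:
    """Study-condition parameters for one batch of simulated regions.

    Defaults reproduce the reference simulation protocol: n=100 individuals,
    variance explained 0.25 at both the SNP->mark and mark->expression
    levels, with blockwise correlation structure of realistic strength
    (SNP LD r=0.65 in blocks of 10; mark correlation r=0.5 in blocks of 5).
    """

    n: int = 100
    s: int = 50
    t: int = 10
    var_explained_g: float = 0.25
    var_explained_h: float = 0.25
    ld_model: str = "blockwise"
    ld_block_size: int = 10
    ld_corr: float = 0.65
    mark_corr_model: str = "blockwise"
    mark_block_size: int = 5
    mark_corr: float = 0.5
    scenario: str = "standard"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n <= 3:
            raise ValidationError("need n > 3 individuals")
        for frac in (self.var_explained_g, self.var_explained_h):
            if not (0 <= frac < 1):
                raise ValidationError("variance fractions must lie in [0, 1)")
        for r in (self.ld_corr, self.mark_corr):
            if not (0 <= r < 1):
                raise ValidationError("correlation parameters must lie in [0, 1)")
        for model in (self.ld_model, self.mark_corr_model):
            if model not in ("blockwise", "ar1", "identity"):
                raise ValidationError(f"unknown correlation model {model!r}")


def _corr_matrix(model: str, p: int, block: int, r: float) -> np.ndarray:
    if model == "identity":
        return np.eye(p)
    if model == "blockwise":
        R = np.eye(p)
        for start in range(0, p, block):
            stop = min(start + block, p)
            R[start:stop, start:stop] = r
        np.fill_diagonal(R, 1.0)
        return R
    # ar1
    idx = np.arange(p)
    return r ** np.abs(idx[:, None] - idx[None, :])


def sample_structure(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw standardized genotype dosages and the target mark correlation matrix."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    R = _corr_matrix(cfg.ld_model, cfg.s, cfg.ld_block_size, cfg.ld_corr)
    maf = rng.uniform(0.05, 0.5, size=cfg.s)
    # Hardy-Weinberg genotype frequencies define the latent thresholds
    q0 = stats.norm.ppf((1 - maf) ** 2)
    q1 = stats.norm.ppf(1 - maf**2)
    # thresholding attenuates the latent correlation by lambda_i * lambda_j
    # (first Hermite coefficient of the dosage step function); inflate the
    # latent correlation so the realized dosage correlation hits the target
    p1 = 2 * maf * (1 - maf)
    p2 = maf**2
    var_d = p1 + 4 * p2 - (2 * maf) ** 2
    lam = (stats.norm.pdf(q0) + stats.norm.pdf(q1)) / np.sqrt(var_d)
    if cfg.ld_model != "identity":
        R = np.clip(R / np.outer(lam, lam), -0.99, 0.99)
        np.fill_diagonal(R, 1.0)
        from .association import regularize_corr

        R = regularize_corr(R, floor=1e-6)
    latent = rng.multivariate_normal(np.zeros(cfg.s), R, size=cfg.n, method="cholesky")
    dosage = (latent > q0).astype(float) + (latent > q1)
    # guard against monomorphic draws at small n: flip one individual
    for j in np.flatnonzero(dosage.std(axis=0) == 0):
        i = int(rng.integers(cfg.n))
        dosage[i, j] = 1.0 if dosage[i, j] != 1.0 else 2.0
    G = standardize(dosage)
    sigma_h = _corr_matrix(cfg.mark_corr_model, cfg.t, cfg.mark_block_size, cfg.mark_corr)
    return G, sigma_h


def _draw_marks(
    rng: np.random.Generator,
    mean: np.ndarray,
    sigma_h: np.ndarray,
    noise_scale: float,
) -> np.ndarray:
    n, t = mean.shape
    L = np.linalg.cholesky(sigma_h)
    noise = rng.standard_normal((n, t)) @ (np.sqrt(noise_scale) * L.T)
    return mean + noise


def _finish(
    cfg: SimConfig,
    G: np.ndarray,
    H: np.ndarray,
    E: np.ndarray,
    truth: CausalConfig,
) -> tuple[RegionDataset, CausalConfig]:
    d = RegionDataset(
        genotypes=G,
        marks=H,
        expression=E,
        snp_ids=[f"snp{j}" for j in range(cfg.s)],
        mark_ids=[f"mark{k}" for k in range(cfg.t)],
        mark_types=[_MARK_TYPES[k % len(_MARK_TYPES)] for k in range(cfg.t)],
    )
    return d, truth


def simulate_standard(
    cfg: SimConfig,
    genotypes: np.ndarray | None = None,
    sigma_h: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[RegionDataset, CausalConfig]:
    """One region with a single causal SNP -> single causal mark -> expression."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    if genotypes is None or sigma_h is None:
        genotypes, sigma_h = sample_structure(cfg, rng)
    G = genotypes
    c = int(rng.integers(cfg.s))
    d = int(rng.integers(cfg.t))
    beta_g = float(rng.normal(0.0, np.sqrt(cfg.var_explained_g)))
    Hc_mean = beta_g * G[:, c]
    mean = np.outer(Hc_mean, sigma_h[d])
    H = _draw_marks(rng, mean, sigma_h, 1.0 - cfg.var_explained_g)
    beta_h = float(np.sqrt(cfg.var_explained_h))
    E = beta_h * H[:, d] + rng.normal(0.0, np.sqrt(1.0 - cfg.var_explained_h), cfg.n)
    truth = CausalConfig(
        causal_snps=[c],
        causal_marks=[d],
        scenario="standard",
        beta_g=[beta_g],
        beta_h=[beta_h],
        var_explained_g=cfg.var_explained_g,
        var_explained_h=cfg.var_explained_h,
    )
    return _finish(cfg, G, H, E, truth)


def _binomial_at_least_two(
    rng: np.random.Generator, n_trials: int
) -> int:
    """Draw from Binomial(n_trials, 1/n_trials) conditioned on >= 2."""
    p = 1.0 / n_trials
    for _ in range(_MAX_REJECTIONS):
        m = int(rng.binomial(n_trials, p))
        if m >= 2:
            return m
    raise ValidationError("rejection sampling failed to produce >= 2 causals")


def simulate_multi(
    cfg: SimConfig,
    which: str,
    genotypes: np.ndarray | None = None,
    sigma_h: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    n_causal: int | None = None,
) -> tuple[RegionDataset, CausalConfig]:
    """Multiple causal SNPs (``which='snps'``) or marks (``which='marks'``).

    The causal count is binomial with expectation 1, conditioned on >= 2
    (or forced via ``n_causal``); per-causal effect variances scale as 1/m
    (or 1/p) so the total expected variance explained stays at its target.
    """
    if which not in ("snps", "marks"):
        raise ValidationError("which must be 'snps' or 'marks'")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    if genotypes is None or sigma_h is None:
        genotypes, sigma_h = sample_structure(cfg, rng)
    G = genotypes

    if which == "snps":
        m = n_causal if n_causal is not None else _binomial_at_least_two(rng, cfg.s)
        m = min(m, cfg.s)
        snps = sorted(int(j) for j in rng.choice(cfg.s, size=m, replace=False))
        d = int(rng.integers(cfg.t))
        betas = rng.normal(0.0, np.sqrt(cfg.var_explained_g / m), size=m)
        Hc_mean = G[:, snps] @ betas
        mean = np.outer(Hc_mean, sigma_h[d])
        H = _draw_marks(rng, mean, sigma_h, 1.0 - cfg.var_explained_g)
        beta_h = float(np.sqrt(cfg.var_explained_h))
        E = beta_h * H[:, d] + rng.normal(0.0, np.sqrt(1.0 - cfg.var_explained_h), cfg.n)
        truth = CausalConfig(
            causal_snps=snps,
            causal_marks=[d],
            scenario="multi_snp",
            beta_g=[float(b) for b in betas],
            beta_h=[beta_h],
            var_explained_g=cfg.var_explained_g,
            var_explained_h=cfg.var_explained_h,
        )
        return _finish(cfg, G, H, E, truth)

    p = n_causal if n_causal is not None else _binomial_at_least_two(rng, cfg.t)
    p = min(p, cfg.t)
    marks = sorted(int(k) for k in rng.choice(cfg.t, size=p, replace=False))
    c = int(rng.integers(cfg.s))
    beta_gs = rng.normal(0.0, np.sqrt(cfg.var_explained_g), size=p)
    mean = np.zeros((cfg.n, cfg.t))
    for bg, d in zip(beta_gs, marks):
        mean += np.outer(bg * G[:, c], sigma_h[d])
    H = _draw_marks(rng, mean, sigma_h, 1.0 - cfg.var_explained_g)
    beta_hs = rng.normal(0.0, np.sqrt(cfg.var_explained_h / p), size=p)
    E = H[:, marks] @ beta_hs + rng.normal(
        0.0, np.sqrt(1.0 - cfg.var_explained_h), cfg.n
    )
    truth = CausalConfig(
        causal_snps=[c],
        causal_marks=marks,
        scenario="multi_mark",
        beta_g=[float(b) for b in beta_gs],
        beta_h=[float(b) for b in beta_hs],
        var_explained_g=cfg.var_explained_g,
        var_explained_h=cfg.var_explained_h,
    )
    return _finish(cfg, G, H, E, truth)


def simulate_violation(
    cfg: SimConfig,
    kind: int,
    genotypes: np.ndarray | None = None,
    sigma_h: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[RegionDataset, CausalConfig]:
    """Generate a region under one of seven causal-diagram violations.

    1. multiple causal SNPs -> one causal mark -> expression
    2. one causal SNP -> multiple causal marks -> expression
    3. two disjoint SNP -> mark paths, both marks -> expression
    4. standard path plus a second SNP with a direct effect on expression
    5. standard path plus a second (non-genetic) mark effect on expression
    6. SNP -> expression -> mark (reversed order at the mark level)
    7. SNP -> mark and SNP -> expression independently (no mediation)
    """
    if kind not in range(1, 8):
        raise ValidationError(f"violation kind must be 1..7, got {kind}")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    if genotypes is None or sigma_h is None:
        genotypes, sigma_h = sample_structure(cfg, rng)
    G = genotypes
    vg, vh = cfg.var_explained_g, cfg.var_explained_h

    if kind == 1:
        d, t = simulate_multi(cfg, "snps", G, sigma_h, rng)
        return d, replace(t, scenario="violation1")
    if kind == 2:
        d, t = simulate_multi(cfg, "marks", G, sigma_h, rng)
        return d, replace(t, scenario="violation2")

    if kind == 3:
        snps = sorted(int(j) for j in rng.choice(cfg.s, size=2, replace=False))
        marks = sorted(int(k) for k in rng.choice(cfg.t, size=2, replace=False))
        betas = rng.normal(0.0, np.sqrt(vg / 2), size=2)
        mean = np.zeros((cfg.n, cfg.t))
        for (c, d_), bg in zip(zip(snps, marks), betas):
            mean += np.outer(bg * G[:, c], sigma_h[d_])
        H = _draw_marks(rng, mean, sigma_h, 1.0 - vg)
        beta_hs = np.full(2, np.sqrt(vh / 2))
        # correlated causal marks add a covariance term; keep total variance ~1
        noise_var = max(1.0 - vh - vh * sigma_h[marks[0], marks[1]], 0.05)
        E = H[:, marks] @ beta_hs + rng.normal(0.0, np.sqrt(noise_var), cfg.n)
        truth = CausalConfig(
            causal_snps=snps,
            causal_marks=marks,
            scenario="violation3",
            beta_g=[float(b) for b in betas],
            beta_h=[float(b) for b in beta_hs],
            var_explained_g=vg,
            var_explained_h=vh,
            causal_paths=list(zip(snps, marks)),
        )
        return _finish(cfg, G, H, E, truth)

    if kind in (4, 5):
        c = int(rng.integers(cfg.s))
        d = int(rng.integers(cfg.t))
        beta_g = float(rng.normal(0.0, np.sqrt(vg)))
        mean = np.outer(beta_g * G[:, c], sigma_h[d])
        H = _draw_marks(rng, mean, sigma_h, 1.0 - vg)
        beta_h = float(np.sqrt(vh))
        # direct (non-mediated) effect gets the same variance budget as the
        # mediated one; residual noise makes total variance ~1
        direct_var = vh
        noise_sd = np.sqrt(max(1.0 - vh - direct_var, 0.05))
        if kind == 4:
            c2 = int(rng.choice([j for j in range(cfg.s) if j != c]))
            beta_direct = float(np.sqrt(direct_var))
            E = (
                beta_h * H[:, d]
                + beta_direct * G[:, c2]
                + rng.normal(0.0, noise_sd, cfg.n)
            )
            truth = CausalConfig(
                causal_snps=[c, c2],
                causal_marks=[d],
                scenario="violation4",
                beta_g=[beta_g],
                beta_h=[beta_h],
                var_explained_g=vg,
                var_explained_h=vh,
                causal_paths=[(c, d)],
            )
        else:
            d2 = int(rng.choice([k for k in range(cfg.t) if k != d]))
            beta_h2 = float(np.sqrt(direct_var))
            # the two marks may be correlated; keep total variance ~1
            nvar = max(
                1.0 - vh - direct_var - 2 * beta_h * beta_h2 * sigma_h[d, d2], 0.05
            )
            E = (
                beta_h * H[:, d]
                + beta_h2 * H[:, d2]
                + rng.normal(0.0, np.sqrt(nvar), cfg.n)
            )
            truth = CausalConfig(
                causal_snps=[c],
                causal_marks=[d, d2],
                scenario="violation5",
                beta_g=[beta_g],
                beta_h=[beta_h, beta_h2],
                var_explained_g=vg,
                var_explained_h=vh,
                causal_paths=[(c, d)],
            )
        return _finish(cfg, G, H, E, truth)

    if kind == 6:
        # SNP -> expression, expression -> mark
        c = int(rng.integers(cfg.s))
        d = int(rng.integers(cfg.t))
        beta_e = float(rng.normal(0.0, np.sqrt(vg)))
        E = beta_e * G[:, c] + rng.normal(0.0, np.sqrt(1.0 - vg), cfg.n)
        gamma = float(np.sqrt(vh)) / max(float(E.std()), 1e-12)
        mean = np.outer(gamma * E, sigma_h[d])
        H = _draw_marks(rng, mean, sigma_h, 1.0 - vh)
        truth = CausalConfig(
            causal_snps=[c],
            causal_marks=[d],
            scenario="violation6",
            beta_g=[beta_e],
            beta_h=[gamma],
            var_explained_g=vg,
            var_explained_h=vh,
            causal_paths=[(c, d)],
        )
        return _finish(cfg, G, H, E, truth)

    # kind == 7: independent SNP -> mark and SNP -> expression effects
    c = int(rng.integers(cfg.s))
    d = int(rng.integers(cfg.t))
    beta_g = float(rng.normal(0.0, np.sqrt(vg)))
    mean = np.outer(beta_g * G[:, c], sigma_h[d])
    H = _draw_marks(rng, mean, sigma_h, 1.0 - vg)
    beta_e = float(np.sqrt(vh))
    E = beta_e * G[:, c] + rng.normal(0.0, np.sqrt(1.0 - vh), cfg.n)
    truth = CausalConfig(
        causal_snps=[c],
        causal_marks=[d],
        scenario="violation7",
        beta_g=[beta_g],
        beta_h=[beta_e],
        var_explained_g=vg,
        var_explained_h=vh,
        causal_paths=[(c, d)],
    )
    return _finish(cfg, G, H, E, truth)


def simulate_region(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[RegionDataset, CausalConfig]:
    """Dispatch on ``cfg.scenario``."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    if cfg.scenario == "standard":
        return simulate_standard(cfg, rng=rng)
    if cfg.scenario == "multi_snp":
        return simulate_multi(cfg, "snps", rng=rng)
    if cfg.scenario == "multi_mark":
        return simulate_multi(cfg, "marks", rng=rng)
    if cfg.scenario.startswith("violation"):
        return simulate_violation(cfg, int(cfg.scenario[-1]), rng=rng)
    raise ValidationError(f"unknown scenario {cfg.scenario!r}")


def simulate_regions(
    cfg: SimConfig, n_regions: int, seed: int | None = None
) -> list[tuple[RegionDataset, CausalConfig]]:
    """Simulate a reproducible batch of regions under one scenario."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    return [simulate_region(cfg, rng=rng) for _ in range(n_regions)]
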