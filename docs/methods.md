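# Methods

## Model

`chromapath` fine-maps the causal chain SNP → chromatin mark → gene
expression inside a gene-centred region with `s` SNPs and `t` chromatin
marks (peaks of any assay type — DHS, H3K4me1, H3K4me3, H3K27ac — treated
as individual quantitative phenotypes). The generative model for a single
causal path (c, d) is

    h = G β_g + ε_g,   ε_g ~ N(0, 1 − σ_g²)
    E = H β_h + ε_h,   ε_h ~ N(0, 1 − σ_h²)

with β_g non-zero only at the causal SNP c and β_h non-zero only at the
causal mark d; σ_g² and σ_h² are the variances explained at the two levels.

Inference works entirely on Wald Z-scores. Writing Σ_h for the mark
correlation matrix and Σ_g for SNP LD:

* **Mark → expression.** The vector of mark-expression Z-scores is
  multivariate normal around the non-centrality parameters (NCPs) induced
  through Σ_h. Integrating the causal mark's NCP against a N(0, w) prior
  gives

      Z_h | C_h ~ N(0, Σ_h + Σ_h (w·Diag(C_h) + ε·I) Σ_h)

  with prior NCP variance `w = prior_ncp_var` (default 5; performance is
  flat over roughly 5–10) and ridge `ε = diag_eps` (default 1e-4) keeping
  the prior covariance positive definite.

* **SNP → mark.** The s×t matrix of SNP-mark Z-scores is matrix-variate
  normal, `Z_g | C_g, C_h ~ MN(M, Σ_g, Σ_h)`, with mean
  `M[j,k] = Σ_g[j,c] · Σ_h[k,d] · λ_{c,d}`. The causal-pair NCP λ is
  approximated by the *observed signed* Z-score `Z_g[c,d]` (integration is
  not tractable in the matrix-variate setting; the signed value keeps the
  induced means directionally consistent).

* **Posterior.** With a uniform (or user-supplied) prior over the s·t
  single-SNP/single-mark paths, the posterior of path (c, d) is
  proportional to the product of the two likelihoods, normalized by
  log-sum-exp. SNP and mark marginals are row and column sums; credible
  sets take candidates in descending posterior order (ties broken by
  ascending index) until the target mass is reached.

### Numerical notes

* All densities are evaluated in log space via Cholesky factorizations.
  The factors of Σ_g and Σ_h are computed once per region and shared across
  all paths. Because both correlation matrices have unit diagonal, the
  matrix-normal quadratic form for path (c, d) reduces algebraically to
  `q₀ − Z_g[c,d]²` with a path-independent `q₀`, so the full s×t likelihood
  surface costs one pair of triangular solves; a per-path evaluation of the
  general density exists alongside and the two are tested for exact
  agreement against a brute-force vec/Kronecker multivariate-normal oracle.
  A consequence worth knowing: given the plug-in NCP, the SNP-mark level
  ranks paths by |Z_g[c,d]| alone, and the model's advantage over
  two-level independent fine-mapping comes from the mark-expression
  covariance structure.
* Empirical correlation matrices can be numerically indefinite; they are
  projected to the PD cone by eigenvalue clipping (floor 1e-6) followed by
  unit-diagonal rescaling, iterated to a fixed point. The model's own ε is
  applied exactly where the likelihood defines it (on the NCP prior
  covariance), not on Σ_g/Σ_h.
* Pairs with |r| = 1 produce infinite Wald statistics; they are reported as
  signed infinity with a warning and are rejected by the posterior engine,
  whose likelihood is undefined there.

## Association statistics

Genotypes, mark signals and expression are standardized (mean 0, unit
sample variance) before any association computation, so every Wald
statistic equals the correlation-based t statistic
`r·sqrt((n−2)/(1−r²))`; whole matrices of Z-scores are computed from cross-
correlation products. All regressions are marginal with intercept; no
covariate adjustment is attempted (upstream corrections such as PEER are
out of scope).

## Synthetic data

The simulator emulates molecular-QTL regions with known ground truth.
Defaults are the reference study conditions: n = 100 individuals, s = 50
SNPs, t = 10 marks, variance explained 0.25 at both levels, one causal SNP
and mark per region, β_g ~ N(0, σ_g²) and β_h = sqrt(σ_h²) (so the realized
mark→expression R² matches its target; the effect-size text admits either
reading and this one is variance-consistent).

* **Genotypes** come from a latent Gaussian with blockwise-exchangeable
  (default; blocks of 10 at r = 0.65) or AR(1) or identity structure,
  thresholded into dosages {0,1,2} at Hardy-Weinberg quantiles for per-SNP
  MAF ~ U(0.05, 0.5), then standardized. Thresholding attenuates
  correlations by the product of the dosage step functions' first Hermite
  coefficients, so the latent correlation is inflated per SNP pair by
  1/(λ_i λ_j) (clipped at 0.99, re-projected to PD) and the *realized*
  dosage correlation matches the configured target. The blockwise strengths
  (SNP r = 0.65, mark r = 0.5 in blocks of 5) were fixed once as realistic
  magnitudes for 50 kb regions and co-located chromatin peaks.
* **Marks** are drawn from an MVN whose mean is the causal mark's genetic
  value propagated through Σ_h (`H_ind = H_c Σ_{h,d·}`) with noise
  covariance (1 − σ_g²) Σ_h; residual mark variances are not rescaled after
  adding induced means.
* **Multi-causal variants** draw the causal count from Binomial(·, mean 1)
  conditioned on ≥ 2 (rejection capped at 1e5 draws) and scale per-causal
  effect variances by 1/m (SNPs) or 1/p (marks) so total expected variance
  explained is unchanged. In the multi-mark case each causal mark receives
  its own SNP→mark effect draw from the single causal SNP and mark-level
  effects are drawn N(0, σ_h²/p).
* **Model violations 1–7** implement: (1) multi-SNP → one mark, (2) one
  SNP → multi-mark, (3) two disjoint SNP→mark paths, (4) standard path plus
  a direct SNP→expression effect, (5) standard path plus a second mark→
  expression effect, (6) SNP → expression → mark, (7) independent SNP→mark
  and SNP→expression effects. Where the diagrams leave effect sizes open,
  the non-mediated effect receives the same variance budget (0.25) as the
  mediated one; noise variances subtract analytically-known covariance
  terms so total expression variance stays near 1. In violation 6 the mark
  mean is γ·E with γ chosen so the mark variance explained by expression
  equals σ_h².

What the generator does **not** emulate: empirical reference-panel LD (long
range, heterogeneous block sizes, allele-frequency/LD coupling), realistic
peak size/spacing, assay-specific noise, shared confounders, or batch
structure. Benchmarks on these synthetic regions therefore demonstrate
correctness and relative method behaviour, not field performance on
empirical chromatin datasets; several reference magnitudes measured on
empirical-LD simulations (notably the violation-scenario degradations and
the overlap-analysis recovery rates) do not transfer quantitatively to this
synthetic structure, as the benchmark outputs themselves show.

## Baselines

* **Independent fine-mapping**: single-causal approximate Bayes factors
  `BF(z) = sqrt(1/(1+W))·exp(z²W/(2(1+W)))` (W = 5 for comparability) on
  each mark's SNP column and on the mark-expression scores; path posterior
  is the product of the conditional SNP posterior and the mark posterior.
* **Naive ranking**: SNPs by |SNP-expression Z|, marks by
  |mark-expression Z|, paths by the product of the two magnitudes.
* **Overlap analysis**: per mark (and for expression) the top-|Z| SNP, with
  permutation-adjusted p-values `(1 + #{max|Z|_perm ≥ obs})/(B+1)` under
  phenotype shuffling (B = 999 by default; the permutation scheme is a
  design choice — shuffling genotypes would be equivalent in distribution),
  Benjamini–Hochberg q-values across marks (a conservative, dependency-free
  stand-in for Storey's estimator), and a 10% FDR gate.

## Filtering and diagnostics

The two-stage filter regresses expression on all marks jointly (ridge with
penalty 1e-3·t on standardized marks when t ≥ n − 1 or the mark matrix is
rank-deficient), then regresses the fitted values — the chromatin-explained
part of expression — on each SNP; a region is kept iff some SNP has
p < 0.05/s. Post-hoc diagnostics compute first-order partial correlations
(t transform, n − 3 df) and the posterior-weighted correlation between the
product of SNP→mark and mark→expression effects and the total
SNP→expression effect, with conditional-independence classifications at
Bonferroni 0.05/n_paths.

## Evaluation

Accumulation pools true causals across regions by *within-region rank
fraction* (regions of different sizes stay comparable; a random ranking
needs a fraction ≈ the recall level) and reports the smallest fraction
capturing the target recall. With t = 10 marks the mark-level fraction is
quantized to multiples of 10%, which floors that metric at 10%.
Credible-set calibration is the fraction of true causals inside their
level-ρ sets with binomial standard errors. The default benchmark scale is
200–500 regions at s = 50, t = 10, n = 100; the full-scale setting
(10,000 × 160 × 25) is supported through `SimConfig`/CLI parameters.

## Known limitations

* The plug-in NCP at the SNP-mark level (rather than integration) slightly
  deflates path credible sets; the package reproduces this deliberately.
* Only single-SNP/single-mark paths are enumerated; multi-causal truth is
  evaluated against this restricted hypothesis space.
* Under the committed synthetic correlation strengths the hierarchical
  model and independent fine-mapping are near-equivalent; the hierarchical
  advantage grows with mark-correlation strength (clearly visible at
  r ≈ 0.9) because the mark-expression covariance is where the models
  differ.
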