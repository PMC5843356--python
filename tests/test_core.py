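"""Likelihood and posterior engine against brute-force Gaussian oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import chromapath as cp
from chromapath.core import (
    _snp_mark_logliks_all,
    credible_set,
    mark_expression_loglik,
    path_posteriors,
    snp_mark_loglik,
)
from chromapath.data_model import ModelPrior, RegionSummary, ValidationError


def _random_corr(rng, p):
    if p == 1:
        return np.eye(1)
    A = rng.normal(size=(p, p + 3))
    R = np.corrcoef(A)
    return cp.regularize_corr(R, floor=1e-4)


class TestMarkExpressionLoglik:
    def test_frozen_diagonal_example(self):
        """t=2, sigma_h=I, w=5, eps=1e-4, d=1, Zh=0: the covariance is
        diag(1.0001, 6.0001), so the log-density is
        -log(2*pi) - 0.5*log(6.0001 * 1.0001)."""
        val = mark_expression_loglik(
            np.zeros(2), np.eye(2), d=1, prior=ModelPrior(prior_ncp_var=5, diag_eps=1e-4)
        )
        expected = -np.log(2 * np.pi) - 0.5 * np.log(6.0001 * 1.0001)
        assert val == pytest.approx(expected, abs=1e-10)
        assert val == pytest.approx(-2.7338, abs=5e-4)

    def test_matches_scipy_mvn_oracle(self, rng):
        sigma_h = _random_corr(rng, 4)
        Zh = rng.normal(size=4)
        prior = ModelPrior(prior_ncp_var=5, diag_eps=1e-4)
        d = 2
        Sc = prior.prior_ncp_var * np.diag(np.eye(4)[d]) + prior.diag_eps * np.eye(4)
        cov = sigma_h + sigma_h @ Sc @ sigma_h
        oracle = stats.multivariate_normal.logpdf(Zh, mean=np.zeros(4), cov=cov)
        assert mark_expression_loglik(Zh, sigma_h, d, prior) == pytest.approx(
            oracle, abs=1e-8
        )

    def test_null_limit_independent_of_mark(self, rng):
        sigma_h = _random_corr(rng, 3)
        Zh = rng.normal(size=3)
        prior = ModelPrior(prior_ncp_var=1e-12, diag_eps=1e-12)
        vals = [mark_expression_loglik(Zh, sigma_h, d, prior) for d in range(3)]
        assert np.ptp(vals) < 1e-8

    def test_exchangeable_marks_symmetric(self):
        sigma_h = np.full((3, 3), 0.4)
        np.fill_diagonal(sigma_h, 1.0)
        Zh = np.array([1.0, 2.0, 2.0])  # symmetric under swapping marks 1 and 2
        a = mark_expression_loglik(Zh, sigma_h, 1)
        b = mark_expression_loglik(Zh, sigma_h, 2)
        assert a == pytest.approx(b, abs=1e-10)


class TestSnpMarkLoglik:
    def test_zero_scores_identity_covariances(self):
        val = snp_mark_loglik(np.zeros((2, 2)), np.eye(2), np.eye(2), 0, 0)
        assert val == pytest.approx(-2 * np.log(2 * np.pi), abs=1e-10)

    def test_matches_kronecker_vec_oracle(self, rng):
        """Matrix-normal density equals the vec-MVN with Kronecker covariance."""
        s, t = 3, 2
        sigma_g = _random_corr(rng, s)
        sigma_h = _random_corr(rng, t)
        Zg = rng.normal(size=(s, t)) * 2
        for c in range(s):
            for d in range(t):
                M = np.outer(sigma_g[:, c], sigma_h[:, d]) * Zg[c, d]
                cov = np.kron(sigma_h, sigma_g)  # vec stacks columns
                oracle = stats.multivariate_normal.logpdf(
                    Zg.T.ravel(), mean=M.T.ravel(), cov=cov
                )
                assert snp_mark_loglik(Zg, sigma_g, sigma_h, c, d) == pytest.approx(
                    oracle, abs=1e-8
                )

    def test_vectorized_path_matches_per_path(self, rng):
        s, t = 5, 3
        sigma_g = _random_corr(rng, s)
        sigma_h = _random_corr(rng, t)
        Zg = rng.normal(size=(s, t)) * 3
        fast = _snp_mark_logliks_all(Zg, sigma_g, sigma_h)
        for c in range(s):
            for d in range(t):
                assert fast[c, d] == pytest.approx(
                    snp_mark_loglik(Zg, sigma_g, sigma_h, c, d), abs=1e-8
                )

    def test_duplicate_snp_rows_exchangeable(self, rng):
        sigma_g = np.array([[1.0, 1.0, 0.2], [1.0, 1.0, 0.2], [0.2, 0.2, 1.0]])
        sigma_g = cp.regularize_corr(sigma_g, floor=1e-6)
        sigma_h = np.eye(2)
        row = rng.normal(size=2)
        Zg = np.vstack([row, row, rng.normal(size=2)])
        a = snp_mark_loglik(Zg, sigma_g, sigma_h, 0, 1)
        b = snp_mark_loglik(Zg, sigma_g, sigma_h, 1, 1)
        assert a == pytest.approx(b, abs=1e-8)


def _summary_from(rng, s, t, scale=2.0):
    return RegionSummary(
        Zg=rng.normal(size=(s, t)) * scale,
        Zh=rng.normal(size=t) * scale,
        Zge=rng.normal(size=s),
        sigma_g=_random_corr(rng, s),
        sigma_h=_random_corr(rng, t),
        n=100,
    )


def naive_path_posteriors(summ, prior=None):
    """Independent dense oracle: form every path's joint density explicitly."""
    prior = prior or ModelPrior()
    s, t = summ.s, summ.t
    pri = prior.path_prior_for(s, t)
    joint = np.zeros((s, t))
    for c in range(s):
        for d in range(t):
            Sc = prior.prior_ncp_var * np.diag(np.eye(t)[d]) + prior.diag_eps * np.eye(t)
            cov_h = summ.sigma_h + summ.sigma_h @ Sc @ summ.sigma_h
            lh = stats.multivariate_normal.logpdf(summ.Zh, np.zeros(t), cov_h)
            M = np.outer(summ.sigma_g[:, c], summ.sigma_h[:, d]) * summ.Zg[c, d]
            lg = stats.multivariate_normal.logpdf(
                summ.Zg.T.ravel(), M.T.ravel(), np.kron(summ.sigma_h, summ.sigma_g)
            )
            joint[c, d] = np.exp(lh + lg) * pri[c, d]
    return joint / joint.sum()


class TestPathPosteriors:
    def test_single_hypothesis(self, rng):
        summ = _summary_from(rng, 1, 1)
        post = path_posteriors(summ)
        assert float(post.path_probs[0, 0]) == pytest.approx(1.0)

    def test_matches_naive_enumeration_oracle(self, rng):
        for s, t in [(3, 2), (5, 3), (2, 3)]:
            summ = _summary_from(rng, s, t)
            post = path_posteriors(summ)
            oracle = naive_path_posteriors(summ)
            assert np.allclose(post.path_probs, oracle, atol=1e-8)

    def test_normalization_and_marginals(self, rng):
        summ = _summary_from(rng, 6, 4, scale=4.0)
        post = path_posteriors(summ)
        assert post.path_probs.sum() == pytest.approx(1.0, abs=1e-8)
        assert np.allclose(post.snp_marginals, post.path_probs.sum(axis=1))
        assert post.snp_marginals.sum() == pytest.approx(1.0, abs=1e-8)
        assert post.mark_marginals.sum() == pytest.approx(1.0, abs=1e-8)

    @settings(deadline=None, max_examples=20)
    @given(st.integers(0, 2**31 - 1))
    def test_relabeling_invariance(self, seed):
        """Permuting SNP/mark order permutes the posterior identically."""
        rng = np.random.default_rng(seed)
        s, t = 4, 3
        summ = _summary_from(rng, s, t)
        post = path_posteriors(summ)
        ps, pt = rng.permutation(s), rng.permutation(t)
        permuted = RegionSummary(
            Zg=summ.Zg[np.ix_(ps, pt)],
            Zh=summ.Zh[pt],
            Zge=summ.Zge[ps],
            sigma_g=summ.sigma_g[np.ix_(ps, ps)],
            sigma_h=summ.sigma_h[np.ix_(pt, pt)],
            n=summ.n,
        )
        post_p = path_posteriors(permuted)
        assert np.allclose(post_p.path_probs, post.path_probs[np.ix_(ps, pt)], atol=1e-10)

    def test_exchangeable_marks_equal_marginals(self):
        """Two marks with identical correlations and Z patterns tie exactly."""
        sigma_h = np.full((3, 3), 0.3)
        np.fill_diagonal(sigma_h, 1.0)
        rng = np.random.default_rng(0)
        sigma_g = _random_corr(rng, 2)
        Zh = np.array([0.5, 2.0, 2.0])
        col = rng.normal(size=2)
        Zg = np.column_stack([rng.normal(size=2), col, col])
        summ = RegionSummary(
            Zg=Zg, Zh=Zh, Zge=np.zeros(2), sigma_g=sigma_g, sigma_h=sigma_h, n=50
        )
        post = path_posteriors(summ)
        assert post.mark_marginals[1] == pytest.approx(post.mark_marginals[2], abs=1e-10)

    def test_identifiability_without_correlations(self):
        """With sigma_g = sigma_h = I the true path tops the posterior in
        most replicates at variance explained 0.25/0.25."""
        cfg = cp.SimConfig(
            n=100, s=8, t=4, ld_model="identity", mark_corr_model="identity", seed=None
        )
        rng = np.random.default_rng(99)
        hits = 0
        reps = 200
        for _ in range(reps):
            d, truth = cp.simulate_standard(cfg, rng=rng)
            post = path_posteriors(cp.build_summary(d))
            top = np.unravel_index(post.path_probs.argmax(), post.path_probs.shape)
            hits += (int(top[0]), int(top[1])) == truth.causal_paths[0]
        # the SNP->mark effect is drawn N(0, 0.25), so ~20% of regions carry
        # almost no genetic signal; the achievable top-1 rate plateaus just
        # below 0.8 (chance level is 1/(s*t) ~ 0.03)
        assert hits / reps >= 0.7

    def test_infinite_z_rejected(self, rng):
        summ = _summary_from(rng, 2, 2)
        summ.Zg[0, 0] = np.inf
        with pytest.raises(ValidationError, match="non-finite"):
            path_posteriors(summ)


class TestCredibleSet:
    @pytest.mark.parametrize(
        "probs,rho,expected",
        [
            ([0.6, 0.3, 0.1], 0.9, [0, 1]),
            ([0.6, 0.3, 0.1], 0.5, [0]),
            ([0.1] * 10, 0.9, list(range(9))),
        ],
    )
    def test_examples(self, probs, rho, expected):
        assert credible_set(np.array(probs), rho) == expected

    def test_tie_break_deterministic(self):
        probs = np.array([0.25, 0.25, 0.25, 0.25])
        assert credible_set(probs, 0.6) == [0, 1, 2]
        assert credible_set(probs, 0.6) == credible_set(probs.copy(), 0.6)

    def test_invalid_level(self):
        with pytest.raises(ValidationError):
            credible_set(np.array([1.0]), 1.5)
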