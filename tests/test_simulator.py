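"""Simulator moment checks, determinism, and violation constructions."""

import numpy as np
import pytest

import chromapath as cp
from chromapath.data_model import ValidationError
from chromapath.model_filter import partial_corr
from chromapath.simulator import SimConfig, _binomial_at_least_two


class TestSampleStructure:
    def test_identity_ld_near_zero_correlation(self):
        cfg = SimConfig(n=1000, s=20, t=4, ld_model="identity", seed=1)
        G, _ = cp.sample_structure(cfg)
        R = np.corrcoef(G.T)
        off = np.abs(R[np.triu_indices(20, 1)])
        assert off.mean() < 0.1

    def test_blockwise_ld_recovers_target(self):
        cfg = SimConfig(
            n=1000, s=20, t=4, ld_model="blockwise", ld_block_size=10, ld_corr=0.8, seed=2
        )
        G, _ = cp.sample_structure(cfg)
        R = np.corrcoef(G.T)
        within = [
            R[i, j] for b in (0, 10) for i in range(b, b + 10) for j in range(i + 1, b + 10)
        ]
        # latent threshold model attenuates the latent correlation somewhat
        assert abs(np.mean(within) - 0.8) < 0.1

    def test_deterministic_under_seed(self):
        cfg = SimConfig(seed=42)
        G1, S1 = cp.sample_structure(cfg)
        G2, S2 = cp.sample_structure(cfg)
        assert np.array_equal(G1, G2)
        assert np.array_equal(S1, S2)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValidationError):
            SimConfig(ld_corr=1.5)
        with pytest.raises(ValidationError):
            SimConfig(var_explained_g=1.0)


class TestSimulateStandard:
    def test_expression_variance_explained_by_causal_mark(self):
        """Mean sample R^2 of expression on the causal mark sits at its
        0.25 target over many regions."""
        cfg = SimConfig(n=100, s=10, t=5, seed=None)
        rng = np.random.default_rng(10)
        r2 = []
        for _ in range(500):
            d, truth = cp.simulate_standard(cfg, rng=rng)
            k = truth.causal_marks[0]
            r2.append(np.corrcoef(d.marks[:, k], d.expression)[0, 1] ** 2)
        assert np.mean(r2) == pytest.approx(0.25, abs=0.03)

    def test_null_effect_gives_standard_normal_z(self):
        """var_explained_g = 0: the causal-pair Z is N(0,1); mean |Z| is the
        half-normal mean sqrt(2/pi) ~ 0.798."""
        cfg = SimConfig(n=100, s=8, t=4, var_explained_g=0.0, seed=None)
        rng = np.random.default_rng(11)
        zs = []
        for _ in range(500):
            d, truth = cp.simulate_standard(cfg, rng=rng)
            summ = cp.build_summary(d)
            zs.append(abs(summ.Zg[truth.causal_snps[0], truth.causal_marks[0]]))
        assert np.mean(zs) == pytest.approx(np.sqrt(2 / np.pi), abs=0.05)

    def test_mark_correlation_matches_target(self):
        cfg = SimConfig(n=1000, s=5, t=8, seed=3)
        rng = np.random.default_rng(3)
        G, sigma_h = cp.sample_structure(cfg, rng)
        d, _ = cp.simulate_standard(cfg, G, sigma_h, rng)
        emp = np.corrcoef(d.marks.T)
        assert np.max(np.abs(emp - sigma_h)) < 0.1

    def test_total_expression_variance_near_one(self):
        cfg = SimConfig(n=100, s=10, t=5, seed=None)
        rng = np.random.default_rng(12)
        v = [np.var(cp.simulate_standard(cfg, rng=rng)[0].expression) for _ in range(500)]
        assert np.mean(v) == pytest.approx(1.0, rel=0.1)


class TestSimulateMulti:
    def test_effect_variance_scaling(self):
        """With m=2 forced, the summed squared effects average sigma_g^2."""
        cfg = SimConfig(n=20, s=10, t=4, seed=None)
        rng = np.random.default_rng(13)
        totals = [
            float(np.sum(np.square(cp.simulate_multi(cfg, "snps", rng=rng, n_causal=2)[1].beta_g)))
            for _ in range(2000)
        ]
        assert np.mean(totals) == pytest.approx(0.25, rel=0.1)

    def test_at_least_two_causals(self):
        cfg = SimConfig(n=50, s=30, t=6, seed=None)
        rng = np.random.default_rng(14)
        for which in ("snps", "marks"):
            for _ in range(20):
                _, truth = cp.simulate_multi(cfg, which, rng=rng)
                idx = truth.causal_snps if which == "snps" else truth.causal_marks
                assert len(idx) >= 2

    def test_binomial_conditioning(self):
        rng = np.random.default_rng(15)
        draws = [_binomial_at_least_two(rng, 50) for _ in range(500)]
        assert min(draws) >= 2

    def test_multi_mark_joint_variance_explained(self):
        """Expression variance explained jointly by two causal marks ~ 0.25."""
        cfg = SimConfig(n=100, s=10, t=5, seed=None)
        rng = np.random.default_rng(16)
        r2 = []
        for _ in range(500):
            d, truth = cp.simulate_multi(cfg, "marks", rng=rng, n_causal=2)
            H = np.column_stack([np.ones(d.n), d.marks[:, truth.causal_marks]])
            beta, *_ = np.linalg.lstsq(H, d.expression, rcond=None)
            resid = d.expression - H @ beta
            tot = np.sum((d.expression - d.expression.mean()) ** 2)
            r2.append(1 - np.sum(resid**2) / tot)
        assert np.mean(r2) == pytest.approx(0.25, abs=0.05)


@pytest.fixture(scope="module", name="cfg")
def _violation_cfg():
    return SimConfig(n=100, s=12, t=5, seed=None)


class TestViolations:

    def test_invalid_kind(self, cfg):
        with pytest.raises(ValidationError):
            cp.simulate_violation(cfg, 8)

    def test_violation7_conditional_independence(self, cfg):
        """Mark and expression are independent given the SNP."""
        rng = np.random.default_rng(17)
        vals = []
        for _ in range(200):
            d, truth = cp.simulate_violation(cfg, 7, rng=rng)
            c, k = truth.causal_paths[0]
            vals.append(abs(partial_corr(d.marks[:, k], d.expression, d.genotypes[:, c])[0]))
        assert np.mean(vals) < 0.15

    def test_violation6_mediation_by_expression(self, cfg):
        """SNP and mark are independent given expression."""
        rng = np.random.default_rng(18)
        vals = []
        for _ in range(200):
            d, truth = cp.simulate_violation(cfg, 6, rng=rng)
            c, k = truth.causal_paths[0]
            vals.append(abs(partial_corr(d.genotypes[:, c], d.marks[:, k], d.expression)[0]))
        assert np.mean(vals) < 0.15

    def test_violation4_both_snps_associate_with_expression(self, cfg):
        rng = np.random.default_rng(19)
        hits = 0
        reps = 200
        for _ in range(reps):
            d, truth = cp.simulate_violation(cfg, 4, rng=rng)
            summ = cp.build_summary(d)
            path_snp, direct_snp = truth.causal_snps
            hits += (abs(summ.Zge[path_snp]) > 2) and (abs(summ.Zge[direct_snp]) > 2)
        assert hits > reps / 2

    @pytest.mark.parametrize("kind", range(1, 8))
    def test_truth_records_scenario_and_variance_is_stable(self, cfg, kind):
        rng = np.random.default_rng(100 + kind)
        v = []
        for _ in range(100):
            d, truth = cp.simulate_violation(cfg, kind, rng=rng)
            assert truth.scenario == f"violation{kind}"
            assert truth.causal_paths
            v.append(np.var(d.expression))
        assert np.mean(v) == pytest.approx(1.0, rel=0.1)


class TestDeterminism:
    @pytest.mark.parametrize(
        "scenario", ["standard", "multi_snp", "multi_mark", "violation3", "violation6"]
    )
    def test_bitwise_identical_under_seed(self, scenario):
        cfg = SimConfig(n=30, s=8, t=4, scenario=scenario, seed=21)
        a = cp.simulate_regions(cfg, 3, seed=21)
        b = cp.simulate_regions(cfg, 3, seed=21)
        for (da, ta), (db, tb) in zip(a, b):
            assert np.array_equal(da.genotypes, db.genotypes)
            assert np.array_equal(da.marks, db.marks)
            assert np.array_equal(da.expression, db.expression)
            assert ta.causal_paths == tb.causal_paths
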