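"""Shared fixtures: small toy regions plus session-scoped simulation batches.

The heavy batches (hundreds of regions with posteriors) are built once per
session and shared by the calibration, ordering and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import chromapath as cp
from chromapath.evaluation import evaluate_region


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture()
def toy_region(rng):
    """Small dense region (n=40, s=6, t=3) with a strong causal path (2, 1)."""
    cfg = cp.SimConfig(
        n=40, s=6, t=3, ld_block_size=3, mark_block_size=3, seed=None
    )
    G, sigma_h = cp.sample_structure(cfg, rng)
    beta_g = 0.9
    mean = np.outer(beta_g * G[:, 2], sigma_h[1])
    L = np.linalg.cholesky(sigma_h)
    H = mean + rng.standard_normal((cfg.n, cfg.t)) @ (np.sqrt(0.5) * L.T)
    E = 0.8 * H[:, 1] + rng.normal(0, 0.6, cfg.n)
    d = cp.RegionDataset(
        genotypes=G,
        marks=H,
        expression=E,
        snp_ids=[f"snp{j}" for j in range(6)],
        mark_ids=[f"mark{k}" for k in range(3)],
        gene_id="toygene",
    )
    return d


@pytest.fixture()
def toy_summary(toy_region):
    return cp.build_summary(toy_region)


def _simulate_batch(scenario: str, n_regions: int, seed: int, **cfg_kwargs):
    cfg = cp.SimConfig(scenario=scenario, seed=seed, **cfg_kwargs)
    return cp.simulate_regions(cfg, n_regions, seed=seed), cfg


@pytest.fixture(scope="session")
def standard_batch():
    """500 standard regions with hierarchical/independent/naive results."""
    sims, _ = _simulate_batch("standard", 500, seed=11)
    results = [
        evaluate_region(d, t, methods=("hierarchical", "independent", "naive"))
        for d, t in sims
    ]
    return sims, results


@pytest.fixture(scope="session")
def overlap_batch(standard_batch):
    """Overlap analysis on the first 200 standard regions."""
    sims, results = standard_batch
    rng = np.random.default_rng(12)
    overlaps = [
        cp.overlap_analysis(d, B=999, fdr=0.10, rng=rng) for d, _ in sims[:200]
    ]
    return sims[:200], results[:200], overlaps


@pytest.fixture(scope="session")
def noise_batch():
    """200 pure-noise regions (no genetic or chromatin effects)."""
    sims, _ = _simulate_batch(
        "standard", 200, seed=13, var_explained_g=0.0, var_explained_h=0.0
    )
    return sims
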