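"""Tests of the block-correlated genotype and phenotype simulator."""

import numpy as np
import pytest
from scipy import stats

from ldblocks.simulate import (SimulationDesign, _maf_thresholds,
                               simulate_dataset, simulate_genotypes,
                               simulate_phenotype, standard_design)


def test_quartile_cutoffs_reproduce_maf_half_exactly():
    lo, hi = _maf_thresholds(np.array([0.5]))
    q = stats.norm.ppf(0.25)
    assert lo[0] == pytest.approx(q, abs=1e-12)
    assert hi[0] == pytest.approx(-q, abs=1e-12)
    p0 = stats.norm.cdf(lo[0])
    p2 = stats.norm.sf(hi[0])
    assert p0 == pytest.approx(0.25, abs=1e-12)
    assert p2 == pytest.approx(0.25, abs=1e-12)
    # expected minor allele frequency = (p1 + 2 p2) / 2 = 0.5 exactly
    assert (1 - p0 - p2 + 2 * p2) / 2 == pytest.approx(0.5, abs=1e-12)


@pytest.mark.parametrize("maf", [0.1, 0.25, 0.4, 0.5])
def test_empirical_maf_matches_target(maf):
    design = SimulationDesign(n=10_000, block_sizes=(4, 4), rho=0.3, maf=maf,
                              causal_snps=1, sig_block=4, r2=0.2)
    X, _ = simulate_genotypes(design, 123)
    emp = X.values.mean(axis=0) / 2.0
    assert np.abs(emp - maf).max() < 0.02


def test_genotype_frequencies_at_maf_half():
    design = SimulationDesign(n=20_000, block_sizes=(2, 2), rho=0.0,
                              causal_snps=1, sig_block=2, r2=0.2)
    X, _ = simulate_genotypes(design, 5)
    freq = np.array([(X.values == g).mean(axis=0) for g in (0, 1, 2)])
    assert np.allclose(freq[0], 0.25, atol=0.02)
    assert np.allclose(freq[1], 0.50, atol=0.02)
    assert np.allclose(freq[2], 0.25, atol=0.02)


def test_rho_zero_gives_independent_columns():
    design = SimulationDesign(n=1000, block_sizes=(10, 10), rho=0.0,
                              causal_snps=1, sig_block=10, r2=0.2)
    X, _ = simulate_genotypes(design, 9)
    C = np.corrcoef(X.values.T)
    off = np.abs(C[np.triu_indices(20, k=1)])
    assert off.mean() < 3.0 / np.sqrt(1000)


def test_within_block_correlation_increases_with_rho():
    means = []
    for rho in (0.1, 0.4, 0.8):
        design = SimulationDesign(n=2000, block_sizes=(8, 8), rho=rho,
                                  causal_snps=1, sig_block=8, r2=0.2)
        X, blocks = simulate_genotypes(design, 21)
        C = np.corrcoef(X.values.T)
        within = []
        between = []
        lab = blocks.labels()
        for j in range(16):
            for k in range(j + 1, 16):
                (within if lab[j] == lab[k] else between).append(abs(C[j, k]))
        means.append(np.mean(within))
        assert np.mean(between) < 0.1
    assert means[0] < means[1] < means[2]


def test_phenotype_r2_calibration_large_n():
    design = SimulationDesign(n=10_000, block_sizes=(8,) * 8, rho=0.4,
                              causal_snps=4, sig_block=8, r2=0.2)
    data = simulate_dataset(design, 77)
    Xc = data.X.values[:, data.truth.causal].astype(float)
    Xc = np.column_stack([np.ones(design.n), Xc])
    resid = data.y - Xc @ np.linalg.lstsq(Xc, data.y, rcond=None)[0]
    r2_emp = 1.0 - resid.var() / data.y.var()
    assert r2_emp == pytest.approx(0.2, abs=0.02)


def test_phenotype_noise_free_limit():
    design = SimulationDesign(n=200, block_sizes=(8,), rho=0.4,
                              causal_snps=2, sig_block=8, r2=1 - 1e-12)
    data = simulate_dataset(design, 3)
    g = data.X.values.astype(float) @ data.truth.beta
    assert np.abs(data.y - g).max() < 1e-4


def test_phenotype_degenerate_inputs_rejected(rng):
    design = SimulationDesign(n=100, block_sizes=(8, 4), rho=0.2,
                              causal_snps=1, sig_block=4, r2=0.2)
    X, blocks = simulate_genotypes(design, 1)
    with pytest.raises(ValueError, match="at least one causal"):
        simulate_phenotype(X, blocks, 0, 4, 0.2, rng)
    with pytest.raises(ValueError, match="no block of size"):
        simulate_phenotype(X, blocks, 1, 7, 0.2, rng)
    with pytest.raises(ValueError, match="R\\^2"):
        simulate_phenotype(X, blocks, 1, 4, 1.5, rng)


def test_design_validation():
    with pytest.raises(ValueError, match="rho"):
        SimulationDesign(rho=1.0)
    with pytest.raises(ValueError, match="cannot exceed"):
        SimulationDesign(causal_snps=9, sig_block=8)


def test_full_reproducibility_under_seed():
    design = SimulationDesign(n=50, block_sizes=(4, 4, 4), rho=0.5,
                              causal_snps=2, sig_block=4, r2=0.2)
    a = simulate_dataset(design, 42)
    b = simulate_dataset(design, 42)
    c = simulate_dataset(design, 43)
    assert np.array_equal(a.X.values, b.X.values)
    assert np.array_equal(a.y, b.y)
    assert np.array_equal(a.truth.causal, b.truth.causal)
    assert not np.array_equal(a.X.values, c.X.values)


def test_block_order_is_permuted_with_truth_recorded():
    design = SimulationDesign(n=30, block_sizes=(2, 4, 8, 16), rho=0.2,
                              causal_snps=1, sig_block=8, r2=0.2)
    _, blocks = simulate_genotypes(design, 11)
    assert sorted(blocks.sizes.tolist()) == [2, 4, 8, 16]
    assert blocks.p == 30


def test_standard_designs_match_published_arithmetic():
    main = standard_design("main")
    assert main.p == 2048
    assert main.n_blocks == 192
    assert main.n == 100 and main.maf == 0.5 and main.r2 == 0.2
    mu = standard_design("maf_uniform")
    assert mu.p == 4096
    assert mu.n_blocks == 384
    assert mu.n == 1000 and mu.r2 == 0.01 and mu.maf == (0.05, 0.5)
    with pytest.raises(ValueError, match="unknown scenario"):
        standard_design("nope")
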