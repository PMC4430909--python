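"""Unit tests of the EM haplotype-frequency r^2 and the lazy LD provider."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ldblocks.genotypes import GenotypeMatrix
from ldblocks.ld import (LDProvider, UndefinedLDError, dissimilarity,
                         filter_undefined_ld, r2, r2_matrix)


def _geno(values, missing=None):
    values = np.asarray(values)
    return GenotypeMatrix(values=values, missing_mask=missing)


def test_identical_polymorphic_columns_have_r2_one(rng):
    g = rng.integers(0, 3, 500).astype(float)
    assert r2(g, g) == pytest.approx(1.0, abs=1e-12)
    assert dissimilarity(g, g) == pytest.approx(0.0, abs=1e-12)


def test_independent_columns_have_r2_near_zero(rng):
    a = rng.integers(0, 3, 10_000).astype(float)
    b = rng.integers(0, 3, 10_000).astype(float)
    val = r2(a, b)
    assert val < 0.01
    # the dosage-correlation estimator agrees with the EM one under the null
    assert r2(a, b, estimator="dosage") < 0.01


def test_no_double_heterozygote_table_closed_forms():
    """Without double heterozygotes every haplotype is unambiguous, so the
    EM closed-forms in one step and r^2 equals the allelic correlation
    computed by direct haplotype counting."""
    # genotype pairs chosen so the (1,1) cell is empty
    pairs = [(0, 0)] * 2 + [(2, 2)] * 2 + [(0, 2), (2, 0), (1, 0), (0, 1), (2, 1)]
    a = np.array([x for x, _ in pairs], dtype=float)
    b = np.array([y for _, y in pairs], dtype=float)

    # direct haplotype counting: genotype g contributes g minor alleles in
    # known phase when no pair is doubly heterozygous
    n = len(pairs)
    hap_counts = {(0, 0): 0, (0, 1): 0, (1, 0): 0, (1, 1): 0}
    for x, y in pairs:
        xa = [1] * int(x) + [0] * (2 - int(x))
        yb = [1] * int(y) + [0] * (2 - int(y))
        for h in range(2):
            hap_counts[(xa[h], yb[h])] += 1
    f11 = hap_counts[(1, 1)] / (2 * n)
    pA = a.mean() / 2
    pB = b.mean() / 2
    D = f11 - pA * pB
    expected = D**2 / (pA * (1 - pA) * pB * (1 - pB))
    assert r2(a, b) == pytest.approx(expected, abs=1e-10)


def test_r2_symmetry_and_range(rng):
    X = _geno(rng.integers(0, 3, (80, 10)))
    R = r2_matrix(X)
    assert np.allclose(R, R.T, atol=1e-12, equal_nan=True)
    finite = R[np.isfinite(R)]
    assert ((finite >= 0) & (finite <= 1)).all()


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_r2_pair_symmetric_in_both_estimators(seed):
    r = np.random.default_rng(seed)
    a = r.integers(0, 3, 50).astype(float)
    b = r.integers(0, 3, 50).astype(float)
    for est in ("em", "dosage"):
        try:
            ab = r2(a, b, estimator=est)
        except UndefinedLDError:
            continue
        assert 0.0 <= ab <= 1.0
        assert ab == pytest.approx(r2(b, a, estimator=est), abs=1e-12)


def test_missing_at_random_changes_r2_little(rng):
    n = 10_000
    z = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], size=n)
    g = (1 + (z > 0.6745) - (z < -0.6745)).astype(float)
    full = r2(g[:, 0], g[:, 1])
    gm = g.copy()
    drop = rng.random((n, 2)) < 0.10
    gm[drop] = np.nan
    masked = r2(gm[:, 0], gm[:, 1])
    assert abs(full - masked) < 0.02


def test_provider_matches_dense_oracle(rng):
    X = _geno(rng.integers(0, 3, (60, 16)))
    dense = r2_matrix(X)
    prov = LDProvider(X)
    for j in range(16):
        for k in range(16):
            if j == k:
                assert prov.r2(j, k) == 1.0
            else:
                # the shared EM tolerance (1e-8) bounds the discrepancy
                # between batched and per-pair iteration stopping
                assert prov.r2(j, k) == pytest.approx(dense[j, k], abs=1e-6)


def test_provider_is_lazy_and_caches(rng):
    X = _geno(rng.integers(0, 3, (40, 3)))
    prov = LDProvider(X)
    prov.r2(0, 1)
    prov.r2(1, 2)
    assert prov.n_computed == 2  # exactly the requested pairs
    prov.r2(1, 0)  # symmetric cache hit
    prov.r2(0, 1)
    assert prov.n_computed == 2
    assert prov.sum_block([0], [1]) == pytest.approx(prov.r2(0, 1))
    assert prov.n_computed == 2


def test_provider_rejects_multi_chromosome(rng):
    X = GenotypeMatrix(
        values=rng.integers(0, 3, (10, 4)),
        chrom=np.array(["1", "1", "2", "2"]),
        pos=np.array([1, 2, 1, 2]),
    )
    with pytest.raises(ValueError, match="single chromosome"):
        LDProvider(X)


def test_monomorphic_pair_raises_undefined_ld(rng):
    a = np.zeros(30)
    b = rng.integers(0, 3, 30).astype(float)
    with pytest.raises(UndefinedLDError):
        r2(a, b)


def test_filter_undefined_drops_monomorphic_snps(rng):
    vals = rng.integers(0, 3, (30, 4))
    vals[:, 2] = 1  # monomorphic
    X = _geno(vals)
    Xf, dropped = filter_undefined_ld(X)
    assert Xf.p == 3
    assert dropped.tolist() == [2]
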