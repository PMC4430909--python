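"""Synthetic GWAS data with a block-diagonal LD structure.

Genotypes: each sample's latent vector Z is multivariate normal with a
block-diagonal correlation matrix (off-diagonal rho within a block, 0
between blocks); each latent coordinate is thresholded into {0, 1, 2}
with Hardy-Weinberg quantile cutoffs for the SNP's target minor allele
frequency m:

    genotype 0  if Z < Phi^-1((1-m)^2)
    genotype 2  if Z > Phi^-1(1-m^2)
    genotype 1  otherwise,

which gives HWE genotype frequencies ((1-m)^2, 2m(1-m), m^2). For
m = 0.5 the cutoffs are the standard-normal quartiles (+/-0.6745) and the
genotype frequencies are (1/4, 1/2, 1/4). The ordering of the blocks
along the genome is randomly permuted for each simulation, with the
truth recorded.

Phenotypes: y = X beta + eps with the causal SNPs placed in one block,
beta_causal = +/-1 equiprobably, and eps ~ N(0, sigma^2) with
sigma^2 = Var(X beta) (1 - R^2)/R^2 so the generating model's coefficient
of determination (total heritability h^2) equals the target R^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .cluster import BlockStructure
from .genotypes import GenotypeMatrix

__all__ = [
    "SimulationDesign",
    "SimulationTruth",
    "SimulatedDataset",
    "simulate_genotypes",
    "simulate_phenotype",
    "simulate_dataset",
    "standard_design",
]

_BASE_PATTERN = (2, 2, 4, 8, 16, 32)


@dataclass
class SimulationDesign:
    """Parameters of one simulation scenario.

    maf is a fixed per-SNP minor allele frequency in (0, 0.5] or a
    (low, high) tuple for per-SNP uniform sampling.
    """

    n: int = 100
    block_sizes: tuple = tuple(_BASE_PATTERN) * 32
    rho: float = 0.4
    maf: float | tuple = 0.5
    causal_snps: int = 8
    sig_block: int = 8
    r2: float = 0.2
    name: str = "custom"

    def __post_init__(self):
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")
        if not 0 < self.r2 < 1:
            raise ValueError("target R^2 must be in (0, 1)")
        if self.causal_snps > self.sig_block:
            raise ValueError("causal_snps cannot exceed the associated block size")
        if min(self.block_sizes) < 1:
            raise ValueError("block sizes must be positive")

    @property
    def p(self) -> int:
        return int(sum(self.block_sizes))

    @property
    def n_blocks(self) -> int:
        return len(self.block_sizes)


def standard_design(name: str, **overrides) -> SimulationDesign:
    """Named scenario presets.

    "main": n = 100, 192 blocks of sizes {2,2,4,8,16,32} x 32 (p = 2048),
    MAF fixed at 0.5, rho = 0.4, target R^2 = 0.2.
    "maf_uniform": n = 1000, 384 blocks (pattern x 64, p = 4096),
    per-SNP MAF ~ U(0.05, 0.5), rho = 0.4, target R^2 = 0.01.
    """
    if name == "main":
        d = SimulationDesign(
            n=100, block_sizes=tuple(_BASE_PATTERN) * 32, rho=0.4,
            maf=0.5, r2=0.2, name="main",
        )
    elif name == "maf_uniform":
        d = SimulationDesign(
            n=1000, block_sizes=tuple(_BASE_PATTERN) * 64, rho=0.4,
            maf=(0.05, 0.5), r2=0.01, name="maf_uniform",
        )
    else:
        raise ValueError(f"unknown scenario {name!r}; use 'main' or 'maf_uniform'")
    return replace(d, **overrides) if overrides else d


@dataclass
class SimulationTruth:
    """Ground truth of one simulated data set."""

    blocks: BlockStructure
    causal: np.ndarray  # column indices of causal SNPs
    beta: np.ndarray  # full-length coefficient vector (+/-1 causal, 0 else)
    causal_block: int  # block index holding the causal SNPs
    sigma: float  # noise standard deviation implied by the R^2 target


@dataclass
class SimulatedDataset:
    X: GenotypeMatrix
    y: np.ndarray
    truth: SimulationTruth
    design: SimulationDesign


def _maf_thresholds(maf: np.ndarray):
    lo = stats.norm.ppf((1.0 - maf) ** 2)
    hi = stats.norm.ppf(1.0 - maf**2)
    return lo, hi


def simulate_genotypes(design: SimulationDesign, rng) -> tuple[GenotypeMatrix, BlockStructure]:
    """Draw a genotype matrix; returns (X, true block structure).

    The order of the blocks along the genome is randomly permuted; block
    sizes in the returned structure reflect the permuted order.
    """
    rng = np.random.default_rng(rng)
    sizes = np.asarray(design.block_sizes, dtype=int)
    sizes = sizes[rng.permutation(len(sizes))]
    p = int(sizes.sum())
    n = design.n
    Z = np.empty((n, p))
    col = 0
    sr = np.sqrt(design.rho)
    si = np.sqrt(1.0 - design.rho)
    for size in sizes:
        shared = rng.standard_normal((n, 1))
        own = rng.standard_normal((n, size))
        Z[:, col : col + size] = sr * shared + si * own
        col += size
    if isinstance(design.maf, tuple):
        maf = rng.uniform(design.maf[0], design.maf[1], size=p)
    else:
        maf = np.full(p, float(design.maf))
    lo, hi = _maf_thresholds(maf)
    vals = np.ones((n, p), dtype=np.int8)
    vals[Z < lo] = 0
    vals[Z > hi] = 2
    X = GenotypeMatrix(values=vals, pos=np.arange(1, p + 1) * 1000)
    return X, BlockStructure.from_sizes(sizes)


def simulate_phenotype(
    X: GenotypeMatrix,
    blocks: BlockStructure,
    causal_snps: int,
    sig_block: int,
    r2: float,
    rng,
) -> tuple[np.ndarray, SimulationTruth]:
    """Generate y = X beta + eps with the noise calibrated to a target R^2.

    The causal SNPs are placed (uniformly at random, without replacement)
    inside one block of size ``sig_block`` chosen uniformly among such
    blocks; their coefficients are +/-1 equiprobably. sigma^2 is set to
    Var(X beta) (1 - r2)/r2 using the realized genetic values.
    """
    rng = np.random.default_rng(rng)
    if causal_snps < 1:
        raise ValueError("need at least one causal SNP (Var(X beta) = 0 otherwise)")
    if not 0 < r2 < 1:
        raise ValueError("target R^2 must be in (0, 1)")
    candidates = np.where(blocks.sizes == sig_block)[0]
    if candidates.size == 0:
        raise ValueError(f"no block of size {sig_block} in the structure")
    gb = int(rng.choice(candidates))
    a, b = blocks.ranges[gb]
    causal = np.sort(rng.choice(np.arange(a, b), size=causal_snps, replace=False))
    beta = np.zeros(X.p)
    beta[causal] = rng.choice([-1.0, 1.0], size=causal_snps)
    g = X.values.astype(float) @ beta
    var_g = g.var()
    if var_g <= 0:
        raise ValueError("Var(X beta) = 0; R^2 calibration undefined")
    sigma = float(np.sqrt(var_g * (1.0 - r2) / r2))
    y = g + rng.normal(0.0, sigma, size=X.n)
    truth = SimulationTruth(
        blocks=blocks, causal=causal, beta=beta, causal_block=gb, sigma=sigma
    )
    return y, truth


def simulate_dataset(design: SimulationDesign, seed) -> SimulatedDataset:
    """Full draw: genotypes + phenotype, reproducible under the seed."""
    rng = np.random.default_rng(seed)
    X, blocks = simulate_genotypes(design, rng)
    y, truth = simulate_phenotype(
        X, blocks, design.causal_snps, design.sig_block, design.r2, rng
    )
    return SimulatedDataset(X=X, y=y, truth=truth, design=design)
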