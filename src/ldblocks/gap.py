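"""Choosing the number of LD blocks with a modified Gap statistic.

The observed within-group dispersion profile W_G (from the constrained
clustering) is compared against its distribution under a structureless
reference: each reference data set redraws every column i.i.d. uniformly
over the distinct genotype values observed in that column. On the
non-log scale used here,

    Gap*(G) = (1/B) sum_b (W^b_G - W_G),

with the spread of the B reference dispersions summarized by
s_G = (1 + B)^(-1/2) * sd_G. The selected number of blocks is the
smallest G with Gap*(G) >= Gap*(G+1) - s_{G+1}. The classical
log-dispersion Gap is available behind ``log_gap=True``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from joblib import Parallel, delayed

from .cluster import DenseSimilarity, ward_constrained
from .genotypes import GenotypeMatrix
from .ld import LDProvider, r2_matrix

__all__ = ["GapProfile", "reference_sample", "gap_profile", "select_G"]

logger = logging.getLogger(__name__)


@dataclass
class GapProfile:
    """Gap*(G) and its standard-error curve over a consecutive grid of G."""

    G_grid: np.ndarray
    gap_star: np.ndarray
    s: np.ndarray
    W_obs: np.ndarray
    W_ref_mean: np.ndarray
    B: int
    G_hat: int | None = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "G": self.G_grid,
                "W_obs": self.W_obs,
                "mean_W_ref": self.W_ref_mean,
                "gap_star": self.gap_star,
                "s": self.s,
            }
        )


def reference_sample(X: GenotypeMatrix, rng) -> GenotypeMatrix:
    """Draw a structureless reference data set of the same shape as X.

    Each column is sampled i.i.d. uniformly over the distinct genotype
    values observed (non-missing) in that column of X; for a typical SNP
    this is the uniform distribution over {0, 1, 2}. The reference has no
    missing values.
    """
    rng = np.random.default_rng(rng)
    vals = np.empty((X.n, X.p), dtype=np.int8)
    for j in range(X.p):
        obs = np.unique(X.values[~X.missing_mask[:, j], j])
        vals[:, j] = rng.choice(obs, size=X.n, replace=True)
    return GenotypeMatrix(
        values=vals,
        snp_ids=X.snp_ids,
        chrom=X.chrom,
        pos=X.pos,
        sample_ids=X.sample_ids,
    )


def _cluster_W(X: GenotypeMatrix, estimator: str, dense: bool) -> np.ndarray:
    """W profile (indexed by G, entry 0 unused) of the constrained clustering."""
    if dense:
        sim = DenseSimilarity(np.nan_to_num(r2_matrix(X, estimator=estimator), nan=0.0))
        np.fill_diagonal(sim.S, 1.0)
    else:
        sim = LDProvider(X, estimator=estimator)
    return ward_constrained(sim, X.p).W_profile


def gap_profile(
    X: GenotypeMatrix,
    tree_obs=None,
    B: int = 100,
    G_max: int | None = None,
    seed=None,
    workers: int = 1,
    estimator: str = "em",
    log_gap: bool = False,
    dense: bool | None = None,
) -> GapProfile:
    """Compute the Gap* profile over G = 1..G_max.

    Each of the B reference data sets is clustered with the same
    constrained algorithm; per-reference seeds are derived
    deterministically from ``seed`` so the result is independent of the
    worker count. ``dense`` precomputes the full reference similarity
    matrix (the default for p <= 4096); the lazy provider is used beyond
    that.
    """
    if B < 2:
        raise ValueError("B must be >= 2 (reference standard deviation undefined)")
    p = X.p
    G_max = p if G_max is None else min(G_max, p)
    if dense is None:
        dense = p <= 4096
    if tree_obs is None:
        if dense:
            sim = DenseSimilarity(
                np.nan_to_num(r2_matrix(X, estimator=estimator), nan=0.0)
            )
            np.fill_diagonal(sim.S, 1.0)
        else:
            sim = LDProvider(X, estimator=estimator)
        tree_obs = ward_constrained(sim, p)
    W_obs_full = tree_obs.W_profile

    seeds = np.random.SeedSequence(seed).spawn(B)

    def one(b_seed):
        ref = reference_sample(X, np.random.default_rng(b_seed))
        return _cluster_W(ref, estimator, dense)

    if workers > 1:
        W_ref = Parallel(n_jobs=workers)(delayed(one)(s) for s in seeds)
    else:
        W_ref = [one(s) for s in seeds]
    W_ref = np.stack(W_ref)  # (B, p+1), column 0 unused

    grid = np.arange(1, G_max + 1)
    W_obs = W_obs_full[grid]
    Wb = W_ref[:, grid]
    if log_gap:
        with np.errstate(divide="ignore"):
            gap = np.log(Wb).mean(axis=0) - np.log(W_obs)
            sd = np.log(Wb).std(axis=0, ddof=1)
        gap = np.where(np.isfinite(gap), gap, 0.0)
        sd = np.where(np.isfinite(sd), sd, 0.0)
    else:
        gap = Wb.mean(axis=0) - W_obs
        sd = Wb.std(axis=0, ddof=1)
    s = sd / np.sqrt(1.0 + B)

    prof = GapProfile(
        G_grid=grid,
        gap_star=gap,
        s=s,
        W_obs=W_obs,
        W_ref_mean=Wb.mean(axis=0),
        B=B,
    )
    prof.G_hat = select_G(prof)
    return prof


def select_G(profile: GapProfile) -> int:
    """Smallest G with Gap*(G) >= Gap*(G+1) - s_{G+1}.

    If no G on the grid satisfies the rule, the largest evaluated G is
    returned with a warning (a G_max cap can trigger this path).
    """
    grid = np.asarray(profile.G_grid)
    if grid.size == 0:
        raise ValueError("empty Gap profile")
    if grid.size > 1 and not (np.diff(grid) == 1).all():
        raise ValueError("Gap profile grid must cover consecutive G values")
    gap = np.asarray(profile.gap_star)
    s = np.asarray(profile.s)
    for i in range(len(grid) - 1):
        if gap[i] >= gap[i + 1] - s[i + 1]:
            return int(grid[i])
    logger.warning(
        "Gap selection rule not satisfied on the evaluated grid; "
        "returning the largest evaluated G = %d",
        grid[-1],
    )
    return int(grid[-1])
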