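"""Pairwise linkage disequilibrium (r^2) from unphased genotypes.

The default estimator is the maximum-likelihood haplotype-frequency r^2:
with genotypes coded as minor-allele counts, only the double-heterozygote
cell of the 3x3 joint genotype table is phase-ambiguous, and an EM
iteration on the (minor, minor) haplotype frequency f11 resolves it.
Writing pA, pB for the minor-allele frequencies on the jointly observed
samples, D = f11 - pA*pB and r^2 = D^2 / (pA(1-pA) pB(1-pB)).

Missing genotypes are handled pairwise-complete: each (j, k) pair is
estimated on the samples where both SNPs are observed.

The induced clustering dissimilarity is 1 - r^2.
"""

from __future__ import annotations

import logging

import numpy as np

from .genotypes import GenotypeMatrix

__all__ = [
    "UndefinedLDError",
    "r2",
    "r2_matrix",
    "dissimilarity",
    "LDProvider",
    "filter_undefined_ld",
]

logger = logging.getLogger(__name__)

EM_TOL = 1e-8
EM_MAX_ITER = 1000


class UndefinedLDError(ValueError):
    """LD is undefined for a pair (a SNP is monomorphic on the overlap)."""


def _pair_stats(A, VA, B, VB):
    """Joint-genotype statistics for every (column of A) x (column of B) pair.

    A, B : float arrays (n x a), (n x b) of dosages with missing set to 0.
    VA, VB : float validity indicators (1.0 observed, 0.0 missing).

    Returns n_used, pA, pB and the heterozygote/homozygote cell counts the
    EM update needs, all as (a x b) arrays.
    """
    n_used = VA.T @ VB
    sumA = (A * VA).T @ VB
    sumB = VA.T @ (B * VB)
    with np.errstate(invalid="ignore", divide="ignore"):
        pA = sumA / (2.0 * n_used)
        pB = sumB / (2.0 * n_used)
    A1 = ((A == 1) & (VA > 0)).astype(float)
    A2 = ((A == 2) & (VA > 0)).astype(float)
    B1 = ((B == 1) & (VB > 0)).astype(float)
    B2 = ((B == 2) & (VB > 0)).astype(float)
    N11 = A1.T @ B1
    N12 = A1.T @ B2
    N21 = A2.T @ B1
    N22 = A2.T @ B2
    return n_used, pA, pB, N11, N12, N21, N22


def _em_r2(n_used, pA, pB, N11, N12, N21, N22, tol=EM_TOL, max_iter=EM_MAX_ITER):
    """Vectorized EM for the (minor, minor) haplotype frequency; returns r^2.

    Initialized at linkage equilibrium f11 = pA*pB. Pairs with an
    undefined denominator (monomorphic on the overlap, or fewer than two
    jointly observed samples) come back as NaN.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = pA * (1 - pA) * pB * (1 - pB)
    bad = ~np.isfinite(denom) | (denom <= 0) | (n_used < 2)
    f11 = pA * pB
    lo = np.maximum(0.0, pA + pB - 1.0)
    hi = np.minimum(pA, pB)
    known = 2.0 * N22 + N21 + N12
    two_n = 2.0 * n_used
    for _ in range(max_iter):
        f10 = pA - f11
        f01 = pB - f11
        f00 = 1.0 - pA - pB + f11
        num = f11 * f00
        den = num + f10 * f01
        with np.errstate(invalid="ignore", divide="ignore"):
            P = np.where(den > 0, num / np.maximum(den, 1e-300), 0.5)
        with np.errstate(invalid="ignore", divide="ignore"):
            f_new = (known + P * N11) / two_n
        f_new = np.clip(f_new, lo, hi)
        delta = np.abs(f_new - f11)
        f11 = f_new
        if np.nanmax(np.where(bad, 0.0, delta), initial=0.0) < tol:
            break
    D = f11 - pA * pB
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (D * D) / denom
    out = np.clip(out, 0.0, 1.0)
    out[bad] = np.nan
    return out


def _pair_stats_aligned(A, VA, B, VB):
    """Like :func:`_pair_stats` but for aligned column pairs (elementwise)."""
    n_used = (VA * VB).sum(axis=0)
    sumA = (A * VA * VB).sum(axis=0)
    sumB = (B * VB * VA).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pA = sumA / (2.0 * n_used)
        pB = sumB / (2.0 * n_used)
    V = (VA * VB) > 0
    A1, A2 = (A == 1) & V, (A == 2) & V
    B1, B2 = (B == 1) & V, (B == 2) & V
    N11 = (A1 & B1).sum(axis=0).astype(float)
    N12 = (A1 & B2).sum(axis=0).astype(float)
    N21 = (A2 & B1).sum(axis=0).astype(float)
    N22 = (A2 & B2).sum(axis=0).astype(float)
    return n_used, pA, pB, N11, N12, N21, N22


def _dosage_r2(A, VA, B, VB):
    """Squared Pearson correlation of dosages on jointly observed samples."""
    n_used = VA.T @ VB
    sA = (A * VA).T @ VB
    sB = VA.T @ (B * VB)
    sAB = (A * VA).T @ (B * VB)
    sA2 = (A * A * VA).T @ VB
    sB2 = VA.T @ (B * B * VB)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sAB - sA * sB / n_used
        varA = sA2 - sA * sA / n_used
        varB = sB2 - sB * sB / n_used
        out = (cov * cov) / (varA * varB)
    bad = ~np.isfinite(out) | (n_used < 2)
    out = np.clip(out, 0.0, 1.0)
    out[bad] = np.nan
    return out


def _prep(X: GenotypeMatrix):
    A = X.values.astype(float)
    V = (~X.missing_mask).astype(float)
    A = A * V  # zero out missing so products ignore them
    return A, V


def r2_matrix(X: GenotypeMatrix, rows=None, cols=None, estimator="em") -> np.ndarray:
    """r^2 for every pair (j in rows, k in cols); NaN where undefined.

    ``rows``/``cols`` default to all SNPs. ``estimator`` is "em"
    (maximum-likelihood haplotype frequencies, default) or "dosage"
    (squared Pearson correlation of dosages, faster).
    """
    A, V = _prep(X)
    rows = np.arange(X.p) if rows is None else np.asarray(rows)
    cols = np.arange(X.p) if cols is None else np.asarray(cols)
    Ar, Vr = A[:, rows], V[:, rows]
    Ac, Vc = A[:, cols], V[:, cols]
    if estimator == "em":
        stats = _pair_stats(Ar, Vr, Ac, Vc)
        return _em_r2(*stats)
    if estimator == "dosage":
        return _dosage_r2(Ar, Vr, Ac, Vc)
    raise ValueError(f"unknown estimator {estimator!r}")


def r2(g_j, g_k, estimator="em"):
    """r^2 between two genotype columns (1-D arrays; NaN marks missing).

    Raises :class:`UndefinedLDError` if either SNP is monomorphic on the
    jointly observed samples or fewer than two such samples exist.
    """
    g_j = np.asarray(g_j, dtype=float)
    g_k = np.asarray(g_k, dtype=float)
    mask = np.column_stack([np.isnan(g_j), np.isnan(g_k)])
    vals = np.column_stack([np.where(mask[:, 0], 0, g_j), np.where(mask[:, 1], 0, g_k)])
    X = GenotypeMatrix(
        values=vals.astype(int),
        missing_mask=mask,
        pos=np.array([1, 2]),
    )
    out = r2_matrix(X, rows=[0], cols=[1], estimator=estimator)[0, 0]
    if np.isnan(out):
        raise UndefinedLDError(
            "LD undefined: a SNP is monomorphic on the jointly observed samples"
        )
    return float(out)


def dissimilarity(g_j, g_k, estimator="em"):
    """Clustering dissimilarity 1 - r^2(j, k)."""
    return 1.0 - r2(g_j, g_k, estimator=estimator)


class LDProvider:
    """Lazy pairwise-similarity provider over a single-chromosome matrix.

    Answers s(j, k) = r^2(j, k) on demand, caching exactly the pairs that
    were requested; the full p x p matrix is never materialized, so memory
    grows with the number of distinct pairs the clustering touches, not
    with p^2. Rectangle queries are computed in one vectorized batch.
    """

    def __init__(self, X: GenotypeMatrix, estimator="em"):
        if len(X.chromosomes()) > 1:
            raise ValueError(
                "LDProvider operates on a single chromosome; got "
                f"{X.chromosomes()} (split the input chromosome by chromosome)"
            )
        self.X = X
        self.p = X.p
        self.estimator = estimator
        self._A, self._V = _prep(X)
        self._cache: dict[tuple[int, int], float] = {}
        self.n_computed = 0  # distinct pairs actually estimated (probe hook)

    def _check(self, j, k):
        if not (0 <= j < self.p and 0 <= k < self.p):
            raise IndexError(f"SNP index out of range: ({j}, {k})")

    def _compute_rect(self, rows, cols):
        Ar, Vr = self._A[:, rows], self._V[:, rows]
        Ac, Vc = self._A[:, cols], self._V[:, cols]
        if self.estimator == "em":
            vals = _em_r2(*_pair_stats(Ar, Vr, Ac, Vc))
        else:
            vals = _dosage_r2(Ar, Vr, Ac, Vc)
        return vals

    def r2(self, j: int, k: int) -> float:
        self._check(j, k)
        if j == k:
            return 1.0
        key = (j, k) if j < k else (k, j)
        if key not in self._cache:
            val = float(self._compute_rect([key[0]], [key[1]])[0, 0])
            if np.isnan(val):
                raise UndefinedLDError(
                    f"LD undefined for SNP pair ({self.X.snp_ids[j]}, "
                    f"{self.X.snp_ids[k]})"
                )
            self._cache[key] = val
            self.n_computed += 1
        return self._cache[key]

    def r2_block(self, rows, cols) -> np.ndarray:
        """r^2 rectangle for rows x cols, served from cache where possible."""
        rows = np.asarray(rows)
        cols = np.asarray(cols)
        out = np.empty((len(rows), len(cols)))
        need_r, need_c = [], []
        for a, j in enumerate(rows):
            for b, k in enumerate(cols):
                if j == k:
                    out[a, b] = 1.0
                    continue
                key = (j, k) if j < k else (k, j)
                if key in self._cache:
                    out[a, b] = self._cache[key]
                else:
                    need_r.append((a, j))
                    need_c.append((b, k))
        if need_r:
            # one vectorized pass over the unique uncached rows x cols
            uj = sorted({j for _, j in need_r})
            uk = sorted({k for _, k in need_c})
            vals = self._compute_rect(uj, uk)
            pos_j = {j: i for i, j in enumerate(uj)}
            pos_k = {k: i for i, k in enumerate(uk)}
            for (a, j), (b, k) in zip(need_r, need_c):
                v = float(vals[pos_j[j], pos_k[k]])
                if np.isnan(v):
                    raise UndefinedLDError(
                        f"LD undefined for SNP pair ({self.X.snp_ids[j]}, "
                        f"{self.X.snp_ids[k]})"
                    )
                key = (j, k) if j < k else (k, j)
                if key not in self._cache:
                    self._cache[key] = v
                    self.n_computed += 1
                out[a, b] = v
        return out

    def r2_pairs(self, js, ks) -> np.ndarray:
        """r^2 for aligned index pairs (js[i], ks[i]), vectorized."""
        js = np.asarray(js)
        ks = np.asarray(ks)
        out = np.empty(len(js))
        need = []
        for i, (j, k) in enumerate(zip(js, ks)):
            if j == k:
                out[i] = 1.0
                continue
            key = (int(j), int(k)) if j < k else (int(k), int(j))
            if key in self._cache:
                out[i] = self._cache[key]
            else:
                need.append(i)
        if need:
            nj, nk = js[need], ks[need]
            if self.estimator == "em":
                vals = _em_r2(
                    *_pair_stats_aligned(
                        self._A[:, nj], self._V[:, nj], self._A[:, nk], self._V[:, nk]
                    )
                )
            else:
                vals = np.array(
                    [float(self._compute_rect([j], [k])[0, 0]) for j, k in zip(nj, nk)]
                )
            for i, v in zip(need, vals):
                if np.isnan(v):
                    raise UndefinedLDError(
                        f"LD undefined for SNP pair ({self.X.snp_ids[js[i]]}, "
                        f"{self.X.snp_ids[ks[i]]})"
                    )
                key = (int(min(js[i], ks[i])), int(max(js[i], ks[i])))
                if key not in self._cache:
                    self._cache[key] = float(v)
                    self.n_computed += 1
                out[i] = float(v)
        return out

    def sum_block(self, rows, cols) -> float:
        """Sum of r^2 over the rows x cols rectangle (clustering cross-sums)."""
        return float(self.r2_block(rows, cols).sum())


def filter_undefined_ld(X: GenotypeMatrix) -> tuple[GenotypeMatrix, np.ndarray]:
    """Drop SNPs that would generate undefined LD values.

    A SNP that is monomorphic on its observed samples (or observed fewer
    than twice) has an undefined r^2 with every partner and is removed
    before clustering. Returns the filtered matrix and the dropped column
    indices; the removal is logged.
    """
    keep = []
    dropped = []
    for j in range(X.p):
        obs = X.values[~X.missing_mask[:, j], j]
        if obs.size >= 2 and np.unique(obs).size >= 2:
            keep.append(j)
        else:
            dropped.append(j)
    if dropped:
        logger.info(
            "filtered %d SNP(s) with undefined LD (monomorphic): %s",
            len(dropped),
            ", ".join(map(str, X.snp_ids[dropped][:10])),
        )
    return X.take_snps(keep), np.asarray(dropped, dtype=int)
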