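"""Penalized regression over LD blocks and comparator selectors.

All objectives use the unnormalized residual sum of squares, matching the
estimators

    Group Lasso:  ||y - X b||_2^2 + lambda * sum_g sqrt(p_g) ||b^g||_2
    Lasso:        ||y - X b||_2^2 + lambda * ||b||_1
    Elastic-Net:  ||y - X b||_2^2 + lambda1 ||b||_1 + lambda2 ||b||_2^2

so every KKT factor of 2 below follows from that convention. The design
is centered and scaled to unit variance and the response centered before
fitting; coefficients are reported on the standardized scale, since only
the selected support is consumed downstream. Optional covariates (e.g.
sex) enter unpenalized, implemented by residualizing y and X on the
covariates first (Frisch-Waugh-Lovell).

The Group Lasso solver is a block proximal coordinate descent with group
soft-thresholding; Lasso and Elastic-Net are delegated to scikit-learn's
coordinate descent with the objective rescaled to sklearn's 1/(2n)
convention. Single-marker analysis (SMA) fits y ~ 1 + X_j per SNP and
reports the two-sided t-test p-value of the slope against the
intercept-only (or covariate-only) model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.linear_model import ElasticNet, Lasso

from .cluster import BlockStructure

__all__ = [
    "RegressionProblem",
    "RegressionPath",
    "SMAResult",
    "group_lasso_path",
    "lasso_path",
    "enet_path",
    "sma",
    "kkt_violation_group_lasso",
    "kkt_violation_lasso",
]

_SUPPORT_EPS = 1e-10


@dataclass
class RegressionProblem:
    """Standardized design, centered response and the block partition."""

    X: np.ndarray
    y: np.ndarray
    groups: BlockStructure | None = None
    covariates: np.ndarray | None = None

    @classmethod
    def from_data(cls, X, y, groups=None, covariates=None) -> "RegressionProblem":
        """Center/scale X, center y, and residualize on covariates."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if not np.isfinite(y).all():
            raise ValueError("response contains non-finite values")
        if not np.isfinite(X).all():
            raise ValueError("design contains non-finite values (impute first)")
        n = len(y)
        if X.shape[0] != n:
            raise ValueError("X and y have different numbers of samples")
        if n < 2:
            raise ValueError("need at least 2 samples")
        if covariates is not None:
            C = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
            Q, _ = np.linalg.qr(C)
            X = X - Q @ (Q.T @ X)
            y = y - Q @ (Q.T @ y)
        else:
            X = X - X.mean(axis=0)
            y = y - y.mean()
        sd = X.std(axis=0)
        if (sd == 0).any():
            bad = np.where(sd == 0)[0]
            raise ValueError(f"zero-variance columns in design: {bad[:10]}")
        X = X / sd
        return cls(X=X, y=y, groups=groups, covariates=None)


@dataclass
class RegressionPath:
    """Per-penalty coefficient vectors along a descending penalty grid."""

    lambdas: np.ndarray
    coefs: np.ndarray  # (n_lambdas, p)
    method: str

    @property
    def supports(self) -> list[np.ndarray]:
        return [np.where(np.abs(c) > _SUPPORT_EPS)[0] for c in self.coefs]

    def to_frame(self, snp_ids=None):
        import pandas as pd

        n_l, p = self.coefs.shape
        ids = np.arange(p) if snp_ids is None else np.asarray(snp_ids)
        rows = []
        for lam, coef in zip(self.lambdas, self.coefs):
            nz = np.where(np.abs(coef) > _SUPPORT_EPS)[0]
            for j in nz:
                rows.append((lam, ids[j], coef[j]))
        return pd.DataFrame(rows, columns=["lambda", "snp_id", "coef"])


def _group_slices(groups: BlockStructure):
    slices = [slice(a, b) for a, b in groups.ranges]
    if any(s.stop - s.start == 0 for s in slices):
        raise ValueError("empty group in block structure")
    return slices


def _auto_grid(lam_max: float, n_lambdas: int, min_ratio: float) -> np.ndarray:
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambdas)


def group_lasso_max_lambda(X, y, groups: BlockStructure) -> float:
    """Smallest lambda at which the all-zero solution satisfies the KKT
    conditions: lambda_max = max_g 2 ||X_g' y||_2 / sqrt(p_g)."""
    vals = []
    for a, b in groups.ranges:
        vals.append(2.0 * np.linalg.norm(X[:, a:b].T @ y) / np.sqrt(b - a))
    return float(max(vals))


def group_lasso_path(
    problem: RegressionProblem,
    lambdas=None,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 1e-3,
    tol: float = 1e-10,
    max_sweeps: int = 10000,
    stop_at_full_support: bool = False,
) -> RegressionPath:
    """Group Lasso solution path by block coordinate descent.

    Each visited block is minimized exactly: the single-group subproblem
    ||r_g - X_g b||^2 + lambda sqrt(p_g) ||b|| is solved in the eigenbasis
    of 2 X_g'X_g with a 1-D root-find on ||b|| (see
    :func:`_group_norm_root`). Sweeps stop when the largest coefficient
    change falls below ``tol``; solutions are warm-started along the
    descending grid. With ``stop_at_full_support`` the path ends early
    once every group is active (further penalty values cannot change the
    selected support, only shrinkage), which is convenient when only the
    selection path is consumed.
    """
    if problem.groups is None:
        raise ValueError("group_lasso_path requires a block structure")
    X, y = problem.X, problem.y
    slices = _group_slices(problem.groups)
    weights = np.sqrt([s.stop - s.start for s in slices])
    if lambdas is None:
        lam_max = group_lasso_max_lambda(X, y, problem.groups)
        lambdas = _auto_grid(lam_max, n_lambdas, lambda_min_ratio)
    lambdas = np.asarray(lambdas, dtype=float)

    Xg = [np.ascontiguousarray(X[:, s]) for s in slices]
    # per-group spectral data for the exact block update:
    # 2 X_g'X_g = V diag(D) V'
    eig = []
    for g_X in Xg:
        D, V = np.linalg.eigh(2.0 * (g_X.T @ g_X))
        eig.append((np.maximum(D, 0.0), V))

    p = X.shape[1]
    beta = np.zeros(p)
    resid = y.copy()
    coefs = np.empty((len(lambdas), p))
    for li, lam in enumerate(lambdas):
        for _ in range(max_sweeps):
            max_delta = 0.0
            for g, (s, g_X) in enumerate(zip(slices, Xg)):
                b_old = beta[s]
                D, V = eig[g]
                # partial-residual correlation c = X_g'(resid + X_g b_old)
                c2 = 2.0 * (g_X.T @ resid)
                if b_old.any():
                    c2 = c2 + (V * D) @ (V.T @ b_old)
                kappa = lam * weights[g]
                norm_c2 = np.linalg.norm(c2)
                if norm_c2 <= kappa:
                    b_new = np.zeros_like(b_old)
                else:
                    z = V.T @ c2
                    s_norm = _group_norm_root(z, D, kappa)
                    b_new = V @ (z * s_norm / (D * s_norm + kappa))
                delta = b_new - b_old
                d = np.abs(delta).max() if delta.size else 0.0
                if d > 0:
                    resid -= g_X @ delta
                    beta[s] = b_new
                    if d > max_delta:
                        max_delta = d
            if max_delta < tol:
                break
        coefs[li] = beta
        if stop_at_full_support and all(
            np.abs(beta[s]).max() > _SUPPORT_EPS for s in slices
        ):
            coefs = coefs[: li + 1]
            lambdas = lambdas[: li + 1]
            break
    return RegressionPath(lambdas=lambdas, coefs=coefs, method="group-lasso")


def _group_norm_root(z, D, kappa, tol=1e-14, max_iter=200):
    """Solve sum_i (z_i / (D_i s + kappa))^2 = 1 for s > 0.

    This is the norm ||b_g|| of the exact minimizer of the single-group
    subproblem ||r - X_g b||^2 + kappa ||b||: the stationarity condition
    (2 X_g'X_g + (kappa/s) I) b = 2 X_g'r becomes the above scalar
    equation in the eigenbasis (z = V' 2X_g'r). The left side is strictly
    decreasing in s, so bisection on a guaranteed bracket converges.
    """
    norm_z = np.linalg.norm(z)
    d_min = D.min()
    lo = 0.0
    if d_min > 1e-12:
        hi = (norm_z - kappa) / d_min
    else:
        hi = max((norm_z - kappa) / max(D.max(), 1e-12), 1.0)
        while np.sum((z / (D * hi + kappa)) ** 2) > 1.0:
            hi *= 2.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if np.sum((z / (D * mid + kappa)) ** 2) > 1.0:
            lo = mid
        else:
            hi = mid
        if hi - lo <= tol * max(1.0, hi):
            break
    return 0.5 * (lo + hi)


def kkt_violation_group_lasso(problem: RegressionProblem, lam: float, beta) -> float:
    """Largest KKT violation of the Group Lasso objective at ``beta``.

    Zero groups must satisfy ||X_g' r||_2 <= (lam/2) sqrt(p_g); active
    groups must satisfy 2 X_g'(Xb - y) + lam sqrt(p_g) b_g/||b_g|| = 0.
    """
    X, y = problem.X, problem.y
    beta = np.asarray(beta)
    resid = y - X @ beta
    worst = 0.0
    for a, b in problem.groups.ranges:
        w = np.sqrt(b - a)
        bg = beta[a:b]
        corr = X[:, a:b].T @ resid
        if np.linalg.norm(bg) <= _SUPPORT_EPS:
            worst = max(worst, np.linalg.norm(corr) - 0.5 * lam * w)
        else:
            grad = -2.0 * corr + lam * w * bg / np.linalg.norm(bg)
            worst = max(worst, np.abs(grad).max())
    return float(worst)


def kkt_violation_lasso(problem: RegressionProblem, lam: float, beta,
                        lambda2: float = 0.0) -> float:
    """Largest KKT violation of the (Elastic-Net) Lasso objective."""
    X, y = problem.X, problem.y
    beta = np.asarray(beta)
    corr = X.T @ (y - X @ beta)
    worst = 0.0
    for j in range(len(beta)):
        if abs(beta[j]) <= _SUPPORT_EPS:
            worst = max(worst, abs(corr[j]) - 0.5 * lam)
        else:
            grad = -2.0 * corr[j] + 2.0 * lambda2 * beta[j] + lam * np.sign(beta[j])
            worst = max(worst, abs(grad))
    return float(worst)


def lasso_max_lambda(X, y) -> float:
    return float(2.0 * np.abs(X.T @ y).max())


def lasso_path(
    problem: RegressionProblem,
    lambdas=None,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 1e-3,
    tol: float = 1e-10,
    max_iter: int = 100000,
) -> RegressionPath:
    """Lasso path; lambda is mapped to sklearn's alpha = lambda / (2n)."""
    X, y = problem.X, problem.y
    n = len(y)
    if lambdas is None:
        lambdas = _auto_grid(lasso_max_lambda(X, y), n_lambdas, lambda_min_ratio)
    lambdas = np.asarray(lambdas, dtype=float)
    coefs = np.empty((len(lambdas), X.shape[1]))
    model = Lasso(alpha=1.0, fit_intercept=False, warm_start=True,
                  tol=tol, max_iter=max_iter)
    for i, lam in enumerate(lambdas):
        model.alpha = lam / (2.0 * n)
        model.fit(X, y)
        coefs[i] = model.coef_
    return RegressionPath(lambdas=lambdas, coefs=coefs, method="lasso")


def enet_path(
    problem: RegressionProblem,
    lambdas=None,
    lambda2: float = 0.8,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 1e-3,
    tol: float = 1e-10,
    max_iter: int = 100000,
) -> RegressionPath:
    """Elastic-Net path at a fixed ridge penalty lambda2 (default 0.8).

    sklearn's parametrization alpha*l1_ratio = lambda1/(2n) and
    0.5*alpha*(1-l1_ratio) = lambda2/(2n) is inverted per grid point.
    """
    if lambda2 < 0:
        raise ValueError("lambda2 must be non-negative")
    X, y = problem.X, problem.y
    n = len(y)
    if lambdas is None:
        lambdas = _auto_grid(lasso_max_lambda(X, y), n_lambdas, lambda_min_ratio)
    lambdas = np.asarray(lambdas, dtype=float)
    coefs = np.empty((len(lambdas), X.shape[1]))
    for i, lam1 in enumerate(lambdas):
        a_l1 = lam1 / (2.0 * n)
        a_l2 = lambda2 / n  # = alpha * (1 - l1_ratio)
        alpha = a_l1 + a_l2
        l1_ratio = a_l1 / alpha if alpha > 0 else 1.0
        model = ElasticNet(alpha=alpha, l1_ratio=l1_ratio, fit_intercept=False,
                           tol=tol, max_iter=max_iter)
        model.fit(X, y)
        coefs[i] = model.coef_
    return RegressionPath(lambdas=lambdas, coefs=coefs, method="enet")


@dataclass
class SMAResult:
    """Per-SNP single-marker OLS slope, t statistic and two-sided p-value."""

    beta: np.ndarray
    t_stat: np.ndarray
    p_value: np.ndarray
    undefined: np.ndarray  # True where the SNP column was constant

    def to_frame(self, snp_ids=None):
        import pandas as pd

        ids = np.arange(len(self.beta)) if snp_ids is None else np.asarray(snp_ids)
        return pd.DataFrame(
            {"snp_id": ids, "beta": self.beta, "t": self.t_stat, "p": self.p_value}
        )


def sma(X, y, covariates=None) -> SMAResult:
    """Single-marker analysis: per SNP, OLS of y on an intercept (plus
    optional covariates) and that SNP, with a t-test on the SNP slope.

    Vectorized across SNPs via Frisch-Waugh-Lovell: y and each X_j are
    residualized on [1, covariates], and the slope of the residual
    regression is tested with n - q - 2 degrees of freedom. Constant
    columns yield NaN and are flagged in ``undefined``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    q = 0
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        q = C.shape[1]
        Q, _ = np.linalg.qr(np.column_stack([np.ones(n), C]))
        Xr = X - Q @ (Q.T @ X)
        yr = y - Q @ (Q.T @ y)
    else:
        Xr = X - X.mean(axis=0)
        yr = y - y.mean()
    df = n - q - 2
    if df <= 0:
        raise ValueError("not enough samples for the SMA t-test")
    sxx = (Xr**2).sum(axis=0)
    undefined = sxx <= 1e-300
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = (Xr * yr[:, None]).sum(axis=0) / sxx
        rss = (yr**2).sum() - beta**2 * sxx
        rss = np.maximum(rss, 0.0)
        se = np.sqrt(rss / df / sxx)
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    beta[undefined] = np.nan
    t[undefined] = np.nan
    p[undefined] = np.nan
    return SMAResult(beta=beta, t_stat=t, p_value=p, undefined=undefined)
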