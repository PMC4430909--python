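"""Tests of the Group Lasso solver and the comparator selectors."""

import itertools

import numpy as np
import pytest
from scipy import stats

from ldblocks.cluster import BlockStructure
from ldblocks.regression import (RegressionProblem, enet_path,
                                 group_lasso_max_lambda, group_lasso_path,
                                 kkt_violation_group_lasso,
                                 kkt_violation_lasso, lasso_max_lambda,
                                 lasso_path, sma)


@pytest.fixture
def small_problem(rng):
    n, p = 50, 12
    X = rng.standard_normal((n, p))
    beta = np.zeros(p)
    beta[:3] = [1.5, -1.0, 0.8]
    y = X @ beta + 0.5 * rng.standard_normal(n)
    groups = BlockStructure.from_sizes([3, 3, 3, 3])
    return RegressionProblem.from_data(X, y, groups=groups)


def test_zero_solution_at_and_above_lambda_max(small_problem):
    lam_max = group_lasso_max_lambda(
        small_problem.X, small_problem.y, small_problem.groups
    )
    for lam in (lam_max, 1.5 * lam_max):
        path = group_lasso_path(small_problem, lambdas=[lam])
        assert np.abs(path.coefs).max() == 0.0
    # strictly below lambda_max something enters
    below = group_lasso_path(small_problem, lambdas=[0.99 * lam_max])
    assert np.abs(below.coefs).max() > 0


def test_kkt_conditions_along_auto_path(small_problem):
    path = group_lasso_path(small_problem, n_lambdas=40)
    worst = max(
        kkt_violation_group_lasso(small_problem, lam, coef)
        for lam, coef in zip(path.lambdas, path.coefs)
    )
    assert worst < 1e-6


def test_groups_all_zero_or_all_nonzero(small_problem):
    path = group_lasso_path(small_problem, n_lambdas=40)
    for coef in path.coefs:
        for a, b in small_problem.groups.ranges:
            g = np.abs(coef[a:b])
            assert (g > 1e-10).all() or (g <= 1e-10).all()


def test_objective_decreases_along_descending_path(small_problem):
    path = group_lasso_path(small_problem, n_lambdas=30)
    X, y = small_problem.X, small_problem.y
    w = np.sqrt(small_problem.groups.sizes)
    prev = np.inf
    for lam, coef in zip(path.lambdas, path.coefs):
        pen = sum(
            wg * np.linalg.norm(coef[a:b])
            for wg, (a, b) in zip(w, small_problem.groups.ranges)
        )
        obj = np.sum((y - X @ coef) ** 2) + lam * pen
        assert obj <= prev + 1e-8
        prev = obj


def test_singleton_groups_reduce_to_lasso(rng):
    n, p = 40, 15
    X = rng.standard_normal((n, p))
    y = X[:, 0] - 0.5 * X[:, 5] + 0.3 * rng.standard_normal(n)
    prob = RegressionProblem.from_data(
        X, y, groups=BlockStructure.from_sizes([1] * p)
    )
    gl = group_lasso_path(prob, n_lambdas=25)
    ls = lasso_path(prob, lambdas=gl.lambdas)
    assert np.abs(gl.coefs - ls.coefs).max() < 1e-6


def test_single_group_orthonormal_closed_form(rng):
    n, pg = 40, 5
    Q, _ = np.linalg.qr(rng.standard_normal((n, pg)))
    y = rng.standard_normal(n)
    y = y - y.mean()
    prob = RegressionProblem(X=Q, y=y, groups=BlockStructure.from_sizes([pg]))
    z = Q.T @ y
    for frac in (0.3, 0.7, 0.95):
        lam = frac * 2.0 * np.linalg.norm(z) / np.sqrt(pg)
        got = group_lasso_path(prob, lambdas=[lam]).coefs[0]
        shrink = max(0.0, 1.0 - lam * np.sqrt(pg) / (2.0 * np.linalg.norm(z)))
        assert np.abs(got - shrink * z).max() < 1e-8


def test_lasso_orthonormal_soft_threshold(rng):
    n, p = 30, 6
    Q, _ = np.linalg.qr(rng.standard_normal((n, p)))
    y = rng.standard_normal(n)
    y = y - y.mean()
    prob = RegressionProblem(X=Q, y=y, groups=None)
    z = Q.T @ y
    lam = np.abs(z).max()  # half the coordinates survive
    got = lasso_path(prob, lambdas=[lam]).coefs[0]
    expected = np.sign(z) * np.maximum(np.abs(z) - lam / 2.0, 0.0)
    assert np.abs(got - expected).max() < 1e-6


def test_lasso_matches_support_enumeration_oracle(rng):
    """p=3: enumerate all sign patterns, solve each candidate stationary
    system in closed form, keep the KKT-consistent one."""
    n, p = 25, 3
    X = rng.standard_normal((n, p))
    X = (X - X.mean(0)) / X.std(0)
    y = X @ np.array([1.0, -0.5, 0.0]) + 0.3 * rng.standard_normal(n)
    y = y - y.mean()
    prob = RegressionProblem(X=X, y=y, groups=None)
    for lam in (0.3 * lasso_max_lambda(X, y), 0.05 * lasso_max_lambda(X, y)):
        best = None
        for signs in itertools.product([-1, 0, 1], repeat=p):
            s = np.array(signs, dtype=float)
            active = np.where(s != 0)[0]
            beta = np.zeros(p)
            if len(active):
                XA = X[:, active]
                beta[active] = np.linalg.solve(
                    XA.T @ XA, XA.T @ y - (lam / 2.0) * s[active]
                )
            if np.any(np.sign(beta[active]) != s[active]):
                continue
            if kkt_violation_lasso(prob, lam, beta) < 1e-8:
                best = beta
                break
        assert best is not None
        got = lasso_path(prob, lambdas=[lam]).coefs[0]
        assert np.abs(got - best).max() < 1e-6


def test_enet_reduces_to_lasso_without_ridge(rng):
    n, p = 40, 10
    X = rng.standard_normal((n, p))
    y = X[:, 0] + rng.standard_normal(n)
    prob = RegressionProblem.from_data(X, y)
    ls = lasso_path(prob, n_lambdas=20)
    en = enet_path(prob, lambdas=ls.lambdas, lambda2=0.0)
    assert np.abs(ls.coefs - en.coefs).max() < 1e-8


def test_enet_splits_duplicated_columns_equally(rng):
    n = 40
    x = rng.standard_normal(n)
    X = np.column_stack([x, x, rng.standard_normal(n)])
    y = 2.0 * x + 0.1 * rng.standard_normal(n)
    # no column scaling issues: standardize by hand, keep duplicates exact
    X = (X - X.mean(0)) / X.std(0)
    y = y - y.mean()
    prob = RegressionProblem(X=X, y=y, groups=None)
    lam = 0.3 * lasso_max_lambda(X, y)
    en = enet_path(prob, lambdas=[lam], lambda2=0.8).coefs[0]
    # strict convexity of the ridge term forces exact symmetry
    assert en[0] == pytest.approx(en[1], abs=1e-6)
    assert en[0] > 0.1


def test_enet_kkt_conditions(rng):
    n, p = 40, 8
    X = rng.standard_normal((n, p))
    y = X[:, 0] + rng.standard_normal(n)
    prob = RegressionProblem.from_data(X, y)
    path = enet_path(prob, n_lambdas=15, lambda2=0.8)
    worst = max(
        kkt_violation_lasso(prob, lam, coef, lambda2=0.8)
        for lam, coef in zip(path.lambdas, path.coefs)
    )
    assert worst < 1e-5


def test_sma_perfect_predictor_has_tiny_pvalue(rng):
    n = 50
    X = rng.integers(0, 3, (n, 4)).astype(float)
    y = X[:, 2].copy()
    res = sma(X, y)
    assert res.p_value[2] < 1e-12


def test_sma_null_pvalues_are_uniform(rng):
    n, p = 200, 1000
    X = rng.integers(0, 3, (n, p)).astype(float)
    y = rng.standard_normal(n)
    res = sma(X, y)
    ks = stats.kstest(res.p_value, "uniform")
    assert ks.pvalue > 0.01


def test_sma_matches_statsmodels_on_small_data(rng):
    sm_api = pytest.importorskip("statsmodels.api")
    n = 8
    X = rng.integers(0, 3, (n, 3)).astype(float)
    y = rng.standard_normal(n)
    res = sma(X, y)
    for j in range(3):
        fit = sm_api.OLS(y, sm_api.add_constant(X[:, j])).fit()
        assert res.beta[j] == pytest.approx(fit.params[1], abs=1e-10)
        assert res.t_stat[j] == pytest.approx(fit.tvalues[1], abs=1e-8)
        assert res.p_value[j] == pytest.approx(fit.pvalues[1], abs=1e-10)
    C = rng.standard_normal((n, 2))
    resc = sma(X, y, covariates=C)
    for j in range(3):
        fit = sm_api.OLS(y, sm_api.add_constant(np.column_stack([C, X[:, j]]))).fit()
        assert resc.t_stat[j] == pytest.approx(fit.tvalues[-1], abs=1e-8)
        assert resc.p_value[j] == pytest.approx(fit.pvalues[-1], abs=1e-10)


def test_sma_flags_constant_columns(rng):
    X = np.column_stack([np.ones(20), rng.integers(0, 3, 20).astype(float)])
    res = sma(X, rng.standard_normal(20))
    assert res.undefined[0] and not res.undefined[1]
    assert np.isnan(res.p_value[0])


def test_problem_validation(rng):
    X = rng.standard_normal((10, 3))
    with pytest.raises(ValueError, match="non-finite"):
        RegressionProblem.from_data(X, np.array([np.nan] * 10))
    Xc = X.copy()
    Xc[:, 1] = 2.0
    with pytest.raises(ValueError, match="zero-variance"):
        RegressionProblem.from_data(Xc, rng.standard_normal(10))
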