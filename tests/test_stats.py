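"""Metrics-table assembly, regressions, correlations and LASSO selection."""

import numpy as np
import pandas as pd
import pytest

from isledv import (
    IslandRecord,
    assemble_table,
    correlation_matrix,
    holm_adjust,
    lasso_select,
    simple_regression,
)
from isledv.diversity_metrics import HetSummary
from isledv.erv import ERVSummary


def island_table(**cols):
    n = len(next(iter(cols.values())))
    df = pd.DataFrame({"log10_area": np.arange(n, dtype=float), **cols})
    df.index = [f"I{i}" for i in range(n)]
    df.index.name = "island"
    return df


class TestAssemble:
    def records(self):
        return [
            IslandRecord("s1", "Alpha", 100.0),
            IslandRecord("s2", "Beta", 10.0),
            IslandRecord("s3", "Gamma", 1_000.0),
        ]

    def test_complete_join(self):
        het = {s: HetSummary(s, 0.001, 0.0005, 0.5, 30, 10_000, 10) for s in ("s1", "s2", "s3")}
        erv = {s: ERVSummary(s, 4, 2, 50) for s in ("s1", "s2", "s3")}
        tb = assemble_table(self.records(), het, None, erv, None)
        assert len(tb) == 3
        assert tb.loc["Alpha", "log10_area"] == pytest.approx(2.0)
        assert tb.loc["Beta", "erv_hom_nonref"] == 4

    def test_partial_metrics_leave_missing_cells(self):
        het = {"s1": HetSummary("s1", 0.001, None, None, 1, 100, 0)}
        tb = assemble_table(self.records(), het, None, None, None)
        assert np.isnan(tb.loc["Beta", "genome_het"])
        assert tb.loc["Alpha", "genome_het"] == pytest.approx(0.001)

    def test_duplicate_sample_id_rejected(self):
        recs = self.records() + [IslandRecord("s1", "Delta", 5.0)]
        with pytest.raises(ValueError, match="duplicate"):
            assemble_table(recs)

    def test_non_positive_area_rejected(self):
        with pytest.raises(ValueError):
            IslandRecord("s1", "Alpha", 0.0)


class TestRegression:
    def test_collinear_points(self):
        tb = island_table(y=[2.0, 4.0, 6.0])
        tb["log10_area"] = [1.0, 2.0, 3.0]
        fit, _ = simple_regression(tb, "y")
        assert fit.slope == pytest.approx(2.0) and fit.r == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(fit.r**2, rel=1e-12)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(29)
        x = rng.random(5) * 10
        y = 3.0 * x - 2.0 + rng.normal(0, 1, 5)
        tb = island_table(y=y)
        tb["log10_area"] = x
        fit, _ = simple_regression(tb, "y")
        X = np.stack([x, np.ones(5)], axis=1)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.slope == pytest.approx(beta[0], abs=1e-10)
        assert fit.intercept == pytest.approx(beta[1], abs=1e-10)

    def test_outlier_exclusion_returns_both_fits(self):
        # five points with slope +1 and one adversarial outlier flipping it
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, -40.0])
        tb = island_table(y=y)
        tb["log10_area"] = x
        full, reduced = simple_regression(tb, "y", exclude=["I5"])
        assert full.slope < 0 < reduced.slope
        assert reduced.excluded_points == ("I5",)
        assert full.n == 6 and reduced.n == 5

    def test_too_few_cases_is_an_error(self):
        tb = island_table(y=[1.0, 2.0])
        with pytest.raises(ValueError, match=">= 3"):
            simple_regression(tb, "y")

    def test_affine_equivariance(self):
        rng = np.random.default_rng(37)
        x = rng.random(8)
        y = 2 * x + rng.normal(0, 0.1, 8)
        tb = island_table(y=y, y2=5.0 * y + 7.0)
        tb["log10_area"] = x
        f1, _ = simple_regression(tb, "y")
        f2, _ = simple_regression(tb, "y2")
        assert f2.slope == pytest.approx(5.0 * f1.slope, rel=1e-9)
        assert f2.r == pytest.approx(f1.r, rel=1e-9)


class TestCorrelation:
    def test_perfect_anticorrelation(self):
        x = np.array([1.0, 2.0, 5.0, 7.0])
        tb = island_table(genome_het=x, het_sd=-x)
        mat, undef = correlation_matrix(tb, ["genome_het", "het_sd"])
        assert mat.loc["genome_het", "het_sd"] == pytest.approx(-1.0)
        assert undef == []

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(43)
        tb = island_table(a=rng.normal(size=1_000), b=rng.normal(size=1_000))
        mat, _ = correlation_matrix(tb, ["a", "b"])
        assert abs(mat.loc["a", "b"]) < 0.1

    def test_symmetry_and_unit_diagonal(self):
        rng = np.random.default_rng(47)
        tb = island_table(a=rng.random(6), b=rng.random(6), c=rng.random(6))
        mat, _ = correlation_matrix(tb, ["a", "b", "c"])
        assert np.allclose(mat.values, mat.values.T, equal_nan=True)
        assert np.allclose(np.diag(mat.values), 1.0)

    def test_constant_column_flagged_not_propagated(self):
        tb = island_table(a=[1.0, 2.0, 3.0, 4.0], b=[5.0, 5.0, 5.0, 5.0], c=[2.0, 1.0, 4.0, 3.0])
        mat, undef = correlation_matrix(tb, ["a", "b", "c"])
        assert ("a", "b") in undef and ("b", "c") in undef
        assert np.isnan(mat.loc["a", "b"])
        assert np.isfinite(mat.loc["a", "c"])


def soft_threshold(z, g):
    return np.sign(z) * max(abs(z) - g, 0.0)


def lasso_coordinate_descent(X, y, lam, n_iter=20_000, tol=1e-13):
    """Independent coordinate-descent oracle for
    (1/2n)||y - Xb||^2 + lam*||b||_1 on centred/standardized inputs."""
    n, p = X.shape
    b = np.zeros(p)
    r = y.copy()
    col_nrm = (X**2).sum(axis=0) / n
    for _ in range(n_iter):
        delta = 0.0
        for j in range(p):
            old = b[j]
            rho = X[:, j] @ r / n + col_nrm[j] * old
            b[j] = soft_threshold(rho, lam) / col_nrm[j]
            if b[j] != old:
                r -= X[:, j] * (b[j] - old)
                delta = max(delta, abs(b[j] - old))
        if delta < tol:
            break
    return b


class TestLasso:
    def make_table(self, seed=53, n=8, beta=1.0, noise=0.1):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 4))
        y = beta * X[:, 0] + rng.normal(0, noise, n)
        tb = pd.DataFrame(X, columns=["true", "n1", "n2", "n3"])
        tb["log10_area"] = y
        tb.index = [f"I{i}" for i in range(n)]
        return tb

    def test_true_predictor_selected(self):
        tb = self.make_table()
        fit = lasso_select(tb, "log10_area", ["true", "n1", "n2", "n3"])
        assert "true" in fit.selected
        assert fit.lambda_selected > 0

    def test_full_shrinkage_at_large_lambda(self):
        tb = self.make_table()
        fit = lasso_select(tb, "log10_area", ["true", "n1", "n2", "n3"], lambda_override=1e6)
        assert fit.selected == []
        assert all(c == 0.0 for c in fit.coefficients.values())

    def test_kkt_conditions_against_coordinate_descent(self):
        tb = self.make_table()
        fit = lasso_select(tb, "log10_area", ["true", "n1", "n2", "n3"])
        X = tb[["true", "n1", "n2", "n3"]].to_numpy()
        Xs = (X - X.mean(0)) / X.std(0)
        y = tb["log10_area"].to_numpy()
        yc = y - y.mean()
        lam = fit.lambda_selected
        b_oracle = lasso_coordinate_descent(Xs, yc, lam)
        b = np.array([fit.coefficients[c] for c in ["true", "n1", "n2", "n3"]])
        np.testing.assert_allclose(b, b_oracle, atol=1e-6)
        # KKT / subgradient: |X'(y-Xb)/n| <= lam, with equality on the support
        grad = Xs.T @ (yc - Xs @ b) / len(yc)
        for j in range(4):
            if b[j] != 0:
                assert grad[j] == pytest.approx(lam * np.sign(b[j]), abs=1e-6)
            else:
                assert abs(grad[j]) <= lam + 1e-6

    def test_monotone_support_on_orthogonal_design(self):
        # orthogonal predictors: the active set only shrinks as lambda grows
        n = 8
        A = np.random.default_rng(59).normal(size=(n, 3))
        A -= A.mean(axis=0)  # zero-mean columns stay orthogonal after standardization
        X = np.linalg.qr(A)[0] * np.sqrt(n)
        y = 2.0 * X[:, 0] + 0.8 * X[:, 1] + 0.1 * X[:, 2]
        tb = pd.DataFrame(X, columns=["a", "b", "c"])
        tb["log10_area"] = y
        tb.index = [f"I{i}" for i in range(n)]
        prev = None
        for lam in (0.01, 0.3, 1.0, 2.5):
            fit = lasso_select(tb, "log10_area", ["a", "b", "c"], lambda_override=lam)
            support = set(fit.selected)
            if prev is not None:
                assert support <= prev
            prev = support

    def test_too_few_cases_suggests_loo(self):
        tb = self.make_table(n=6)
        with pytest.raises(ValueError, match="loo"):
            lasso_select(tb, "log10_area", ["true", "n1", "n2", "n3"], cv="kfold", n_folds=10)
        with pytest.raises(ValueError, match=">= 5"):
            lasso_select(tb.iloc[:4], "log10_area", ["true", "n1", "n2", "n3"])


def test_holm_adjustment_orders_and_caps():
    adj = holm_adjust([0.01, 0.04, 0.03, 0.9])
    assert adj[0] == pytest.approx(0.04)
    assert adj[3] == pytest.approx(0.9)
    assert all(a <= 1.0 for a in adj)
    raw_order = np.argsort([0.01, 0.04, 0.03, 0.9])
    assert np.all(np.diff(np.asarray(adj)[raw_order]) >= -1e-15)
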