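import numpy as np
import pandas as pd
import pytest
from scipy import stats

from commphylo import (
    ValidationError,
    build_weights,
    great_circle_distances,
    morans_i,
    ols_standardized,
    regression_table,
    sar_error_ml,
    vif,
)
from commphylo.spatialstats import WeightsMatrix


def rook_lattice_weights(side):
    """4-neighbour lattice adjacency (test helper)."""
    n = side * side
    base = np.zeros((n, n))
    for i in range(side):
        for j in range(side):
            a = i * side + j
            for di, dj in ((1, 0), (0, 1)):
                ii, jj = i + di, j + dj
                if ii < side and jj < side:
                    b = ii * side + jj
                    base[a, b] = base[b, a] = 1.0
    return WeightsMatrix(base, style="rook", row_standardized=True)


class TestDistances:
    def test_identical_points_zero(self):
        d = great_circle_distances([5.0, 5.0], [10.0, 10.0])
        assert d[0, 1] == pytest.approx(0.0)

    def test_one_degree_equator(self):
        d = great_circle_distances([0.0, 1.0], [0.0, 0.0])
        assert d[0, 1] == pytest.approx(111.2, abs=0.5)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        d = great_circle_distances(rng.uniform(-180, 180, 10), rng.uniform(-60, 60, 10))
        np.testing.assert_allclose(d, d.T, atol=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError, match="range"):
            great_circle_distances([200.0], [0.0])


class TestWeights:
    def test_three_equidistant_sites(self):
        d = np.full((3, 3), 10.0)
        np.fill_diagonal(d, 0.0)
        W = build_weights(d, style="inverse_distance")
        off = W.values[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 0.5)

    def test_knn_full_connectivity(self):
        rng = np.random.default_rng(2)
        pts = rng.random((6, 2)) * 10
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        W = build_weights(d, style="knn", k=5, row_standardize=False)
        assert (W.base[~np.eye(6, dtype=bool)] == 1.0).all()

    def test_row_sums_one(self):
        rng = np.random.default_rng(3)
        d = great_circle_distances(rng.uniform(100, 110, 8), rng.uniform(20, 30, 8))
        W = build_weights(d)
        np.testing.assert_allclose(W.values.sum(axis=1), 1.0, rtol=1e-12)

    def test_coincident_sites_rejected(self):
        d = np.zeros((3, 3))
        with pytest.raises(ValidationError, match="jitter|knn"):
            build_weights(d, style="inverse_distance")

    def test_eigvals_real_and_bounded(self):
        rng = np.random.default_rng(4)
        d = great_circle_distances(rng.uniform(100, 110, 12), rng.uniform(20, 30, 12))
        W = build_weights(d)
        assert np.isrealobj(W.eigvals)
        assert W.eigvals.max() == pytest.approx(1.0, abs=1e-9)  # row-standardized


class TestMoran:
    def test_expected_value(self):
        rng = np.random.default_rng(5)
        d = great_circle_distances(rng.uniform(100, 110, 11), rng.uniform(20, 30, 11))
        W = build_weights(d)
        res = morans_i(rng.standard_normal(11), W)
        assert res.expected == pytest.approx(-0.1)

    def test_checkerboard_negative(self):
        W = rook_lattice_weights(4)
        vals = np.array([(i + j) % 2 for i in range(4) for j in range(4)], dtype=float)
        res = morans_i(vals, W)
        assert res.I < 0
        assert res.p < 0.01

    def test_permutation_agrees_with_analytic(self):
        rng = np.random.default_rng(6)
        d = great_circle_distances(rng.uniform(100, 110, 30), rng.uniform(20, 30, 30))
        W = build_weights(d)
        for seed in range(5):
            x = np.random.default_rng(seed).standard_normal(30)
            res = morans_i(x, W, n_perm=500, seed=seed)
            assert abs(res.p - res.p_perm) < 0.05 or min(res.p, res.p_perm) > 0.2

    def test_affine_invariance(self):
        W = rook_lattice_weights(4)
        rng = np.random.default_rng(7)
        x = rng.standard_normal(16)
        a = morans_i(x, W)
        b = morans_i(5.0 * x - 3.0, W)
        assert a.I == pytest.approx(b.I, rel=1e-12)

    def test_constant_rejected(self):
        W = rook_lattice_weights(3)
        with pytest.raises(ValidationError, match="constant"):
            morans_i(np.ones(9), W)


class TestOLS:
    def test_identity(self):
        x = np.arange(10.0)
        fit = ols_standardized(x, x)
        assert fit.coef == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_coef_equals_pearson(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(50)
        y = 0.4 * x + rng.standard_normal(50)
        fit = ols_standardized(y, x)
        assert fit.coef == pytest.approx(stats.pearsonr(x, y)[0], rel=1e-9)
        assert fit.r2 == pytest.approx(fit.coef**2, abs=1e-10)

    def test_independent_near_zero(self):
        rng = np.random.default_rng(9)
        fit = ols_standardized(rng.standard_normal(10000), rng.standard_normal(10000))
        assert abs(fit.coef) < 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError, match="variance"):
            ols_standardized(np.ones(5), np.arange(5.0))


class TestSAR:
    @pytest.fixture
    def setting(self):
        rng = np.random.default_rng(10)
        n = 60
        lon, lat = rng.uniform(100, 110, n), rng.uniform(20, 30, n)
        W = build_weights(great_circle_distances(lon, lat), style="knn", k=5)
        x = rng.standard_normal(n)
        y = 0.6 * x + rng.normal(0, 0.5, n)
        return y, x, W

    def test_lambda_zero_matches_ols(self, setting):
        y, x, W = setting
        fit0 = sar_error_ml(y, x, W, lam=0.0)
        ols = ols_standardized(y, x)
        assert fit0.coef == pytest.approx(ols.coef, abs=1e-6)

    def test_aic_identity(self, setting):
        y, x, W = setting
        fit = sar_error_ml(y, x, W)
        assert fit.aic == pytest.approx(2 * fit.k_params - 2 * fit.loglik, abs=1e-8)

    def test_lambda_near_zero_for_iid_noise(self):
        rng = np.random.default_rng(11)
        n = 200
        W = build_weights(
            great_circle_distances(rng.uniform(100, 110, n), rng.uniform(20, 30, n)),
            style="knn", k=5,
        )
        x = rng.standard_normal(n)
        y = 0.5 * x + rng.normal(0, 0.5, n)
        fit = sar_error_ml(y, x, W, standardize=False)
        assert abs(fit.lam) < 0.2
        ols = ols_standardized(y, x)
        fit_std = sar_error_ml(y, x, W)
        assert fit_std.coef == pytest.approx(ols.coef, abs=0.02)

    def test_boundary_warning(self):
        # strongly negative autocorrelation pushes lambda to the bound
        rng = np.random.default_rng(12)
        W = rook_lattice_weights(5)
        vals = np.array([(i + j) % 2 for i in range(5) for j in range(5)], dtype=float)
        y = vals + 0.01 * rng.standard_normal(25)
        with pytest.warns(UserWarning, match="boundary"):
            sar_error_ml(y, rng.standard_normal(25), W)


class TestVIF:
    def test_orthogonal_columns(self):
        rng = np.random.default_rng(13)
        # columns orthogonal to each other and to the intercept
        q, _ = np.linalg.qr(np.column_stack([np.ones(30), rng.standard_normal((30, 4))]))
        X = pd.DataFrame(q[:, 1:], columns=list("abcd"))
        out = vif(X)
        np.testing.assert_allclose(out.to_numpy(), 1.0, atol=1e-9)

    def test_duplicate_column_infinite(self):
        rng = np.random.default_rng(14)
        x = rng.standard_normal(20)
        X = pd.DataFrame({"a": x, "b": x, "c": rng.standard_normal(20)})
        out = vif(X)
        assert np.isinf(out["a"]) and np.isinf(out["b"])

    def test_near_collinear_large(self):
        rng = np.random.default_rng(15)
        x = rng.standard_normal(100)
        X = pd.DataFrame({"a": x, "b": x + 0.01 * rng.standard_normal(100)})
        assert (vif(X) > 10).all()


class TestRegressionTable:
    def test_shape_and_columns(self):
        rng = np.random.default_rng(16)
        n = 20
        idx = [f"s{i}" for i in range(n)]
        sites = pd.DataFrame(
            {"longitude": rng.uniform(100, 110, n), "latitude": rng.uniform(20, 30, n),
             "Area": rng.random(n), "Plant.ric": rng.random(n)}, index=idx)
        responses = pd.DataFrame(
            {"SR": rng.random(n), "PD": rng.random(n)}, index=idx)
        W = build_weights(great_circle_distances(sites.longitude, sites.latitude))
        out = regression_table(responses, sites, W)
        assert len(out) == 2 * 4
        for col in ("coef_ols", "r2_ols", "I_ols", "coef_sar", "AIC_sar", "I_sar"):
            assert col in out.columns
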