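"""Standardization, VIF, OLS, lmg, commonality, spatial diagnostics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from basinrates.inference import (
    coordinate_correlation,
    fit_standardized_ols,
    group_commonality,
    lmg_partition,
    morans_i,
    spatial_weights,
    standardize,
    vif_screen,
    vif_table,
)


def rand_design(rng, n=120, p=4, corr=0.5):
    L = np.linalg.cholesky(corr * np.ones((p, p)) + (1 - corr) * np.eye(p))
    X = rng.standard_normal((n, p)) @ L.T
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(p)])


def brute_force_lmg(y, X):
    """Average incremental R^2 over all p! orderings (independent oracle)."""
    names = list(X.columns)
    p = len(names)

    def r2(cols):
        if not cols:
            return 0.0
        A = np.column_stack([np.ones(len(y)), X[list(cols)].to_numpy()])
        resid = y.to_numpy() - A @ np.linalg.lstsq(A, y.to_numpy(), rcond=None)[0]
        tss = ((y - y.mean()) ** 2).sum()
        return 1.0 - (resid @ resid) / tss

    shares = dict.fromkeys(names, 0.0)
    orderings = list(itertools.permutations(names))
    for order in orderings:
        sofar = []
        for nm in order:
            before = r2(sofar)
            sofar.append(nm)
            shares[nm] += r2(sofar) - before
    return {k: v / len(orderings) for k, v in shares.items()}


class TestStandardize:
    def test_hand_arithmetic_sample_sd(self):
        out = standardize(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
        assert np.allclose(out["a"], [-1.0, 0.0, 1.0])  # sample SD of (1,2,3) is 1

    def test_idempotent_on_standardized_input(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"a": rng.standard_normal(50)})
        once = standardize(X)
        twice = standardize(once)
        assert np.allclose(once, twice, atol=1e-12)

    def test_constant_column_named(self):
        with pytest.raises(ValueError, match="a"):
            standardize(pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]}))

    def test_log_column_applied_before_zscore(self):
        X = pd.DataFrame({"area": [1.0, 10.0, 100.0]})
        out = standardize(X, log_cols=("area",))
        assert np.allclose(out["area"], [-1.0, 0.0, 1.0])


class TestVIF:
    def test_orthogonal_all_one(self):
        n = 64
        M = np.column_stack([np.ones(n), np.random.default_rng(1).standard_normal((n, 3))])
        Q, _ = np.linalg.qr(M)
        X = pd.DataFrame(Q[:, 1:], columns=list("abc"))
        v = vif_table(X)
        assert np.allclose(v, 1.0, atol=1e-10)
        reduced, log = vif_screen(X, threshold=5.0)
        assert log.empty and reduced.shape[1] == 3

    def test_constructed_pair_vif_25(self):
        """x2 built so that R^2(x2 ~ x1) = 0.96 exactly -> VIF = 1/(1-0.96)."""
        rng = np.random.default_rng(2)
        n = 200
        x1 = rng.standard_normal(n)
        x1 = (x1 - x1.mean()) / x1.std()
        e = rng.standard_normal(n)
        e = e - e.mean()
        e -= x1 * (e @ x1) / (x1 @ x1)  # orthogonalize
        e /= e.std()
        x2 = np.sqrt(0.96) * x1 + np.sqrt(0.04) * e
        X = pd.DataFrame({"x1": x1, "x2": x2})
        v = vif_table(X)
        assert v["x1"] == pytest.approx(25.0, abs=1e-6)
        assert v["x2"] == pytest.approx(25.0, abs=1e-6)

    def test_near_duplicate_pair_screen_matches_brute_force(self):
        rng = np.random.default_rng(3)
        n = 150
        a = rng.standard_normal(n)
        b = a + 0.1 * rng.standard_normal(n)  # near-duplicate of a
        c = rng.standard_normal(n)
        X = pd.DataFrame({"a": a, "b": b, "c": c})
        reduced, log = vif_screen(X, threshold=5.0)
        assert reduced.shape[1] == 2
        # brute force: the only all-VIF<5 subsets of size 2 keep c plus one of a/b
        ok_subsets = []
        for pair in itertools.combinations(X.columns, 2):
            if vif_table(X[list(pair)]).max() < 5.0:
                ok_subsets.append(set(pair))
        assert set(reduced.columns) in ok_subsets

    def test_collapse_to_single_predictor_errors(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal(80)
        X = pd.DataFrame({"a": a, "b": a + 0.01 * rng.standard_normal(80)})
        with pytest.raises(ValueError):
            vif_screen(X, threshold=5.0)


class TestOLS:
    def test_exact_linear_fit(self):
        rng = np.random.default_rng(5)
        X = standardize(rand_design(rng, n=60, p=3))
        y = 2 * X["x0"] - X["x1"] + 0.5 * X["x2"]
        rep = fit_standardized_ols(y, X)
        assert rep.r_squared == pytest.approx(1.0)
        assert np.allclose(rep.residuals, 0.0, atol=1e-10)

    def test_single_predictor_coefficient_is_pearson_r(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(100)
        y = 0.4 * x + rng.standard_normal(100)
        d = standardize(pd.DataFrame({"x": x, "y": y}))
        rep = fit_standardized_ols(d["y"], d[["x"]])
        r = stats.pearsonr(d["x"], d["y"]).statistic
        assert rep.coefficients.loc["x", "coef"] == pytest.approx(r, abs=1e-12)

    def test_ci_coverage_of_true_coefficient(self):
        """95% t-CIs cover the generating coefficient ~95% of the time."""
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            elev = rng.standard_normal(460)
            y = 0.6 * elev + rng.standard_normal(460)  # R^2 about 0.26
            d = standardize(pd.DataFrame({"elev": elev, "y": y}))
            rep = fit_standardized_ols(d["y"], d[["elev"]])
            beta_true = 0.6 * elev.std() / y.std()
            lo, hi = rep.coefficients.loc["elev", ["ci_low", "ci_high"]]
            hits += lo <= beta_true <= hi
        assert 0.90 <= hits / n_rep <= 0.99


class TestLmg:
    def test_single_predictor_share_is_r2(self):
        rng = np.random.default_rng(7)
        X = rand_design(rng, p=1)
        y = X["x0"] * 0.5 + rng.standard_normal(len(X))
        out = lmg_partition(pd.Series(y), X)
        assert out["share"].iloc[0] == pytest.approx(out.attrs["r_squared"], abs=1e-12)

    def test_orthogonal_predictors_marginal_r2(self):
        rng = np.random.default_rng(8)
        n = 200
        M = np.column_stack([np.ones(n), rng.standard_normal((n, 3))])
        Q, _ = np.linalg.qr(M)  # columns 1..3 are mean-zero and orthogonal
        X = pd.DataFrame(Q[:, 1:] * np.sqrt(n - 1), columns=list("abc"))
        y = pd.Series(X["a"] + 0.5 * X["b"] + rng.standard_normal(n))
        out = lmg_partition(y, X)
        for c in X.columns:
            r2 = stats.pearsonr(X[c], y).statistic ** 2
            assert out.loc[c, "share"] == pytest.approx(r2, abs=1e-10)

    def test_matches_all_orderings_brute_force(self):
        rng = np.random.default_rng(9)
        X = rand_design(rng, n=80, p=4, corr=0.6)
        y = pd.Series(
            X.to_numpy() @ np.array([1.0, -0.5, 0.2, 0.0]) + rng.standard_normal(80)
        )
        mine = lmg_partition(y, X)["share"]
        brute = brute_force_lmg(y, X)
        for c in X.columns:
            assert mine[c] == pytest.approx(brute[c], abs=1e-10)

    def test_shares_nonneg_sum_to_r2(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            X = rand_design(rng, n=60, p=5, corr=0.4)
            y = pd.Series(rng.standard_normal(60))
            out = lmg_partition(y, X)
            assert (out["share"] >= -1e-12).all()
            assert out["share"].sum() == pytest.approx(out.attrs["r_squared"], abs=1e-8)

    def test_p_cap(self):
        rng = np.random.default_rng(11)
        X = rand_design(rng, n=40, p=4)
        with pytest.raises(ValueError, match="cap"):
            lmg_partition(pd.Series(rng.standard_normal(40)), X, max_predictors=3)


class TestCommonality:
    def test_orthogonal_groups_no_shared(self):
        rng = np.random.default_rng(12)
        n = 150
        M = np.column_stack([np.ones(n), rng.standard_normal((n, 4))])
        Q, _ = np.linalg.qr(M)  # mean-zero orthogonal predictors
        X = pd.DataFrame(Q[:, 1:] * np.sqrt(n - 1), columns=list("abcd"))
        groups = {"a": "G1", "b": "G1", "c": "G2", "d": "G2"}
        y = pd.Series(X["a"] + X["c"] + rng.standard_normal(n))
        out = group_commonality(y, X, groups)
        shared = out[~out["unique"]]["component"]
        assert np.all(np.abs(shared) < 1e-10)
        g1 = fit_standardized_ols(
            standardize(y.to_frame("y"))["y"], standardize(X[["a", "b"]])
        ).r_squared
        assert out.loc["G1", "component"] == pytest.approx(g1, abs=1e-8)

    def test_duplicated_group_fully_shared(self):
        rng = np.random.default_rng(13)
        a = rng.standard_normal(100)
        X = pd.DataFrame({"a": a, "b": a.copy() * 2.0})
        y = pd.Series(a + rng.standard_normal(100))
        out = group_commonality(y, X, {"a": "G1", "b": "G2"})
        assert abs(out.loc["G1", "component"]) < 1e-10
        assert abs(out.loc["G2", "component"]) < 1e-10
        assert out.loc["G1 & G2", "component"] == pytest.approx(
            out.attrs["r_squared"], abs=1e-10
        )

    def test_three_group_inclusion_exclusion_brute_force(self):
        rng = np.random.default_rng(14)
        X = rand_design(rng, n=100, p=6, corr=0.5)
        groups = {"x0": "A", "x1": "A", "x2": "B", "x3": "B", "x4": "C", "x5": "C"}
        y = pd.Series(X.to_numpy() @ rng.normal(0, 0.5, 6) + rng.standard_normal(100))
        out = group_commonality(y, X, groups)

        # independent oracle: fit the 7 union R^2s, invert by hand
        def r2(cols):
            A = np.column_stack([np.ones(100), X[cols].to_numpy()])
            res = y.to_numpy() - A @ np.linalg.lstsq(A, y.to_numpy(), rcond=None)[0]
            return 1 - (res @ res) / ((y - y.mean()) ** 2).sum()

        mem = {"A": ["x0", "x1"], "B": ["x2", "x3"], "C": ["x4", "x5"]}
        R = {}
        for k in range(1, 4):
            for S in itertools.combinations("ABC", k):
                R[frozenset(S)] = r2([c for g in S for c in mem[g]])
        full = R[frozenset("ABC")]

        def F(T):
            if not T:
                return 0.0
            rest = frozenset("ABC") - frozenset(T)
            return full - (R[rest] if rest else 0.0)

        for k in range(1, 4):
            for S in itertools.combinations("ABC", k):
                expect = sum(
                    (-1) ** (len(S) - t) * F(T)
                    for t in range(len(S) + 1)
                    for T in itertools.combinations(S, t)
                )
                assert out.loc[" & ".join(S), "component"] == pytest.approx(
                    expect, abs=1e-10
                )
        assert out["component"].sum() == pytest.approx(full, abs=1e-8)

    def test_unlabeled_predictor_errors(self):
        rng = np.random.default_rng(15)
        X = rand_design(rng, p=2)
        y = pd.Series(rng.standard_normal(len(X)))
        with pytest.raises(ValueError, match="x1"):
            group_commonality(y, X, {"x0": "A"})


class TestSpatialWeights:
    def test_knn_exact_k_nonzeros(self):
        rng = np.random.default_rng(16)
        pts = rng.random((30, 2))
        W = spatial_weights(pts, "knn", k=4, row_standardize=False)
        assert (np.count_nonzero(W, axis=1) == 4).all()
        assert np.all(np.diag(W) == 0)

    def test_knn_tie_broken_by_index(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        W = spatial_weights(pts, "knn", k=1, row_standardize=False)
        # middle point is equidistant to both ends; links to the lower index
        assert W[1, 0] == 1.0 and W[1, 2] == 0.0

    def test_lattice_band_is_rook(self):
        pts = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        W = spatial_weights(pts, "distance_band", band=1.0, row_standardize=False)
        assert np.allclose(W.sum(axis=1), 2.0)
        assert np.allclose(W, W.T)

    def test_row_standardized_rows_sum_one(self):
        rng = np.random.default_rng(17)
        W = spatial_weights(rng.random((20, 2)), "knn", k=5, row_standardize=True)
        assert np.allclose(W.sum(axis=1), 1.0)

    def test_errors(self):
        rng = np.random.default_rng(18)
        pts = rng.random((10, 2))
        with pytest.raises(ValueError):
            spatial_weights(pts, "knn", k=10)
        with pytest.raises(ValueError):
            spatial_weights(pts * 100, "distance_band", band=0.01)


class TestMoran:
    def test_checkerboard_strongly_negative(self):
        n = 8
        xs, ys = np.meshgrid(np.arange(n), np.arange(n))
        pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
        W = spatial_weights(pts, "distance_band", band=1.0)
        z = ((xs + ys) % 2 * 2 - 1).ravel().astype(float)
        res = morans_i(z, W, n_perm=199, seed=0)
        assert res.I < -0.5
        assert res.expected == pytest.approx(-1 / 63)

    def test_smooth_gradient_positive_significant(self):
        rng = np.random.default_rng(19)
        pts = rng.random((100, 2))
        W = spatial_weights(pts, "knn", k=8)
        z = pts[:, 0] + 0.1 * rng.standard_normal(100)
        res = morans_i(z, W, n_perm=999, seed=1)
        assert res.I > 0
        assert res.p_value < 0.01

    def test_null_mean_matches_expectation(self):
        rng = np.random.default_rng(20)
        pts = rng.random((50, 2))
        W = spatial_weights(pts, "knn", k=8)
        Is = []
        for _ in range(150):
            Is.append(morans_i(rng.standard_normal(50), W, n_perm=0 + 1, seed=0).I)
        se = np.std(Is) / np.sqrt(len(Is))
        assert abs(np.mean(Is) - (-1 / 49)) < 4 * se

    def test_constant_residuals_error(self):
        W = spatial_weights(np.random.default_rng(21).random((10, 2)), "knn", k=3)
        with pytest.raises(ValueError):
            morans_i(np.ones(10), W)


class TestCoordinateCorrelation:
    def test_values_equal_to_y_coordinate(self):
        rng = np.random.default_rng(22)
        coords = pd.DataFrame(rng.random((30, 2)), columns=["x", "y"])
        out = coordinate_correlation(pd.Series(coords["y"].to_numpy()), coords)
        assert out.loc["y", "r"] == pytest.approx(1.0)

    def test_hand_worked_five_points(self):
        coords = pd.DataFrame({"x": [0, 1, 2, 3, 4], "y": [1, 0, 2, 1, 3]}, dtype=float)
        vals = pd.Series([2.0, 2.5, 1.0, 3.0, 2.2])
        out = coordinate_correlation(vals, coords)
        for ax in ("x", "y"):
            c = coords[ax].to_numpy()
            v = vals.to_numpy()
            r = ((c - c.mean()) * (v - v.mean())).sum() / np.sqrt(
                ((c - c.mean()) ** 2).sum() * ((v - v.mean()) ** 2).sum()
            )
            assert out.loc[ax, "r"] == pytest.approx(r, abs=1e-12)

    def test_independent_values_mean_r_near_zero(self):
        rng = np.random.default_rng(23)
        coords = pd.DataFrame(rng.random((60, 2)), columns=["x", "y"])
        rs = []
        for _ in range(300):
            rs.append(
                coordinate_correlation(pd.Series(rng.standard_normal(60)), coords).loc[
                    "x", "r"
                ]
            )
        assert abs(np.mean(rs)) < 0.03
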