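"""OLS, class equations, rank transforms, floor-exponential fits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from transelect import datasets
from transelect.regression_suite import (
    derive_class_equations,
    fit_floor_exponential,
    ols_fit,
    rank_regression,
    rank_transform,
)


class TestOLS:
    def test_exact_line(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4, 5], "y": [2.0, 4, 6, 8, 10]})
        res = ols_fit(df, "y", ["x"])
        assert res["x"] == pytest.approx(2.0)
        assert res["Intercept"] == pytest.approx(0.0, abs=1e-10)
        assert res.r_squared == pytest.approx(1.0)

    def test_published_aug_model(self):
        res = ols_fit(datasets.load_aug_percent(), "AUG%",
                      ["RankGT", "GC%", "GE"])
        assert res["RankGT"] == pytest.approx(-2.53863, abs=5e-6)
        assert res["GE"] == pytest.approx(-9.17674, abs=5e-6)

    def test_published_mfe_interaction_model(self):
        res = ols_fit(datasets.load_mean_mfe(), "MeanMFE",
                      ["RankGT", "GC%", "GE"], interactions=[("GC%", "GE")])
        assert res["GC%*GE"] == pytest.approx(-0.10972, abs=5e-5)
        assert res.r_squared == pytest.approx(0.982, abs=5e-4)

    def test_singular_design_rejected(self):
        df = pd.DataFrame({"y": [1.0, 2, 3, 4], "x": [1.0, 2, 3, 4],
                           "z": [2.0, 4, 6, 8]})
        with pytest.raises(ValueError, match="singular"):
            ols_fit(df, "y", ["x", "z"])

    def test_residual_orthogonality_and_r2_identity(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"x1": rng.normal(size=40),
                           "x2": rng.normal(size=40)})
        df["y"] = 1 + 2 * df.x1 - df.x2 + rng.normal(size=40)
        res = ols_fit(df, "y", ["x1", "x2"])
        X = np.column_stack([np.ones(40), df.x1, df.x2])
        fitted = X @ res.coef
        resid = df.y - fitted
        for j in range(3):
            assert abs(resid @ X[:, j]) < 1e-8
        r = np.corrcoef(fitted, df.y)[0, 1]
        assert res.r_squared == pytest.approx(r ** 2, abs=1e-10)

    def test_one_tailed_p_is_half(self):
        res = ols_fit(datasets.load_mean_mfe(), "MeanMFE",
                      ["RankGT", "GC%", "GE"], interactions=[("GC%", "GE")])
        assert res.one_tailed_p("RankGT") == pytest.approx(
            res.p[res.terms.index("RankGT")] / 2)


class TestClassEquations:
    def test_published_aug_equations(self):
        res = ols_fit(datasets.load_aug_percent(), "AUG%",
                      ["RankGT", "GC%", "GE"])
        eqs = derive_class_equations(res)
        assert eqs["HEG"]["Intercept"] == pytest.approx(125.86, abs=5e-3)
        assert eqs["REST"]["Intercept"] == pytest.approx(116.68, abs=5e-3)
        assert eqs["HEG"]["RankGT"] == pytest.approx(-2.54, abs=5e-3)
        assert eqs["HEG"]["GC%"] == pytest.approx(-0.52, abs=5e-3)

    def test_published_mfe_equations_fold_interaction_into_slope(self):
        res = ols_fit(datasets.load_mean_mfe(), "MeanMFE",
                      ["RankGT", "GC%", "GE"], interactions=[("GC%", "GE")])
        eqs = derive_class_equations(res)
        assert eqs["REST"]["GC%"] == pytest.approx(-0.21009, abs=5e-4)
        assert eqs["HEG"]["GC%"] == pytest.approx(-0.10038, abs=5e-4)

    def test_zero_ge_coefficient_gives_identical_classes(self):
        df = pd.DataFrame({"y": [1.0, 2, 3, 4, 5, 6],
                           "x": [1.0, 2, 3, 1, 2, 3],
                           "GE": ["HEG"] * 3 + ["REST"] * 3})
        res = ols_fit(df, "y", ["x", "GE"])
        res.coef[res.terms.index("GE")] = 0.0
        eqs = derive_class_equations(res)
        assert eqs["HEG"] == pytest.approx(eqs["REST"])

    def test_missing_ge_term_errors(self):
        df = pd.DataFrame({"y": [1.0, 2, 3, 4], "x": [1.0, 2, 4, 8]})
        with pytest.raises(ValueError):
            derive_class_equations(ols_fit(df, "y", ["x"]))


class TestRanks:
    def test_midranks_with_ties(self):
        assert rank_transform([10, 20, 20, 30]).tolist() == [1, 2.5, 2.5, 4]

    def test_published_dite_ranks(self):
        table = datasets.load_dite()
        assert rank_transform(table["DITE"]).tolist() == \
            table["RankDITE"].tolist()

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=60))
    def test_matches_sort_based_oracle(self, values):
        def oracle(vals):
            order = sorted(range(len(vals)), key=lambda i: vals[i])
            ranks = [0.0] * len(vals)
            i = 0
            while i < len(order):
                j = i
                while j + 1 < len(order) and vals[order[j + 1]] == vals[order[i]]:
                    j += 1
                mid = (i + j) / 2 + 1
                for k in range(i, j + 1):
                    ranks[order[k]] = mid
                i = j + 1
            return ranks

        assert rank_transform(values).tolist() == oracle(values)

    def test_rank_regression_published_r2(self):
        table = datasets.load_dite()
        res = rank_regression(rank_transform(table["DITE"]), table["RankGT"])
        assert res.r_squared == pytest.approx(0.8784, abs=5e-5)

    def test_perfect_concordance(self):
        res = rank_regression([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.r_squared == pytest.approx(1.0)

    def test_nac_on_dite_ranks_negative_slope(self):
        nac = datasets.load_n_ac()
        dite = datasets.load_dite()
        res = rank_regression(rank_transform(nac["N_AC"]),
                              rank_transform(dite["DITE"]))
        assert res["x"] < 0

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        base = rank_regression(rank_transform(y), rank_transform(x))
        warped = rank_regression(rank_transform(np.exp(y)),
                                 rank_transform(x ** 3))
        assert warped.r_squared == pytest.approx(base.r_squared, abs=1e-12)


class TestFloorExponential:
    def test_noiseless_recovery_fixed_floor(self):
        x = np.arange(1, 10, dtype=float)
        y = 1 + 50 * np.exp(-0.5 * x)
        fit = fit_floor_exponential(x, y, floor=1.0)
        assert fit.a == pytest.approx(50.0, abs=1e-6)
        assert fit.b == pytest.approx(0.5, abs=1e-6)
        assert fit.c == 1.0 and fit.floor_fixed

    def test_published_trna_floor_rounds_to_thirty(self):
        table = datasets.load_machinery_counts()
        fit = fit_floor_exponential(table["RankGT"], table["N_tRNA"])
        assert round(fit.c) == 30
        assert fit.converged

    def test_noisy_replicates_recover_floor(self):
        rng = np.random.default_rng(13)
        x = np.arange(1, 10, dtype=float)
        cs = []
        for _ in range(100):
            y = 30 + 125 * np.exp(-0.24 * x) + rng.normal(0, 2, size=9)
            cs.append(fit_floor_exponential(x, y).c)
        assert 25 <= np.median(cs) <= 35

    def test_degenerate_flat_data_flagged(self):
        fit = fit_floor_exponential([1.0, 2, 3, 4], [5.0, 5, 5, 5])
        assert fit.degenerate

    def test_multi_start_never_worse_than_grid(self):
        """Best RSS is at least as good as any single-start local fit."""
        from scipy import optimize

        from transelect.regression_suite import B_START_GRID

        table = datasets.load_machinery_counts()
        x = table["RankGT"].to_numpy(dtype=float)
        y = table["N_tRNA"].to_numpy(dtype=float)
        fit = fit_floor_exponential(x, y)
        for b0 in B_START_GRID:
            res = optimize.least_squares(
                lambda p: p[0] + p[1] * np.exp(-p[2] * x) - y,
                [y.min(), y.max() - y.min(), b0], max_nfev=10000)
            assert fit.rss <= 2 * res.cost + 1e-9

    def test_nonpositive_x_rejected(self):
        with pytest.raises(ValueError):
            fit_floor_exponential([0.0, 1, 2, 3], [3.0, 2, 1, 1])
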