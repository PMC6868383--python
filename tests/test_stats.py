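"""Correlation and regression layer against closed forms and matrix oracles."""

import numpy as np
import pandas as pd
import pytest

from triacyl import (
    build_system_table,
    correlation_screen,
    generate_system_table,
    ols,
    pearson,
    pearson_pvalue,
    pre_test,
)


def normal_equations(x, y):
    """Independent oracle: solve (X'X) b = X'y with an explicit intercept."""
    design = np.column_stack([np.ones(len(y)), x])
    beta = np.linalg.solve(design.T @ design, design.T @ y)
    rss = float(((y - design @ beta) ** 2).sum())
    return beta, rss


class TestPearson:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        res = pearson(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "r,n,expected_p,tol",
        [
            # printed significance triples for the exposure/preference and
            # half-life correlations (two-sided t-test)
            (0.71, 29, 0.00002, 1.5e-5),
            (-0.87, 29, 0.00001, 1e-5),  # reported as P < 0.00001
            (-0.90, 5, 0.03739, 5e-4),
            (-0.94, 7, 0.00164, 5e-5),
            (0.008, 29, 0.97, 5e-3),
        ],
    )
    def test_printed_significance_triples(self, r, n, expected_p, tol):
        _, p = pearson_pvalue(r, n)
        if expected_p == 0.00001:  # an upper bound in the source
            assert p < expected_p
        else:
            assert p == pytest.approx(expected_p, abs=tol)

    def test_t_statistic_identity(self):
        r, n = 0.5, 20
        t, _ = pearson_pvalue(r, n)
        assert t == pytest.approx(r * np.sqrt(n - 2) / np.sqrt(1 - r**2))

    def test_affine_invariance_of_p_values(self, rng):
        x = rng.normal(size=30)
        y = 0.4 * x + rng.normal(size=30)
        base = pearson(x, y)
        scaled = pearson(3.0 * x - 7.0, -2.0 * y + 11.0)
        assert scaled.p_value == pytest.approx(base.p_value, rel=1e-10)
        assert scaled.r == pytest.approx(-base.r, abs=1e-12)

    def test_constant_vector_is_an_error(self):
        with pytest.raises(ValueError, match="constant"):
            pearson(np.ones(5), np.arange(5.0))


class TestOLS:
    def test_exact_linear_relationship(self, rng):
        x = rng.uniform(size=(12, 3))
        y = 1.0 + x @ np.array([2.0, -1.0, 0.5])
        fit = ols(x, y)
        assert fit.r_squared == pytest.approx(1.0)
        assert np.abs(fit.residuals).max() < 1e-10
        assert fit.coefficients == pytest.approx([1.0, 2.0, -1.0, 0.5], abs=1e-10)

    def test_null_model_has_small_r_squared(self, rng):
        x = rng.uniform(size=(400, 3))
        y = rng.normal(size=400)
        fit = ols(x, y)
        assert fit.r_squared < 0.05
        assert fit.f_p_value > 0.001

    def test_matches_normal_equations_oracle_on_designed_dataset(self, rng):
        x = rng.uniform(size=(8, 2))
        y = rng.normal(size=8)
        fit = ols(x, y)
        beta, rss = normal_equations(x, y)
        assert fit.coefficients == pytest.approx(beta, rel=1e-9)
        assert fit.rss == pytest.approx(rss, rel=1e-9)

    def test_single_predictor_f_test_equals_pearson_t_test(self, rng):
        x = rng.uniform(size=25)
        y = 0.8 * x + rng.normal(scale=0.3, size=25)
        fit = ols(x, y)
        corr = pearson(x, y)
        assert fit.r_squared == pytest.approx(corr.r**2, abs=1e-10)
        assert fit.f_p_value == pytest.approx(corr.p_value, rel=1e-8)

    def test_rank_deficiency_names_collinear_columns(self, rng):
        x = rng.uniform(size=(10, 2))
        x = np.column_stack([x, x[:, 0]])  # duplicate column 0 as column 2
        with pytest.raises(ValueError, match=r"\(0, 2\)"):
            ols(x, np.arange(10.0))


class TestPRE:
    def test_orthogonal_predictor_contributes_nothing(self, rng):
        n = 200
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)  # independent of y and x1
        y = 2.0 * x1 + rng.normal(scale=0.1, size=n)
        # null PRE is O(F/(n-3)): a few percent at most for n = 200
        assert pre_test(np.column_stack([x1, x2]), y, 1) < 0.03

    def test_sole_informative_predictor_dominates(self, rng):
        n = 60
        xj = rng.uniform(size=n)
        noise = rng.uniform(size=(n, 2))
        y = xj.copy()  # exactly determined by predictor 1
        pre = pre_test(np.column_stack([noise[:, 0], xj, noise[:, 1]]), y, 1)
        assert pre > 0.999999

    def test_matches_double_fit_oracle(self, rng):
        x = rng.uniform(size=(15, 4))
        y = rng.normal(size=15)
        for j in range(4):
            _, rss_full = normal_equations(x, y)
            _, rss_red = normal_equations(np.delete(x, j, axis=1), y)
            oracle = (rss_red - rss_full) / rss_red
            assert pre_test(x, y, j) == pytest.approx(oracle, rel=1e-8)

    def test_relates_to_partial_f_statistic(self, rng):
        """PRE and the partial F statistic describe the same nested
        comparison: F = PRE * (n - k - 1) / (1 - PRE) for one added term."""
        n, k = 40, 3
        x = rng.uniform(size=(n, k))
        y = x @ np.array([1.0, -0.5, 0.2]) + rng.normal(scale=0.3, size=n)
        j = 1
        pre = pre_test(x, y, j)
        _, rss_full = normal_equations(x, y)
        _, rss_red = normal_equations(np.delete(x, j, axis=1), y)
        f_partial = (rss_red - rss_full) / (rss_full / (n - k - 1))
        assert f_partial == pytest.approx(pre * (n - k - 1) / (1 - pre), rel=1e-8)

    def test_single_predictor_pre_equals_r_squared(self, rng):
        x = rng.uniform(size=30)
        y = 0.5 * x + rng.normal(scale=0.2, size=30)
        assert pre_test(x, y, 0) == pytest.approx(ols(x, y).r_squared, rel=1e-10)


class TestCorrelationScreen:
    def make_table(self, rng, n=24):
        table, _ = generate_system_table(
            n, planted={"stack23": 0.8}, noise_sigma=0.02, seed=int(rng.integers(2**31))
        )
        return table

    def test_planted_slope_sign_recovered_per_stratum(self, rng):
        table = self.make_table(rng)
        screen = correlation_screen(
            table, "mean_relative_exposure", ["stack23", "sc_b1"], strata="attachment"
        )
        planted = screen[(screen.predictor == "stack23") & screen.computable]
        assert (planted.r > 0).all()

    def test_small_stratum_flagged_not_computable(self, rng):
        table = self.make_table(rng, n=5)
        table.loc[table.index[:2], "attachment"] = "tiny"
        table.loc[table.index[2:], "attachment"] = "rest"
        screen = correlation_screen(
            table, "mean_relative_exposure", ["stack23"], strata="attachment"
        )
        tiny = screen[screen.stratum == "tiny"].iloc[0]
        assert not tiny.computable and tiny.n == 2

    def test_row_permutation_invariance(self, rng):
        table = self.make_table(rng)
        screen1 = correlation_screen(table, "mean_relative_exposure", ["stack23"])
        shuffled = table.sample(frac=1.0, random_state=0).reset_index(drop=True)
        screen2 = correlation_screen(shuffled, "mean_relative_exposure", ["stack23"])
        assert screen1.r.iloc[0] == pytest.approx(screen2.r.iloc[0], abs=1e-12)

    def test_unknown_column_errors(self, rng):
        with pytest.raises(KeyError):
            correlation_screen(self.make_table(rng), "nope", ["stack23"])

    def test_nan_rows_dropped_listwise(self, rng):
        table = self.make_table(rng)
        table.loc[table.index[:3], "stack23"] = np.nan
        screen = correlation_screen(table, "mean_relative_exposure", ["stack23"])
        assert screen.n.iloc[0] == len(table) - 3


class TestSystemTable:
    def test_duplicate_keys_rejected(self):
        row = dict(
            triplet="CCA", amino_acid="ALA", attachment="2p", chirality="L", sc_b2=0.5
        )
        with pytest.raises(ValueError, match="duplicated"):
            build_system_table([row, dict(row)])

    def test_slope_recovery_without_noise(self):
        table, truth = generate_system_table(
            30, planted={"sc_b2": -0.5}, noise_sigma=0.0, seed=4
        )
        from triacyl.stats import PREDICTOR_ORDER

        fit = ols(table[list(PREDICTOR_ORDER)].to_numpy(), table["mean_relative_exposure"].to_numpy())
        assert fit.slopes[PREDICTOR_ORDER.index("sc_b2")] == pytest.approx(-0.5, abs=1e-10)
        assert np.abs(np.delete(fit.slopes, PREDICTOR_ORDER.index("sc_b2"))).max() < 1e-10
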