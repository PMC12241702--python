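"""Inference layer: ANOVA decompositions, rank correlations, power."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy.stats import rankdata

from metaflex.inference import (
    anova_power,
    anova_sensitivity,
    compare_correlations,
    fisher_z,
    mixed_anova,
    partial_spearman,
    spearman,
    two_way_anova,
)


class TestTwoWayAnova:
    def test_balanced_toy_matches_hand_decomposition(self):
        # 2x2, n=3 per cell; classical balanced sums of squares computed
        # explicitly here, independent of the model-matrix route
        cells = {
            ("a1", "b1"): [1.0, 2.0, 3.0],
            ("a1", "b2"): [2.0, 3.0, 4.0],
            ("a2", "b1"): [5.0, 6.0, 7.0],
            ("a2", "b2"): [4.0, 5.0, 6.0],
        }
        y, A, B = [], [], []
        for (a, b), vals in cells.items():
            y += vals
            A += [a] * 3
            B += [b] * 3
        y = np.array(y)
        grand = y.mean()
        mean_a = {a: y[np.array(A) == a].mean() for a in ("a1", "a2")}
        mean_b = {b: y[np.array(B) == b].mean() for b in ("b1", "b2")}
        ss_a = sum(6 * (mean_a[a] - grand) ** 2 for a in mean_a)
        ss_b = sum(6 * (mean_b[b] - grand) ** 2 for b in mean_b)
        cell_mean = {k: np.mean(v) for k, v in cells.items()}
        ss_cells = sum(3 * (m - grand) ** 2 for m in cell_mean.values())
        ss_ab = ss_cells - ss_a - ss_b
        ss_err = sum(
            (v - cell_mean[k]) ** 2 for k, vals in cells.items() for v in vals
        )
        table = two_way_anova(y, A, B).set_index("effect")
        assert table.loc["group", "F"] == pytest.approx(ss_a / (ss_err / 8))
        assert table.loc["region", "F"] == pytest.approx(ss_b / (ss_err / 8))
        assert table.loc["group:region", "F"] == pytest.approx(ss_ab / (ss_err / 8))
        assert table.loc["group", "partial_eta_sq"] == pytest.approx(
            ss_a / (ss_a + ss_err)
        )
        assert (table["df_error"] == 8).all()

    def test_constant_response_gives_zero_f(self):
        table = two_way_anova([3.0] * 12, ["a", "b"] * 6, ["x"] * 6 + ["y"] * 6)
        assert (table["F"] == 0).all()
        assert (table["p"] == 1).all()

    def test_partial_eta_identity(self, rng):
        y = rng.normal(size=40)
        table = two_way_anova(
            y, rng.choice(["a", "b"], 40), rng.choice(["x", "y"], 40)
        )
        for r in table.itertuples():
            expected = r.F * r.df_effect / (r.F * r.df_effect + r.df_error)
            assert r.partial_eta_sq == pytest.approx(expected, rel=1e-9)

    def test_matches_pingouin_type3_on_unbalanced_data(self, rng):
        df = pd.DataFrame(
            {
                "y": rng.normal(size=50),
                "A": rng.choice(["asd", "td"], 50),
                "B": rng.choice(["es", "pt"], 50),
            }
        )
        mine = two_way_anova(df["y"], df["A"], df["B"]).set_index("effect")
        ref = pg.anova(data=df, dv="y", between=["A", "B"], ss_type=3).set_index(
            "Source"
        )
        assert mine.loc["group", "F"] == pytest.approx(ref.loc["A", "F"], rel=1e-6)
        assert mine.loc["region", "F"] == pytest.approx(ref.loc["B", "F"], rel=1e-6)
        assert mine.loc["group:region", "F"] == pytest.approx(
            ref.loc["A * B", "F"], rel=1e-6
        )
        assert mine.loc["group", "partial_eta_sq"] == pytest.approx(
            ref.loc["A", "np2"], abs=1e-6
        )

    def test_empty_cell_is_an_error(self):
        with pytest.raises(ValueError, match="cell"):
            two_way_anova([1, 2, 3, 4], ["a", "a", "b", "b"], ["x", "x", "x", "x"])

    def test_covariate_effect_is_reported(self, rng):
        x = rng.normal(size=40)
        y = 2 * x + rng.normal(size=40)
        table = two_way_anova(
            y, rng.choice(["a", "b"], 40), rng.choice(["x", "y"], 40), covariate=x
        )
        cov = table.set_index("effect").loc["covariate"]
        assert cov["p"] < 0.001


class TestMixedAnova:
    @staticmethod
    def _toy(rng, accuracy_gap=0.8, n=24):
        groups = np.repeat(["asd", "td"], n // 2)
        regions = np.tile(np.repeat(["A", "B"], n // 4), 2)
        base = rng.normal(3.0, 0.3, size=n)
        return pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(n)],
                "group": groups,
                "region": regions,
                "conf_correct": base + accuracy_gap + rng.normal(0, 0.2, n),
                "conf_incorrect": base + rng.normal(0, 0.2, n),
            }
        )

    def test_identical_within_levels_give_zero_accuracy_effect(self, rng):
        df = self._toy(rng, accuracy_gap=0.0)
        df["conf_incorrect"] = df["conf_correct"]
        table = mixed_anova(df).set_index("effect")
        assert table.loc["accuracy", "F"] == pytest.approx(0.0, abs=1e-20)

    def test_confidence_higher_on_correct_is_detected(self, rng):
        table = mixed_anova(self._toy(rng)).set_index("effect")
        assert table.loc["accuracy", "p"] < 0.001
        assert table.loc["accuracy", "partial_eta_sq"] > 0.3
        assert table.loc["accuracy", "df_error"] == 20  # 24 subjects - 4 cells

    def test_matches_pingouin_single_between_factor(self, rng):
        df = self._toy(rng)
        df["region"] = "A"  # reduce to one between factor for the oracle
        long = df.melt(
            id_vars=["subject_id", "group"],
            value_vars=["conf_correct", "conf_incorrect"],
            var_name="accuracy",
            value_name="conf",
        )
        ref = pg.mixed_anova(
            data=long, dv="conf", within="accuracy", subject="subject_id",
            between="group",
        ).set_index("Source")
        mine = mixed_anova(
            df, between_cols=("group", "group"), within_name="accuracy"
        ).set_index("effect")
        assert mine.loc["accuracy", "F"] == pytest.approx(
            ref.loc["accuracy", "F"], rel=1e-6
        )
        assert mine.loc["group", "F"] == pytest.approx(
            ref.loc["group", "F"], rel=1e-6
        )
        assert mine.loc["accuracy:group", "F"] == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-6
        )

    def test_subject_missing_a_level_is_excluded_with_warning(self, rng):
        df = self._toy(rng)
        df.loc[0, "conf_incorrect"] = np.nan
        with pytest.warns(UserWarning, match="excluded"):
            table = mixed_anova(df).set_index("effect")
        assert table.loc["accuracy", "df_error"] == 19


class TestSpearman:
    def test_perfect_monotone_pairs(self):
        res = spearman([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert res.rho == pytest.approx(1.0, abs=1e-12)
        res = spearman([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert res.rho == pytest.approx(-1.0, abs=1e-12)

    def test_ten_point_fixture_matches_rank_formula(self):
        x = [3.1, 1.2, 5.5, 2.2, 4.0, 6.6, 0.5, 7.7, 2.9, 4.4]
        y = [2.0, 1.0, 4.1, 3.3, 2.5, 6.0, 1.5, 5.5, 4.8, 3.9]
        rx, ry = rankdata(x), rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]  # Pearson on ranks
        res = spearman(x, y)
        assert res.rho == pytest.approx(expected, abs=1e-12)
        assert res.z == pytest.approx(np.arctanh(expected), abs=1e-12)

    def test_constant_vector_is_an_error(self):
        with pytest.raises(ValueError, match="zero rank variance"):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_invariant_under_monotone_transforms(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        base = spearman(x, y).rho
        assert spearman(np.exp(x), y).rho == pytest.approx(base, abs=1e-12)
        assert spearman(x, y**3).rho == pytest.approx(base, abs=1e-12)

    def test_permutation_p_is_close_to_t_approximation(self, rng):
        x = rng.normal(size=25)
        y = x + rng.normal(size=25)
        t_p = spearman(x, y).p
        perm_p = spearman(x, y, method="permutation", seed=0).p
        assert perm_p == pytest.approx(t_p, abs=0.02)


class TestPartialSpearman:
    def test_independent_covariate_changes_little(self, rng):
        n = 10_000
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        c = rng.normal(size=n)
        simple = spearman(x, y).rho
        partial = partial_spearman(x, y, c).rho
        assert abs(partial - simple) < 0.05

    def test_six_point_fixture_matches_pingouin(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y = [2.0, 1.0, 4.0, 3.0, 6.0, 5.0]
        c = [1.5, 1.0, 2.0, 3.5, 3.0, 4.0]
        res = partial_spearman(x, y, c)
        df = pd.DataFrame({"x": x, "y": y, "c": c})
        ref = pg.partial_corr(df, x="x", y="y", covar="c", method="spearman")
        assert res.rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-9)

    def test_covariate_equal_to_input_is_an_error(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        with pytest.raises(ValueError, match="degenerate"):
            partial_spearman(x, [2, 1, 4, 3, 5], x)


class TestFisherAndComparison:
    def test_worked_transform_values(self):
        assert fisher_z(0.384) == pytest.approx(0.405, abs=5e-4)
        assert fisher_z(-0.583) == pytest.approx(-0.667, abs=5e-4)
        assert fisher_z(0.0) == 0.0

    def test_transform_inverts_tanh(self):
        for z in np.linspace(-3.9, 3.9, 41):
            assert fisher_z(np.tanh(z)) == pytest.approx(z, abs=1e-12)

    def test_out_of_domain_is_an_error(self):
        with pytest.raises(ValueError):
            fisher_z(1.0)

    def test_worked_two_sample_comparisons(self):
        res = compare_correlations(0.384, 33, 0.033, 33)
        assert res.z_observed == pytest.approx(1.44, abs=5e-3)
        assert res.p == pytest.approx(0.075, abs=5e-4)
        res = compare_correlations(0.463, 33, 0.36, 33)
        assert res.z_observed == pytest.approx(0.481, abs=5e-4)
        assert res.p == pytest.approx(0.315, abs=5e-4)

    def test_antisymmetry_and_null(self):
        a = compare_correlations(0.5, 30, 0.2, 40)
        b = compare_correlations(0.2, 40, 0.5, 30)
        assert a.z_observed == pytest.approx(-b.z_observed, abs=1e-12)
        assert a.p == b.p
        assert compare_correlations(0.3, 20, 0.3, 20).z_observed == 0.0

    def test_insufficient_n_is_an_error(self):
        with pytest.raises(ValueError):
            compare_correlations(0.5, 3, 0.2, 30)


class TestSensitivity:
    def test_study_design_minimal_effect(self):
        # 66 subjects, 2x2 design, alpha .05, power .80
        f = anova_sensitivity(n_total=66, alpha=0.05, power=0.80,
                              df_effect=1, n_cells=4)
        assert round(f, 2) == 0.35

    def test_root_satisfies_monte_carlo_power(self, rng):
        """Independent check: simulate the noncentral F rejection rate."""
        f = anova_sensitivity(n_total=66, power=0.80)
        lam = f * f * 66
        u, v = 1, 62
        num = rng.noncentral_chisquare(u, lam, size=200_000) / u
        den = rng.chisquare(v, size=200_000) / v
        from scipy.stats import f as f_dist

        crit = f_dist.ppf(0.95, u, v)
        mc_power = np.mean(num / den > crit)
        assert mc_power == pytest.approx(0.80, abs=0.01)

    def test_monotonicity(self):
        f_small = anova_sensitivity(n_total=66, power=0.2)
        f_mid = anova_sensitivity(n_total=66, power=0.8)
        f_large = anova_sensitivity(n_total=66, power=0.95)
        assert f_small < f_mid < f_large
        assert anova_sensitivity(n_total=132, power=0.8) < f_mid
        assert f_small < 0.2

    def test_power_function_bounds(self):
        assert anova_power(0.0, 66, 1, 4) == pytest.approx(0.05, abs=1e-6)
        with pytest.raises(ValueError):
            anova_sensitivity(n_total=66, power=1.5)
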