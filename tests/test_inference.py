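"""Inference chain: t tests, mixed ANOVA reduction, ANCOVA, correlations,
Fisher r-to-z comparisons."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import beliefupdate as bu
from beliefupdate.scoring import COVARIATE_COLUMNS
from conftest import random_summary_table
from oracles import (
    glm_mixed_anova_oracle,
    partial_corr_recursive,
    pearson_brute,
    permutation_pearson_p,
)


class TestSummaryT:
    def test_first_estimation_error_groups(self):
        """Printed group means/SDs of the first estimation error give
        |t(34)| = 3.60."""
        res = bu.two_sample_t_summary(-4.71, 6.26, 18, -12.24, 6.29, 18)
        assert res.df == (34,)
        assert abs(res.statistic) == pytest.approx(3.60, abs=0.005)

    def test_undesirable_trial_counts(self):
        res = bu.two_sample_t_summary(25, 5.80, 18, 30, 4.53, 18)
        assert res.statistic == pytest.approx(2.88, abs=0.005)
        assert res.p == pytest.approx(0.007, abs=0.001)

    def test_identical_groups_give_zero(self):
        res = bu.two_sample_t_summary(5, 2, 10, 5, 2, 10)
        assert res.statistic == 0
        assert res.p == 1

    def test_zero_variance_equal_means_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            bu.two_sample_t_summary(5, 0, 10, 5, 0, 10)

    def test_matches_raw_data_t(self, rng):
        x = rng.normal(0, 1, 12)
        y = rng.normal(0.5, 1.2, 9)
        from_raw = bu.two_sample_t(x, y)
        from_summary = bu.two_sample_t_summary(
            x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y)
        )
        assert from_raw.statistic == pytest.approx(from_summary.statistic, rel=1e-12)


class TestMixedAnova:
    def test_agrees_with_glm_oracle(self, rng):
        """F values equal a brute-force sum-to-zero cell-means fit to
        1e-8 relative on 200 random (balanced and unbalanced) datasets."""
        for _ in range(200):
            n1, n2 = rng.integers(3, 15, 2)
            table = random_summary_table(rng, int(n1), int(n2))
            ours = bu.mixed_anova_2x2(table)
            f_val, f_age, f_int = glm_mixed_anova_oracle(table)
            assert ours.valence.statistic == pytest.approx(f_val, rel=1e-8)
            assert ours.age.statistic == pytest.approx(f_age, rel=1e-8)
            assert ours.interaction.statistic == pytest.approx(f_int, rel=1e-8)

    def test_interaction_is_squared_bias_t(self, rng):
        table = random_summary_table(rng, 10, 12)
        ours = bu.mixed_anova_2x2(table)
        bias = table["mean_update_desirable"] - table["mean_update_undesirable"]
        t = bu.two_sample_t(
            bias[table["age_group"] == "older"], bias[table["age_group"] == "young"]
        )
        assert ours.interaction.statistic == pytest.approx(t.statistic**2, rel=1e-12)

    def test_equal_groups_zero_interaction(self):
        half = pd.DataFrame(
            {
                "participant_id": [f"p{i}" for i in range(6)],
                "age_group": ["young"] * 3 + ["older"] * 3,
                "mean_update_desirable": [5.0, 6.0, 7.0] * 2,
                "mean_update_undesirable": [3.0, 3.0, 3.0] * 2,
            }
        )
        assert bu.mixed_anova_2x2(half).interaction.statistic == pytest.approx(0, abs=1e-12)

    def test_df_bookkeeping(self, scored_cohort):
        """36 participants, no covariates: every effect carries df (1, 34)."""
        _, _, _, _, table = scored_cohort
        anova = bu.mixed_anova_2x2(table)
        for res in (anova.valence, anova.age, anova.interaction):
            assert res.df == (1, 34)

    def test_agrees_with_pingouin_on_balanced_data(self, rng):
        """Second independent route: pingouin's mixed ANOVA on balanced
        long-format data reproduces all three F values."""
        pg = pytest.importorskip("pingouin")
        table = random_summary_table(rng, 9, 9)
        ours = bu.mixed_anova_2x2(table)
        long = pd.melt(
            table,
            id_vars=["participant_id", "age_group"],
            value_vars=["mean_update_desirable", "mean_update_undesirable"],
            var_name="valence",
            value_name="update",
        )
        res = pg.mixed_anova(
            long, dv="update", within="valence", subject="participant_id", between="age_group"
        ).set_index("Source")["F"]
        assert ours.age.statistic == pytest.approx(res["age_group"], rel=1e-8)
        assert ours.valence.statistic == pytest.approx(res["valence"], rel=1e-8)
        assert ours.interaction.statistic == pytest.approx(res["Interaction"], rel=1e-8)

    def test_small_group_rejected(self):
        table = pd.DataFrame(
            {
                "participant_id": ["a", "b", "c"],
                "age_group": ["young", "older", "older"],
                "mean_update_desirable": [1.0, 2.0, 3.0],
                "mean_update_undesirable": [0.0, 1.0, 2.0],
            }
        )
        with pytest.raises(ValueError):
            bu.mixed_anova_2x2(table)


class TestAncova:
    def test_zero_covariates_equals_anova_interaction(self, scored_cohort):
        _, _, _, _, table = scored_cohort
        anova = bu.mixed_anova_2x2(table)
        ancova = bu.ancova_interaction(table, [])
        assert ancova.statistic == pytest.approx(anova.interaction.statistic, rel=1e-10)
        assert ancova.df == (1, 34)

    def test_orthogonal_covariates_leave_f_close(self, rng):
        """Covariates independent of group and bias leave the F near the
        unadjusted value on average (Monte-Carlo over 300 datasets)."""
        ratios = []
        for _ in range(300):
            table = random_summary_table(rng, 12, 12)
            table["update_bias"] = (
                table["mean_update_desirable"] - table["mean_update_undesirable"]
            )
            table["iq"] = rng.normal(100, 10, 24)
            table["lot_r"] = rng.normal(18, 3, 24)
            f0 = bu.ancova_interaction(table, []).statistic
            f1 = bu.ancova_interaction(table, ["iq", "lot_r"]).statistic
            ratios.append(f1 / f0 if f0 > 1e-8 else 1.0)
        # noise covariates should not systematically inflate or deflate F
        assert np.median(ratios) == pytest.approx(1.0, abs=0.15)

    def test_rank_deficiency_names_columns(self, scored_cohort):
        _, _, _, _, table = scored_cohort
        table = table.copy()
        table["iq"] = 2 * table["lot_r"]  # force collinearity
        with pytest.raises(ValueError, match="rank-deficient"):
            bu.ancova_interaction(table, ["iq", "lot_r"])


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert bu.pearson(x, x).statistic == pytest.approx(1.0)
        assert bu.pearson(x, -x).statistic == pytest.approx(-1.0)

    def test_matches_brute_force_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 5.0])
        res = bu.pearson(x, y)
        assert res.statistic == pytest.approx(pearson_brute(x, y), rel=1e-12)
        assert res.df == (2,)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            bu.pearson(np.ones(5), np.arange(5.0))

    def test_p_agrees_with_permutation_null(self, rng):
        """The t-transform p matches a 10,000-shuffle permutation p
        within 3 Monte-Carlo standard errors."""
        n_perm = 10_000
        for seed in (1, 2):
            x = rng.normal(0, 1, 12)
            y = 0.5 * x + rng.normal(0, 1, 12)
            p_t = bu.pearson(x, y).p
            p_perm = permutation_pearson_p(x, y, n_perm, seed)
            mcse = math.sqrt(p_perm * (1 - p_perm) / n_perm)
            assert abs(p_t - p_perm) < 3 * mcse + 1e-4


class TestPartialPearson:
    def test_orthogonal_controls_equal_plain_r(self, rng):
        # Gram-Schmidt the control against centred x and y, so it carries
        # no shared variance: the partial r must equal the plain r
        x = rng.normal(0, 1, 25)
        y = 0.6 * x + rng.normal(0, 1, 25)
        z = rng.normal(0, 1, 25)
        xc, yc = x - x.mean(), y - y.mean()
        basis = np.linalg.qr(np.column_stack([xc, yc]))[0]
        z = z - basis @ (basis.T @ z)
        assert abs(pearson_brute(x, z)) < 1e-10 and abs(pearson_brute(y, z)) < 1e-10
        res_plain = bu.pearson(x, y)
        res_partial = bu.partial_pearson(x, y, z)
        assert res_partial.statistic == pytest.approx(res_plain.statistic, rel=1e-10)

    def test_matches_recursive_formula(self, rng):
        x = rng.normal(0, 1, 30)
        z = rng.normal(0, 1, 30)
        y = 0.5 * x + 0.7 * z + rng.normal(0, 1, 30)
        r_xy = pearson_brute(x, y)
        r_xz = pearson_brute(x, z)
        r_yz = pearson_brute(y, z)
        expect = partial_corr_recursive(r_xy, r_xz, r_yz)
        res = bu.partial_pearson(x, y, z)
        assert res.statistic == pytest.approx(expect, rel=1e-10)
        assert res.df == (27,)

    def test_agrees_with_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        df = pd.DataFrame(
            {
                "x": rng.normal(0, 1, 40),
                "z1": rng.normal(0, 1, 40),
                "z2": rng.normal(0, 1, 40),
            }
        )
        df["y"] = 0.4 * df["x"] + 0.5 * df["z1"] + rng.normal(0, 1, 40)
        res = bu.partial_pearson(df["x"], df["y"], df[["z1", "z2"]].to_numpy())
        ref = pg.partial_corr(df, x="x", y="y", covar=["z1", "z2"])
        p_col = "p-val" if "p-val" in ref.columns else "p_val"
        assert res.statistic == pytest.approx(float(ref["r"].iloc[0]), rel=1e-8)
        assert res.p == pytest.approx(float(ref[p_col].iloc[0]), rel=1e-6)

    def test_y_linear_in_controls_gives_zero(self, rng):
        x = rng.normal(0, 1, 20)
        z = rng.normal(0, 1, (20, 2))
        y = z @ np.array([1.0, -2.0]) + 3.0
        with pytest.raises(ValueError, match="linear function"):
            bu.partial_pearson(x, y, z)

    def test_rank_deficient_controls_rejected(self, rng):
        x = rng.normal(0, 1, 15)
        y = rng.normal(0, 1, 15)
        z = rng.normal(0, 1, 15)
        with pytest.raises(ValueError, match="rank-deficient"):
            bu.partial_pearson(x, y, np.column_stack([z, 2 * z]))


class TestFisherZ:
    def test_equal_correlations_give_zero(self):
        res = bu.fisher_z_compare(0.5, 20, 0.5, 30)
        assert res.statistic == 0
        assert res.p == pytest.approx(0.5)

    def test_closed_form_value(self):
        """High-precision evaluation of the closed form for
        (r1=0.72, n=18) vs (r2=0.34, n=18)."""
        z1, z2 = math.atanh(0.72), math.atanh(0.34)
        expect = (z1 - z2) / math.sqrt(2.0 / 15.0)
        res = bu.fisher_z_compare(0.72, 18, 0.34, 18)
        assert res.statistic == pytest.approx(expect, rel=1e-12)

    def test_antisymmetry(self):
        a = bu.fisher_z_compare(0.6, 20, 0.2, 25)
        b = bu.fisher_z_compare(0.2, 25, 0.6, 20)
        assert a.statistic == pytest.approx(-b.statistic, rel=1e-12)
        assert a.p == pytest.approx(b.p, rel=1e-12)

    @given(st.floats(-0.95, 0.95), st.floats(-0.95, 0.95))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_monotone_in_r1(self, r1a, r1b):
        if r1a > r1b:
            r1a, r1b = r1b, r1a
        za = bu.fisher_z_compare(r1a, 20, 0.3, 20).statistic
        zb = bu.fisher_z_compare(r1b, 20, 0.3, 20).statistic
        assert za <= zb + 1e-12

    def test_degenerate_r_rejected(self):
        with pytest.raises(ValueError):
            bu.fisher_z_compare(1.0, 20, 0.3, 20)

    def test_one_tailed_default_matches_normal_tail(self):
        res = bu.fisher_z_compare(0.72, 18, 0.34, 18)
        from scipy import stats
        assert res.p == pytest.approx(float(stats.norm.sf(abs(res.statistic))), rel=1e-12)

    def test_dependent_variant_zero_at_equal_r(self):
        res = bu.fisher_z_compare_dependent(0.5, 0.5, 0.3, 20)
        assert res.statistic == 0

    def test_dependent_variant_shrinks_se_with_overlap(self):
        """Higher correlation between the two competing predictors makes
        the dependent test more sensitive (larger |z|) at fixed r1, r2."""
        low = bu.fisher_z_compare_dependent(0.6, 0.3, 0.1, 30).statistic
        high = bu.fisher_z_compare_dependent(0.6, 0.3, 0.7, 30).statistic
        assert abs(high) > abs(low)
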