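"""Group-level statistics: permutation floor, t-tests, Bayes factors,
balanced mixed ANOVA against independent oracles, power analysis."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from quantnav import (
    DesignError,
    DomainError,
    jzs_bayes_factor,
    mixed_anova,
    one_sample_t,
    pairwise_posthoc,
    pearson_group_test,
    per_participant_glm,
    power_sample_size,
    signflip_test,
    welch_t,
)


# --------------------------------------------------------------------------
# per-participant GLM
# --------------------------------------------------------------------------

class TestPerParticipantGLM:
    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=12)
        y = 1.5 + 2.0 * x + rng.normal(size=12)
        table = pd.DataFrame(dict(agent_id=0, x=x, y=y))
        out = per_participant_glm(table, "y", ["x"])
        # independent oracle: solve the normal equations by hand
        X = np.column_stack([np.ones(12), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        s2 = resid @ resid / (12 - 2)
        se = math.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        assert out.t.iloc[0] == pytest.approx(beta[1] / se, rel=1e-10)

    def test_perfect_fit_is_capped_and_flagged(self):
        x = np.arange(10.0)
        table = pd.DataFrame(dict(agent_id=0, x=x, y=2 * x))
        out = per_participant_glm(table, "y", ["x"])
        assert out.flagged.iloc[0]
        assert out.t.iloc[0] == 1e6

    def test_null_regressor_t_centred_on_zero(self):
        rng = np.random.default_rng(1)
        tabs = pd.concat([
            pd.DataFrame(dict(agent_id=i, x=rng.normal(size=20),
                              y=rng.normal(size=20)))
            for i in range(40)
        ])
        out = per_participant_glm(tabs, "y", ["x"])
        assert abs(out.t.mean()) < 0.5

    def test_singular_design_rejected(self):
        table = pd.DataFrame(dict(agent_id=0, x=np.ones(10),
                                  y=np.arange(10.0)))
        with pytest.raises(DesignError):
            per_participant_glm(table, "y", ["x"])


# --------------------------------------------------------------------------
# sign-flip permutation test
# --------------------------------------------------------------------------

class TestSignFlip:
    def test_p_floor_and_z_ceiling(self):
        res = signflip_test(np.full(45, 4.0), n_perm=10_000, tail="greater",
                            seed=0)
        assert res.p == 0.0001
        assert res.z == pytest.approx(3.719, abs=1e-3)

    def test_flipping_all_signs_reverses_the_tail(self):
        t = np.array([2.0, 3.0, 1.5, 2.5, 4.0])
        a = signflip_test(t, 2000, tail="greater", seed=3)
        b = signflip_test(-t, 2000, tail="less", seed=3)
        assert a.p == b.p and a.statistic == -b.statistic

    def test_null_p_values_are_uniform(self):
        # symmetric-about-zero inputs: p uniform over repeated cohorts
        rng = np.random.default_rng(9)
        ps = [signflip_test(rng.normal(size=20), 500, "greater", rng).p
              for _ in range(300)]
        d = stats.kstest(ps, "uniform").statistic
        assert d < 0.08

    def test_empty_input_rejected(self):
        with pytest.raises(DomainError):
            signflip_test([], 100)


# --------------------------------------------------------------------------
# t-tests
# --------------------------------------------------------------------------

class TestTTests:
    def test_identical_groups(self):
        x = np.arange(10.0)
        res = welch_t(x, x)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_welch_df_matches_hand_formula(self):
        a = np.array([4.1, 5.3, 6.2, 5.9, 4.8, 5.1, 6.6])
        b = np.array([3.2, 4.0, 3.8, 4.4, 3.1])
        res = welch_t(a, b)
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        assert res.df == pytest.approx(df)
        sp = stats.ttest_ind(a, b, equal_var=False)
        assert res.statistic == pytest.approx(sp.statistic)
        assert res.p == pytest.approx(sp.pvalue)

    def test_one_sample_against_scipy(self):
        x = np.array([0.3, 0.5, 0.45, 0.62, 0.48, 0.55])
        res = one_sample_t(x, mu0=0.5)
        sp = stats.ttest_1samp(x, 0.5)
        assert res.statistic == pytest.approx(sp.statistic)
        assert res.p == pytest.approx(sp.pvalue)

    def test_degenerate_input_rejected(self):
        with pytest.raises(DomainError):
            one_sample_t(np.full(5, 0.5), mu0=0.5)


# --------------------------------------------------------------------------
# JZS Bayes factor
# --------------------------------------------------------------------------

def jzs_oracle(t, n1, n2=None, r=math.sqrt(2) / 2):
    """Independent dense-grid quadrature of the JZS integral (Cauchy prior
    via its inverse-gamma mixture representation)."""
    if n2 is None:
        N, nu = n1, n1 - 1
    else:
        N, nu = n1 * n2 / (n1 + n2), n1 + n2 - 2
    x = np.linspace(1e-8, 1 - 1e-8, 200_001)
    g = x / (1 - x)
    jac = 1 / (1 - x) ** 2
    f = ((1 + N * g * r * r) ** -0.5
         * (1 + t * t / ((1 + N * g * r * r) * nu)) ** (-(nu + 1) / 2)
         * (2 * np.pi) ** -0.5 * g ** -1.5 * np.exp(-1 / (2 * g)) * jac)
    alt = np.trapezoid(f, x)
    null = (1 + t * t / nu) ** (-(nu + 1) / 2)
    return alt / null


class TestBayesFactor:
    def test_matches_quadrature_oracle(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0.4, 1.0, 45)
        b = rng.normal(0.0, 1.0, 45)
        bf = jzs_bayes_factor(a, b)
        n1, n2 = len(a), len(b)
        sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
        t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
        assert bf == pytest.approx(jzs_oracle(t, n1, n2), rel=1e-3)

    def test_one_sample_matches_oracle(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0.2, 1.0, 30)
        t = x.mean() / (x.std(ddof=1) / math.sqrt(len(x)))
        assert jzs_bayes_factor(x) == pytest.approx(jzs_oracle(t, 30), rel=1e-3)

    def test_identical_large_samples_favour_the_null(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 200)
        b = rng.normal(0, 1, 200)
        assert jzs_bayes_factor(a, b) < 1 / 3  # moderate null evidence

    def test_consistency_in_n(self):
        # BF10 -> 0 under the null, -> infinity under a fixed effect
        rng = np.random.default_rng(11)
        null_small = jzs_bayes_factor(rng.normal(0, 1, 20))
        null_large = jzs_bayes_factor(rng.normal(0, 1, 2000))
        assert null_large < null_small
        eff_small = jzs_bayes_factor(rng.normal(0.5, 1, 20))
        eff_large = jzs_bayes_factor(rng.normal(0.5, 1, 2000))
        assert eff_large > eff_small > 0


# --------------------------------------------------------------------------
# mixed ANOVA
# --------------------------------------------------------------------------

def anova_fixture():
    """Seed-reproducible 2-group x 6-subject x 2x2-within dataset; the
    frozen expectations below were computed with base-R aov Error strata."""
    rng = np.random.default_rng(2024)
    rows = []
    sid = 0
    for g in ("A", "B"):
        for _ in range(6):
            base = rng.normal(10, 2)
            for w1 in ("pre", "post"):
                for w2 in ("hi", "lo"):
                    y = (base + (1.5 if w1 == "post" else 0)
                         + (0.8 if w2 == "hi" else 0)
                         + (0.5 if (g == "B" and w1 == "post") else 0)
                         + rng.normal(0, 1))
                    rows.append((f"s{sid}", g, w1, w2, y))
            sid += 1
    return pd.DataFrame(rows, columns=["subject", "group", "w1", "w2", "y"])


R_AOV_EXPECTED = {
    # effect: (F, p) from aov(y ~ group*w1*w2 + Error(subject/(w1*w2)))
    "group": (0.193878, 0.66907318),
    "w1": (32.499848, 0.00019807),
    "w1 x group": (2.183884, 0.17025187),
    "w2": (35.527262, 0.00013927),
    "w2 x group": (1.780935, 0.21162393),
    "w1 x w2": (1.591511, 0.23574323),
    "w1 x w2 x group": (0.038455, 0.84845973),
}


class TestMixedAnova:
    def test_against_r_aov_oracle(self):
        res = mixed_anova(anova_fixture(), "y", "subject", "group",
                          ["w1", "w2"])
        table = res.effect_table.set_index("effect")
        for effect, (F, p) in R_AOV_EXPECTED.items():
            assert table.loc[effect, "F"] == pytest.approx(F, abs=2e-5)
            assert table.loc[effect, "p"] == pytest.approx(p, abs=2e-6)

    def test_against_pingouin_one_within(self):
        import pingouin as pg

        df = anova_fixture()
        df = df[df.w2 == "hi"]
        mine = mixed_anova(df, "y", "subject", "group", ["w1"]) \
            .effect_table.set_index("effect")
        theirs = pg.mixed_anova(df, dv="y", within="w1", between="group",
                                subject="subject").set_index("Source")
        for ours, pgname in [("group", "group"), ("w1", "w1"),
                             ("w1 x group", "Interaction")]:
            assert mine.loc[ours, "F"] == pytest.approx(
                theirs.loc[pgname, "F"], rel=1e-9)

    def test_constant_dv_gives_zero_f(self):
        df = anova_fixture().assign(y=3.0)
        res = mixed_anova(df, "y", "subject", "group", ["w1", "w2"])
        assert (res.effect_table.F == 0.0).all()
        assert (res.effect_table.p == 1.0).all()

    def test_two_level_within_f_equals_paired_t_squared(self):
        df = anova_fixture()
        df = df[df.w2 == "hi"].assign(group="only")
        res = mixed_anova(df, "y", "subject", "group", ["w1"])
        wide = df.pivot(index="subject", columns="w1", values="y")
        t = stats.ttest_rel(wide["pre"], wide["post"])
        assert res.statistic == pytest.approx(t.statistic**2)
        assert res.p == pytest.approx(t.pvalue)

    def test_two_level_factors_need_no_sphericity_correction(self):
        res = mixed_anova(anova_fixture(), "y", "subject", "group",
                          ["w1", "w2"])
        assert (res.effect_table.eps == 1.0).all()
        assert (res.effect_table.p_corr == res.effect_table.p).all()

    def test_unbalanced_design_rejected(self):
        df = anova_fixture().iloc[:-1]
        with pytest.raises(DesignError):
            mixed_anova(df, "y", "subject", "group", ["w1", "w2"])


class TestPosthoc:
    def test_identical_conditions_give_p_one(self):
        df = anova_fixture()
        wide = df[df.w2 == "hi"][["subject", "group", "w1", "y"]].copy()
        wide["y"] = 1.0
        out = pairwise_posthoc(wide, "y", "subject", "w1", by=["group"])
        assert (out.p == 1.0).all()

    def test_no_correction_equals_raw_p(self):
        df = anova_fixture()
        raw = pairwise_posthoc(df, "y", "subject", "w1", by=["group", "w2"],
                               correction="none")
        assert (raw.p == raw.p_corr).all()

    def test_single_contaminated_subgroup_flagged_only_uncorrected(self):
        # null everywhere except one subgroup with a mild injected effect
        rng = np.random.default_rng(17)
        rows = []
        for g in ("A", "B"):
            for s in range(20):
                base = rng.normal(0, 1)
                for w1 in ("pre", "post"):
                    for w2 in ("hi", "lo"):
                        bump = 1.0 if (g, w2, w1) == ("A", "lo", "post") else 0.0
                        rows.append((f"{g}{s}", g, w1, w2,
                                     base + bump + rng.normal(0, 1)))
        df = pd.DataFrame(rows, columns=["subject", "group", "w1", "w2", "y"])
        out = pairwise_posthoc(df, "y", "subject", "w1", by=["group", "w2"])
        hit = out[(out.group == "A") & (out.w2 == "lo")].iloc[0]
        others = out[~((out.group == "A") & (out.w2 == "lo"))]
        assert (out.p_corr >= out.p).all()
        assert hit.p == out.p.min()
        assert hit.p < 0.05
        assert (others.p_corr > 0.05).all()


# --------------------------------------------------------------------------
# power analysis and correlation group test
# --------------------------------------------------------------------------

class TestPower:
    def test_study_sample_size(self):
        n = power_sample_size(0.5, alpha=0.05, power=0.95,
                              design="one_sample", tail="greater")
        assert n == 45

    def test_tiny_power_floors_at_two(self):
        assert power_sample_size(0.5, alpha=0.05, power=0.01,
                                 design="one_sample", tail="greater") == 2

    def test_matches_statsmodels_across_effect_sizes(self):
        from statsmodels.stats.power import TTestPower

        solver = TTestPower()
        for d in (0.3, 0.5, 0.8, 1.0):
            n = power_sample_size(d, 0.05, 0.95, "one_sample", "greater")
            cont = solver.solve_power(effect_size=d, alpha=0.05, power=0.95,
                                      alternative="larger")
            assert n == math.ceil(cont - 1e-9)

    def test_doubling_d_roughly_quarters_n(self):
        n1 = power_sample_size(0.5, 0.05, 0.95, "one_sample", "greater")
        n2 = power_sample_size(1.0, 0.05, 0.95, "one_sample", "greater")
        assert 0.2 <= n2 / n1 <= 0.35

    def test_invalid_arguments(self):
        with pytest.raises(DomainError):
            power_sample_size(0.5, alpha=1.5)
        with pytest.raises(DomainError):
            power_sample_size(-1.0)


class TestPearsonGroupTest:
    def test_all_zero_correlations(self):
        res = pearson_group_test([0.0, 0.01, -0.01, 0.0, 0.0])
        assert abs(res.statistic) < 1e-9 or res.p > 0.9

    def test_undefined_correlations_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="undefined"):
            res = pearson_group_test([0.5, 0.6, np.nan, 0.4])
        assert res.meta["n"] == 3

    def test_positive_mean_r_detected(self):
        rng = np.random.default_rng(6)
        r = rng.normal(0.5, 0.1, 45)
        res = pearson_group_test(r)
        assert res.p < 1e-6 and res.meta["mean_r"] > 0.4
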