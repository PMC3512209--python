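"""Mixed ANOVA against independent oracles, t-tests, planned contrasts."""

import numpy as np
import pandas as pd
import pytest

from pitiming import mixed_anova, one_sample_t, paired_t, planned_comparison
from pitiming.stats import DesignError


def make_mixed_data(rng, n_per_group=8, g_eff=0.0, w_eff=0.0, noise=1.0,
                    within=("drug",), levels=("SAL", "NOM")):
    rows = []
    for gi, group in enumerate(("FEAR", "CTRL")):
        for s in range(n_per_group):
            subj = f"{group}{s}"
            base = rng.normal(0, 1)  # random subject intercept
            for wi, lev in enumerate(levels):
                rows.append(
                    {
                        "subject": subj,
                        "group": group,
                        within[0]: lev,
                        "y": base + gi * g_eff + wi * w_eff + rng.normal(0, noise),
                    }
                )
    return pd.DataFrame(rows)


def split_plot_oracle_2x2x2(df, dv="y"):
    """Textbook split-plot sums of squares from explicit marginal means
    (one between factor g, two within factors a, b; balanced)."""
    g_levels = sorted(df["group"].unique())
    a_levels = sorted(df["a"].unique())
    b_levels = sorted(df["b"].unique())
    subjects = sorted(df["subject"].unique())
    n = len(subjects) // len(g_levels)
    na, nb, ng = len(a_levels), len(b_levels), len(g_levels)
    N = len(df)
    grand = df[dv].mean()

    def cell_mean(**kw):
        m = pd.Series(True, index=df.index)
        for k, v in kw.items():
            m &= df[k] == v
        return df.loc[m, dv].mean()

    ss_g = n * na * nb * sum((cell_mean(group=g) - grand) ** 2 for g in g_levels)
    ss_subj = na * nb * sum(
        (cell_mean(subject=s) - cell_mean(group=df[df.subject == s]["group"].iloc[0])) ** 2
        for s in subjects
    )
    ss_a = n * ng * nb * sum((cell_mean(a=a) - grand) ** 2 for a in a_levels)
    ss_ga = n * nb * sum(
        (cell_mean(group=g, a=a) - cell_mean(group=g) - cell_mean(a=a) + grand) ** 2
        for g in g_levels for a in a_levels
    )
    ss_b = n * ng * na * sum((cell_mean(b=b) - grand) ** 2 for b in b_levels)
    ss_gb = n * na * sum(
        (cell_mean(group=g, b=b) - cell_mean(group=g) - cell_mean(b=b) + grand) ** 2
        for g in g_levels for b in b_levels
    )
    ss_ab = n * ng * sum(
        (cell_mean(a=a, b=b) - cell_mean(a=a) - cell_mean(b=b) + grand) ** 2
        for a in a_levels for b in b_levels
    )
    ss_gab = n * sum(
        (
            cell_mean(group=g, a=a, b=b)
            - cell_mean(group=g, a=a) - cell_mean(group=g, b=b) - cell_mean(a=a, b=b)
            + cell_mean(group=g) + cell_mean(a=a) + cell_mean(b=b) - grand
        ) ** 2
        for g in g_levels for a in a_levels for b in b_levels
    )
    ss_as = nb * sum(
        (
            cell_mean(subject=s, a=a) - cell_mean(subject=s)
            - cell_mean(group=df[df.subject == s]["group"].iloc[0], a=a)
            + cell_mean(group=df[df.subject == s]["group"].iloc[0])
        ) ** 2
        for s in subjects for a in a_levels
    )
    ss_bs = na * sum(
        (
            cell_mean(subject=s, b=b) - cell_mean(subject=s)
            - cell_mean(group=df[df.subject == s]["group"].iloc[0], b=b)
            + cell_mean(group=df[df.subject == s]["group"].iloc[0])
        ) ** 2
        for s in subjects for b in b_levels
    )
    ss_total = ((df[dv] - grand) ** 2).sum()
    ss_abs = ss_total - (
        ss_g + ss_subj + ss_a + ss_ga + ss_as + ss_b + ss_gb + ss_bs + ss_ab + ss_gab
    )
    df_err_a = (len(subjects) - ng) * (na - 1)
    df_err_b = (len(subjects) - ng) * (nb - 1)
    df_err_ab = (len(subjects) - ng) * (na - 1) * (nb - 1)
    return {
        "group": ss_g / (ng - 1) / (ss_subj / (len(subjects) - ng)),
        "a": ss_a / (na - 1) / (ss_as / df_err_a),
        "group x a": ss_ga / ((ng - 1) * (na - 1)) / (ss_as / df_err_a),
        "b": ss_b / (nb - 1) / (ss_bs / df_err_b),
        "group x b": ss_gb / ((ng - 1) * (nb - 1)) / (ss_bs / df_err_b),
        "a x b": ss_ab / ((na - 1) * (nb - 1)) / (ss_abs / df_err_ab),
        "group x a x b": ss_gab / ((ng - 1) * (na - 1) * (nb - 1)) / (ss_abs / df_err_ab),
    }


class TestMixedAnova:
    def test_constant_within_factor_gives_zero_f(self, rng):
        df = make_mixed_data(rng, w_eff=0.0)
        df["y"] = df.groupby("subject")["y"].transform("mean")  # same at both levels
        table = mixed_anova(df, "y", "subject", between="group", within=["drug"])
        assert table.effect("drug")["F"] == pytest.approx(0.0, abs=1e-12)

    def test_equal_group_means_give_near_zero_group_f(self, rng):
        df = make_mixed_data(rng)
        # mirror FEAR values into CTRL so group means match exactly
        fear = df[df.group == "FEAR"].copy()
        ctrl = fear.copy()
        ctrl["group"] = "CTRL"
        ctrl["subject"] = ctrl["subject"].str.replace("FEAR", "CTRL")
        df = pd.concat([fear, ctrl], ignore_index=True)
        table = mixed_anova(df, "y", "subject", between="group", within=["drug"])
        assert table.effect("group")["F"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_pingouin_one_within(self, rng):
        pg = pytest.importorskip("pingouin")
        df = make_mixed_data(rng, g_eff=0.8, w_eff=0.5)
        table = mixed_anova(df, "y", "subject", between="group", within=["drug"])
        ref = pg.mixed_anova(
            data=df, dv="y", within="drug", between="group", subject="subject"
        ).set_index("Source")
        assert table.effect("group")["F"] == pytest.approx(ref.loc["group", "F"], rel=1e-8)
        assert table.effect("drug")["F"] == pytest.approx(ref.loc["drug", "F"], rel=1e-8)
        assert table.effect("group x drug")["F"] == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-8
        )

    def test_matches_hand_oracle_two_within(self, rng):
        rows = []
        for gi, group in enumerate(("FEAR", "CTRL")):
            for s in range(8):
                base = rng.normal(0, 1)
                for ai, a in enumerate(("SAL", "NOM")):
                    for bi, b in enumerate(("PI", "PIN")):
                        rows.append(
                            {
                                "subject": f"{group}{s}", "group": group,
                                "a": a, "b": b,
                                "y": base + 0.4 * gi + 0.3 * ai + 0.6 * bi
                                + 0.2 * ai * bi + rng.normal(0, 1),
                            }
                        )
        df = pd.DataFrame(rows)
        table = mixed_anova(df, "y", "subject", between="group", within=["a", "b"])
        oracle = split_plot_oracle_2x2x2(df)
        for name, f_ref in oracle.items():
            assert table.effect(name)["F"] == pytest.approx(f_ref, rel=1e-8), name

    def test_f_equals_squared_paired_t_for_two_level_within(self, rng):
        """Pure within design: F(drug) == t_paired^2 to 1e-8."""
        df = make_mixed_data(rng, n_per_group=10, w_eff=0.7)
        df = df[df.group == "FEAR"]
        table = mixed_anova(df, "y", "subject", between=None, within=["drug"])
        a = df[df.drug == "SAL"].sort_values("subject")["y"].to_numpy()
        b = df[df.drug == "NOM"].sort_values("subject")["y"].to_numpy()
        t = paired_t(a, b)
        assert table.effect("drug")["F"] == pytest.approx(t["t"] ** 2, abs=1e-8)

    def test_missing_cell_names_subject(self, rng):
        df = make_mixed_data(rng).iloc[:-1]
        with pytest.raises(DesignError, match="CTRL7"):
            mixed_anova(df, "y", "subject", between="group", within=["drug"])

    def test_refuses_three_level_within(self, rng):
        df = make_mixed_data(rng, within=("dose",), levels=("a", "b", "c"))
        with pytest.raises(DesignError, match="two levels"):
            mixed_anova(df, "y", "subject", between="group", within=["dose"])


class TestTTests:
    def test_all_equal_to_mu(self):
        res = one_sample_t([3.0, 3.0, 3.0], 3.0)
        assert res["t"] == 0.0 and res["p"] == 1.0

    def test_hand_arithmetic(self):
        res = one_sample_t([1.0, 2.0, 3.0], 0.0)
        assert res["t"] == pytest.approx(3.464, abs=1e-3)
        assert res["df"] == 2

    def test_paired_identical_vectors(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["t"] == 0.0

    def test_zero_variance_flagged(self):
        res = one_sample_t([2.0, 2.0, 2.0], 0.0)
        assert res["zero_variance"] and res["p"] < 1e-12


class TestPlannedComparison:
    def test_pooled_contrast_hand_value(self, rng):
        df = make_mixed_data(rng, g_eff=1.0, w_eff=0.5, n_per_group=8)
        table = mixed_anova(df, "y", "subject", between="group", within=["drug"])
        res = planned_comparison(
            df, "y", {"group": "FEAR", "drug": "SAL"},
            {"group": "CTRL", "drug": "SAL"}, anova=table, error_term="group x drug",
        )
        ya = df[(df.group == "FEAR") & (df.drug == "SAL")]["y"]
        yb = df[(df.group == "CTRL") & (df.drug == "SAL")]["y"]
        mse = table.effect("group x drug")["ms_error"]
        f_ref = (ya.mean() - yb.mean()) ** 2 / (mse * (1 / 8 + 1 / 8))
        assert res["F"] == pytest.approx(f_ref, rel=1e-12)

    def test_cellwise_equals_welch_t_squared(self, rng):
        df = make_mixed_data(rng, g_eff=1.0)
        res = planned_comparison(
            df, "y", {"group": "FEAR"}, {"group": "CTRL"}, pooled=False
        )
        from scipy import stats as sps

        t = sps.ttest_ind(
            df[df.group == "FEAR"]["y"], df[df.group == "CTRL"]["y"], equal_var=False
        )
        assert res["F"] == pytest.approx(t.statistic**2, rel=1e-9)
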