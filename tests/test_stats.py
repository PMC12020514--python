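"""t-tests, Levene gate, split-plot ANOVA/ANCOVA and power, each against
an independent route (scipy raw-data tests, design-matrix least squares,
pingouin, direct noncentral-F evaluation)."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from emostop.stats import (
    PowerSpec,
    SummaryStats,
    ancova_2x2_mixed,
    cohens_d,
    levene_gate,
    mixed_anova_2x2,
    power_min_n,
    power_within_between,
    summarize,
    ttest_from_summary,
    ttest_raw,
)


class TestTTests:
    def test_summary_equals_raw_scipy(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(10, 2, 30), rng.normal(11, 3, 25)
        for variant, equal_var in [("pooled", True), ("welch", False)]:
            mine = ttest_from_summary(summarize(x), summarize(y), variant)
            ref = sps.ttest_ind(x, y, equal_var=equal_var)
            assert mine.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert mine.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_identical_summaries(self):
        s = SummaryStats(5.0, 1.0, 10)
        res = ttest_from_summary(s, s, "welch")
        assert res.statistic == 0.0 and res.p == 1.0

    @given(
        st.tuples(
            st.floats(-50, 50), st.floats(0.5, 30), st.integers(3, 80),
            st.floats(-50, 50), st.floats(0.5, 30), st.integers(3, 80),
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_welch_df_never_exceeds_pooled_df(self, args):
        m1, s1, n1, m2, s2, n2 = args
        a, b = SummaryStats(m1, s1, n1), SummaryStats(m2, s2, n2)
        assert ttest_from_summary(a, b, "welch").df <= ttest_from_summary(a, b, "pooled").df + 1e-9

    def test_cohens_d_zero_variance_errors(self):
        with pytest.raises(ValueError, match="pooled variance"):
            cohens_d(SummaryStats(1.0, 0.0, 5), SummaryStats(2.0, 0.0, 5))

    def test_equal_means_zero_d(self):
        assert cohens_d(SummaryStats(3.0, 1.0, 5), SummaryStats(3.0, 2.0, 5)) == 0.0


class TestLeveneGate:
    def test_unequal_spread_chooses_welch(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, 50)
        res, variant = levene_gate(base, 5 * rng.normal(0, 1, 50))
        assert variant == "welch" and res.p < 0.05

    def test_levene_equals_anova_on_deviation_scores(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 40), rng.normal(0, 3, 35)
        res, _ = levene_gate(x, y)
        dx, dy = np.abs(x - x.mean()), np.abs(y - y.mean())
        ref = sps.f_oneway(dx, dy)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)

    def test_identical_groups_choose_pooled(self):
        x = np.arange(20, dtype=float)
        _, variant = levene_gate(x, x.copy())
        assert variant == "pooled"

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 30), rng.normal(0, 2, 30)
        a, _ = levene_gate(x, y)
        b, _ = levene_gate(y, x)
        assert a.statistic == pytest.approx(b.statistic)


def toy_mixed_data(n_per_group=4, group_effect=2.0, cond_effect=1.0, inter=0.5, seed=10):
    rng = np.random.default_rng(seed)
    rows = []
    for gi, g in enumerate(["younger", "older"]):
        for i in range(n_per_group):
            pid = f"{g}{i}"
            subj = rng.normal(0, 1)
            for ci, c in enumerate(["pleasant", "unpleasant"]):
                value = (
                    10 + gi * group_effect + ci * cond_effect + gi * ci * inter
                    + subj + rng.normal(0, 0.5)
                )
                rows.append(
                    {"participant_id": pid, "group": g, "condition": c, "value": value}
                )
    return pd.DataFrame(rows)


def oracle_split_plot(df):
    """Design-matrix least-squares oracle for the balanced 2x2 split plot.

    Model comparisons with explicit projections: the group effect is
    tested on subject means against the subject residual; condition and
    interaction on the full observation model against the within
    residual.
    """

    def sse(X, y):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    wide = df.pivot(index="participant_id", columns="condition", values="value")
    groups = df.groupby("participant_id")["group"].first().loc[wide.index]
    g = np.where(groups == sorted(groups.unique())[0], -1.0, 1.0)
    n = len(wide)
    # between stratum: subject means
    sm = wide.mean(axis=1).to_numpy()
    ones = np.ones(n)
    ss_group = (sse(ones[:, None], sm) - sse(np.column_stack([ones, g]), sm)) * 2
    ss_subj = sse(np.column_stack([ones, g]), sm) * 2
    f_group = (ss_group / 1) / (ss_subj / (n - 2))
    # within stratum: condition differences (halved contrast keeps scale)
    d = (wide.iloc[:, 1] - wide.iloc[:, 0]).to_numpy() / np.sqrt(2)
    ss_cond = (sse(np.empty((n, 0)), d) - sse(ones[:, None], d))
    ss_int = (sse(ones[:, None], d) - sse(np.column_stack([ones, g]), d))
    ss_err = sse(np.column_stack([ones, g]), d)
    f_cond = ss_cond / (ss_err / (n - 2))
    f_int = ss_int / (ss_err / (n - 2))
    return {"between": f_group, "within": f_cond, "interaction": f_int}


class TestMixedAnova:
    def test_matches_design_matrix_oracle(self):
        df = toy_mixed_data()
        mine = mixed_anova_2x2(df)
        ref = oracle_split_plot(df)
        for effect in ("between", "within", "interaction"):
            assert mine[effect].statistic == pytest.approx(ref[effect], abs=1e-8)

    def test_matches_pingouin_unbalanced(self):
        pg = pytest.importorskip("pingouin")
        df = toy_mixed_data(n_per_group=6, seed=4)
        df = df[df["participant_id"] != "younger0"]  # 5 vs 6 subjects
        mine = mixed_anova_2x2(df)
        ref = pg.mixed_anova(
            data=df, dv="value", within="condition", between="group",
            subject="participant_id",
        ).set_index("Source")
        assert mine["between"].statistic == pytest.approx(ref.loc["group", "F"], abs=1e-8)
        assert mine["within"].statistic == pytest.approx(ref.loc["condition", "F"], abs=1e-8)
        assert mine["interaction"].statistic == pytest.approx(
            ref.loc["Interaction", "F"], abs=1e-8
        )
        assert mine["between"].effect_size == pytest.approx(ref.loc["group", "np2"], abs=1e-8)

    def test_degenerate_within_effect(self):
        df = toy_mixed_data()
        wide = df.pivot_table(index=["participant_id", "group"], columns="condition", values="value")
        wide["unpleasant"] = wide["pleasant"]  # identical per participant
        long = wide.reset_index().melt(
            id_vars=["participant_id", "group"], var_name="condition", value_name="value"
        )
        res = mixed_anova_2x2(long)
        assert res["within"].statistic == 0.0 and res["within"].p == 1.0

    def test_group_label_swap_leaves_within_effect(self):
        df = toy_mixed_data(inter=0.0)
        swapped = df.assign(group=df["group"].map({"younger": "older", "older": "younger"}))
        assert mixed_anova_2x2(df)["within"].statistic == pytest.approx(
            mixed_anova_2x2(swapped)["within"].statistic
        )

    def test_partial_eta_sq_in_unit_interval(self):
        res = mixed_anova_2x2(toy_mixed_data(seed=8))
        assert all(0.0 <= r.effect_size <= 1.0 for r in res.values())

    def test_missing_cell_errors(self):
        df = toy_mixed_data().iloc[:-1]
        with pytest.raises(ValueError, match="per condition"):
            mixed_anova_2x2(df)


class TestAncova:
    def test_constant_covariate_falls_back_with_warning(self):
        df = toy_mixed_data()
        cov = pd.Series(0.0, index=df["participant_id"].unique())
        with pytest.warns(UserWarning, match="constant covariate"):
            adj = ancova_2x2_mixed(df, cov)
        plain = mixed_anova_2x2(df)
        for effect in plain:
            assert adj[effect].statistic == pytest.approx(plain[effect].statistic)

    def test_group_indicator_covariate_absorbs_between_effect(self):
        df = toy_mixed_data(group_effect=5.0)
        cov = df.groupby("participant_id")["group"].first().map(
            {"younger": 0.0, "older": 1.0}
        )
        adj = ancova_2x2_mixed(df, cov)
        assert adj["between"].statistic == pytest.approx(0.0, abs=1e-8)

    def test_between_f_matches_design_matrix_oracle(self):
        rng = np.random.default_rng(20)
        df = toy_mixed_data(seed=21)
        pids = df["participant_id"].unique()
        cov = pd.Series(rng.normal(size=len(pids)), index=pids)
        adj = ancova_2x2_mixed(df, cov)

        def sse(X, y):
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ beta
            return float(r @ r)

        wide = df.pivot(index="participant_id", columns="condition", values="value")
        sm = wide.mean(axis=1).to_numpy()
        groups = df.groupby("participant_id")["group"].first().loc[wide.index]
        g = (groups == sorted(groups.unique())[1]).to_numpy(float)
        x = cov.loc[wide.index].to_numpy()
        ones = np.ones(len(sm))
        full = sse(np.column_stack([ones, x, g]), sm)
        red = sse(np.column_stack([ones, x]), sm)
        f_ref = (red - full) / (full / (len(sm) - 3))
        assert adj["between"].statistic == pytest.approx(f_ref, abs=1e-8)
        # within-subject stratum unchanged by a between-subject covariate
        plain = mixed_anova_2x2(df)
        assert adj["within"].statistic == pytest.approx(plain["within"].statistic)

    def test_missing_covariate_errors(self):
        df = toy_mixed_data()
        cov = pd.Series(1.0, index=df["participant_id"].unique()[:-1])
        with pytest.raises(ValueError, match="covariate missing"):
            ancova_2x2_mixed(df, cov)


class TestPower:
    def test_minimum_n_for_default_interaction_spec(self):
        assert power_min_n(PowerSpec()) == 68

    def test_bracketing(self):
        spec = PowerSpec()
        n = power_min_n(spec)
        assert power_within_between(n, spec) >= spec.target_power
        assert power_within_between(n - 1, spec) < spec.target_power

    def test_monotone_in_effect_size_and_power(self):
        assert power_min_n(PowerSpec(f=0.4)) < power_min_n(PowerSpec(f=0.2))
        assert power_min_n(PowerSpec(target_power=0.95)) > power_min_n(
            PowerSpec(target_power=0.80)
        )
        assert power_min_n(PowerSpec(alpha=0.01)) > power_min_n(PowerSpec(alpha=0.05))

    def test_large_effect_small_n_limit(self):
        n = power_min_n(PowerSpec(f=5.0))
        assert n >= 3  # bounded below by df2 > 0

    def test_power_agrees_with_direct_noncentral_f(self):
        spec = PowerSpec()
        n = 68
        lam = spec.f**2 * n * 2 / (1 - spec.rho)
        crit = sps.f.isf(0.05, 1, n - 2)
        assert power_within_between(n, spec) == pytest.approx(
            sps.ncf.sf(crit, 1, n - 2, lam), abs=1e-12
        )
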