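"""Tests of the inference stage.

The mixed ANOVA is checked three ways: a hand-computed toy partition, an
independent implementation (pingouin) on a random 2 x 4 mixed design, and
values frozen from R's aov Error-strata decomposition on a 2 x (2 x 3)
design.
"""

import numpy as np
import pandas as pd
import pytest

from fnirspipe import stats as st


def _long(groups, values, times=None):
    """Build a long table from per-subject value lists."""
    times = times or [f"t{i+1}" for i in range(len(values[0]))]
    rows = []
    for s, (g, vals) in enumerate(zip(groups, values)):
        for tp, v in zip(times, vals):
            rows.append({"subj": f"s{s}", "grp": g, "tp": tp, "y": v})
    return pd.DataFrame(rows)


class TestGgEpsilon:
    def test_compound_symmetry_gives_one(self):
        k = 4
        cov = 0.3 * np.ones((k, k)) + 0.7 * np.eye(k)
        assert st.gg_epsilon(cov) == pytest.approx(1.0)

    def test_two_levels_always_one(self):
        cov = np.array([[2.0, 0.3], [0.3, 1.0]])
        assert st.gg_epsilon(cov) == 1.0

    def test_matches_direct_formula_on_random_psd(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            a = rng.standard_normal((5, 5))
            cov = a @ a.T
            k = cov.shape[0]
            # independent evaluation of the double-centered formula
            cbar = cov.mean()
            row = cov.mean(axis=0)
            s_centered = cov - row[:, None] - row[None, :] + cbar
            num = np.trace(s_centered) ** 2
            den = (k - 1) * np.sum(s_centered ** 2)
            expected = np.clip(num / den, 1 / (k - 1), 1.0)
            assert st.gg_epsilon(cov) == pytest.approx(expected, abs=1e-10)

    def test_lower_bound_clamp(self):
        # rank-one covariance: maximal sphericity violation
        v = np.array([3.0, 1.0, 0.2, 0.05])
        cov = np.outer(v, v)
        assert st.gg_epsilon(cov) >= 1.0 / 3.0

    def test_non_psd_raises(self):
        cov = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(st.StatsError):
            st.gg_epsilon(cov)


class TestMixedAnovaToy:
    def test_hand_computed_interaction_partition(self):
        """2 groups x 2 subjects x 2 times with values EG {(1,2),(1,2)},
        CG {(1,1),(1,1)}: interaction SS = 0.5 by hand; zero within-cell
        error is flagged degenerate."""
        df = _long(["EG", "EG", "CG", "CG"], [[1, 2], [1, 2], [1, 1], [1, 1]])
        res = st.mixed_rm_anova(df, dv="y", subject="subj", between="grp",
                                within=("tp",))
        assert res.table.loc["tp", "SS"] == pytest.approx(0.5)
        assert res.table.loc["grp:tp", "SS"] == pytest.approx(0.5)
        assert res.table.loc["tp", "SS_error"] == pytest.approx(0.0)
        assert res.table.loc["tp", "degenerate_error"]

    def test_two_level_within_epsilon_is_exactly_one(self):
        rng = np.random.default_rng(1)
        df = _long(["A"] * 6 + ["B"] * 6, rng.standard_normal((12, 2)))
        res = st.mixed_rm_anova(df, dv="y", subject="subj", between="grp",
                                within=("tp",))
        assert res.table.loc["tp", "eps"] == 1.0

    def test_ss_decomposition_is_exhaustive(self):
        rng = np.random.default_rng(2)
        df = _long(["A"] * 8 + ["B"] * 8, rng.standard_normal((16, 4)))
        res = st.mixed_rm_anova(df, dv="y", subject="subj", between="grp",
                                within=("tp",))
        wide = df.pivot_table(index="subj", columns="tp", values="y")
        total_ss = float(((wide - wide.to_numpy().mean()) ** 2).to_numpy().sum())
        # effects plus the unique error strata (between-subject error is
        # carried on the group row) must account for the total
        err = res.table.drop_duplicates("SS_error")["SS_error"].sum()
        decomposed = res.table["SS"].sum() + err
        assert decomposed == pytest.approx(total_ss, rel=1e-8)

    def test_listwise_deletion_of_incomplete_subjects(self):
        rng = np.random.default_rng(3)
        df = _long(["A"] * 5 + ["B"] * 5, rng.standard_normal((10, 3)))
        df = df.drop(df[(df.subj == "s0") & (df.tp == "t2")].index)
        res = st.mixed_rm_anova(df, dv="y", subject="subj", between="grp",
                                within=("tp",))
        assert res.n_subjects == 9 and res.n_dropped == 1


class TestMixedAnovaVsPingouin:
    def _data(self):
        rng = np.random.default_rng(42)
        rows = []
        for g, n in (("A", 9), ("B", 12)):
            for i in range(n):
                base = rng.normal()
                for j, tp in enumerate(["t1", "t2", "t3", "t4"]):
                    rows.append({"subj": f"{g}{i}", "grp": g, "tp": tp,
                                 "y": base + 0.3 * j * (g == "A") + rng.normal()})
        return pd.DataFrame(rows)

    def test_f_and_p_match_independent_implementation(self):
        pg = pytest.importorskip("pingouin")
        df = self._data()
        res = st.mixed_rm_anova(df, dv="y", subject="subj", between="grp",
                                within=("tp",))
        ref = pg.mixed_anova(data=df, dv="y", within="tp", subject="subj",
                             between="grp", correction=True).set_index("Source")
        for mine, theirs in (("grp", "grp"), ("tp", "tp"),
                             ("grp:tp", "Interaction")):
            assert res.table.loc[mine, "F"] == pytest.approx(
                ref.loc[theirs, "F"], rel=1e-8)
            assert res.table.loc[mine, "p"] == pytest.approx(
                ref.loc[theirs, "p_unc"], rel=1e-8)
            assert res.table.loc[mine, "SS"] == pytest.approx(
                ref.loc[theirs, "SS"], rel=1e-8)
        # epsilon conventions differ (pooled within-group vs total
        # covariance) but must agree closely
        assert res.table.loc["tp", "eps"] == pytest.approx(
            float(ref.loc["tp", "eps"]), abs=0.02)


class TestMixedAnovaVsRAov:
    """Frozen oracle: R aov(y ~ grp*w1*w2 + Error(subj/(w1*w2))) on the
    dataset reconstructed below printed these F values."""

    R_F = {"grp": 0.592081, "w1": 21.690782, "grp:w1": 0.007436,
           "w2": 4.029726, "grp:w2": 1.139325, "w1:w2": 1.048812,
           "grp:w1:w2": 0.369611}
    R_P = {"grp": 0.461332, "w1": 0.001190, "w2": 0.035790}

    def _data(self):
        rng = np.random.default_rng(123)
        rows = []
        for g, n in (("A", 5), ("B", 6)):
            for i in range(n):
                b = rng.normal()
                for w1 in ("x", "y"):
                    for w2 in ("p", "q", "r"):
                        rows.append({"subj": f"{g}{i}", "grp": g, "w1": w1,
                                     "w2": w2, "y": b + 0.5 * (w1 == "x")
                                     + 0.3 * (w2 == "q") + rng.normal() * 0.8})
        return pd.DataFrame(rows)

    def test_two_within_factor_design_matches_r(self):
        res = st.mixed_rm_anova(self._data(), dv="y", subject="subj",
                                between="grp", within=("w1", "w2"))
        for eff, f_ref in self.R_F.items():
            assert res.table.loc[eff, "F"] == pytest.approx(f_ref, abs=5e-6)
        for eff, p_ref in self.R_P.items():
            assert res.table.loc[eff, "p"] == pytest.approx(p_ref, abs=5e-6)


class TestPlannedContrasts:
    def test_identical_pre_post_gives_t0_p1(self):
        df = _long(["A"] * 4, [[1.0, 1.0]] * 4, times=["pre", "post15"])
        df = df.rename(columns={"grp": "group", "tp": "time_point", "y": "rcs"})
        out = st.planned_contrasts(df, dv="rcs", subject="subj")
        assert out["t"].iloc[0] == 0.0 and out["p"].iloc[0] == 1.0

    def test_constant_shift_zero_variance_flagged_degenerate(self):
        df = _long(["A"] * 4, [[1.0, 2.0]] * 4, times=["pre", "post15"])
        df = df.rename(columns={"grp": "group", "tp": "time_point", "y": "rcs"})
        out = st.planned_contrasts(df, dv="rcs", subject="subj")
        assert out["degenerate"].iloc[0]
        assert np.isinf(out["t"].iloc[0])

    def test_bonferroni_is_monotone_and_capped(self):
        rng = np.random.default_rng(4)
        df = _long(["A"] * 8, rng.standard_normal((8, 4)),
                   times=["pre", "post15", "post30", "post45"])
        df = df.rename(columns={"grp": "group", "tp": "time_point", "y": "rcs"})
        out = st.planned_contrasts(df, dv="rcs", subject="subj")
        assert (out["p_bonf"] >= out["p"] - 1e-15).all()
        assert (out["p_bonf"] <= 1.0).all()

    def test_matches_scipy_paired_ttest(self):
        from scipy import stats as sps
        rng = np.random.default_rng(5)
        vals = rng.standard_normal((10, 2)) + [0, 0.5]
        df = _long(["A"] * 10, vals, times=["pre", "post15"])
        df = df.rename(columns={"grp": "group", "tp": "time_point", "y": "rcs"})
        out = st.planned_contrasts(df, dv="rcs", subject="subj")
        ref = sps.ttest_rel(vals[:, 1], vals[:, 0])
        assert out["t"].iloc[0] == pytest.approx(ref.statistic, rel=1e-10)
        assert out["p"].iloc[0] == pytest.approx(ref.pvalue, rel=1e-10)


class TestWelchPairwise:
    def test_identical_cells_t_zero(self):
        df = pd.DataFrame({"cell": ["a"] * 5 + ["b"] * 5, "y": [1.0] * 10})
        out = st.welch_pairwise_emmeans(df, dv="y", cell_col="cell")
        assert out["t"].iloc[0] == 0.0 and out["degenerate"].iloc[0]

    def test_matches_closed_form_welch(self):
        rng = np.random.default_rng(6)
        xa = rng.normal(0, 1, 50)
        xb = rng.normal(1, 1, 50)
        df = pd.DataFrame({"cell": ["a"] * 50 + ["b"] * 50,
                           "y": np.concatenate([xa, xb])})
        out = st.welch_pairwise_emmeans(df, dv="y", cell_col="cell")
        # textbook Welch formula as the oracle
        va, vb = xa.var(ddof=1) / 50, xb.var(ddof=1) / 50
        t_ref = (xa.mean() - xb.mean()) / np.sqrt(va + vb)
        df_ref = (va + vb) ** 2 / (va ** 2 / 49 + vb ** 2 / 49)
        assert out["t"].iloc[0] == pytest.approx(t_ref, abs=1e-8)
        assert out["df"].iloc[0] == pytest.approx(df_ref, abs=1e-6)

    def test_pair_count_is_k_choose_2(self):
        rng = np.random.default_rng(7)
        k = 5
        df = pd.DataFrame({"cell": np.repeat([f"c{i}" for i in range(k)], 4),
                           "y": rng.standard_normal(4 * k)})
        out = st.welch_pairwise_emmeans(df, dv="y", cell_col="cell")
        assert len(out) == k * (k - 1) // 2

    def test_subject_averaging_gives_emmeans(self):
        # two observations per subject per cell; pairwise test must act
        # on the per-subject means
        df = pd.DataFrame({
            "subj": ["s1", "s1", "s2", "s2"] * 2,
            "cell": ["a"] * 4 + ["b"] * 4,
            "y": [0.0, 2.0, 1.0, 3.0, 4.0, 6.0, 5.0, 7.0],
        })
        out = st.welch_pairwise_emmeans(df, dv="y", cell_col="cell", subject="subj")
        assert out["mean_a"].iloc[0] == pytest.approx(1.5)
        assert out["mean_b"].iloc[0] == pytest.approx(5.5)
        assert out["n_a"].iloc[0] == 2


class TestForcedEntryRegression:
    def test_exact_linear_response_r2_one(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal((30, 2))
        df = pd.DataFrame({"x1": x[:, 0], "x2": x[:, 1],
                           "y": 2.0 * x[:, 0] - 1.0 * x[:, 1] + 3.0})
        res = st.forced_entry_regression(df, "y", ("x1", "x2"))
        assert res.r2 == pytest.approx(1.0)
        assert res.adj_r2 == pytest.approx(1.0)
        assert res.table.loc["x1", "B"] == pytest.approx(2.0)

    def test_three_point_perfect_fit(self):
        df = pd.DataFrame({"x": [0.0, 1.0, 2.0], "y": [0.0, 1.0, 2.0]})
        res = st.forced_entry_regression(df, "y", ("x",))
        assert res.table.loc["x", "B"] == pytest.approx(1.0)

    def test_beta_is_b_scaled_by_sd_ratio(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame({"x": 5 * rng.standard_normal(100)})
        df["y"] = 0.4 * df["x"] + rng.standard_normal(100)
        res = st.forced_entry_regression(df, "y", ("x",))
        expected = res.table.loc["x", "B"] * df["x"].std() / df["y"].std()
        assert res.table.loc["x", "beta"] == pytest.approx(expected, rel=1e-10)

    def test_null_predictors_small_betas(self):
        """With a response independent of all predictors, standardized
        coefficients stay near zero and the model F is rarely significant."""
        rng = np.random.default_rng(10)
        small, nonsig = 0, 0
        reps = 50
        for _ in range(reps):
            df = pd.DataFrame(rng.standard_normal((1000, 4)),
                              columns=["y", "x1", "x2", "x3"])
            res = st.forced_entry_regression(df, "y", ("x1", "x2", "x3"))
            small += int((res.table["beta"].abs() < 0.1).all())
            nonsig += int(res.p > 0.05)
        assert small >= 0.9 * reps
        assert nonsig >= 0.85 * reps

    def test_collinear_predictors_named(self):
        df = pd.DataFrame({"x1": [1.0, 2, 3, 4, 5, 6], "y": [0.0, 1, 2, 3, 4, 5]})
        df["x2"] = 2 * df["x1"]
        with pytest.raises(st.StatsError, match="x1|x2"):
            st.forced_entry_regression(df, "y", ("x1", "x2"))

    def test_too_few_observations_raise(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "y": [1.0, 2.0]})
        with pytest.raises(st.StatsError):
            st.forced_entry_regression(df, "y", ("x",))
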