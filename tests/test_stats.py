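import numpy as np
import pandas as pd
import pingouin as pg
import pytest

from filmgaze import (
    ContingencyTable,
    NotComputableError,
    cell_count_guard,
    cohen_kappa,
    cohens_d,
    mixed_anova,
    pearson_chi2,
    posthoc_pairwise,
)

from .oracles import glm_mixed_anova


def long_data(rng, n_groups, n_subjects, n_shots, group_shift=0.0, noise=1.0):
    rows = []
    for gi in range(n_groups):
        for si in range(n_subjects):
            subj = f"g{gi}s{si}"
            for k in range(n_shots):
                rows.append(
                    (subj, f"g{gi}", k + 1, gi * group_shift + noise * rng.standard_normal())
                )
    return pd.DataFrame(rows, columns=["participant", "group", "shot", "value"])


class TestPearsonChi2:
    def test_symmetric_table_gives_zero(self):
        res = pearson_chi2(ContingencyTable(np.array([[10, 10], [10, 10]])))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_agrees_with_hand_formula_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            t = rng.integers(1, 51, size=(2, 2))
            res = pearson_chi2(ContingencyTable(t))
            n = t.sum()
            expected = np.outer(t.sum(1), t.sum(0)) / n
            stat = ((t - expected) ** 2 / expected).sum()
            assert abs(res.statistic - stat) < 1e-10

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            pearson_chi2(ContingencyTable(np.array([[0, 0], [5, 5]])))

    def test_guard_blocks_small_cells_when_enabled(self):
        t = ContingencyTable(np.array([[3, 41], [0, 44]]))
        with pytest.raises(NotComputableError):
            pearson_chi2(t, guard_threshold=5)
        # explicit override: no guard, statistic computed
        assert pearson_chi2(t).statistic > 0

    def test_continuity_correction_available(self):
        t = ContingencyTable(np.array([[40, 9], [24, 25]]))
        plain = pearson_chi2(t).statistic
        corrected = pearson_chi2(t, correction=True).statistic
        assert corrected < plain


class TestCellCountGuard:
    def test_sparse_segmentation_counts_fail(self):
        # 3 vs 0 segmenters out of 44 per condition
        t = ContingencyTable(
            np.array([[3, 41], [0, 44]]),
            row_labels=["context", "no-context"],
            col_labels=["segmented", "did not"],
        )
        guard = cell_count_guard(t)
        assert not guard
        assert "<= 5" in guard.reason

    def test_all_cells_above_threshold_pass(self):
        assert cell_count_guard(ContingencyTable(np.array([[6, 6], [6, 6]])))

    def test_threshold_zero_only_fails_empty_cells(self):
        assert cell_count_guard(ContingencyTable(np.array([[1, 1], [1, 1]])), threshold=0)
        assert not cell_count_guard(ContingencyTable(np.array([[1, 0], [1, 1]])), threshold=0)


class TestCohenKappa:
    def test_perfect_agreement(self):
        codes = ["a", "b", "a", "c", "b"]
        assert cohen_kappa(codes, codes) == 1.0

    def test_independent_coders_near_zero(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 2, 10_000)
        b = rng.integers(0, 2, 10_000)
        assert abs(cohen_kappa(a, b)) < 0.03

    def test_hand_built_agreement_table(self):
        # coder A: 45 yes / 5 no; B agrees on 48 items (one disagreement each way)
        # p_o = 0.96, p_e = 0.81 + 0.01 = 0.82, kappa = 0.14/0.18 = 7/9
        a = ["yes"] * 45 + ["no"] * 5
        b = ["yes"] * 44 + ["no"] + ["yes"] + ["no"] * 4
        assert cohen_kappa(a, b) == pytest.approx(7 / 9, abs=1e-12)

    def test_constant_identical_coders_convention(self):
        with pytest.warns(UserWarning, match="convention"):
            assert cohen_kappa(["x", "x"], ["x", "x"]) == 1.0


class TestMixedAnova:
    def test_degenerate_constant_data(self):
        df = long_data(np.random.default_rng(0), 2, 3, 4, noise=0.0)
        res = mixed_anova(df)
        assert res.attrs["degenerate"]
        assert res["F"].isna().all()
        assert (res["note"] == "degenerate: zero total variance").all()

    def test_pure_group_shift_gives_infinite_between_f(self):
        df = long_data(np.random.default_rng(0), 2, 3, 4, group_shift=1.0, noise=0.0)
        res = mixed_anova(df).set_index("effect")
        assert np.isinf(res.loc["group", "F"])
        assert res.loc["group x shot", "ss"] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("sizes", [(4, 4), (3, 5, 7)])
    def test_matches_glm_projection_oracle(self, sizes):
        rng = np.random.default_rng(42)
        rows = []
        for gi, n in enumerate(sizes):
            for si in range(n):
                for k in range(3):
                    rows.append((f"g{gi}s{si}", f"g{gi}", k, rng.standard_normal()))
        df = pd.DataFrame(rows, columns=["participant", "group", "shot", "value"])
        res = mixed_anova(df).set_index("effect")
        oracle = glm_mixed_anova(df)
        part = res.attrs["ss_partition"]
        for key in ("ss_between_groups", "ss_subjects_within_groups",
                    "ss_within_factor", "ss_interaction", "ss_error"):
            assert part[key] == pytest.approx(oracle[key], abs=1e-8)
        assert res.loc["group", "F"] == pytest.approx(oracle["F_between"], abs=1e-8)
        assert res.loc["shot", "F"] == pytest.approx(oracle["F_within"], abs=1e-8)
        assert res.loc["group x shot", "F"] == pytest.approx(
            oracle["F_interaction"], abs=1e-8
        )

    def test_ss_partition_is_additive(self):
        df = long_data(np.random.default_rng(3), 3, 5, 6, group_shift=0.4)
        part = mixed_anova(df).attrs["ss_partition"]
        total = (
            part["ss_between_groups"]
            + part["ss_subjects_within_groups"]
            + part["ss_within_factor"]
            + part["ss_interaction"]
            + part["ss_error"]
        )
        assert total == pytest.approx(part["ss_total"], abs=1e-8)

    def test_agrees_with_pingouin(self):
        df = long_data(np.random.default_rng(9), 3, 6, 4, group_shift=0.5)
        res = mixed_anova(df).set_index("effect")
        pg_res = pg.mixed_anova(
            df, dv="value", between="group", within="shot", subject="participant"
        ).set_index("Source")
        assert res.loc["group", "F"] == pytest.approx(pg_res.loc["group", "F"], rel=1e-6)
        assert res.loc["shot", "F"] == pytest.approx(pg_res.loc["shot", "F"], rel=1e-6)
        assert res.loc["group x shot", "F"] == pytest.approx(
            pg_res.loc["Interaction", "F"], rel=1e-6
        )
        assert res.loc["group", "partial_eta_sq"] == pytest.approx(
            pg_res.loc["group", "np2"], rel=1e-6
        )

    def test_reported_df_match_design(self):
        # 3 groups x 6 shots, unequal n summing to 166 subjects: the classic
        # split-plot df are (2, 163) between and (5, 815) within
        rng = np.random.default_rng(5)
        rows = []
        for gi, n in enumerate((79, 61, 26)):
            for si in range(n):
                for k in range(6):
                    rows.append((f"g{gi}s{si}", f"g{gi}", k, rng.standard_normal()))
        df = pd.DataFrame(rows, columns=["participant", "group", "shot", "value"])
        res = mixed_anova(df).set_index("effect")
        assert (res.loc["group", "df1"], res.loc["group", "df2"]) == (2, 163)
        assert (res.loc["shot", "df1"], res.loc["shot", "df2"]) == (5, 815)
        assert (res.loc["group x shot", "df1"], res.loc["group x shot", "df2"]) == (10, 815)

    def test_unbalanced_within_rejected(self):
        df = long_data(np.random.default_rng(0), 2, 3, 4)
        df = df.drop(index=0)
        with pytest.raises(ValueError, match="unbalanced"):
            mixed_anova(df)


class TestPosthocPairwise:
    def test_identical_groups(self):
        rng = np.random.default_rng(0)
        vals = rng.standard_normal(10)
        df = pd.DataFrame(
            {"group": ["a"] * 10 + ["b"] * 10, "value": np.concatenate([vals, vals])}
        )
        res = posthoc_pairwise(df)
        assert res["t"].iloc[0] == 0.0
        assert res["cohen_d"].iloc[0] == 0.0
        assert res["p_adj"].iloc[0] == 1.0

    def test_bonferroni_multiplies_by_family_size(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            {
                "group": np.repeat(["a", "b", "c"], 12),
                "value": rng.standard_normal(36),
            }
        )
        res = posthoc_pairwise(df)
        assert len(res) == 3
        np.testing.assert_allclose(res["p_adj"], np.minimum(1.0, res["p"] * 3))

    def test_cohens_d_recovers_unit_effect(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            x = rng.normal(1.0, 1.0, 10_000)
            y = rng.normal(0.0, 1.0, 10_000)
            assert cohens_d(x, y) == pytest.approx(1.0, abs=0.05)

    def test_small_group_skipped_with_reason(self):
        df = pd.DataFrame({"group": ["a", "b", "b", "b"], "value": [1.0, 2.0, 3.0, 4.0]})
        res = posthoc_pairwise(df)
        assert "skipped" in res["note"].iloc[0]
        assert np.isnan(res["t"].iloc[0])

    def test_welch_variant_differs_under_unequal_variance(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(
            {
                "group": np.repeat(["a", "b"], 30),
                "value": np.concatenate(
                    [rng.normal(0, 0.5, 30), rng.normal(1, 3.0, 30)]
                ),
            }
        )
        pooled = posthoc_pairwise(df, equal_var=True)["df"].iloc[0]
        welch = posthoc_pairwise(df, equal_var=False)["df"].iloc[0]
        assert welch < pooled
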