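"""Normality gate, gated comparisons, dual-control policy, pooling, ddCt."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from drosoquant import stats
from drosoquant.stats import GroupSet


class TestNormalityGate:
    def test_gaussian_groups_take_parametric_branch(self):
        rng = np.random.default_rng(42)
        gs = GroupSet(
            {"a": rng.normal(0, 1, 20), "b": rng.normal(0, 1, 20)}, "a"
        )
        branch, details = stats.normality_gate(gs)
        assert branch == "parametric"
        assert all(p > 0.05 for p in details["shapiro_p"].values())
        assert details["levene_p"] > 0.05

    def test_skewed_group_forces_nonparametric_branch(self):
        rng = np.random.default_rng(7)
        gs = GroupSet(
            {"a": rng.normal(0, 1, 30), "b": rng.exponential(1.0, 30) ** 2}, "a"
        )
        branch, details = stats.normality_gate(gs)
        assert branch == "nonparametric"
        assert details["shapiro_p"]["b"] <= 0.05

    def test_constant_group_warns_and_goes_nonparametric(self):
        gs = GroupSet({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]}, "a")
        with pytest.warns(UserWarning, match="zero-variance"):
            branch, details = stats.normality_gate(gs)
        assert branch == "nonparametric"
        assert details["degenerate_groups"] == ["a"]

    def test_tiny_group_rejected(self):
        gs = GroupSet({"a": [1.0, 2.0], "b": [1.0, 2.0, 3.0]}, "a")
        with pytest.raises(ValueError, match="too small"):
            stats.normality_gate(gs)

    def test_gate_matches_reference_implementations(self):
        rng = np.random.default_rng(3)
        groups = {
            "a": rng.normal(5, 1, 15),
            "b": rng.normal(5, 1, 15),
            "c": rng.normal(5, 3, 15),
        }
        gs = GroupSet(groups, "a", design="multi_group_vs_reference")
        _, details = stats.normality_gate(gs)
        for k, vals in groups.items():
            assert details["shapiro_p"][k] == pytest.approx(
                sps.shapiro(vals).pvalue
            )
        assert details["levene_p"] == pytest.approx(
            sps.levene(*groups.values(), center="median").pvalue
        )


class TestCompare:
    def test_identical_groups_not_significant(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        gs = GroupSet({"exp": vals, "ctrl": vals}, "ctrl")
        res = stats.compare(gs)
        assert res.p_values["exp"] > 0.9
        assert not res.significant["exp"]

    def test_separated_supports_hit_exact_enumeration_minimum(self):
        # a heavily skewed group forces the nonparametric branch; full
        # separation at n=10 gives the smallest achievable two-sided
        # exact Mann-Whitney p: 2 / C(20,10)
        low = [1.0, 1.1, 1.2, 1.3, 1.4, 1.5, 1.6, 1.7, 1.8, 50.0]
        high = [100.0 + i for i in range(10)]
        gs = GroupSet({"exp": high, "ctrl": low}, "ctrl")
        res = stats.compare(gs)
        assert res.branch == "nonparametric"
        assert res.tests_used == ["mann_whitney"]
        assert res.p_values["exp"] == pytest.approx(2 / math.comb(20, 10))

    def test_parametric_two_group_uses_t_test(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 20), rng.normal(2, 1, 20)
        gs = GroupSet({"exp": b, "ctrl": a}, "ctrl")
        res = stats.compare(gs)
        assert res.branch == "parametric"
        assert res.p_values["exp"] == pytest.approx(sps.ttest_ind(b, a).pvalue)

    def test_multi_group_parametric_reports_holm_sidak_adjusted(self):
        rng = np.random.default_rng(9)
        groups = {
            "ctrl": rng.normal(0, 1, 15),
            "g1": rng.normal(0, 1, 15),
            "g2": rng.normal(2, 1, 15),
        }
        gs = GroupSet(groups, "ctrl", design="multi_group_vs_reference")
        res = stats.compare(gs)
        assert res.branch == "parametric"
        assert set(res.p_values) == {"g1", "g2"}
        raw = [
            sps.ttest_ind(groups[k], groups["ctrl"]).pvalue for k in ("g1", "g2")
        ]
        from statsmodels.stats.multitest import multipletests

        expected = multipletests(raw, method="holm-sidak")[1]
        assert res.p_values["g1"] == pytest.approx(expected[0])
        assert res.p_values["g2"] == pytest.approx(expected[1])

    def test_multi_group_nonparametric_uses_kruskal_and_dunn(self):
        rng = np.random.default_rng(10)
        groups = {
            "ctrl": rng.exponential(1, 15),
            "g1": rng.exponential(1, 15) ** 3,
            "g2": rng.exponential(4, 15) ** 3,
        }
        gs = GroupSet(groups, "ctrl", design="multi_group_vs_reference")
        res = stats.compare(gs)
        assert res.branch == "nonparametric"
        assert res.tests_used == ["kruskal_wallis", "dunn_vs_reference"]
        assert res.omnibus_p == pytest.approx(
            sps.kruskal(*groups.values()).pvalue
        )


class TestDunn:
    def test_hand_computed_no_tie_example(self):
        # ref {1,2,3}, g {4,5,6}: mean ranks 2 and 5, var term 6*7/12,
        # z = 3 / sqrt(3.5 * 2/3), p = 2 * (1 - Phi(z))
        gs = GroupSet(
            {"ref": [1.0, 2.0, 3.0], "g": [4.0, 5.0, 6.0]},
            "ref",
            design="multi_group_vs_reference",
        )
        p = stats.dunn_vs_reference(gs, p_adjust="none")["g"]
        z = 3.0 / math.sqrt((6 * 7 / 12) * (2 / 3))
        assert p == pytest.approx(2 * sps.norm.sf(z))

    def test_tie_correction_applied(self):
        # all values tied -> zero variance contribution from ranks is
        # fully corrected; mean-rank difference is 0 so p = 1
        gs = GroupSet(
            {"ref": [5.0, 5.0, 5.0], "g": [5.0, 5.0, 5.0]},
            "ref",
            design="multi_group_vs_reference",
        )
        # var term: N(N+1)/12 - (t^3 - t)/(12 (N-1)) with one tie group t=6
        assert stats._tie_correction(np.array([5.0] * 6)) == pytest.approx(
            (216 - 6) / (12 * 5)
        )
        p = stats.dunn_vs_reference(gs, p_adjust="none")["g"]
        assert p == pytest.approx(1.0)


class TestConservativeP:
    def test_most_conservative_p_reported(self):
        assert stats.conservative_p(0.01, 0.20) == (0.20, False)

    def test_both_below_alpha_is_significant(self):
        assert stats.conservative_p(0.03, 0.04) == (0.04, True)

    def test_boundary_not_significant(self):
        assert stats.conservative_p(0.05, 0.01) == (0.05, False)

    def test_commutative_and_idempotent(self, rng):
        for _ in range(50):
            pa, pb = rng.random(2)
            ab = stats.conservative_p(pa, pb)
            assert ab == stats.conservative_p(pb, pa)
            assert stats.conservative_p(ab[0], ab[0])[0] == ab[0]

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            stats.conservative_p(1.2, 0.5)


class TestNormalizeAndPool:
    def _frame(self):
        return pd.DataFrame(
            {
                "experiment": ["A"] * 4 + ["B"] * 4,
                "group": ["ctrl", "ctrl", "exp", "exp"] * 2,
                "value": [1.0, 3.0, 2.0, 4.0, 10.0, 10.0, 10.0, 30.0],
            }
        )

    def test_each_experiment_divided_by_its_control_mean(self):
        out = stats.normalize_and_pool(self._frame(), "ctrl")
        exp_vals = out.loc[out["group"] == "exp", "normalized"].tolist()
        assert exp_vals == [1.0, 2.0, 1.0, 3.0]
        for _, sub in out.groupby("experiment"):
            assert sub.loc[sub["group"] == "ctrl", "normalized"].mean() == 1.0

    def test_missing_control_error_names_experiment(self):
        df = self._frame()
        df = df[~((df["experiment"] == "B") & (df["group"] == "ctrl"))]
        with pytest.raises(ValueError, match="'B'"):
            stats.normalize_and_pool(df, "ctrl")

    def test_within_experiment_ratios_preserved(self, rng):
        df = pd.DataFrame(
            {
                "experiment": ["E"] * 6,
                "group": ["ctrl"] * 3 + ["exp"] * 3,
                "value": rng.uniform(1, 9, 6),
            }
        )
        out = stats.normalize_and_pool(df, "ctrl")
        ratio_raw = df["value"].iloc[4] / df["value"].iloc[1]
        ratio_norm = out["normalized"].iloc[4] / out["normalized"].iloc[1]
        assert ratio_norm == pytest.approx(ratio_raw)


class TestQpcrDdct:
    def _table(self):
        return pd.DataFrame(
            {
                "condition": ["control", "control", "induced", "induced"],
                "ct_target": [20.0, 21.0, 22.5, 23.5],
                "ct_reference": [15.0, 16.0, 15.0, 16.0],
            }
        )

    def test_induced_at_control_mean_dct_gives_unity(self):
        df = pd.DataFrame(
            {
                "condition": ["control", "control", "induced"],
                "ct_target": [20.0, 20.0, 18.0],
                "ct_reference": [15.0, 15.0, 13.0],
            }
        )
        out = stats.qpcr_ddct(df)
        assert out.loc[2, "rel_expression"] == 1.0

    def test_one_cycle_ddct_halves_expression(self):
        out = stats.qpcr_ddct(self._table())
        # induced dCt = 7.5 each; control mean dCt = 5 -> ddCt 2.5
        assert np.allclose(out.loc[out["condition"] == "induced", "ddct"], 2.5)
        df = self._table()
        df.loc[2:, "ct_target"] = [21.0, 22.0]  # ddCt exactly 1
        out = stats.qpcr_ddct(df)
        assert np.allclose(
            out.loc[out["condition"] == "induced", "rel_expression"], 0.5
        )

    def test_four_sample_table_matches_hand_calculation(self):
        out = stats.qpcr_ddct(self._table())
        # dCt = [5, 5, 7.5, 7.5]; control mean 5; expression 2^-ddCt
        assert out["rel_expression"].tolist() == [1.0, 1.0, 2.0**-2.5, 2.0**-2.5]

    def test_control_mean_expression_unity_for_balanced_controls(self):
        out = stats.qpcr_ddct(self._table())
        ctrl = out.loc[out["condition"] == "control", "rel_expression"]
        assert ctrl.mean() == pytest.approx(1.0)

    def test_invariant_to_common_ct_shift(self):
        df = self._table()
        shifted = df.copy()
        shifted.loc[1, ["ct_target", "ct_reference"]] += 3.0
        assert np.allclose(
            stats.qpcr_ddct(df)["rel_expression"],
            stats.qpcr_ddct(shifted)["rel_expression"],
        )

    def test_missing_reference_rejected(self):
        df = self._table()
        df.loc[0, "ct_reference"] = np.nan
        with pytest.raises(ValueError, match="reference"):
            stats.qpcr_ddct(df)
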