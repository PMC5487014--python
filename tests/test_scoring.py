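"""Unit and property tests for the seven-equation scoring chain and plan rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import oracle_scores, random_instance

from dataplan.ema import ComplianceRecord, DiagnosisRecord
from dataplan.exceptions import (
    DegenerateInputWarning,
    DegenerateSeverityError,
    EmptyModelError,
    IdentifierMismatchError,
    SchemaError,
    ValidationError,
)
from dataplan.scoring import (
    DynamicModel,
    FactorSolution,
    ItemModuleMatrix,
    ItemStats,
    ScoreTable,
    TreatmentPlan,
    build_plan,
    compute_scores,
    module_scores,
    normalize,
    raw_factor_scores,
    raw_item_scores,
    variance_explained,
)


def make_solution(loadings, pct, items=None, factors=None):
    items = items or [f"i{n}" for n in range(len(loadings))]
    factors = factors or [f"F{n}" for n in range(len(loadings[0]))]
    return FactorSolution(
        loadings=pd.DataFrame(loadings, index=items, columns=factors),
        pct_variance=pd.Series(pct, index=factors),
    )


def make_dynamics(paths, factors=None, retained=None):
    factors = factors or [f"F{n}" for n in range(len(paths))]
    frame = pd.DataFrame(paths, index=factors, columns=factors)
    mask = None if retained is None else pd.DataFrame(retained, index=factors, columns=factors)
    return DynamicModel(paths=frame, retained=mask)


class TestRawFactorScores:
    def test_printed_worked_example(self):
        """A factor with 30% variance share, AR .58 and one .26 cross among
        three factors scores .30 x (.58^2 + .26^2) / 3 = 0.0404."""
        sol3 = make_solution(
            [[0.9, np.nan, np.nan], [np.nan, 0.8, np.nan], [np.nan, np.nan, 0.7]],
            [0.30, 0.24, 0.22],
        )
        dyn3 = make_dynamics(
            [[0.58, 0.26, 0.0], [0.0, 0.4, 0.0], [0.0, 0.0, 0.64]],
            retained=[[True, True, False], [False, True, False], [False, False, True]],
        )
        scores = raw_factor_scores(sol3, dyn3)
        assert scores.iloc[0] == pytest.approx(0.30 * (0.58**2 + 0.26**2) / 3, abs=1e-12)
        assert scores.iloc[0] == pytest.approx(0.0404, abs=1e-10)

    def test_zero_variance_share_annihilates(self):
        sol = make_solution([[0.9, np.nan], [np.nan, 0.8]], [0.0, 0.5])
        dyn = make_dynamics([[0.9, 0.5], [0.3, 0.9]])
        assert raw_factor_scores(sol, dyn).iloc[0] == 0.0

    def test_identity_case_single_factor(self):
        p = 0.37
        sol = make_solution([[1.0]], [p])
        dyn = make_dynamics([[1.0]])
        assert raw_factor_scores(sol, dyn).iloc[0] == pytest.approx(p)

    def test_only_retained_crosses_count(self):
        sol = make_solution([[0.9, np.nan], [np.nan, 0.8]], [0.4, 0.3])
        dyn_all = make_dynamics([[0.5, 0.4], [0.0, 0.5]])
        dyn_pruned = make_dynamics(
            [[0.5, 0.4], [0.0, 0.5]],
            retained=[[True, False], [False, True]],
        )
        full = raw_factor_scores(sol, dyn_all)
        pruned = raw_factor_scores(sol, dyn_pruned)
        assert pruned.iloc[0] == pytest.approx(0.4 * 0.25 / 2)
        assert full.iloc[0] > pruned.iloc[0]

    def test_mismatched_factors_raise(self):
        sol = make_solution([[0.9]], [0.3], factors=["A"])
        dyn = make_dynamics([[0.5]], factors=["B"])
        with pytest.raises(IdentifierMismatchError):
            raw_factor_scores(sol, dyn)

    def test_empty_model_raises(self):
        sol = make_solution([[0.9]], [0.3])
        object.__setattr__(sol, "loadings", sol.loadings.iloc[:, :0])
        object.__setattr__(sol, "pct_variance", sol.pct_variance.iloc[:0])
        dyn = make_dynamics(np.zeros((0, 0)), factors=[])
        with pytest.raises(EmptyModelError):
            raw_factor_scores(sol, dyn)


class TestNormalize:
    def test_strongest_maps_to_one(self):
        out = normalize(pd.Series({"a": 0.0404, "b": 0.0128, "c": 0.03}))
        assert out["a"] == 1.0
        assert out.idxmax() == "a"

    def test_all_equal_inputs(self):
        out = normalize(pd.Series([0.3, 0.3, 0.3]))
        assert (out == 1.0).all()

    def test_all_zero_flags_degenerate(self):
        with pytest.warns(DegenerateInputWarning):
            out = normalize(pd.Series([0.0, 0.0]))
        assert (out == 0.0).all()

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            normalize(pd.Series([0.1, -0.2]))

    @given(st.lists(st.floats(min_value=1e-6, max_value=1e6), min_size=1, max_size=10))
    @settings(max_examples=100, derandomize=True)
    def test_maximum_is_exactly_one(self, values):
        out = normalize(pd.Series(values))
        assert abs(out.max() - 1.0) < 1e-12


class TestRawItemScores:
    def test_printed_anhedonia_case(self):
        """Normalized mean .67 and loading .42 on the strongest factor
        (normalized score 1) gives .67 x .42 = .2814."""
        sol = make_solution([[0.42], [0.9]], [0.3], items=["anhedonia", "other"])
        fs_norm = pd.Series({"F0": 1.0})
        stats = ItemStats(means=pd.Series({"anhedonia": 67.0, "other": 100.0}))
        scores = raw_item_scores(sol, fs_norm, stats)
        assert scores["anhedonia"] == pytest.approx(0.67 * 0.42, abs=1e-12)

    def test_zero_mean_scores_zero(self):
        sol = make_solution([[0.5], [0.5]], [0.3])
        stats = ItemStats(means=pd.Series({"i0": 0.0, "i1": 50.0}))
        assert raw_item_scores(sol, pd.Series({"F0": 1.0}), stats)["i0"] == 0.0

    def test_two_factor_sum(self):
        sol = make_solution([[0.5, 0.5]], [0.3, 0.3])
        stats = ItemStats(means=pd.Series({"i0": 80.0}))
        fs_norm = pd.Series({"F0": 1.0, "F1": 1.0})
        assert raw_item_scores(sol, fs_norm, stats)["i0"] == pytest.approx(1.0)

    def test_degenerate_severity(self):
        sol = make_solution([[0.5]], [0.3])
        stats = ItemStats(means=pd.Series({"i0": 0.0}))
        with pytest.raises(DegenerateSeverityError):
            raw_item_scores(sol, pd.Series({"F0": 1.0}), stats)

    def test_missing_mean_raises(self):
        sol = make_solution([[0.5]], [0.3])
        stats = ItemStats(means=pd.Series({"elsewhere": 10.0}))
        with pytest.raises(SchemaError):
            raw_item_scores(sol, pd.Series({"F0": 1.0}), stats)


class TestModuleScores:
    def test_single_module_single_item(self):
        mm = ItemModuleMatrix(entries=pd.DataFrame({2: [1]}, index=["i0"]))
        _, _, final, _ = module_scores(pd.Series({"i0": 0.7}), mm)
        assert final[2] == 1.0

    def test_empty_module_scores_zero(self):
        mm = ItemModuleMatrix(entries=pd.DataFrame({2: [1], 3: [0]}, index=["i0"]))
        avg, sums, final, n = module_scores(pd.Series({"i0": 0.7}), mm)
        assert sums[3] == 0.0 and avg[3] == 0.0 and final[3] == 0.0 and n[3] == 0

    def test_breadth_vs_average_balance(self):
        """One strong item vs two middling: raw sums {1.0, 1.2} and averages
        {1.0, 0.6} balance to finals {0.9167, 0.8}."""
        mm = ItemModuleMatrix(
            entries=pd.DataFrame(
                {2: [1, 0, 0], 3: [0, 1, 1]}, index=["a", "b1", "b2"]
            )
        )
        isn = pd.Series({"a": 1.0, "b1": 0.6, "b2": 0.6})
        avg, sums, final, _ = module_scores(isn, mm)
        assert sums[2] == pytest.approx(1.0) and sums[3] == pytest.approx(1.2)
        assert final[2] == pytest.approx((1.0 + 1.0 / 1.2) / 2)
        assert final[3] == pytest.approx((0.6 + 1.0) / 2)
        assert final[2] > final[3]

    def test_unknown_present_items_raise(self):
        mm = ItemModuleMatrix(entries=pd.DataFrame({2: [1]}, index=["i0"]))
        with pytest.raises(SchemaError):
            module_scores(pd.Series({"i0": 0.5, "ghost": 0.5}), mm)


class TestBuildPlan:
    @staticmethod
    def table(finals):
        empty = pd.Series(dtype=float)
        return ScoreTable(
            raw_factor_scores=empty, norm_factor_scores=empty,
            raw_item_scores=empty, norm_item_scores=empty,
            item_avg_module=pd.Series(finals, dtype=float) * 0,
            raw_sum_module=pd.Series(finals, dtype=float) * 0,
            final_module=pd.Series(finals, dtype=float),
            n_items_present=pd.Series(finals, dtype=float) * 0,
        )

    def test_sort_and_zero_exclusion(self):
        scores = self.table({2: 0.9, 3: 0.8, 5: 0.85, 4: 0.0, 6: 0.3, 7: 0.0})
        plan = build_plan(scores, ComplianceRecord(96, 120), DiagnosisRecord(False))
        assert plan.ordered_modules == [2, 5, 3, 6]
        assert plan.plan_string == "2-5-3-6"

    def test_recurrent_appends_module8(self):
        scores = self.table({2: 0.9, 3: 0.5})
        plan = build_plan(scores, ComplianceRecord(120, 120), DiagnosisRecord(True))
        assert plan.ordered_modules[-1] == 8 and plan.included_module8

    def test_reminder_prepends_module1(self):
        scores = self.table({2: 0.9, 3: 0.5})
        rec = ComplianceRecord(120, 120, received_reminder=True)
        plan = build_plan(scores, rec, DiagnosisRecord(False))
        assert plan.ordered_modules[0] == 1 and plan.included_module1

    def test_low_compliance_prepends_module1(self):
        scores = self.table({2: 0.9})
        plan = build_plan(scores, ComplianceRecord(95, 120), DiagnosisRecord(False))
        assert plan.ordered_modules[0] == 1

    def test_boundary_compliance_excludes_module1(self):
        plan = build_plan(self.table({2: 0.9}), ComplianceRecord(96, 120), DiagnosisRecord(False))
        assert 1 not in plan.ordered_modules

    def test_slow_threshold_prepends_module1(self):
        rec = ComplianceRecord(110, 130, days_to_threshold=33)
        plan = build_plan(self.table({2: 0.9}), rec, DiagnosisRecord(False))
        assert plan.ordered_modules[0] == 1

    def test_ties_broken_by_module_number(self):
        plan = build_plan(self.table({5: 0.5, 3: 0.5, 2: 0.5}), None, None)
        assert plan.ordered_modules == [2, 3, 5]

    def test_all_zero_warns_not_silent(self):
        with pytest.warns(DegenerateInputWarning):
            plan = build_plan(self.table({2: 0.0, 3: 0.0}), None, None)
        assert plan.ordered_modules == []

    def test_plan_invariant_validation(self):
        with pytest.raises(ValidationError):
            TreatmentPlan(ordered_modules=[2, 2], included_module1=False, included_module8=False)
        with pytest.raises(ValidationError):
            TreatmentPlan(ordered_modules=[2, 1], included_module1=True, included_module8=False)


class TestVarianceExplained:
    @pytest.mark.parametrize(
        "beta,expected",
        [(0.58, 34), (0.26, 7), (1.0, 100), (0.0, 0), (-0.58, 34), (0.5, 25)],
    )
    def test_r_to_r_squared(self, beta, expected):
        assert variance_explained(beta) == expected

    def test_out_of_range(self):
        with pytest.raises(ValidationError):
            variance_explained(1.2)


# ---------------------------------------------------------------------------
# properties
# ---------------------------------------------------------------------------


class TestProperties:
    def test_oracle_equivalence_small_instances(self):
        """Vectorized chain matches the straight-line oracle on random instances."""
        rng = np.random.default_rng(12345)
        for _ in range(200):
            sol, dyn, stats, mm, d = random_instance(rng)
            import warnings as w

            with w.catch_warnings():
                w.simplefilter("ignore", DegenerateInputWarning)
                table = compute_scores(sol, dyn, stats, mm)
            expected = oracle_scores(**d)
            for f in d["factors"]:
                assert table.raw_factor_scores[f] == pytest.approx(
                    expected["raw_factor"][f], abs=1e-10)
                assert table.norm_factor_scores[f] == pytest.approx(
                    expected["norm_factor"][f], abs=1e-10)
            for i in d["items"]:
                assert table.norm_item_scores[i] == pytest.approx(
                    expected["norm_item"][i], abs=1e-10)
            for m in d["modules"]:
                assert table.final_module[m] == pytest.approx(
                    expected["final"][m], abs=1e-10)

    def test_scale_invariance_of_ordering(self):
        """Multiplying all raw factor scores by a positive constant (e.g. the
        1/N term) leaves every normalized quantity and the plan unchanged."""
        rng = np.random.default_rng(7)
        sol, dyn, stats, mm, _ = random_instance(rng)
        table = compute_scores(sol, dyn, stats, mm)
        for c in (0.01, 3.0, 1e4):
            scaled = normalize(table.raw_factor_scores * c)
            pd.testing.assert_series_equal(scaled, table.norm_factor_scores)
            rescored = raw_item_scores(sol, scaled, stats)
            pd.testing.assert_series_equal(
                normalize(rescored), table.norm_item_scores
            )

    def test_item_mean_monotonicity(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            sol, dyn, stats, mm, _ = random_instance(rng)
            fs_norm = normalize(raw_factor_scores(sol, dyn))
            base = raw_item_scores(sol, fs_norm, stats)
            item = stats.means.index[int(rng.integers(len(stats.means)))]
            bumped_means = stats.means.copy()
            bumped_means[item] = min(bumped_means[item] + 10, 100.0)
            bumped = raw_item_scores(sol, fs_norm, ItemStats(means=bumped_means))
            assert bumped[item] >= base[item] - 1e-12

    def test_cross_prediction_monotonicity(self):
        sol = make_solution([[0.8, np.nan], [np.nan, 0.7]], [0.3, 0.2])
        without = make_dynamics([[0.5, 0.0], [0.0, 0.5]],
                                retained=[[True, False], [False, True]])
        withx = make_dynamics([[0.5, 0.3], [0.0, 0.5]],
                              retained=[[True, True], [False, True]])
        assert (raw_factor_scores(sol, withx).iloc[0]
                > raw_factor_scores(sol, without).iloc[0])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(23)
        sol, dyn, stats, mm, _ = random_instance(rng, max_factors=4, max_items=8)
        table = compute_scores(sol, dyn, stats, mm)

        iperm = rng.permutation(sol.item_ids).tolist()
        fperm = rng.permutation(sol.factor_ids).tolist()
        mperm = rng.permutation(mm.module_ids).tolist()
        sol2 = FactorSolution(
            loadings=sol.loadings.loc[iperm, fperm],
            pct_variance=sol.pct_variance.loc[fperm],
        )
        dyn2 = DynamicModel(
            paths=dyn.paths.loc[fperm, fperm], retained=dyn.retained.loc[fperm, fperm]
        )
        stats2 = ItemStats(means=stats.means.loc[iperm])
        mm2 = ItemModuleMatrix(entries=mm.entries.loc[iperm, mperm])
        table2 = compute_scores(sol2, dyn2, stats2, mm2)
        pd.testing.assert_series_equal(
            table2.final_module.sort_index(), table.final_module.sort_index()
        )
        pd.testing.assert_series_equal(
            table2.norm_item_scores.sort_index(), table.norm_item_scores.sort_index()
        )

    def test_plan_scores_non_increasing(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            sol, dyn, stats, mm, _ = random_instance(rng)
            import warnings as w

            with w.catch_warnings():
                w.simplefilter("ignore", DegenerateInputWarning)
                table = compute_scores(sol, dyn, stats, mm)
                plan = build_plan(table, None, DiagnosisRecord(True))
            core = [m for m in plan.ordered_modules if m not in (1, 8)]
            finals = [table.final_module[m] for m in core]
            assert all(a >= b - 1e-12 for a, b in zip(finals, finals[1:]))
            assert all(table.final_module[m] > 0 for m in core)
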