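import numpy as np
import pandas as pd
import pytest

from akival.agreement import ConfusionMatrix, cross_tabulate, gwet_coefficient
from akival.aki_engine import determine_live_dates, run_central_algorithm
from akival.datasets import AUDIT_CROSS_TAB
from akival.io_model import Cohort
from akival.study_pipeline import (build_pairs, build_table1, overall_analysis,
                                   per_group_analysis, run_matrix_analysis,
                                   run_study, sensitivity_complete_case,
                                   sensitivity_complete_months,
                                   subgroup_analysis, write_report)
from akival.synthetic_data import (CohortParams, LabBehavior, corrupt_alerts,
                                   generate_cohort, simulate_lab_alerts)

from conftest import make_alerts, make_cohort, make_results


def _paired(cohort):
    central = run_central_algorithm(cohort)
    live = determine_live_dates(cohort.alerts)
    return build_pairs(cohort, central, live), central


class TestBuildPairs:
    def test_result_before_live_date_unalerted_no_pair(self):
        cohort = make_cohort(
            [("P1", "L1", "2019-01-01T08:00", 90),
             ("P2", "L1", "2019-06-01T08:00", 250)],
            [("P2", "L1", "2019-06-01T08:00", 2, 250)])
        pairs, _ = _paired(cohort)
        assert "P1" not in set(pairs["mpi"])

    def test_unalerted_after_live_gives_inferred_zero_pair(self):
        cohort = make_cohort(
            [("P1", "L1", "2019-06-02T08:00", 90),
             ("P2", "L1", "2019-06-01T08:00", 250)],
            [("P2", "L1", "2019-06-01T08:00", 2, 250)])
        pairs, _ = _paired(cohort)
        row = pairs[pairs["mpi"] == "P1"].iloc[0]
        assert row["local_stage"] == 0
        assert row["inferred"]

    def test_zero_corruption_closure(self, zero_corruption_run):
        cohort, _, _ = zero_corruption_run
        pairs, _ = _paired(cohort)
        assert (pairs["local_stage"] == pairs["central_stage"]).all()

    def test_covariates_attached(self, zero_corruption_run):
        cohort, _, _ = zero_corruption_run
        pairs, _ = _paired(cohort)
        assert pairs["age_at_test"].between(18, 99).all()
        assert set(pairs["year"]) <= {2018, 2019, 2020}
        assert pairs["baseline_scr"].notna().mean() > 0.5

    def test_reordering_inputs_changes_nothing(self, zero_corruption_run):
        cohort, _, _ = zero_corruption_run
        pairs1, _ = _paired(cohort)
        shuffled = Cohort(
            cohort.results.sample(frac=1, random_state=0).reset_index(drop=True),
            cohort.alerts.sample(frac=1, random_state=0).reset_index(drop=True))
        pairs2, _ = _paired(shuffled)
        pd.testing.assert_frame_equal(pairs1, pairs2)


class TestOverallAnalysis:
    def test_zero_corruption_coefficient_is_one(self, zero_corruption_run):
        cohort, _, _ = zero_corruption_run
        pairs, _ = _paired(cohort)
        _, res = overall_analysis(pairs)
        assert res.coefficient == pytest.approx(1.0)

    def test_suppression_lowers_coefficient(self, zero_corruption_run):
        cohort, _, _ = zero_corruption_run
        central = run_central_algorithm(cohort)
        rng = np.random.default_rng(0)
        behavior = LabBehavior(suppression_prob={1: .5, 2: .5, 3: .5})
        alerts, _ = corrupt_alerts(central, behavior, rng)
        corrupted = Cohort(cohort.results, alerts)
        pairs, _ = _paired(corrupted)
        _, res = overall_analysis(pairs)
        assert res.coefficient < 1.0

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            overall_analysis(pd.DataFrame(columns=["local_stage", "central_stage"]))

    def test_pooled_equals_sum_of_per_lab_matrices(self, zero_corruption_run):
        cohort, _, _ = zero_corruption_run
        pairs, _ = _paired(cohort)
        pooled, _ = overall_analysis(pairs)
        summed = np.zeros((4, 4))
        for _, sub in pairs.groupby("lab_code"):
            summed += cross_tabulate(sub["local_stage"], sub["central_stage"]).counts
        assert np.array_equal(pooled.counts, summed)


class TestPerGroupAnalysis:
    def test_corrupted_lab_scores_lower(self, zero_corruption_run):
        cohort, _, _ = zero_corruption_run
        central = run_central_algorithm(cohort)
        rng = np.random.default_rng(1)
        # suppress alerts only at LAB00
        behavior = LabBehavior(suppression_prob={1: .8, 2: .8, 3: .8})
        alerts_all, _ = corrupt_alerts(central, behavior, rng)
        clean = cohort.alerts[cohort.alerts["lab_code"] != "LAB00"]
        corrupted = alerts_all[alerts_all["lab_code"] == "LAB00"]
        merged = pd.concat([clean, corrupted]).sort_values(
            ["mpi", "alert_dt"], kind="mergesort").reset_index(drop=True)
        pairs, _ = _paired(Cohort(cohort.results, merged))
        table = per_group_analysis(pairs, "lab").set_index("group")
        assert table.loc["LAB00", "coefficient"] < \
            table.drop("LAB00")["coefficient"].min()
        # ascending sort convention
        coefs = per_group_analysis(pairs, "lab")["coefficient"]
        assert coefs.is_monotonic_increasing

    def test_uniform_behavior_near_equal_coefficients(self, zero_corruption_run):
        cohort, _, _ = zero_corruption_run
        pairs, _ = _paired(cohort)
        table = per_group_analysis(pairs, "lab")
        assert (table["coefficient"] == 1.0).all()

    def test_unknown_lims_grouping(self, zero_corruption_run):
        cohort, _, _ = zero_corruption_run
        pairs, _ = _paired(cohort)
        table = per_group_analysis(pairs, "lims",
                                   lims_map={"LAB00": "VendorA"})
        assert set(table["group"]) == {"VendorA", "Unknown"}

    def test_year_grouping_sorted_by_year(self, zero_corruption_run):
        cohort, _, _ = zero_corruption_run
        pairs, _ = _paired(cohort)
        table = per_group_analysis(pairs, "year")
        assert list(table["group"]) == sorted(table["group"])

    def test_unknown_grouping_rejected(self, zero_corruption_run):
        cohort, _, _ = zero_corruption_run
        pairs, _ = _paired(cohort)
        with pytest.raises(ValueError):
            per_group_analysis(pairs, "postcode")


class TestSensitivityAnalyses:
    def test_complete_case_on_published_matrix(self):
        res = run_matrix_analysis(AUDIT_CROSS_TAB)
        assert round(res["overall"]["coefficient"], 2) == 0.97
        assert round(res["complete_case"]["coefficient"], 2) == 0.83

    def test_no_inferred_zeros_identical_to_overall(self):
        pairs = pd.DataFrame({
            "local_stage": [1, 2, 3, 1], "central_stage": [1, 2, 3, 2],
            "inferred": [False] * 4})
        _, overall = overall_analysis(pairs)
        _, cc = sensitivity_complete_case(pairs)
        assert cc.coefficient == pytest.approx(overall.coefficient)

    def test_all_inferred_rejected(self):
        pairs = pd.DataFrame({
            "local_stage": [0, 0], "central_stage": [0, 1],
            "inferred": [True, True]})
        with pytest.raises(ValueError, match="no pairs remain"):
            sensitivity_complete_case(pairs)

    def test_complete_case_leq_overall_on_published_matrix(self):
        res = run_matrix_analysis(AUDIT_CROSS_TAB)
        assert res["complete_case"]["coefficient"] < res["overall"]["coefficient"]

    def test_complete_months_all_complete_identical(self):
        cohort = make_cohort(
            [("P1", "L1", "2019-01-10T08:00", 80),
             ("P1", "L1", "2019-01-20T08:00", 200)],
            [("P1", "L1", "2019-01-10T08:00", 1, 80)])
        pairs, _ = _paired(cohort)
        _, overall = overall_analysis(pairs)
        _, cm, labs = sensitivity_complete_months(pairs, cohort)
        assert labs == ["L1"]
        assert cm.coefficient == pytest.approx(overall.coefficient)

    def test_incomplete_lab_excluded(self):
        cohort = make_cohort(
            [("P1", "L1", "2019-01-10T08:00", 80),
             ("P1", "L1", "2019-01-20T08:00", 200),
             ("P2", "L2", "2019-01-10T08:00", 80),
             ("P2", "L2", "2019-03-10T08:00", 80)],   # February missing
            [("P1", "L1", "2019-01-10T08:00", 1, 80),
             ("P2", "L2", "2019-01-10T08:00", 1, 80),
             ("P2", "L2", "2019-03-10T08:00", 1, 80)])
        pairs, _ = _paired(cohort)
        m, _, labs = sensitivity_complete_months(pairs, cohort)
        assert labs == ["L1"]
        assert m.n == (pairs["lab_code"] == "L1").sum()

    def test_simulated_monthly_drop_flags_lab_incomplete(self):
        rng = np.random.default_rng(8)
        cohort, _ = generate_cohort(CohortParams(n_patients=150, seed=8), rng)
        behavior = LabBehavior(monthly_missing_prob=0.4)
        alerts, gt = simulate_lab_alerts(cohort, behavior, rng=rng)
        full = Cohort(cohort.results, alerts)
        dropped_labs = set(gt.loc[gt["status"] == "dropped_month", "lab_code"])
        assert dropped_labs
        from akival.io_model import complete_labs
        assert not dropped_labs & set(complete_labs(full))


class TestSubgroupAnalysis:
    def test_near_equal_quartile_sizes(self, zero_corruption_run):
        cohort, _, _ = zero_corruption_run
        pairs, _ = _paired(cohort)
        tab = subgroup_analysis(pairs, "baseline_scr")
        assert len(tab) == 4
        sizes = tab["n_pairs"].to_numpy()
        assert sizes.max() - sizes.min() < 0.2 * sizes.mean()

    def test_age_quintiles_default(self, zero_corruption_run):
        cohort, _, _ = zero_corruption_run
        pairs, _ = _paired(cohort)
        tab = subgroup_analysis(pairs, "age")
        assert len(tab) == 5

    def test_targeted_ckd_suppression_lowers_top_quartile(self):
        rng = np.random.default_rng(21)
        cohort, truth = generate_cohort(
            CohortParams(n_patients=800, seed=21), rng)
        central = run_central_algorithm(cohort)
        ckd = set(truth["patients"].loc[truth["patients"]["ckd"], "mpi"])
        u = np.where(central["mpi"].isin(ckd), 0.0, 1.0)
        behavior = LabBehavior(suppression_prob={1: .9, 2: .9, 3: .9})
        alerts, _ = corrupt_alerts(central, behavior,
                                   np.random.default_rng(0), suppress_u=u)
        pairs, _ = _paired(Cohort(cohort.results, alerts))
        tab = subgroup_analysis(pairs, "baseline_scr")
        assert tab.iloc[-1]["coefficient"] < tab.iloc[0]["coefficient"]

    def test_degenerate_strata_warn(self):
        pairs = pd.DataFrame({
            "local_stage": [0, 1, 2], "central_stage": [0, 1, 2],
            "inferred": [False] * 3, "baseline_scr": [80.0, 80.0, 80.0]})
        with pytest.warns(UserWarning):
            subgroup_analysis(pairs, "baseline_scr")

    def test_unknown_axis_rejected(self, zero_corruption_run):
        cohort, _, _ = zero_corruption_run
        pairs, _ = _paired(cohort)
        with pytest.raises(ValueError):
            subgroup_analysis(pairs, "shoe_size")


class TestTable1:
    def test_local_totals_additive(self, zero_corruption_run):
        cohort, _, _ = zero_corruption_run
        pairs, central = _paired(cohort)
        t1 = build_table1(cohort, pairs, central)
        local = t1["local"]
        assert local["n_nonzero"] == sum(local[f"aki{s}_n"] for s in (1, 2, 3))

    def test_zero_corruption_local_equals_central(self, zero_corruption_run):
        cohort, _, _ = zero_corruption_run
        pairs, central = _paired(cohort)
        t1 = build_table1(cohort, pairs, central)
        for s in (1, 2, 3):
            assert t1["local"][f"aki{s}_n"] == t1["central"][f"aki{s}_n"]

    def test_percent_columns_sum_to_100(self, zero_corruption_run):
        cohort, _, _ = zero_corruption_run
        pairs, central = _paired(cohort)
        t1 = build_table1(cohort, pairs, central)
        total = sum(t1["local"][f"aki{s}_pct"] for s in (1, 2, 3))
        assert total == pytest.approx(100.0, abs=0.3)


class TestRunStudy:
    CONFIG = {
        "seed": 5,
        "simulate": {"n_patients": 120, "months": 18, "n_labs": 2,
                     "behavior": {"suppression_prob": {"3": 0.5}}},
    }

    def test_same_seed_byte_identical_bundles(self, tmp_path):
        digests = []
        for run in ("a", "b"):
            report = run_study(dict(self.CONFIG))
            out = write_report(report, tmp_path / run, self.CONFIG)
            digests.append({p.name: p.read_bytes()
                            for p in sorted(out.iterdir())})
        assert digests[0].keys() == digests[1].keys()
        for name in digests[0]:
            assert digests[0][name] == digests[1][name], name

    def test_report_bundle_contents(self, tmp_path):
        report = run_study(dict(self.CONFIG))
        out = write_report(report, tmp_path / "r", self.CONFIG)
        names = {p.name for p in out.iterdir()}
        assert {"table1.json", "table2.csv", "table3.csv", "lims.csv",
                "sensitivity.csv", "run.json"} <= names

    def test_empty_cohort_fatal(self):
        with pytest.raises(ValueError, match="n_patients"):
            run_study({"simulate": {"n_patients": 0}})

    def test_missing_sections_fatal(self):
        with pytest.raises(ValueError, match="simulate"):
            run_study({})

    def test_file_inputs_route(self, tmp_path, zero_corruption_run):
        from akival.synthetic_data import write_fixture
        cohort, _, _ = zero_corruption_run
        paths = write_fixture(cohort, cohort.alerts, tmp_path)
        report = run_study({"inputs": {"scr": str(paths["scr"]),
                                       "alerts": str(paths["alerts"])}})
        assert report.overall.coefficient == pytest.approx(1.0)

    def test_matrix_only_mode_reproduces_published_values(self):
        res = run_matrix_analysis(AUDIT_CROSS_TAB)
        assert res["n"] == 9_096_667
        assert res["local_nonzero_total"] == 1_579_633
        assert round(res["overall"]["coefficient"], 2) == 0.97
        assert round(res["complete_case"]["coefficient"], 2) == 0.83
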