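"""End-to-end orchestration: pairing, agreement surfaces and report tables.

The pipeline pairs every evaluable creatinine result with a local stage
(received alert, or inferred 0 after the laboratory's live date) and the
centrally recomputed stage, then reproduces the audit's analysis surfaces:
the pooled cross-tabulation, per-laboratory and per-LIMS agreement tables,
complete-case and complete-months sensitivity analyses, and subgroup
analyses over baseline creatinine and age strata.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .agreement import (AgreementResult, ConfusionMatrix, cross_tabulate,
                        gwet_coefficient, matrix_report, ordinal_weights,
                        percent_positive_agreement)
from .aki_engine import determine_live_dates, infer_local_stage, run_central_algorithm
from .config import EngineConfig, ReadConfig, engine_config_from_mapping
from .io_model import (Cohort, apply_age_exclusion, censor_post_krt,
                       complete_labs, read_submission, _age_completed_years)
from .synthetic_data import CohortParams, LabBehavior, generate_cohort, simulate_lab_alerts

log = logging.getLogger("akival")


@dataclass
class StudyReport:
    """All analysis surfaces of one pipeline run."""

    table1: dict[str, Any]
    table2: ConfusionMatrix
    overall: AgreementResult
    table3: pd.DataFrame                 # per-laboratory, ascending agreement
    lims_table: pd.DataFrame
    sensitivity_table: pd.DataFrame
    subgroup_tables: dict[str, pd.DataFrame]
    counts: dict[str, Any] = field(default_factory=dict)


def build_pairs(cohort: Cohort, central: pd.DataFrame,
                live_dates: dict[str, pd.Timestamp],
                config: EngineConfig | None = None) -> pd.DataFrame:
    """One staged pair per evaluable creatinine result.

    Local stage comes from the received alert matched to the result, or is
    inferred 0 for unalerted results after the lab's live date; results that
    are not evaluable (before live date, unalerted) are dropped.  Attaches
    the stratification covariates: baseline SCr (long-window median when
    present, else short-window minimum), completed age at test, and year.
    """
    local = infer_local_stage(central, cohort.alerts, live_dates, config)
    keep = local["local_stage"].notna()

    pairs = central.loc[keep, ["mpi", "lab_code", "specimen_dt", "c1"]].copy()
    pairs["local_stage"] = local.loc[keep, "local_stage"].astype(int)
    pairs["central_stage"] = central.loc[keep, "stage"].astype(int)
    pairs["inferred"] = local.loc[keep, "inferred"]
    pairs["baseline_scr"] = central.loc[keep, "rv2"].fillna(central.loc[keep, "rv1"])

    dob_map = (cohort.results[["mpi", "dob"]].drop_duplicates("mpi")
               .set_index("mpi")["dob"])
    dob = pairs["mpi"].map(dob_map)
    pairs["age_at_test"] = _age_completed_years(dob, pairs["specimen_dt"])
    pairs["year"] = pairs["specimen_dt"].dt.year
    return pairs.reset_index(drop=True)


def overall_analysis(pairs: pd.DataFrame, w: np.ndarray | None = None,
                     ) -> tuple[ConfusionMatrix, AgreementResult]:
    """Pooled cross-tabulation and weighted coefficient."""
    if pairs.empty:
        raise ValueError("no pairs to analyse")
    m = cross_tabulate(pairs["local_stage"], pairs["central_stage"])
    return m, gwet_coefficient(m, w)


def _group_row(name: Any, sub: pd.DataFrame,
               w: np.ndarray | None) -> dict[str, Any]:
    m = cross_tabulate(sub["local_stage"], sub["central_stage"])
    res = gwet_coefficient(m, w)
    ppa = percent_positive_agreement(m, w)
    return {
        "group": name,
        "n_pairs": len(sub),
        "n_lab_alerts": int((sub["local_stage"] >= 1).sum()),
        "n_central_alerts": int((sub["central_stage"] >= 1).sum()),
        "percent_positive_agreement": round(ppa["unweighted"], 4),
        "coefficient": round(res.coefficient, 4),
        "ci_low": round(res.ci95[0], 4),
        "ci_high": round(res.ci95[1], 4),
        "band": res.band,
    }


def per_group_analysis(pairs: pd.DataFrame, grouping: str,
                       lims_map: dict[str, str] | None = None,
                       w: np.ndarray | None = None) -> pd.DataFrame:
    """Agreement per laboratory, LIMS provider or calendar year.

    Labs with no LIMS mapping are pooled under "Unknown".  Rows are sorted
    in ascending order of the coefficient (report-table convention).
    """
    if grouping == "lab":
        key = pairs["lab_code"]
    elif grouping == "lims":
        key = pairs["lab_code"].map(lims_map or {}).fillna("Unknown")
    elif grouping == "year":
        key = pairs["year"]
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    rows = [_group_row(name, sub, w)
            for name, sub in pairs.groupby(key, sort=True)]
    out = pd.DataFrame(rows)
    if grouping == "year":
        return out.sort_values("group", kind="mergesort").reset_index(drop=True)
    return out.sort_values("coefficient", kind="mergesort").reset_index(drop=True)


def sensitivity_complete_case(pairs: pd.DataFrame,
                              w: np.ndarray | None = None,
                              ) -> tuple[ConfusionMatrix, AgreementResult]:
    """Drop pairs whose local stage was only inferred (no alert received).

    All four categories are retained, leaving a zero local-0 marginal.
    """
    kept = pairs[~pairs["inferred"]]
    if kept.empty:
        raise ValueError("no pairs remain after discarding inferred zeros")
    m = cross_tabulate(kept["local_stage"], kept["central_stage"])
    return m, gwet_coefficient(m, w)


def sensitivity_complete_months(pairs: pd.DataFrame, cohort: Cohort,
                                w: np.ndarray | None = None,
                                ) -> tuple[ConfusionMatrix, AgreementResult, list[str]]:
    """Restrict to laboratories with both streams present in every month."""
    labs = complete_labs(cohort)
    kept = pairs[pairs["lab_code"].isin(labs)]
    if kept.empty:
        raise ValueError("no complete laboratories remain")
    m = cross_tabulate(kept["local_stage"], kept["central_stage"])
    return m, gwet_coefficient(m, w), labs


_AXIS_DEFAULTS = {"baseline_scr": 4, "age": 5}


def subgroup_analysis(pairs: pd.DataFrame, axis: str,
                      n_strata: int | None = None,
                      w: np.ndarray | None = None) -> pd.DataFrame:
    """Agreement per quantile stratum of baseline SCr or age at test.

    Cut-points are empirical quantiles of the pairs themselves; values equal
    to a cut-point fall in the lower stratum.  Strata left empty (or made
    degenerate by ties) are omitted with a warning.  Each row carries the
    per-stage percentage distribution of local and central alerts, used to
    inspect under-reporting patterns within a stratum.
    """
    col = {"baseline_scr": "baseline_scr", "age": "age_at_test"}.get(axis)
    if col is None:
        raise ValueError(f"unknown subgroup axis {axis!r}")
    n_strata = n_strata or _AXIS_DEFAULTS[axis]

    avail = pairs[pairs[col].notna()].copy()
    if len(avail) < n_strata:
        warnings.warn(f"only {len(avail)} pairs with {col}; strata degenerate")
    try:
        strata = pd.qcut(avail[col], n_strata, labels=False, duplicates="drop")
    except ValueError:
        warnings.warn(f"could not form {n_strata} strata on {col}")
        strata = pd.Series(0, index=avail.index)

    rows = []
    for name, sub in avail.groupby(strata, sort=True):
        if sub.empty:
            warnings.warn(f"stratum {name} of {axis} is empty; omitted")
            continue
        row = _group_row(int(name) + 1, sub, w)
        row["median_covariate"] = float(sub[col].median())
        for s in range(4):
            row[f"local_pct_{s}"] = round(
                float((sub["local_stage"] == s).mean() * 100), 2)
            row[f"central_pct_{s}"] = round(
                float((sub["central_stage"] == s).mean() * 100), 2)
        rows.append(row)
    return pd.DataFrame(rows)


def _stage_block(stages: pd.Series, scr: pd.Series) -> dict[str, Any]:
    nonzero = stages >= 1
    total = int(nonzero.sum())
    block: dict[str, Any] = {"n_nonzero": total}
    for s in (1, 2, 3):
        mask = stages == s
        block[f"aki{s}_n"] = int(mask.sum())
        block[f"aki{s}_pct"] = round(mask.sum() / total * 100, 1) if total else None
        block[f"aki{s}_median_scr"] = (float(scr[mask].median())
                                       if mask.any() else None)
    return block


def build_table1(cohort: Cohort, pairs: pd.DataFrame,
                 central: pd.DataFrame) -> dict[str, Any]:
    """Cohort and alert descriptives (persons, age, sex, stage mix, SCr)."""
    res = cohort.results
    first = res.drop_duplicates("mpi")
    age = _age_completed_years(first["dob"], first["specimen_dt"])

    local = _stage_block(pairs["local_stage"], pairs["c1"])
    central_b = _stage_block(central["stage"], central["c1"])

    def _alerts_per_person(frame: pd.DataFrame, col: str) -> float | None:
        nz = frame[frame[col] >= 1]
        return float(nz.groupby("mpi").size().median()) if len(nz) else None

    return {
        "n_persons": int(res["mpi"].nunique()),
        "n_results": int(len(res)),
        "age_median": float(age.median()) if len(age) else None,
        "age_q1": float(age.quantile(0.25)) if len(age) else None,
        "age_q3": float(age.quantile(0.75)) if len(age) else None,
        "pct_female": round(float((first["sex"] == "F").mean() * 100), 1)
        if len(first) else None,
        "local": local,
        "central": central_b,
        "median_alerts_per_person_local": _alerts_per_person(pairs, "local_stage"),
        "median_alerts_per_person_central": _alerts_per_person(central, "stage"),
    }


def run_matrix_analysis(counts: np.ndarray,
                        w: np.ndarray | None = None) -> dict[str, Any]:
    """Matrix-only mode: agreement surfaces from a literal 4x4 cross-tab."""
    m = ConfusionMatrix(np.asarray(counts, float))
    w = ordinal_weights(m.q) if w is None else w
    overall = gwet_coefficient(m, w)
    complete = gwet_coefficient(m.drop_local_stage(0), w)
    ppa = percent_positive_agreement(m, w)
    return {
        "n": int(m.n),
        "overall": overall.to_dict(),
        "complete_case": complete.to_dict(),
        "percent_positive_agreement": ppa,
        "local_nonzero_total": int(m.row_totals[1:].sum()),
        "central_nonzero_total": int(m.col_totals[1:].sum()),
    }


def _load_inputs(config: dict[str, Any]) -> tuple[Cohort, dict[str, Any]]:
    counts: dict[str, Any] = {}
    if "simulate" in config:
        sim = dict(config["simulate"])
        behavior_cfg = sim.pop("behavior", {}) or {}
        seed = int(config.get("seed", sim.pop("seed", 0)))
        params = CohortParams(seed=seed, **sim)
        rng = np.random.default_rng(seed)
        cohort, _truth = generate_cohort(params, rng)
        behavior = LabBehavior(
            suppression_prob={int(k): float(v) for k, v in
                              (behavior_cfg.get("suppression_prob") or {}).items()},
            miscode_matrix=(np.asarray(behavior_cfg["miscode_matrix"], float)
                            if behavior_cfg.get("miscode_matrix") is not None
                            else None),
            monthly_missing_prob=float(behavior_cfg.get("monthly_missing_prob", 0.0)),
            variant_config=engine_config_from_mapping(behavior_cfg.get("variant_config"))
            if behavior_cfg.get("variant_config") else None)
        alerts, truth = simulate_lab_alerts(
            cohort, behavior,
            engine_config_from_mapping(config.get("engine")), rng=rng)
        cohort = Cohort(cohort.results, alerts, cohort.krt_start, cohort.lims_map)
        counts["simulated"] = True
        counts["alert_status"] = truth["status"].value_counts().to_dict()
    elif "inputs" in config:
        paths = config["inputs"]
        cohort, report = read_submission(
            paths["scr"], paths["alerts"],
            krt_path=paths.get("krt"), lims_path=paths.get("lims"))
        counts["read_report"] = {"rejected": report.rejected,
                                 "duplicates": report.duplicates}
    else:
        raise ValueError("config needs a 'simulate' or 'inputs' section")
    if "lims_map" in config:
        cohort.lims_map.update(config["lims_map"])
    return cohort, counts


def run_study(config: dict[str, Any]) -> StudyReport:
    """Execute the full pipeline: read/simulate -> exclusions -> engine ->
    pairing -> agreement surfaces.  Deterministic under a fixed seed."""
    engine_cfg = engine_config_from_mapping(config.get("engine"))
    w = ordinal_weights(4, config.get("weight_family", "ordinal"))

    cohort, counts = _load_inputs(config)
    if cohort.results.empty:
        raise ValueError("empty cohort: no creatinine results to analyse")
    counts["n_results_in"] = len(cohort.results)
    counts["n_alerts_in"] = len(cohort.alerts)

    cohort, age_report = apply_age_exclusion(cohort)
    counts["age_exclusion"] = age_report
    cohort, krt_report = censor_post_krt(
        cohort, drop_scr=bool(config.get("censor_krt_scr", False)))
    counts["krt_censoring"] = krt_report

    central = run_central_algorithm(cohort, engine_cfg)
    live_dates = determine_live_dates(cohort.alerts)
    pairs = build_pairs(cohort, central, live_dates, engine_cfg)
    counts["n_pairs"] = len(pairs)
    counts["n_not_evaluable"] = len(central) - len(pairs)
    if pairs.empty:
        raise ValueError("no evaluable pairs (no laboratory ever alerted?)")

    table2, overall = overall_analysis(pairs, w)
    table3 = per_group_analysis(pairs, "lab", w=w)
    lims_table = per_group_analysis(pairs, "lims", lims_map=cohort.lims_map, w=w)
    year_table = per_group_analysis(pairs, "year", w=w)

    sens_rows = [{"analysis": "overall", "n_pairs": len(pairs),
                  "coefficient": round(overall.coefficient, 4)}]
    try:
        _, cc, = sensitivity_complete_case(pairs, w)
        sens_rows.append({"analysis": "complete_case",
                          "n_pairs": int((~pairs["inferred"]).sum()),
                          "coefficient": round(cc.coefficient, 4)})
    except ValueError as exc:
        log.warning("complete-case analysis skipped: %s", exc)
    try:
        _, cm, labs = sensitivity_complete_months(pairs, cohort, w)
        sens_rows.append({"analysis": "complete_months",
                          "n_pairs": int(pairs["lab_code"].isin(labs).sum()),
                          "coefficient": round(cm.coefficient, 4)})
    except ValueError as exc:
        log.warning("complete-months analysis skipped: %s", exc)

    subgroups = {}
    for axis in ("baseline_scr", "age"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tab = subgroup_analysis(pairs, axis, w=w)
        if len(tab):
            subgroups[axis] = tab

    table1 = build_table1(cohort, pairs, central)
    return StudyReport(table1=table1, table2=table2, overall=overall,
                       table3=table3, lims_table=lims_table,
                       sensitivity_table=pd.DataFrame(sens_rows),
                       subgroup_tables={**subgroups, "year": year_table},
                       counts=counts)


def write_report(report: StudyReport, out_dir: str | Path,
                 config: dict[str, Any] | None = None) -> Path:
    """Write the report bundle (CSV tables + run.json) to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with open(out / "table1.json", "w", encoding="utf-8") as fh:
        json.dump(report.table1, fh, indent=2, sort_keys=True)
    matrix_report(report.table2).to_csv(out / "table2.csv")
    report.table3.to_csv(out / "table3.csv", index=False)
    report.lims_table.to_csv(out / "lims.csv", index=False)
    report.sensitivity_table.to_csv(out / "sensitivity.csv", index=False)
    for axis, tab in report.subgroup_tables.items():
        tab.to_csv(out / f"subgroups_{axis}.csv", index=False)
    run_info = {
        "version": __version__,
        "config": config or {},
        "counts": report.counts,
        "overall": report.overall.to_dict(),
    }
    with open(out / "run.json", "w", encoding="utf-8") as fh:
        json.dump(run_info, fh, indent=2, sort_keys=True, default=str)
    log.info("report bundle written to %s", out)
    return out
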