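"""Domain types, submission-file I/O, validation and cohort exclusions.

Registry submissions arrive as two monthly CSV streams per laboratory:
serum-creatinine results and stage 1-3 alert records.  This module reads
them into a validated :class:`Cohort`, rejecting (and counting) malformed
rows rather than failing the run, and implements the cohort exclusions
applied before any agreement analysis: age limits, duplicate removal and
censoring of alerts after the start of long-term kidney replacement
therapy.

Tabular data are held as :class:`pandas.DataFrame` columns named after the
record dataclasses below; the dataclasses document the row schema and are
used for single-record construction in tests and the simulator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .config import ReadConfig

log = logging.getLogger("akival")

#: canonical column order of the creatinine submission file
SCR_COLUMNS = ["mpi", "lab_code", "specimen_dt", "scr_umol_l", "dob", "sex",
               "location_code"]
#: canonical column order of the alert submission file
ALERT_COLUMNS = ["mpi", "lab_code", "alert_dt", "stage", "scr_at_alert"]

_DT_FMT = "%Y-%m-%dT%H:%M"
_DATE_FMT = "%Y-%m-%d"


@dataclass(frozen=True)
class ScrResult:
    """One serum-creatinine measurement for one patient at one laboratory."""

    mpi: str
    lab_code: str
    specimen_dt: pd.Timestamp
    scr: float                      # umol/L, positive
    dob: pd.Timestamp
    sex: str = "unknown"            # {"F", "M", "unknown"}
    location_code: str | None = None


@dataclass(frozen=True)
class AlertRecord:
    """One laboratory-issued AKI alert; registries never receive stage 0."""

    mpi: str
    lab_code: str
    alert_dt: pd.Timestamp
    stage: int                      # in {1, 2, 3}
    scr_at_alert: float | None = None


@dataclass
class ReadReport:
    """Row-level accounting for one read/validation pass."""

    n_scr_read: int = 0
    n_alerts_read: int = 0
    rejected: dict[str, int] = field(default_factory=dict)
    duplicates: int = 0
    alert_duplicates: int = 0
    time_conflicts: int = 0         # same (mpi, specimen_dt), different scr

    def add_reject(self, reason: str, n: int = 1) -> None:
        if n:
            self.rejected[reason] = self.rejected.get(reason, 0) + n

    @property
    def n_rejected(self) -> int:
        return sum(self.rejected.values())


@dataclass
class Cohort:
    """Validated submission data for one analysis run.

    ``results`` is sorted by (mpi, specimen_dt) and deduplicated on
    (mpi, specimen_dt, scr).  ``krt_start`` maps patient id to the start
    date of long-term kidney replacement therapy; ``lims_map`` maps
    laboratory code to its LIMS provider label.
    """

    results: pd.DataFrame
    alerts: pd.DataFrame
    krt_start: dict[str, pd.Timestamp] = field(default_factory=dict)
    lims_map: dict[str, str] = field(default_factory=dict)

    @property
    def n_patients(self) -> int:
        return self.results["mpi"].nunique()

    def copy(self) -> "Cohort":
        return Cohort(self.results.copy(), self.alerts.copy(),
                      dict(self.krt_start), dict(self.lims_map))


def _empty_results() -> pd.DataFrame:
    return pd.DataFrame({
        "mpi": pd.Series(dtype=str),
        "lab_code": pd.Series(dtype=str),
        "specimen_dt": pd.Series(dtype="datetime64[ns]"),
        "scr": pd.Series(dtype=float),
        "dob": pd.Series(dtype="datetime64[ns]"),
        "sex": pd.Series(dtype=str),
        "location_code": pd.Series(dtype=object),
    })


def _empty_alerts() -> pd.DataFrame:
    return pd.DataFrame({
        "mpi": pd.Series(dtype=str),
        "lab_code": pd.Series(dtype=str),
        "alert_dt": pd.Series(dtype="datetime64[ns]"),
        "stage": pd.Series(dtype=int),
        "scr_at_alert": pd.Series(dtype=float),
    })


def _check_header(df: pd.DataFrame, expected: list[str], what: str) -> None:
    if list(df.columns) != expected:
        raise ValueError(
            f"malformed {what} header: expected {expected}, got {list(df.columns)}")


def _validate_scr(raw: pd.DataFrame, config: ReadConfig,
                  report: ReadReport) -> pd.DataFrame:
    report.n_scr_read = len(raw)
    if raw.empty:
        return _empty_results()

    specimen_dt = pd.to_datetime(raw["specimen_dt"], errors="coerce")
    dob = pd.to_datetime(raw["dob"], errors="coerce")
    scr = pd.to_numeric(raw["scr_umol_l"], errors="coerce")
    sex = raw["sex"].fillna("unknown").astype(str)
    sex = sex.where(sex.isin(["F", "M"]), "unknown")

    ok = pd.Series(True, index=raw.index)

    bad_dt = specimen_dt.isna()
    report.add_reject("bad_specimen_dt", int(bad_dt.sum()))
    ok &= ~bad_dt

    bad_scr = scr.isna() | (scr <= 0) | (scr >= config.scr_max_umol)
    report.add_reject("bad_scr", int((bad_scr & ok).sum()))
    ok &= ~bad_scr

    missing_id = raw["mpi"].isna() | raw["lab_code"].isna()
    report.add_reject("missing_identifier", int((missing_id & ok).sum()))
    ok &= ~missing_id

    before_birth = dob.notna() & (specimen_dt < dob)
    report.add_reject("specimen_before_dob", int((before_birth & ok).sum()))
    ok &= ~before_birth

    out = pd.DataFrame({
        "mpi": raw["mpi"].astype(str),
        "lab_code": raw["lab_code"].astype(str),
        "specimen_dt": specimen_dt,
        "scr": scr,
        "dob": dob,
        "sex": sex,
        "location_code": raw["location_code"],
    })[ok]

    # byte-identical duplicate = identical (mpi, specimen_dt, scr)
    dup = out.duplicated(subset=["mpi", "specimen_dt", "scr"])
    report.duplicates = int(dup.sum())
    out = out[~dup]
    conflict = out.duplicated(subset=["mpi", "specimen_dt"], keep=False)
    report.time_conflicts = int(conflict.sum())

    return out.sort_values(["mpi", "specimen_dt", "scr"],
                           kind="mergesort").reset_index(drop=True)


def _validate_alerts(raw: pd.DataFrame, report: ReadReport) -> pd.DataFrame:
    report.n_alerts_read = len(raw)
    if raw.empty:
        return _empty_alerts()

    alert_dt = pd.to_datetime(raw["alert_dt"], errors="coerce")
    stage = pd.to_numeric(raw["stage"], errors="coerce")
    scr_at_alert = pd.to_numeric(raw["scr_at_alert"], errors="coerce")

    ok = pd.Series(True, index=raw.index)

    bad_dt = alert_dt.isna()
    report.add_reject("bad_alert_dt", int(bad_dt.sum()))
    ok &= ~bad_dt

    bad_stage = ~stage.isin([1, 2, 3])
    report.add_reject("bad_stage", int((bad_stage & ok).sum()))
    ok &= ~bad_stage

    missing_id = raw["mpi"].isna() | raw["lab_code"].isna()
    report.add_reject("missing_identifier", int((missing_id & ok).sum()))
    ok &= ~missing_id

    out = pd.DataFrame({
        "mpi": raw["mpi"].astype(str),
        "lab_code": raw["lab_code"].astype(str),
        "alert_dt": alert_dt,
        "stage": stage.fillna(0).astype(int),
        "scr_at_alert": scr_at_alert,
    })[ok]

    dup = out.duplicated(subset=["mpi", "lab_code", "alert_dt", "stage"])
    report.alert_duplicates = int(dup.sum())
    out = out[~dup]
    return out.sort_values(["mpi", "alert_dt", "stage"],
                           kind="mergesort").reset_index(drop=True)


def read_submission(scr_path: str | Path, alert_path: str | Path,
                    config: ReadConfig | None = None,
                    krt_path: str | Path | None = None,
                    lims_path: str | Path | None = None,
                    ) -> tuple[Cohort, ReadReport]:
    """Read, validate and deduplicate a pair of submission files.

    Unparseable rows are rejected and counted by reason; a malformed header
    is fatal, as is a reject fraction above ``config.reject_threshold``.
    """
    config = config or ReadConfig()
    report = ReadReport()

    raw_scr = pd.read_csv(scr_path, dtype=str)
    _check_header(raw_scr, SCR_COLUMNS, "creatinine file")
    raw_alerts = pd.read_csv(alert_path, dtype=str)
    _check_header(raw_alerts, ALERT_COLUMNS, "alert file")

    results = _validate_scr(raw_scr, config, report)
    alerts = _validate_alerts(raw_alerts, report)

    krt_start: dict[str, pd.Timestamp] = {}
    if krt_path is not None:
        krt = pd.read_csv(krt_path, dtype=str)
        _check_header(krt, ["mpi", "krt_start_date"], "KRT file")
        dates = pd.to_datetime(krt["krt_start_date"], errors="coerce")
        krt_start = {m: d for m, d in zip(krt["mpi"], dates) if pd.notna(d)}

    lims_map: dict[str, str] = {}
    if lims_path is not None:
        lims = pd.read_csv(lims_path, dtype=str)
        _check_header(lims, ["lab_code", "lims_provider"], "LIMS file")
        lims_map = dict(zip(lims["lab_code"], lims["lims_provider"]))

    n_read = report.n_scr_read + report.n_alerts_read
    if n_read and report.n_rejected / n_read > config.reject_threshold:
        raise ValueError(
            f"{report.n_rejected}/{n_read} rows rejected "
            f"({report.rejected}); exceeds threshold {config.reject_threshold:.0%}")
    log.info("read %d results, %d alerts; rejected %s; %d duplicate results",
             len(results), len(alerts), report.rejected or 0, report.duplicates)
    return Cohort(results, alerts, krt_start, lims_map), report


def write_submission(cohort: Cohort, scr_path: str | Path,
                     alert_path: str | Path) -> None:
    """Write a cohort back to the canonical CSV dialect.

    Formatting is fixed (ISO minute timestamps, shortest float repr) so that
    ``write(read(f))`` is idempotent byte-for-byte.
    """
    res = cohort.results
    out = pd.DataFrame({
        "mpi": res["mpi"],
        "lab_code": res["lab_code"],
        "specimen_dt": res["specimen_dt"].dt.strftime(_DT_FMT),
        "scr_umol_l": res["scr"].map(_fmt_float),
        "dob": res["dob"].dt.strftime(_DATE_FMT),
        "sex": res["sex"],
        "location_code": res["location_code"],
    })
    out.to_csv(scr_path, index=False)
    al = cohort.alerts
    out = pd.DataFrame({
        "mpi": al["mpi"],
        "lab_code": al["lab_code"],
        "alert_dt": al["alert_dt"].dt.strftime(_DT_FMT),
        "stage": al["stage"],
        "scr_at_alert": al["scr_at_alert"].map(_fmt_float),
    })
    out.to_csv(alert_path, index=False)


def _fmt_float(x: float) -> str:
    if pd.isna(x):
        return ""
    if float(x) == int(x):
        return str(int(x))
    return repr(round(float(x), 2))


def _age_completed_years(dob: pd.Series, at: pd.Series) -> pd.Series:
    """Whole years elapsed between dob and a timestamp (birthday-exact)."""
    years = at.dt.year - dob.dt.year
    before_birthday = ((at.dt.month < dob.dt.month)
                       | ((at.dt.month == dob.dt.month)
                          & (at.dt.day < dob.dt.day)))
    return (years - before_birthday.astype(int)).where(dob.notna())


def apply_age_exclusion(cohort: Cohort, config: ReadConfig | None = None,
                        ) -> tuple[Cohort, dict[str, int]]:
    """Drop results (and their patients' alerts) outside the 18-99 y range.

    Age is completed years at the specimen date, inclusive at both bounds.
    Alerts are excluded under the same rule evaluated at the alert date so
    that alert/result pairs always move together.
    """
    config = config or ReadConfig()
    res, alerts = cohort.results, cohort.alerts

    age = _age_completed_years(res["dob"], res["specimen_dt"])
    missing = res["dob"].isna()
    keep = (~missing & (age >= config.min_age_years)
            & (age <= config.max_age_years))
    report = {
        "missing_dob": int(missing.sum()),
        "age_out_of_range": int((~keep & ~missing).sum()),
    }

    dob_map = res[["mpi", "dob"]].drop_duplicates("mpi").set_index("mpi")["dob"]
    a_dob = alerts["mpi"].map(dob_map)
    a_age = _age_completed_years(a_dob, alerts["alert_dt"])
    keep_a = (a_dob.notna() & (a_age >= config.min_age_years)
              & (a_age <= config.max_age_years))
    report["alerts_excluded"] = int((~keep_a).sum())

    out = Cohort(res[keep].reset_index(drop=True),
                 alerts[keep_a].reset_index(drop=True),
                 dict(cohort.krt_start), dict(cohort.lims_map))
    log.info("age exclusion: %s", report)
    return out, report


def censor_post_krt(cohort: Cohort, drop_scr: bool = False,
                    ) -> tuple[Cohort, dict[str, int]]:
    """Remove alerts dated on/after the patient's long-term KRT start.

    Creatinine results are kept by default (they remain look-back history);
    ``drop_scr=True`` also censors post-KRT results.
    """
    if not cohort.krt_start:
        return cohort.copy(), {"alerts_removed": 0, "results_removed": 0}
    starts = pd.Series(cohort.krt_start)

    a_start = cohort.alerts["mpi"].map(starts)
    drop_a = a_start.notna() & (cohort.alerts["alert_dt"] >= a_start)
    alerts = cohort.alerts[~drop_a].reset_index(drop=True)

    results = cohort.results
    n_res_removed = 0
    if drop_scr:
        r_start = results["mpi"].map(starts)
        drop_r = r_start.notna() & (results["specimen_dt"] >= r_start)
        n_res_removed = int(drop_r.sum())
        results = results[~drop_r].reset_index(drop=True)

    report = {"alerts_removed": int(drop_a.sum()),
              "results_removed": n_res_removed}
    log.info("KRT censoring: %s", report)
    return Cohort(results, alerts, dict(cohort.krt_start),
                  dict(cohort.lims_map)), report


def assess_monthly_completeness(cohort: Cohort, lab_code: str) -> pd.DataFrame:
    """Per-calendar-month (has_scr, has_alerts) flags for one laboratory.

    Months span the lab's first to last submission across both streams.  A
    lab is "complete" iff every month has both creatinine and alert rows.
    """
    res = cohort.results[cohort.results["lab_code"] == lab_code]
    al = cohort.alerts[cohort.alerts["lab_code"] == lab_code]
    if res.empty and al.empty:
        raise ValueError(f"no data for laboratory {lab_code!r}")

    scr_months = res["specimen_dt"].dt.to_period("M")
    alert_months = al["alert_dt"].dt.to_period("M")
    all_months = pd.concat([scr_months, alert_months])
    span = pd.period_range(all_months.min(), all_months.max(), freq="M")
    return pd.DataFrame({
        "has_scr": span.isin(set(scr_months)),
        "has_alerts": span.isin(set(alert_months)),
    }, index=span)


def lab_is_complete(cohort: Cohort, lab_code: str) -> bool:
    flags = assess_monthly_completeness(cohort, lab_code)
    return bool((flags["has_scr"] & flags["has_alerts"]).all())


def complete_labs(cohort: Cohort) -> list[str]:
    """Laboratories whose every month has both submission streams."""
    labs = sorted(set(cohort.results["lab_code"]) | set(cohort.alerts["lab_code"]))
    return [lab for lab in labs if lab_is_complete(cohort, lab)]
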