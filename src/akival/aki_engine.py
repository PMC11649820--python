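"""Deterministic re-implementation of the national AKI e-alert algorithm.

For every creatinine result the engine compares the index value (C1)
against two patient-level reference values drawn from a 365-day look-back:

* RV1 - lowest result in the preceding 0-7 days (exclusive of the index),
* RV2 - median result in the preceding 8-365 days,

plus the lowest result within the preceding 48 hours for the absolute-rise
rule.  Stages follow KDIGO-style ratio cut-offs (1.5x / 2x / 3x) with an
absolute >26 umol/L rise in 48 h flagging stage 1 and C1 >= 354 umol/L
escalating a >=1.5x rise to stage 3.

Window conventions (the source rules give only day ranges): RV1 uses the
half-open interval (t-7d, t), RV2 the closed interval [t-365d, t-7d]; a
result exactly 7 days before the index therefore contributes to RV2 only.
Results sharing the index timestamp are excluded from all windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import EngineConfig
from .io_model import Cohort

log = logging.getLogger("akival")

RULE_NONE = "none"
RULE_RATIO = "ratio"
RULE_DELTA48 = "delta48"
RULE_HIGH_C1 = "high_c1"

_HOUR_NS = 3_600_000_000_000
_DAY_NS = 24 * _HOUR_NS


@dataclass(frozen=True)
class ReferenceValues:
    """Look-back summaries for one index result; None when window is empty."""

    rv1: float | None        # lowest SCr, (t-7d, t)
    rv2: float | None        # median SCr, [t-365d, t-7d]
    min_48h: float | None    # lowest SCr, (t-48h, t)


@dataclass(frozen=True)
class CentralAlert:
    """Recomputed stage for one creatinine result."""

    mpi: str
    specimen_dt: pd.Timestamp
    c1: float
    stage: int
    ratio_rv1: float | None
    ratio_rv2: float | None
    rule_fired: str


def _window_stats(times_ns: np.ndarray, values: np.ndarray,
                  config: EngineConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised (rv1, rv2, min48) for one patient's sorted series.

    O(n^2) pairwise masks; patient series are short so this beats an
    index-by-index rescan.
    """
    t = times_ns[:, None]          # index result
    tj = times_ns[None, :]         # candidate history
    prior = tj < t                 # equal timestamps excluded everywhere

    in_rv1 = prior & (tj > t - config.rv1_window_days * _DAY_NS)
    in_rv2 = (tj >= t - config.rv2_window_days * _DAY_NS) \
        & (tj <= t - config.rv1_window_days * _DAY_NS)
    in_48h = prior & (tj > t - config.delta_window_hours * _HOUR_NS)

    vals = np.broadcast_to(values[None, :], in_rv1.shape)

    def _min(mask: np.ndarray) -> np.ndarray:
        masked = np.where(mask, vals, np.inf)
        out = masked.min(axis=1)
        return np.where(np.isfinite(out), out, np.nan)

    rv1 = _min(in_rv1)
    min48 = _min(in_48h)

    rv2 = np.full(len(times_ns), np.nan)
    counts = in_rv2.sum(axis=1)
    for i in np.nonzero(counts)[0]:
        rv2[i] = np.median(values[in_rv2[i]])
    return rv1, rv2, min48


def compute_reference_values(series: pd.DataFrame, index: int,
                             config: EngineConfig | None = None,
                             ) -> ReferenceValues:
    """Reference values for the ``index``-th result of one patient's series.

    ``series`` must be sorted by ``specimen_dt`` and carry columns
    ``specimen_dt`` and ``scr``.
    """
    config = config or EngineConfig()
    times = series["specimen_dt"].to_numpy("datetime64[ns]").astype(np.int64)
    values = series["scr"].to_numpy(float)
    if not (times[:-1] <= times[1:]).all():
        raise ValueError("series must be sorted by specimen_dt")
    rv1, rv2, min48 = _window_stats(times, values, config)
    opt = lambda x: None if np.isnan(x) else float(x)
    return ReferenceValues(opt(rv1[index]), opt(rv2[index]), opt(min48[index]))


def _stage_arrays(c1: np.ndarray, rv1: np.ndarray, rv2: np.ndarray,
                  min48: np.ndarray, config: EngineConfig,
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised staging; returns (stage, rule, ratio_rv1, ratio_rv2)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        r1 = np.where(np.isnan(rv1), np.nan, c1 / rv1)
        r2 = np.where(np.isnan(rv2), np.nan, c1 / rv2)
    if config.use_both_ratios:
        ratio = np.fmax(r1, r2)              # fmax ignores NaN
    else:
        ratio = np.where(np.isnan(r1), r2, r1)

    has_ratio = ~np.isnan(ratio)
    with np.errstate(invalid="ignore"):
        ge15 = has_ratio & (ratio >= config.ratio_stage1)
        ge2 = has_ratio & (ratio >= config.ratio_stage2)
        ge3 = has_ratio & (ratio >= config.ratio_stage3)
    delta = ~np.isnan(min48) & (c1 - min48 > config.delta48_umol)
    high = (config.high_c1_enabled & ge15 & (c1 >= config.high_c1_umol)
            & ~ge3)

    stage = np.zeros(len(c1), dtype=int)
    rule = np.full(len(c1), RULE_NONE, dtype=object)

    delta_path = ~ge15 & delta               # ratio < 1.5 or absent
    stage[delta_path] = 1
    rule[delta_path] = RULE_DELTA48
    stage[ge15] = 1
    stage[ge2] = 2
    stage[ge3] = 3
    rule[ge15] = RULE_RATIO
    stage[high] = 3
    rule[high] = RULE_HIGH_C1
    return stage, rule, r1, r2


def stage_result(c1: float, rv: ReferenceValues,
                 config: EngineConfig | None = None) -> CentralAlert:
    """Stage a single index result against its reference values."""
    config = config or EngineConfig()
    if c1 <= 0:
        raise ValueError("index creatinine must be positive")
    nan = lambda x: np.nan if x is None else x
    stage, rule, r1, r2 = _stage_arrays(
        np.array([float(c1)]), np.array([nan(rv.rv1)]),
        np.array([nan(rv.rv2)]), np.array([nan(rv.min_48h)]), config)
    opt = lambda x: None if np.isnan(x) else float(x)
    return CentralAlert(mpi="", specimen_dt=pd.NaT, c1=float(c1),
                        stage=int(stage[0]), ratio_rv1=opt(r1[0]),
                        ratio_rv2=opt(r2[0]), rule_fired=str(rule[0]))


def run_central_algorithm(cohort: Cohort,
                          config: EngineConfig | None = None) -> pd.DataFrame:
    """Stage every creatinine result in the cohort.

    Returns one row per result with columns ``mpi, lab_code, specimen_dt,
    c1, stage, rv1, rv2, min_48h, ratio_rv1, ratio_rv2, rule_fired``, in
    (mpi, specimen_dt) order regardless of input ordering.
    """
    config = config or EngineConfig()
    res = cohort.results.sort_values(
        ["mpi", "specimen_dt", "scr"], kind="mergesort").reset_index(drop=True)
    n = len(res)
    rv1 = np.full(n, np.nan)
    rv2 = np.full(n, np.nan)
    min48 = np.full(n, np.nan)

    times = res["specimen_dt"].to_numpy("datetime64[ns]").astype(np.int64)
    values = res["scr"].to_numpy(float)
    codes, _ = pd.factorize(res["mpi"])
    starts = np.flatnonzero(np.r_[True, np.diff(codes) != 0])
    bounds = np.r_[starts, n]
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        rv1[lo:hi], rv2[lo:hi], min48[lo:hi] = _window_stats(
            times[lo:hi], values[lo:hi], config)

    stage, rule, r1, r2 = _stage_arrays(values, rv1, rv2, min48, config)
    out = res[["mpi", "lab_code", "specimen_dt"]].copy()
    out["c1"] = values
    out["stage"] = stage
    out["rv1"] = rv1
    out["rv2"] = rv2
    out["min_48h"] = min48
    out["ratio_rv1"] = r1
    out["ratio_rv2"] = r2
    out["rule_fired"] = rule
    log.info("central algorithm: %d results, stage counts %s", n,
             out["stage"].value_counts().sort_index().to_dict())
    return out


def determine_live_dates(alerts: pd.DataFrame) -> dict[str, pd.Timestamp]:
    """Per-laboratory activation date = date of the first-ever received alert."""
    if alerts.empty:
        return {}
    return alerts.groupby("lab_code")["alert_dt"].min().to_dict()


def match_alerts(results: pd.DataFrame, alerts: pd.DataFrame,
                 config: EngineConfig | None = None) -> pd.Series:
    """Match each result to a received alert stage (NaN when unmatched).

    Linkage key: same patient and laboratory, |alert_dt - specimen_dt| within
    the configured tolerance.  Matching is one-to-one and greedy by time
    distance - the closest (result, alert) pairs are claimed first - so an
    alert issued for one result cannot also label an unalerted neighbour.
    Time ties are broken by agreement of ``scr_at_alert`` with the result's
    value, then by the higher stage.

    ``results`` needs columns ``mpi, lab_code, specimen_dt`` and, for the
    value tie-break, ``scr`` or ``c1``.
    """
    config = config or EngineConfig()
    matched = pd.Series(np.nan, index=results.index)
    if alerts.empty or results.empty:
        return matched
    value_col = "scr" if "scr" in results else ("c1" if "c1" in results else None)
    cols = ["index", "mpi", "lab_code", "specimen_dt"]
    if value_col:
        cols.append(value_col)
    left = results.reset_index()[cols]
    right = alerts.reset_index(drop=True).reset_index(names="alert_idx")
    merged = left.merge(right[["alert_idx", "mpi", "lab_code", "alert_dt",
                               "stage", "scr_at_alert"]],
                        on=["mpi", "lab_code"], how="inner")
    if merged.empty:
        return matched
    diff = (merged["alert_dt"] - merged["specimen_dt"]).abs()
    tol = pd.Timedelta(hours=config.match_tolerance_hours)
    merged = merged[diff <= tol].assign(absdiff=diff[diff <= tol])
    if value_col:
        merged["value_mismatch"] = ~(merged[value_col] == merged["scr_at_alert"])
    else:
        merged["value_mismatch"] = True
    merged = merged.sort_values(["absdiff", "value_mismatch", "stage"],
                                ascending=[True, True, False], kind="mergesort")

    used_result: set[int] = set()
    used_alert: set[int] = set()
    for ridx, aidx, stg in zip(merged["index"].to_numpy(),
                               merged["alert_idx"].to_numpy(),
                               merged["stage"].to_numpy(float)):
        if ridx in used_result or aidx in used_alert:
            continue
        used_result.add(ridx)
        used_alert.add(aidx)
        matched.loc[ridx] = stg
    return matched


def infer_local_stage(results: pd.DataFrame, alerts: pd.DataFrame,
                      live_dates: dict[str, pd.Timestamp],
                      config: EngineConfig | None = None) -> pd.DataFrame:
    """Local stage for every result: received alert stage, inferred 0, or NaN.

    Unalerted results dated strictly after the laboratory's live date are
    recoded to stage 0 (the algorithm was active and chose not to fire);
    unalerted results at or before the live date, or at labs with no live
    date, are not evaluable and get NaN.  The ``inferred`` column flags the
    recoded zeros for the complete-case sensitivity analysis.
    """
    matched = match_alerts(results, alerts, config)
    live = results["lab_code"].map(live_dates)
    after_live = live.notna() & (results["specimen_dt"] > live)

    local = matched.copy()
    inferred = matched.isna() & after_live
    local[inferred] = 0.0
    return pd.DataFrame({"local_stage": local, "inferred": inferred},
                        index=results.index)


def write_central_alerts(central: pd.DataFrame, path) -> None:
    """Write the central-alert CSV (mpi,lab_code,specimen_dt,c1,stage,...)."""
    out = central[["mpi", "lab_code", "specimen_dt", "c1", "stage",
                   "ratio_rv1", "ratio_rv2", "rule_fired"]].copy()
    out["specimen_dt"] = out["specimen_dt"].dt.strftime("%Y-%m-%dT%H:%M")
    for col in ("c1", "ratio_rv1", "ratio_rv2"):
        out[col] = out[col].map(lambda x: "" if pd.isna(x) else f"{x:.4f}")
    out.to_csv(path, index=False)
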