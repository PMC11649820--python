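"""Synthetic registry cohorts with known ground truth.

Generates longitudinal serum-creatinine trajectories that mimic the
marginal structure of the audited registry population (baseline SCr median
~77 umol/L with IQR ~57-108, age median ~72, 47% female, a 15% high-baseline
CKD sub-population at median ~164 umol/L), runs the staging engine to
obtain *true* alerts, and then corrupts the laboratory submission stream
with the discordance mechanisms hypothesised for real laboratories:
stage miscoding, per-stage alert suppression, and wholesale loss of monthly
files.  Every stochastic step draws from one seeded generator, so a single
seed reproduces the entire cohort.

The trajectory model is deliberately simple - a piecewise multiplicative
injury (linear log-rise to a stage-dependent peak over 1-5 days, then
exponential recovery) on top of a log-normal baseline with log-normal
measurement noise.  Only the marginal summaries above are calibrated; no
real time-course data informed the shape.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .aki_engine import run_central_algorithm
from .config import EngineConfig
from .io_model import Cohort, write_submission, _empty_alerts, _empty_results

log = logging.getLogger("akival")


@dataclass(frozen=True)
class CohortParams:
    """Knobs of the cohort generator; defaults are desk-scale."""

    n_patients: int = 500
    seed: int = 0
    months: int = 24
    n_labs: int = 3
    start_date: str = "2018-01-01"
    # baseline SCr: log-normal mixture calibrated to median 77, IQR 57-108
    baseline_median: float = 70.0
    baseline_sigma: float = 0.40
    ckd_fraction: float = 0.15
    ckd_median: float = 164.0
    ckd_sigma: float = 0.30
    # age = age_offset - LogNormal(log(age_gap_median), age_sigma), years
    age_offset: float = 100.0
    age_gap_median: float = 27.6
    age_sigma: float = 0.60
    frac_female: float = 0.47
    # episode process
    episode_rate: float = 1.0            # episodes per patient-year
    stage_mix: tuple[float, float, float] = (0.63, 0.18, 0.19)
    tests_per_month: float = 0.7         # baseline testing intensity
    episode_tests_per_day: float = 0.8   # in-episode testing intensity
    noise_cv: float = 0.05               # multiplicative measurement noise

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.months <= 0 or self.n_labs <= 0:
            raise ValueError("months and n_labs must be positive")
        if not np.isclose(sum(self.stage_mix), 1.0):
            raise ValueError("stage_mix must sum to 1")
        for p in (self.ckd_fraction, self.frac_female, *self.stage_mix):
            if not 0.0 <= p <= 1.0:
                raise ValueError("proportions must lie in [0, 1]")
        if min(self.episode_rate, self.tests_per_month,
               self.episode_tests_per_day) < 0:
            raise ValueError("rates must be non-negative")


@dataclass(frozen=True)
class LabBehavior:
    """Corruption model applied by a simulated laboratory.

    ``suppression_prob`` maps stage -> probability an issued alert is
    withheld from submission; ``miscode_matrix`` is a 4x4 row-stochastic
    matrix perturbing the stage a laboratory reports; ``monthly_missing_prob``
    drops an entire (lab, month) alert file; ``variant_config`` swaps in an
    "in-house" rule set for alert generation.
    """

    suppression_prob: dict[int, float] = field(default_factory=dict)
    miscode_matrix: np.ndarray | None = None
    monthly_missing_prob: float = 0.0
    variant_config: EngineConfig | None = None

    def validate(self) -> None:
        for s, p in self.suppression_prob.items():
            if s not in (0, 1, 2, 3) or not 0.0 <= p <= 1.0:
                raise ValueError(f"bad suppression entry {s}: {p}")
        if self.miscode_matrix is not None:
            m = np.asarray(self.miscode_matrix, float)
            if m.shape != (4, 4) or (m < 0).any() \
                    or not np.allclose(m.sum(axis=1), 1.0):
                raise ValueError("miscode_matrix must be 4x4 row-stochastic")
        if not 0.0 <= self.monthly_missing_prob <= 1.0:
            raise ValueError("monthly_missing_prob must lie in [0, 1]")

    def suppression_vector(self) -> np.ndarray:
        v = np.zeros(4)
        for s, p in self.suppression_prob.items():
            v[s] = p
        return v


_STAGE_PEAK_RANGES = {1: (1.60, 1.95), 2: (2.10, 2.90), 3: (3.20, 5.00)}


def generate_cohort(params: CohortParams,
                    rng: np.random.Generator | None = None,
                    ) -> tuple[Cohort, dict[str, pd.DataFrame]]:
    """Draw a cohort of longitudinal SCr series with injected AKI episodes.

    Returns the cohort (alerts empty - they come from
    :func:`simulate_lab_alerts`) and ground-truth tables: per-patient
    attributes and the injected episode parameters.
    """
    params.validate()
    rng = rng or np.random.default_rng(params.seed)
    n = params.n_patients
    start = pd.Timestamp(params.start_date)
    horizon_days = params.months * 30.44

    labs = np.array([f"LAB{i:02d}" for i in range(params.n_labs)])
    lab_of = labs[rng.integers(0, params.n_labs, size=n)]
    mpi = np.array([f"P{i:06d}" for i in range(n)])

    ckd = rng.random(n) < params.ckd_fraction
    baseline = np.where(
        ckd,
        np.exp(np.log(params.ckd_median)
               + params.ckd_sigma * rng.standard_normal(n)),
        np.exp(np.log(params.baseline_median)
               + params.baseline_sigma * rng.standard_normal(n)))

    age = params.age_offset - np.exp(
        np.log(params.age_gap_median) + params.age_sigma * rng.standard_normal(n))
    age = np.clip(age, 19.0, 98.0)      # inside the 18-99 inclusion window
    dob = start - pd.to_timedelta(age * 365.25, unit="D")
    dob = dob.floor("D")
    sex = np.where(rng.random(n) < params.frac_female, "F", "M")

    n_episodes = rng.poisson(params.episode_rate * params.months / 12.0, size=n)
    stages = np.array([1, 2, 3])
    episode_rows = []
    for i in range(n):
        for _ in range(n_episodes[i]):
            stage = int(rng.choice(stages, p=params.stage_mix))
            lo, hi = _STAGE_PEAK_RANGES[stage]
            episode_rows.append({
                "mpi": mpi[i],
                "t0_day": float(rng.uniform(0.0, horizon_days)),
                "stage_target": stage,
                "peak_ratio": float(rng.uniform(lo, hi)),
                "rise_days": float(rng.uniform(1.0, 5.0)),
                "recovery_tau": float(rng.uniform(3.0, 21.0)) / 3.0,
            })
    episodes = pd.DataFrame(episode_rows, columns=[
        "mpi", "t0_day", "stage_target", "peak_ratio", "rise_days",
        "recovery_tau"])

    noise_sigma = float(np.sqrt(np.log1p(params.noise_cv ** 2)))
    frames = []
    ep_by_patient = {k: g for k, g in episodes.groupby("mpi")} if len(episodes) else {}
    for i in range(n):
        t_base = rng.uniform(0.0, horizon_days,
                             size=rng.poisson(params.tests_per_month * params.months))
        t_list = [t_base]
        eps = ep_by_patient.get(mpi[i])
        if eps is not None:
            for ep in eps.itertuples():
                window = ep.rise_days + 3.0 * ep.recovery_tau
                k = rng.poisson(params.episode_tests_per_day * window)
                t_ep = ep.t0_day + rng.uniform(0.0, window, size=k)
                # one guaranteed draw at the peak so the episode is observable
                t_list.append(np.r_[t_ep, ep.t0_day + ep.rise_days])
        t = np.concatenate(t_list)
        t = t[t <= horizon_days]
        if t.size == 0:
            continue
        t.sort()

        mult = np.ones_like(t)
        if eps is not None:
            for ep in eps.itertuples():
                rel = t - ep.t0_day
                rise = (rel >= 0) & (rel <= ep.rise_days)
                rec = rel > ep.rise_days
                m = np.ones_like(t)
                m[rise] = ep.peak_ratio ** (rel[rise] / ep.rise_days)
                m[rec] = 1.0 + (ep.peak_ratio - 1.0) * np.exp(
                    -(rel[rec] - ep.rise_days) / ep.recovery_tau)
                mult = np.maximum(mult, m)

        scr = baseline[i] * mult * np.exp(
            noise_sigma * rng.standard_normal(t.size) - noise_sigma ** 2 / 2)
        scr = np.clip(np.round(scr, 1), 10.0, 3500.0)
        dt = (start + pd.to_timedelta(t, unit="D")).floor("min")
        frames.append(pd.DataFrame({
            "mpi": mpi[i], "lab_code": lab_of[i], "specimen_dt": dt,
            "scr": scr, "dob": dob[i], "sex": sex[i],
            "location_code": None}))

    results = pd.concat(frames, ignore_index=True) if frames else _empty_results()
    results = results.drop_duplicates(["mpi", "specimen_dt", "scr"])
    results = results.sort_values(["mpi", "specimen_dt", "scr"],
                                  kind="mergesort").reset_index(drop=True)

    patients = pd.DataFrame({
        "mpi": mpi, "lab_code": lab_of, "dob": dob, "sex": sex,
        "ckd": ckd, "baseline_scr": baseline, "age_at_start": age,
        "n_episodes": n_episodes})
    log.info("generated cohort: %d patients, %d results, %d episodes",
             n, len(results), len(episodes))
    return (Cohort(results, _empty_alerts()),
            {"patients": patients, "episodes": episodes})


def corrupt_alerts(central: pd.DataFrame, behavior: LabBehavior,
                   rng: np.random.Generator,
                   suppress_u: np.ndarray | None = None,
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply miscoding, suppression and monthly file loss to true alerts.

    ``central`` is the engine output (one row per SCr result).  Corruption
    order is fixed: miscode -> suppress -> drop month.  ``suppress_u`` lets
    callers supply common random numbers for monotonicity experiments.
    Returns (alert records, ground truth per result).
    """
    behavior.validate()
    truth = central[["mpi", "lab_code", "specimen_dt", "c1", "stage"]].copy()
    truth = truth.rename(columns={"stage": "true_stage"})
    n = len(truth)

    submitted = truth["true_stage"].to_numpy(int).copy()
    if behavior.miscode_matrix is not None:
        m = np.asarray(behavior.miscode_matrix, float)
        u = rng.random(n)
        cum = m.cumsum(axis=1)
        submitted = (u[:, None] < cum[submitted]).argmax(axis=1)
    truth["submitted_stage"] = submitted

    status = np.where(submitted >= 1, "submitted", "zero").astype(object)

    sup = behavior.suppression_vector()
    if suppress_u is None:
        suppress_u = rng.random(n)
    suppressed = (submitted >= 1) & (suppress_u < sup[submitted])
    status[suppressed] = "suppressed"

    if behavior.monthly_missing_prob > 0:
        month = truth["specimen_dt"].dt.to_period("M").astype(str)
        key = truth["lab_code"].str.cat(month, sep="|")
        uniq = np.sort(key.unique())
        dropped = set(uniq[rng.random(len(uniq)) < behavior.monthly_missing_prob])
        drop_mask = key.isin(dropped).to_numpy() & (status == "submitted")
        status[drop_mask] = "dropped_month"

    truth["status"] = status
    emit = status == "submitted"
    alerts = pd.DataFrame({
        "mpi": truth.loc[emit, "mpi"].to_numpy(),
        "lab_code": truth.loc[emit, "lab_code"].to_numpy(),
        "alert_dt": truth.loc[emit, "specimen_dt"].to_numpy(),
        "stage": submitted[emit],
        "scr_at_alert": truth.loc[emit, "c1"].to_numpy(),
    }).sort_values(["mpi", "alert_dt", "stage"],
                   kind="mergesort").reset_index(drop=True)
    return alerts, truth


def simulate_lab_alerts(cohort: Cohort, behavior: LabBehavior,
                        engine_config: EngineConfig | None = None,
                        rng: np.random.Generator | None = None,
                        seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Produce the laboratory alert stream for a cohort under a behavior.

    Runs the staging engine (with the behavior's variant rule set if any) to
    obtain true alerts, then corrupts them.  Only stages >= 1 are emitted as
    alert records - registries never receive stage 0.
    """
    rng = rng or np.random.default_rng(seed)
    config = behavior.variant_config or engine_config or EngineConfig()
    central = run_central_algorithm(cohort, config)
    return corrupt_alerts(central, behavior, rng)


def write_fixture(cohort: Cohort, alerts: pd.DataFrame,
                  out_dir: str | Path,
                  truth: pd.DataFrame | None = None) -> dict[str, Path]:
    """Write a simulated cohort in the submission CSV dialect."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"scr": out / "scr.csv", "alerts": out / "alerts.csv"}
    full = Cohort(cohort.results, alerts, dict(cohort.krt_start),
                  dict(cohort.lims_map))
    write_submission(full, paths["scr"], paths["alerts"])
    if truth is not None:
        paths["truth"] = out / "truth.csv"
        t = truth.copy()
        t["specimen_dt"] = t["specimen_dt"].dt.strftime("%Y-%m-%dT%H:%M")
        t.to_csv(paths["truth"], index=False)
    return paths
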