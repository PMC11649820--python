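import os
import sys

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, os.path.dirname(__file__))

from akival.io_model import Cohort, _empty_alerts  # noqa: E402


def make_results(rows):
    """Build a results frame from (mpi, lab, dt, scr[, dob, sex]) tuples."""
    recs = []
    for row in rows:
        mpi, lab, dt, scr = row[:4]
        dob = row[4] if len(row) > 4 else "1950-06-15"
        sex = row[5] if len(row) > 5 else "F"
        recs.append({"mpi": mpi, "lab_code": lab,
                     "specimen_dt": pd.Timestamp(dt), "scr": float(scr),
                     "dob": pd.Timestamp(dob), "sex": sex,
                     "location_code": None})
    df = pd.DataFrame(recs)
    return df.sort_values(["mpi", "specimen_dt", "scr"],
                          kind="mergesort").reset_index(drop=True)


def make_alerts(rows):
    """Build an alerts frame from (mpi, lab, dt, stage[, scr]) tuples."""
    if not rows:
        return _empty_alerts()
    recs = []
    for row in rows:
        mpi, lab, dt, stage = row[:4]
        scr = row[4] if len(row) > 4 else np.nan
        recs.append({"mpi": mpi, "lab_code": lab,
                     "alert_dt": pd.Timestamp(dt), "stage": int(stage),
                     "scr_at_alert": scr})
    return pd.DataFrame(recs)


def make_cohort(result_rows, alert_rows=(), **kwargs):
    return Cohort(make_results(result_rows), make_alerts(list(alert_rows)),
                  **kwargs)


@pytest.fixture
def audit_matrix():
    from akival.datasets import audit_confusion_matrix
    return audit_confusion_matrix()


@pytest.fixture
def zero_corruption_run():
    """Small simulated cohort with an uncorrupted alert stream (cached)."""
    return _zero_corruption_run()


_CACHE = {}


def _zero_corruption_run():
    if "run" not in _CACHE:
        from akival.synthetic_data import (CohortParams, LabBehavior,
                                           generate_cohort, simulate_lab_alerts)
        rng = np.random.default_rng(11)
        cohort, truth = generate_cohort(CohortParams(n_patients=300, seed=11), rng)
        alerts, gt = simulate_lab_alerts(cohort, LabBehavior(), rng=rng)
        _CACHE["run"] = (Cohort(cohort.results, alerts), truth, gt)
    cohort, truth, gt = _CACHE["run"]
    return cohort.copy(), truth, gt.copy()
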