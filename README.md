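# akival

Validation tooling for laboratory acute-kidney-injury (AKI) e-alert streams.

A national e-alert rule set stages every serum-creatinine (SCr) result 0-3
by comparing it with patient-level reference values from a 365-day
look-back. Laboratories run the algorithm locally and submit their stage
1-3 alerts (never stage 0) plus the creatinine results to a central
registry. `akival` re-implements the rule set centrally, pairs each result's
locally issued stage (received alert, or an inferred 0 after the lab's
first-ever alert) with the centrally recomputed stage, and quantifies
agreement with a weighted chance-corrected coefficient (Gwet's AC1,
combinatorial ordinal weights). A synthetic cohort generator with known
ground truth - including laboratory misbehaviour models (stage miscoding,
alert suppression, missing monthly files, variant "in-house" thresholds) -
makes the whole pipeline testable without access to registry data.

## Modules

| module | contents |
|---|---|
| `akival.io_model` | submission CSV readers/writers, validation, dedup, age/KRT exclusions, monthly completeness |
| `akival.aki_engine` | reference values (RV1/RV2/48-h minimum), staging rules, live dates, local-stage inference |
| `akival.synthetic_data` | cohort generator, lab-behaviour corruption, fixture writer |
| `akival.agreement` | confusion matrices, ordinal weights, weighted AC1 + closed-form SE/CI, bootstrap cross-check, interpretation bands |
| `akival.study_pipeline` | pairing, overall/per-lab/per-LIMS/per-year analyses, sensitivity and subgroup analyses, report bundle |
| `akival.datasets` | published aggregate tables (pooled cross-tabulation, stage counts) used by the acceptance report |

## CLI

```sh
# synthetic submission files with ground truth
akival simulate --n-patients 500 --months 24 --seed 1 --out sim/

# run the central staging algorithm over a submission
akival stage --scr sim/scr.csv --alerts sim/alerts.csv \
             --out central.csv --summary summary.json

# agreement for a paired-stage CSV or a literal 4x4 matrix
akival agree --pairs pairs.csv
akival agree --matrix matrix.csv --weights ordinal

# full pipeline from a YAML config
akival study --config study.yaml --out report/
```

A minimal `study.yaml`:

```yaml
seed: 1
simulate:
  n_patients: 500
  months: 24
  n_labs: 3
  behavior:
    suppression_prob: {"3": 0.5}
    monthly_missing_prob: 0.05
```

`report/` then contains `table1.json`, `table2.csv`, `table3.csv` (per-lab
agreement, ascending), `lims.csv`, `sensitivity.csv`,
`subgroups_*.csv` and `run.json`. Runs are byte-identical under a fixed
seed.

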