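# agreekit

Agreement analysis for method-comparison studies with clustered,
unbalanced, time-matched repeated measures — e.g. two devices measuring
respiratory rate on the same patients across many activities.

From a long-format table of readings (subject, device, activity,
replicate, value), agreekit estimates linear mixed models with crossed
random intercepts by REML and derives five agreement indices from the
fitted variance components:

- **CCC** — concordance correlation coefficient for repeated measures
  (a variance-ratio intraclass correlation under a fixed device effect);
- **Limits of agreement** — mixed-effects Bland–Altman limits, computed
  from a differences model (primary) and from the full two-device model,
  plus a fixed-effects ANOVA variant and the naive (clustering-ignoring)
  limits for comparison;
- **Coverage probability** — probability that a between-device
  difference falls within a clinically acceptable difference ±δ;
- **Total deviation index** — the half-width containing a proportion
  *p* of between-device differences (the inverse of CP), with a
  nonparametric quantile-based variant;
- **CIA** — coefficient of individual agreement (within-device
  replication MSD over between-device MSD), with the repeatability
  coefficient as its benchmark check.

Uncertainty comes from a subject-level (cluster) nonparametric bootstrap.
A synthetic-data module generates tables from the same generative models
with known variance components, including an unbalanced 21-subject /
11-activity template, so the full pipeline is testable with no external
data. Diagnostics (Q-Q data for BLUPs and residuals, residual-vs-fitted)
and Bland–Altman plot specs round out the toolkit.

## CLI

```sh
# simulate a COPD-like unbalanced dataset
agreekit simulate --seed 7 --out data.csv

# full agreement report (five indices + verdicts against the CAD)
agreekit report --input data.csv --reference gold --cad 5 --tdi-p 0.95

# cluster-bootstrap CI for one index
agreekit boot --input data.csv --reference gold --index cp --boot 1000 --seed 1

# nonparametric TDI with patient-level bootstrap upper bound
agreekit np-tdi --input data.csv --reference gold --boot 1000 --seed 1

# Bland-Altman plot spec (JSON) and image; model diagnostics
agreekit plot --input data.csv --reference gold --spec-out ba.json --image-out ba.png
agreekit diagnose --input data.csv --reference gold
```

Column names can be remapped with `--subject-col/--device-col/...` flags
or a YAML config (`subject:`, `device:`, `activity:`, `time:`, `value:`,
`reference:`). Machine output goes to stdout / `--out`; logs to stderr.
Exit codes: 2 usage error, 1 data/convergence error.

## Library

```python
from agreekit import (read_measurements, pair_differences, fit_full_model,
                      fit_diff_model, build_report, AgreementSettings)

table = read_measurements("data.csv", reference_device="gold")
pairs = pair_differences(table)                 # diff = test - reference
report = build_report(
    full_fit=fit_full_model(table),
    diff_fit=fit_diff_model(pairs),
    pairs=pairs,
    settings=AgreementSettings(cad_delta=5.0),
)
print(report.to_text())
```

Indices can also be evaluated directly from known variance components
(e.g. published estimates) via `FullModelFit.from_components(...)` /
`DiffModelFit.from_components(...)`.

## Optional real-data integration test

A public COPD respiratory-rate dataset (two devices, 21 subjects, 11
activities) can be used to reproduce the full published analysis. It is
not bundled; to enable the test, convert the public supplementary file to
`data/copd_rr.csv` as a long-format CSV with columns
`subject,device,activity,value` (device labels `gold` and the test
device). The tests in `tests/test_acceptance.py::TestRealDatasetIntegration`
then run automatically.

## Notes on estimation

REML with profiled residual variance and fixed effects; the optimizer
works on square-root variance ratios (exact boundary zeros allowed) with
analytic gradients in the dense path. Each objective evaluation factors
the q×q capacitance matrix; large crossed designs eliminate the biggest
random factor through a Schur complement. Fits are deterministic given
the data; all stochastic routines (simulation, bootstrap) take explicit
seeds.
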