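# obesim

A two-part Markov cohort model of lifetime BMI trajectories under two
infant-feeding strategies (lower-protein vs higher-protein formula), with a
health-economic evaluation layer: discounted lifetime costs and QALYs,
incremental cost-effectiveness (ICER), net monetary benefit (NMB) over a
willingness-to-pay grid, cost-effectiveness acceptability curves (CEAC) from
probabilistic sensitivity analysis (PSA), averted years with overweight or
obesity, and population-level savings scaling.

## Model structure

- **M1 (ages 0–18)** — annual transitions over four BMI states (normal
  weight incl. underweight, overweight, obese, dead), with arm-specific
  matrices during the intervention effect window (ages 0–5 by default) and
  life-table mortality applied uniformly across BMI states. Anyone who ever
  occupies overweight/obese carries an `EVER` history flag.
- **M2 (ages 18–100)** — continues from the age-18 hand-off with
  history-dependent mortality: baseline life-table risk × adult
  overweight/obesity relative risks × a childhood-history relative risk.
  Costs (direct + indirect, EUR 2015) accrue per age/sex/state; utilities
  accrue from age 18. Both streams are discounted to birth (3% default).

The LP arm's effect is a pair of relative risks multiplying the per-cycle
probabilities of becoming overweight/obese out of normal weight; arm
matrices may instead be estimated directly from a longitudinal panel.

## Modules

| module                | contents |
|-----------------------|----------|
| `obesim.params`       | domain types, BMI classification, CSV parameter bundle I/O, run configuration |
| `obesim.transitions`  | interval-to-annual probability conversion, panel MLE, relative-risk embedding |
| `obesim.engine`       | the two-part cohort engine, discounting, lifetime summaries |
| `obesim.psa`          | distribution specs (log-normal / gamma / uniform / fixed), PSA runner |
| `obesim.cea`          | increments, ICER, NMB, CEAC, averted years, population savings |
| `obesim.synth`        | synthetic ground-truth generator and trial-like panel simulator |
| `obesim.cli`          | `obesim` command-line pipeline |

## CLI

```sh
obesim synth --profile baseline --seed 42 --out bundle/ --panel-size 500
obesim estimate --panel bundle/panel.csv --out bundle/transitions_est.csv
obesim simulate --config bundle/config.yaml --params bundle/ --out run/
obesim psa --config bundle/config.yaml --params bundle/ \
    --specs bundle/psa_specs.yaml --draws 4000 --out psa/
obesim cea --config bundle/config.yaml --params bundle/ \
    --psa-draws psa/psa_draws.csv --out cea/
```

Exit codes: 0 success, 1 validation failure (the message names the offending
cell or file), 2 runtime failure. Runs are fully reproducible given the
seed; `simulate` writes a manifest with config/bundle hashes.

### Parameter bundle

A directory of UTF-8 CSV tables: `transitions.csv` (age, sex, arm,
from_state, to_state, prob), `mortality.csv` (age, sex, qx),
`mortality_rr.csv` (context, rr, ci_low, ci_high), `costs.csv` (age, sex,
state, component, mean, se), `utilities.csv` (age, sex, state, mean, se),
`intervention.csv` (outcome, rr, ci_low, ci_high, duration_years) and
`initial.csv` (sex, state, share). The run configuration is YAML or JSON
with unknown keys rejected.

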