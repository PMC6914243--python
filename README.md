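# trialcea

Trial-based cost-effectiveness analysis for a two-arm randomized trial with
repeated assessments (weeks 0/10/20/30): synthetic trial generation, clinical
and utility outcome derivation, resource-use costing from societal and
health-care-provider perspectives, baseline-adjusted mixed-model estimation of
incremental costs and effects, and Monte Carlo propagation to ICERs,
cost-effectiveness planes, and acceptability curves (CEACs) — plus the
CEAC-stability simulation used for sample-size planning.

## Modules

| Module | What it does |
| --- | --- |
| `trialcea.synthetic` | Two-arm trial generator: depression-score trajectories, utilities linked to severity, right-skewed window costs with rare inpatient events, session/feedback counts, and logistic (age/employment) follow-up missingness. |
| `trialcea.outcomes` | Reliable change index (change / SE 4.78), response (RCI < −1.96), remission (response AND score < 13), severity classes, completer status (≥ 14 of 18 sessions), cumulative QALYs via trapezoid integration of interpolated utilities. |
| `trialcea.costing` | Unit-cost tables (configurable; illustrative defaults), per-window category costs (medication + €6 dispensing fee, 30-min therapist feedback costing), cumulative costs via rate interpolation, perspective/variant aggregates. |
| `trialcea.models` | REML linear mixed models (statsmodels-backed, plus a fast self-contained profiled-REML random-intercept fitter used for bootstrap refits), logistic models for binary outcomes, and paired ΔC/ΔE estimation. |
| `trialcea.cea` | Cluster-bootstrap or parametric (ΔC, ΔE) draws, ICER with quadrant labels, plane quadrant distributions, CEACs (net-monetary-benefit rule), sensitivity variants, CEAC-stability power simulation. |
| `trialcea.pipeline` / `trialcea.cli` | Reproducible end-to-end runs with manifest, validation, and content-hash stage caching. |

## CLI

```bash
# generate a synthetic trial dataset
trialcea generate --seed 1 --out trial.csv

# validate dataset invariants
trialcea validate trial.csv

# full analysis (generate -> outcomes -> costs -> models -> CEA)
trialcea analyze --seed 1 --n-draws 1000 --out run/
trialcea analyze --dataset trial.csv --perspective provider --effect response \
    --n-draws 2000 --method cluster_bootstrap --sensitivity exclude_inpatient --out run/

# CEAC-stability sample-size simulation (n = 10..500 per arm)
trialcea power --n-grid 10,25,50,75,100,150,250,500 --reps 100 --out power.csv
```

Outputs land in the run directory: `dataset.csv`, `outcomes.csv`, `costs.csv`,
`models.csv`, `cea_summary.csv` (one row per perspective × effect measure with
ΔC/ΔE, CIs, ICER, quadrant percentages), `ceac.csv`, and `manifest.json`
(config echo, seed, versions, row counts). Identical config + seed reproduce
byte-identical artifacts.

## Notes

- The default unit-cost table is illustrative, not the national unit-cost
  manual; supply a real table (`--unit-costs costs.yaml`) for substantive work.
- QALYs use a year of 365.25/7 weeks; cumulative costs convert each 4-week
  recall window to a per-week rate and integrate the piecewise-linear rate
  curve (a window-scaling shortcut is available as `method="window_scale"`).
- The default Monte Carlo method is a within-arm patient-level cluster
  bootstrap with model refits; `parametric` draws independent normals per
  coefficient and ignores the within-patient cost–effect correlation.
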