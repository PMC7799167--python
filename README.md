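# prevproj

Discrete-time Markov illness-death projections of chronic-disease burden
under demographic change.

`prevproj` projects age- and gender-specific patient counts and average
prevalence rates (apr) for ten common chronic diseases (arthrosis, pulmonary
cancer, CHD, COPD, cerebrovascular disease, dementia, depression, diabetes,
dorsal pain, heart failure) from a base year (2018) to a horizon (2060). The
engine is a yearly three-state model — healthy, diseased, dead — with
recovery: each cohort is advanced along its Lexis diagonal with a survival
rate `sr`, a disease-specific mortality difference `md`, a recovery rate `r`
and an incidence rate `i`, and the resulting age-specific prevalence obeys a
cohort-size-free recursion with an analytic sensitivity decomposition and
fixed point.

## Modules

| module | role |
|---|---|
| `prevproj.demography` | cohort-component population projection, life-expectancy calibration (bisection-scaled death probabilities), old-age dependency ratio |
| `prevproj.illness_death` | the projection engine: cohort ledger (D/ND/I/P), prevalence recursion, sensitivity decomposition, status-quo comparator |
| `prevproj.scenarios` | six what-if transforms of the base-year rates (expansion 1/2, compression 1/2, prevention, extended recovery) plus status quo |
| `prevproj.claims_estimation` | p/i/r/md estimation from person-level claims panels (M2Q/M3Q quarter rules, gap-fill, lookback/follow-up windows) |
| `prevproj.synthetic_data` | bundled German reference tables (age-group rates, 83.0 M pyramid, survival), mean-preserving single-age expansion, and an individual-level microsimulator |
| `prevproj.cli_reporting` | pipeline driver (variant × disease × scenario), result tables, CLI |

Population variants: `stationary`, `le_constant`, `le_increasing` (life
expectancy at birth ramps to 88.1 years for women / 84.4 for men by 2060)
and `migration` (illustrative stylised net-immigration schedule).

## CLI

```sh
prevproj fixture --out fixture/            # emit the bundled reference inputs
prevproj project --variant le_increasing \
    --disease dementia --scenario expansion1 --out results/
prevproj simulate --n-persons 50000 --years 10 --seed 1 --out panel.tsv
prevproj estimate panel.tsv --disease diabetes --out rates.csv
```

`project` writes `trajectories.csv` (year × apr × patient count),
`snapshots.csv` (2018/2040/2060), `relative_change.csv` and a
`manifest.json` with the config hash and any clamping warnings. A YAML
config can replace the flags (`prevproj project --config run.yaml`).

## Qualitative behaviour on the bundled fixture

Under the baseline expansion scenario with rising life expectancy, dementia
shows the largest *relative* apr increase (~2.6× by 2060) while dorsal pain
remains the largest *absolute* burden; the base-year disease ranking by apr
is unchanged in 2060. Prevention (incidence −30 % by 2035) is the only
scenario that lowers long-term burden for every disease, and even the
compression scenarios leave an increase for all ten diseases.

## Notes

- 2040/2060 *numerical* projections depend on official single-age inputs
  that are not bundled; the suite instead verifies the machinery with exact
  invariants (ledger/recursion equivalence at 1e-12, analytic fixed point,
  finite-difference checks) and Monte-Carlo equivalence against the
  microsimulator.
- The migration variant's schedule is stylised and results carry an
  `illustrative_variant` flag in the run manifest.
- Claims estimators follow treatment-rate conventions (insured-day-weighted
  period prevalence, disease-free-lookback cumulative incidence,
  follow-up-window recovery, survival-difference md); their small known
  biases are characterised in the test suite.
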