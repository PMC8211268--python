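# mammosim

Multilevel breast-cancer microsimulation: per-woman natural histories
across tumor, person, and health-system levels; screening and treatment
intervention scenarios under common random numbers; and benefit/harm
outputs (overdiagnosis, deaths averted, life-years gained, harm/benefit
ratios, screening-vs-treatment mortality attribution).

All parameter tables ship as documented **synthetic defaults**: the
stratification shapes (age groups, BI-RADS density, ER/HER2 subtype,
stage, screening interval, calendar period) are meaningful; the values
are plausible but deliberately uncalibrated.  Nothing is downloaded.

## Layout

| module | role |
|---|---|
| `mammosim.fixtures` | parameter tables: synthetic defaults, CSV/YAML I/O, validation, background incidence (table or linear-from-1975 variant) |
| `mammosim.population` | person level: other-cause death sampling, BI-RADS density trajectories (triangular stay-or-step-down solve), risk profiles, cohorts |
| `mammosim.natural_history` | latent tumor histories: clinical-incidence draw, subtype, sojourn, stage via table / stage-dwell / Gompertz-growth mechanisms |
| `mammosim.dcis` | DCIS multistate model (undetectable → preclinical → clinical/invasive/regressed) and overdiagnosis estimation |
| `mammosim.screening` | strategies, schedules, stratified test performance, screen events, first detection |
| `mammosim.treatment` | dissemination-based treatment assignment; hazard-reduction or cure-fraction survival |
| `mammosim.outcomes` | counters, direct age standardization, deaths averted / life-years gained, harm/benefit ratios, Shapley attribution, ensemble summaries |
| `mammosim.engine` / `mammosim.cli` | scenario orchestration under common random numbers; command-line interface |

Common random numbers: every draw comes from a stream keyed by
`(seed, woman, purpose)` (and, for screens, the quantized screen age), so
natural histories are bitwise identical across scenarios and paired
scenario differences are low-variance.

## CLI

```sh
mammosim params init --variant hazard_reduction --seed 1 --out params/
mammosim params validate params/config.yaml

cat > run.yaml <<'YAML'
cohort: {n: 20000, birth_year: 1970}
parameters: {variant: hazard_reduction}
comparator: none
scenarios:
  - {label: none}
  - {label: screen_only, screening: {segments: [[50, 74, 2]]}}
  - {label: treat_only, treatment: true}
  - {label: both, screening: {segments: [[50, 74, 2]]}, treatment: true}
YAML
mammosim run --config run.yaml --seed 7 --out results/
mammosim attribute --results results/       # screening vs treatment shares
mammosim report --results results/
mammosim dcis sweep --progression 0.3,0.5,0.8 --regression on,off
```

Screening segments are `[start_age, end_age, interval_years]` (interval
`null` = one-time screen); a hybrid strategy is a list of segments, e.g.
annual 45–54 then biennial 55–74: `[[45, 54, 1], [55, 74, 2]]`.

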