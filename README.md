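# nsum

A toolkit for the **network scale-up method (NSUM)** of hidden-population
size estimation, as used in HIV key-population surveillance:

- **Known-population degree estimation** — a respondent's personal network
  size `c = m·t/e0` from counts of alters in subpopulations of known size
  (`study_frame`, `scale_up`).
- **Quantitative unrelated-question randomized response** — masking of a
  sensitive alter-count question and algebraic unmasking of its mean and
  variance (`rrt`).
- **Basic scale-up estimate** `e1 = (m1/c)·t` and the name-proportion
  correlation diagnostic (`scale_up`).
- **Barrier/transmission adjustment** — popularity ratio `δ` and
  information transmission rate `τ` from a chain-referral (RDS) survey of
  the hidden population; adjusted size `e1/(δ·τ)` and adult prevalence
  (`adjustment`).
- **Bootstrap confidence intervals** — respondent/cluster bootstrap for the
  general survey, a recruitment-chain bootstrap for the RDS survey, and a
  joint bootstrap that re-runs the whole chain (including RRT re-unmasking)
  per resample (`uncertainty`).
- **Synthetic survey generator** — both surveys simulated from a fully
  specified ground truth (true size, popularity ratio, transmission rate,
  RRT design, recruitment chains), so every estimator is verifiable
  end-to-end (`synthetic`).

## CLI

```bash
# generate a synthetic world (surveys + frame config + ground truth)
nsum simulate --out sim/ --seed 1 --n-general 1747 --n-rds 302

# run the full estimation chain with joint-bootstrap CIs
nsum estimate --general sim/general_survey.csv --rds sim/rds_survey.csv \
              --frame sim/frame.yaml --out results/ --seed 1 --B 10000

# recompute the published arithmetic chain from its printed inputs
nsum replicate-paper
```

`estimate` writes `report.json` (machine-readable, schema-stable) and
`report.txt`. All warnings (popularity ratio above 1, name-fraction band
violations, negative unmasked means) are surfaced in the report.

### Input formats

- **Frame config** (YAML/JSON): `t`, `adult_pop`,
  `known: [{label, size}, ...]`, plus `rrt: {p1, p2}` for the estimate
  command.
- **General survey CSV**: `id, industry, unit, department,
  name_<label>…, rrt_group, rrt_answer, answered`. Missing counts are read
  as unanswered (blank sheets).
- **RDS survey CSV**: `id, recruiter_id, wave, name_<label>…,
  aware_<label>…`. Empty `recruiter_id` marks a seed (wave 0).

## Notes

- All ratio estimators are ratio-of-means (one pooled mean, one ratio), as
  in the source analysis; mean-of-ratios variants exist for diagnostics.
- Bootstrap CIs are percentile intervals; the RDS flavor regrows
  recruitment chains (a plain respondent bootstrap is available via
  `--rds-flavor respondent`).
- Every stochastic operation takes a seed and is exactly reproducible.
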