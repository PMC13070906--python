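# tnsalvage

Reusable, tested building blocks for studying **salvage therapy of recurrent
trigeminal neuralgia (TN)** after failed microvascular decompression, where the
salvage procedure is percutaneous balloon compression (PBC) and the comparator
is Gamma Knife radiosurgery (GKRS). The package covers the full analysis chain
such a study needs, exercised entirely on a calibrated synthetic cohort
generator (no patient data ship with, or are needed by, this package):

1. **`tnsalvage.cohort`** — a seeded synthetic cohort generator. Recurrence
   times follow a piecewise-exponential proportional-hazards model
   λ(t | x) = λ_epoch · exp(Σ_j β_epoch,j x_j) with epoch-specific covariate
   effects switching at 24 months (hypertension acts early, ophthalmic-division
   (V1) involvement late, a latent "PBC-resistant" class in both epochs),
   administrative censoring, and biomarkers (IL-6, norepinephrine, a scalar
   default-mode-network score). Baseline hazards are calibrated so the
   population-marginal survival passes through target (time, survival) points;
   an IL-6/time coupling coefficient is calibrated by bisection so that
   corr(IL-6, pain-free time) hits a target.
2. **`tnsalvage.survival`** — from-scratch survival machinery on
   counting-process data: Kaplan–Meier product-limit estimation with Greenwood
   variance and log-log bands, Brookmeyer–Crowley median CIs, the two-group
   log-rank test, Cox partial-likelihood fitting (Efron ties, Newton–Raphson),
   and the 24-month epoch-split (time-varying-effect) Cox analysis.
3. **`tnsalvage.latent`** — latent class analysis: EM for a finite mixture of
   independent Bernoulli indicators, BIC model selection, MAP assignment, and
   the class-vs-outcome Cox association.
4. **`tnsalvage.markov`** — a two-arm, four-state (PainFree, Recurred,
   PostReintervention, Dead) annual-cycle Markov cohort cost-utility engine:
   probability/rate identities, transition calibration to printed
   reintervention and recurrence-free survival rates, value calibration to
   printed per-arm cost/QALY totals, ICER/dominance logic, one-way sensitivity
   analysis and probabilistic sensitivity analysis with a CEAC.
5. **`tnsalvage.pipeline`** — one reproducible run of the whole chain
   (generate → impute → survival → LCA → cost-utility → report bundle), with
   simplified chained-equations multiple imputation pooled by Rubin's rules.

## Worked example

```bash
tnsalvage survival --seed 42 --out results/
```

generates a calibrated cohort of 5,000 synthetic patients and prints

```
median pain-free interval: 3.22 y (95% CI 3.10-3.85)
  hypertension[early]: HR 2.15 (1.93-2.39), p=6.32e-46
  v1_involved[late]: HR 2.57 (2.17-3.04), p=1.07e-27
  latent_resistant[all]: HR 3.85 (3.51-4.23), p=3.64e-176
```

The epoch-partitioned Cox fit recovers the generator's configured effects: a
hazard ratio ≈ 2.15 for hypertension on early relapse (≤ 24 months), ≈ 3.02
for V1 involvement on late relapse (the 2.57 here is 1.9 standard errors below
the configured value — sampling noise at n = 5000), and ≈ 4.12 for the
resistant latent class. The cost-utility verb

```bash
tnsalvage cua --out results/
```

prints

```
PBC: cost 14230, QALY 9.70
GKRS: cost 16075, QALY 8.90
delta cost -1845, delta QALY 0.80 -> dominant
```

i.e. after transition and value calibration, PBC saves 1,845 monetary units
and gains 0.8 QALYs over the 10-year horizon — PBC *dominates* GKRS (cheaper
and more effective), so no ICER is defined. `tnsalvage report` runs the whole
pipeline and writes a checksummed bundle of tables, curves and JSON results;
`tnsalvage psa` writes the cost-effectiveness acceptability curve.

The library surface mirrors the CLI: see `tnsalvage.generate_cohort`,
`km_estimate`, `epoch_cox`, `lca_em`, `run_cohort_trace`, `compare_arms`,
`run_pipeline`.

## Layout

```
src/tnsalvage/      cohort.py survival.py latent.py markov.py pipeline.py cli.py
tests/              unit, property and acceptance tests (pytest + hypothesis)
docs/methods.md     model assumptions, calibration details, design choices
scripts/acceptance.py
```
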