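# resistscope

Statistical pipeline for dissecting metabolic and target-site
insecticide resistance in mosquito populations, built around the
multi-assay evidence chain used for extreme bendiocarb (carbamate)
resistance in *Anopheles gambiae*: cytochrome P450 (CYP6) over-
expression combined with duplication of resistant *ACE-1* G119S
alleles.

It is aimed at vector-biology and resistance-surveillance analysts who
have tabular assay exports (two-colour microarray log-ratios, qPCR Ct
tables, TaqMan endpoint fluorescence, WHO-bioassay counts, dose-
response survival, HPLC peak areas) and want a reproducible, tested
path from those tables to candidate genes and resistance statistics.

## What it computes

* **Differential expression** — per-probe least squares on the
  log-ratio scale, one equation per array
  (`M = offset[cy5] − offset[cy3] + ε`), for dye-swap and interwoven
  loop designs alike; empirical-Bayes variance moderation
  (posterior s̃² = (d₀s₀² + d·s²)/(d₀ + d)) and Benjamini–Hochberg
  q-values per comparison.
* **Consensus filtering** — a probe is called resistance-associated
  only if every resistant-vs-susceptible comparison agrees in sign,
  every q < 0.05, and selected-line fold-changes are more extreme than
  unexposed ones; overall calls require both experiments, aggregated
  to genes as significant/total probe counts.
* **qPCR** — efficiency-corrected ΔΔCt relative expression
  (quantity = (1+E)^(−Ct), reference genes combined by geometric
  mean), F-test-guided pooled/Welch over-expression tests, and
  *ACE-1* copy-number ratios from three amplicons × two single-copy
  references against calibrator pools, with carriers flagged at
  ratio > 1.5.
* **Genotyping** — TaqMan G119S calls by angular position against
  control-anchored references with no-call guards, heterozygote
  FAM/VIC dye-balance contrasts (Welch t), allele frequencies with
  Wilson intervals, Hardy–Weinberg χ², 2×2 association with Woolf
  odds-ratio intervals, and Woolf homogeneity-of-odds-ratios across
  strata.
* **Phenotypes** — pooled bioassay mortality with Wilson 95% limits,
  PBO-synergism odds ratios, LC50 = 10^((0.5 − a)/b) from
  survival-on-log10-dose regression with Fieller confidence limits,
  exact (enumerated, tie-aware) two-sided Mann–Whitney tests at a
  discriminating dose, and percent substrate depletion versus
  no-NADPH controls.
* **Synthetic data** — generators that plant ground truth for every
  stage, so each estimator can be validated against known answers.

## Worked example

Simulate a complete study with planted truth and run the whole chain:

```sh
resistscope simulate all --seed 4 --out data/
resistscope run-all --data data/ --out out/
```

which prints

```
report written to out/report.json
consensus genes: ACE1, CYB5, CYP6M2, CYP6P1, CYP6P2, CYP6P3, CYP6P4
```

— exactly the seven genes the simulation planted as resistance-
associated in both experiments (decoy genes perturbed in only one
experiment are correctly excluded). From `out/report.json` of that
run:

* `copy_number`: `survivor_extra: 15/16`, `dead_extra: 5/16`,
  Welch p ≈ 1.6e-4 — bioassay survivors carry extra *ACE-1* copies at
  the planted split, and the ratio contrast flags it.
* `synergism.bendiocarb`: mortality 0.18 without vs 0.74 with PBO,
  odds ratio 12.6 (95% CI 7.8–20.4) — the planted strong carbamate
  synergism, consistent with P450-mediated resistance.
* `discriminating_dose.CYP6M2`: resistance ratio 5.9 with exact
  Mann–Whitney p = 0.000155, the smallest two-sided p attainable with
  8 + 8 vials (2/12870).
* `depletion`: CYP6P3 63.1 ± 0.5 % substrate depletion; CYP6M2 raw
  −1.2 % reported as 0 % (clamped) — one enzyme metabolises the
  insecticide in vitro, the other does not.

Every number in the report traces to a stage output file
(`contrasts_exp1.tsv`, `genes.tsv`, `copynumber.tsv`, `lc50.tsv`, …)
and the provenance block records the config hash and package version.

The same stages are importable as a library
(`resistscope.diffexpr.run_differential_expression`,
`resistscope.qpcr.copy_number_ratio`,
`resistscope.phenotypes.fit_lc50`, …) and as individual CLI
subcommands (`diffexpr`, `consensus`, `qpcr expression|copynumber`,
`genotype`, `bioassay`, `doseresponse`, `depletion`).

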