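# gutmr

Two-sample Mendelian randomization (MR) for microbiome-associated genetic
variants: a tested, reusable implementation of the full decision framework
used to ask whether genetically-predicted gut bacterial abundance causally
affects health outcomes.

## Who this is for

Epidemiologists and statistical geneticists who have (a) instrument tables —
per-variant summary statistics linking SNPs to the relative abundance of a
bacterial taxon, harvested from microbiome GWAS — and (b) outcome summary
statistics from a phenome-wide scan, and who want to run the complete
two-sample MR palette with its diagnostics, rather than a single estimator.
Because individual-level biobank data are typically access-restricted, the
package ships a synthetic-cohort generator that reproduces the statistical
structure of the design (non-overlapping exposure/outcome samples, latent
relative-abundance exposure, liability-threshold binary outcomes, planted
pleiotropy, weak instruments, winner's curse, reverse causation), so every
stage is testable end to end.

## What it computes

Instruments are assembled by a genome-wide significance filter
(P < 5×10⁻⁸), within-study LD clumping at r² < 0.005 in a 5 Mb window,
deduplication to the most differentiated taxonomic level, a
relative-abundance unit filter, and pooling to family/genus/species rank.
After allele harmonization and Steiger directionality filtering (with
liability-scale R² for binary outcomes), the instrument count k routes the
analysis:

* **k = 1** — Wald ratio β̂ = β_Y/β_X with SE = SE_Y/|β_X|, Steiger verdict,
  and instrument strength F = R²(n−2)/(1−R²) (weak below 10);
* **k = 2** — IVW fixed and multiplicative random effects
  (β̂ = Σwβ_Xβ_Y / Σwβ_X², w = 1/SE_Y²; random-effects SE inflated by
  max(1, √(Q/(k−1)))), Cochran's Q and I², and the "unweighted" MR
  (exposure betas replaced by ±1, SE by 0) guarding against unit
  differences between source studies;
* **k ≥ 3** — additionally MR-Egger (free intercept = average directional
  pleiotropy), the Rucker model-selection sequence (Q vs Q′, selecting IVW
  fixed / IVW random / Egger), I²_GX for Egger regression-dilution risk,
  weighted median and weighted mode with parametric-bootstrap SEs, and
  MR-Lasso (L1-penalized per-variant intercepts with a heterogeneity
  stopping rule);
* **k ≥ 4** — additionally MR-PRESSO (simulation-based global, outlier and
  distortion tests with an outlier-corrected IVW).

A conditional sensitivity stage builds unweighted family-level genetic risk
scores (integer sums of abundance-increasing allele dosages) and refits
single-variant associations with the community of scores as covariates.

## Worked example

```bash
gutmr run --preset valid_instruments --seed 3 --out demo_run
```

simulates two non-overlapping cohorts of 20,000 people with 25 instruments
and a true causal effect of 0.3, assembles and harmonizes the instrument
tables, and writes `demo_run/mr_estimates.tsv`. The pooled FamilyA set
(5 instruments) yields, abridged to four decimals:

```
exposure_label  level   method           model   beta    se      p          k_snps
FamilyA         family  ivw_fe           fixed   0.2855  0.0108  8.0e-154   5
FamilyA         family  ivw_re           random  0.2855  0.0121  1.2e-123   5
FamilyA         family  egger_slope              0.2345  0.0594  7.9e-05    5
FamilyA         family  egger_intercept          0.0341  0.0389  0.3797     5
FamilyA         family  weighted_median          0.2755  0.0146  5.7e-79    5
FamilyA         family  lasso                    0.2855  0.0108  8.0e-154   5
```

The IVW estimate recovers the planted effect of 0.3 to within sampling
error, the Egger intercept is compatible with zero (no directional
pleiotropy, as constructed), and the diagnostics table reports Q = 4.99 on
4 df (P = 0.29), I²_GX = 97.1% and `selected_model = ivw_fixed` for this
exposure — the Rucker sequence finds no heterogeneity to explain.
`demo_run/mr_diagnostics.tsv` carries Q, Q′, I², I²_GX, the Egger intercept
test and the Rucker-selected model per exposure, and `manifest.json`
records configuration, per-stage counts and output checksums for exact
reruns. The `directional_pleiotropy`, `weak_instruments`, `winners_curse`
and `reverse_causation` presets demonstrate each failure mode the
diagnostics are designed to catch.

The library surface mirrors the pipeline: `gutmr.ivw`, `gutmr.egger`,
`gutmr.weighted_median`, `gutmr.mr_presso`, `gutmr.steiger_filter`,
`gutmr.rucker_framework`, `gutmr.route_analysis`, … operate on
`HarmonizedPair` lists built by `gutmr.harmonize_tables`.

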