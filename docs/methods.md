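# Methods

## The estimation problem

Each analysis asks whether the relative abundance of a gut bacterial taxon
(exposure X) causally affects a health outcome Y, using genetic variants
G_j as instruments in a two-sample design: per-variant exposure effects
(β_Xj, SE_Xj) come from microbiome GWAS, outcome effects (β_Yj, SE_Yj)
from a phenome-wide scan in an independent cohort. Under the instrumental
conditions (relevance, independence from confounders, exclusion
restriction) each ratio β_Yj/β_Xj estimates the causal effect θ; the
methods differ in which violations they tolerate.

## Estimators

**Wald ratio** (k = 1): θ̂ = β_Y/β_X, SE = SE_Y/|β_X| (first-order delta;
exposure-side uncertainty ignored, standard when the exposure GWAS is
large — a second-order correction is a documented possible extension).

**IVW**: weighted zero-intercept regression of β_Y on β_X with weights
w_j = 1/SE_Yj², i.e. θ̂ = Σw β_X β_Y / Σw β_X². Fixed-effects
SE = (Σw β_X²)^{-1/2}; the multiplicative random-effects model scales it
by max(1, √(Q/(k−1))), never below the fixed SE, so overdispersion only
ever widens intervals.

**MR-Egger**: the same regression with a free intercept after orienting
every pair to β_X ≥ 0. The slope estimates θ when the InSIDE condition
holds; the intercept estimates average directional pleiotropy and its
P < 0.05 flags unbalanced pleiotropy. SEs are inflated by
max(1, √(Q′/(k−2))).

**Weighted median / weighted mode**: ratio estimates ordered with weights
β_X²/SE_Y²; the median interpolates the ordered ratios at cumulative
midpoint weight 0.5, the mode maximizes a normal-kernel weighted density
on a 512-point grid spanning the ratios ± 3 bandwidths (modified Silverman
bandwidth 0.9·min(sd, IQR/1.349)·k^{−1/5}, scale factor configurable;
when all ratios coincide the common ratio is returned). Both SEs come from
a seeded parametric bootstrap resampling (β_X, β_Y) from normal
distributions at their SEs; default 5,000 draws.

**Unweighted MR**: β_X replaced by sign(β_X) ∈ {−1, +1} with SE_X = 0,
then IVW with outcome weights, and Cochran's Q recomputed on the
transformed pairs. This deliberately discards the exposure effect scale,
guarding against relative-abundance units meaning different things across
source studies; the estimand is therefore per allele, not per unit of
exposure, and the estimate is exactly invariant to positive rescaling of
the exposure betas.

**MR-Lasso**: β_Yj = θβ_Xj + α_j with L1 penalty λΣ|α_j| and weights
1/SE_Yj², solved by coordinate descent (soft-thresholding the α update).
The grid runs 50 log-spaced values from λ_max (the smallest penalty
zeroing every α) down to λ_max·10⁻³; traversing from the largest penalty
down, the first λ whose valid set (α_j = 0, at least two variants) passes
Cochran's Q at the 95% chi-square point is selected — the least-penalized
model consistent with homogeneity — and θ̂ is the IVW fit on that set.

**MR-PRESSO** (k ≥ 4): each variant's squared residual about its
leave-one-out IVW prediction is summed into an observed RSS and compared
with n_sim = 1,000 parametric simulations drawn at the leave-one-out fits
(β_X* ~ N(β_X, SE_X), β_Y* ~ N(θ̂_{−j}β_X, SE_Y)); the global p is the
fraction of simulated RSS at least as large. Per-variant outlier p-values
come from each variant's simulated residual distribution,
Bonferroni-corrected over k at α = 0.05. The distortion test compares the
shift between all-variant and outlier-corrected IVW estimates against
1,000 random removals of the same size. Simulation size, seed and outlier
α are recorded in every result object.

## Diagnostics and decision logic

Cochran's Q = Σ (β_X²/SE_Y²)(ratio_j − θ̂)² with df = k−1 and
I² = max(0, (Q−df)/Q)·100. Rucker's Q′ is the Egger residual
heterogeneity (df = k−2); adding the intercept can only reduce the
weighted RSS, so Q′ ≤ Q always. Model selection: Q non-significant → IVW
fixed; Q significant but Q−Q′ not → IVW random (at least balanced
pleiotropy); Q−Q′ significant → Egger (unbalanced pleiotropy). The Q−Q′
statistic is referred to χ²₁ after scaling by the residual overdispersion
max(1, Q′/(k−2)): the unscaled difference is the squared fixed-effects
z-score of the intercept, which rejects almost surely whenever balanced
pleiotropy inflates heterogeneity, defeating the framework's own purpose
of separating balanced from directional pleiotropy.

Instrument strength: per-variant R² = 2β²f(1−f) / (2β²f(1−f) +
SE²·2nf(1−f)) — the allele-frequency factors cancel, so R² depends only
on the z-ratio and n — and F = R²(n−2)/(1−R²), flagged weak below 10.
I²_GX = max(0, (Q_GX−(k−1))/Q_GX)·100 with Q_GX the dispersion of the
oriented exposure betas against their SEs; values well above 95% indicate
low Egger regression-dilution risk.

Steiger filtering converts exposure and outcome R² (the latter mapped to
the liability scale for binary traits via the multiplier
K²(1−K)²/(z²P(1−P)), z the normal density at the prevalence threshold) to
correlations and compares them with a two-sample Fisher z-test using
independent-cohort SEs √(1/(n_X−3) + 1/(n_Y−3)). A variant is removed
only when the outcome R² significantly exceeds the exposure R²
(P < 0.05) — evidence that it acts on the outcome first. The liability
multiplier grows as a disease gets rarer when the analyzed case fraction
tracks the prevalence (K(1−K)/z² at P = K); at a fixed case fraction the
K-dependent factor instead shrinks toward K = 0.

The router is a pure function of the instrument count: k = 1 → Wald +
Steiger + F only; k = 2 → IVW fixed/random, Q, I², unweighted MR; k ≥ 3
adds Egger, Rucker, weighted median/mode, MR-Lasso, I²_GX; k ≥ 4 adds
MR-PRESSO.

## Scan stage

The phenome scan fits outcome ~ dose + covariates per (variant, outcome):
ordinary least squares for continuous outcomes, logistic IRLS
(tolerance 10⁻⁸, 50 iterations) for binary, two-sided Wald p against the
standard normal (chosen over t because the design targets biobank-scale n;
small-n synthetic tests use the same reference). Binary outcomes at
prevalence ≤ 1% are excluded; multiple testing is Bonferroni over the full
variant × outcome grid. Missing data are complete-case per pair;
monomorphic variants and non-converged or separated logistic fits are
flagged rather than silently dropped. Linear fits use a
Frisch–Waugh–Lovell projection (covariates residualized out once), which
is algebraically identical to the full OLS fit and is cross-checked
against a normal-equations oracle in the tests. Sex-interaction scans add
a dose×sex term (sex retained as a main effect) and test the interaction
coefficient.

## Synthetic cohorts

`simulate_cohort` draws genotypes i.i.d. Binomial(2, maf) with maf ~
U(0.1, 0.5), a latent continuous relative-abundance exposure
X = Σγ_j G_j + confounder load + N(0, σ²), and a continuous outcome
Y = θX + Σα_j G_j + confounder load + N(0, 1); binary outcomes threshold
the liability at the empirical prevalence quantile. Exposure and outcome
samples share the generating parameters but no individuals, and one root
seed expands to per-purpose child streams so adding a component never
perturbs earlier draws. The generator emulates the statistical structure
the estimators assume — it does not simulate compositional microbiome
communities, 16S reads, LD between instruments, or assortative mating, so
passing tests certify estimator behaviour under the stated model, not
robustness to those real-data features.

Preset scenarios (defaults: 25 instruments, 20,000 per sample, θ = 0.3):

* `valid_instruments` — γ ~ U(0.15, 0.9), no pleiotropy. This is the
  strong-instrument idealization under which the framework's validity
  gates hold with margin (median F ≈ 500, I²_GX ≈ 99%): mean-unbiasedness
  of the estimators is only a meaningful target when the exposure betas
  are precise relative to their spread, since every ratio-based method
  carries an O(1/F) attenuation and Egger an attenuation of roughly
  (1 − I²_GX/100). The preset's instruments are the designed set — no
  in-sample significance selection, which is precisely the
  `winners_curse` failure mode. The implied heritability is accordingly
  higher than a typical single taxon's; realism on that axis is traded
  for a clean validity benchmark, and the weak/winner's-curse presets
  cover the realistic-strength regime.
* `balanced_pleiotropy` — α ~ N(0, 0.1): heterogeneity without bias.
* `directional_pleiotropy` — α ~ N(0.1, 0.05): IVW biased upward, the
  Egger intercept detects it.
* `weak_instruments` — γ ~ U(0.02, 0.06) discovered in n = 2,000 (F near
  or below 10).
* `winners_curse` — γ ~ U(0.09, 0.15) in n = 5,000 with in-sample
  P < 5×10⁻⁸ selection: selected exposure betas are inflated, attenuating
  two-sample estimates toward the null.
* `reverse_causation` — instruments act on the outcome; the exposure is
  downstream (X = θ·liability + noise), so Steiger filtering should
  remove most variants.

## Numerical choices and degenerate inputs

Wald ratio at β_X = 0 is a domain error; pairs with β_X = 0 are excluded
from the unweighted MR with a log entry. IVW with all β_X = 0 is
degenerate. Egger requires k ≥ 3 and non-collinear oriented β_X. Clumping
ties on p break by chromosome string, then position, then variant id, for
platform-independent determinism; the clump window |Δpos| ≤ 5 Mb is
inclusive; variant pairs absent from the LD table count as r² = 0 (an
optional distance-only radius can force r² = 1 nearby, disabled by
default). Palindromic (A/T, C/G) variants are dropped when either allele
frequency lies in 0.5 ± 0.08, is missing, or the two frequencies sit on
opposite sides of 0.5. Missing exposure SEs are reconstructed from
(β, p) via the two-sided normal quantile. All bootstrap and simulation
procedures are bit-reproducible given their seed and size. p-values are
floored at the smallest positive double rather than reported as 0.

## Problem sizes in the shipped checks

The test suite and the acceptance script run the recovery studies at the
preset conditions with 200 replicate cohort pairs (bootstrap SEs reduced
to 8 draws there, since only point estimates enter the means), 1,000 null
replicates for error-control calibration, 100 seeds at n_sim = 1,000 for
the planted-outlier study, and 10 cohort pairs per arm for the Steiger
drop rates; these sizes give Monte-Carlo SEs well below the effects being
checked.

## Known limitations

* MR-Egger's regression-dilution attenuation (~1 − I²_GX/100) is
  irreducible at fixed discovery-sample size; at n = 20,000 it amounts to
  roughly 1% of θ under the valid preset, visible in a 200-replicate mean.
  No SIMEX-style correction is implemented.
* Multivariable MR, colocalization, radial-Q variants and
  contamination-mixture estimators are out of scope.
* The harmonization rules reconstruct standard two-sample practice; the
  audit log flags every action so alternative conventions can be compared.
* LD information must be supplied; the package does not compute r² from
  reference panels or search for proxy variants.
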