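# Methods

## Dose conversions

All conversions use the linear-quadratic model with a single tumor α/β
ratio (default 10 Gy, configurable, strictly positive). For a scheme of
`n` fractions of `d` Gy:

* `BED = n·d·(1 + d/(α/β))` — always strictly greater than the physical
  dose `n·d`, increasing in both `n` and `d`, and larger for fewer, bigger
  fractions at fixed total dose.
* `EQD2 = n·d·(d + α/β)/(2 + α/β)` — equal to the physical dose exactly at
  d = 2 Gy.

The isocenter (plan-maximum) dose is modelled by scaling the *dose per
fraction* by the normalization factor rather than the total dose alone:
the maximum dose is delivered in the same number of fractions, and because
BED is nonlinear in `d`, per-fraction scaling makes the isocenter BED grow
faster than the factor itself. Normalization scenarios P110 and P120 place
the plan maximum at 1.10× and 1.20× prescription; the factor must strictly
exceed 1 (a plan maximum at or below prescription is rejected as invalid).

## TCP models

Five dose-response families sit behind one `predict()` router that selects
the dose quantity (prescription vs isocenter; BED vs EQD2) per model and
enforces each model's horizon contract (a 2-year-only model asked for a
3-year value raises an error, mirroring the NA cells of the report tables).

* **Logistic (Ohri / Guckenberger / Santiago).**
  `TCP(x) = exp((x−TCD50)/k)/(1+exp((x−TCD50)/k))` evaluated via
  `scipy.special.expit`, which is overflow-safe and saturates to 0/1 for
  |x| far from the midpoint. TCD50 is a fitted regression constant on the
  BED scale and may be negative; k > 0 sets the steepness. Parameters:
  Ohri (0 Gy, 31 Gy) on the **prescription** BED₁₀ with a linear size
  penalty `x = BED − c·L` (c = 10 Gy/cm, L = greatest tumor diameter in
  cm); Guckenberger (−1 Gy, 80 Gy) and Santiago (−60.2 Gy, 113.3 Gy) on
  the **isocenter** BED₁₀ at 3 years.
* **Martel (2 years).** The literature pins down only "a logistic
  dose-response" with D50 = 72.0 Gy and normalized slope γ50 = 2.0, so the
  functional form is a configurable strategy. The default is the logit
  power form `1/(1+(D50/D)^(4γ50))`, computed as
  `expit(4γ50·ln(D/D50))` for symmetry; zero dose maps to zero control.
  The alternative `exponential-logistic` form
  `1/(1+exp(4γ50(1−D/D50)))` crosses 0.5 at the same midpoint with the
  same normalized slope but differs away from it; reproductions of
  published numbers may require either. The dose argument is the
  2-Gy-equivalent (EQD2) of the **isocenter** dose — the design leans on
  the isocenter dose being the better-determined predictor in lung SBRT,
  and the choice is exposed in configuration.
* **Tai (2 and 3 years).** A regrowth dose-response on the isocenter
  BED₁₀: control at a later follow-up can only be lower, encoded as a
  horizon-indexed midpoint that is non-decreasing in the horizon, with a
  shared slope scale. The published multi-institutional coefficients
  ("Model Fit II" of Tai et al.) are not redistributed here. The shipped
  defaults (k = 45 Gy; midpoints −15 Gy at 2 y, +5 Gy at 3 y) are a
  synthetic placeholder chosen once to give ≈95%/92% LC at an isocenter
  BED₁₀ of ~115 Gy with a 2-to-3-year drop of a few points — plausible
  behaviour, not the published fit — and they are disabled by default:
  reports include the Tai columns only after an explicit
  `tai.allow_placeholder: true` acknowledgment or user-supplied
  `tai.params`. Requesting a horizon without a parameter set raises an
  error naming the missing source fit.

Every model output is a probability in [0, 1] with no overflow up to BED
10⁴ Gy and beyond.

## Cohort and plan generators

The bundled cohort carries the published per-patient id / sex / age /
T-stage of the 17-patient reference cohort (14 T1, 3 T2; ages 51–76, mean
65.3, sample SD 7.0). The file is checksummed (SHA-256) at load. Tumor
diameters were published only as a cohort summary (2.5 ± 0.9 cm), so
per-patient diameters are **imputed**: a seeded normal draw truncated below
at 0.5 cm, labelled synthetic in the run manifest. Note the truncation
shifts the theoretical mean to ≈2.53 cm; tests check the sample mean
against the truncated-normal expectation (scipy.stats.truncnorm), not the
nominal 2.5.

Fully synthetic cohorts draw diameters from the same truncated normal,
stage from Bernoulli(t2_fraction, default 3/17), ages uniformly over
[51, 76], and sex fairly. Plans realize the "about 110%/120%" planning
constraint as nominal factor + uniform jitter of configurable half-width
(default 0.02, i.e. ±2 percentage points of prescription; jitter 0 yields
the exact nominal factor). The uniform law is the simplest bounded scatter
model; nothing in the source material constrains its shape. Everything is
reproducible: the same seed yields byte-identical cohort/plan/report CSVs
(floats serialized at 17 significant digits and re-read with round-trip
parsing).

What the generator does **not** emulate: real DVH structure (a scalar Dmax
factor per plan is the entire dose interface), diameter–stage correlation
(an open question in the source cohort), inter-patient dosimetric
variation beyond Dmax scatter, and the actual unpublished per-patient
diameters and achieved doses. Passing tests therefore validate the
machinery and the qualitative orderings (normalization invariance of the
prescription-dose model, monotone gains for isocenter models, collapsed
ranges at zero jitter), not the exact published medians, which are not
reproducible without the unpublished per-patient inputs and the exact
Martel/Tai source forms.

## Comparison pipeline

For each (patient, scheme, scenario) cell the roster models produce LC
probabilities; per-horizon reports compare each model against a benchmark
(Martel at 2 years, Guckenberger at 3 years) as paired per-patient
differences × 100 (percentage points). Summaries are median (midpoint of
the central pair for even n) and (min, max) range, computed before any
rounding; text tables format to one decimal with the benchmark column as
NA and a dagger at p < 0.05. No multiple-testing correction is applied:
each comparison is reported at its own p-value.

**Wilcoxon signed-rank.** Zero differences are dropped before ranking by
default (classical convention; with 17 continuous predictions ties at zero
are rare), with a Pratt variant (rank zeros, then discard their ranks)
available for sensitivity checks; all-zero vectors give p = 1. For up to
25 nonzero pairs the two-sided p-value is exact:
`p = min(1, 2·min(P(W⁺ ≤ w), P(W⁺ ≥ w)))` with the null distribution of
the positive rank sum computed by dynamic programming over the midranks
(doubled to integers, exact integer counts), which remains valid under
tied |differences| — the reason this statistic is authored in-package
rather than delegated (scipy's exact method does not guarantee exactness
with ties; it serves as an independent cross-check in tie-free tests).
Above 25 pairs a normal approximation with tie-corrected variance
(Σr²/4 over the realized ranks) and a 0.5 continuity correction is used.

## Numerical choices and degenerate inputs

* Logistic evaluation through `expit`; no explicit exponentials of large
  arguments anywhere.
* Martel at D = 0 returns 0 (no dose, no control); negative doses and
  diameters, non-positive slope scales, α/β ≤ 0, fraction counts < 1 and
  non-positive fraction doses are rejected at construction.
* Per-scenario plan seeds are derived as `seed + 1000003·(index+1)` so one
  user seed yields distinct deterministic streams per scenario.
* Median of an even-length vector is the mean of the central pair.

## Problem sizes

Default runs use the 17-patient cohort × 5 schemes × 2 scenarios
(170 plans, ≤ 6 models per plan); the similarity scan uses 16 001 grid
points over BED₁₀ 100–180 Gy; generator calibration tests draw 10⁵
diameters. A full pipeline run completes in well under a second.

## Known limitations

* The Tai placeholder is not the published fit; Tai-dependent numbers are
  therefore illustrative until `tai.params` is supplied.
* The Martel functional form and dose argument are inferred, not printed
  in the available source; both are configurable for that reason.
* A scalar Dmax factor per plan cannot capture within-target dose
  heterogeneity; no DICOM-RT/DVH parsing is provided or planned.
* Published per-patient medians/ranges are structurally, not numerically,
  reproduced (see generator section).
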