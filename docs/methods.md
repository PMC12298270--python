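# Methods

## Scope

`caftorlab` implements the computational layer of a targeted LC-MS/MS
bioanalytical workflow for the CFTR modulators ivacaftor (IVA), tezacaftor
(TEZ) and elexacaftor (ELX), plus the limited-sampling pharmacokinetic
exposure analysis used for ivacaftor therapeutic drug monitoring. It does
not touch vendor raw files or peak integration: its inputs are tabular
response ratios, peak areas, peak geometries and concentrations.

Units are fixed: µg/mL for concentration, hours for time, µg/mL·h for AUC,
minutes for chromatographic time. Displayed tables round half-up to two
decimals; JSON output keeps full precision.

## Calibration

Responses (analyte/internal-standard area ratios) are modeled as a straight
line in nominal concentration and fit by weighted least squares with
weights 1, 1/x or 1/x². The default is 1/x²: over a 200-fold range
(0.1–20 µg/mL) with multiplicative detector noise, unweighted fits let the
high calibrators dominate and inflate back-calculation bias at the LLOQ
(the package's own Monte-Carlo test demonstrates this). R² is computed on
the weighted fit. Back-calculated concentrations may be negative for
sub-blank responses; they are returned unclipped and flagged downstream so
QC diagnostics keep the information.

Per-calibrator acceptance is ±15% bias (±20% at the LLOQ); the curve as a
whole passes when ≥75% of calibrators pass across at least six distinct
levels, the conventional regulatory rule. Both bounds are arguments, not
constants.

## Validation statistics

* **Accuracy** = mean %bias = 100·(mean − nominal)/nominal;
  **precision** = %CV with the n−1 standard deviation. Tolerance 15%
  (20% at the LLOQ).
* **Intra- vs inter-run**: the guideline language ("independent runs over a
  period of months") does not pin down the decomposition, so the package
  uses the conventional one: intra-run statistics are computed within each
  run and the *worst* run (largest of |bias| and CV) is reported; inter-run
  statistics are computed on run means. Median and range are reported
  alongside for table parity but acceptance uses mean bias and CV.
* **Selectivity / carry-over**: the median blank (or post-ULOQ blank)
  response must stay below 20% of the LLOQ analyte response and 5% of the
  internal-standard response.
* **Matrix effect** = 100·B/A per lot (post-extraction spike over neat
  solution), acceptable mean 85–115%; **extraction recovery** = 100·C/B
  (pre- over post-extraction spike), acceptable 90–110%; IS-normalized
  matrix effect = 100·ME_analyte/ME_IS. The telescoping identity
  C/A = (B/A)·(C/B) holds per lot by construction and is property-tested.
* **Stability** = 100·C(t)/C(0) against the *measured* time-0 value, not
  the nominal — this is the arithmetic that reproduces published
  autosampler-stability tables cell for cell (e.g. 8.55/8.56 → 99.88%).
  Acceptable window 85–115%.
* **LLOQ qualification**: overall and per-session |bias| and CV within 20%;
  fewer than five sessions is a warning, not a failure.

## System suitability

From a sampled trace, the apex is located by parabolic interpolation of the
three samples around the maximum and crossing times at 50/10/5% of apex
height by linear interpolation between samples. Metrics follow USP
conventions: capacity factor k′ = (tR − t0)/t0 with the dead time t0 an
input (never estimated); asymmetry As = b/a at 10% height; tailing
T = W05/(2·f) at 5% height; resolution Rs = 2·ΔtR/(w1 + w2) with baseline
widths derived from the half-height width as w = FWHM·4/2.355 (exact for
Gaussians). Default acceptance ranges — Rs ≥ 2, 0.8 ≤ As ≤ 1.5, T ≤ 2,
1 ≤ k′ ≤ 10 — are conventional values and fully configurable, since no
numeric targets are published for this assay. A Gaussian peak gives
As = T = 1 and FWHM = 2σ√(2 ln 2); these closed forms are the test oracles
(0.5% agreement at grid step σ/50).

## PK exposure

With steady-state samples at T0 (trough) and T4 (protocol-defined Cmax for
ivacaftor), the 12 h concentration is extrapolated mono-exponentially,
C12 = C4·e^(−β·8), using a configured terminal elimination rate β (default
0.0866 /h, an 8 h half-life; β is configuration because no per-patient
estimate is available from two samples). AUC0–12h is the trapezoidal rule
on (0, C0), (4, C4), (12, C12) — with only three points the linear rule is
the least-assumption choice; a linear-up/log-down variant is available and
falls back (flagged) to linear when the 4→12 h segment does not decline.
AUC0–24h = 2·AUC0–12h for the q12h regimen. The three-point linear estimate
is biased *upward* on convex mono-exponential decay (chords above the
curve); the sign is asserted in tests against the closed form
C0·(1 − e^(−βT))/β.

Cohort exposure is summarized by OLS of AUC0–24h on C_trough (line, R²,
slope standard error), the Spearman rank correlation with a Fisher-z 95% CI
(se = 1/√(n−3), average ranks for ties), and per-patient residual %CV
= 100·(measured − predicted)/predicted reported as mean ± SD. The fitted
line can be inverted to back-calculate a trough from an AUC. Percentiles
use linear interpolation between order statistics (numpy's default,
type 7), stated because quartile conventions differ.

## Synthetic data

The generator produces every input the pipeline consumes, with known truth:

* **Noise model**: all noise is mean-one multiplicative lognormal; a
  fractional CV maps to σ² = ln(1 + cv²). This is heteroscedastic (SD grows
  with level), as LC-MS/MS response ratios behave, keeps every generated
  quantity strictly positive, and gives exact zero-noise limits so every
  estimator can be tested for exact truth recovery.
* **Calibration/QC**: response = (slope·c + intercept)·ε; QC runs add a
  shared per-run lognormal factor (the inter-run variance component).
* **Stability**: first-order decay, measured(t) = base·e^(−k·t)·ε — the
  simplest model consistent with a monotone loss.
* **Matrix-effect triplets**: A = neat·ε, B = A·f_ME·ε, C = B·f_ER·ε.
* **Peaks**: exponentially modified Gaussian via the erfcx form (stable for
  small τ/σ); τ = 0 degenerates to a Gaussian, giving asymmetry metrics a
  tunable truth. Traces are normalized to the requested height.
* **PK cohort**: steady-state one-compartment first-order absorption by
  superposition, Css(t) = (D·ka)/(V/F·(ka−ke))·[e^(−ke·t)/(1−e^(−ke·τ)) −
  e^(−ka·t)/(1−e^(−ka·τ))], with per-patient lognormal deviates on ka, ke
  and V/F. Unequal morning/evening doses are supported as two interleaved
  24 h-periodic trains; the default is equal 150 mg q12h, consistent with
  the AUC-doubling convention of the exposure analysis. Defaults —
  ka = 0.5 /h (steady-state Tmax ≈ 4 h), ke = 0.0866 /h, V/F = 150 L, 40%
  between-patient CV, n = 25 — put the simulated cohort in the observed
  pediatric ivacaftor regime (median C4 ≈ 1.5 µg/mL, AUC0–12h ≈
  11–14 µg/mL·h, trough–AUC Spearman r ≈ 0.94). The table carries each
  patient's true parameters and true AUCτ = D/(V/F·ke).

What the generator does *not* emulate: food effects, enterohepatic
recirculation, two-compartment kinetics, metabolite kinetics, non-lognormal
outliers, drug–drug interactions, or real chromatographic baselines.
Passing tests therefore demonstrate the *estimators'* correctness and the
pipeline's internal consistency under the stated model, not the clinical
behavior of real cohorts.

## Recovery study design

The regression-recovery study simulates 200 cohorts of 25 patients (40%
between-patient CV, 5% assay CV). For each cohort the reference slope is
the OLS slope of the same cohort's *noise-free* pipeline quantities
(three-point AUC from exact model concentrations), so assay noise is the
only perturbation whose coverage is assessed; the noisy fit's 95% CI
(t-based, n−2 df) is then checked against that reference, and the Spearman
r against the 0.85 threshold. With 5% noise on the trough the design has a
mild errors-in-variables attenuation, far smaller than the CI width at
n = 25. Observed at seed 1: 94% coverage, 100% of replicates with r > 0.85,
median r ≈ 0.95.

## Numerical choices and degenerate inputs

* Calibration with all standards at one level raises a degenerate-design
  error; slope ≤ 0 makes a fit unusable for back-calculation.
* `stability_percent`, `matrix_effect`, `extraction_recovery` and
  `is_normalized` reject non-positive denominators.
* Peak measurement requires the apex off the trace edge and all three
  height fractions crossed on both sides; the trace generator rejects grids
  coarser than σ/10.
* ka = ke is rejected (the one-compartment formula is singular there);
  β < 0 is rejected for C12 extrapolation (no accumulation extrapolation).
* Patients missing either sampling time are skipped with a warning rather
  than failing the cohort.

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen as adequate for their
purpose: 500 runs for the weighting comparison, 200 cohorts × 25 patients
for the recovery study, 20 000 draws for noise-CV checks, trace grids of
σ/50–σ/200 for closed-form peak checks. The full suite completes in a few
seconds.

## Known limitations

* β is an input; the package cannot estimate it from two-point sampling.
* AUC for TEZ and ELX is deliberately not computed (their Tmax of ~3 h and
  ~6 h invalidates the T4-anchored extrapolation); summaries mark those
  columns not applicable.
* The three-point AUC carries a model-dependent positive bias relative to
  the true exposure; the regression analysis is internally consistent but
  inherits that bias in absolute terms.
* Printed reference tables are reproduced only where the published cells
  are themselves consistent with half-up rounding of the printed inputs.
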