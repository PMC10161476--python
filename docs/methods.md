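# Methods

This note documents the models, conventions and numerical choices behind
`autonomic-beta`, and what the synthetic calibration does and does not
demonstrate.

## HRV from labelled beat series

The pipeline starts at classified heartbeats (time in seconds, label
N/E/A); QRS detection is out of scope. The NN-interval rule is strict: an
interbeat interval enters the analysis only when *both* delimiting beats
are sinus, so one ectopic or artifact beat removes its two flanking
intervals. Successive-difference statistics (RMSSD, NN50, SDSD) are
computed within maximal contiguous runs of retained intervals and never
span an exclusion gap. Effective duration is the summed length of retained
intervals; recordings under 18 h of sinus coverage are unusable
(boundary inclusive: 18.0 h passes).

Conventions, applied consistently and asserted in the tests:

* all standard deviations use the sample (n−1) denominator;
* NN50 counts successive differences strictly greater than 50 ms;
* pNN50 divides NN50 by the total NN-interval count (not the pair count);
* SDANN and the SDNN index summarise 5-minute segments of the recording
  clock; SDANN is missing with fewer than two segments;
* SDSD is reported equal to RMSSD.

Spectral analysis uses one full-record periodogram rather than Welch
averaging because the ULF band (≤ 0.003 Hz) needs full-record frequency
resolution. The tachogram (interval value at interval onset) is resampled
to an even 4-Hz grid, mean-detrended and Hann-windowed; the periodogram is
normalised so its integral equals the variance of the detrended tachogram
(ms²). Bands are half-open [lo, hi) with ULF = (0, 0.003) Hz; total power
integrates (0, 0.4] Hz, so ULF+VLF+LF+HF = TP by construction of the
partition (asserted to 1%).

**Resampling interpolation.** The default interpolant is a cubic spline.
Linear interpolation of samples spaced ~0.8 s acts as a triangular-kernel
low-pass filter and attenuates HF-band (0.15–0.4 Hz) power by roughly 20%;
the spline is amplitude-faithful through the HF band at typical heart
rates (a 0.25-Hz, 50-ms RR sinusoid yields HF within a few percent of the
analytic a²/2 = 1250 ms²). Linear interpolation remains selectable
(`interp="linear"`) for comparison with software that uses it.

Composite z-scores are cohort-level: each index is z-scored against the
analysis sample and each domain composite is the mean of its five index
z-scores. Skewed indices (pNN50, band powers) enter as raw z-scores
without log-transformation; with heavy-tailed inputs the composite is
dominated by the tail subjects, which is a property of the formula, not of
this implementation.

## Beta-cell secretion model

Insulin secretion rate per m² body surface is modelled as

    ISR(t) = P(t) · max(f₀ + s_G (G(t) − G₀), 0) + s_R · max(dG/dt, 0)

* `s_G` — glucose sensitivity, the slope of a linear dose-response
  anchored at fasting glucose (pmol·min⁻¹·m⁻²·mM⁻¹); reported as the
  dose-response average slope.
* `s_R` — rate sensitivity, acting on rising glucose only
  (pmol·m⁻²·mM⁻¹).
* `P(t)` — potentiation, a positive factor interpolated between knots
  every 20 min, normalised to time-average 1 over the record for
  identifiability; its excursion is reported as P(120)/P(0).

This is a deliberate minimal re-implementation of the classical
OGTT beta-cell dose-response/potentiation framework, not a clone of any
proprietary implementation; equivalence with other software can only be
qualitative.

Plasma C-peptide follows linear two-compartment kinetics with population
constants (Van Cauter-type scheme): fast fraction 0.76, fast half-life
4.95 min, slow half-life 29.2 / 27.3 / 32.5 min for lean / obese (BMI ≥ 30)
/ type-2-diabetes subjects, distribution volume linear in body surface
area (Mosteller, sex-specific default heights). The constants are
deterministic in (age, sex, BMI, glucose-metabolism class) and selectable
in configuration; because the same kinetic layer is used to synthesise and
to fit, round-trip tests are insensitive to the exact published values.

Numerics: glucose between the 7 samples is the piecewise-linear
interpolant on a 1-min grid; the ODE advances by the exact matrix
exponential of the 2×2 system with midpoint-constant secretion per step.
Fitting minimises the squared C-peptide misfit plus a curvature penalty
(weight `smoothness`, default 10.0) on the second differences of the
log-potentiation knots plus a tiny ridge (0.02) that pins the flat
overall-scale direction; parameters are bounded (f₀, s_G, s_R ≥ 0, knots
within e^±3) and optimised with trust-region least squares. Starting
values come from regularised non-negative deconvolution of ISR
(piecewise-constant 5-min bins, second-difference penalty λ = 5.0,
non-negativity via bounded linear least squares) followed by a linear
regression of deconvolved ISR on (G − G₀, dG⁺/dt).

Penalty weights were chosen by an L-curve sweep on synthetic records: at
`smoothness = 10` the fit recovers noise-free generating parameters
essentially exactly, keeps the median glucose-sensitivity error under 4%
measurement noise near 8–11%, invents no systematic potentiation when the
truth is flat (cohort-median fitted ratio within a few percent of 1), and
still recovers a true ratio of 1.6 to within ~2% noise-free. Under 4%
noise, *individual* potentiation ratios scatter ~±10–15%: seven C-peptide
samples cannot pin a ratio of two normalised endpoints more tightly. The
deconvolution round trip reconstructs smooth secretion profiles to ~2%
RMSE; profiles with a derivative-step spike (a large rate-sensitivity
term) hit a structural resolution floor near 9% whatever λ. As λ → ∞ the
second-difference penalty drives the deconvolved profile to the
best-fitting *affine* function of time (a linear trend has zero second
difference), which reduces to a constant for steady-state records.

Formula-based indices: C-peptidogenic index (CP₃₀−CP₀)/(G₃₀−G₀), flagged
missing when the denominator is zero and retained-but-flagged when
negative; overall insulin secretion CP_AUC/G_AUC by trapezoid over
[0, 120] min; Matsuda index 10000/√(G₀·I₀·Ḡ·Ī) with glucose in mg/dL
(× 18.016) and insulin in µU/mL (÷ 6.0), means over all seven samples.
OGTT eligibility excludes insulin users and fasting glucose strictly above
11.0 mmol/L. The beta-cell composite z-scores the five indices on the
analysis sample, averages them, and re-standardises the average to mean 0
/ SD 1 (sample SD).

## Association ladder

Outcome and determinant are z-scored on the analysis sample (after the
complete-case restriction); the determinant is multiplied by −1 so
coefficients read per SD *lower* HRV. Covariate sets are cumulative —
crude; +age, sex, education; +Matsuda; +cholesterol/HDL ratio, lipid
medication, BMI, smoking, alcohol; +systolic blood pressure,
antihypertensive medication. One complete-case set spanning the union of
all ladder covariates is used for every model, so the ladder is internally
comparable. Categorical covariates are indicator-coded against documented
reference levels (education = low, smoking = never, alcohol = none,
sex = F, glucose metabolism = NGM). CIs and p-values come from the usual
OLS t distribution; no multiplicity correction is applied. Interaction
tests augment the fully adjusted model with modifier-by-determinant *and*
modifier-by-covariate terms; the p-value is a joint Wald F test on the
determinant interactions (2 df for the three-level glucose-metabolism
modifier). Stratified ladders keep the full-sample z-scoring so strata are
on a common scale. The tertile logistic analysis for the skewed
rate-sensitivity outcome cuts at the 33.3/66.7 percentiles and contrasts
the top tertile against the lower two by default (configurable), with the
odds ratio per SD lower HRV.

## Synthetic cohorts

**Score level.** A standardized linear-Gaussian SEM: independent unit
confounders C_i, exposure X = Σ a_i C_i + e_X, outcomes
Y_j = d_j X + Σ b_ij C_i + e_j, residual SDs solved so every node has unit
variance (infeasible path sets raise). Closed forms: crude coefficient
d_j + Σ a_i b_ij; adjusting a subset removes its products. The ladder
calibration assigns each adjustment stage one block of confounders (age →
model 1, Matsuda → model 2, cholesterol ratio and BMI → model 3A, blood
pressure → model 3B) and solves the block's products to match the target
coefficient path stage by stage, so the whole printed ladder — not just
its endpoints — is the generator's population truth.

Design choices worth stating: score-mode covariates are affine transforms
of the standardized confounders (display means/SDs only), because any
non-affine marginal transform would leave residual confounding after
linear adjustment and break the exact calibration. Categorical ladder
covariates (education, smoking, alcohol, sex, medication flags,
glucose-metabolism status) are drawn independently with zero paths; they
exercise the indicator-coding machinery without being able to bias the
calibrated coefficients. Realistic skewed marginals and
glucose-metabolism-linked shifts live in the signal-level covariate
generator (`draw_covariates`), whose age is a moment-matched truncated
normal (realized mean 60, SD 8 on [40, 75]), sex 52% men, and
glucose-metabolism mix 60/16/24% NGM/prediabetes/T2D; its documented
correlations (higher BMI, blood pressure, medication use and lower insulin
sensitivity in diabetes) are plausible defaults and do not reproduce any
real cohort's joint covariate structure.

**Signal level.** Instantaneous RR(t) is the mean plus circadian (24-h),
LF (0.1 Hz) and HF (0.25 Hz) sinusoids and band-limited jitter, all
amplitudes multiplied by 1 + 0.2·latent (floored at 0.3) so one latent
autonomic score drives variability in every band. Default baseline
amplitudes (circadian 100 ms, LF 35 ms, HF 50 ms, jitter 12 ms at mean RR
850 ms) give 24-h index values of realistic order (SDNN ~ 80–130 ms range
across latents) and enough successive-difference spread for pNN50 to vary
across subjects. Beat times are level crossings of the integrated
instantaneous rate (vectorised); a `sampled` mode instead sets each
interval to RR at its onset, preserving modulation amplitudes exactly, and
is used for spectral oracles. 2% of beats are labelled ectopic and 0.5%
artifact by default — which is why a 24-h recording, not an 18-h one, is
needed to clear the 18-h sinus-coverage rule. OGTT curves come from fixed
per-class piecewise-linear glucose templates (editable), C-peptide from
forward-simulating the secretion model through the subject's kinetics,
insulin as a class-specific fraction of C-peptide (highest in prediabetes,
emulating hyperinsulinaemic compensation), and multiplicative lognormal
measurement noise with configurable CV (floored at a small positive
value). Per-subject substreams are keyed by (master seed, subject index),
so subject k is reproducible regardless of cohort size.

The generator's score-level HRV composites for signal-mode subjects follow
its own structural law: the time-domain composite tracks the common
amplitude scale factor and the frequency-domain composite tracks its
square (band powers are quadratic in amplitude). With measurement noise
off, composites computed by the metric pipeline from synthesized signals
correlate with these at r > 0.99 (checked at n = 100 subjects, 24 h each —
a problem size chosen to keep the default test run fast).

## What the calibration shows — and what it does not

The cohort-scale checks run the *estimation* machinery against a generator
whose population coefficients are set to the published estimates the
package emulates: 20 cohorts of n = 2,007, full ladder, mean standardized
beta compared with generator truth within Monte-Carlo tolerance (±0.012).
The acceptance script additionally pairs each cohort with an antithetic
twin (outcome residuals sign-flipped), which cancels first-order
Monte-Carlo noise in the coefficient means and makes the reported values
stable to ~0.001 across master seeds without changing the estimator, the
sample size or the targets. Passing these checks demonstrates that the
ladder, standardization, inversion and complete-case contracts are
implemented correctly and that the generator's calibration algebra is
exact. It does **not** validate the substantive findings on real data: the
synthetic confounding structure is linear-Gaussian by construction, the
real covariate joint distribution is unknown, and measurement error in
real HRV and OGTT data attenuates associations in ways score-level
simulation does not model (which is exactly why the acceptance targets are
defined on score-level cohorts).

Statistical calibration checks (95% CI coverage 95% ± 2%, interaction
type-I error 5% ± 2% over 500 null replicates at n = 2,007) are exercises
of the finite-sample behaviour of OLS on this generator, seeded and
deterministic in the test suite.

## Known limitations

* The secretion model's dose-response is linear; saturating dose-response
  shapes and incretin terms are out of scope, so `s_G` is an average slope
  by construction.
* Potentiation at the individual level is weakly identified from seven
  samples; cohort-level summaries are the reliable quantity.
* The frequency-domain pipeline assumes the recording clock is continuous;
  very fragmented recordings (many exclusion gaps) are bridged by
  interpolation, which flattens genuine variability in long gaps.
* Signal-level OGTT realism is limited: glucose templates are fixed per
  class rather than mechanistically simulated, and insulin is a scaled
  C-peptide rather than an independently modelled hormone.
* The CLI's signal mode writes one text file per subject and is intended
  for cohorts of tens to hundreds of subjects, not tens of thousands.
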