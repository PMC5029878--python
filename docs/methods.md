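# Methods

This note records the models implemented by `musclefat`, the defaults and
why they were chosen, the numerical decisions that affect results, and
what the synthetic-data tests do and do not demonstrate.

## Signal model and reconstruction

The three-point Dixon forward model assumes a single-peak fat resonance
and echo spacing equal to half the fat–water beat period at 3 T, so the
chemical-shift phase of fat relative to water is (0, π, 2π) across the
three echoes:

    S_k = (W + F·e^{i(k−1)π})·e^{i(φ₀ + (k−1)φ)} + ε_k,  k = 1..3,

with complex Gaussian noise ε of equal per-component standard deviation.
T1/T2* relaxation, multi-peak fat spectra and coil-profile modulation are
deliberately outside the model.

Reconstruction proceeds in four steps.

1. **Wrapped field map.** `arg(conj(S₁)·S₃)` estimates 2φ wrapped into
   (−π, π]. Both φ₀ and the fat term cancel because fat is in phase on
   echoes 1 and 3. Zero-magnitude pixels return phase 0 and zero quality.
2. **Unwrapping.** Quality-guided region growing with quality |S₁·S₃|,
   seeded at the highest-quality pixel of each slice; the flood front is a
   max-heap on quality with deterministic index tie-breaks. Slices are
   unwrapped independently (the protocol is 2D with 12 mm inter-slice
   gaps, so through-slice continuity is not assumed). The result is exact
   up to one global 2π multiple per slice whenever the true 2φ map steps
   less than π between neighbours; the phantom's field generator enforces
   that capture bound by default and can violate it on request for
   failure-mode studies. Disconnected signal regions within a slice are
   unwrapped independently of one another (each acquires its own offset).
3. **Separation.** With φ = (unwrapped 2φ)/2, the in-phase channel is the
   SNR-improved average `(S₁ + S₃e^{−2iφ})/2` (a config flag can fall back
   to S₁ alone), and the opposed-phase echo is projected onto the
   in-phase phase reference as a *signed* amplitude `d ≈ W − F`. Then
   water = (A+d)/2, fat = (A−d)/2 with A the in-phase amplitude.
4. **Fat fraction.** f.f. = fat/(water+fat)·100, clamped to [0, 100] in
   the released map; pixels below the signal threshold or with zero total
   are flagged undefined rather than set to NaN.

### Why signed combination, and where clamping happens

At a true fat fraction near zero the fat-channel noise is symmetric about
a value close to zero. Taking magnitudes (|S₁|−|S₂|-style recombination)
rectifies that noise and floors the pixel estimate at the Rician mean —
at SNR 50 this inflates a 0.9% ROI by roughly +0.8 percentage points.
Clamping the *pixel* f.f. at zero before ROI averaging still leaves about
+0.18. The implementation therefore keeps the signed estimate per pixel:
the public map `FatFractionMap.ff` is clamped to [0, 100] so it is always
a valid percentage image, while the signed values ride along as
`ff_raw` and back all ROI statistics, whose means are clamped only after
averaging. ROI-mean bias at SNR 50 is then below 0.05 percentage points
across the 0–60% range, at the price of individual out-of-range pixel
values existing internally. Noise in the phase maps enters the separation
only at second order (through cosines), so the signed estimator sits at
the least-squares noise floor for this acquisition.

### Swap resolution

Halving 2φ leaves a π ambiguity in φ per slice — the global water–fat
swap. The branch maximizing total water is chosen *within the muscle
compartment* when a label mask is available (`vote_mask`), since muscle
remains majority-water even at advanced fat replacement, whereas the
subcutaneous ring is pure fat and would tip a whole-image vote. A
uniformly fat-dominant compartment (>50% everywhere) would defeat the
heuristic; `flip_branch` exists for that case.

### Signal threshold

Pixels with |S₁| below 5% of the robust (99th-percentile) image maximum
are masked. The value is a package choice: it cleanly excludes air and
the signal-free bone disc of the phantom while keeping all muscle at the
noise levels studied.

## Phantom

Geometry is schematic by design: a signal-free "bone" disc (radius 7 mm),
a muscle annulus to 30 mm split into ten equal angular sectors standing in
for the ten forearm muscle-group ROIs (dorsal 1–6, volar 7–10), and a
6 mm pure-fat subcutaneous ring, on the protocol grid (320×320 pixels of
0.56×0.56 mm; nine 6 mm slices, 12 mm gaps, so slice centres are 18 mm
apart). The compartment tapers 5% across the stack so slice levels
differ. Only the label/statistics structure matters for validating the
pipeline; no anatomical realism is claimed. Within each sector the fat
share is exactly the specified true fat fraction, making every
downstream quantity analytically known. `scale_ff_to_target` rescales a
per-muscle profile so the CSA-weighted central-slice mean hits a chosen
value exactly, which is how control-level (0.9%) and patient-level
(14.1%) phantoms are produced.

Field maps φ₀ and φ are low-order 2D polynomials on normalized
coordinates; the defaults span a few radians across the FOV (2φ spanning
several wraps) while respecting the unwrapping capture bound. The default
noise level targets in-phase magnitude SNR 50 in muscle — the protocol
itself reports no SNR, so this is a package choice of a plausibly
conservative surface-coil value, configurable via `ReconOptions.snr` or
`noise_sd`.

Simulated cohorts follow the study design they emulate: 15 subjects at
baseline with monotone dropout to 9/7/7 at months 3/6/12, baseline mean
14.1%, generating visit-mean changes (1.4, 3.9, 5.0) percentage points,
time non-ambulant uniform on 4.7–41.6 months. Between-subject SD 5 and
residual SD 2 percentage points are the calibration used throughout the
simulation studies. The covariate slope (0.2 %/month) is a plausible
value consistent with reported correlations of fat fraction with time
non-ambulant; its exact value is immaterial to the estimator checks
because the model adjusts for it. The generator applies the covariate
centred at the range midpoint so `baseline_mean` is directly the expected
baseline outcome.

### What the synthetic data do not capture

Real data differ in ways the phantom deliberately ignores: anatomy and
partial-volume mixing at muscle boundaries, multi-peak fat spectra and
T2* decay (which bias real Dixon f.f. estimates), coil shading, motion,
imperfect longitudinal slice matching, and manual-segmentation
variability. Passing tests therefore demonstrate the correctness of the
*computational chain* — separation, summarization, estimation — under its
stated model, not scanner-level accuracy of fat quantification.

## Statistics

**Change model.** y_ij = β₀ + Σ_t β_t·1[visit=t] + γ·z_i + b_i + e_ij,
with subject random intercept b_i, fitted by REML (statsmodels MixedLM;
optimizers tried in order lbfgs → bfgs → powell → nm). β_t are the
adjusted mean changes. Confidence intervals and p-values use the t
distribution with residual degrees of freedom N_obs − #fixed-effects
(38 − 5 = 33 at the default design) — Satterthwaite/Kenward-Roger
corrections are out of scope, and this simple choice is stated so the
numbers are exactly reproducible. Simulation at the default design gives
95% CI coverage within [92%, 98%] for the 12-month effect. Declared
significance uses the 0.01 threshold. The single-subject-off-steroids
sensitivity analysis is a row filter (`exclude_no_steroid`), not a
separate model. Outcomes are analyzed untransformed; the Shapiro–Francia
W′ of the baseline values is reported as a diagnostic alongside each fit.

**Shapiro–Francia.** W′ is the squared correlation between the ordered
sample and Blom scores Φ⁻¹((i−3/8)/(n+1/4)); p-values use Royston's
log-normal approximation for ln(1−W′), valid for 5 ≤ n ≤ 5000. The
implementation matches the R `nortest` reference to 1e-9 on fixed
samples and holds its nominal type-I error within Monte-Carlo tolerance
at n = 10, 25, 50.

**Sample size.** The normal-approximation two-group formula
n = ⌈2σ²(z_{1−α/2}+z_{power})²/δ²⌉. The iterative t-based correction
would give 17 where this gives 16 at the fat-fraction design values; the
normal form is the one this endpoint's planning numbers are built on,
and the choice is fixed here for reproducibility.

**Baseline comparison.** Welch's unequal-variance t-test (the
pooled-variance choice is unstated in the source analyses; Welch is the
safer default), group means with t-based 95% intervals.

## Numerical and interface decisions

- Slice selection: ±74 mm does not fall on the 18 mm slice-centre
  lattice; the nearest-centre slice is used (±72 mm, indices 0 and 8
  around a central index 4) and offsets reaching beyond the stack raise
  errors naming the reachable range.
- The central slice index is an explicit input; its anatomical definition
  (first slice distal to the supinator) cannot be inferred from synthetic
  geometry.
- Remaining-area identity `remaining + CSA·f.f./100 = CSA` holds exactly
  by construction; when ROIs partition the compartment the CSA-weighted
  total equals the pooled pixel mean exactly. Note the order of averaging
  matters for *group*-level tables: the remaining area computed from
  group-mean CSA and f.f. differs from the mean of per-subject remaining
  areas; the package computes per-subject (per-phantom) values and leaves
  any group reduction to the caller.
- Undefined (masked) pixels are excluded from ROI means, never imputed;
  their counts are carried in `CompartmentSummary.per_roi_undefined`.
- Complex NIfTI dialect: one real-part and one imaginary-part volume per
  echo, with echo time recorded in the header description. Chosen over
  native complex dtypes for maximal reader compatibility.
- Determinism: every stochastic step takes a seed; the pipeline spawns
  per-stage seeds from the top-level one, and each output CSV carries the
  resolved-config hash and seed.
- Problem sizes in the shipped simulation studies (96×96 phantoms for
  Monte-Carlo robustness, 200 cohort replicates, 10,000-replicate
  normality calibrations) were chosen to give Monte-Carlo standard errors
  comfortably below the tolerances being checked.

## Known limitations

- Single-peak fat model and no T2*: real-scanner fat fractions carry
  known multi-peak/relaxation biases this package neither simulates nor
  corrects.
- The swap heuristic assumes a majority-water compartment.
- 2D unwrapping only; no continuity across the 12 mm slice gaps.
- The mixed model fits a random intercept only — no random slopes or
  serial correlation — matching the small-cohort designs it targets.
- Group-level inference with 7–15 subjects relies on the t/residual-df
  approximation; coverage was verified by simulation at the default
  design only.
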