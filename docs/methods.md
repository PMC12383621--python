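# Methods

`peblkit` implements a complete, testable analogue of a PPG-based
blood-loss prediction study: because the in-vivo recordings such studies
use are not publicly available, the package pairs the analysis pipeline
with a synthetic data generator that reproduces the acquisition protocol
and carries a controlled, recoverable signal. This note documents the
models, the parameters that matter, and the design decisions taken where
the problem was genuinely open.

## Ground-truth model

Percent estimated blood loss is

    PEBL(t) = V_hem(t) / V_total,      V_total = 60 mL/kg x weight,

a fraction in [0, 1]. During resuscitation the target generalizes to net
fluid balance

    FB(t) = (V_hem(t) - V_wb(t) - V_cr(t) / 3) / V_total,

counting whole blood 1:1 against blood loss and crystalloid by the 3:1
replacement rule (about one third of infused crystalloid stays
intravascular). Positive FB is net blood loss; the sign swaps to negative
once infusion overtakes the maximum loss. Where no fluid has been infused
FB reduces to PEBL exactly, so models trained on PEBL can be evaluated on
FB without recalibration.

Assumptions worth keeping in mind: blood volume is a fixed per-kg
constant (no hemodilution), the 3:1 rule is a population-level
convention, and bleeding stops before resuscitation begins (the FB
formula as written also covers concurrent bleeding, should a protocol
produce it).

## Synthetic cohort generator

The generator emulates the study protocol per subject: a ~40 kg subject,
a 600 s baseline, constant-rate hemorrhage toward a target PEBL of 0.40
(capped at 90 min), a 600 s hypovolemic hold, then resuscitation with
600 mL of whole blood at 100 mL/min followed by crystalloid at
100 mL/min over a 1200 s window. Those resuscitation defaults mirror a
two-units-of-whole-blood-then-crystalloid protocol at desk scale and are
chosen so the default cohort crosses FB = 0 (net gain) near the end of
resuscitation, exercising the sign swap. The default hemorrhage rate of
60 mL/min reaches the 0.40 target in 16 min for a 40 kg subject — a
compressed but physiologically plausible controlled-hemorrhage rate that
keeps desk-scale runs affordable; the pipeline is insensitive to the
absolute phase lengths because all pairing is done per sample.

The PPG waveform is a per-beat two-Gaussian template (systolic lobe +
delayed, smaller dicrotic lobe, parameterized in cycle fractions) with
morphology coupled monotonically to the instantaneous PEBL:

* pulse amplitude `= base x exp(-2.5 x PEBL)`,
* heart rate `= baseline x (1 + 0.8 x PEBL)`,
* dicrotic fraction `= base x exp(-3.0 x PEBL)`.

The coupling constants are free design parameters, not physiological
estimates: they are set so that the morphology change over the protocol's
PEBL range is large relative to the noise (amplitude falls to ~37% of
baseline at PEBL 0.4) and deliberately nonlinear, so that tree ensembles
hold a genuine advantage over a linear model — the qualitative ordering
the pipeline is designed to detect. Additive Gaussian noise
(sd 0.02 in units of the unit-amplitude pulse) and a < 0.5 Hz sinusoidal
baseline wander (amplitude 0.10) are applied last; these are "moderate
noise" relative to the unit pulse and exercise detrending without
overwhelming the morphology signal. Cohorts jitter weight (±10%),
baseline heart rate (±10%), pulse amplitude (±20%) and the coupling
coefficients (±15%) uniformly per subject, each subject receiving a child
seed, so runs are reproducible bit-for-bit from a single cohort seed.

What the generator does **not** emulate: baroreflex compensation, MAP or
lactate dynamics, motion artifacts, sensor-site and perfusion effects, or
any uncertainty in the fluid log itself. Passing tests on this cohort
therefore demonstrate that the pipeline recovers a monotone
morphology-to-PEBL coupling through its windowing, fiducial detection and
feature code — not that PPG morphology in a real subject carries that
coupling.

## Harmonization and truncation

The 500 Hz PPG is decimated 5:1 to 100 Hz with a polyphase FIR anti-alias
filter (cutoff below the 50 Hz target Nyquist, linear edge padding to
avoid boundary transients). The 0.2 Hz cumulative fluid channels are
interpolated linearly onto the same grid — pumps deliver volume
continuously, and linear interpolation preserves monotonicity between log
points, which zero-order hold would also do but with a systematic lag.
Training data are truncated to the final 10 baseline minutes (the segment
closest to hemorrhage onset), the hemorrhage event and the hypovolemic
hold; the resuscitation phase is held out for the extended evaluation.

## Feature extraction

Windows of 5, 10, 30 or 60 s are cut contiguously without overlap (the
trailing partial window is dropped); each window's target is the mean
ground truth over its span, which is unbiased at every window length.
Pulse onsets are waveform feet (local minimum preceding each prominent
first-derivative peak); beats outside 40–240 bpm or below an adaptive
amplitude floor are flagged invalid, and windows with no valid pulse are
excluded. The dicrotic notch is the most prominent local minimum after
the systolic peak, falling back to the second-derivative maximum (the
e-wave region) for the weak-notch pulses that deep hemorrhage produces,
so notch-dependent features stay defined. The 58-feature manifest
(morphology 12, width 16, derivative 12, frequency 9, statistical 9) is
listed in `feature_manifest.md` and frozen by test; each feature carries
a declared amplitude/time scaling signature that is property-tested.
Width crossings are linearly interpolated between bracketing samples.
Frequency and statistical features are computed once per window (not per
pulse) — the averaging-per-segment convention is applied to the per-pulse
categories only.

Per-subject 0–1 normalization rescales each feature within each subject,
including a blind test subject within its own data. This mirrors the
study procedure exactly; it leaks the blind subject's own min/max into
its features and is documented as such rather than "fixed", since the
pipeline's purpose is to compare this choice against no normalization.

## Models and tuning

Four architectures run behind one `fit`/`predict` interface: gradient
boosted trees (XGBoost), random forest, elastic net and kernel SVR, each
with its library defaults as the untuned configuration. The Bayesian
tuner removes four whole subjects (seeded draw) as a validation set and
runs 100 sequential candidate evaluations scored by pooled validation
RMSE: the default configuration first, ten random probes, then
expected-improvement proposals from a Matern-5/2 Gaussian-process
surrogate over the unit-cube encoding of the declared search space
(bounds in `modeling.SEARCH_SPACES`; log-uniform for rates and
regularization strengths). Because the default is always a candidate,
the tuned configuration is never worse than the default on the
validation split. Hyperparameters are tuned once per architecture on a
seeded split of the whole cohort rather than re-tuned inside every
leave-one-subject-out fold; this keeps the tuning budget independent of
cohort size and is the documented interpretation of a procedure that a
per-fold reading would make infeasible for small cohorts (with six
subjects, a fold leaves five, and removing four for validation would
leave a single training subject). The audit trail records the validation
subjects and every candidate, and the isolation checks verify that
validation subjects never appear in tuning-time training data and that
LOSO blind subjects never appear in their own fold's training data.

## Down-selection and statistics

Stage 1 evaluates all architecture x window combinations un-normalized
and eliminates the worst architecture at its best window (4 -> 3); stage
2 compares per-subject normalization against none for the survivors and
eliminates the worst (3 -> 2); stage 3 Bayesian-tunes the two survivors
and flags the single best configuration final. Mean R² over blind
subjects drives every decision (not median), with ties broken by lower
mean MSE and then architecture name, so the table is a pure function of
the metric values plus seed.

The extended phase keeps each architecture's best pre-elimination setup
(un-normalized, untuned defaults for those eliminated early), trains on
the truncated PEBL timeline and scores the full timeline against fluid
balance. On the default synthetic cohort this is out-of-regime by
construction — the models never see resuscitation morphology — so
extended R² is expected at or below the hemorrhage-phase R² for every
architecture. The effect is stark on synthetic data: the generator
couples morphology to PEBL, and PEBL freezes at its maximum once
bleeding stops, so the waveform carries no information about the
declining fluid balance during resuscitation and extended R² is
typically near or below zero. A real subject's waveform partially
recovers as volume is restored, which is why in-vivo extended
performance degrades more gently; the synthetic cohort reproduces the
direction of the degradation, not its magnitude.

Configuration comparisons use matched nonparametric tests on per-subject
metric vectors: Shapiro–Wilk per group for normality, Wilcoxon
matched-pairs for two groups, Friedman plus Dunn's post hoc for more.
Dunn's test is computed on the Friedman within-block mean ranks with
z = (R_i - R_j) / sqrt(k(k+1)/(6n)) and Bonferroni adjustment over the
pairs (the adjustment is an explicit argument, since "Dunn's multiple
comparison test" admits several adjustment conventions). All significance
is judged at alpha = 0.05.

## Numerical choices and problem sizes

* Degenerate inputs: constant windows yield zero pulses and are excluded;
  constant features normalize to 0; a constant truth vector makes R²
  undefined and raises rather than returning a sentinel.
* Determinism: every stochastic step (cohort jitter, noise, validation
  draw, tuner proposals, tree seeds) derives from an explicit seed;
  equal seeds reproduce results bit-for-bit, and estimators run
  single-threaded for reproducibility.
* The test suite and the reproduction script run the pipeline at desk
  scale — 12-subject default cohorts for recoverability and the extended
  phase, a 6-subject compact-protocol cohort for the full down-selection —
  sizes chosen as the smallest cohorts at which the LOSO and tuning
  machinery is exercised in full.

## Known limitations

* The 58-feature manifest is this package's own concrete instantiation
  of the five published category counts; other instantiations of the
  same categories exist.
* The derivative category's fixed count of 12 forces one of the 13
  natural members out; the first-derivative-minimum timing was dropped.
* The synthetic coupling is monotone and noise is stationary; none of
  the confounds that limit real PPG (perfusion loss at the sensor site,
  vasoconstriction, motion) are modelled, so absolute R² values on
  synthetic cohorts are optimistic by design.
* Fiducial detection assumes a dominant systolic upstroke per beat; it is
  not an arrhythmia-robust beat detector.
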