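# Methods

## Problem and model

During progressive hemorrhage, a subject's *absolute blood-volume status*
(ABVS) is the fraction of its tolerable blood loss already incurred, scored
0–100% with 100% at cardiovascular decompensation (operationally, a 20% drop
in mean arterial pressure). The package estimates ABVS per heartbeat from
wearable cardiomechanical features — ECG-derived heart rate and
heart-rate-variability summaries, seismocardiogram systolic-timing intervals
(PEP, LVET, PEP/LVET), and photoplethysmogram pulse features (PPGamp, PAT,
PTT, nPAT, PVI) — using a bagged random-forest regressor (200 trees, depth
10) with per-beat class weights that equalize the influence of every
(subject, ABVS level) group. Generalization to unseen subjects is measured
by leave-one-subject-out cross-validation (LOSO-CV): pooled out-of-fold
predictions give one R², decompensation AUC (prediction scored against the
binary label "ABVS = 100%", Mann–Whitney midrank convention) and RMSE (in
percent ABVS) per trial; trials re-seed only the forest's bootstrap/feature
sampling, and the mean ± sample SD over 10 trials is reported.

Each subject tolerates 2–4 equal bleed steps, so its discrete labels are the
grid 100·i/n_steps (displayed rounded: 0/33/67/100 for three steps).
Training uses the exact values; rounding is display-only.

## Normalization methods

The scientific question is whether the subject's own baseline is needed.
The reference is individual-baseline normalization (IBN),
x′ = (x − µ_b,p)/µ_b,p with µ_b,p the subject's pre-hemorrhage baseline mean.
Seven baseline-free alternatives replace µ_b,p with statistics available
without the subject's history (see `abvs.normalization` for the table):
LOSO z-score (M1) and fractional change (M3), external-cohort z-score (M2)
and fractional change (M4), their weight-scaled variants (M5, M6), and a
feature-specific mix (M7: M3 × weight for HR and LVET, M6 for PEP and
PEP/LVET). Statistics are pooled over baseline + post-step stabilization
beats only, with sample (n−1) SDs; the alternative "mean of subject means"
pooling was considered and rejected as a less literal reading of a
held-in-subjects statistic, but the pooling is isolated in `loso_stats` if a
user needs to change it.

A structural fact shapes the results: axis-aligned decision trees are
invariant to any *fixed* strictly increasing per-feature transform applied
identically to training and test data. Methods 2 and 4 are exactly such
transforms, so their LOSO metrics equal no-normalization to within floating
tolerance — the mechanism behind the near-identical rows of the evaluation
table. With the default fold-scoped LOSO statistics (below), Methods 1 and 3
are also fold-fixed affine maps and thus provably identical to no
normalization, and M5 ≡ M6 (they differ by a fixed per-feature factor
σ/µ). Only IBN, M7 (subject weight enters with opposite sign per feature
group) and the `per_subject` LOSO scope produce subject-specific warping the
forest can actually see. This is the exact-arithmetic version of the
empirical finding that baseline-free normalization "may not be required".

### LOSO scope

Inside a CV fold the leakage contract is absolute: the held-out subject's
rows influence neither the normalization statistics nor the fitted model.
The default (`loso_scope="fold"`) computes one µ/σ from all held-in
stabilized beats and applies it to train and test alike. The
`"per_subject"` scope additionally re-normalizes each *training* subject
with statistics excluding that subject (computed from training rows only),
reproducing the subject-specific scaling of schemes that normalize every
subject by "all the others" while still honoring the leakage contract.

### Numerical conditioning of the forest

scikit-learn's split finder applies an absolute tie tolerance when scanning
candidate thresholds, so tree structure is not scale-free across feature
units. Before fitting, features are standardized with training-fold
statistics (a fixed affine map, invisible to the trees in exact arithmetic);
this makes the monotone-invariance property hold numerically, not just
mathematically. Training rows are also sorted into a content-based
canonical order (subject, label, feature values) so that predictions are
invariant to input row permutation despite order-dependent bootstrap draws.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
porcine physiology in detail:

* **Between-subject baselines** — log-normal around population means
  (positivity of ratio-scaled features), default between-subject CV 0.10.
  Population anchors (HR 75 bpm, PEP 80 ms, LVET 300 ms, PAT 150 ms, …) are
  typical resting values for juvenile swine.
* **Dose response** — each feature is linear in the ABVS fraction with a
  per-subject multiplicative sensitivity: x = m·(1 + s·ℓ/100) + ε. Default
  population sensitivities are signed by the expected hemodynamic direction
  (HR +45%, LVET −25%, PEP/LVET +73% at full decompensation, …) with a 15%
  between-subject spread; magnitudes are calibration choices of this
  generator — the source study reports no effect sizes.
* **Noise** — additive Gaussian per beat with SD proportional to the
  subject's baseline mean (default CV 0.05).
* **Design** — six subjects, step counts drawn from {2: 1/6, 3: 3/6,
  4: 2/6}, 60 beats per level; only baseline and post-step stabilization
  beats are emitted (mid-bleed transients are excluded from the analysis by
  design). A baseline-only external cohort (default n = 18) carries only
  the shared ECG/SCG features HR, PEP, LVET, PEP/LVET, emulating a separate
  study with an unusable optical channel.

What the generator does **not** emulate: fiducial morphology variation,
artifacts and signal dropout, autonomic dynamics within a level,
resuscitation, or relative (vasodilatory) hypovolemia. Passing tests
therefore demonstrate correctness of the pipeline's statistics and
contracts, and recoverability under the stated generative model — not
field performance on real animals.

`simulate_waveforms` renders ECG/SCG/RPPG traces with exactly known
fiducials (QRS trains; AO/AC deflections at R+PEP and R+PEP+LVET; PPG
pulses with the foot at R+PAT and PTT = PAT − PEP by construction) for
round-trip testing of the extractor.

## Signal processing choices

* Zero-phase band-pass: Kaiser-window FIR (0.5–40 Hz ECG, 1–40 Hz SCG,
  0.5–10 Hz RPPG), transition width 1 Hz, 60 dB one-pass stopband design,
  applied forward–backward (`filtfilt`), which squares the response and
  leaves zero net delay. The filter order is large (~7 k taps at 2 kHz),
  so inputs must be a few times longer than the filter.
* R peaks: smoothed derivative-energy transform, amplitude-priority
  acceptance with a 200 ms refractory, refinement to the local ECG maximum.
* AO in (R, R+160 ms], AC in (AO+150 ms, AO+450 ms] — standard SCG search
  windows, all configurable.
* PPG foot: latest pre-peak minimum; exact on clean onsets, but any
  band-limiting smears a pulse foot, so clean synthetic round-trip checks
  run with `prefilter=False` (the sub-sample recovery claim is about the
  fiducial logic, not about filtering).
* HRV: SDRR and Poincaré SD1/SD2 from RR (sample SDs; a perfectly
  alternating RR series has SD2 = 0 and an undefined ratio); LF/HF from a
  Welch periodogram of the RR series resampled at 4 Hz, LF 0.04–0.15 Hz,
  HF 0.15–0.40 Hz (human-standard bands; configurable), requiring a 30 s
  span. nPAT = PAT/RR; PVI over an 8 s sliding window.
* Undefined features are NaN, never zero; affected rows are dropped (with a
  logged count) from training and metrics.

## Problem sizes

Default verification runs use the 6-subject cohort (≈1.5 k beats), 10
trials of the 200-tree forest for the recovery check, 100 random toy
tables for the normalization oracle suite, and 15 s waveform records at
2 kHz — sizes chosen so the full suite runs comfortably on a laptop core.

## Known limitations

* The acceptance properties are generator-relative; reproducing the source
  study's metric values requires its real recordings (the public deposit
  can be fed through `extract-features`/`compare`, but fiducial definitions
  of the original work are only partially specified, so agreement is
  reported, not asserted).
* The simple R-peak and foot detectors target clean or mildly noisy data;
  no artifact-rejection pipeline is included.
* Normalization is static; time-adaptive normalization is out of scope.
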