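# Methods

This package implements a per-contact decoding analysis for stereotactic
EEG (sEEG) recorded during a passive number-recognition task, together
with a synthetic signal generator that makes every stage testable without
patient data. This note documents the models, the defaults and why they
were chosen, and what the synthetic validation does and does not show.

## Task model and synthetic data

Each trial is: fixation cross (uniform 0.5–1.5 s) → 1-s number stimulus in
one of four modalities (arabic numerals, dot assortments, spoken numbers,
beep sequences; quantities 1–9) → inter-trial interval (uniform 1.5–3.5 s).
The default schedule holds exactly 40 presentations per modality (160
stimulus trials) plus extra catch trials so that catch trials are ~10% of
all trials (18 of 178 by default). Catch trials exist to keep subjects
attentive; they are flagged in the schedule, carry no response model, and
are excluded from every analysis stage.

Synthetic recordings are per-contact Gaussian noise with a 1/f^α amplitude
spectrum (default α = 1, RMS 20 µV — a typical depth-contact LFP scale),
optionally with mains interference. Ground-truth effects are planted per
contact:

* **Band-limited power changes.** The background's own band-passed
  component (4th-order Butterworth, zero phase) is gain-modulated inside
  the effect window on stimulus trials of the target modalities, with
  50-ms raised-cosine ramps. The gain is `magnitude` for increases and
  `1/magnitude` for decreases, so the band amplitude is multiplied by
  exactly the configured factor up to ramping. Gain modulation (rather
  than adding independent band noise) is used because it realizes
  decreases as naturally as increases.
* **Evoked potentials.** A fixed biphasic template (Gaussian peaks at 150
  and 300 ms, 600 ms long) scaled to `erp_amplitude` µV is added at
  stimulus onset.

Every planted effect is returned in a JSON manifest, which downstream
validation uses as ground truth.

What the generator does **not** emulate: epileptiform transients, state
changes (drowsiness), correlated noise across contacts, volume conduction,
stimulus acoustics/graphics, reaction-time variability, or non-stationary
1/f slopes. Passing the synthetic validation therefore demonstrates the
statistical machinery is calibrated and sensitive under a clean,
stationary noise model — not that real recordings will reach the same
accuracies.

## Preprocessing

* **Common-average reference.** Output = input minus the instantaneous
  channel mean; idempotent; requires ≥ 2 channels.
* **Epoching.** Stimulus epochs: (−1, +1) s around each non-catch
  stimulus onset. Baseline epochs: one per trial, aligned to a point at
  least 1.99 s after the stimulus offset (so activity has returned to
  baseline) and placed so the 2-s epoch ends before the next fixation
  onset; the alignment point is the midpoint of the eligible interval.
  Inter-trial intervals shorter than 2.99 s therefore host no baseline
  epoch; with the default jitter about a quarter of trials yield one
  (~45 baseline epochs per run). Baselines after catch trials are
  eligible (the guard applies regardless of what preceded).
* **Rejection.** A single global peak-to-peak threshold is selected by
  cross-validation: candidate thresholds span the observed per-epoch
  maximum peak-to-peak range (30 candidates); for each candidate the RMSE
  between the mean of threshold-surviving training epochs and the median
  of held-out epochs is accumulated over 5 folds; the minimizing candidate
  is returned. This is the cross-validated global-threshold criterion
  popularized for M/EEG artifact rejection, without channel-level repair.
  Epochs whose max-over-channels peak-to-peak exceeds it are dropped.
* **Balancing.** Classes are kept balanced by seeded uniform subsampling
  of the larger class (after rejection, and within each per-format
  contrast), which keeps the fair-coin binomial null valid.

## Features

Per contact and epoch, Morlet wavelet power is computed at 50 log-spaced
frequencies from 3 to 250 Hz with `n_cycles = max(freq/2, 3)`. The 3 Hz
floor is set by the epochs: a 3-cycle wavelet at 3 Hz spans 1 s, the
longest support a 2-s epoch can host while leaving usable time points
after edge cropping (longer epochs admit lower frequencies; the range is
configurable). Power is decimated to a 100 samples/s grid — comfortably
above twice the 40 Hz voltage-row band edge — and all time points within
half the longest wavelet support (0.5 s) of an epoch edge are cropped, so
features span (−0.5, +0.5) s and contain no wavelet edge artifacts.

The voltage row appended beneath the spectrogram carries the
event-related potential. Its nominal 0.1–40 Hz band is implemented as
per-epoch mean removal plus a zero-phase 4th-order 40 Hz low-pass: on a
2-s epoch the 0.1 Hz edge lies below the 0.5 Hz spectral resolution, and
a true 0.1 Hz IIR high-pass is dominated by multi-second filter
transients (measured 60 Hz stop-band leakage 0.55 instead of the design
value 0.04). A resolvable low edge gets a real high-pass.

Power features are log10-transformed and all features are z-scored using
training-epoch statistics only, inside each cross-validation fold. Raw
power spans orders of magnitude across the 1/f spectrum and the voltage
row has different units; without per-feature standardization the PCA is
dominated by low-frequency power rows.

## Decoding model

Per contact and format (each of the four modalities, plus a pooled "all"
contrast of all stimulus epochs against an equal-sized baseline sample):
stratified 6-fold cross-validation; within each training fold,
standardization → PCA to 50 components (`svd_solver="full"`, reduced with
a warning when a training fold cannot support 50) → linear SVM (C = 1, no
tuning). Held-out epochs are scored and pooled over folds into one
accuracy.

Significance uses an exact fair-coin binomial upper tail with the
observation count set to the per-modality presentation count (n = 40 by
default): pooled accuracy is rescaled to `round(accuracy × 40)` correct
out of 40, and the contact is significant when the exact tail probability
is below α = 0.01 (critical accuracy 28/40 = 0.70). Referring the test to
40 observations rather than the ~80 pooled test epochs is deliberate and
conservative; the pooled count can be used instead via `NullSpec`. With
fair-coin chance the tail is computed in exact integer arithmetic.

The companion power analysis (`power_one_sample_t`) evaluates the
noncentral-t power of a one-sample t-test; at d = 0.4, n = 40 and
one-tailed α = 0.05 it gives 79.97% — the one-tailed convention is fixed
by that reference figure (two-tailed gives 69.4%).

## Coefficient interpretation

The fitted classifier is linear in the standardized features, so each
fold's SVM weights are back-projected through its PCA basis into an
"eigenspectrogram": `grid = Σ_k w_k · component_k`, with an effective
intercept absorbing the PCA centering. The identity
`grid · z + intercept = component-space decision value` holds to machine
precision and is asserted in tests at 1e−10.

Reliability of coefficient structure is assessed with per-epoch signed
contribution maps — the element-wise product of the held-out fold's
coefficient grid with the epoch's standardized feature grid, signed +1
for stimulus and −1 for baseline epochs. Per-fold coefficient maps (n =
6) cannot support a sign-flip test at α = 0.01 (2⁶ = 64 orderings), so
the per-epoch construction (n ≈ 80–96) is used. A contribution map
measures classification *evidence*: it is positive in expectation
wherever a feature reliably discriminates, whether the underlying power
change is an increase or a decrease — the sign of the spectral change
itself lives in the coefficient map.

The one-sample cluster permutation test thresholds the pointwise
t-statistic at the (1 − α) quantile of central t (df = n − 1), forms
4-connected clusters separately for positive and negative suprathreshold
points, uses summed t as cluster mass, and builds the null from the
maximum |mass| over 1000 random sign-flip permutations (resolution 0.001
≪ α = 0.01; means under sign flips are a single matrix product because
sums of squares are flip-invariant). The appended voltage row is its own
connectivity domain — clusters never bridge power and voltage rows, which
are incommensurate. Zero-variance points get t = 0: the sign-flip null
cannot assess them. Cluster p-values use the add-one correction
`(1 + #{perm ≥ |mass|}) / (n_perm + 1)`.

## Group maps

* **Counts**: significant contacts per format, and the intersection
  significant in all four modalities.
* **Region accuracy**: per anatomical label, the max (default; mean
  available) accuracy over that region's significant contacts; regions
  with none are omitted. Max is the transparent choice for a "best
  decoding per region" display.
* **Feature maps**: at each (frequency, time) point, (1) the proportion
  of analyzed contacts with a significant cluster covering the point
  (denominator: all analyzed contacts, configurable), (2) among covering
  contacts, the fraction whose covering cluster has positive mass, and
  (3) the mean accuracy of covering contacts. Maps (2) and (3) are
  NaN-masked where no contact covers the point. "Classification value" of
  a point is defined here as that mean accuracy — the simplest reading
  consistent with a per-point summary of covering contacts.

## Determinism

A master seed fans out through `SeedSequence(master, spawn_key=(stage,
contact, format))` to every random draw (schedule, noise, subsampling,
fold assignment, permutations), so per-contact work is order-independent
and two runs of one config produce byte-identical TSVs. All derived seeds
are < 2³¹.

## Validation experiment sizes

The packaged experiments (`seegdecode.experiments`) use: 200 effect-free
contacts (eight 25-contact cohorts, bounding memory at ~160 MB per
cohort) for binomial-null calibration; 500 pure-noise repetitions (40
observations, 26 × 21 grids) for cluster family-wise error; and a
16-contact recovery cohort with magnitude-3 effects on six contacts — two
broadband (70–150 Hz, 0–0.5 s, transient as high-frequency responses
are), two alpha decreases and two theta increases (8–13 / 4–8 Hz,
sustained through the 1-s stimulus, as low-frequency
(de)synchronization is). Narrow-band effects confined to 0.5 s are
roughly halved at feature level by wavelet temporal smoothing and land
near the decision boundary; the sustained windows realize the intended
high-SNR regime (single-contact accuracies ≈ 0.73–1.0).

## Known limitations

* The rejection-threshold estimator is the global-threshold criterion
  only; no per-channel repair or interpolation.
* No notch filtering, ICA, or seizure-onset-zone exclusion.
* The "all" contrast reuses baseline epochs that per-format contrasts
  also sample, so results across formats are correlated by construction.
* Feature-map directionality inherits the evidence-sign caveat above:
  contribution clusters for genuine effects are predominantly positive.
* EDF output is 16-bit quantized over each channel's observed range;
  round-trip error is bounded by one quantization step (~1/65535 of the
  range).
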