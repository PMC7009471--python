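# Methods

`burstdecode` re-implements, end to end, a movement-decoding analysis for
subthalamic local field potentials (LFPs): six directional contacts are
recorded at 2048 Hz while a subject makes cued upper- or lower-limb
movements, windowed spectral features predict the limb about to be moved,
and the analysis asks how transient alpha/beta bursts change the information
available in the signal.  Because the clinical recordings such analyses run
on are not publicly distributable, the package ships a synthetic-session
generator with known ground truth, and every stage of the analysis is
validated against it.

## Analysis pipeline

**Conditioning.**  Each contact is high-pass filtered at 2 Hz (zero-phase
4th-order Butterworth), linearly detrended and z-scored over the whole
recording, before any segmentation.  Flat or amplifier-clipped contacts
(> 5% of samples pinned at an extremum) are excluded.  The 2 Hz corner and
filter family are conventional; zero-phase filtering preserves event timing.

**Segmentation.**  Trials are cut as half-open epochs [−4, +3) s around each
auditory cue, with an extra 0.5 s of real signal on each side kept
internally so that wavelet edges never touch analysis windows.  Task
periods: rest (7 s pseudo-trials cut from the dedicated rest segment),
pre-cue [−4, 0), pre-movement [cue, movement onset), post-movement
[onset, offset).

**Time-frequency decomposition.**  Complex Morlet wavelets, 7 cycles at
every frequency, on a 1 Hz grid from 8 to 500 Hz.  Power is evaluated
directly at output points spaced 10 ms apart by a banded matrix product
(wavelets grouped by support length), which is numerically identical to
convolving at the full rate and decimating but ~100x cheaper; the
implementation is cross-checked against MNE's `tfr_array_morlet` in the test
suite.  100 ms feature windows then average >= 10 decimated samples.

**Baseline normalization.**  Every 1 Hz component of every trial is divided
by its mean power in a 500 ms baseline window of the same trial, placed at
[−2.0, −1.5] s before the cue (for rest pseudo-trials: the chunk's leading
500 ms).  Power, not amplitude, is normalized; the baseline position and
length are configuration options.

**Features and selection.**  One feature per contact per band: mean
baseline-normalized power over nine bands (8–12, 13–20, 21–30, 31–45,
56–95, 106–200, 201–300, 301–349, 350–500 Hz; the 46–55 and 96–105 Hz gaps
are line-noise guards, and nothing below 7 Hz is used because a 100 ms
window cannot estimate it).  Features are standardized (population SD) on
the training folds only.  ReliefF (10 Euclidean neighbours, every instance
iterated, no subsampling) ranks features on each training split; the top
six enter the classifier, and a feature's importance is its selection count
across the four folds divided by four.  Folds are stratified by class at
the *trial* level, so windows from one trial never straddle the train/test
boundary.  Optional time-domain descriptors (Hjorth parameters, entropy,
moments, extrema) are implemented but excluded from the main analyses.

**Classifier.**  Gaussian naive Bayes, written from first principles:
class priors are relative frequencies, each selected feature gets a
per-class Gaussian, and posteriors are evaluated in log space with
log-sum-exp normalization (a six-feature density product underflows double
precision otherwise).  Per-class variances are floored at 1e-9 times the
largest variance.  Exact posterior ties resolve to the first class in
sorted label order.  The implementation is checked against a direct
product-of-densities oracle and against scikit-learn's `GaussianNB`.

**Evaluation.**  The decoding score of a window is the out-of-fold
posterior of the "upper" class; AUC is the Mann–Whitney statistic with ties
at 1/2 (0.5 = chance).  Task-period AUC is computed per contact per
cue-aligned 100 ms window position, averaged over a period's windows and
then over contacts.  The condition-comparison helper chains Lilliefors
normality checks, a Box-Cox transform when any condition is non-normal,
repeated-measures ANOVA with Mauchly sphericity and Greenhouse-Geisser
correction, paired t-tests, and Benjamini-Hochberg FDR.

**Burst detection.**  Band power envelopes (alpha 8–12, beta 13–30,
low-gamma 35–45 Hz) are the mean over the band's 1 Hz rows, smoothed with a
200 ms moving average; a burst is a maximal run above the contact- and
band-specific 75th percentile (computed over the concatenated pre-cue
spans, so movement-related suppression never biases the threshold) lasting
at least 100 ms.  Detection uses its own *constant-bandwidth* Morlet bank
(sigma_f = 2 Hz, i.e. n_cycles = f/2) rather than the 7-cycle map used for
features: at 10 Hz a 7-cycle wavelet spans ~0.9 s and smears 0.17 s bursts
into one another, while a fixed-cycle fast wavelet is so broad in frequency
that a strong alpha burst bleeds into the beta envelope; a fixed 2 Hz
bandwidth gives ~0.08 s localization *and* keeps the adjacent bands
separate.  Low-gamma bursts are detected only to exclude their time from
non-burst periods.  Alpha and beta bursts that overlap are both removed;
one 100 ms window is centred on the midpoint of every surviving burst and
every burst-free period of at least 100 ms.  Burst statistics (rate, mean
duration, occupancy, cross-band overlap proportion) are computed on the
detections *before* overlap removal.

**Burst-state decoding.**  For each contact, one cross-validated model is
trained on all pre-cue windows pooled across states, and each state's AUC
is computed from that state's out-of-fold scores.  Training per state is
available as a configuration option (with window counts subsampled to the
smallest state), but pooled training is the default because the non-burst
state has roughly three times as many windows as either burst state, and
that training-set-size advantage otherwise masquerades as a burst effect.
Two contact summaries are reported: the *same best three* contacts (the
triple maximizing the state-averaged AUC, applied to every state) and a
*different best three* per state.  The latter maximizes over a superset, so
per state it can never be smaller — the direction of that inequality is a
structural fact, not a finding.  Both summaries select contacts on the data
they are reported on; the optimistic bias this introduces is accepted for
fidelity to how such summaries are usually reported, and a nested selection
would be the conservative alternative.

## Synthetic sessions

`synthdata.generate_session` produces a rest segment (default 100 s)
followed by cued trials (default 16 per limb, intertrial interval
7.7 ± 1.6 s clipped to roughly 6–12 s for the fixed-limb design, 7 ± 2.1 s
for random-limb), sampled at 2048 Hz on six contacts with a 550 Hz
recording low-pass.  Each contact carries:

- **1/f background**: Gaussian noise with power-law spectrum (default
  exponent 1.5 above 1 Hz), independent across contacts.
- **Bursts**: per contact and band, Poisson onsets (alpha 1.0125/s, beta
  0.7342/s — the pre-cue rates the analysis targets) and durations drawn as
  0.1 s plus a Gamma(shape 2) excess with overall means 0.1672 s (alpha)
  and 0.2015 s (beta).  The 0.1 s offset makes every planted burst satisfy
  the detector's minimum-duration definition, which is the population the
  reported duration statistics describe.  Each burst is a band-centre
  cosine with random phase under a Hanning envelope, at 12x the band's
  background RMS.  The gain is deliberately high: the percentile detector
  finds *something* occupying ~25% of any signal, and only a strong
  amplitude separation makes its detections coincide with the planted
  bursts (at 2.5x, only a third of detected alpha bursts matched a planted
  one).
- **Class contrast**: "upper" trials multiply selected band components'
  power by (1 + c_b g(t)); the default contrast vector is
  (0, 0, 0, 0, 2, 2, 2, 4, 4) over the nine feature bands.  The contrast is
  kept out of the four lowest bands so that the planted alpha/beta carriers
  (and their spectral skirts) cannot dilute it — the gating factor below is
  then the *only* mechanism coupling bursts to information content.
- **Temporal profile**: because every trial is normalized by a baseline
  inside the trial, a time-constant multiplicative contrast cancels exactly
  and carries no decodable information.  The profile g(t) is therefore
  U-shaped for the forewarned (fixed-limb) design: 1 at the trial start,
  falling quadratically to 0 at the centre of the baseline window
  (−1.75 s), rising back to 1 at the cue and holding through the movement.
  The baseline window thus measures the tonic, class-free level; the
  window/baseline power ratio of "upper" trials deviates from 1 with a
  single sign everywhere, which both per-position decoding and pooled
  burst-state decoding can exploit.  For the random-limb design the
  contrast switches on 0.3 s after the cue, so pre-cue windows are
  exchangeable between classes.  The defaults were calibrated once so that
  forewarned pre-cue decoding lands in the ~0.75–0.8 AUC regime and the
  chance-level controls stay at 0.5.
- **Burst gating**: while a burst is ongoing (plus a 0.05 s margin covering
  detector centre jitter), the profile is relaxed toward its baseline
  level: g_eff = gamma g + (1 − gamma) g_base.  gamma = 1 leaves the
  contrast untouched; gamma = 0 pins it at the level the baseline division
  removes, so a fully gated burst window carries exactly zero class
  information — which is what "bursts erase the information" should mean
  under ratio features.  (Simply multiplying the instantaneous contrast by
  gamma does *not* achieve this: the baseline itself carries contrast, and
  an "erased" window remains decodable through the ratio.)

Ground truth (burst intervals per contact and band, and the applied
contrast profile) is returned alongside the recording and event table.
Sessions round-trip through an HDF5 + CSV container.

### What the generator does not emulate

Contacts differ only by independent noise (no volume conduction or
directional geometry); there is no EMG, no artifacts beyond optional
clipping, no trial-to-trial variability in contrast amplitude, and the
class contrast is a smooth deterministic modulation rather than a
physiological pattern.  Detected burst statistics consequently match the
planted rates only approximately (the smoothed percentile detector pins
occupancy near 25% and stretches durations by its ~0.2 s blur; cross-band
overlap of *detected* bursts is correspondingly higher than the planted
overlap).  Passing tests therefore demonstrate that the pipeline measures
what it claims under its own assumptions — chance level when no contrast
exists, signal when it does, degradation exactly when bursts gate it — not
that real subthalamic data behave like the generator.

## Numerical choices and degenerate inputs

- Morlet wavelets are truncated at ±3 sigma_t and L2-normalized; edge
  samples whose support crosses real data boundaries are flagged invalid.
- Zero baseline power flags that frequency/trial as invalid (NaN) rather
  than dividing by zero; windows containing invalid samples are dropped and
  counted.
- Constant envelopes produce no bursts (strict `>` threshold); empty burst
  sets report rate 0 and *missing* (NaN) duration.
- Zero-variance feature columns are excluded from ReliefF with weight 0;
  classes too small for 10 neighbours reduce the neighbour count with a
  warning; folds reduce below 4 only if a class has fewer trials than folds.
- ReliefF under permuted labels has a small negative finite-sample bias
  (unequal hit/miss candidate pools); it is two orders of magnitude below
  informative-feature weights and is documented in the tests.
- Exact GNB posterior ties break toward the first sorted class label.

## Problem sizes

The shipped checks run at desk scale, chosen as a compromise between
statistical resolution and turnaround: 50 zero-contrast sessions (rest
null), 6 random-limb and 3 fixed-limb sessions (pre-cue dissociation),
50 seeds per gating level at 16 trials/class with a 10 s rest stub (the
burst-state analysis does not use rest), and 3 seeds of 200 s rest-only
signal for detector rate recovery.  A full single session analyses in a
few seconds on one core.

## Known limitations

- The percentile burst detector cannot recover planted rates exactly even
  at high SNR (occupancy pinning, merging of close bursts); recovered rates
  are within ~15%, and recall of planted bursts is ~95%.
- Best-contact summaries are selected on the reported data (see above).
- The rmANOVA chain applies a single Box-Cox transform to all conditions
  pooled rather than per condition, matching how such transforms are
  usually applied to matched designs.
- Rest pseudo-trials receive balanced arbitrary labels; rest AUC is a null
  calibration, not a measurement of any real rest-state information.
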