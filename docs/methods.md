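# Methods

`errpkit` implements a complete analysis chain for error-related potentials
(ErrPs) recorded during tasks with *continuous* feedback — e.g. steering a
cursor with a thumbstick while the interface occasionally perturbs the
mapping (an **execution error**) or the cursor collides with an obstacle
(an **outcome error**). Because no public recording of this paradigm is
available, the package is driven by a synthetic-data generator that states
the assumed signal model explicitly; every downstream stage is tested
against that stated world.

## Signal model of the generator

A session is simulated at `fs = 512 Hz` with 28 scalp channels (standard
10–20 subset), 3 EOG channels and a 2-D thumbstick trace.

**Ongoing EEG.** Each channel is an AR(4) process driven by white noise.
The default denominator has real poles at 0.88 and 0.70 (1/f-like roll-off)
and a complex pair at radius 0.9 tuned to 10 Hz (alpha resonance). Channels
are mixed by a fixed distance-based kernel (`exp(-d²/2σ²)`, σ = 0.5 in
normalized head coordinates) and rescaled to a per-channel RMS of 5 µV.

**Events.** Execution errors last 2 s; the gap from the end of one
perturbation to the next onset is uniform on [5, 8] s (the spacing is
ambiguous in the field's descriptions; this reading yields ≈ 3600/8.5 ≈ 424
events/h, the right order of magnitude, and is *not* tuned to match any
published count). Severities are drawn from {45°, 90°, 180°, 270°, 315°}.
Outcome errors are a homogeneous Poisson stream (86/h) with a 1.5 s
refractory period, thinned so collisions never fall inside a perturbation.

**ErrP templates.** Each event injects a sum of signed Gaussian bumps times
a frontocentral topography (Gaussian gain profile peaked between FCz and
Cz, σ = 0.25). Execution: +229, −287, +367, −461 ms; outcome: −2, +268,
−486, +742 ms. On top of the deterministic bumps, band-limited noise bursts
(delta 1–4 Hz and theta 5–7 Hz, starting 0.1 s post-onset) realize the
error-related spectral response; their `power_gain` parameter is the burst
RMS in µV at the topography peak. By default severity changes only the
event label, never the waveform (mirroring the published null finding);
`severity_scales_amplitude=True` scales the amplitude with the folded angle
for sensitivity checks.

**Ocular artifacts.** Blinks (12/min, ~150 µV raised-cosine pulses) and
saccade pulses (18/min, signed) form the EOG channels, and leak into the
EEG with a frontally weighted profile (leakage scale 0.12). The EOG sensor
noise itself does not leak — only the ocular sources do.

**SNR calibration (done once, then frozen).** The literature reports no
single-trial SNR, so the free amplitude/noise scales were calibrated so
that the *default* world (`snr_scale = 1`) reproduces the published
event-locked operating point: single-trial accuracies in the ~65–75 % range
for the three contrasts. All acceptance checks were written after this
calibration and the parameters were not revisited. Consequences worth
knowing: the synthetic world is cleaner than real EEG (stationary
background, no EMG, no non-stationary drift, perfectly time-locked
responses), so asynchronous AUCs at `snr_scale = 1` come out around 0.9
rather than the ~0.65–0.75 seen on real recordings. A green recovery test
therefore establishes correctness of the pipeline, not expected field
performance.

## Preprocessing

Order is fixed and recorded in a provenance flag: Butterworth band-pass
0.5–60 Hz plus 50 Hz IIR notch (Q = 30) → EOG regression → common average
reference (EEG channels only) → segmentation. Filtering is zero-phase
(forward–backward) for offline analysis; a causal mode exists for
deployment-style detection. EOG regression solves
`coefficients = Cov(EOG)⁻¹ Cov(EOG, EEG)` on the full band-passed recording
(no separate calibration segment; band-passed regressors), falling back to
a ridge-regularized solve when the EOG covariance is near singular. EOG
channels are kept unmodified for the confound analyses.

Trials are 1 s, half-open windows `[start, end)`; epoch sample *i* covers
`onset + start + i/fs`. noError candidates tile the recording on a 1 s
grid and survive only if the window ± 1 s guard contains no event onset and
no part of a 2 s perturbation interval.

## Event-locked classification

Features from 0.2–0.9 s post-event (358 samples/channel at 512 Hz): raw
time samples, the first 40 Welch bins (segments 256, overlap 128, Hann,
FFT 512 → 1 Hz bins spanning 0–39 Hz), or both. Classifier: linear SVM,
C = 1, on per-feature z-scored data (required because time- and
frequency-domain features live on very different scales). Evaluation:
stratified 10-fold CV with balancing (majority down-sampling) *and*
standardization fitted inside each training fold; the held-out score is the
balanced accuracy, which keeps chance at 0.5 even though the untouched test
folds are imbalanced. Significance: the label vector is permuted before
training, the full CV re-run (1200 repetitions by default), and the
threshold is the empirical 95th percentile.

Severity analysis runs every severity pair plus the pooled mirror-angle
contrasts (45+315 vs 90+270, and each vs 180).

## Asynchronous detection

A 1 s window slides in 62.5 ms steps (32 samples). Features: Burg
maximum-entropy spectra, model order 16, evaluated at 1–12 Hz in 1 Hz bins,
computed on the 0.1–0.5 s sub-window only (better asynchronous performance
and a 0.5 s reaction latency). The Burg recursion is implemented in-house,
vectorized over window × channel batches (the detector evaluates ~10⁵
channel-windows per session), with reflection coefficients clipped at
|k| < 1 − 10⁻⁷ and a flat-epsilon guard for near-constant segments; it is
cross-checked in the tests against the independent `statsmodels`
implementation.

Training: top-20 features by squared point-biserial correlation (ties break
toward the lower index), linear SVM with a 5× error-class cost for outcome
detectors (heavy class imbalance; execution detectors use equal costs),
Platt sigmoid calibration `p = 1/(1 + exp(A·d + B))` fitted by regularized
maximum likelihood on decision values from an internal 3-fold cross-fit
(in-sample decision values give overconfident sigmoids). The probability
stream is smoothed by a weighted average of the last three outputs —
default weights (1, 2, 3)/6, most recent heaviest, renormalized over the
available history at the first two steps — and thresholded (default 0.8).

A window counts as *containing an error* when its start lies within
0.5 s after an event onset, so the feature sub-window overlaps the
discriminative part of the response. Chronological 10-fold CV keeps
training and test temporally disjoint: contiguous equal segments, training
restricted to event-locked trials wholly outside the held-out segment, test
windows never straddling segment boundaries.

## Metrics

ROC curves sweep thresholds 0…1 in 0.01 steps, anchored at (0,0) and (1,1),
trapezoid AUC (equal to the Mann–Whitney statistic up to threshold
quantization ≤ 0.01). PSR_θ / NSR_θ partition the timeline into 1 s bins
anchored at t = 0: PSR is the percentage of error-containing seconds with
at least one above-threshold decision, NSR the percentage of error-free
seconds with none. ERP contrasts use pointwise unequal-variance two-sample
t-tests with Bonferroni correction over the number of time samples at the
tested channel (the test statistic is a package choice; the correction
scope can be widened to channels via an option). Aggregation across
sessions/subjects is the plain arithmetic mean at full precision; published
comparison tables round half-up.

## Numerical and design choices

* All randomness flows from one `numpy` Generator per entry point; seeds
  are recorded in recording metadata and EDF headers.
* EDF I/O is a minimal in-house codec (1 s records, 16-bit samples,
  per-channel scaling, zero-padded tail with the true sample count stored
  in the reserved header field) — sufficient for round-tripping this
  package's own files, not a general-purpose EDF reader. Events travel in
  a sidecar TSV because EDF annotations cannot carry severity metadata.
* Balancing before vs inside CV folds: balancing is label-only subsampling
  and cannot leak feature statistics, but it is still fitted inside each
  training fold together with the scaler, and the balanced-accuracy metric
  absorbs the resulting test-fold imbalance.
* Degenerate inputs: empty event selections yield empty trial sets (not
  errors); detectors with fewer than 20 available features keep all with a
  warning; folds without error events are evaluated for specificity only.

## Known limitations

The generator's stationary AR background and strictly repeated template
shape make classification easier than on real EEG; inter-subject
variability, electrode drift, EMG and line-noise non-stationarity are not
modelled. The thumbstick trace is only weakly informative about
perturbations, so confound classification lands near (not exactly at)
chance. The asynchronous detector is an offline sliding-window evaluation,
not a streaming implementation.
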