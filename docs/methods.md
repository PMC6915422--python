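# Methods

This note documents the models and procedures implemented in `swimu`, the
parameters that matter, the synthetic study conditions, and the numerical
choices made where the design was genuinely open.

## Signal model and conventions

One sample per 10 ms (100 Hz nominal): time in ms, accelerometer (g),
gyroscope (deg/s), magnetometer (gauss), pitch, roll, heading (degrees).
Pitch is positive nose-up in [−90, 90]; roll positive to the swimmer's
right in [−180, 180); heading in [0, 360). The device provides fused
orientation (AHRS); no sensor fusion happens here. I/O keeps units as
logged; the g → m/s² conversion (9.80665) happens only inside the energy
features, keeping the CSV round trip lossless. Non-uniform sampling is
tolerated to 10% on the median gap (the FIR filters assume a fixed rate);
linear resampling is offered as an explicit repair, never applied silently.

## Lap segmentation

* `apex_trigger_deg = 70`: the descriptive claim is only that turn pitch
  gets "close to ±90°", so the trigger sits comfortably below the apex but
  far above the ±20° swim band. Configurable.
* Turn vs. stop: an excursion is a stop when the separation between its
  governing local pitch extrema is ≥ `stop_min_s = 3` s. With noise, the
  extremum locations inside a −90° plateau are arbitrary, so the decision
  uses the *maximum* of the extremum separation and the dwell time beyond
  the apex trigger; both are monotone in `stop_min_s`, so the documented
  turn→stop reclassification behavior is preserved. Slow turns (> 3 s) are
  deliberately reported as stops — the threshold is a coach-tunable
  parameter, not a hidden heuristic.
* Boundary refinement slides the 0.5 s averaging window one sample at a
  time (the step size was unspecified; one sample is the finest choice and
  is what the brute-force oracle in the tests checks). Start uses a
  trailing window ending at the candidate instant, end a leading window;
  at session edges the boundary clips to the signal bounds rather than
  dropping the event, so warm-up/cool-down fragments stay visible.
* Scaled MAD uses the normal-consistency constant 1.4826. With MAD = 0
  only exact-median lap times are inliers.
* Missed-turn recovery: heading is unwrapped and a reversal requires an
  accumulated change ≥ 150° within 5 s (thresholds invented — the source
  description says only that heading reverses — and exposed as
  parameters). The apex goes to the local pitch maximum nearest the
  reversal midpoint. Recovery iterates (split lap → re-scan outliers) to a
  fixed point, at most 4 passes.
* Lap times exclude the adjoining event durations; event durations are
  reported separately per lap. Laps are 1-based; sample spans half-open.

## Style classification

* The 0.5 Hz, 48th-order Hamming FIR is applied as a centered convolution
  on a reflect-padded copy: linear phase, group delay compensated, output
  length preserved. At 100 Hz this filter's transition band is wide
  (≈ 6.6 Hz), so stroke-cadence content (~0.5 Hz) is attenuated but far
  from removed — the energy features operate on that residual.
* Backstroke threshold −0.5 g: midway between the supine (−1 g) and prone
  (+1 g) regimes. A lap with mean az near 0 g (sideways, degenerate) logs
  a warning and falls through to the prone branch.
* Energy rounding is half-away-from-zero ("round" was otherwise
  unspecified).
* SVM: polynomial kernel with box constraint 10⁵. The kernel degree in the
  source setting is printed ambiguously ("ρ=1"); degree 1 (an inhomogeneous
  linear kernel) is the default here and the parameter is exposed.
* ANN: 3 inputs (Ex, Ey, Ez), 10 logistic hidden units, 3 outputs with
  one-hot targets and argmax decoding; plain SGD with momentum 0.5 and
  learning rate 0.3, stopping on a training-loss plateau (no stopping rule
  was published); all randomness seeded.
* Serialized models (JSON: hyperparameters + weights / support vectors)
  predict through a hand-written forward pass — a one-vs-one kernel vote
  for the SVM, a logistic forward pass for the MLP — verified in the tests
  to reproduce the fitted estimator's predictions.
* The `rule` classifier in the CLI (y-dominance for front crawl, a z-energy
  threshold for butterfly vs. breaststroke) is an ad-hoc fallback for
  running the pipeline without a trained model; it is not the evaluated
  classifier.

## Stroke counting

* Both counters filter at 3 Hz (48th-order Hamming) and use local extrema
  with a 0.25 s minimum separation (invented, configurable) and plateau
  midpoint selection.
* The k·σ gate keeps extrema *outside* the band mean ± k·σ of the per-lap
  filtered signal, with σ the sample standard deviation (ddof = 1). The
  printed inequality defines the inside of the band and its intended
  direction is ambiguous; strokes are the large deflections, so the
  outside-band reading is used. Note the consequence: with k = 2 a pure
  sinusoid (σ = 0.707·A) has *no* sample outside the band — the per-style
  k values only make sense for waveforms peakier than a sinusoid, which
  real trunk-roll traces are and the synthetic generator emulates (see
  below).
* Symmetric-style cycles are resampled to 200 samples by linear
  interpolation on the time-normalized segment; the mean wave is the
  pointwise mean of samples 50–149 (the central 50%). DTW uses squared
  local cost, symmetric steps, no warping window, and returns the root of
  the accumulated cost.
* The DTW rejection threshold was "empirically determined" upstream but
  never published. Default here: self-calibrating,
  max(3 × median cycle-to-template distance, 15.0), computed per session.
  The floor keeps near-identical clean cycles (whose distances are all
  tiny) from rejecting each other; 15 sits an order of magnitude above
  clean-cycle distances (~0.5–2.5 at 1° angle noise) and an order below
  artifact distances (~100+). A fixed threshold and a corpus-level
  template can be supplied instead.

## Indicators

* Trunk elevation: per-cycle pitch_max − pitch_min, symmetric styles only;
  explicit null with a reason code otherwise (mirroring the n.a. layout of
  the reference report format).
* Body balance: overall mean ± sd of lap pitch (nonsymmetric); per-cycle
  pitch maxima and minima statistics (symmetric).
* Body rotation: the mirror image on roll — per-side stroke-peak
  statistics (nonsymmetric), overall mean (symmetric). Min/Max are defined
  numerically; the reference tables appear to use a different labeling
  convention for some style/sex blocks that is not explained there, so no
  attempt is made to reproduce it.
* Stroke rate = 60 · count / lap_time with lap_time excluding events; the
  counted unit is whatever the style's counter returns (arm strokes for
  nonsymmetric styles, cycles for symmetric ones).
* sd is the sample standard deviation (ddof = 1) everywhere; a single
  observation reports sd 0.
* Detection accuracy: one-to-one greedy nearest-neighbor matching within
  0.3 s (the matching rule was never stated operationally; nearest-neighbor
  one-to-one is the standard convention). Discarded candidates that do not
  correspond to a missed true stroke are true negatives; a wrongly
  discarded true stroke is a false negative.

## Synthetic study conditions

The generator emulates exactly the features the detectors consume:

* **Waveforms.** Nonsymmetric roll is a train of alternating-sign raised-
  cosine pulses (one per stroke) with duty cycle 0.50 (front crawl) /
  0.35 (backstroke) of the stroke slot — the trunk snaps to the pulling
  side and passes through neutral during recovery. This peakiness is what
  makes the k = 2 / 2.36 gates pass every true peak with ~4° of margin on
  clean signals. Symmetric pitch rides near a glide value (+5°) and dips
  30° once per cycle (duty 0.45); n cycles are delimited by n + 1 interior
  minima. Roll amplitude 45°.
* **Defaults** (25 m pool): front crawl 16 strokes / 20 s, backstroke
  16 / 24 s, breaststroke 10 cycles / 28 s, butterfly 9 cycles / 22 s.
  Angle noise sd 1.0°, acceleration noise sd 0.05 g — no noise levels were
  published for the reference recordings; these are plausible AHRS figures
  chosen once and stated here, not fitted to anything.
* **Events.** Tumble/open turns: 1.5 s raised-cosine pitch excursion to
  ±85°. Stops: descend to −85°, hold 5 s, ascend, with 1 s ramps. Bucket/
  cross-over turns: a muted +12° bump (below the ±20° band) over 1.6 s.
  Every event carries a smooth 180° heading reversal.
* **Accelerometer.** az baseline −1 g for backstroke, +1 g otherwise;
  per-style oscillation amplitudes at the stroke cadence with ~10% per-lap
  lognormal jitter, chosen so the rounded energies form separated clusters
  (front crawl y-dominant, butterfly z/x-elevated vs. breaststroke) with
  the qualitative geometry of the reference feature space.
* **Butterfly artifact.** With probability 0.2 a butterfly lap's final
  undulation is half depth and late, emulating the continuous trunk
  rotation into the wall; the artifact stroke stays in ground truth, so
  missing it costs a false negative — reproducing the known failure mode.

**What passing these tests does and does not show.** The synthetic corpus
is *more* separable than real data: energies cluster cleanly, waveforms
are stationary within a lap, noise is white and Gaussian, and there is no
inter-swimmer variability, breathing asymmetry, push-off glide or fatigue
drift. Perfect or near-perfect synthetic scores therefore validate the
implementation against its own assumptions — boundary conditions, gating
arithmetic, template rejection, parameter monotonicity — not field
performance. In particular, the published real-data figure of ~89–90%
three-class style accuracy is a property of the overlapping real feature
clouds and is not reproducible (nor meaningfully comparable) on synthetic
clusters; the trained classifiers here are instead held to ≥ 95% on their
own, more separable geometry.

## Problem sizes

The evaluation corpora are 50 mixed-style 8-lap sessions (~210 s each) for
segmentation, 50 single-lap sessions per style for backstroke recognition
and stroke counting, and 75-lap feature corpora for classifier training —
sizes at which every quantity is stable to well under the acceptance
tolerances while the full suite runs in well under a minute.

## Known limitations

* Turn types (tumble vs. open vs. bucket) are detected but not labeled in
  reports.
* Kick counting and limb-mounted symmetry metrics are out of scope (single
  lower-back unit).
* The stop/turn boundary at exactly 3 s misclassifies unusually slow turns
  as stops by design; retune `stop_min_s` per squad.
* The DTW rejection floor (15) is calibrated to degree-scale angle
  signals; template matching on differently scaled series needs an
  explicit threshold.
* Streaming/real-time operation is not supported; the pipeline is
  batch-per-session.
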