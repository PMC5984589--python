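# Methods

This note records the models the package implements, the defaults that
matter, what the synthetic-data generator does and does not emulate, and the
design choices made where the design was genuinely open.

## Conventions

All series share one time base: float seconds since the deployment's first
sensor sample, joining the 40 Hz sensor stream, the 1 Hz products and the
1-per-minute GPS fixes on a single monotone axis. Body axes are x = sway
(animal's right), y = surge (forward), z = heave, right-handed, z positive up
when standing, so a level tag reads static acceleration (0, 0, 1) g. The sign
conventions matter: pitch is positive head-up, and heading is the compass
bearing of the surge axis, clockwise from north. Geographic coordinates are
WGS84; local metric coordinates come from a tangent-plane projection built
from the meridian and prime-vertical radii of curvature at a fixed origin
(the first GPS fix by default). This is accurate to well under a metre at
paddock scale and exactly invertible, which the round-trip tests exploit.
Rasters are north-up, cell-centre registered, sampled nearest-cell, and are
stored as ESRI ASCII grids or single-band GeoTIFFs with a JSON sidecar
carrying name, kind (categorical/continuous), legend and CRS.

## Signal features

**Static/dynamic split.** Static = centred running mean per axis over a
window of 2.0 s (configurable); dynamic = raw − static. The window must cover
a few locomotion cycles but stay shorter than postural changes; 2 s does both
at sheep stride rates (~2–3 Hz). Edges shrink the window rather than pad, so
no sample is extrapolated. The split is exact by construction (static +
dynamic = raw to 1 ulp).

**VeDBA** = √(d_x² + d_y² + d_z²) per sample, with an optional 1 s boxcar;
annotation and speed calibration use the 1 s mean. VeDBA is rotation
invariant, which makes it robust to tag mounting.

**Head pitch** = atan2(s_y, √(s_x² + s_z²)) degrees. A zero static vector is
undefined and yields NaN with a log message rather than a fabricated value.

**Activity counts** = Σ over a 1 s window of |raw − window mean| across the
three axes. The commercial tag software computes an unpublished quantity of
this kind; this windowed mean-absolute-deviation sum is our documented proxy,
and a test pins its rank agreement with VeDBA (Spearman ρ ≥ 0.9) rather than
any absolute scale.

**Heading** uses standard e-compass tilt compensation: roll = atan2(−s_x,
s_z) and pitch from the static vector, the magnetometer vector de-rotated by
roll about the surge axis then pitch about the sway axis, heading =
atan2(−m_x, m_y) + declination (default 0°, configurable — magnetic vs
geographic north shifts every dead-reckoned path). The minus sign is the
compass-needle convention: the Earth field appears rotated by −heading in
body coordinates. Samples with |pitch| > 85° are flagged low-confidence
rather than dropped. The implementation is verified against an independent
full 3-D rotation oracle to 1e-6°.

## Behaviour classification

The classifier is deliberately transparent: per-behaviour feature envelopes
("threshold trees"), not an opaque learner. For each behaviour the training
blocks define an interval per feature; a 1 Hz block is assigned the first
behaviour in the evaluation order whose intervals all contain it.

* **Features per 1 Hz block** (aligned to integer seconds): mean pitch, mean
  VeDBA, activity counts, and the summed per-axis magnetometer variance
  ("mag_var" — search behaviour is conspicuous by its noisy magnetometer
  signal). Raw-axis acceleration means are available via config but excluded
  from the default feature set: they duplicate the posture information pitch
  already carries, and each additional envelope multiplies the own-class
  rejection rate (~5 % per independent feature at the default quantiles).
* **Envelopes**: [0.025, 0.975] quantiles by default. Strict min/max — the
  classical rule — is a config away (quantiles (0, 1)); quantiles were chosen
  because min/max is brittle to single outlying training blocks.
* **Evaluation order**: fast_walk → grazing → search → vigilance → resting,
  most to least kinematically distinctive, so rare high-energy behaviours are
  not swallowed by broad low-energy envelopes. Configurable.
* **Unclassified** is an explicit outcome for blocks matching no envelope,
  and a majority-vote tie within a second also maps to unclassified.
  Accuracy numbers count unclassified seconds as misses.
* Rumination is not separated from resting (they are indistinguishable in
  these signals); agonistic interactions are out of scope.

**Bite detection.** Within grazing-classified seconds only: a bite is a local
peak in |dynamic heave| with height ≥ θ, pitch below 0° (head down), and at
least 0.25 s after the previous accepted bite — the refractory gap caps the
rate at 4 s⁻¹, matching the plausible physiological range. θ is trained from
the labelled bite times the focal observations carry: per labelled bite the
tallest peak within ±0.15 s is a bite height, every other grazing peak is
background, and θ is the midpoint between the background 0.9 quantile and
the bite 0.1 quantile (falling back to the latter when the populations
overlap, with a warning). Both quantiles, the pitch gate and the refractory
gap are config. Bite-time matching for validation is greedy one-to-one within
±0.5 s.

## Dead reckoning and GPS correction

Speed is a linear function of 1 s VeDBA, clipped to [0, 3] m s⁻¹, with slope
and intercept fitted by least squares against GPS segment speeds (fallback
m = 1.5 (m s⁻¹)/g, c = 0 with a warning when the fit is degenerate or
negative). DR runs at 1 Hz on circular-mean heading (arithmetic angle means
are wrong across the 0/360 wrap) and per-second speed; 40 Hz propagation
exists behind the API but the 1 Hz product is what annotation uses.
Thinning a native-rate track takes the position *at* each integer second —
positions are not averaged, which would shortcut corners.

**Linear correction** distributes each inter-fix closure error linearly in
time; the result passes through every fix exactly and the operation is
idempotent. Its σ is only a diagnostic (zero at fixes, peaking mid-segment).

**Anchored smoother ("melding" contract).** The DR offset (truth − DR) is
modelled per axis as a random walk observed at fix times with SD `gps_sd_m`
(default 10 m, typical consumer GPS); a Kalman forward filter and RTS
backward smoother give the posterior mean offset and variance. The corrected
path is DR + offset; σ is the per-axis RMS posterior SD, minimal at fixes and
maximal between them. Two limits pin the contract: gps_sd → 0 forces the path
through the fixes; drift_sd → 0 collapses to a single rigid shift. This
anchored linear-Gaussian smoother delivers the posterior-mean-plus-
uncertainty contract of Bayesian path melding; the full melding estimator of
the movement literature is intentionally out of scope.

The drift step SD is, by default, estimated from the data by the method of
moments: mean squared inter-fix closure-error increment, minus the 2·gps_sd²
contributed by fix noise, divided by the fix interval. DR drift is largely
*systematic* (heading bias, speed-proxy error), so a fixed small random-walk
rate cannot follow it between fixes; the matched diffusion rate lets the
random-walk prior cover the drift actually present, and with it the smoother
consistently beats the linear correction in RMSE on simulated deployments
(the comparison is a test, not an assumption).

## Landscape fusion

Annotation joins track, behaviour, bite rate, 1 s VeDBA and temperature on
integer seconds and samples each raster nearest-cell; positions outside a
layer yield NaN with a logged count. Summaries conserve mass by construction
(map totals equal column totals), and the tests assert it. Vigilance "rate"
defaults to interruption *onsets* per second (bout starts), with indicator
seconds as the config alternative. Slope bins default to 5°; grazing
intensity defaults to the vegetation raster's geometry.

## The synthetic-data generator

The generator is the package's instrument for verification, not a model of
sheep physiology. Its defaults are the study conditions: activity budget
grazing 0.36, resting 0.25, search 0.31, vigilance 0.02, fast walk 0.06 (the
field means for this kind of deployment), bite rate 1.22 s⁻¹ during grazing,
40 Hz sampling, 60 s GPS interval with 10 m isotropic error, and a 5°
constant heading bias as the dead-reckoning drift source.

* **Behaviour sequence**: semi-Markov; bout durations exponential (whole
  seconds, ≥ 1 s) with per-behaviour means (grazing 180 s, resting 600 s,
  search 120 s, vigilance 15 s, fast walk 30 s — chosen as realistic
  magnitudes and fixed); the next bout's behaviour is drawn with probability
  ∝ budget/mean-bout, which makes stationary occupancy equal the budget. A
  gamma option exists in structure but exponential is the documented default.
* **Signals**: static acceleration is gravity rotated by per-bout head pitch
  (behaviour means −40° grazing, −20° search, −10° resting, +20° vigilance,
  0° fast walk) plus a slow AR(1) within-bout wander (τ = 20 s; the 0.6/0.8
  bout/wander split keeps the stationary SD at the configured value — real
  heads wander within a bout, and a frozen per-bout offset would make
  labelled data unlearnably clustered at bout level). Dynamic noise is
  Gaussian with per-behaviour amplitude (0.01–0.35 g), fast walk adds a
  2.5 Hz gait sine, and bites are half-sine heave pulses (0.15 s, 0.6 g) at a
  refractory-Poisson rate. The magnetometer is a 30-count Earth field at
  −55° inclination rotated into the body frame of (heading + bias, pitch),
  plus per-behaviour jitter — search gets conspicuously noisy magnetometry.
  Temperature follows a skewed diel curve (min 10 °C at 06:00, max 23 °C at
  14:00, cosine rise and fall).
* **Track**: per-second correlated random walk with behaviour-specific speed
  and turning, reflected at the paddock (raster extent) fence. Labels mirror
  the field protocol: focal observations in blocks of at most 300 s, so long
  bouts produce several consecutive labelled intervals.
* **Rasters**: six vegetation classes (Voronoi patches, or deterministic
  bands for tests that must cross every class), elevation ramp plus smooth
  relief with slope by finite differences (exact on a planar ramp), ordinal
  risk high in/near forest, competition high on meadow. Optional couplings
  gate bites to one vegetation class and restrict vigilance to high-risk
  cells, for the landscape-summary contracts.

What the generator does **not** emulate: real jaw or gait kinematics (the
bite pulse is stereotyped and one-sided, which slightly biases grazing-pitch
estimates — measurable in the tests), magnetometer hard/soft-iron distortion
(readers assume calibrated values), GPS outages and multipath, weather beyond
the diel temperature curve, inter-animal interactions, and any behaviour–
terrain coupling beyond the explicit options above. Passing tests therefore
demonstrate that the pipeline recovers known structure of this statistical
kind at realistic signal separations — not field accuracy on real animals,
which depends on labelling quality and signal idiosyncrasies no simulation
fixes.

## Problem sizes and numerics

The recovery experiments use 24 h (budget recovery), 12 h (accuracy floor),
2 h of grazing (bite rate), 10 min noiseless (bite matching), and 20 × 1 h
replicates (correction ordering) — sizes at which every recovered quantity's
sampling error is well inside its tolerance. All randomness flows through
`numpy.random.default_rng` seeds; every generator output is a pure function
of (config, seed). Quantile envelopes use `numpy.quantile` defaults; envelope
membership is inclusive on both ends; peak detection uses `scipy.signal.
find_peaks` with inclusive height, which is what makes the noiseless
stereotyped-train case exact. Degenerate inputs fail loudly (non-monotone
time, overlapping labels, budget not summing to 1) or are flagged (zero
static vector, gimbal-adjacent heading, constant-feature envelopes).

## Known limitations

* The threshold-tree accuracy ceiling is set by the envelope rejection rate:
  with four roughly independent features at [0.025, 0.975] quantiles, ~10–20 %
  of own-class blocks fall outside at least one envelope and end up
  unclassified. That is the price of the transparent classifier; the
  classical min/max rule trades it against outlier sensitivity.
* The smoother's random-walk offset model is a convenience prior; it covers
  systematic drift only through the matched diffusion rate, and its σ is
  calibrated only to the extent that prior holds.
* Speed calibration assumes one linear VeDBA–speed mapping across behaviours;
  gait differences (grazing shuffle vs trot) bend that relation in real data.
* The head-mounted and collar-mounted streams run through the same pipeline;
  no cross-placement transfer of trained trees is attempted.
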