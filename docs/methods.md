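# Methods

This note documents the models implemented in `aioa`, the defaults chosen
where the design was genuinely open, and what the synthetic-data test
harness does and does not demonstrate.

## Problem setting

A microcontroller-class bio-logger (tens of kB of program memory, battery
good for ~2 h of continuous video but ~20 h of low-cost sensing) should
record video only during a target behaviour.  The on-board classifier is a
single binary decision tree over window features of low-cost sensors:
1-s windows of 25 Hz acceleration magnitude for fast body-movement
behaviours (gull foraging), or sliding 10-min windows of one-per-minute GPS
fixes for movement modes (shearwater area-restricted search, ARS).  Most of
the memory a deployed tree costs is the feature-extraction code, so the
classifier's footprint is governed by *which distinct features* its nodes
reference.

## Feature definitions

Acceleration windows (25 magnitude samples): mean, population variance and
standard deviation, min, max, range, RMS, crest factor (max/RMS, 0 for an
all-zero window), population non-excess kurtosis m4/m2² and skewness
m3/m2^1.5 (both defined as 0 on a constant window), mean-crossing count
(consecutive pairs strictly straddling the window mean), and mean absolute
first difference.  No bias corrections are applied: population moments are
the cheapest to mirror exactly in generated MCU code, and the scalar Python
extractors are written loop-for-loop identical to the C templates so the
differential test can demand exact agreement.

GPS windows (10 fixes, nominal 60 s spacing): haversine path length and net
displacement (mean Earth radius 6 371 000 m; windows span ≤ ~10 km so a
planar treatment of residuals is adequate), average speed over the nominal
600 s window, maximum leg speed, straightness (net/path, defined 1 for a
zero-length path), and axis statistics after a rotation search: the
mean-centred (lon, lat) pairs are rotated clockwise by the candidate angles
0°, 22.5°, 45°, 67.5°, 90° and the angle maximising longitude variance is
kept.  "Primary" statistics (variance, mean-cross) are computed on the
rotated longitude axis, "secondary" on the perpendicular axis; the chosen
angle always satisfies primary ≥ secondary variance.  0° is included among
the candidates so an already-optimal orientation is representable.  Speeds
use the nominal fix interval rather than per-fix timestamps — at 60 s
cadence the difference is negligible and the on-device code has no
timestamp arithmetic.

## Budgeted tree induction

Trees are grown CART-style with Gini impurity, minimum leaf size 5, no
depth cap, and `mtry = ceil(sqrt(p))` candidate features per node — the
random-forest conventions, since the stopping conditions and `mtry` for
this application are not prescribed anywhere.  The one non-standard
ingredient is the candidate draw: features enter the per-node comparison
set by sequential weighted sampling without replacement with probability
proportional to 1/size_bytes (renormalising after each draw).  Split
thresholds are midpoints between adjacent distinct sorted values; values
equal to a threshold descend left.  Exact ties in impurity decrease break
toward the cheaper feature, then the lexicographically earlier name, so a
fixed seed reproduces a build bit-for-bit.

Footprint estimation counts each distinct feature's byte cost once (the
extractor is shared code) plus an optional per-node overhead, default 0 —
the node logic itself is a few comparison instructions and the accounting
convention that matters for the budget is the feature code.  Batch
generation grows trees until `n_trees` fall under the byte threshold (or a
20×`n_trees` attempt cap is reached, in which case the budget is reported
infeasible along with the smallest footprint seen).  Each retained tree's
accuracy is estimated by stratified k-fold cross-validation (default 5
folds; folds are split with scikit-learn, the fold models are grown by this
package's own induction).  Selection takes the highest estimated accuracy,
ties to the smaller footprint; the full (size, accuracy) Pareto frontier is
also exposed.

Only the kurtosis byte cost (680 B) in the default catalogue is anchored to
a published MCU implementation; the other defaults are order-of-magnitude
placeholders reflecting relative code complexity, flagged
`from_source: false` in the shipped catalogue, and fully user-configurable.
Catalogue costs only steer sampling probabilities, so conclusions about
*relative* footprint shrinkage are insensitive to their exact values.

## Robustness

Rotation invariance is obtained structurally: features see only ‖a‖, which
is exactly invariant under any proper rotation of the device.  The
`rotation_experiment` harness quantifies the alternative strategies — raw
per-axis features and raw features trained with randomly-rotated copies of
the training data — across a grid of test-time device rotations.

Noise augmentation copies every training window scaled by one factor drawn
from Uniform(1 − λ, 1 + λ) (λ = 0.2 is the field setting; a Gaussian
factor is available via configuration).  One factor per window, not per
sample: loose attachment rescales a whole movement bout, not individual
samples.  Each pass exactly doubles the training set and never touches
labels; λ ≥ 1 triggers a warning because factors may reach zero.

## Trigger runtime and battery model

The gull machine: 5 consecutive flying windows arm the trigger; while
armed, a single foraging detection starts the camera (the dip is only
sporadically detectable, so waiting for consecutive foraging detections
would miss it); 10 consecutive stationary windows disarm.  A foraging
detection while armed resets the stationary counter — foraging implies
activity, so it should not count toward the timeout.  The ARS machine fires
after k = 2 consecutive ARS detections and resets its counter after
firing.  Camera requests during an active recording are ignored (the
hardware cannot overlap recordings); the start-up delay defaults to 3 s
(the hardware exhibits a 2–3 s power-on delay) and video durations default to 60 s (acceleration
pipeline) and 300 s (GPS pipeline).  The periodic baseline activates at
t = 0 and every interval thereafter (15 min / 30 min defaults).

Battery drain is linear and two-rate, calibrated so a full charge lasts
exactly 20 h sensing-only and 2 h under continuous video: base rate 1/20
charge·h⁻¹ plus (1/2 − 1/20) charge·h⁻¹ while the camera is on.  Charge is
computed from the closed form at every step (no incremental accumulation),
so the endpoint runtimes are exact to floating-point and the battery trace
is monotone by construction.  The simulator halts at the exact within-window
exhaustion time and truncates any recording in progress.

## Exact-test statistics

Methods are compared on 2×2 video-count tables with the two-sided Fisher
exact test.  The p-value defaults to the minimum-likelihood rule (sum of
null hypergeometric probabilities ≤ the observed one, via scipy); the
central rule (2·min(tails), capped at 1) is exposed because reference
software supports both.  The reported effect size is the conditional
maximum-likelihood odds ratio: the noncentrality ψ of Fisher's noncentral
hypergeometric distribution equating the conditional expectation of the
first cell to its observed value.  Two solver conventions are provided:

* `reference` (default) — a faithful port of the root-finder used by R's
  `fisher.test`/`exact2x2` (Brent's *zeroin*, tolerance eps^0.25, solved on
  a reciprocal noncentrality scale).  This reproduces the estimates printed
  by that software digit for digit, which is what published values are.
* `tight` — the same score equation solved to relative tolerance ~1e-12.

The two agree to about four significant digits; the difference is purely
the reference solver's stopping rule.  Confidence intervals invert the
exact conditional test (central), via scipy's `odds_ratio`; other software
can differ in the last digits of the upper limit.  Degenerate margins make
the odds ratio unidentifiable and it is reported as NaN.  Boundary tables
(observed count at the edge of the support) return 0 or ∞, matching the
reference convention.

## Synthetic data

The generators supply the statistical *structure* the method assumes, not
the waveforms of real birds.  Acceleration: stationary is a 1 g gravity
vector plus 0.02 g noise; flying adds a 4 Hz, 1 g flapping sinusoid with
0.08 g noise; foraging keeps the flapping background but raises the noise
floor to 0.3 g and injects ±(1.5–3) g spikes at 30 % sample probability —
a dip/surge signature that makes range, max and variance discriminative.
Schedules are bout-structured (rest, then a flight bout with embedded
foraging dips preceded by ≥ 6 s of flight so the arming logic is
exercised); per-cycle stationary durations are steered so realized class
shares stay within one percentage point of the targets (defaults 88.4 % /
9.96 % / 1.6 %) on long traces.  GPS: a correlated random walk with
per-regime speed and turning-angle spread (transit 10 m s⁻¹, heading sd
0.05 rad min⁻¹; ARS 4 m s⁻¹, sd 1.8; stationary drift), regime mix steered
to 23.2 % ARS / 34.4 % transit / 42.4 % stationary.

What passing tests show: the pipeline is internally correct (windowing,
features, induction, budget accounting, triggers, battery, statistics) and
the design's qualitative claims hold under the assumed structure —
cost-weighting shrinks footprints at equal accuracy, magnitude features are
rotation-invariant, triggered recording beats periodic sampling on video
precision.  What they do not show: performance on real birds, whose
behaviours are less separable, whose labels are noisier, and whose foraging
signatures vary between individuals; the field window-level metrics
(precision 0.27/recall 0.56 for gulls) are therefore not reproduced here,
and in-silico precision figures are optimistic by construction.

## Problem sizes and runtime

Default experiment sizes were chosen to make every stochastic comparison
statistically stable yet quick on a single CPU: 15-min training traces
(~950 windows) for induction experiments; 50 paired seeds for the
cost-vs-uniform weighting comparison; 20 independent 2-h synthetic
deployments (training on a separate 20-min trace each) for the
triggered-vs-periodic comparison; 5-angle rotation grids.  The full test
suite runs in well under a minute; `scripts/acceptance.py` in ~15 s.

## Known limitations

* Byte costs other than kurtosis are placeholders; absolute footprints are
  illustrative, relative comparisons are the supported conclusion.
* The GPS pipeline treats residual lon/lat as planar and ignores fix
  dropout; no fix-acquisition failure model.
* The simulator has no storage limits, no water-immersion gating, and does
  not model re-triggering behaviour during recordings beyond ignoring
  requests.
* Ensemble inference is deliberately out of scope: the deployed artifact is
  a single tree.
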