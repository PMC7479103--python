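# Methods

`nervekit` quantifies three kinds of measurements made on the peripheral
nervous system of *Drosophila* larvae: rule-based locomotion ethograms from
tracker-style posture tables, nerve conduction velocity from dual-electrode
extracellular recordings, and axon morphometry from EM cross-section
annotations. Because the measurements come from live animals and no public
dataset accompanies them, the package ships a synthetic-data module
(`nervekit.simkit`) whose generators carry known ground truth, so every
downstream estimator has a parameter-recovery test.

## Ethogram model

Posture per frame is a centroid, a K-point head→tail spine (K = 5 by
default), the bending angle γ at the spine midpoint (180° = straight,
deviation = |180° − γ|), the silhouette area, and the spine length. The four
behavior classes are threshold rules:

| behavior  | rule | minimum duration |
|-----------|------|------------------|
| stop      | centroid step < `move_eps` every frame | 5 frames |
| head bend | deviation ≥ 20° | 5 frames |
| turn      | motionless run ≥ 4 frames containing a ≥ 20° bend, then ≥ 20 moving frames whose mean heading differs ≥ 20° from the pre-stop heading | — |
| coil      | head–tail distance ≤ 15% of spine length | 1 frame |

Choices the rules leave open, fixed here and configurable in
`EthogramParams`:

* **"No movement"** is a per-frame centroid step below 5% of the resting
  spine length. The criterion is scale-free and robust to tracker pixel
  noise. A run of m sub-threshold steps is counted as m+1 motionless frames
  (the larva holds one position across those frames).
* **Coil threshold** is 15% of spine length; a literal zero head–tail
  distance never occurs in sampled data.
* **Heading** is the angle of the centroid displacement box-smoothed over 3
  frames; the pre-stop heading is the circular mean over up to 10 moving
  steps before the stop, the post-stop heading over the first 20 steps after
  it.
* The ≥ 20° bend may occur anywhere within the turn's motionless run.
* An optional moving average over the bending series before thresholding is
  available (`smooth_bend_frames`) and off by default.

## Locomotion statistics

Accumulated distance is the centroid path length per minute (cm/min);
distance to origin is the first-to-last-frame displacement per minute (the
final displacement, not the maximum — both readings of the definition are
defensible; this one is implemented and configurable by post-processing).
Stops and turns are counted per minute, head bends per 10 s. Coiling is the
percentage of coiled frames pooled across tracks (movie-level pooling), and
the clip histogram classifies non-overlapping 300-frame windows, anchored at
frame 0 with partial tails dropped, into {0, 1–30, 31–60, >60} coiled
frames.

Peristalsis frequency is measured from the body-size series ("body size" is
taken as silhouette area; spine length is a possible alternative the
data model also carries). The series is linearly detrended; peaks with
prominence ≥ 25% of the series IQR and separation ≥ 0.3 s count as
contraction waves. Both constants are artifact choices validated on
synthetic sinusoids: a pure f Hz oscillation is recovered within 1/duration
for f in 0.5–1.5 Hz at 10 fps. Efficacy is accumulated distance (cm) per
wave; a flat series yields 0 cycles/s and a flagged, undefined efficacy.

Group comparisons are gated by normality: Shapiro–Wilk at α = 0.05 on both
groups selects Student's t test, otherwise the Wilcoxon rank-sum test; the
chosen test is reported with the two-tailed p value.

## Conduction velocity

The estimator implements the distance/delay-quotient procedure: v = Δd/Δt
with Δd the electrode separation (mm) and Δt the per-spike arrival delay
(ms), so v is in m/s. Spike times use the positive-peak convention.

* **Detection**: the trace is boxcar-smoothed over 0.25 ms (a crude matched
  filter for a 2-ms biphasic spike) and thresholded at 5 robust (MAD-based)
  standard deviations; detections are realigned to the raw-trace extremum
  and separated by a 2-ms refractory period. The pre-filter is what lets a
  unit at signal-to-noise 5 reach ≥ 95% recall while keeping the
  false-positive rate of pure noise near zero; raw-trace thresholding cannot
  do both.
* **Sorting**: units are separated by peak amplitude with a deterministic
  1-D k-means (quantile initialization, order-invariant labels). This is a
  stand-in for interactive spike sorting in acquisition software and is
  validated only against the simulator's ground truth.
* **Matching**: candidate cross-electrode pairs with 0 < Δt ≤ `max_delay`
  are collected; the modal delay of the candidate set (0.5-ms correlogram
  bins) anchors a greedy assignment by |Δt − mode|, each spike used at most
  once. Anchoring matters because the propagation delay (≈ 10–25 ms here)
  can exceed a unit's minimum inter-spike interval; greedy smallest-Δt
  matching would then systematically cross-pair consecutive spikes.
  `max_delay` defaults to 2Δd / 0.05 m/s so that even strongly slowed nerves
  stay inside the search window.
* **Averaging**: per-pair velocities are pruned by an iterated two-sided
  Grubbs test (α = 0.05, one point per iteration, capped at 20% of the
  sample since the procedure's iteration policy is not standardized), and
  the recording mean is taken over the survivors. Group statistics operate
  on recording means, not pooled spikes.

## Axon morphometry

Radii are circular-equivalent, r = √(area/π), from measured surface areas
(areas are less sensitive to fixation-induced shape artifacts than
diameters). Nerves with fewer than 76 or more than 82 axons are excluded
before statistics. The wrapping index is
w_i = 100 × (individually wrapped axons + wrapped fascicles)/(total axons);
axons enclosed by no glial unit form a single naked unit that contributes
zero to the numerator (the formula is silent on them). Mean radii are pooled
over all axons of the retained nerves rather than averaged per nerve. Size
histograms use half-open area bins of 0.04 µm² by default (fully
configurable; reported bin conventions in the literature are not always
dimensionally unambiguous, so the width is never asserted as a fixed
constant), and per-bin relative change is (n_t − n_c)/n_c, undefined (NaN)
for bins empty in the control.

## Synthetic-data generators

All randomness derives from one integer seed per generator call
(`numpy` `SeedSequence` spawning per larva); with the seed fixed every
generator is bit-reproducible. No distributional description of larval
kinematics accompanies the original measurements, so all simulator
distributions are artifact choices, documented here.

**Tracks.** Bout scheduling is a discrete-time renewal process at frame
resolution: from crawling, each eligible frame enters a bout kind with its
per-frame rate; dwells are minimum + Poisson (the turn's stop phase is fixed
at 4 frames); every bout is followed by a forced crawl refractory (12 frames
after stops and bends, 24 after turns, 5 after coils) and scheduling starts
after a 12-frame warm-up. The expected fraction of eligible frames is
φ = 1/(1 + Σ_k r_k(d_k + R_k)), which gives closed-form expected bout counts
(`expected_bout_statistics`) and an exact calibration of the coil entry rate
for a requested coiled-frame fraction. Kinematics: crawl speed 3 mm/s
(spine length 4 mm) modulated ±20% by the peristaltic phase, heading noise
1.5°/frame, reflective walls in a 200 × 200 mm arena; stops and turn-stops
freeze the centroid exactly; bend deviations are drawn strictly above the
20° threshold; the coil posture lays the spine on a closed circle so the
head coincides with the tail tip (generated geometrically — the classifier
only tests head–tail proximity). Turns rotate the heading by 45–120° and
are only scheduled when the arena leaves room for the post-turn straight
run, so every logged bout is geometrically detectable: the classifiers'
precision and recall against the log are exactly 1. The body area
oscillates ±8% at the peristalsis frequency while the larva locomotes and
is held during stationary or coiled frames.

Deliberate idealizations, hence what passing recovery tests do *not* show
about real data: coil events are single-frame postural flags (real coils
persist for several frames, which would overdisperse coiled-frame counts
relative to a binomial and blur the bend/coil boundary); bouts never
overlap; posture noise never crosses classifier thresholds; there are no
tracking errors, collisions, or missing frames. The default crawl speed is
set so that crawling steps stay above the movement threshold — a generator
consistency requirement, flagged with a warning when violated.

**Recordings.** Each of `n_units` units fires as a Poisson process (default
5 Hz/unit, thinned to a 5-ms minimum ISI so templates do not overlap within
a unit); spikes are a fixed 2-ms biphasic template scaled by a unit-specific
amplitude (1, 2, …) — amplitude separation is the minimal model that makes
sorting testable. Electrode 2 repeats each spike after Δd/v plus Gaussian
jitter; both traces carry white Gaussian noise. Spike times are quantized
to the 20-kHz sample grid, so with zero jitter and a delay that is an
integer number of samples the downstream estimate equals the generating
velocity exactly. Every electrode-1 spike has exactly one electrode-2
counterpart.

**Nerves.** Axon radii are lognormal (default median 0.194 µm, log-SD 0.55,
spanning ≈ 0.05–1 µm); areas are πr². A configured fraction of axons is
individually wrapped, the rest fill the requested number of wrapped
fascicles (each at least one axon), or a single naked unit when no
fascicles are requested. The generator returns the ground-truth wrapping
index, which the estimator must reproduce exactly.

## Problem sizes and numerical conventions

Recovery tests run at the scale the measurements suggest: 3-min tracks at
10 fps, 10–50 larvae for behavioral recovery, 12–60 s recordings at 20 kHz,
and 27 nerves of ~80 axons for the radius recovery (the per-condition scale
of the morphometric dataset). Coordinates are mm, origin at the arena's
lower-left corner, y up, frame indices 0-based; CSV floats carry 6
significant digits, and velocity means are reported to 3 decimals.
Head/tail orientation in feature extraction follows net motion over a
10-frame window with ties keeping the previous assignment. Degenerate
inputs (constant statistical groups, single-frame tracks, empty nerves,
flat body-size series) raise typed errors or return flagged values rather
than guessing.

## Known limitations

The behavioral simulator is a scheduling model, not a biomechanical one: it
reproduces the classifiers' operational definitions, not larval dynamics.
Spike sorting is 1-D amplitude clustering and will not separate units of
similar amplitude. The feature extractor assumes one larva per frame and
does not resolve collisions. None of the printed group-level animal results
are re-derivable from data shipped here; they enter only as generator
calibration targets and worked-example arithmetic.
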