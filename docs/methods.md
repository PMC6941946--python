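# Methods

`wormpulse` models the software half of an LED-based optogenetics rig for
*C. elegans*: schedules that drive the light, image analysis that turns
worm videos into posture traces and contraction events, survival analysis
for the downstream aldicarb assay, and a simulator that generates
synthetic videos with ground truth so that every analysis stage can be
validated quantitatively without recorded data. This note records the
models, the defaults and why, the numerical choices, and what the
synthetic validation does and does not establish.

## Light schedules

A schedule is a sorted set of half-open `[t_on, t_off)` intervals on an
integer tick grid (default tick 5 ms, the exposure resolution of the
relay-driven LED hardware this format targets). Integer ticks make total
on-time exact — the hour-long exercise regimen (10 ms pulses at 20 Hz for
the first 30 s of every minute) expands to 36,000 pulses and exactly
360 s of light with no float drift. Conventions:

* pulses start at the beginning of each burst window; a pulse that would
  extend past the window (or the schedule end) is clipped, not dropped;
* a burst regimen whose total duration is not a multiple of the burst
  period simply truncates the final burst;
* interval protocols (e.g. 1 s on / 8 s off) start at t = 0 and clip a
  final partial exposure;
* requested times are quantized to the nearest tick; a pulse that would
  quantize to zero width is an error.

The half-open convention makes adjacency unambiguous: with zero off-time
consecutive exposures abut into continuous light, and `light_state(t_off)`
is off.

Schedules export to a two-column CSV (`t_on_s,t_off_s`, 3-decimal fixed
format) with a leading `#` comment carrying the tick resolution and total
duration so a file round-trips losslessly.

## Photometry

Power-meter readings are calibrated at 633 nm; under the ~450 nm LED they
are multiplied by the manufacturer's correction factor (default 3.29) and
divided by the area of the meter's circular sensor (default diameter
9 mm, treated as a flat disk) to give average intensity in mW/mm².
Values are kept at full precision internally and rounded only for
display.

## Segmentation

**Solid media** (one dark crawling worm on a bright field): the frame is
min–max normalized to [0, 1], so results are invariant to additive
intensity offsets. Starting from the global Otsu threshold, the level is
decremented in steps of 0.01 until the largest dark component's area (a)
lies in a plausible-worm band (default 200–20,000 px at 4×-like
magnification) and (b) has changed by less than 5% over two consecutive
steps — an algorithmic stand-in for "decrement until the silhouette looks
well defined". A minimum-area cutoff then grows from 10 px in 10 px steps
(capped at half the largest component) until one component remains;
debris smaller than the worm is removed, while multiple comparably sized
survivors raise an "ambiguous scene" error rather than guessing.

**Liquid media** (a grid of wells, one swimming worm each): the frame is
cropped into wells from known grid geometry (half-open windows, row-major
order; re-tiling the crops reproduces the frame pixel-exactly). The
background of each well is the per-pixel temporal median of its frames —
exact wherever the worm occupies a pixel in under half the frames. Each
frame is background-subtracted, median-filtered (3×3), inverted so the
worm is the bright tail of the residual distribution (automatic via the
skewness sign, overridable), and thresholded at the 98.75th percentile of
the processed well's pixel values. The percentile is computed per well
per frame. The largest connected component is kept; a largest component
below 30 px is treated as an unoccupied well (the percentile threshold
always selects *some* pixels, so an area floor is what distinguishes
noise from a worm). Empty wells are a signal, not an error.

Components and skeleton neighborhoods use 8-connectivity; coordinates
are (row, col), 0-based, top-left origin. Largest-component ties break to
the topmost-then-leftmost centroid for determinism.

**Skeletons.** Masks are thinned to a 1-px topological skeleton. Side
branches shorter than 10% of the skeleton's length are pruned
iteratively; if more than two endpoints (pixels with exactly one
8-neighbor) survive, the head/tail pair is the one maximizing geodesic
distance along the skeleton. Degenerate skeletons (loops, near-disks)
fall back to the Euclidean-farthest pixel pair; a one-pixel skeleton
reports that pixel twice, and downstream metrics that need two distinct
endpoints mark the frame invalid instead of failing.

## Posture metrics

**Eccentricity** is that of the ellipse sharing the region's second
central moments: focal distance over major-axis length,
`sqrt(1 − λ₂/λ₁)` with λ the moment eigenvalues. Moments use the discrete
pixel-center model with no continuous per-pixel correction; by symmetry a
rasterized disk gives exactly 0, and an ideal zero-width straight segment
(continuous moments, transverse moment zero) gives exactly 1. The moment
ellipse is fitted to the **filled mask by default**. The alternative —
fitting the skeleton — is available (`eccentricity_on="skeleton"`), but
pixel-level skeleton jitter under imaging noise widens the trace enough
that undulation minima spuriously cross a mean − 1σ threshold; the filled
silhouette tracks contraction with the same trend and is far more stable,
so it is the default.

**HTOL** (head-to-tail over length) is the endpoint Euclidean distance
divided by the geodesic skeleton path length between the endpoints
(axial steps 1, diagonal steps √2), clipped into (0, 1]. The √2
chain-code convention is exact for straight and diagonal paths but
systematically overestimates curved arc lengths by up to ~5% (≈5.2%
asymptotically on a circle) — a known raster limitation; HTOL values on
strongly curved postures carry that bias.

**Traces.** `compute_trace` segments every frame, computes eccentricity,
HTOL, length and centroid, and flags failed frames (no worm, empty well,
degenerate skeleton) as invalid rather than aborting. Invalid frames are
carried as gaps and never interpolated by default — interpolation would
fabricate contraction shapes. The light state is sampled at each frame's
midpoint time. Frame timestamps are `index / frame_rate` (constant-rate
capture).

## Contraction events and habituation

The contraction threshold is one sample standard deviation (n−1
denominator, appropriate for small control cohorts) below the mean of all
valid eccentricity samples pooled across control traces; for the control
statistics reported for crawling animals (mean 0.978, SD 0.022) this
gives 0.956. The threshold is always derived from control data or
supplied explicitly — never hard-coded.

Events are maximal runs of valid sub-threshold frames. Runs separated by
less than `merge_window` (default 1 s) are merged whether the gap holds
supra-threshold or invalid frames, so brief segmentation dropouts or
single-frame recoveries do not split one physical contraction; the event
ends where the trace re-crosses the threshold for at least the merge
window. The trough is the run minimum (earliest frame on ties) and the
magnitude is the drop from the control mean to the trough.

An event is attributed to a light stimulus if its onset falls within
`max_latency` (default 0.1 s — the platform's observed sub-100 ms
response) after the light onset, or its trough falls within
`response_window` (default 3 s, the observed contraction-relaxation span)
after it. The earliest eligible stimulus wins and each event attaches to
at most one stimulus; latency is the onset delay, clipped at zero for
events whose measured onset precedes the light by a frame. Habituation is
summarized as the least-squares slope of contraction magnitude against
stimulus index; a negative slope indicates declining responses. When
several events attach to one stimulus, the earliest — the light-locked
evoked response — provides the magnitude: later events inside the
response window are typically spontaneous behavior, not the evoked
contraction.

Chance-level coupling is estimated by circularly shifting the schedule:
shifting destroys true light–event coupling while preserving the
schedule's on/off statistics, so the mean attributed fraction over
shifted schedules is the coincidence rate expected from timing alone.

## Aldicarb paralysis analysis

Fraction-moving curves evaluate, at each multiple of the observation
interval (default 10 min), the percentage of worms whose paralysis time
exceeds that time: right-continuous steps from 100% to 0 (the assay runs
until every animal is paralyzed; censoring is supported in the data model
but defaults to none). Replicates are averaged pointwise and unweighted;
pooled analysis is available separately. The two-group comparison is the
standard logrank test with the hypergeometric tie correction — mandatory
here because interval observation records many animals at the same
10-minute mark — with a two-sided p-value from χ² with 1 df. The test
statistic is delegated to `lifelines`; the test suite checks it against
an independently hand-coded per-event-time table computation and
verifies type-I calibration (3–7% rejections at α = 0.05 over 1,000 null
assays with 20–25 worms per group and 10-min rounding).

## The simulator

The synthetic worm is a fixed-arc-length midline with tangent angle

    θ(s) = heading + α·sin(2π·n_waves·s/L + phase) + curl·(s/L − ½)

rendered as a tapered stadium tube (elliptic width profile, blunt
0.75 px tips) over a uniform background with seeded Gaussian noise.
Key conventions:

* `n_waves` defaults to 2.0 — an integer wave count makes the undulation
  turning-neutral, so total body turning equals `curl` exactly and the
  rendered eccentricity decreases strictly monotonically with curl over
  the working range 0–4.5 rad (verified on 0.5-rad sweeps across phases).
* Undulation amplitudes are shallow (swim preset: 2.5 px on a 54 px
  body; crawl: 5 px on 120 px) so the baseline eccentricity sits near
  the straight-worm regime that the mean − 1σ threshold convention was
  designed around.
* The swim-preset body covers ~1% of a 150×150 well — below the 1.25% of
  pixels kept by the default 98.75th-percentile threshold, so the
  silhouette segments whole.
* Contrast: worm 35% darker than a 0.6 background; noise SD 0.02 (8-bit
  scale ≈ 5 gray levels).
* Worms wander as a confined random walk (1.5 px/frame position SD,
  0.08 rad/frame heading SD). This matters for analysis validity: the
  temporal-median background is only exact where per-pixel occupancy
  stays under 50%, which a sessile worm would violate.

A responsive ("ATR-fed") worm answers the k-th schedule interval with a
curl transient: latency 0.05 s (the platform's observed <100 ms), linear
rise over 0.1 s to a peak of `curl_gain · habituation_factor^k` (defaults
4.0 rad and 0.8), and linear relaxation to baseline over the remainder of
3 s. Unresponsive worms ignore the light entirely. Both kinds produce
spontaneous bends — curl transients of comparable shape and random sign,
magnitude 60–100% of `curl_gain` — as a seeded Poisson process at
1/minute, mirroring the occasional light-uncorrelated dips real control
animals show; these bends are also what gives a control cohort a
realistic eccentricity SD (without them the pooled SD collapses to the
undulation-phase jitter and a mean − 1σ threshold sits inside the normal
oscillation band). Contraction magnitudes are a synthetic convention —
no quantitative reference magnitude exists — so the defaults are set to
carry dips well past a mean − 1σ threshold.

Determinism: every output is a pure function of (parameters, seed).
Multi-well plates derive one random substream per well from
`(seed, well_index)`, so adding a worm to one well never perturbs
another.

## Validation studies (what passing shows, and does not)

The acceptance suite runs four simulation studies at desk scale:

* **End-to-end recovery** — ten 20 s liquid-mode videos at 10 fps, two
  1 s pulses each (the 1 s on / 8 s off geometry), full segmentation →
  trace → event pipeline; the control baseline comes from five 60 s
  unresponsive cohort videos through the same pipeline. Requires
  sensitivity ≥ 0.95, FDR ≤ 0.05, and mean absolute error of the
  measured response latency ≤ 1 frame.
* **Chance-level control** — ten unresponsive videos; the attributed
  event count must stay within one-sided binomial sampling range (95th
  percentile) of the circular-shift chance rate. The binomial allowance
  is necessary because the expected attributed rate of genuinely
  uncoupled events *equals* the chance rate; a strict inequality would
  fail half the time by construction.
* **Habituation** — 100 seeded simulations of 5 pulses (1 s on / 8 s
  off) with habituation factor 0.8, posture and event calling on the
  simulator's ground-truth masks (the segmentation stage is already
  covered above); ≥ 95% must recover a negative magnitude-vs-stimulus
  slope. Five pulses keeps every stimulus's true response above the
  detection threshold (factor 0.8⁴ of the initial curl), so the slope is
  estimated from genuinely evoked magnitudes.
* **Logrank calibration** — oracle equivalence plus 1,000 null assays.

Problem sizes (video lengths, cohort sizes, run counts) are the package's
validation conventions, chosen to exercise every stage at meaningful
statistical resolution while keeping the default test run fast.

Passing these studies shows the pipeline recovers what the simulator
injects under the simulator's assumptions. Real recordings differ in
ways the simulator does not emulate: non-uniform illumination and
vignetting, out-of-focus and partially submerged postures, self-occluding
coils and omega turns, bacterial debris, stage drift, and worms leaving
the field of view. Segmentation quality on real video therefore needs
its own spot checks; the analysis stages downstream of a correct mask
(posture metrics, event calling, survival statistics) transfer directly.

## Known limitations

* Chain-code arc lengths (worm length, HTOL denominator) are biased
  ~+5% on curved paths; lengths are comparable across frames but not
  calibrated against curved ground truth.
* Eccentricity from the moment ellipse saturates near 1 for straight
  worms; it cannot distinguish stretching from straightening.
* One worm per frame/well: no multi-worm tracking, no identity across
  occlusions.
* The simulator's contraction is a pure curvature transient; real
  contractions also shorten the body, which the fixed-arc-length model
  ignores.
* AVI input requires an imageio backend with video support; TIFF stacks
  are the first-class format.
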