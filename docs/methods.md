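# Methods

## Problem and system model

`bedwatch` models a contactless night-time bed-exit monitor for care
settings: a ceiling-mounted (nadir) time-of-flight depth camera over each
bed, paired with an ultra-wideband impulse radar (UWB-IR) that senses
presence and respiration through bedding. The goal is to alert caregivers
when a resident leaves the bed area at night — the operational proxy for
wandering risk — while almost never alarming on the many benign night-time
episodes (sitting up, rolling over, sitting on the bed edge, a roommate or
caregiver passing by, items left in the room).

The processing chain is deliberately simple and threshold-based:

1. **Depth → height.** The sensor reports, per pixel, the perpendicular
   distance (mm) from the sensor plane to the first surface below. With a
   nadir mount at height *H*, height above the floor is *h = H − d*,
   clipped to [0, *H*]. Floor-plane coordinates follow the pinhole model
   *x = (u − c_u)·d/f_u*, *y = (v − c_v)·d/f_v*, with focal lengths
   derived from the field of view (defaults 70.6° × 60°, 512 × 424 px,
   typical of the consumer ToF class this emulates). Zero depth marks an
   invalid return and is carried as a mask, never as height 0.
2. **Virtual fence.** Three nested polygons in floor coordinates: the
   *bed zone* (mattress), the *leave zone* (a buffer the resident may
   occupy) and the *boundary zone* (outer ring). Point-in-polygon tests
   use inclusive boundary semantics with inner-zone precedence
   (BED > LEAVE > BOUNDARY > OUTSIDE), so a point exactly on a shared
   edge stays "in bed" — the conservative direction for a monitor.
3. **Segmentation and tracking.** Foreground is anything more than
   100 mm above a calibration background (median of 50 empty-room
   frames; non-adaptive so a motionless sleeper is never absorbed).
   8-connected components with a true footprint below 0.05 m² are
   discarded. Tracks are formed by greedy nearest-centroid association
   with a 500 mm gate per 0.1 s frame interval; tracks unmatched for 3 s
   close. Greedy (rather than optimal) assignment is adequate at the
   one-to-two-person densities of a single-bed scene and is a documented
   limitation beyond that.
4. **Posture decision tree.** Per frame, from the centroid zone and blob
   height: in bed, rise above the mattress ≤ 400 mm → LYING (→ SLEEPING
   after 60 s with motion ≤ 10 mm), ≤ 750 mm → SITTING (→
   SITTING_ON_EDGE within 200 mm of the bed rim), otherwise STANDING if
   the crown exceeds 1100 mm above the floor; in the leave zone STANDING
   or BED_EXITING (when approaching the outer rim); in the boundary zone
   BED_EXITING; EMPTY/OTHER as fallbacks. The tier constants are
   anthropometric choices exposed in `ClassifierThresholds`.
5. **Alarm state machine.** GREEN while safely in bed; YELLOW once an
   edge condition (sitting on the edge, standing within the edge band)
   persists ≥ 2 s — the debounce is what makes fast oscillation across
   the rim alarm-free; RED at the resident track's LEAVE → BOUNDARY
   crossing, latched until the resident returns to bed or an operator
   resets; GREY when the fused presence channel agrees the bed is empty
   and no RED is latched.
6. **Radar channel.** The slow-time trace is detrended, band-passed to
   the physiologic band 0.1–0.7 Hz (6–42 breaths/min), and a Welch
   periodogram (10 s Hann segments, 50% overlap, zero-padded) yields the
   rate as the in-band peak × 60 with parabolic refinement. The rate is
   reported only when the peak clears a 6 dB peak-over-median in-band
   gate; gross motion is the RMS of the > 0.8 Hz residual against an
   absolute threshold (3.0 amplitude units, ≈3× the modelled noise
   floor). In-bed presence is the OR of depth and radar channels;
   "empty" requires both negative for ≥ 10 s. Averaging across Welch
   segments is what keeps the white-noise false-presence rate low: the
   peak-to-median statistic of an averaged periodogram has much lighter
   tails than a raw periodogram's.
7. **Events and evaluation.** One BED_EXIT per maximal RED episode,
   episodes closer than 30 s merged; ASSISTED when a second concurrent
   track that never dwelt in the bed zone is present within ±30 s of the
   exit start. Detected exits match truth exits when start times agree
   within 10 s (greedy, one-to-one, time-ordered — verified against an
   exhaustive assignment oracle); true non-exit episodes with no
   detection inside count as true negatives. Metrics are event-level
   accuracy, precision, sensitivity and specificity, rounded half-up to
   one decimal percent.

## What the resident-track gate does

RED can only be raised by a track that has spent ≥ 1 s with its centroid
in the bed zone. This single rule is what makes the two classic
false-alarm scenarios benign: a caregiver entering from the door and a
roommate passing through the outer zones never acquire bed history, so
their LEAVE → BOUNDARY crossings are ignored. The cost is symmetric: if
the monitored resident's track were lost and re-acquired outside the bed,
the exit would be missed. The simulator keeps persons ≥ 0.6 m apart so
tracks never merge; real overlapping bodies (a caregiver leaning over the
bed) would merge into one blob and are treated as one observation — a
known limitation.

## The synthetic scene generator

The simulator is the package's data source and its defaults are the study
conditions, not tuning knobs:

- **Geometry.** Mount height 2500 mm (valid band 2300–2700, warned
  outside), 512 × 424 px, 10 fps processing rate, 1 fps archival
  silhouettes. A 2.0 × 0.9 m bed at the nadir with a 500 mm mattress
  surface; leave zone extending 0.55 m past the bed toward the exit
  side; boundary ring out to ±1.6 m × 1.35 m, inside the sensor
  footprint.
- **Bodies.** Standing/walking persons are vertical cylinders (radius
  210 mm) of the scripted stature, drawn uniformly from 1390–1730 mm
  (the recruited-population range the system targets); seated torsos are
  cylinders topping out at 38% of stature above the mattress; lying
  bodies are boxes 250 mm proud of the mattress (80 mm for the
  under-blanket case, deliberately below the foreground threshold so
  only the radar sees that sleeper). No articulation: the classifier
  consumes only heights, footprints and positions, so capsules exercise
  every decision path that limb detail would.
- **Rendering.** Exact per-pixel ray intersection with cylinders and
  boxes, nearest surface wins (so occlusion is physical), Gaussian depth
  noise σ = 10 mm and 1% invalid pixels — typical ToF behaviour.
- **Radar.** An in-bed person contributes a respiration sinusoid at the
  scripted rate with 20% amplitude jitter (amplitude 5 units over a unit
  noise floor); ambulation contributes broadband energy (8 units);
  an empty bed leaves white noise.
- **Truth.** Constructed from the scripts, not annotated: a bed-exit
  exists iff a resident trajectory crosses leave → boundary, validated
  at generation time; each negative scenario contributes one non-exit
  episode.

The standard suite is 72 seeded instances across eight families — 12 solo
exits, 10 assisted exits (22 positives) and 12 sit-up, 12 roll-over, 12
edge-sit, 6 pass-through, 4 parked-wheelchair and 4 under-blanket
scenarios (50 negatives). Scenario clips run 32–45 s around the scripted
episode (≈ 26,000 frames in total) — long enough to cover calibration,
the manoeuvre and the return, short enough that the whole suite runs in a
few minutes on one core. Every random stream derives from
`default_rng([seed, family, instance])`, so the suite is bit-reproducible
and insensitive to generation order.

### What the simulator does not model

Real bedding ("quilts and blankets") is reduced to a body-thickness
change; multi-person occlusion is scripted to avoid blob merging; there
is no articulated movement, no furniture rearrangement, no double-deck
beds, no sensor drift or interference. Passing the suite therefore
demonstrates the logic chain — geometry, segmentation, fencing, fusion,
alarms, scoring — under idealised but physically consistent conditions;
it does not certify field performance on real residents.

## Numerical choices

- **Motion index.** The per-blob mean |Δ height| between consecutive
  frames is computed on a 3 × 3 box-smoothed surface with pixels
  adjacent to an invalid return (in either frame) excluded. Raw noisy
  differences would average ≈ 11 mm (E|N(0, σ√2)| at σ = 10 mm) — above
  the 10 mm stillness threshold — so an unsmoothed index could never
  flag anything stationary; smoothing brings the noise floor to ≈ 4 mm
  while real posture shifts remain two orders larger.
- **Blob max height** is taken over the same smoothed surface: a raw max
  over thousands of noisy pixels is biased upward by ≈ σ√(2 ln n) ≈
  36 mm, enough to push a seated torso over a tier boundary.
- **Footprint area** integrates the true per-pixel ground footprint
  (d²/(f_u f_v)), so the 0.05 m² blob gate means the same thing at every
  image position.
- **Ties and edges.** Shared zone edges take the inner zone; the YELLOW
  debounce is evaluated on a continuous edge-condition run; RED episodes
  separated by < 30 s merge into one event (a pause in the boundary zone
  is one exit, not two).
- **Degenerate inputs.** All-invalid frames render empty silhouettes
  with a logged warning; empty detection+truth yields zero-filled
  matrices with metrics reported absent (never 0) on zero denominators;
  traces shorter than the 30 s analysis window are rejected.
- **Projection sanity.** The rendered pixel area of a standing person is
  monotone decreasing with lateral distance only beyond ≈ 0.9 m from the
  nadir; nearer in, the increasingly visible cylinder side compensates
  for the foreshortened top. The invariant test asserts the monotone
  regime.

## Open design decisions taken

- The depth value is read as the perpendicular distance from the sensor
  plane (not slant range): consistent with a nadir mount and makes the
  height transform a subtraction; the box-inversion test would fail
  within ±5 mm under a slant-range reading.
- Zone shapes are rectangles by default (`default_zones`); real
  deployments supply polygons via JSON.
- Assistance labelling is automated by the concurrent-second-track rule;
  operationally this label would be confirmed by staff, and it is
  evaluated here only against scripted truth.
- Radar thresholds (6 dB SNR gate, 30 s window, 1 s hop, 0.1–0.7 Hz
  band, absolute motion threshold) are standard periodogram practice
  plus a noise-floor calibration; none are claimed to be device values.
- All transient states are emitted (OTHER marks them); a deployment UI
  could choose not to display them.

## Known limitations

Single bed per sensor; merged blobs for overlapping persons; no identity
re-acquisition after a track is lost outside the bed; greedy association
beyond two persons; silhouette shading normalises per frame, so absolute
depth is not recoverable from archived silhouettes (by design, for
privacy); field-scale negative-episode structure is emulated, not
re-derived from field recordings.
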