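# Methods

## Overview

`fatiguekit` quantifies driver drowsiness from a time series of 68-point
facial landmarks (iBUG-68 convention, 0-based). It does not detect faces
or regress landmarks; it consumes the output of such detectors and turns
it into graded fatigue assessments in four stages:

1. **Geometric features** — per frame, the eye aspect ratio (EAR), mouth
   aspect ratio (MAR) and head-pose Euler angles.
2. **Temporal detection** — EWMA smoothing, a personalised eye-closure
   threshold with hysteresis, and duration-filtered extraction of blink,
   yawn, and nod events.
3. **Sliding windows** — overlapping windows accumulate blink frequency
   (BF), yawn frequency (YF), nod frequency (NF) and PERCLOS.
4. **Fusion** — clamped min–max normalisation of the four indicators and
   a weighted sum into a fatigue index F, graded into four alert levels
   with an independent sleep warning.

A seeded simulator generates feature series and fully projected landmark
sequences with scripted ground-truth events, so every stage is testable
offline without video data.

## Geometric features

With 0-based iBUG indices (right eye 36–41, left eye 42–47, mouth 48–67):

    EAR_right = (|P37−P41| + |P38−P40|) / (2 |P36−P39|)
    EAR_left  = (|P43−P47| + |P44−P46|) / (2 |P42−P45|)
    MAR       = (|P50−P58| + |P52−P56|) / (2 |P54−P48|)

Both ratios are invariant to translation, rotation and uniform scaling
of the landmark set. Downstream logic uses `ear_mean`, the average of
both eyes: the laterality choice is ours, made for robustness to
unilateral occlusion.

Head pose is recovered by a perspective-n-point fit of a canonical 3-D
face template to a rigid landmark subset (chin, nose bridge and tip,
nose wings, eye corners, mouth corners — points that do not deform with
blinks or yawns). The solver is a scaled-orthographic (weak-perspective)
Procrustes initialisation followed by Levenberg–Marquardt refinement of
the pixel reprojection error (`scipy.optimize.least_squares`). The
template is a synthetic generic anthropometric layout shipped as plain
text (`data/face_template_68.txt`, millimetres); the eye and mouth
regions are planar so that projected aspect ratios are exact under a
frontal pose. Default intrinsics follow the standard monocular
assumption: focal length = image width, principal point at the image
centre, no distortion.

Euler angles use the intrinsic z–y–x composition
`R = Rz(roll)·Ry(yaw)·Rx(pitch)`, the unique convention inverted by the
extraction `pitch = atan2(r21, r22)`, `yaw = atan2(−r20, √(r21²+r22²))`,
`roll = atan2(r10, r00)`. Near |yaw| = 90° the extraction degenerates;
results are flagged `gimbal_lock` with roll fixed at 0. Anatomical
ranges — pitch (−60.4°, 69.6°), roll (−41°, 36.3°), yaw (−75°, 75°) —
support an abnormality flag raised when an angle strictly exceeds 70 %
of the bound on its own side.

## Temporal detection

Every channel (EAR, MAR, pitch) is smoothed independently with an
exponentially weighted moving average, `out[t] = α·x[t] + (1−α)·out[t−1]`,
seeded with the first sample; α = 0.2 by default. Smoothing suppresses
sensor and micro-expression noise at the cost of lag: a step change
reaches ~90 % of its amplitude after about 10 frames at α = 0.2, which
is why event-duration filters and the simulator's event spacing leave
margins around threshold crossings.

The eye-closure threshold is personalised once per sequence: the mean of
the first two valid raw EAR samples, capped at the population baseline
0.25. No continuous re-estimation is performed — only the initialisation
rule is defined, so nothing further is invented. Eye state is a
hysteresis machine: open→closed when smoothed EAR < threshold,
closed→open only when it exceeds threshold + h (h = 0.02 EAR units, our
choice: small relative to the 0.26–0.30 alert band, large enough to stop
chatter).

Events are maximal runs of a thresholded smoothed channel passing a
duration filter, one event per maximal run:

| event | condition                         | min duration (frames) |
|-------|-----------------------------------|----------------------|
| blink | eye state closed                  | 2                    |
| yawn  | smoothed MAR > 0.75               | 50                   |
| nod   | \|smoothed pitch − neutral\| > 10° | 15                   |

The neutral pitch is the median smoothed pitch over the first 2 s,
making nod detection a *deviation* test robust to camera mounting angle.
The 50-frame yawn minimum reflects that genuine yawns hold an elevated
MAR far longer than speech; 15 frames (~0.5 s at 30 fps) is our choice
for a deliberate head nod. Blink counting uses completed closed runs
(not closing transitions); the two readings differ only for a run still
open at the end of a sequence.

Sliding windows are T = 900 frames with stride S = 150 (30 s windows
re-evaluated every 5 s at 30 fps). Full windows start at 0, S, 2S, …
while they fit; trailing frames form one partial window. Per window, BF,
YF and NF count events whose *start* frame lies inside (an event may be
counted by several overlapping windows — inherent to stride < T), and
PERCLOS is the closed-frame fraction. Partial windows are, by default,
extrapolated to full-window scale (counts × T / remaining); a
`rate-only` switch leaves counts untouched and relies on the per-minute
rates. PERCLOS, being a proportion, is never rescaled.

## Fusion and grading

Each window's indicator vector X = (BF, PERCLOS %, YF, NF) is
normalised feature-wise:

    F_i = clamp((X_i − X_i0) / (X_im − X_i0), 0, 1)

against baselines (15, 5, 1, 3) and maxima (40, 50, 5, 10), then fused:

    F = Σ W_i F_i,  W = (0.10, 0.40, 0.30, 0.20)

— PERCLOS dominant, YF and NF supporting, BF de-emphasised. Levels:
F < 0.25 awake, < 0.45 mild, < 0.65 moderate, ≥ 0.65 severe (F = 1
included in severe to keep the map total). A sleep warning fires when
the window PERCLOS fraction exceeds 0.4; it is reported *alongside* the
level, never replacing it, since the reference worked examples grade
severely fatigued windows that also exceed the sleep threshold.

Two unit bridges matter and are fixed by reproducing the reference
worked examples exactly:

* PERCLOS is normalised on the percent scale (fraction × 100 against
  5/50) while the sleep warning uses the fraction (> 0.4).
* BF/YF/NF enter normalisation as raw per-window counts. The bounds are
  nominally per-minute figures; a `use_rates` switch normalises the
  per-minute rates instead, which coincides with counts only for 60
  s-equivalent windows.

Of the twelve published worked examples, only four (the ones asserted in
tests and recomputed by `scripts/acceptance.py`) follow from the stated
normalisation and weights applied to their printed window inputs; the
remaining eight do not recompute from the printed rows under any unit
convention we could identify (plausibly they were computed per sub-window
and averaged). We assert nothing about those rows.

## Synthetic data

The simulator renders an event script — placed blink/yawn/nod intervals
plus signal-shape parameters — into per-frame channels: baselines
(EAR 0.28, MAR 0.34, pitch 0°) with trapezoidal excursions (3-frame
linear ramps around a flat core; defaults: blink dip to EAR 0.10 for 8
frames, yawn plateau at MAR 0.90 for 70 frames, nod excursion of 15° for
30 frames) and optional i.i.d. Gaussian noise per channel. The trapezoid
is the simplest shape with controllable duration; the baseline and event
scales match the bands observed in alert/fatigued subjects (EAR
0.26–0.30 alert band, MAR ≈ 0.34 with > 50-frame yawn plateaus).

Placement is uniform over admissible arrangements: events of all kinds
share one timeline, are kept ≥ 30 frames apart (so smoothing lag cannot
merge adjacent excursions), and the first 90 frames stay event-free for
threshold and neutral-pose calibration. Infeasible requests raise an
error naming the constraint. One seed drives everything in a documented
order — placement first, then EAR, MAR, pitch noise — so fixtures are
bitwise reproducible.

In landmark mode, the canonical template is deformed by vertical
displacement of the eyelid and inner-lip points calibrated so the
projected ratios hit the scripted EAR/MAR exactly under a frontal pose
(the ratios depend on nothing else), rotated by the scripted pitch about
the inter-ocular origin, placed 600 mm from the camera and projected.
Under a nod-scale pitch the projected EAR compresses by ~cos(pitch)
(≈ 4 % at 15°), which stays well inside the open-eye band, so event
recovery is unaffected; tests assert EAR/MAR recovery to 1e-3 on frontal
frames and pitch to 1° everywhere.

What the simulator does **not** emulate: landmark-estimator error
structure (correlated, heteroscedastic, occlusion dropouts), yaw/roll
motion, expression changes beyond blink/yawn, illumination effects, or
variable frame rate. Passing recovery tests therefore demonstrates the
correctness of the temporal and fusion logic under the stated signal
model, not field performance of a full video system.

## Problem sizes and numerical choices

* Event-recovery tests run 100 noise-free and 100 noisy seeded series of
  2700 frames (90 s) each, with 0–10 events per kind — the shortest
  length into which ten 70-frame yawns plus guards always pack.
* The IoU Monte-Carlo oracle uses 1000 random box pairs at 60 000 points
  per pair (standard error ≲ 0.003, against a 0.01 tolerance).
* The PnP refinement runs to `xtol = ftol = 1e-12`; pose grids inside
  the anatomical ranges recover to well under 1°.
* Bounding-box losses short-circuit bitwise-identical boxes so the
  zero-iff-identical property holds exactly in floating point.
* Display rounding is decimal half-up, applied in reports only.

## Detection-side math

Standalone, training-free implementations are included for the detector
losses and the attention kernel rule used by the upstream face-detection
stage: IoU; CIoU loss `1 − IoU + ρ²/c² + αv` with
`v = (4/π²)(atan(w_gt/h_gt) − atan(w/h))²`, `α = v/((1−IoU)+v)`; EIoU
loss `1 − IoU + ρ²(b,b_gt)/(w_c²+h_c²) + ρ²(w,w_gt)/w_c² +
ρ²(h,h_gt)/h_c²` with (w_c, h_c) the enclosing-box sides; and the
channel-to-kernel map `k = |log₂(C)/γ + b/γ|_odd` (γ = b = 2), where an
exact tie rounds up to the larger odd neighbour (any fixed rule works;
this one is documented for determinism). Gradient formulas used only in
network training are out of scope.

## Known limitations

* Batch-only API; no streaming/online operation.
* fps is sequence metadata; variable-rate video is unsupported.
* The personalised EAR threshold uses only the first two frames; a noisy
  or mid-blink start degrades it (the baseline cap bounds the damage).
* Nod detection needs a pose channel; without one it is skipped with a
  warning and NF = 0.
* The fusion weights and bounds are fixed reference values; no
  per-driver learning is provided.
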