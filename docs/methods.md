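# Methods

`predetach` analyses micromanipulation videos in which a micropipette
("tube") aspirates a single adherent cell off the substrate of a culture
dish.  The mechanically interesting signal is purely kinematic: the
target cell sits through calm plateaus, starts oscillating under suction
while still adherent (the *pre-detachment* phase), and finally lets go —
visible as one large inter-frame displacement of its centroid followed
by disappearance from the field of view.  The package implements that
signal chain end to end: image quality control, detection tables,
trajectory kinematics, event rules, evaluation metrics, and a synthetic
scene generator that makes every stage testable without recorded data.

Units throughout: pixels for space, frames for time (one frame = one
image of the sequence).

## Coordinate and table conventions

Detections use 0-based pixel coordinates, bounding boxes as
`(left, top, width, height)`, and centres `x + w/2`, `y + h/2` (which may
be half-integers).  The canonical on-disk artifact is a UTF-8 comma CSV
with one row per (frame, object) — chosen over a spreadsheet format so
fixtures diff bit-exactly and round-trip losslessly (floats are written
in shortest-repr form).  Any external detector can drive the analysis by
exporting this schema.

## Imaging quality control

The QC pipeline runs four conditional stages in a fixed order —
sharpness, impulse noise, contrast, morphology — each stage firing only
on its trigger, and reports what it measured and did.

* **Sharpness.**  Blur is scored as the variance of the 4-neighbour
  Laplacian of the Lab lightness channel (D65 white point, computed in
  floating point), with L rescaled to 0–255 so the familiar 8-bit
  threshold convention applies; the default blur threshold is 100
  (configurable), compared strictly (`variance < threshold` means
  blurred).  The variance is taken over the interior of the response
  (1-px border excluded); all filters in the package use reflect
  padding.  Restoration defaults to unsharp masking per RGB channel
  (`amount` 1.0, `radius` 2.0); Wiener deconvolution is used instead
  when a point-spread function is configured, i.e. when something is
  known about the blur.  When impulse noise is present it dominates the
  Laplacian response, so in that case the *measurement* (only) is made
  on a median-prefiltered copy; the restoration order is unchanged.
* **Impulse noise.**  The per-channel weight of pixels at the extreme
  intensities (exactly 0 or 255 by default) estimates the
  salt-and-pepper fraction.  If any channel exceeds the trigger (0.1 %),
  a synchronized per-channel 3×3 median filter is applied — identical
  kernel and border policy on all channels, preserving inter-channel
  alignment.
* **Contrast.**  The contrast score is the robust lightness range
  (p99 − p1 of L), chosen because it is outlier-tolerant and monotone
  under the generator's contrast compression.  Frames scoring at or
  above 60 % of the 255 range are passed through untouched; otherwise
  CLAHE is applied to L only and recombined with the original a, b
  channels, so chromatic relationships survive.  The clip limit is
  accepted in the common 8-bit convention (default 2.0) and divided by
  100 for scikit-image's normalised scale; the tile grid defaults to
  8×8.  A constant frame is returned unchanged (equalising a
  zero-range channel is a no-op by definition).
* **Morphology.**  Greyscale opening then closing with a disk of radius
  1, per channel, removes residual specks.  It runs only when the
  impulse-noise trigger fired — specks are a residue of impulse
  corruption, and unconditional morphology would erode fine structure in
  clean frames.

## Reference detector and tracking

The intensity detector exists so rendered scenes run end to end without
a trained segmentation model; it is not a general cell detector.  It
thresholds the lightness channel at the larger of the Otsu threshold
and background-median + 20 grey levels (Otsu alone can split inside the
background texture when objects are small), keeps connected components
of ≥ 30 px² whose mean lightness exceeds the background by 40 grey
levels, and classes the single most elongated component (aspect ratio
> 2.5) as the tube.  Touching objects merge into one component — a
documented limitation of connectivity-based detection.

Tracking is greedy nearest-centroid association with a 50 px gate and a
5-frame persistence gap, deterministic (candidate pairs ordered by
distance, then track id).  The gate is deliberately *below* the 85–90 px
detachment band: a genuine detachment jump breaks the track, and the
event layer is designed around that fact (below).

## Kinematic series and intervals

Per object: bounding-box diagonal `sqrt(w² + h²)` (a size/deformation
proxy), centroid displacement between consecutive present frames
(absence gaps yield no value — they are events, not zeros), and an
oscillation score defined as the rolling maximum (window 5) of the
absolute frame-to-frame differences of position or diagonal.  The
rolling max turns raw jitter into a monotone, threshold-friendly
envelope.

Interval segmentation labels frames below the calm threshold
(default 2 px/frame) as calm and the rest as oscillation, then merges
maximal runs shorter than the minimum length (default 5 frames) into the
longer of their neighbours (ties to the preceding run), coalescing as it
goes.  The output spans are disjoint, sorted and partition the observed
range; an exhaustive reference scan is kept in the test suite as an
independent oracle.  The calm threshold sits far below the detachment
band and above sub-pixel jitter; "calm" is intentionally generous.

Velocity variability ranks objects by the standard deviation of their
displacement series (ties by id); the top-ranked non-tube object is the
*suspect* — the cell whose erratic motion marks it as the one under
suction.

## Event rules

**Detachment** is the first frame `t` with displacement
`d(t−1→t) > threshold` (default 87.5 px, the midpoint of the empirical
85–90 px band; strict inequality, configurable across the band) where
the object then stays absent or more than the threshold away from its
pre-jump position for the whole reappearance horizon (default
10 frames).  Return within the horizon is reattachment, not detachment.
A track that simply ends is **lost**, never detached — tracker failures
must not masquerade as biology.  Because the association gate breaks
tracks at genuine jumps, the detector accepts candidate trajectories: a
track dying at frame `e` is matched to a track born at `e+1` at
super-threshold distance (smallest candidate id on ties), and the jump
is reconstructed across the break; the consumed fragment is excluded
from its own report.

**Pre-detachment** is the earliest frame, before any detachment, where
three conditions hold at once: the tube's displacement stayed within
2 px/frame over the 10-frame stability window (insufficient history
counts as unstable); the tube–cell centre distance is under 90 px; and
the cell's oscillation score has reached the onset threshold (default
3 × calm threshold = 6 px) with a calm interval having ended within the
last stability-window frames.  The conjunction — settled tube, close
approach, oscillation onset after a plateau — is this package's
operationalisation of the qualitative pre-detachment signature; each
conjunct is independently configurable.  Searching is bounded by the
detachment frame, so pre-detachment strictly precedes detachment
whenever both are reported.

All detectors are pure functions of trajectories plus configuration:
replays are bit-reproducible.

## Synthetic scenes

The generator scripts each object's behaviour: linear drifts (the tube's
approach), calm stretches with uniform sub-pixel jitter (default bound
0.5 px per-frame displacement — small enough to read as calm under
default thresholds, large enough to be non-degenerate), oscillation
bursts modelled as a zero-mean sinusoid (0.171 cycles/frame, per-frame
uniform phase noise, random direction) whose amplitude is directly the
threshold-relevant quantity, optional bounding-box dilation under
suction, and a terminal jump of exact magnitude followed by absence.
The jump direction defaults to away-from-tube so the displaced centroid
stays in the rendered field of view (physically, the cell leaves along
the aspiration axis and promptly vanishes; what matters kinematically is
the magnitude).  Validation rejects contradictory scripts (calm
overlapping bursts or drifts), out-of-range intervals, and scenes
without exactly one tube.

Rendering draws cells as filled ellipses and the tube as an elongated
rectangle (≥ 50 grey levels above a smooth static background texture);
degradations apply Gaussian blur, then contrast compression, then
impulse noise — noise last so exactly `round(fraction × n_pixels)`
pixels per frame end at the extremes, which is what the noise estimator
is tested against.  One scenario seed drives named RNG sub-streams
(trajectories, rendering, degradations, in that order), so identical
(spec, seed) gives bit-identical trajectories and frames.

What the generator does *not* emulate: real cell texture and shape
change, fluid–structure interaction, partial adhesion (tethering,
rolling), occlusion, illumination drift, and detector noise correlated
with cell appearance.  Passing tests therefore demonstrate that the
analysis layer is correct *given* detections with these statistics, not
that any particular segmentation model produces such detections on real
microscopy.

## Evaluation metrics

IoU uses continuous box-area arithmetic; a pixel-rasterization counter
is kept in the tests as the oracle.  Precision/recall/F1 use the
defined-zero convention (undefined ratio → 0; F1 = 0 when TP = 0), and
the harmonic-mean and `2TP/(2TP+FP+FN)` forms agree identically.
Average precision follows the COCO protocol: greedy score-descending
matching (ties keep input order), each ground truth matched at most
once, 101-point interpolated precision–recall area; mAP averages over
classes, and the threshold-grid variant averages over IoU 0.50:0.95 in
steps of 0.05.  The dataset splitter shuffles deterministically by seed
and assigns floor shares with remainders going to the largest-ratio
subsets first (train, then validation).

## Problem sizes used in the test bench

The reproduction scripts use scenario families a workstation handles
comfortably while preserving the study conditions: 395-frame
trajectories for detachment recovery (100 random scenarios, jumps
95–200 px at frames 50–300, calm jitter 0.5 px), 50 canonical scenarios
for pre-detachment ordering, 80–120-frame rendered scenes (256×384) for
the full image pipeline, 1,000 random cases for each metric/segmentation
oracle comparison, and 50 five-object scenes for tracking identity
recovery.  Events are detected from trajectories, so trajectory-level
benchmarks need no rendering.

## Known limitations

* The detector/tracker layer is built for high-contrast rendered blobs;
  real microscopy requires substituting an external detector via the
  CSV contract.
* The detachment rule is kinematic only; borderline cases (partial
  release, tethering) need orthogonal confirmation (fluorescent adhesion
  markers, impedance) that is out of scope here.
* Thresholds are in pixels at acquisition scale and do not
  auto-normalise across resolutions.
* The pre-detachment conjunction was designed against the synthetic
  scenario family; on real recordings its onset threshold and stability
  window are the parameters most likely to need retuning.
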