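# Methods

This note documents the models, numerical choices and limitations behind
`neotherm`. It is the design record a maintainer needs; empirical claims
below are limited to what the test suite and `scripts/acceptance.py`
themselves compute.

## Problem setting

Two co-mounted cameras view a supine neonate in an open incubator in a
dark room: an RGB camera (1920×1200 px) where body landmarks can be
detected, and an infrared thermography (IRT) camera (1024×768 px, 16-bit)
where each pixel encodes a surface temperature. The cameras share a
viewing direction but differ in optics and resolution, so landmarks found
in RGB must be mapped into IRT coordinates before temperatures can be read
at them. The clinical quantity is the central-peripheral temperature
difference (cpTD): mean skin temperature over central body sites minus the
mean over peripheral sites.

## Registration model

The RGB→IRT mapping is modeled as a symmetric field-of-view crop followed
by an affine transform:

    u = A (p − c) + t ,   A ∈ R^{2×2},  c = (crop_x, crop_y)

with `p` in full-RGB pixel coordinates and `u` in IRT pixel coordinates.
Conventions fixed package-wide: 0-based coordinates, x = column,
y = row, origin top-left, coordinates refer to pixel centers. Crops are
symmetric margins removed from both borders per axis, which keeps the crop
at two parameters. Crop and translation are redundant for the *composite*
point mapping (only the validity mask distinguishes them); point-transfer
accuracy therefore never depends on resolving that redundancy.

Alignment is scored by the mutual information (MI) of the joint intensity
histogram of the warped RGB luminance (ITU-R BT.601 weights) and the IRT
temperature map, in nats, with 0·log 0 = 0. Histograms use 64 equal-width
bins per image spanning the min–max over the overlap mask: 64 bins
balances bias and variance at IRT resolution. Warping is inverse-mapped
bilinear interpolation; points are transformed exactly and only rounded
when indexing ROIs.

**Overlap guard.** MI computed on a small overlap is inflated — a zoomed-in
partial match can out-score the true alignment. Candidates whose valid
overlap fraction falls below `min_overlap_fraction` have their MI scaled by
`overlap / min_overlap_fraction`. The default is 0.75, which makes the
working objective effectively MI × overlap (total shared information) for
most candidates; during development the weaker guard of 0.25 let the
optimizer park at exactly 25 % overlap on a wrong high-MI solution.

**Optimizer.** A fixed budget of 500 objective evaluations (a per-patient
calibration, so robustness matters more than speed), deterministic given
the seed, in two stages over the decomposed parameters
(tx, ty, sx, sy, θ, crop_x, crop_y); a direct-matrix-entries search is
retained behind `OptimizerSettings(direct_entries=True)`.

1. *Global stage (150 evaluations):* principal-axes moment seeding — the
   foreground (pixels above the mid-range intensity) of each image gives a
   centroid and covariance; per-axis scales come from the variance ratios,
   the rotation is scanned over an 8-angle grid inside its bounds (second
   moments cannot give the angle robustly under anisotropic scaling), and
   the translation closes each candidate so the centroids coincide. The
   crop seeds near the low end of its range to keep the overlap large.
   The seeds are followed by 40 uniform draws within bounds and Gaussian
   draws around the best seed. Moment initialization is the classic remedy
   for MI's narrow capture range; pure uniform sampling of this
   7-parameter space essentially never lands inside the basin.
2. *Local stage (350 evaluations):* Nelder-Mead over
   (tx, ty, sx, sy, θ) with an explicit per-parameter initial simplex
   (default simplexes scale with the coordinate values and fail for
   mixed-magnitude parameters); candidates are clipped to bounds; the crop
   stays at its stage-1 value by the redundancy argument above.

Default bounds: scale ∈ [0.3, 1.5] (the IRT/RGB sensor-size ratio ≈ 0.6
sits centrally), θ ∈ [−15°, 15°] (co-mounted cameras), translation
∈ [−200, 200] px, crop margins ∈ [0, 400] px capped below half the frame.
Failure modes are explicit: constant images raise a degenerate-input
error; if no candidate achieves positive penalized MI the error names
`min_overlap_fraction`.

## Keypoints and their evaluation

Landmarks are the 17 COCO person keypoints plus a neck defined as the
midpoint of the two shoulders (visibility = min of the two; absent if
either shoulder is unlabeled; any stale neck value is overwritten). The
default region scheme marks face, neck and shoulders central and elbows,
wrists, hips, knees, ankles peripheral; whether hips belong to the "upper
body" is genuinely ambiguous, so the scheme is a config object, not a
constant.

OKS uses `exp(−d_i² / (2 s² k_i²))` averaged over labeled ground-truth
keypoints, with `s² = mask area` and `k_i = 2σ_i` for the published COCO
annotation sigmas (neck inherits the shoulder value) — this matches the
canonical COCO evaluator exactly. Detections a detector missed contribute
zero. AP averages 101-point interpolated precision over OKS thresholds
0.50:0.05:0.95 (×100); AR is the mean recall at ≤ 20 detections per frame.
Matching is greedy in descending detection confidence by highest OKS, each
ground truth matched once; on small frames this equals exhaustive
best-assignment matching (property-tested).

The mock detector stands in for a trained pose network: per-keypoint
dropout, isotropic Gaussian jitter, confidence decaying with jitter
magnitude (floor 0.05) so confidence ordering correlates with quality, and
Poisson-distributed false positives placed into empty slots with low
confidence. It is seeded and deterministic.

## Thermal extraction

Thermograms are float maps in °C; the 16-bit raster encoding is linear
centikelvin, `raw = round((T + 273.15)·100)`, valid for
T ∈ [−273.15, 382.2] °C with quantization error < 0.005 °C (finer than the
20 mK sensitivity of clinical IRT sensors).

Each landmark reads the maximum temperature in a square window centered on
it — default 10×10 px², configurable because a 20×20 px² window is equally
defensible when registration errors approach 20 px. Window anchoring is
fixed for exact testing: half-open `[round(c) − n//2, round(c) − n//2 + n)`
per axis, clipped at frame borders (limbs near borders would otherwise be
dropped). The window maximum absorbs registration offsets smaller than the
window half-size because skin is locally warmer than background, which is
the reason point-transfer errors of a few px do not propagate into cpTD.

Group means are unweighted arithmetic means of ROI maxima;
cpTD = central mean − peripheral mean. Landmarks that are unlabeled or map
outside the frame are excluded and listed; a region left empty makes the
cpTD undefined — flagged on the record, never an exception, because frames
with only a few found keypoints are an expected operating condition
(medical interventions, clothing). Negative cpTD values are valid outputs:
warm clothing over peripheral sites produces them.

Error statistics: MAE = mean |est − ref|; SDs use the n−1 denominator
(0.0 for a single pair). Bland-Altman differences are reference − estimate
(positive mean difference = underestimation), x-coordinates are pairwise
means, limits of agreement are MD ± 1.96 SD.

## The phantom

The synthetic data generator defines the study conditions; every
quantitative claim in the tests is relative to it.

*Geometry.* A fixed canonical supine pose (head up, limbs splayed, 18
landmarks in a unit body frame) with configurable global scale, rotation
and offset. The body is an ellipse (trunk) plus a disc (head) plus
capsules along the limb chains shoulder–elbow–wrist and hip–knee–ankle —
the simplest geometry whose per-landmark temperature maxima are known in
closed form. The figure is auto-placed so its image lands at the IRT frame
center under the configured true map. RGB renders skin at ≈180/255
luminance on a ≈10/255 background (dark-room, panel-light illumination);
the thermogram is the same analytic scene sampled at IRT pixel locations
through the inverse of the true map, so it is exactly the crop+affine
image of the RGB-frame geometry.

*Temperature field.* Trunk, head, face, neck, shoulders and hips sit at
`t_central` (default 36.8 °C). Along each limb chain the temperature falls
to `t_peripheral` (default 33.5 °C) at the wrist/ankle, with mid-chain
joints (elbows, knees) at the arc-length-fractional value; background
defaults to 28 °C (incubator surroundings). The along-limb profile is
piecewise linear with a flat plateau (default 18 RGB px radius) around
each joint: a strictly linear profile would make the windowed ROI maximum
at an interior joint read the warmer proximal side of the window rather
than the joint value, whereas the plateau makes the noiseless ROI maximum
*exactly* the closed-form joint temperature whenever the window's
half-diagonal mapped into RGB coordinates (5√2 / min-scale px) stays
inside the plateau — true for map scales ≥ 0.45 at the default plateau.
This exactness is what turns the end-to-end pipeline test into an equality
check rather than a tolerance check.

*Noise and occlusion.* Gaussian sensor noise per modality (defaults
0.05 °C IRT, 4 intensity units RGB); axis-aligned full-RGB-frame
rectangles overwrite the surface temperature (clothing) and recolor the
RGB. Occlusion parameters are free configuration — the clinical study
conditions they emulate were not quantified. Identical config + seed
reproduces byte-identical outputs.

*What the phantom does not emulate:* lens distortion (explicitly the
dominant clinical error source toward frame edges), pose articulation
beyond rigid placement, interleaved or overlapping body parts, photometric
texture, staff hands, motion. Passing tests therefore certify the
algorithmic chain — objective, optimizer, transfer, extraction,
statistics — under an affine-consistent world, not detector or distortion
robustness on clinical images.

## Problem sizes in tests and the acceptance script

Registration-recovery runs use half-scale frames (RGB 960×600,
IRT 512×384, figure scale 500 px) with true maps sampled from the interior
of the optimizer bounds (scales 0.45–0.75, θ ±8°, translation ±80 px·f,
crops scaled with frame width); unit tests use quarter-scale frames. These
sizes keep the full suite and the acceptance script to a few minutes while
leaving the basin geometry of the objective unchanged; the success
criterion (keypoint-transfer MAE ≤ 5 px in ≥ 8/10 seeded runs) is in IRT
pixels of the half-scale sensor. The exactness chain samples 20 random
configurations (sizes 480–640 px wide, temperatures t_central ∈
[36, 37.5] °C, t_peripheral ∈ [32.5, 34.5] °C, background ∈ [26, 30] °C)
with zero noise and checks pipeline cpTD = analytic cpTD to 1e-12 °C.

## Known limitations

- The affine+crop model cannot represent lens distortion; on clinical
  data, residual errors grow toward frame edges and with subject
  displacement. Deformable or learned registration is out of scope.
- MI is estimated from a single-resolution histogram; no multi-resolution
  pyramid, no robust-MI variants for outliers (time-synchronous capture is
  assumed).
- The mock detector models localization noise, dropout and false
  positives, but not structured failures (left/right swaps, limb
  confusion between subjects).
- Group means do not weight ROIs by valid-pixel count; border-clipped
  windows contribute equally.
- No emissivity or radiometric calibration: cpTD is a relative quantity;
  absolute skin temperature validation requires contact reference sensors.
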