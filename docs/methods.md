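# Methods

## Pixel classification model

A fruit photograph is modeled as a mixture of a uniform contrasting
background, fruit surface, and color-defined feature regions on that
surface (the motivating case is red drupelet reversion, where black
blackberry drupelets redden after harvest handling and cold storage).
Both background removal and feature detection are per-pixel
classifications: a pixel passes a threshold specification iff it
satisfies *every* per-channel acceptance interval, where channels may be
drawn from sRGB (R, G, B on 0–255), hexcone HSB (hue in degrees,
saturation/brightness in [0, 1]), and CIELAB (L\* in [0, 100], a\*/b\*
unbounded). Channels not mentioned are unconstrained — the "FR" (full
range) idiom of published settings tables — and bounds are strict
inequalities by default, matching the `>` form those tables print.
Hue intervals may wrap (lo > hi allowed for H only).

Colorimetry is fixed: sRGB companding, D65/2° white point, CIELAB on the
conventional scale, computed in floating point with no internal
quantization. The working illuminant of threshold values quoted from
other tools is generally unrecorded; D65 is the sRGB-native choice and
the one assumed here. For users porting ImageJ settings, the mapping to
ImageJ's 0–255 Lab convention (L·255/100, a+128, b+128, clamped) is
exposed as `lab_to_imagej_scale`; e.g. an ImageJ reverted cutoff of
a255 > 138 corresponds to a\* > 10.

## Preprocessing

Order is fixed: downsize → contrast stretch → enhance → exclusion-zone
flagging.

- **Downsize** to max dimension 1500 px (bilinear; aspect preserved to
  the rounding pixel). The applied scale factor is tracked for
  calibration. Idempotent.
- **Contrast stretch** x → (x−m)·255/(M−m) with m, M the *joint*
  min/max over all three channels. Per-channel stretching would change
  hue and silently move every Lab threshold; the joint stretch is a pure
  intensity rescale. Constant images pass through.
- **Enhance**: per-channel median filter of window (2r+1)², r = 1 by
  default, then an unsharp mask x + amount·(x − gaussian(x, σ=1)) with
  amount 1.0 by default. Both stages are toggleable (radius 0 /
  amount 0) to reproduce analyses done without preprocessing. Sharpening
  matters quantitatively: it hardens blended boundary pixels, pushing
  them toward their dominant side before thresholding (see "Validation"
  below).
- **Exclusion region**: the area around the in-photo size reference is
  flagged ineligible rather than geometrically cropped, so pixel
  coordinates remain comparable across stages. The region is given in
  fractional coordinates so one setting applies batch-wide.

## Despeckling and objects

Despeckling is morphological opening — erosion then dilation with a disc
of configurable radius (default 2) — which removes any connected group
that cannot survive the erosion (dust, juice droplets, debris) while
preserving the bulk of large regions. Pixels outside the frame count as
background (`border_value=0`), so edge-clipped groups shrink from the
frame side too. Opening is idempotent and anti-extensive; feature masks
are despeckled *after* intersection with the fruit mask, so
feature ⊆ fruit is guaranteed.

Objects are 8-connected components of the fruit mask with at least
`min_object_area` pixels (default 50), labeled 1..n in row-major order
of first pixel for determinism. Touching berries are *not* split: no
watershed step exists, matching the target workflow; per-image fractions
are unaffected, and per-fruit sizes on suspicious objects are flagged
(`merged_suspect` when area > 2.5× the median object area, and
`touches_border` for possibly truncated fruit).

## Measurement conventions

- **Length** is the vertical image-axis extent of the object (uppermost
  to lowest fruit pixel), *not* the Feret/major axis. This makes results
  orientation-dependent by design — fruit must be staged upright — and
  mirrors how operators already stage samples. A `length_mode:
  major_axis` option provides the orientation-free ellipse-fit axes
  instead. **Width** is the horizontal bounding-box extent; an
  operational definition is needed and the horizontal extent is the
  natural complement (it will generally differ from a caliper's
  equatorial measurement on non-upright fruit).
- Extents are inclusive (+1), so a single-pixel object has size one
  pixel rather than zero.
- **Calibration**: mm/px = reference length in mm / (reference pixel
  extent × downsize scale). One calibration per batch; the protocol
  assumption is a fixed camera height. Requesting size traits without a
  calibration is a validation error before any image is touched.
- **Feature fraction** is a pure pixel-count ratio (100·|feature|/|fruit|),
  independent of calibration; 0 for an empty fruit mask (recorded with an
  `empty_segmentation` status rather than an error).
- **Color profile**: among feature pixels, the minimum and maximum are
  the actual pixels of lowest/highest L\* (ties broken lexicographically
  by RGB), the median is channel-wise (nearest-rank). Each is matched to
  the nearest named chart color by Euclidean CIELAB distance.

### The named-color table

Horticultural color descriptors conventionally reference the proprietary
RHS colour chart, which cannot be redistributed. The bundled table
(`data/color_table.csv`) is this package's own documented approximation
— 38 plausibly spaced entries across the chart's group names — with one
exception: Greyed-Purple 185-A carries its published reference triple
(L\*a\*b\* = 34.4, 42.0, 12.7), the standard visual threshold for a
reverted drupelet. Users can supply their own table with the same
columns. Matching distances are computed against each entry's Lab *after*
rendering to 8-bit sRGB and back: camera pixels live in the quantized
sRGB gamut, and comparing in that same gamut makes a patch of an entry's
displayable color match it at distance exactly zero instead of at the
quantization residual.

## Batch contract

A run is a pure function of (image directory, configuration): files are
processed in lexicographic order, every number is derived
deterministically, and re-runs produce byte-identical CSVs. The CSV
schema is fixed (`image_id, object_label, n_pixels, length_mm, width_mm,
area_mm2, <feature>_pct…, color_min_name, color_median_name,
color_max_name, flags, status`), with `object_label = 0` marking the
per-image summary row; sizes are written at 4 decimals. Settings are
echoed to a `settings.json` sidecar (kept out of the CSV so it stays
strictly tabular); reloading the sidecar as a config replays the run
identically. Unreadable files yield `decode_error` status rows and the
batch continues.

## Synthetic scenes and what validation shows

The generator emulates the staging protocol: a green cutting board
(sRGB (60, 120, 60), a\* ≈ −33), berries as ellipses filled with black
drupelet color ((25, 15, 20), a\* ≈ +5) and packed hexagonally with
drupelet discs, a per-berry fraction of which is drawn in reverted red
((150, 40, 40), a\* ≈ +45); red debris specks; and a reference bar of
declared mm length in a bottom strip that analysis configs exclude. The
palette deliberately straddles the working cutoffs (board < −12 <
−8.5 < black < 7.51 < 16.15 < red), which is asserted at render time
via the color model itself. Scenes are deterministic given their seed.
With anti-aliasing off, every pixel is exactly one palette color, so
ground-truth pixel counts are exact; with anti-aliasing on, geometry is
rendered at 2× and block-averaged, giving realistic soft boundaries
while the truth still refers to the hard rasterization. Note that at
reverted fraction 1 the true *pixel* fraction equals the disc coverage
of the ellipse (≈ 75%), since inter-disc gaps stay black.

Default scene geometry: 480 × 360 px, three berries of 20–40 px
semi-axes, drupelet radius 4.5–6 px, a 160-px / 50-mm bar
(0.3125 mm/px), five single-pixel specks — i.e. 18–25 mm berries, the
realistic range for commercial blackberries. Recovery experiments use
100 scenes (5 reverted fractions × 20 seeds); these sizes keep the full
validation suite fast while leaving dozens of drupelets per berry.

The canonical analysis configuration for rendered scenes
(`scene_analysis_config`) keeps sharpening at its default (1.0) but
turns median denoising and range normalization off: scenes carry no
sensor noise for the median filter to remove (it only distorts disc
boundaries), and the palette's thresholds are calibrated on the raw
palette rather than on stretched values. Under this configuration the
anti-aliased reverted-fraction error is ≤ 0.02 absolute across the
0–60% severity range, and with anti-aliasing off (plus despeckling
radius 0, since opening shaves boundary pixels of even large objects)
recovery of fractions and sizes is exact. What this does and does not
show: the pipeline's counting, calibration, morphology and thresholding
are correct, and boundary blending costs well under two points of
fraction; it does not exercise glossiness/specular reflection (which can
mask drupelet color), white-balance drift between sessions, lighting
gradients, non-RDR discolorations (desiccation, anthracnose), or
touching-fruit merging — on real photos those remain the user's staging
and threshold-choice problems.

## Numerical and degenerate-input choices

- Re-rendering the same scene at 2× resolution reproduces calibrated
  lengths/widths to within about one coarse pixel: bounding-box extents
  quantize to whole pixels, so agreement is bounded by 1/extent —
  roughly 2% on a 45-px-wide berry, proportionally tighter on larger
  fruit. This is rasterization, not measurement error; fraction
  estimates agree far tighter (< 0.1 point) because they average over
  whole regions.
- Bilinear interpolation for downsizing (boundary pixel counts shift by
  ~±0.5% under area-average resampling; the choice is fixed, not
  configurable per-image, so batches are internally consistent).
- Joint-range normalization skips constant images (M = m).
- Empty threshold specs accept everything but emit a warning (almost
  always a configuration mistake).
- Empty feature regions yield a null color profile and an
  `empty_feature` flag, never an error.
- An empty fruit mask produces a zero-object summary row with
  `empty_segmentation` status.
- Achromatic pixels take hue 0.
- Sizes are reported at 4 decimal places; percentages at 4 decimal
  places.

## Limitations

- One-sided imaging: only the upper fruit surface is measured, so
  severity on the hidden side is unobserved (protocol advice: image more
  fruit).
- Orientation-dependent length (by definition; see above).
- No instance segmentation of touching fruit or individual drupelets;
  aggregate-feature counting is out of scope.
- No ICC/white-balance handling: thresholds are only transferable
  between sessions if capture conditions are controlled.
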