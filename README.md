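# fruitpheno

Batch image-based fruit phenotyping: detect fruit in staged photographs by
colorspace thresholding, measure calibrated per-fruit size, and quantify
color-defined surface features — such as **red drupelet reversion (RDR)** in
blackberry — as pixel fractions.

## Who this is for

Fruit breeders and postharvest researchers who photograph samples (e.g. a
clamshell of blackberries spread on a green cutting board with a size
reference in frame) and need objective, repeatable trait values at breeding-
program scale, replacing calipers and subjective per-drupelet scoring.

## The method

Each photograph passes through a fixed pipeline:

1. **Read-in normalization** — downsize so max(H, W) ≤ 1500 px, stretch
   contrast so pixel values span the full RGB range (jointly over channels, so
   hue is preserved), optionally median-denoise and unsharp-sharpen.
2. **Background removal** — classify every pixel against a conjunction of
   per-channel acceptance intervals in RGB, HSB, or CIELAB. A typical
   background cutoff for dark fruit on a green board is a single CIELAB
   interval, *a*\* > −10 (green board *a*\* ≈ −33; fruit *a*\* > −9). Channels
   not mentioned are full-range ("FR"). The strip around the in-photo size
   reference is excluded. The mask is then **despeckled**: morphological
   opening (erosion then dilation with a disc) deletes dust, juice and debris
   specks.
3. **Feature detection** — the same machinery with a feature threshold (e.g.
   reverted-red pixels at *a*\* > 16.15), intersected with the fruit mask and
   despeckled, so feature ⊆ fruit always.
4. **Measurement** — 8-connected components above a minimum area become fruit
   objects. Per object and per image:
   - RDR% = 100 · (feature pixels) / (fruit pixels),
   - length = vertical pixel extent × mm/px, width = horizontal extent
     (fruit must be staged upright — length is image-vertical by definition),
   - area = pixel count × (mm/px)²,
   - optionally a **color profile**: darkest / median / brightest feature
     colors matched to the nearest named chart color in CIELAB.

   The mm/px scale comes from a size reference of known physical length
   (coin, ruler edge) photographed in every frame at fixed camera height.
5. **Output** — a results CSV (one summary row per image plus one row per
   fruit) and a `settings.json` sidecar echoing the exact configuration, so
   any run can be reproduced byte-for-byte.

A synthetic-scene generator (`fruitpheno.synthetic`) renders staged
photographs with exact ground truth — berries as ellipses of packed drupelet
discs with a known reverted fraction, debris specks, and a reference bar —
so the whole pipeline is testable without real photo sets.

## Worked example

Generate two hard-edged synthetic scenes and analyze them:

```sh
fruitpheno simulate --n-scenes 2 --f 0.2 --seed 3 --out demo/ --hard-edges
fruitpheno analyze --config cfg.yaml --input demo/ --output results.csv
```

with `cfg.yaml`:

```yaml
background:
  - {space: lab, channel: a, min: -10.0}   # fruit: a* above -10, L and b FR
features:
  rdr:
    - {space: lab, channel: a, min: 16.15} # reverted red: a* above 16.15
exclude_region: {top: 0.85, left: 0.0, bottom: 1.0, right: 1.0}
reference_length_mm: 50.0                  # the 160-px reference bar is 50 mm
reference_px: 160.0
normalize: false
sharpen_amount: 0.0
denoise_radius: 0
background_despeckle_radius: 0
feature_despeckle_radius: 0
min_object_area: 50
```

The run prints `processed 2 images, 6 fruit objects` and `results.csv`
begins:

```
image_id,object_label,n_pixels,length_mm,width_mm,area_mm2,rdr_pct,color_min_name,color_median_name,color_max_name,flags,status
scene_000.png,0,7219,,,,6.6076,,,,,ok
scene_000.png,1,2588,20.625,15.625,252.7344,10.5873,,,,,ok
scene_000.png,2,2587,20.625,15.9375,252.6367,7.6537,,,,,ok
scene_000.png,3,2039,18.125,13.75,199.1211,0.0,,,,,ok
```

Row `object_label=0` is the image summary: 7219 fruit pixels of which
6.61% are reverted-red. Rows 1–3 are the individual berries: e.g. berry 1
is 20.6 mm long, 15.6 mm wide, 252.7 mm² of visible area, with 10.6% of its
pixels reverted. On hard-edged scenes these values equal the generator's
ground truth exactly.

## Library surface

```python
from fruitpheno import (
    rgb_to_lab, apply_threshold, ThresholdSpec, ChannelInterval,  # color model
    downsize, normalize_contrast, enhance,                        # preprocessing
    remove_background, detect_feature, despeckle, label_objects,  # segmentation
    calibrate_scale, measure_object, feature_fraction, color_profile,
    PipelineConfig, load_config, process_image, process_batch,    # batch layer
    default_scene, render_scene,                                  # synthetic truth
)
```

See `docs/methods.md` for the measurement conventions, parameter defaults,
and the limitations of the synthetic validation.
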