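"""Calibrated per-fruit and per-image trait measurement.

Converts masks and object labels into the traits a breeder records:

* **Length / width** — the vertical and horizontal pixel extents of each
  object's bounding box, converted to millimetres via the size
  reference.  Length is deliberately the *image-vertical* extent (top
  fruit pixel to bottom fruit pixel), not the major axis, so results are
  orientation dependent: fruit must be staged upright.  A
  ``length_mode="major_axis"`` option is available for free-orientation
  protocols.
* **Feature fraction** — feature pixels over fruit pixels, per image and
  per object; the pixel-fraction definition of red drupelet reversion
  severity.
* **Color profile** — the darkest, median, and brightest colors among
  feature pixels, each matched to the nearest entry of a bundled
  named-color table (an approximation of the RHS colour chart) by
  Euclidean distance in CIELAB.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from skimage import measure as _skmeasure

from .color_model import rgb_to_lab
from .segment import LabeledObjects


class CalibrationError(ValueError):
    """Invalid or missing size calibration."""


@dataclass(frozen=True)
class Calibration:
    """Pixel-to-millimetre scale from an in-photo size reference.

    ``reference_px`` is the reference object's pixel extent as measured
    on the image it was digitized from; if that was the original (not yet
    downsized) photo, pass the downsize ``scale`` so the ratio refers to
    working-resolution pixels.  The camera height is assumed fixed across
    the batch — the single calibration is applied to every image.
    """

    reference_length_mm: float
    reference_px: float
    mm_per_px: float

    @property
    def mm2_per_px2(self) -> float:
        return self.mm_per_px**2


def calibrate_scale(
    reference_length_mm: float,
    reference_px: float,
    downsize_scale: float = 1.0,
) -> Calibration:
    """Derive mm-per-pixel from a reference of known physical length.

    ``downsize_scale`` is the factor by which the image was shrunk after
    the reference was measured (1.0 if measured at working resolution):
    a 50 mm reference spanning 200 px, downsized 2× (scale 0.5), yields
    0.5 mm/px.
    """
    if reference_length_mm <= 0 or reference_px <= 0 or downsize_scale <= 0:
        raise CalibrationError(
            "reference_length_mm, reference_px and downsize_scale must all be positive "
            f"(got {reference_length_mm}, {reference_px}, {downsize_scale})"
        )
    return Calibration(
        reference_length_mm=reference_length_mm,
        reference_px=reference_px,
        mm_per_px=reference_length_mm / (reference_px * downsize_scale),
    )


def measure_object(
    labels: LabeledObjects,
    k: int,
    cal: Calibration,
    length_mode: str = "vertical",
) -> tuple[float, float, float]:
    """Calibrated (length_mm, width_mm, area_mm2) of object ``k``.

    Pixel extents are inclusive (+1), so a single-pixel object has size
    one pixel, not zero.  ``length_mode="vertical"`` (default) measures
    the uppermost-to-lowest fruit pixel along the image's vertical axis;
    ``"major_axis"`` instead reports the ellipse-fit major/minor axis
    lengths, which are orientation independent.
    """
    if k not in labels.pixel_counts:
        raise KeyError(f"object {k} not present")
    area_mm2 = labels.pixel_counts[k] * cal.mm2_per_px2
    if length_mode == "major_axis":
        props = _skmeasure.regionprops(labels.mask_of(k).astype(np.uint8))[0]
        return (
            props.axis_major_length * cal.mm_per_px,
            props.axis_minor_length * cal.mm_per_px,
            area_mm2,
        )
    if length_mode != "vertical":
        raise ValueError(f"length_mode must be 'vertical' or 'major_axis', got {length_mode!r}")
    min_row, min_col, max_row, max_col = labels.bboxes[k]
    length_px = max_row - min_row + 1
    width_px = max_col - min_col + 1
    return (length_px * cal.mm_per_px, width_px * cal.mm_per_px, area_mm2)


def feature_fraction(
    fruit: np.ndarray,
    feature: np.ndarray,
    labels: LabeledObjects | None = None,
) -> tuple[float, dict[int, float]]:
    """Feature pixels over fruit pixels, as percentages.

    Returns the per-image percentage and, when ``labels`` is given, a
    per-object percentage for each labeled object.  An empty fruit mask
    yields 0.0 (there is nothing to be a fraction of).  The ratio is a
    pure pixel count and needs no calibration.
    """
    fruit = np.asarray(fruit, dtype=bool)
    feature = np.asarray(feature, dtype=bool)
    if (feature & ~fruit).any():
        raise ValueError("feature mask must be a subset of the fruit mask")
    n_fruit = int(fruit.sum())
    image_pct = 100.0 * int(feature.sum()) / n_fruit if n_fruit else 0.0
    per_object: dict[int, float] = {}
    if labels is not None:
        for k, n in labels.pixel_counts.items():
            n_feat = int(feature[labels.labels == k].sum())
            per_object[k] = 100.0 * n_feat / n if n else 0.0
    return image_pct, per_object


# ---------------------------------------------------------------------------
# Named-color profile


@dataclass(frozen=True)
class ColorMatch:
    name: str
    distance: float  # Euclidean in CIELAB


@dataclass(frozen=True)
class ColorProfile:
    """Darkest / median / brightest feature colors with chart names.

    min/max are the actual feature pixels of lowest and highest L*
    lightness (ties broken lexicographically by RGB); median is the
    channel-wise median pixel value.  Each is matched to the nearest
    named chart color in CIELAB.
    """

    min_rgb: tuple[int, int, int]
    median_rgb: tuple[int, int, int]
    max_rgb: tuple[int, int, int]
    min_match: ColorMatch
    median_match: ColorMatch
    max_match: ColorMatch


class ColorTable:
    """Named-color lookup table for chart-descriptor matching.

    Loaded from a CSV with columns ``name, L, a, b``.  Matching operates
    on each entry's CIELAB coordinates *after* rendering to 8-bit sRGB
    and back: chart entries are compared in the same quantized gamut as
    the camera pixels, so a patch displaying an entry's sRGB color
    matches it at distance exactly zero.
    """

    def __init__(self, names: list[str], lab: np.ndarray):
        if len(names) != len(lab):
            raise ValueError("names and Lab rows differ in length")
        self.names = list(names)
        self.lab_nominal = np.asarray(lab, dtype=np.float64)
        self.srgb = np.array([lab_entry_to_rgb8(row) for row in self.lab_nominal])
        self.lab_matching = rgb_to_lab(self.srgb)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ColorTable":
        names: list[str] = []
        rows: list[list[float]] = []
        with open(path, newline="") as fh:
            reader = csv.DictReader(row for row in fh if not row.startswith("#"))
            for rec in reader:
                names.append(rec["name"])
                rows.append([float(rec["L"]), float(rec["a"]), float(rec["b"])])
        if not names:
            raise ValueError(f"color table {path} contains no entries")
        return cls(names, np.array(rows))

    @classmethod
    def bundled(cls) -> "ColorTable":
        with resources.as_file(
            resources.files("fruitpheno").joinpath("data/color_table.csv")
        ) as p:
            return cls.from_csv(p)

    def rgb_of(self, name: str) -> tuple[int, int, int]:
        """8-bit sRGB rendering of a named entry."""
        return tuple(int(v) for v in self.srgb[self.names.index(name)])

    def nearest(self, lab: np.ndarray) -> ColorMatch:
        """Nearest entry to a CIELAB triple, by Euclidean distance."""
        d = np.sqrt(((self.lab_matching - np.asarray(lab, dtype=np.float64)) ** 2).sum(axis=1))
        i = int(np.argmin(d))
        return ColorMatch(name=self.names[i], distance=float(d[i]))


def lab_entry_to_rgb8(lab: np.ndarray) -> np.ndarray:
    """Render a CIELAB triple to 8-bit sRGB (gamut-clipped)."""
    from skimage import color as _skcolor

    rgb = _skcolor.lab2rgb(np.asarray(lab, dtype=np.float64).reshape(1, 1, 3))
    return np.clip(np.rint(rgb[0, 0] * 255.0), 0, 255).astype(np.uint8)


def color_profile(
    img: np.ndarray,
    feature: np.ndarray,
    table: ColorTable | None = None,
) -> ColorProfile | None:
    """Summarize the colors of the feature region against the chart table.

    Returns ``None`` for an empty feature mask (the caller flags the
    record instead of erroring).
    """
    feature = np.asarray(feature, dtype=bool)
    if not feature.any():
        return None
    if table is None:
        table = ColorTable.bundled()
    pixels = np.asarray(img)[feature].astype(np.uint8)  # N×3
    lab = rgb_to_lab(pixels)
    lightness = lab[:, 0]

    # ties on L* broken lexicographically by (R, G, B)
    order = np.lexsort((pixels[:, 2], pixels[:, 1], pixels[:, 0], lightness))
    p_min = tuple(int(v) for v in pixels[order[0]])
    p_max = tuple(int(v) for v in pixels[order[-1]])
    p_med = tuple(
        int(np.percentile(pixels[:, c], 50, method="nearest")) for c in range(3)
    )

    def match(p: tuple[int, int, int]) -> ColorMatch:
        return table.nearest(rgb_to_lab(np.array(p, dtype=np.uint8)))

    return ColorProfile(
        min_rgb=p_min,
        median_rgb=p_med,
        max_rgb=p_max,
        min_match=match(p_min),
        median_match=match(p_med),
        max_match=match(p_max),
    )
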