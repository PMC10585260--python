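"""Synthetic staged-photograph generator with exact ground truth.

Renders scenes emulating the staging protocol the pipeline targets:
dark aggregate fruit (ellipses packed with drupelet discs, a known
fraction of which are drawn in a "reverted" red) on a green cutting
board, plus juice/debris specks and a reference bar of declared
millimetre length in a strip that the pipeline is configured to crop
out.  Every pixel of a hard-rendered scene is exactly one of the four
palette colors, so oracle counts (fruit pixels, reverted pixels, object
extents) are exact; with anti-aliasing on, geometry is rendered at 2×
and block-averaged, giving realistic soft boundaries.

The palette is chosen so the CIELAB a* values straddle the background /
fruit / reverted thresholds used in practice (board a* ≈ −33 < −12;
black drupelet a* ≈ +5, between −8.5 and +7.51; reverted a* ≈ +45 >
16.15); :func:`validate_palette` asserts this at scene-render time via
the color model itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .color_model import rgb_to_lab
from .preprocess import ImageRGB

#: Default palette (sRGB).
BACKGROUND_RGB = (60, 120, 60)
BLACK_DRUPELET_RGB = (25, 15, 20)
REVERTED_RGB = (150, 40, 40)
REFERENCE_BAR_RGB = (235, 235, 235)

# palette indices in the hard render
_BG, _BLACK, _RED, _BAR = 0, 1, 2, 3


class SceneError(ValueError):
    """Scene specification cannot be rendered (e.g. berries cannot fit)."""


@dataclass(frozen=True)
class BerrySpec:
    """One berry: an ellipse of packed drupelet discs."""

    center: tuple[float, float]  # (row, col)
    radii: tuple[float, float]  # (vertical, horizontal) semi-axes, px
    drupelet_radius: float = 5.0
    reverted_fraction: float = 0.15


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one synthetic staged photograph.

    The reference bar lives in the bottom strip of the image (below
    ``bar_strip_top`` as a fraction of height); analysis configs exclude
    that strip, mirroring the protocol of cropping out the area around
    the size reference.  ``seed`` fixes the scene exactly.
    """

    height: int = 360
    width: int = 480
    background_rgb: tuple[int, int, int] = BACKGROUND_RGB
    black_rgb: tuple[int, int, int] = BLACK_DRUPELET_RGB
    reverted_rgb: tuple[int, int, int] = REVERTED_RGB
    bar_rgb: tuple[int, int, int] = REFERENCE_BAR_RGB
    berries: tuple[BerrySpec, ...] = field(default_factory=tuple)
    n_specks: int = 0
    speck_radius: float = 0.5  # ~single-pixel juice droplets
    bar_strip_top: float = 0.85
    bar_length_px: float = 160.0
    bar_thickness_px: float = 8.0
    bar_length_mm: float = 50.0
    anti_alias: bool = False
    seed: int = 0

    @property
    def mm_per_px(self) -> float:
        return self.bar_length_mm / self.bar_length_px

    @property
    def exclusion_top(self) -> float:
        """Fractional top of the strip analysis configs should exclude."""
        return self.bar_strip_top

    def scaled(self, factor: float) -> "SceneSpec":
        """Same scene geometry at ``factor``× resolution (same mm length)."""
        return replace(
            self,
            height=int(round(self.height * factor)),
            width=int(round(self.width * factor)),
            berries=tuple(
                replace(
                    b,
                    center=(b.center[0] * factor, b.center[1] * factor),
                    radii=(b.radii[0] * factor, b.radii[1] * factor),
                    drupelet_radius=b.drupelet_radius * factor,
                )
                for b in self.berries
            ),
            speck_radius=self.speck_radius * factor,
            bar_length_px=self.bar_length_px * factor,
            bar_thickness_px=self.bar_thickness_px * factor,
        )


@dataclass
class SceneTruth:
    """Exact ground truth for a rendered scene (at hard-render resolution)."""

    berry_masks: list[np.ndarray]  # per-berry boolean masks (full frame)
    reverted_counts: list[int]  # per-berry reverted-pixel counts
    bboxes: list[tuple[int, int, int, int]]  # (min_r, min_c, max_r, max_c) inclusive
    mm_per_px: float
    n_fruit_pixels: int
    n_reverted_pixels: int

    @property
    def reverted_fraction(self) -> float:
        """True reverted-pixel fraction of all fruit pixels (0-1)."""
        return self.n_reverted_pixels / self.n_fruit_pixels if self.n_fruit_pixels else 0.0

    def berry_length_mm(self, i: int) -> float:
        r0, _, r1, _ = self.bboxes[i]
        return (r1 - r0 + 1) * self.mm_per_px

    def berry_width_mm(self, i: int) -> float:
        _, c0, _, c1 = self.bboxes[i]
        return (c1 - c0 + 1) * self.mm_per_px


def scene_analysis_config(spec: SceneSpec, *, exact: bool = False, **overrides):
    """Canonical pipeline configuration for analyzing rendered scenes.

    Thresholds are a representative year of settings (background
    a* > −10, reversion a* > 16.15), the reference-bar strip is
    excluded, and the bar provides the calibration.  ``exact=True``
    disables enhancement and despeckling for hard-edged, speck-free
    scenes where pixel counts must match ground truth exactly; the
    default keeps sharpening on (it hardens anti-aliased boundaries)
    but median denoising off, since rendered scenes carry no sensor
    noise for it to remove.
    """
    from .batch import PipelineConfig
    from .color_model import ChannelInterval, ThresholdSpec
    from .preprocess import CropRegion

    kwargs = dict(
        background=ThresholdSpec((ChannelInterval("a", lo=-10.0),)),
        features={"rdr": ThresholdSpec((ChannelInterval("a", lo=16.15),))},
        normalize=False,
        sharpen_amount=0.0 if exact else 1.0,
        denoise_radius=0,
        background_despeckle_radius=0 if exact else 2,
        feature_despeckle_radius=0 if exact else 2,
        exclude_region=CropRegion(top=spec.exclusion_top, left=0.0, bottom=1.0, right=1.0),
        reference_length_mm=spec.bar_length_mm,
        reference_px=spec.bar_length_px,
        min_object_area=50,
    )
    kwargs.update(overrides)
    return PipelineConfig(**kwargs)


def default_scene(
    seed: int = 0,
    n_berries: int = 3,
    reverted_fraction: float = 0.15,
    n_specks: int = 5,
    anti_alias: bool = False,
    height: int = 360,
    width: int = 480,
) -> SceneSpec:
    """Randomly place non-overlapping berries in the staging area.

    Berry semi-axes are drawn from realistic staged-photo ranges
    (roughly 12-18 mm long fruit at the default 0.25 mm/px scale); the
    bottom strip is reserved for the reference bar.
    """
    rng = np.random.default_rng(seed)
    strip_top = 0.85
    usable_h = int(height * strip_top)
    berries: list[BerrySpec] = []
    attempts = 0
    while len(berries) < n_berries:
        attempts += 1
        if attempts > 500:
            raise SceneError(
                f"could not place {n_berries} non-overlapping berries in "
                f"{width}×{usable_h}; reduce count or size"
            )
        ry = rng.uniform(28, 40)
        rx = rng.uniform(20, 30)
        cy = rng.uniform(ry + 4, usable_h - ry - 4)
        cx = rng.uniform(rx + 4, width - rx - 4)
        ok = True
        for b in berries:
            dy, dx = cy - b.center[0], cx - b.center[1]
            min_gap = max(ry, rx) + max(b.radii) + 6
            if dy * dy + dx * dx < min_gap * min_gap:
                ok = False
                break
        if ok:
            berries.append(
                BerrySpec(
                    center=(cy, cx),
                    radii=(ry, rx),
                    drupelet_radius=float(rng.uniform(4.5, 6.0)),
                    reverted_fraction=reverted_fraction,
                )
            )
    return SceneSpec(
        height=height,
        width=width,
        berries=tuple(berries),
        n_specks=n_specks,
        bar_strip_top=strip_top,
        anti_alias=anti_alias,
        seed=seed,
    )


def validate_palette(spec: SceneSpec) -> None:
    """Assert the palette a* values straddle the working thresholds."""
    a_bg = rgb_to_lab(np.array(spec.background_rgb, dtype=np.uint8))[1]
    a_black = rgb_to_lab(np.array(spec.black_rgb, dtype=np.uint8))[1]
    a_red = rgb_to_lab(np.array(spec.reverted_rgb, dtype=np.uint8))[1]
    if not (a_bg < -12.0 < -8.5 < a_black < 7.51 < 16.15 < a_red):
        raise SceneError(
            "palette a* values do not straddle the background/fruit/reverted "
            f"thresholds: background {a_bg:.1f}, black {a_black:.1f}, red {a_red:.1f}"
        )


def _hex_disc_centers(
    berry: BerrySpec, frame: tuple[int, int]
) -> list[tuple[float, float, bool]]:
    """Hexagonally packed drupelet centers inside the berry ellipse.

    Returns (row, col, is_reverted).  The reversion RNG is seeded from
    the berry center *normalized by the frame size*, and the hex grid
    shape depends only on radius ratios, so re-rendering the same scene
    at k× resolution reverts the same discs.
    """
    cy, cx = berry.center
    ry, rx = berry.radii
    rd = berry.drupelet_radius
    step_x = rd * 1.9
    step_y = rd * 1.9 * np.sqrt(3) / 2
    centers: list[tuple[float, float, bool]] = []
    n_rows = int(np.ceil(2 * ry / step_y)) + 1
    n_cols = int(np.ceil(2 * rx / step_x)) + 1
    h, w = frame
    rng = np.random.default_rng(
        abs(hash((round(cy / h, 9), round(cx / w, 9)))) % (2**31)
    )
    for i in range(n_rows):
        for j in range(n_cols):
            y = cy - ry + i * step_y
            x = cx - rx + j * step_x + (step_x / 2 if i % 2 else 0.0)
            # keep disc fully inside the ellipse (margin of one radius)
            ey = (y - cy) / max(ry - rd, 1e-9)
            ex = (x - cx) / max(rx - rd, 1e-9)
            reverted = bool(rng.random() < berry.reverted_fraction)
            if ey * ey + ex * ex <= 1.0:
                centers.append((y, x, reverted))
    return centers


def _render_hard(spec: SceneSpec, scale: int = 1) -> np.ndarray:
    """Palette-index raster at ``scale``× the spec's resolution.

    Pixel (i, j) takes the palette index of the shape covering its
    center — integer rasterization, fully deterministic.
    """
    s = spec.scaled(scale) if scale != 1 else spec
    h, w = s.height, s.width
    idx = np.full((h, w), _BG, dtype=np.uint8)
    rows = np.arange(h)[:, None] + 0.5
    cols = np.arange(w)[None, :] + 0.5

    for berry in s.berries:
        cy, cx = berry.center
        ry, rx = berry.radii
        inside = ((rows - cy) / ry) ** 2 + ((cols - cx) / rx) ** 2 <= 1.0
        idx[inside] = _BLACK
        for y, x, reverted in _hex_disc_centers(berry, (h, w)):
            if not reverted:
                continue
            rd = berry.drupelet_radius
            r0, r1 = max(0, int(y - rd - 1)), min(h, int(y + rd + 2))
            c0, c1 = max(0, int(x - rd - 1)), min(w, int(x + rd + 2))
            sub_r = rows[r0:r1, :]
            sub_c = cols[:, c0:c1]
            disc = (sub_r - y) ** 2 + (sub_c - x) ** 2 <= rd * rd
            patch = idx[r0:r1, c0:c1]
            patch[disc & (patch == _BLACK)] = _RED

    # juice/debris specks on the background, reverted-red colored;
    # drawn in base coordinates then scaled, so 1x and 2x renders agree
    rng = np.random.default_rng(spec.seed + 77_000)
    base_usable_h = int(spec.height * spec.bar_strip_top)
    for _ in range(s.n_specks):
        y = rng.uniform(2, base_usable_h - 2) * scale
        x = rng.uniform(2, spec.width - 2) * scale
        sr = s.speck_radius
        r0, r1 = max(0, int(y - sr - 1)), min(h, int(y + sr + 2))
        c0, c1 = max(0, int(x - sr - 1)), min(w, int(x + sr + 2))
        disc = (rows[r0:r1, :] - y) ** 2 + (cols[:, c0:c1] - x) ** 2 <= max(sr, 0.5) ** 2
        patch = idx[r0:r1, c0:c1]
        patch[disc & (patch == _BG)] = _RED

    # reference bar centered in the bottom strip
    strip_mid = (s.bar_strip_top + 1.0) / 2 * s.height
    bar_r0 = strip_mid - s.bar_thickness_px / 2
    bar_r1 = strip_mid + s.bar_thickness_px / 2
    bar_c0 = s.width / 2 - s.bar_length_px / 2
    bar_c1 = s.width / 2 + s.bar_length_px / 2
    if bar_r0 < s.bar_strip_top * s.height:
        raise SceneError("reference bar does not fit inside its strip")
    bar = (rows >= bar_r0) & (rows < bar_r1) & (cols >= bar_c0) & (cols < bar_c1)
    if (bar & (idx != _BG)).any():
        raise SceneError("reference bar overlaps a berry or speck")
    idx[bar] = _BAR
    return idx


def _palette(spec: SceneSpec) -> np.ndarray:
    return np.array(
        [spec.background_rgb, spec.black_rgb, spec.reverted_rgb, spec.bar_rgb],
        dtype=np.uint8,
    )


def render_scene(spec: SceneSpec) -> tuple[ImageRGB, SceneTruth]:
    """Render the scene and its exact ground truth.

    Deterministic given ``spec`` (including its seed).  With
    ``anti_alias=False`` every pixel is exactly one palette color and
    the truth is consistent with the image pixel-for-pixel; with
    ``anti_alias=True`` the image is a 2× render block-averaged down,
    while the truth still refers to the hard 1× rasterization.
    """
    validate_palette(spec)
    idx1 = _render_hard(spec, scale=1)
    palette = _palette(spec)
    if spec.anti_alias:
        idx2 = _render_hard(spec, scale=2)
        rgb2 = palette[idx2].astype(np.float64)
        h, w = spec.height, spec.width
        rgb = rgb2.reshape(h, 2, w, 2, 3).mean(axis=(1, 3))
        pixels = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)
    else:
        pixels = palette[idx1]

    berry_masks: list[np.ndarray] = []
    reverted_counts: list[int] = []
    bboxes: list[tuple[int, int, int, int]] = []
    rows = np.arange(spec.height)[:, None] + 0.5
    cols = np.arange(spec.width)[None, :] + 0.5
    fruitish = (idx1 == _BLACK) | (idx1 == _RED)
    for berry in spec.berries:
        cy, cx = berry.center
        ry, rx = berry.radii
        ellipse = ((rows - cy) / ry) ** 2 + ((cols - cx) / rx) ** 2 <= 1.0
        mask = ellipse & fruitish
        if not mask.any():
            raise SceneError(f"berry at {berry.center} rasterized to zero pixels")
        berry_masks.append(mask)
        reverted_counts.append(int((mask & (idx1 == _RED)).sum()))
        rr, cc = np.nonzero(mask)
        bboxes.append((int(rr.min()), int(cc.min()), int(rr.max()), int(cc.max())))

    # fruit/reverted totals count berry pixels only, never debris specks
    truth = SceneTruth(
        berry_masks=berry_masks,
        reverted_counts=reverted_counts,
        bboxes=bboxes,
        mm_per_px=spec.mm_per_px,
        n_fruit_pixels=int(sum(m.sum() for m in berry_masks)),
        n_reverted_pixels=int(sum(reverted_counts)),
    )
    img = ImageRGB(pixels=pixels, source_path=f"<synthetic seed={spec.seed}>")
    return img, truth


def truth_report(truth: SceneTruth, records: list[dict]) -> dict:
    """Compare pipeline per-object records against scene ground truth.

    ``records`` are per-object dicts with keys ``length_mm``,
    ``width_mm`` and a feature percentage column; objects are matched to
    true berries by bounding-box center proximity.  A count mismatch is
    reported in the result, never raised.
    """
    n_true = len(truth.berry_masks)
    report: dict = {
        "n_true": n_true,
        "n_detected": len(records),
        "count_mismatch": len(records) != n_true,
        "length_errors_mm": [],
        "width_errors_mm": [],
    }
    true_centers = [((b[0] + b[2]) / 2, (b[1] + b[3]) / 2) for b in truth.bboxes]
    for rec in records:
        bbox = rec.get("bbox")
        if bbox is None or not true_centers:
            continue
        cy, cx = (bbox[0] + bbox[2]) / 2, (bbox[1] + bbox[3]) / 2
        i = int(
            np.argmin([(cy - ty) ** 2 + (cx - tx) ** 2 for ty, tx in true_centers])
        )
        report["length_errors_mm"].append(
            abs(rec["length_mm"] - truth.berry_length_mm(i))
        )
        report["width_errors_mm"].append(abs(rec["width_mm"] - truth.berry_width_mm(i)))
    for key in ("length_errors_mm", "width_errors_mm"):
        errs = report[key]
        report[key.replace("errors", "max_error")] = max(errs) if errs else None
        report[key.replace("errors", "mean_error")] = (
            float(np.mean(errs)) if errs else None
        )
    return report


def write_scenes(
    out_dir: str | Path,
    n_scenes: int,
    reverted_fraction: float = 0.15,
    seed: int = 0,
    anti_alias: bool = True,
) -> list[Path]:
    """Write PNG scenes plus a truth JSON sidecar (CLI `simulate` verb)."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    truths: dict[str, dict] = {}
    for i in range(n_scenes):
        spec = default_scene(
            seed=seed + i, reverted_fraction=reverted_fraction, anti_alias=anti_alias
        )
        img, truth = render_scene(spec)
        name = f"scene_{i:03d}.png"
        Image.fromarray(img.pixels).save(out / name)
        truths[name] = {
            "reverted_fraction": truth.reverted_fraction,
            "mm_per_px": truth.mm_per_px,
            "n_fruit_pixels": truth.n_fruit_pixels,
            "berry_lengths_mm": [
                truth.berry_length_mm(i) for i in range(len(truth.bboxes))
            ],
            "berry_widths_mm": [
                truth.berry_width_mm(i) for i in range(len(truth.bboxes))
            ],
        }
        paths.append(out / name)
    (out / "truth.json").write_text(json.dumps(truths, indent=2))
    return paths
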