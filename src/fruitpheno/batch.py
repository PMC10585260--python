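"""Batch orchestration: configuration, per-image processing, CSV output.

The repeatability contract: a batch run is a pure function of (image
directory, configuration).  Images are processed in lexicographic
filename order; the results CSV is accompanied by a ``settings.json``
sidecar echoing the exact configuration and tool version, so any run can
be replayed bit-for-bit.  Per-image failures (unreadable files, empty
segmentations) are captured as status rows, never aborting the batch.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .color_model import ChannelInterval, ThresholdSpec
from .measure import (
    Calibration,
    CalibrationError,
    ColorTable,
    calibrate_scale,
    color_profile,
    feature_fraction,
    measure_object,
)
from .preprocess import ConfigurationError, CropRegion, ImageRGB, load_image, preprocess
from .segment import detect_feature, label_objects, remove_background

logger = logging.getLogger(__name__)

_SPACE_CHANNELS = {
    "rgb": {"r": "R", "g": "G", "b": "B"},
    "hsb": {"h": "H", "s": "S", "v": "V", "b": "V"},
    "lab": {"l": "L", "a": "a", "b": "b"},
}

SIZE_TRAITS = {"length", "width", "area"}
KNOWN_TRAITS = SIZE_TRAITS | {"feature_pct", "color_profile"}

#: area > this multiple of the median object area flags a merged-berry suspect
MERGED_SUSPECT_FACTOR = 2.5


class ConfigError(ValueError):
    """Configuration file violates the schema; message lists every offense."""


def _interval_from_dict(d: dict) -> ChannelInterval:
    errs = []
    space = d.get("space")
    chan = d.get("channel")
    if space not in _SPACE_CHANNELS:
        errs.append(f"unknown colorspace {space!r} (expected rgb/hsb/lab)")
    elif str(chan).lower() not in _SPACE_CHANNELS[space] and chan not in _SPACE_CHANNELS[space]:
        errs.append(f"unknown channel {chan!r} for space {space!r}")
    unknown = set(d) - {"space", "channel", "min", "max", "min_inclusive", "max_inclusive"}
    if unknown:
        errs.append(f"unknown threshold keys: {sorted(unknown)}")
    if errs:
        raise ConfigError("; ".join(errs))
    mapping = _SPACE_CHANNELS[space]
    channel = mapping.get(chan, mapping.get(str(chan).lower()))
    return ChannelInterval(
        channel=channel,
        lo=d.get("min"),
        hi=d.get("max"),
        lo_strict=not d.get("min_inclusive", False),
        hi_strict=not d.get("max_inclusive", False),
    )


def _interval_to_dict(iv: ChannelInterval) -> dict:
    space = {"R": "rgb", "G": "rgb", "B": "rgb", "H": "hsb", "S": "hsb", "V": "hsb"}.get(
        iv.channel, "lab"
    )
    chan = iv.channel.lower() if space != "lab" else iv.channel
    if space == "lab":
        chan = {"L": "L", "a": "a", "b": "b"}[iv.channel]
    d: dict = {"space": space, "channel": chan}
    if iv.lo is not None:
        d["min"] = iv.lo
        if not iv.lo_strict:
            d["min_inclusive"] = True
    if iv.hi is not None:
        d["max"] = iv.hi
        if not iv.hi_strict:
            d["max_inclusive"] = True
    return d


@dataclass
class PipelineConfig:
    """Validated settings for one batch run.

    Threshold specs follow the settings-table idiom: channels not
    mentioned are full-range ("FR"), and bounds are strict inequalities
    unless marked inclusive.  A whole year's settings row — e.g.
    background a > −10.00, reversion a > 7.51, everything else FR — is
    expressible verbatim.
    """

    background: ThresholdSpec
    features: dict[str, ThresholdSpec] = field(default_factory=dict)
    max_dim: int = 1500
    normalize: bool = True
    sharpen_amount: float = 1.0
    denoise_radius: int = 1
    exclude_region: CropRegion | None = None
    background_despeckle_radius: int = 2
    feature_despeckle_radius: int = 2
    min_object_area: int = 50
    reference_length_mm: float | None = None
    reference_px: float | None = None
    traits: tuple[str, ...] = ("length", "width", "area", "feature_pct")
    color_table_path: str | None = None
    random_seed: int = 0
    version: str = __version__

    def __post_init__(self) -> None:
        errs = []
        unknown_traits = set(self.traits) - KNOWN_TRAITS
        if unknown_traits:
            errs.append(f"unknown traits: {sorted(unknown_traits)} (known: {sorted(KNOWN_TRAITS)})")
        if SIZE_TRAITS & set(self.traits):
            if self.reference_length_mm is None or self.reference_px is None:
                errs.append(
                    "size traits requested but calibration missing: set both "
                    "reference_length_mm and reference_px"
                )
        if self.min_object_area < 1:
            errs.append(f"min_object_area must be >= 1, got {self.min_object_area}")
        if self.max_dim < 1:
            errs.append(f"max_dim must be >= 1, got {self.max_dim}")
        for r in (self.background_despeckle_radius, self.feature_despeckle_radius):
            if r < 0:
                errs.append(f"despeckle radius must be >= 0, got {r}")
        if errs:
            raise ConfigError("; ".join(errs))
        self.traits = tuple(self.traits)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d: dict = {
            "background": [_interval_to_dict(iv) for iv in self.background.intervals],
            "features": {
                name: [_interval_to_dict(iv) for iv in spec.intervals]
                for name, spec in self.features.items()
            },
            "max_dim": self.max_dim,
            "normalize": self.normalize,
            "sharpen_amount": self.sharpen_amount,
            "denoise_radius": self.denoise_radius,
            "background_despeckle_radius": self.background_despeckle_radius,
            "feature_despeckle_radius": self.feature_despeckle_radius,
            "min_object_area": self.min_object_area,
            "traits": list(self.traits),
            "random_seed": self.random_seed,
            "version": self.version,
        }
        if self.exclude_region is not None:
            d["exclude_region"] = dataclasses.asdict(self.exclude_region)
        if self.reference_length_mm is not None:
            d["reference_length_mm"] = self.reference_length_mm
        if self.reference_px is not None:
            d["reference_px"] = self.reference_px
        if self.color_table_path is not None:
            d["color_table_path"] = self.color_table_path
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        if "background" not in d:
            raise ConfigError("missing required key: background")
        kwargs: dict = {}
        kwargs["background"] = ThresholdSpec(
            tuple(_interval_from_dict(iv) for iv in d.pop("background"))
        )
        kwargs["features"] = {
            name: ThresholdSpec(tuple(_interval_from_dict(iv) for iv in ivs))
            for name, ivs in d.pop("features", {}).items()
        }
        if "exclude_region" in d:
            region = d.pop("exclude_region")
            kwargs["exclude_region"] = None if region is None else CropRegion(**region)
        if "traits" in d:
            kwargs["traits"] = tuple(d.pop("traits"))
        kwargs.update(d)
        try:
            return cls(**kwargs)
        except (ConfigurationError, CalibrationError, ValueError) as e:
            if isinstance(e, ConfigError):
                raise
            raise ConfigError(str(e)) from e

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def calibration(self, downsize_scale: float = 1.0) -> Calibration | None:
        if self.reference_length_mm is None or self.reference_px is None:
            return None
        return calibrate_scale(self.reference_length_mm, self.reference_px, downsize_scale)

    def color_table(self) -> ColorTable:
        if self.color_table_path:
            return ColorTable.from_csv(self.color_table_path)
        return ColorTable.bundled()


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"configuration root must be a mapping, got {type(data).__name__}")
    return PipelineConfig.from_dict(data)


# ---------------------------------------------------------------------------
# Per-image processing

#: Fixed results-CSV schema (feature percentage columns are inserted after
#: area_mm2, one per configured feature, named ``<feature>_pct``).
BASE_COLUMNS = [
    "image_id",
    "object_label",
    "n_pixels",
    "length_mm",
    "width_mm",
    "area_mm2",
    "color_min_name",
    "color_median_name",
    "color_max_name",
    "flags",
    "status",
]


def result_columns(cfg: PipelineConfig) -> list[str]:
    cols = BASE_COLUMNS[:6]
    if "feature_pct" in cfg.traits:
        cols += [f"{name}_pct" for name in cfg.features]
    return cols + BASE_COLUMNS[6:]


def process_image(
    img_or_path: ImageRGB | str | Path,
    cfg: PipelineConfig,
    image_id: str | None = None,
) -> tuple[list[dict], dict, dict[str, np.ndarray]]:
    """Run the full pipeline on one photograph.

    Returns (per-object rows, per-image summary row, masks).  Masks maps
    ``"fruit"``, ``"<feature>"`` → boolean arrays for preview/overlay
    output.  Deterministic: identical input and config give identical
    rows.
    """
    t0 = time.perf_counter()
    if isinstance(img_or_path, (str, Path)):
        image_id = image_id or Path(img_or_path).name
        try:
            img = load_image(img_or_path)
        except Exception as e:  # unreadable/corrupt file: record, don't raise
            logger.warning("could not decode %s: %s", img_or_path, e)
            return [], _status_row(image_id, cfg, status="decode_error"), {}
    else:
        img = img_or_path
        image_id = image_id or Path(img.source_path).name

    proc, exclusion = preprocess(
        img,
        max_dim=cfg.max_dim,
        normalize=cfg.normalize,
        sharpen_amount=cfg.sharpen_amount,
        denoise_radius=cfg.denoise_radius,
        exclude_region=cfg.exclude_region,
    )
    fruit = remove_background(
        proc.pixels, cfg.background, cfg.background_despeckle_radius, exclusion
    )
    masks: dict[str, np.ndarray] = {"fruit": fruit}
    feature_masks: dict[str, np.ndarray] = {}
    for name, spec in cfg.features.items():
        feature_masks[name] = detect_feature(
            proc.pixels, fruit, spec, cfg.feature_despeckle_radius
        )
        masks[name] = feature_masks[name]

    cal = cfg.calibration(downsize_scale=1.0)  # reference_px given at working scale
    want_size = bool(SIZE_TRAITS & set(cfg.traits))
    want_profile = "color_profile" in cfg.traits
    table = cfg.color_table() if want_profile else None

    labels = label_objects(fruit, cfg.min_object_area)
    image_pcts = {
        name: feature_fraction(fruit, fmask)[0] for name, fmask in feature_masks.items()
    }

    h, w = fruit.shape
    rows: list[dict] = []
    median_area = (
        float(np.median(list(labels.pixel_counts.values()))) if labels.n_objects else 0.0
    )
    for k in range(1, labels.n_objects + 1):
        rec: dict = {
            "image_id": image_id,
            "object_label": k,
            "n_pixels": labels.pixel_counts[k],
            "length_mm": "",
            "width_mm": "",
            "area_mm2": "",
            "status": "ok",
        }
        if want_size and cal is not None:
            length_mm, width_mm, area_mm2 = measure_object(labels, k, cal)
            rec["length_mm"] = round(length_mm, 4)
            rec["width_mm"] = round(width_mm, 4)
            rec["area_mm2"] = round(area_mm2, 4)
        obj_mask = labels.labels == k
        if "feature_pct" in cfg.traits:
            for name, fmask in feature_masks.items():
                n_feat = int((fmask & obj_mask).sum())
                rec[f"{name}_pct"] = round(100.0 * n_feat / labels.pixel_counts[k], 4)
        flags = []
        r0, c0, r1, c1 = labels.bboxes[k]
        if r0 == 0 or c0 == 0 or r1 == h - 1 or c1 == w - 1:
            flags.append("touches_border")
        if median_area and labels.pixel_counts[k] > MERGED_SUSPECT_FACTOR * median_area:
            flags.append("merged_suspect")
        rec["flags"] = "|".join(flags)
        rec["bbox"] = labels.bboxes[k]  # not serialized; used by truth_report
        if want_profile:
            obj_feature = np.zeros_like(obj_mask)
            for fmask in feature_masks.values():
                obj_feature |= fmask & obj_mask
            _fill_profile(rec, color_profile(proc.pixels, obj_feature, table))
        else:
            rec["color_min_name"] = rec["color_median_name"] = rec["color_max_name"] = ""
        rows.append(rec)

    summary = _status_row(
        image_id,
        cfg,
        status="ok" if fruit.any() else "empty_segmentation",
        n_pixels=int(fruit.sum()),
    )
    for name, pct in image_pcts.items():
        if "feature_pct" in cfg.traits:
            summary[f"{name}_pct"] = round(pct, 4)
    if want_profile:
        merged_feature = np.zeros_like(fruit)
        for fmask in feature_masks.values():
            merged_feature |= fmask
        _fill_profile(summary, color_profile(proc.pixels, merged_feature, table))
    logger.info(
        "%s: %d objects, %d fruit px, %.2fs",
        image_id,
        labels.n_objects,
        int(fruit.sum()),
        time.perf_counter() - t0,
    )
    return rows, summary, masks


def _fill_profile(rec: dict, prof) -> None:
    if prof is None:
        rec["color_min_name"] = rec["color_median_name"] = rec["color_max_name"] = ""
        flags = rec.get("flags", "")
        rec["flags"] = "|".join(filter(None, [flags, "empty_feature"]))
    else:
        rec["color_min_name"] = prof.min_match.name
        rec["color_median_name"] = prof.median_match.name
        rec["color_max_name"] = prof.max_match.name


def _status_row(image_id: str, cfg: PipelineConfig, status: str, n_pixels: int = 0) -> dict:
    row = {
        "image_id": image_id,
        "object_label": 0,  # 0 marks the per-image summary row
        "n_pixels": n_pixels,
        "length_mm": "",
        "width_mm": "",
        "area_mm2": "",
        "flags": "",
        "status": status,
    }
    if "feature_pct" in cfg.traits:
        for name in cfg.features:
            row.setdefault(f"{name}_pct", 0.0)
    return row


# ---------------------------------------------------------------------------
# Batch


IMAGE_SUFFIXES = {".jpg", ".jpeg", ".png"}


def process_batch(
    input_dir: str | Path,
    cfg: PipelineConfig,
    output_csv: str | Path,
    save_masks: str | Path | None = None,
) -> tuple[pd.DataFrame, int]:
    """Process every image of a directory under one configuration.

    Writes ``output_csv`` (fixed schema, '.' decimals, one summary row
    per image plus one row per detected fruit) and a ``settings.json``
    sidecar next to it with the exact configuration echo and tool
    version.  Returns (results table, number of images with errors).
    """
    input_dir = Path(input_dir)
    paths = sorted(
        p for p in input_dir.iterdir() if p.suffix.lower() in IMAGE_SUFFIXES
    )
    if not paths:
        raise FileNotFoundError(f"no images (jpg/png) found in {input_dir}")
    logger.info("batch of %d images; background=%s", len(paths), cfg.background.describe())
    for name, spec in cfg.features.items():
        logger.info("feature %s: %s", name, spec.describe())

    all_rows: list[dict] = []
    n_errors = 0
    for p in paths:
        rows, summary, masks = process_image(p, cfg)
        if summary["status"] not in ("ok", "empty_segmentation"):
            n_errors += 1
        all_rows.append(summary)
        all_rows.extend(rows)
        if save_masks is not None and masks:
            _write_masks(Path(save_masks), p.stem, masks)

    cols = result_columns(cfg)
    table = pd.DataFrame(
        [{c: r.get(c, "") for c in cols} for r in all_rows], columns=cols
    )
    output_csv = Path(output_csv)
    output_csv.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(output_csv, index=False, lineterminator="\n")
    sidecar = output_csv.with_name("settings.json")
    sidecar.write_text(json.dumps(cfg.to_dict(), indent=2, sort_keys=True) + "\n")
    return table, n_errors


def _write_masks(out_dir: Path, stem: str, masks: dict[str, np.ndarray]) -> None:
    """Fruit mask as white-on-black; features as red overlay on the fruit."""
    from PIL import Image

    out_dir.mkdir(parents=True, exist_ok=True)
    fruit = masks["fruit"]
    Image.fromarray((fruit * 255).astype(np.uint8)).save(out_dir / f"{stem}_fruit.png")
    for name, mask in masks.items():
        if name == "fruit":
            continue
        overlay = np.zeros(fruit.shape + (3,), dtype=np.uint8)
        overlay[fruit] = (255, 255, 255)
        overlay[mask] = (255, 0, 0)
        Image.fromarray(overlay).save(out_dir / f"{stem}_{name}.png")
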