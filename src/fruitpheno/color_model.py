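"""Colorspace conversions and threshold evaluation.

Every other stage of the pipeline speaks this vocabulary: pixels are
classified by conjunctions of per-channel acceptance intervals evaluated
in RGB, HSB (hue-saturation-brightness, i.e. HSV) or CIELAB space.
Red-drupelet detection, for example, is typically a single interval on
the CIELAB a* (green-red opponent) channel.

Colorimetry is fixed to the sRGB companding curve with the D65/2-degree
white point, the native sRGB choice.  Lab values are kept in floating
point on the conventional scale (L* in [0, 100], a*/b* roughly in
[-128, 127]); the ImageJ 0-255 convention is available only as the
explicit compatibility mapping :func:`lab_to_imagej_scale`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import color as _skcolor

logger = logging.getLogger(__name__)

#: Channels addressable by a :class:`ChannelInterval`, grouped by space.
RGB_CHANNELS = ("R", "G", "B")
HSB_CHANNELS = ("H", "S", "V")
LAB_CHANNELS = ("L", "a", "b")
ALL_CHANNELS = RGB_CHANNELS + HSB_CHANNELS + LAB_CHANNELS

_SPACE_OF = {c: "rgb" for c in RGB_CHANNELS}
_SPACE_OF.update({c: "hsb" for c in HSB_CHANNELS})
_SPACE_OF.update({c: "lab" for c in LAB_CHANNELS})

#: Natural full range of each channel (used for validation messages only;
#: an unset bound imposes no constraint at all).
CHANNEL_RANGE = {
    "R": (0.0, 255.0),
    "G": (0.0, 255.0),
    "B": (0.0, 255.0),
    "H": (0.0, 360.0),
    "S": (0.0, 1.0),
    "V": (0.0, 1.0),
    "L": (0.0, 100.0),
    "a": (-128.0, 127.0),
    "b": (-128.0, 127.0),
}


class ThresholdError(ValueError):
    """Raised for malformed channel intervals or threshold specs."""


def _as_float_rgb(img: np.ndarray) -> np.ndarray:
    """8-bit H×W×3 (or N×3) sRGB array → float in [0, 1]."""
    arr = np.asarray(img)
    if arr.ndim < 2 or arr.shape[-1] != 3:
        raise ValueError(f"expected (..., 3) RGB array, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    arr = arr.astype(np.float64)
    if arr.max(initial=0.0) > 1.0:
        arr = arr / 255.0
    return arr


def rgb_to_lab(rgb: np.ndarray) -> np.ndarray:
    """Convert sRGB (8-bit or [0,1] float) to CIELAB under D65/2 degrees.

    Accepts a single pixel ``(3,)``, a list of pixels ``(N, 3)`` or a whole
    raster ``(H, W, 3)``; the output has the same leading shape with
    channels ``(L*, a*, b*)``, L* in [0, 100].
    """
    arr = _as_float_rgb(np.atleast_2d(np.asarray(rgb)))
    single = np.asarray(rgb).ndim == 1
    lab = _skcolor.rgb2lab(arr)
    return lab[0] if single else lab


def rgb_to_hsb(rgb: np.ndarray) -> np.ndarray:
    """Convert sRGB to hue-saturation-brightness (hexcone HSV).

    Hue is returned in degrees [0, 360); saturation and brightness in
    [0, 1].  Achromatic pixels have hue 0 by convention.
    """
    arr = _as_float_rgb(np.atleast_2d(np.asarray(rgb)))
    single = np.asarray(rgb).ndim == 1
    hsv = _skcolor.rgb2hsv(arr)
    hsv[..., 0] = (hsv[..., 0] * 360.0) % 360.0
    return hsv[0] if single else hsv


def lab_to_imagej_scale(lab: np.ndarray) -> np.ndarray:
    """Map conventional CIELAB to the ImageJ 0-255 integer convention.

    L255 = L*·255/100, a255 = a*+128, b255 = b*+128, each clamped to
    [0, 255].  Provided so users can port ImageJ threshold settings (for
    example an ImageJ reverted-pixel cutoff of a255 > 138 corresponds to
    a* > 10).
    """
    lab = np.asarray(lab, dtype=np.float64)
    out = np.empty_like(lab)
    out[..., 0] = lab[..., 0] * 255.0 / 100.0
    out[..., 1] = lab[..., 1] + 128.0
    out[..., 2] = lab[..., 2] + 128.0
    return np.clip(out, 0.0, 255.0)


@dataclass(frozen=True)
class ChannelInterval:
    """Acceptance interval on one color channel.

    An unset bound (``None``) is open — the "FR" (full range) notation of
    threshold tables.  Bounds are strict by default, matching the ``>``
    inequalities such tables print.  For the hue channel ``H`` only,
    ``lo > hi`` denotes a wraparound interval (e.g. 350°-10°).
    """

    channel: str
    lo: float | None = None
    hi: float | None = None
    lo_strict: bool = True
    hi_strict: bool = True

    def __post_init__(self) -> None:
        if self.channel not in ALL_CHANNELS:
            raise ThresholdError(
                f"unknown channel {self.channel!r}; expected one of {ALL_CHANNELS}"
            )
        if self.lo is not None and self.hi is not None and self.lo >= self.hi:
            if self.channel != "H":
                raise ThresholdError(
                    f"channel {self.channel}: lower bound {self.lo} must be "
                    f"below upper bound {self.hi}"
                )

    @property
    def space(self) -> str:
        return _SPACE_OF[self.channel]

    @property
    def is_full_range(self) -> bool:
        return self.lo is None and self.hi is None

    @property
    def wraps(self) -> bool:
        return (
            self.channel == "H"
            and self.lo is not None
            and self.hi is not None
            and self.lo > self.hi
        )

    def contains(self, values: np.ndarray) -> np.ndarray:
        """Boolean mask of which values satisfy the interval."""
        values = np.asarray(values, dtype=np.float64)
        if self.is_full_range:
            return np.ones(values.shape, dtype=bool)
        above = None
        if self.lo is not None:
            above = values > self.lo if self.lo_strict else values >= self.lo
        below = None
        if self.hi is not None:
            below = values < self.hi if self.hi_strict else values <= self.hi
        if above is None:
            return below
        if below is None:
            return above
        if self.wraps:
            return above | below
        return above & below


@dataclass(frozen=True)
class ThresholdSpec:
    """Conjunction of channel intervals: a pixel passes iff it satisfies
    every interval.  At most one interval per channel; channels not
    mentioned impose no constraint."""

    intervals: tuple[ChannelInterval, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "intervals", tuple(self.intervals))
        seen: set[str] = set()
        for iv in self.intervals:
            if iv.channel in seen:
                raise ThresholdError(f"duplicate interval for channel {iv.channel!r}")
            seen.add(iv.channel)

    @property
    def spaces(self) -> set[str]:
        return {iv.space for iv in self.intervals if not iv.is_full_range}

    def describe(self) -> str:
        if not self.intervals:
            return "FR (accept all)"
        parts = []
        for iv in self.intervals:
            if iv.is_full_range:
                parts.append(f"{iv.channel}: FR")
                continue
            lo = "" if iv.lo is None else f"{'>' if iv.lo_strict else '>='}{iv.lo:g}"
            hi = "" if iv.hi is None else f"{'<' if iv.hi_strict else '<='}{iv.hi:g}"
            parts.append(f"{iv.channel} {lo} {hi}".strip())
        return "; ".join(parts)


def channel_values(img: np.ndarray, channel: str) -> np.ndarray:
    """Extract one channel of an sRGB raster in that channel's native space."""
    space = _SPACE_OF[channel]
    if space == "rgb":
        return np.asarray(img)[..., RGB_CHANNELS.index(channel)].astype(np.float64)
    if space == "hsb":
        return rgb_to_hsb(img)[..., HSB_CHANNELS.index(channel)]
    return rgb_to_lab(img)[..., LAB_CHANNELS.index(channel)]


def apply_threshold(img: np.ndarray, spec: ThresholdSpec) -> np.ndarray:
    """Classify every pixel of ``img`` against ``spec``.

    Returns an H×W boolean mask, true where the pixel satisfies every
    interval of the spec.  Colorspace conversions are computed once per
    space actually constrained.  An empty spec accepts everything (with a
    warning, since it usually indicates a configuration mistake).
    """
    arr = np.asarray(img)
    if arr.size == 0:
        raise ValueError("empty image")
    shape = arr.shape[:-1]
    active = [iv for iv in ThresholdSpec(spec.intervals).intervals if not iv.is_full_range]
    if not active:
        logger.warning("threshold spec has no constrained channel; accepting all pixels")
        warnings.warn("empty threshold spec accepts all pixels", stacklevel=2)
        return np.ones(shape, dtype=bool)

    cache: dict[str, np.ndarray] = {}
    mask = np.ones(shape, dtype=bool)
    for iv in active:
        if iv.space not in cache:
            if iv.space == "rgb":
                cache["rgb"] = arr.astype(np.float64)
            elif iv.space == "hsb":
                cache["hsb"] = rgb_to_hsb(arr)
            else:
                cache["lab"] = rgb_to_lab(arr)
        space_arr = cache[iv.space]
        idx = {"rgb": RGB_CHANNELS, "hsb": HSB_CHANNELS, "lab": LAB_CHANNELS}[iv.space]
        mask &= iv.contains(space_arr[..., idx.index(iv.channel)])
    return mask
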