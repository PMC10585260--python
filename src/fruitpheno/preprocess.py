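"""Read-in normalization of raw photographs before segmentation.

Staged fruit photographs arrive at arbitrary camera resolution.  The
pipeline first downsizes them so the maximum dimension does not exceed
1500 pixels (cheaper batch processing at the cost of fine resolution),
stretches contrast so pixel values span the full RGB range, optionally
denoises and sharpens, and finally flags a configured exclusion region
(the strip around the in-photo size reference) as ineligible for all
downstream masks.

Contrast normalization is a *joint* linear stretch over all three
channels: stretching each channel independently would change hue and
silently shift CIELAB thresholds.  The exclusion region is implemented
as a mask rather than geometric cropping so pixel coordinates stay
comparable across every stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image, ImageOps
from scipy import ndimage


class ConfigurationError(ValueError):
    """Invalid preprocessing parameter."""


@dataclass
class ImageRGB:
    """An 8-bit sRGB raster plus its provenance.

    ``scale`` is the cumulative downsize factor applied relative to the
    original file (1.0 = untouched); size calibration must divide
    reference pixel lengths measured on the *original* image by it.
    """

    pixels: np.ndarray
    source_path: str = "<memory>"
    original_dims: tuple[int, int] = field(default=None)  # (H0, W0)
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"expected H×W×3 raster, got shape {self.pixels.shape}")
        if self.pixels.dtype != np.uint8:
            self.pixels = np.clip(np.rint(self.pixels), 0, 255).astype(np.uint8)
        if self.original_dims is None:
            self.original_dims = self.pixels.shape[:2]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class CropRegion:
    """Rectangular exclusion zone in fractional image coordinates.

    Half-open [top, bottom) × [left, right), each in [0, 1], so a single
    region applies batch-wide regardless of image size.
    """

    top: float
    left: float
    bottom: float
    right: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.top < self.bottom <= 1.0):
            raise ConfigurationError(f"need 0 <= top < bottom <= 1, got {self.top}, {self.bottom}")
        if not (0.0 <= self.left < self.right <= 1.0):
            raise ConfigurationError(f"need 0 <= left < right <= 1, got {self.left}, {self.right}")


def load_image(path: str | Path) -> ImageRGB:
    """Decode a JPEG/PNG photograph, honoring EXIF orientation."""
    with Image.open(path) as im:
        im = ImageOps.exif_transpose(im)
        arr = np.asarray(im.convert("RGB"))
    return ImageRGB(pixels=arr, source_path=str(path), original_dims=arr.shape[:2])


def downsize(img: ImageRGB, max_dim: int = 1500) -> ImageRGB:
    """Rescale so the maximum dimension does not exceed ``max_dim``.

    Images already within the bound are returned unchanged.  Aspect ratio
    is preserved to within a pixel (rounding); interpolation is bilinear.
    The applied scale factor is accumulated on the result for use in size
    calibration.
    """
    if max_dim < 1:
        raise ConfigurationError(f"max_dim must be >= 1, got {max_dim}")
    h, w = img.shape
    if max(h, w) <= max_dim:
        return img
    factor = max_dim / max(h, w)
    if h >= w:
        new_h, new_w = max_dim, max(1, round(w * factor))
    else:
        new_h, new_w = max(1, round(h * factor)), max_dim
    pil = Image.fromarray(img.pixels)
    resized = pil.resize((new_w, new_h), Image.BILINEAR)
    return replace(
        img,
        pixels=np.asarray(resized),
        scale=img.scale * factor,
    )


def normalize_contrast(img: ImageRGB) -> ImageRGB:
    """Linear stretch so pixel values span the full 0-255 range.

    The stretch x → (x−m)·255/(M−m) uses the joint minimum m and maximum
    M over all three channels; per-channel stretching would alter hue.
    Constant images (M = m) are returned unchanged.
    """
    px = img.pixels
    m = int(px.min())
    big = int(px.max())
    if m == 0 and big == 255:
        return img
    if big == m:
        return img
    stretched = (px.astype(np.float64) - m) * (255.0 / (big - m))
    return replace(img, pixels=np.clip(np.rint(stretched), 0, 255).astype(np.uint8))


def enhance(img: ImageRGB, sharpen_amount: float = 1.0, denoise_radius: int = 1) -> ImageRGB:
    """Reduce pixel noise, then sharpen color-intensity differences.

    A per-channel median filter of window (2·radius+1)² removes
    salt-and-pepper noise; an unsharp mask (Gaussian-blurred subtraction,
    ``out = x + amount·(x − blur(x))``) then increases local contrast.
    ``denoise_radius=0`` and ``sharpen_amount=0`` are both identities.
    """
    if denoise_radius < 0:
        raise ConfigurationError(f"denoise_radius must be >= 0, got {denoise_radius}")
    if sharpen_amount < 0:
        raise ConfigurationError(f"sharpen_amount must be >= 0, got {sharpen_amount}")
    px = img.pixels.astype(np.float64)
    if denoise_radius > 0:
        size = 2 * denoise_radius + 1
        px = ndimage.median_filter(px, size=(size, size, 1), mode="nearest")
    if sharpen_amount > 0:
        blurred = ndimage.gaussian_filter(px, sigma=(1.0, 1.0, 0.0), mode="nearest")
        px = px + sharpen_amount * (px - blurred)
    return replace(img, pixels=np.clip(np.rint(px), 0, 255).astype(np.uint8))


def exclusion_mask(shape: tuple[int, int], region: CropRegion | None) -> np.ndarray:
    """Boolean H×W mask, true where pixels are ineligible for detection.

    ``region=None`` excludes nothing.  A region that maps to zero pixels
    after scaling is a configuration error (the caller almost certainly
    meant to exclude something).
    """
    h, w = shape
    mask = np.zeros((h, w), dtype=bool)
    if region is None:
        return mask
    top = int(np.floor(region.top * h))
    bottom = int(np.ceil(region.bottom * h))
    left = int(np.floor(region.left * w))
    right = int(np.ceil(region.right * w))
    if bottom <= top or right <= left:
        raise ConfigurationError(f"exclusion region {region} is empty at image size {h}×{w}")
    mask[top:bottom, left:right] = True
    return mask


def preprocess(
    img: ImageRGB,
    max_dim: int = 1500,
    normalize: bool = True,
    sharpen_amount: float = 1.0,
    denoise_radius: int = 1,
    exclude_region: CropRegion | None = None,
) -> tuple[ImageRGB, np.ndarray]:
    """Full read-in chain: downsize → contrast stretch → enhance → exclusion.

    Returns the processed image and the exclusion mask at its final size.
    The stage order is fixed; individual stages are disabled via their
    parameters (``normalize=False``, ``sharpen_amount=0``,
    ``denoise_radius=0``) e.g. to mirror analyses done without any
    pre-processing.
    """
    out = downsize(img, max_dim=max_dim)
    if normalize:
        out = normalize_contrast(out)
    if sharpen_amount > 0 or denoise_radius > 0:
        out = enhance(out, sharpen_amount=sharpen_amount, denoise_radius=denoise_radius)
    return out, exclusion_mask(out.shape, exclude_region)
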