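"""Segmentation: fruit mask, feature mask, and labeled fruit objects.

Background removal and color-feature detection are both plain threshold
classifications (see :mod:`fruitpheno.color_model`) followed by
*despeckling*: a morphological opening — erosion ("shrinking") then
dilation ("swelling") with a disc structuring element — that deletes
small isolated pixel groups such as dust, juice droplets and debris
while leaving large fruit regions intact.

The feature mask is always a subset of the fruit mask, so the feature
pixel fraction is well defined, and objects are 8-connected components
of the fruit mask above a minimum area, labeled deterministically in
row-major order of their first pixel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as _ndimage
from skimage import measure as _skmeasure
from skimage import morphology as _skmorph

from .color_model import ThresholdSpec, apply_threshold

logger = logging.getLogger(__name__)


@dataclass
class LabeledObjects:
    """Connected components of a fruit mask.

    ``labels`` is H×W integer, 0 = background, k >= 1 = object k.  Labels
    are assigned in row-major order of each component's first pixel, so
    repeated runs produce identical labelings.
    """

    labels: np.ndarray
    n_objects: int
    pixel_counts: dict[int, int] = field(default_factory=dict)
    bboxes: dict[int, tuple[int, int, int, int]] = field(default_factory=dict)
    #: (min_row, min_col, max_row, max_col), inclusive

    def mask_of(self, k: int) -> np.ndarray:
        if k < 1 or k > self.n_objects:
            raise KeyError(f"object {k} does not exist (n_objects={self.n_objects})")
        return self.labels == k


def despeckle(mask: np.ndarray, radius: int) -> np.ndarray:
    """Morphological opening with a disc of the given radius.

    Erosion then dilation: connected groups too small to survive erosion
    (every pixel within ``radius`` of the group's complement) vanish
    entirely; larger regions keep their bulk, with convex corners rounded.
    ``radius=0`` is the identity.  Opening is idempotent and
    anti-extensive (output ⊆ input).
    """
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    mask = np.asarray(mask, dtype=bool)
    if radius == 0:
        return mask.copy()
    footprint = _skmorph.disk(radius)
    # border_value=0: pixels outside the frame count as background, so
    # groups clipped by the image edge still shrink from that side
    eroded = _ndimage.binary_erosion(mask, structure=footprint, border_value=0)
    return _ndimage.binary_dilation(eroded, structure=footprint, border_value=0)


def remove_background(
    img: np.ndarray,
    spec: ThresholdSpec,
    despeckle_radius: int = 2,
    exclusion: np.ndarray | None = None,
) -> np.ndarray:
    """Threshold out the background, leaving the fruit mask.

    Pipeline: threshold classification, clearing of the excluded zone
    (the strip around the size reference), then despeckling.  The result
    is the set of non-background ("fruit") pixels — the denominator of
    every feature fraction.  An empty result is legal (all-background
    photo) and only logged; the batch layer records it as a zero-object
    row.
    """
    mask = apply_threshold(img, spec)
    if exclusion is not None:
        mask &= ~np.asarray(exclusion, dtype=bool)
    mask = despeckle(mask, despeckle_radius)
    if not mask.any():
        logger.warning("background removal produced an empty fruit mask")
    return mask


def detect_feature(
    img: np.ndarray,
    fruit: np.ndarray,
    spec: ThresholdSpec,
    despeckle_radius: int = 2,
) -> np.ndarray:
    """Detect a color-defined feature (e.g. reverted drupelets) within fruit.

    Threshold classification intersected with the fruit mask, then
    despeckled; the despeckling happens after the intersection so the
    guarantee feature ⊆ fruit holds (opening never adds pixels).
    """
    mask = apply_threshold(img, spec) & np.asarray(fruit, dtype=bool)
    return despeckle(mask, despeckle_radius)


def label_objects(fruit: np.ndarray, min_object_area: int = 1) -> LabeledObjects:
    """8-connected component labeling with a minimum-area filter.

    Components below ``min_object_area`` pixels are dropped (they are
    typically debris that survived despeckling or clipped fragments).
    Surviving components are relabeled 1..n in row-major order of their
    first pixel for determinism.
    """
    if min_object_area < 1:
        raise ValueError(f"min_object_area must be >= 1, got {min_object_area}")
    fruit = np.asarray(fruit, dtype=bool)
    raw = _skmeasure.label(fruit, connectivity=2)
    flat = raw.ravel()
    nz = np.flatnonzero(flat)
    uniq, first = np.unique(flat[nz], return_index=True)
    order = uniq[np.argsort(first)]

    labels = np.zeros_like(raw)
    counts: dict[int, int] = {}
    bboxes: dict[int, tuple[int, int, int, int]] = {}
    next_label = 1
    for lab in order:
        comp = raw == lab
        n = int(comp.sum())
        if n < min_object_area:
            continue
        labels[comp] = next_label
        rows, cols = np.nonzero(comp)
        counts[next_label] = n
        bboxes[next_label] = (
            int(rows.min()),
            int(cols.min()),
            int(rows.max()),
            int(cols.max()),
        )
        next_label += 1
    return LabeledObjects(
        labels=labels,
        n_objects=next_label - 1,
        pixel_counts=counts,
        bboxes=bboxes,
    )
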