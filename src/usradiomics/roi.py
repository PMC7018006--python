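"""ROI recovery from red-curve annotations and normalized patch extraction.

Ultrasound lesions are outlined by hand with a red brush on a *duplicate*
of the image (so the marking never touches the original intensities).
This module finds the red closed curve on the annotated copy, fills its
interior, transfers the mask to the untouched original, and produces a
min-max-normalized, quantized patch — the unit of texture analysis.

Conventions: 0-based (row, col) pixel-centered coordinates; masks include
boundary pixels; 8-bit grayscale originals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

DEFAULT_REDNESS_THRESHOLD = 60.0
MIN_ROI_PIXELS = 16
GAP_BRIDGE_PX = 5  # hand-drawn curves may leave small gaps


class RoiError(ValueError):
    pass


class AnnotationMissingError(RoiError):
    pass


class OpenContourError(RoiError):
    pass


class EmptyRoiError(RoiError):
    pass


@dataclass
class AnnotatedPair:
    """An untouched grayscale original plus its red-annotated duplicate."""

    original: np.ndarray   # (H, W) in [0, 255]
    annotated: np.ndarray  # (H, W, 3)
    lesion_id: str = ""

    def __post_init__(self) -> None:
        self.original = np.asarray(self.original)
        self.annotated = np.asarray(self.annotated)
        if self.original.ndim != 2:
            raise ValueError("original must be a 2-D grayscale grid")
        if self.annotated.ndim != 3 or self.annotated.shape[2] != 3:
            raise ValueError("annotated must be a 3-channel color grid")
        if self.original.shape != self.annotated.shape[:2]:
            raise ValueError("original and annotated dimensions differ")
        if self.original.min() < 0 or self.original.max() > 255:
            raise ValueError("original intensities must lie in [0, 255]")


@dataclass
class RoiMask:
    """Filled interior of the traced red curve, boundary pixels included."""

    mask: np.ndarray                       # (H, W) bool
    boundary: np.ndarray = field(default=None)  # ordered (row, col) vertices

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.boundary is not None:
            self.boundary = np.asarray(self.boundary)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class RoiPatch:
    """Bounding-box crop of the original, masked and quantized.

    ``values`` covers the whole bounding box (quantized with the in-mask
    min-max map, clipped); ``mask`` flags the in-ROI pixels.  Inside the
    mask values are integers in [0, levels-1].
    """

    values: np.ndarray
    mask: np.ndarray
    levels: int
    constant: bool = False  # raw ROI had a single intensity

    @property
    def masked_values(self) -> np.ndarray:
        return self.values[self.mask]


def redness(annotated: np.ndarray) -> np.ndarray:
    """Red dominance R - max(G, B) per pixel (float)."""
    a = np.asarray(annotated, dtype=float)
    return a[..., 0] - np.maximum(a[..., 1], a[..., 2])


def detect_annotation(
    pair: AnnotatedPair,
    redness_threshold: float = DEFAULT_REDNESS_THRESHOLD,
) -> RoiMask:
    """Trace the red curve on the annotated copy and fill its interior.

    A pixel belongs to the curve when its red dominance exceeds
    ``redness_threshold`` (default 60 on the 8-bit scale — tolerant of
    JPEG chroma bleed while rejecting bright gray speckle).  Gaps up to
    5 px are bridged morphologically before filling; the mask is the
    filled interior including the curve itself.
    """
    red = redness(pair.annotated) > redness_threshold
    if not red.any():
        raise AnnotationMissingError("annotation missing")

    # bridge small gaps: dilate until a <=5-px gap closes, fill the hole,
    # then erode back so the mask hugs the drawn curve
    radius = (GAP_BRIDGE_PX + 1) // 2
    selem = morphology.disk(radius)
    dilated = ndimage.binary_dilation(red, structure=selem)
    filled = ndimage.binary_erosion(ndimage.binary_fill_holes(dilated),
                                    structure=selem)
    mask = filled | red
    if mask.sum() == red.sum():  # nothing enclosed: curve never closed
        raise OpenContourError("open contour")

    # enforce a single 8-connected component (keep the largest)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    if mask.sum() < MIN_ROI_PIXELS:
        raise OpenContourError(
            f"degenerate ROI: {int(mask.sum())} px < {MIN_ROI_PIXELS}"
        )

    contours = measure.find_contours(mask.astype(float), 0.5)
    boundary = None
    if contours:
        longest = max(contours, key=len)
        boundary = np.clip(
            np.rint(longest).astype(int),
            0,
            [mask.shape[0] - 1, mask.shape[1] - 1],
        )
    return RoiMask(mask=mask, boundary=boundary)


def quantize(
    values: np.ndarray,
    mask: np.ndarray,
    levels: int,
    normalization: str = "minmax",
) -> RoiPatch:
    """Min-max rescale in-mask values and quantize to ``levels`` bins.

    The in-mask minimum maps to 0 and the maximum to levels-1 ("256 bins
    of width 1" at the default).  ``normalization='zscore'`` instead
    standardizes by the in-mask mean/SD, clips at +-3 SD and maps that
    range linearly onto [0, levels-1].
    """
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    inside = values[mask]
    if inside.size == 0:
        raise EmptyRoiError("empty ROI")
    if normalization == "minmax":
        lo, hi = inside.min(), inside.max()
    elif normalization == "zscore":
        mu, sd = inside.mean(), inside.std()
        if sd == 0:
            lo = hi = mu
        else:
            values = (values - mu) / sd
            lo, hi = -3.0, 3.0
            values = np.clip(values, lo, hi)
    else:
        raise ValueError(f"unknown normalization: {normalization!r}")
    constant = hi == lo
    if constant:
        q = np.zeros_like(values)
    else:
        q = np.rint((values - lo) / (hi - lo) * (levels - 1))
        q = np.clip(q, 0, levels - 1)
    return RoiPatch(values=q, mask=mask, levels=levels, constant=bool(constant))


def extract_patch(
    pair: AnnotatedPair,
    mask: RoiMask,
    levels: int = 256,
    normalization: str = "minmax",
) -> RoiPatch:
    """Crop the ORIGINAL image to the mask's bounding box and quantize.

    Intensities are always read from the untouched original, never from
    the annotated copy, so the red marking cannot contaminate texture.
    """
    if not 8 <= levels <= 256:
        raise ValueError("levels must lie in [8, 256]")
    m = np.asarray(mask.mask, dtype=bool)
    if m.shape != pair.original.shape:
        raise ValueError("mask dimensions do not match the image")
    rows, cols = np.nonzero(m)
    if rows.size == 0:
        raise EmptyRoiError("empty ROI")
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    crop = np.asarray(pair.original, dtype=float)[r0:r1, c0:c1]
    crop_mask = m[r0:r1, c0:c1]
    return quantize(crop, crop_mask, levels, normalization=normalization)


def load_pair(original_path, annotated_path, lesion_id: str = "") -> AnnotatedPair:
    """Read an original/annotated image pair from disk (PNG or JPEG)."""
    from PIL import Image

    orig = np.asarray(Image.open(original_path).convert("L"), dtype=np.uint8)
    ann = np.asarray(Image.open(annotated_path).convert("RGB"), dtype=np.uint8)
    return AnnotatedPair(original=orig, annotated=ann, lesion_id=lesion_id)


def save_mask(mask: RoiMask, path) -> None:
    """Export a mask as an 8-bit PNG for audit."""
    from PIL import Image

    Image.fromarray((mask.mask * np.uint8(255))).save(path)
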