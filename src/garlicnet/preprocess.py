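"""Threshold-based foreground segmentation of garlic images.

The pipeline assumes produce photographed on a near-black background:
grayscale conversion, fixed-threshold binarisation (default 0.3, picked from
the bimodal grey-level histogram such scenes exhibit), pixelwise masking of
the colour image, then largest-connected-component selection with boundary
tracing and a tight bounding box around the bulb.

All images are H x W (x3) float arrays in [0, 1]; bounding boxes are 0-based,
half-open ``(row_min, col_min, row_max, col_max)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

__all__ = [
    "SegmentationError",
    "SegmentationResult",
    "to_grayscale",
    "binarize",
    "apply_mask",
    "extract_target",
    "segment",
]

#: Rec.601 luma weights, the standard grayscale convention.
_LUMA = np.array([0.299, 0.587, 0.114])


class SegmentationError(ValueError):
    """Raised when segmentation cannot proceed (e.g. empty foreground)."""


@dataclass
class SegmentationResult:
    """Foreground of one image: masked colour image, binary mask, the tight
    bounding box of the selected component and its traced boundary contour
    (an ordered (n, 2) array of row/column coordinates)."""

    masked_image: np.ndarray
    mask: np.ndarray
    bbox: tuple
    contour: np.ndarray


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Luminance-weighted grayscale of an H x W x 3 image in [0, 1]."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 image, got shape {image.shape}")
    return image @ _LUMA


def binarize(gray: np.ndarray, threshold: float = 0.3) -> np.ndarray:
    """Binary mask: 1 where ``gray >= threshold``, 0 below.

    The threshold must lie strictly inside (0, 1).  Values exactly at the
    threshold count as foreground (half-open convention).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    gray = np.asarray(gray, dtype=float)
    return (gray >= threshold).astype(np.uint8)


def apply_mask(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Pixelwise product: keep masked pixels, zero (black) the background."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask)
    if image.shape[:2] != mask.shape:
        raise ValueError(
            f"image {image.shape[:2]} and mask {mask.shape} sizes differ"
        )
    if image.ndim == 3:
        return image * mask[:, :, None]
    return image * mask


def extract_target(masked: np.ndarray, mask: np.ndarray) -> SegmentationResult:
    """Select the largest 8-connected foreground component.

    Every other component is removed from both the mask and the masked image;
    the result carries the component's traced boundary and its tight,
    half-open bounding box.  Multi-bulb frames are therefore reduced to the
    dominant bulb.
    """
    mask = np.asarray(mask).astype(np.uint8)
    if mask.sum() == 0:
        raise SegmentationError("no foreground pixels above threshold")
    labels = measure.label(mask, connectivity=2)  # 8-connectivity
    counts = np.bincount(labels.ravel())
    counts[0] = 0  # background
    keep = counts.argmax()
    component = (labels == keep).astype(np.uint8)
    masked = apply_mask(np.asarray(masked, dtype=float), component)
    rows, cols = np.nonzero(component)
    bbox = (int(rows.min()), int(cols.min()),
            int(rows.max()) + 1, int(cols.max()) + 1)
    contour = _trace_boundary(component)
    return SegmentationResult(masked_image=masked, mask=component,
                              bbox=bbox, contour=contour)


def _trace_boundary(component: np.ndarray) -> np.ndarray:
    """Ordered boundary of a binary component (sub-pixel marching squares)."""
    padded = np.pad(component.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:  # single-pixel or degenerate component
        rows, cols = np.nonzero(component)
        return np.column_stack([rows, cols]).astype(float)
    longest = max(contours, key=len)
    return longest - 1.0  # undo padding offset


def segment(image: np.ndarray, threshold: float = 0.3) -> SegmentationResult:
    """Full pipeline: grayscale -> binarise -> mask -> largest component."""
    gray = to_grayscale(image)
    mask = binarize(gray, threshold)
    masked = apply_mask(image, mask)
    return extract_target(masked, mask)
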