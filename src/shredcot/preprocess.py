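"""Raw-photograph preprocessing: foreground extraction and object-tight crop.

Photographs of objects on a dark stage carry mostly background; cropping to
the minimum circle enclosing the foreground (plus a small pad) shrinks the
image dramatically before annotation or segmentation.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .geometry import min_enclosing_circle
from .types import EnclosingCircle, as_binary_mask

__all__ = ["to_grayscale", "extract_foreground", "crop_to_object", "min_enclosing_circle"]

#: Rec.601 luminance weights for RGB -> gray.
_LUMA = np.array([0.299, 0.587, 0.114])


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Collapse an RGB(A) image to luminance; pass 2-D input through."""
    arr = np.asarray(image, dtype=float)
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] >= 3:
        return arr[:, :, :3] @ _LUMA
    raise ValueError(f"unsupported image shape {arr.shape}")


def extract_foreground(image: np.ndarray, min_blob_px: int = 25) -> np.ndarray:
    """Otsu-threshold the image; keep the brighter side as foreground.

    Connected specks smaller than ``min_blob_px`` pixels are removed
    (sensor noise).  A uniform image has no foreground: an empty mask is
    returned with a warning rather than an error.
    """
    gray = to_grayscale(image)
    if gray.size == 0:
        raise ValueError("empty image")
    if float(gray.min()) == float(gray.max()):
        warnings.warn("uniform image: no foreground found")
        return np.zeros(gray.shape, dtype=np.uint8)
    thr = threshold_otsu(gray)
    fg = gray > thr  # the above-threshold class always has the higher mean
    if min_blob_px > 1:
        labels, n = ndimage.label(fg, structure=np.ones((3, 3), int))
        if n:
            sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
            small = np.flatnonzero(sizes < min_blob_px) + 1
            fg &= ~np.isin(labels, small)
    return fg.astype(np.uint8)


def crop_to_object(
    image: np.ndarray, circle: EnclosingCircle, pad: int = 10
) -> np.ndarray:
    """Crop the axis-aligned square around the enclosing circle plus pad.

    Bounds are rounded outward to integers and clamped to the image; every
    foreground pixel inside the circle is therefore retained.
    """
    if pad < 0:
        raise ValueError("pad must be >= 0")
    arr = np.asarray(image)
    h, w = arr.shape[:2]
    cx, cy = circle.center
    r = circle.radius
    c0 = max(0, int(np.floor(cx - r - pad)))
    c1 = min(w - 1, int(np.ceil(cx + r + pad)))
    r0 = max(0, int(np.floor(cy - r - pad)))
    r1 = min(h - 1, int(np.ceil(cy + r + pad)))
    return arr[r0 : r1 + 1, c0 : c1 + 1]


def preprocess_image(
    image: np.ndarray, pad: int = 10, min_blob_px: int = 25
) -> tuple[np.ndarray, np.ndarray, EnclosingCircle]:
    """Full chain: foreground mask, enclosing circle, cropped image.

    Returns ``(cropped_image, foreground_mask, circle)``; the mask is on
    the original canvas.
    """
    fg = extract_foreground(image, min_blob_px=min_blob_px)
    if fg.sum() == 0:
        return np.asarray(image), fg, EnclosingCircle(center=(0.0, 0.0), radius=0.0)
    circle = min_enclosing_circle(as_binary_mask(fg))
    return crop_to_object(image, circle, pad=pad), fg, circle
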