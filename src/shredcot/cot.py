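"""Overlap-region reconstruction for occluded elongated objects (COT).

An object partially covered by another appears in an instance-segmentation
output as a mask split into two or more connected components.  The hidden
part between the two largest fragments is reconstructed geometrically:

1.  Classify each instance: a single connected component means unoccluded
    (it is the covering object); two or more mean occluded.
2.  In the occluded instance's two largest fragments, fit the maximum
    inscribed circle of each (distance-transform maximum).  Join the two
    circles by their common external tangent lines and close the region
    with the chords between tangent points, giving a trapezoid-like quad
    that spans the gap.
3.  Rasterize the quad and intersect it with the covering instance's mask;
    the pixel count of that intersection is the recovered hidden-overlap
    area CD.

When the tangent construction degenerates (one circle inside the other's
radial span) the fitted region falls back to the convex hull of the two
fragments.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from skimage.morphology import convex_hull_image

from .geometry import (
    TangentDegenerateError,
    external_tangent_quad,
    max_inscribed_circle,
    rasterize_polygon,
)
from .types import InstanceMask, OverlapResult, Sample, as_binary_mask, mask_area

__all__ = [
    "connected_components",
    "classify_occlusion",
    "overlap_from_fit",
    "fit_overlap_region",
    "cot_pipeline",
    # geometry re-exports used by callers of this module
    "max_inscribed_circle",
    "external_tangent_quad",
    "rasterize_polygon",
    "TangentDegenerateError",
]

_EIGHT = np.ones((3, 3), dtype=int)


def connected_components(mask: np.ndarray) -> list[np.ndarray]:
    """8-connected components of a mask, largest area first.

    Ties in area are broken by the top-left-most foreground pixel
    (smallest row, then smallest col) so the ordering is deterministic.
    """
    m = as_binary_mask(mask)
    labels, n = ndimage.label(m, structure=_EIGHT)
    comps = []
    for lab in range(1, n + 1):
        comp = (labels == lab).astype(np.uint8)
        rows, cols = np.nonzero(comp)
        first = (int(rows[0]), int(cols[np.argmin(cols[rows == rows[0]])]))
        comps.append((comp, int(comp.sum()), first))
    comps.sort(key=lambda t: (-t[1], t[2]))
    return [c for c, _, _ in comps]


def classify_occlusion(instance: InstanceMask) -> str:
    """``"unoccluded"`` for a single-component mask, ``"occluded"`` for >= 2.

    An occluded object is one whose visible mask was split by a covering
    object.  Raises on an empty mask.
    """
    if instance.area == 0:
        raise ValueError("cannot classify an empty instance mask")
    _, n = ndimage.label(instance.mask, structure=_EIGHT)
    return "unoccluded" if n == 1 else "occluded"


def overlap_from_fit(fitted_mask: np.ndarray, covering: InstanceMask) -> tuple[np.ndarray, int]:
    """Intersect the fitted region with the covering mask; count pixels (CD)."""
    fm = as_binary_mask(fitted_mask)
    if fm.shape != covering.mask.shape:
        raise ValueError(f"shape mismatch: {fm.shape} vs {covering.mask.shape}")
    overlap = fm & covering.mask
    return overlap, mask_area(overlap)


def fit_overlap_region(occluded_mask: np.ndarray) -> tuple[np.ndarray, object, bool]:
    """Fit the hidden-gap region between the two largest fragments.

    Returns ``(fitted_mask, construction_or_None, fallback_used)``.  The
    fallback (convex hull of the two fragments) triggers only when the
    external-tangent construction is degenerate.
    """
    comps = connected_components(occluded_mask)
    if len(comps) < 2:
        raise ValueError("occluded mask must have >= 2 components")
    frag1, frag2 = comps[0], comps[1]
    c1 = max_inscribed_circle(frag1)
    c2 = max_inscribed_circle(frag2)
    shape = frag1.shape
    try:
        construction = external_tangent_quad(c1, c2)
    except TangentDegenerateError:
        hull = convex_hull_image((frag1 | frag2).astype(bool)).astype(np.uint8)
        return hull, None, True
    fitted = rasterize_polygon(construction.quad, shape)
    return fitted, construction, False


def cot_pipeline(sample: Sample) -> OverlapResult:
    """Run the full overlap reconstruction on a two-instance sample.

    Exactly one instance is expected to classify as occluded.  If neither
    is occluded there is no hidden area and CD = 0.  If both are occluded
    each is processed against the other and the CDs are summed, with a
    warning (the geometry is then less reliable).
    """
    if len(sample.instances) != 2:
        raise ValueError(f"expected exactly 2 instances, got {len(sample.instances)}")
    shape = tuple(sample.image_shape)
    status = [classify_occlusion(inst) for inst in sample.instances]
    empty = np.zeros(shape, dtype=np.uint8)

    occluded_idx = [i for i, s in enumerate(status) if s == "occluded"]
    if not occluded_idx:
        return OverlapResult(
            occluded_instance_id=None, fitted_mask=empty, overlap_mask=empty.copy(), cd=0
        )
    if len(occluded_idx) == 2:
        warnings.warn("both instances are occluded; summing both reconstructions")
        total_fit = empty.copy()
        total_ov = empty.copy()
        cd = 0
        fallback = False
        for i in (0, 1):
            fitted, _, fb = fit_overlap_region(sample.instances[i].mask)
            ov, c = overlap_from_fit(fitted, sample.instances[1 - i])
            total_fit |= fitted
            total_ov |= ov
            cd += c
            fallback |= fb
        return OverlapResult(
            occluded_instance_id=sample.instances[occluded_idx[0]].instance_id,
            fitted_mask=total_fit,
            overlap_mask=total_ov,
            cd=cd,
            fallback_used=fallback,
        )

    occ = occluded_idx[0]
    covering = sample.instances[1 - occ]
    fitted, construction, fallback = fit_overlap_region(sample.instances[occ].mask)
    overlap, cd = overlap_from_fit(fitted, covering)
    return OverlapResult(
        occluded_instance_id=sample.instances[occ].instance_id,
        fitted_mask=fitted,
        overlap_mask=overlap,
        cd=cd,
        construction=construction,
        fallback_used=fallback,
    )
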