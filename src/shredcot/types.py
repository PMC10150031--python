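"""Core data model shared across the pipeline.

Masks are plain 2-D numpy arrays with values in {0, 1} (dtype uint8),
indexed ``(row, col)`` from the top-left corner.  Geometric quantities
(circle centers, polygon vertices) use ``(x, y)`` floats with ``x = col``
and ``y = row``, matching annotation-tool conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "as_binary_mask",
    "mask_area",
    "InstanceMask",
    "Sample",
    "EnclosingCircle",
    "InscribedCircle",
    "TangentConstruction",
    "OverlapResult",
    "AreaRecord",
    "AreaSummary",
]


def as_binary_mask(arr: np.ndarray) -> np.ndarray:
    """Validate and normalise *arr* to a uint8 {0,1} mask.

    Any nonzero value counts as foreground.  Raises ``ValueError`` for
    non-2-D input.
    """
    a = np.asarray(arr)
    if a.ndim != 2:
        raise ValueError(f"binary mask must be 2-D, got shape {a.shape}")
    return (a != 0).astype(np.uint8)


def mask_area(mask: np.ndarray) -> int:
    """Number of foreground pixels."""
    return int(np.count_nonzero(mask))


@dataclass
class InstanceMask:
    """One object's visible mask plus its class label.

    ``class_label`` is one of the shred varieties G/P/Y/Z for real data, or
    any string for synthetic instances.
    """

    mask: np.ndarray
    class_label: str = ""
    instance_id: int = 0

    def __post_init__(self) -> None:
        self.mask = as_binary_mask(self.mask)

    @property
    def area(self) -> int:
        return mask_area(self.mask)


@dataclass
class Sample:
    """A set of per-instance visible masks sharing one image canvas.

    Instance masks are pairwise disjoint at pixel level: each pixel belongs
    to at most one instance.
    """

    instances: list[InstanceMask]
    image_shape: tuple[int, int]

    def __post_init__(self) -> None:
        for inst in self.instances:
            if inst.mask.shape != tuple(self.image_shape):
                raise ValueError(
                    f"instance mask shape {inst.mask.shape} != image shape {self.image_shape}"
                )

    def validate_disjoint(self) -> None:
        """Raise if any pixel is claimed by two instances."""
        if not self.instances:
            return
        total = np.zeros(self.image_shape, dtype=np.int32)
        for inst in self.instances:
            total += inst.mask
        if total.max(initial=0) > 1:
            raise ValueError("instance masks are not pairwise disjoint")


@dataclass(frozen=True)
class EnclosingCircle:
    """Smallest circle containing all foreground pixel centers."""

    center: tuple[float, float]  # (x, y)
    radius: float


@dataclass(frozen=True)
class InscribedCircle:
    """Maximum circle fully inside one connected component.

    The center sits at the (exact Euclidean) distance-transform maximum of
    the component; the radius is that maximum distance.  ``diameter`` is
    provided because overlap-fitting formulas are usually written in
    diameters d1/d2.
    """

    center: tuple[float, float]  # (x, y)
    radius: float

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius


@dataclass(frozen=True)
class TangentConstruction:
    """Common-external-tangent construction around two circles.

    ``l0`` is the center line (a pair of endpoints); ``l1``/``l2`` are the
    two external tangent lines, each as ``(point, direction)``; ``quad`` is
    the 4-vertex fitted polygon closed by the chords between tangent points,
    ordered counter-clockwise.
    """

    l0: tuple[tuple[float, float], tuple[float, float]]
    l1: tuple[tuple[float, float], tuple[float, float]]
    l2: tuple[tuple[float, float], tuple[float, float]]
    quad: np.ndarray  # (4, 2) float array of (x, y) vertices


@dataclass
class OverlapResult:
    """Output of the overlap-region fit for one two-instance sample."""

    occluded_instance_id: int | None
    fitted_mask: np.ndarray
    overlap_mask: np.ndarray
    cd: int
    construction: TangentConstruction | None = None
    fallback_used: bool = False


@dataclass
class AreaRecord:
    """Per-sample area bookkeeping.

    ``area_1``/``area_2`` are the true (amodal) areas of the two objects,
    ``ad`` the visible composite area, ``cd`` the recovered hidden-overlap
    area, and ``aar``/``car`` the area-recovery ratios before and after the
    correction.
    """

    sample_id: str
    area_1: float
    area_2: float
    ad: float
    cd: float
    aar: float
    car: float


@dataclass
class AreaSummary:
    """n-sample summary of area-recovery ratios."""

    n: int
    avg_aar: float
    avg_car: float
    min_increase: float
    max_increase: float
    mean_increase: float
    negative_optimization_count: int

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "avg_aar": self.avg_aar,
            "avg_car": self.avg_car,
            "min_increase": self.min_increase,
            "max_increase": self.max_increase,
            "mean_increase": self.mean_increase,
            "negative_optimization_count": self.negative_optimization_count,
        }
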