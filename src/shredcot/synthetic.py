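"""Seeded generator of overlapped elongated-ribbon samples with known
hidden-overlap ground truth.

Real overlapped-shred photographs are not publicly deposited, so every
pipeline stage is exercised on synthetic ribbons: thick quadratic Bezier
curves emulating long, thin, gently curved shreds.  Two overlap regimes are
generated, mirroring how two shreds can interact on the imaging stage:

* ``inter-overlapped`` — one ribbon partially covers the other, so the
  covered ribbon's visible mask splits into >= 2 connected components;
* ``adhesion`` — the ribbons touch along their borders with only a
  marginal hidden area (at most a small fraction of the smaller ribbon).

Each sample carries the amodal (un-occluded) masks of both ribbons, hence
the exact hidden-overlap area, giving an oracle for the reconstruction:
with CD replaced by the true overlap area, CAR equals 1 identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .cot import cot_pipeline
from .metrics import aar, car, summarize
from .types import AreaRecord, AreaSummary, InstanceMask, Sample, mask_area

__all__ = [
    "GeneratorConfig",
    "SyntheticSample",
    "ribbon_from_spine",
    "make_ribbon",
    "make_overlapped_sample",
    "perpendicular_cross_sample",
    "run_benchmark",
]


@dataclass
class GeneratorConfig:
    """Knobs of the ribbon generator.

    ``width_range`` is the ribbon thickness in pixels (drawn uniformly per
    ribbon); ``curvature`` is the fractional sideways spread of the middle
    Bezier control point relative to the canvas size (0 = straight).
    ``overlap_type`` selects the regime; ``adhesion_max_overlap`` caps the
    hidden area of an adhesion pair as a fraction of the smaller ribbon.
    """

    image_shape: tuple[int, int] = (192, 256)
    width_range: tuple[int, int] = (14, 22)
    curvature: float = 0.15
    overlap_type: str = "inter-overlapped"  # or "adhesion" or "none"
    min_fragments: int = 2
    max_retries: int = 50
    adhesion_max_overlap: float = 0.05

    def __post_init__(self) -> None:
        if self.width_range[0] <= 0 or self.width_range[1] < self.width_range[0]:
            raise ValueError("width_range must be positive and ordered")
        if self.max_retries < 1:
            raise ValueError("max_retries must be >= 1")
        if self.overlap_type not in {"inter-overlapped", "adhesion", "none"}:
            raise ValueError(f"unknown overlap_type {self.overlap_type!r}")


@dataclass
class SyntheticSample:
    """One generated pair with amodal ground truth.

    ``sample`` holds the *visible* instances (ribbon 1 on top; ribbon 2's
    visible mask is its full mask minus ribbon 1).  ``true_overlap`` is the
    amodal intersection — the area the reconstruction should recover.
    """

    shred1_full: np.ndarray
    shred2_full: np.ndarray
    sample: Sample
    true_overlap: np.ndarray
    true_overlap_area: int
    seed: int

    @property
    def ad(self) -> int:
        """Visible composite area (union of the visible instances)."""
        return mask_area(self.shred1_full | self.shred2_full)


def _bezier_points(p0, p1, p2, n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2


def ribbon_from_spine(
    spine_points: np.ndarray, width: float, shape: tuple[int, int]
) -> np.ndarray:
    """Thicken a polyline spine into a ribbon mask of the given width.

    The ribbon is the set of pixels whose center lies within Euclidean
    distance ``width / 2`` of the (continuous, sub-pixel) spine polyline.
    A spine placed on half-integer coordinates therefore yields a ribbon
    exactly ``width`` pixels thick for even widths.
    """
    h, w = shape
    pts = np.asarray(spine_points, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("spine needs >= 2 (x, y) points")
    # densify so consecutive samples are < 0.5 px apart (keeps the union of
    # discs, hence the ribbon, connected)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if seg.max(initial=0.0) > 0.5:
        dense = [pts[0]]
        for a, b, d in zip(pts[:-1], pts[1:], seg):
            k = max(1, int(np.ceil(d / 0.5)))
            for t in np.linspace(0, 1, k + 1)[1:]:
                dense.append(a + t * (b - a))
        pts = np.asarray(dense)
    cols, rows = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    centers = np.column_stack([cols.ravel(), rows.ravel()])
    dist, _ = cKDTree(pts).query(centers, k=1)
    return (dist.reshape(shape) <= width / 2.0).astype(np.uint8)


def _random_spine(
    rng: np.random.Generator, shape: tuple[int, int], axis: str, curvature: float
) -> np.ndarray:
    """Quadratic Bezier spanning the canvas along ``axis`` ('h' or 'v')."""
    h, w = shape
    if axis == "h":
        y0, y2 = rng.uniform(0.25 * h, 0.75 * h, size=2)
        p0 = np.array([0.0, y0])
        p2 = np.array([w - 1.0, y2])
        mid_y = (y0 + y2) / 2 + rng.uniform(-curvature, curvature) * h
        p1 = np.array([w / 2 + rng.uniform(-0.1, 0.1) * w, mid_y])
    else:
        x0, x2 = rng.uniform(0.25 * w, 0.75 * w, size=2)
        p0 = np.array([x0, 0.0])
        p2 = np.array([x2, h - 1.0])
        mid_x = (x0 + x2) / 2 + rng.uniform(-curvature, curvature) * w
        p1 = np.array([mid_x, h / 2 + rng.uniform(-0.1, 0.1) * h])
    # resample if control points coincide (degenerate spine)
    if np.allclose(p0, p2):
        return _random_spine(rng, shape, axis, curvature)
    n = 4 * max(h, w)
    return _bezier_points(p0, p1, p2, n)


def make_ribbon(
    seed: int | np.random.Generator, config: GeneratorConfig, axis: str = "h"
) -> np.ndarray:
    """One random ribbon mask spanning the canvas; single connected component."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spine = _random_spine(rng, config.image_shape, axis, config.curvature)
    width = rng.uniform(*config.width_range)
    return ribbon_from_spine(spine, width, config.image_shape)


def _assemble(full1: np.ndarray, full2: np.ndarray, shape, seed: int) -> SyntheticSample:
    visible2 = (full2 & ~full1).astype(np.uint8)
    overlap = (full1 & full2).astype(np.uint8)
    sample = Sample(
        instances=[
            InstanceMask(mask=full1, class_label="S1", instance_id=0),
            InstanceMask(mask=visible2, class_label="S2", instance_id=1),
        ],
        image_shape=shape,
    )
    return SyntheticSample(
        shred1_full=full1,
        shred2_full=full2,
        sample=sample,
        true_overlap=overlap,
        true_overlap_area=mask_area(overlap),
        seed=seed,
    )


def _n_components(mask: np.ndarray) -> int:
    _, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    return n


def make_overlapped_sample(seed: int, config: GeneratorConfig) -> SyntheticSample:
    """Generate one two-ribbon sample of the configured overlap regime.

    Resamples (up to ``config.max_retries``) until the regime's geometric
    constraints hold; raises naming the unmet constraint otherwise.
    """
    rng = np.random.default_rng(seed)
    shape = config.image_shape
    last_reason = "no attempt made"
    for _ in range(config.max_retries):
        if config.overlap_type == "none":
            h, w = shape
            half = (h // 2, w)
            top = np.zeros(shape, dtype=np.uint8)
            bot = np.zeros(shape, dtype=np.uint8)
            sub = GeneratorConfig(
                image_shape=half,
                width_range=config.width_range,
                curvature=config.curvature,
                overlap_type="none",
            )
            top[: h // 2] = make_ribbon(rng, sub, axis="h")
            bot[h - h // 2 :] = make_ribbon(rng, sub, axis="h")
            if not (top & bot).any() and not (ndimage.binary_dilation(top) & bot).any():
                return _assemble(top, bot, shape, seed)
            last_reason = "disjoint ribbons still touch"
            continue

        full1 = make_ribbon(rng, config, axis="h")  # covering ribbon, on top
        full2 = make_ribbon(rng, config, axis="v")  # covered ribbon

        if config.overlap_type == "inter-overlapped":
            overlap = full1 & full2
            if not overlap.any():
                last_reason = "ribbons do not intersect"
                continue
            visible2 = full2 & ~full1
            if _n_components(visible2) < config.min_fragments:
                last_reason = f"covered ribbon has < {config.min_fragments} visible fragments"
                continue
            if _n_components(full1) != 1 or _n_components(full2) != 1:
                last_reason = "ribbon not a single component"
                continue
            return _assemble(full1, full2, shape, seed)

        # adhesion: two roughly parallel ribbons; slide the second one
        # vertically until grazing contact with a marginal intersection
        full2 = make_ribbon(rng, config, axis="h")
        overlap_cap = config.adhesion_max_overlap * min(mask_area(full1), mask_area(full2))
        rows2 = np.nonzero(full2.any(axis=1))[0]
        best = None
        for shift in range(-(rows2.min()), shape[0] - rows2.max()):
            moved = np.roll(full2, shift, axis=0)
            inter = mask_area(full1 & moved)
            if 1 <= inter <= overlap_cap and (inter < best[0] if best else True):
                best = (inter, moved)
        if best is not None:
            return _assemble(full1, best[1].astype(np.uint8), shape, seed)
        last_reason = "no adhesive placement with small enough overlap"

    raise RuntimeError(
        f"generator exhausted {config.max_retries} retries ({config.overlap_type}): {last_reason}"
    )


def perpendicular_cross_sample(
    shape: tuple[int, int] = (140, 140), width: int = 20
) -> SyntheticSample:
    """Canonical test case: two straight perpendicular ribbons through the
    canvas center; the true hidden area is the ``width x width`` strip
    intersection (400 px for the default width of 20)."""
    h, w = shape
    # half-integer center lines make even widths exact
    yc, xc = h / 2 - 0.5, w / 2 - 0.5
    horiz = ribbon_from_spine(
        np.column_stack([np.arange(w, dtype=float), np.full(w, yc)]), width, shape
    )
    vert = ribbon_from_spine(
        np.column_stack([np.full(h, xc), np.arange(h, dtype=float)]), width, shape
    )
    return _assemble(horiz, vert, shape, seed=0)


def run_benchmark(
    n: int, seed: int, config: GeneratorConfig | None = None
) -> tuple[AreaSummary, list[AreaRecord]]:
    """Generate ``n`` samples, run the overlap reconstruction on each, and
    score it against the amodal ground truth.

    Per sample: Area_1/Area_2 are the amodal ribbon areas, AD the visible
    composite area, CD the reconstructed hidden area.  Each sample draws
    from its own stream keyed by ``(seed, index)`` so results do not depend
    on ``n``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    config = config or GeneratorConfig()
    records: list[AreaRecord] = []
    for i in range(n):
        sub_seed = int(np.random.SeedSequence(entropy=seed, spawn_key=(i,)).generate_state(1)[0] % (2**31))
        syn = make_overlapped_sample(sub_seed, config)
        a1 = mask_area(syn.shred1_full)
        a2 = mask_area(syn.shred2_full)
        ad = syn.ad
        cd = cot_pipeline(syn.sample).cd
        records.append(
            AreaRecord(
                sample_id=f"syn-{i}",
                area_1=a1,
                area_2=a2,
                ad=ad,
                cd=cd,
                aar=aar(ad, a1, a2),
                car=car(ad, cd, a1, a2),
            )
        )
    return summarize(records), records
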