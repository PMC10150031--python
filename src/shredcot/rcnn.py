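"""Region-proposal anchor generation and feature-pyramid topology.

Two anchor parameterizations are bundled: the stock Mask R-CNN defaults
(sizes [128, 256, 512], aspect ratios [0.5, 1, 2]; 9 anchors per position)
and the small-object tuning for thin elongated targets (sizes
[32, 64, 128, 256], ratios [0.5, 1, 1.5, 2]; 16 per position).  Anchors are
area-preserving: an anchor of size s and ratio q = h/w has width s/sqrt(q)
and height s*sqrt(q), so its area is exactly s^2 for every ratio.

The module also emits a machine-readable fusion topology for the pyramid:
either plain top-down FPN, or the U-shaped variant that adds bottom-up
stride-2 edges (P_{k-1} -> P_k for P3..P6) and an extra 3x3 lateral edge
feeding shallow backbone detail (C3 -> P3 by default) — useful shallow
features of thin objects otherwise wash out at depth.  Backbone taps are
the four DenseNet-121 dense blocks at strides 4/8/16/32.  No network is
built or trained here; the outputs are anchors and a validated topology
document.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = [
    "AnchorConfig",
    "Anchor",
    "FeatureLevelSpec",
    "IMPROVED_ANCHORS",
    "LEGACY_ANCHORS",
    "generate_anchors",
    "anchors_per_position",
    "anchor_coverage",
    "build_topology",
    "topology_to_json",
    "topology_from_json",
]

_OPERATORS = {
    "lateral-1x1",
    "topdown-up2",
    "bottomup-3x3s2",
    "lateral-3x3",
    "maxpool-s2",
    "identity",
}


@dataclass(frozen=True)
class AnchorConfig:
    """Anchor sizes (sqrt of area, px) and aspect ratios (h/w)."""

    sizes: tuple[float, ...] = (32, 64, 128, 256)
    aspect_ratios: tuple[float, ...] = (0.5, 1, 1.5, 2)

    def __post_init__(self) -> None:
        if not self.sizes or not self.aspect_ratios:
            raise ValueError("sizes and aspect_ratios must be non-empty")
        if min(self.sizes) <= 0 or min(self.aspect_ratios) <= 0:
            raise ValueError("sizes and aspect_ratios must be positive")


#: Small-object tuning for thin elongated targets (16 anchors/position).
IMPROVED_ANCHORS = AnchorConfig()
#: Stock Mask R-CNN defaults (9 anchors/position).
LEGACY_ANCHORS = AnchorConfig(sizes=(128, 256, 512), aspect_ratios=(0.5, 1, 2))


@dataclass(frozen=True)
class Anchor:
    center: tuple[float, float]  # (x, y) px
    width: float
    height: float

    @property
    def area(self) -> float:
        return self.width * self.height


def anchors_per_position(config: AnchorConfig) -> int:
    return len(config.sizes) * len(config.aspect_ratios)


def _anchor_wh(size: float, ratio: float) -> tuple[float, float]:
    return size / np.sqrt(ratio), size * np.sqrt(ratio)


def generate_anchors(
    config: AnchorConfig, stride: int, grid: tuple[int, int]
) -> list[Anchor]:
    """Tile every (size, ratio) anchor at every grid position.

    Anchor centers sit at ``(col * stride, row * stride)``; the total count
    is ``grid_h * grid_w * |sizes| * |ratios|``.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    gh, gw = grid
    if gh < 1 or gw < 1:
        raise ValueError("grid must be positive")
    anchors: list[Anchor] = []
    for row in range(gh):
        for col in range(gw):
            cx, cy = float(col * stride), float(row * stride)
            for size in config.sizes:
                for ratio in config.aspect_ratios:
                    w, h = _anchor_wh(size, ratio)
                    anchors.append(Anchor(center=(cx, cy), width=float(w), height=float(h)))
    return anchors


def _centered_iou(w1: float, h1: float, w2: float, h2: float) -> float:
    inter = min(w1, w2) * min(h1, h2)
    return inter / (w1 * h1 + w2 * h2 - inter)


def anchor_coverage(
    config: AnchorConfig,
    widths: list[float] | np.ndarray,
    heights: list[float] | np.ndarray,
    iou_threshold: float = 0.5,
) -> float:
    """Fraction of ground-truth boxes matched by some anchor shape.

    A box is covered when its best IoU against the anchor set (compared
    center-aligned, i.e. shape-only, as at the best-matching position and
    stride) exceeds ``iou_threshold``.
    """
    widths = np.asarray(widths, dtype=float)
    heights = np.asarray(heights, dtype=float)
    if widths.size == 0 or widths.shape != heights.shape:
        raise ValueError("widths and heights must be non-empty, equal-length")
    shapes = [_anchor_wh(s, q) for s in config.sizes for q in config.aspect_ratios]
    covered = 0
    for bw, bh in zip(widths, heights):
        best = max(_centered_iou(bw, bh, aw, ah) for aw, ah in shapes)
        if best > iou_threshold:
            covered += 1
    return covered / widths.size


# ---------------------------------------------------------------------------
# pyramid topology


@dataclass
class FeatureLevelSpec:
    """One pyramid level: name, stride, channels and fusion edges.

    ``fusion_inputs`` lists ``(source_level, operator)`` pairs; operators
    are drawn from ``{lateral-1x1, topdown-up2, bottomup-3x3s2,
    lateral-3x3, maxpool-s2}``.
    """

    name: str
    stride: int
    channels: int
    fusion_inputs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for _, op in self.fusion_inputs:
            if op not in _OPERATORS:
                raise ValueError(f"unknown fusion operator {op!r}")


def build_topology(
    variant: str = "u-fpn",
    backbone: str = "densenet121-taps",
    channels: int = 256,
    extra_lateral_levels: tuple[str, ...] = ("C3",),
) -> list[FeatureLevelSpec]:
    """Feature-pyramid fusion graph for the given variant.

    ``fpn`` is the plain top-down pyramid (P6 is a stride-2 subsample of
    P5, no bottom-up fusion).  ``u-fpn`` runs the top-down pass into
    intermediate maps T2..T6 and then a second, bottom-up pass producing
    the final P2..P6: each of P3..P6 fuses its top-down map with a
    bottom-up 3x3/stride-2 edge from the previous (final) P level, plus a
    3x3 lateral edge from each backbone level named in
    ``extra_lateral_levels`` (Ck feeds Pk).  The two-pass structure keeps
    the fusion graph acyclic.
    """
    if variant not in {"fpn", "u-fpn"}:
        raise ValueError(f"unknown variant {variant!r}")
    if backbone != "densenet121-taps":
        raise ValueError(f"unknown backbone {backbone!r}")
    if not set(extra_lateral_levels) <= {"C2", "C3"}:
        raise ValueError("extra lateral taps are only defined for C2/C3")

    levels: list[FeatureLevelSpec] = []
    # backbone taps: dense blocks 1-4 after 2/3/4/5 halvings -> strides 4..32
    backbone_channels = {"C2": 256, "C3": 512, "C4": 1024, "C5": 1024}
    for k in range(2, 6):
        name = f"C{k}"
        levels.append(FeatureLevelSpec(name=name, stride=2**k, channels=backbone_channels[name]))

    if variant == "fpn":
        p_inputs: dict[str, list[tuple[str, str]]] = {
            "P5": [("C5", "lateral-1x1")],
            "P4": [("C4", "lateral-1x1"), ("P5", "topdown-up2")],
            "P3": [("C3", "lateral-1x1"), ("P4", "topdown-up2")],
            "P2": [("C2", "lateral-1x1"), ("P3", "topdown-up2")],
            "P6": [("P5", "maxpool-s2")],
        }
    else:
        # first pass: top-down intermediates T2..T6
        t_inputs: dict[str, list[tuple[str, str]]] = {
            "T5": [("C5", "lateral-1x1")],
            "T4": [("C4", "lateral-1x1"), ("T5", "topdown-up2")],
            "T3": [("C3", "lateral-1x1"), ("T4", "topdown-up2")],
            "T2": [("C2", "lateral-1x1"), ("T3", "topdown-up2")],
            "T6": [("T5", "maxpool-s2")],
        }
        for k in range(2, 7):
            levels.append(
                FeatureLevelSpec(
                    name=f"T{k}", stride=2**k, channels=channels, fusion_inputs=t_inputs[f"T{k}"]
                )
            )
        # second pass: bottom-up outputs P2..P6
        p_inputs = {"P2": [("T2", "identity")]}
        for k in range(3, 7):
            p_inputs[f"P{k}"] = [(f"T{k}", "identity"), (f"P{k - 1}", "bottomup-3x3s2")]
        for c in extra_lateral_levels:
            p_inputs[f"P{c[1]}"].append((c, "lateral-3x3"))

    for k in range(2, 7):
        name = f"P{k}"
        levels.append(
            FeatureLevelSpec(name=name, stride=2**k, channels=channels, fusion_inputs=p_inputs[name])
        )
    _validate_topology(levels)
    return levels


def _validate_topology(levels: list[FeatureLevelSpec]) -> None:
    names = {lv.name for lv in levels}
    g = nx.DiGraph()
    g.add_nodes_from(names)
    for lv in levels:
        for src, _ in lv.fusion_inputs:
            if src not in names:
                raise ValueError(f"fusion input {src!r} of {lv.name} is not a level")
            g.add_edge(src, lv.name)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("fusion topology contains a cycle")
    p_levels = sorted((lv for lv in levels if lv.name.startswith("P")), key=lambda lv: lv.name)
    for a, b in zip(p_levels, p_levels[1:]):
        if b.stride != 2 * a.stride:
            raise ValueError(f"strides must double per level: {a.name}->{b.name}")


def topology_to_json(levels: list[FeatureLevelSpec], path: str | Path | None = None) -> str:
    doc = [
        {
            "name": lv.name,
            "stride": lv.stride,
            "channels": lv.channels,
            "fusion_inputs": [list(e) for e in lv.fusion_inputs],
        }
        for lv in levels
    ]
    text = json.dumps(doc, indent=2)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def topology_from_json(text_or_path: str | Path) -> list[FeatureLevelSpec]:
    s = str(text_or_path)
    if s.lstrip().startswith("["):
        text = s
    else:
        text = Path(s).read_text()
    doc = json.loads(text)
    levels = [
        FeatureLevelSpec(
            name=d["name"],
            stride=d["stride"],
            channels=d["channels"],
            fusion_inputs=[tuple(e) for e in d["fusion_inputs"]],
        )
        for d in doc
    ]
    _validate_topology(levels)
    return levels
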