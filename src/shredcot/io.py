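"""Readers and writers: PNG masks, LabelMe/COCO polygon annotations, area reports.

Mask PNG dialect: on write, background is 0 and foreground 255 (8-bit
grayscale); on read, any nonzero intensity is foreground.  Annotation
polygons store vertices as (x=col, y=row) floats.
"""

from __future__ import annotations

import csv
import json
import warnings
from pathlib import Path

import numpy as np
from PIL import Image

from .geometry import rasterize_polygon
from .metrics import summarize
from .types import AreaRecord, InstanceMask, Sample, as_binary_mask

__all__ = [
    "read_mask_png",
    "write_mask_png",
    "read_labelme",
    "read_coco",
    "write_area_report",
    "read_area_report",
    "write_area_report_json",
]


def read_mask_png(path: str | Path) -> np.ndarray:
    """Read a binary mask from an 8-bit PNG (grayscale or RGB).

    Pixels with intensity > 0 in any channel map to foreground.
    """
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.size == 0:
        raise ValueError(f"zero-size image: {path}")
    if arr.ndim == 3:
        arr = arr.max(axis=2)
    return as_binary_mask(arr)


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Write a {0,1} mask as 8-bit grayscale PNG (foreground = 255)."""
    m = as_binary_mask(mask)
    Image.fromarray((m * 255).astype(np.uint8), mode="L").save(path)


def _rasterize_disjoint(
    polys: list[tuple[str, np.ndarray]], image_shape: tuple[int, int]
) -> list[InstanceMask]:
    """Rasterize labelled polygons enforcing pairwise disjointness.

    The FIRST-listed polygon wins contested pixels (the annotator draws the
    covering object first); later polygons have already-claimed pixels
    erased.
    """
    occupied = np.zeros(image_shape, dtype=bool)
    instances: list[InstanceMask] = []
    for idx, (label, verts) in enumerate(polys):
        mask = rasterize_polygon(verts, image_shape)
        mask[occupied] = 0
        occupied |= mask.astype(bool)
        instances.append(InstanceMask(mask=mask, class_label=label, instance_id=idx))
    return instances


def read_labelme(path: str | Path, image_shape: tuple[int, int]) -> Sample:
    """Read a LabelMe-style polygon annotation JSON into a Sample.

    Polygons with fewer than 3 vertices are skipped with a warning.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if "shapes" not in doc:
        raise ValueError(f"not a LabelMe annotation (no 'shapes' key): {path}")
    polys: list[tuple[str, np.ndarray]] = []
    for shape in doc["shapes"]:
        pts = np.asarray(shape.get("points", []), dtype=float)
        if pts.ndim != 2 or len(pts) < 3:
            warnings.warn(f"skipping degenerate polygon ({len(pts)} vertices) in {path}")
            continue
        polys.append((str(shape.get("label", "")), pts))
    return Sample(instances=_rasterize_disjoint(polys, image_shape), image_shape=image_shape)


def read_coco(path: str | Path, image_id: int | None = None) -> Sample:
    """Read one image's instances from a COCO-style annotation JSON.

    Only polygon segmentations are supported (no RLE).  ``image_id``
    defaults to the first image listed.
    """
    with open(path) as fh:
        doc = json.load(fh)
    images = {im["id"]: im for im in doc.get("images", [])}
    if not images:
        raise ValueError(f"no images in COCO file: {path}")
    if image_id is None:
        image_id = doc["images"][0]["id"]
    if image_id not in images:
        raise ValueError(f"image id {image_id} not present in {path}")
    info = images[image_id]
    shape = (int(info["height"]), int(info["width"]))
    cats = {c["id"]: c.get("name", str(c["id"])) for c in doc.get("categories", [])}
    polys: list[tuple[str, np.ndarray]] = []
    for ann in doc.get("annotations", []):
        if ann.get("image_id") != image_id:
            continue
        seg = ann.get("segmentation")
        if not isinstance(seg, list) or not seg:
            raise ValueError("only polygon segmentations are supported")
        # one polygon per instance part; merge parts into one mask later via OR
        flat = np.asarray(seg[0], dtype=float).reshape(-1, 2)
        polys.append((cats.get(ann.get("category_id"), ""), flat))
    return Sample(instances=_rasterize_disjoint(polys, shape), image_shape=shape)


def _fmt_ratio(x: float) -> str:
    return f"{x:.3f}"


def write_area_report(records: list[AreaRecord], path: str | Path) -> None:
    """Write per-sample area records as CSV plus a final Average row.

    Columns: sample_id, area_1, area_2, ad, cd, aar, car.  Ratios are
    printed with 3 decimals; the Average row carries the mean AAR and CAR
    over raw (unrounded) values.
    """
    if not records:
        raise ValueError("no records to write")
    summary = summarize(records)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "area_1", "area_2", "ad", "cd", "aar", "car"])
        for r in records:
            w.writerow(
                [r.sample_id, r.area_1, r.area_2, r.ad, r.cd, _fmt_ratio(r.aar), _fmt_ratio(r.car)]
            )
        w.writerow(["Average", "", "", "", "", _fmt_ratio(summary.avg_aar), _fmt_ratio(summary.avg_car)])


def read_area_report(path: str | Path) -> list[AreaRecord]:
    """Read a CSV area report (ignoring any trailing Average row)."""
    records: list[AreaRecord] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            if row["sample_id"] == "Average":
                continue
            records.append(
                AreaRecord(
                    sample_id=row["sample_id"],
                    area_1=float(row["area_1"]),
                    area_2=float(row["area_2"]),
                    ad=float(row["ad"]),
                    cd=float(row["cd"]),
                    aar=float(row["aar"]),
                    car=float(row["car"]),
                )
            )
    return records


def write_area_report_json(records: list[AreaRecord], path: str | Path) -> None:
    """JSON twin of the CSV report (same fields, plus the summary block)."""
    if not records:
        raise ValueError("no records to write")
    doc = {
        "records": [vars(r) for r in records],
        "summary": summarize(records).to_dict(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
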