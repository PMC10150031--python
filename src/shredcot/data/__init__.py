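"""Bundled reference tables from the overlapped tobacco-shred evaluation.

Three small tables ship with the package:

* ``shred_areas.csv`` — true pixel areas of the 20 constituent shred
  samples (5 each of the G/P/Y/Z varieties), measured on un-occluded
  photographs.
* ``overlap_benchmark.csv`` — the 24 two-shred overlap samples with the
  published per-sample AAR and CAR ratios and the constituent-area sums.
* ``recognition_confidence.json`` — per-overlap-class recognition
  confidences (percent) reported by the segmentation stage, grouped by
  overlap type.

Per-row AD and CD are not published; ``benchmark_records`` reconstructs
them from the printed ratios (``AD = AAR * (Area_1 + Area_2)``,
``CD = (CAR - AAR) * (Area_1 + Area_2)``), which is exact up to the
3-decimal rounding of the printed ratios.
"""

from __future__ import annotations

import csv
import json
from importlib import resources

from ..types import AreaRecord

__all__ = [
    "load_shred_areas",
    "load_overlap_benchmark",
    "load_recognition_confidence",
    "benchmark_records",
]


def _open_text(name: str):
    return resources.files(__package__).joinpath(name).open()


def load_shred_areas() -> dict[str, float]:
    """Constituent shred areas (px) keyed by sample id (e.g. ``"G-1"``)."""
    with _open_text("shred_areas.csv") as fh:
        return {row["sample_id"]: float(row["area"]) for row in csv.DictReader(fh)}


def load_overlap_benchmark() -> list[dict]:
    """The 24 overlap rows: ids, constituent ids, area sum, AAR, CAR."""
    with _open_text("overlap_benchmark.csv") as fh:
        rows = []
        for row in csv.DictReader(fh):
            rows.append(
                {
                    "serial": int(row["serial"]),
                    "sample_id": row["sample_id"],
                    "shred_1": row["shred_1"],
                    "shred_2": row["shred_2"],
                    "area_sum": float(row["area_sum"]),
                    "aar": float(row["aar"]),
                    "car": float(row["car"]),
                }
            )
        return rows


def load_recognition_confidence() -> dict[str, dict[str, float]]:
    """Per-class recognition confidences (%) grouped by overlap type."""
    with _open_text("recognition_confidence.json") as fh:
        return json.load(fh)


def benchmark_records() -> list[AreaRecord]:
    """The benchmark rows as AreaRecords, with AD/CD reconstructed."""
    areas = load_shred_areas()
    records = []
    for row in load_overlap_benchmark():
        a1 = areas[row["shred_1"]]
        a2 = areas[row["shred_2"]]
        denom = a1 + a2
        records.append(
            AreaRecord(
                sample_id=row["sample_id"],
                area_1=a1,
                area_2=a2,
                ad=row["aar"] * denom,
                cd=(row["car"] - row["aar"]) * denom,
                aar=row["aar"],
                car=row["car"],
            )
        )
    return records
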