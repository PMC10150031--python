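"""Area-recovery metrics for overlapped-object samples.

For a two-object sample with true per-object areas Area_1 and Area_2,
visible composite area AD and recovered hidden-overlap area CD:

    AAR = AD / (Area_1 + Area_2)
    CAR = (AD + CD) / (Area_1 + Area_2)

AAR measures how much of the true total area is visible; CAR measures how
much is accounted for after the overlap correction.  CAR is deliberately
NOT clipped at 1 — an over-estimated overlap produces CAR > 1 and must stay
visible in the report.  A correction is a "negative optimization" when it
moves CAR further from 1 than AAR was: |CAR - 1| > |AAR - 1|.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

from .types import AreaRecord, AreaSummary

__all__ = ["aar", "car", "summarize", "group_mean", "round_half_up"]


def round_half_up(x: float, decimals: int) -> float:
    """Round with ties away from zero (half-up), as report tables print."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def aar(ad: float, area_1: float, area_2: float) -> float:
    """Actual area ratio: AD / (Area_1 + Area_2)."""
    denom = area_1 + area_2
    if denom <= 0:
        raise ValueError("area_1 + area_2 must be positive")
    if ad < 0:
        raise ValueError("ad must be >= 0")
    return ad / denom


def car(ad: float, cd: float, area_1: float, area_2: float) -> float:
    """Corrected area ratio: (AD + CD) / (Area_1 + Area_2); not clipped at 1."""
    if cd < 0:
        raise ValueError("cd must be >= 0")
    denom = area_1 + area_2
    if denom <= 0:
        raise ValueError("area_1 + area_2 must be positive")
    return (ad + cd) / denom


def summarize(records: list[AreaRecord]) -> AreaSummary:
    """Average AAR/CAR over n samples plus correction-increase statistics.

    Increases are ``car_i - aar_i``; averages are taken over raw values
    (rounding happens only at print time).
    """
    if not records:
        raise ValueError("cannot summarize an empty record list")
    n = len(records)
    aars = [r.aar for r in records]
    cars = [r.car for r in records]
    increases = [c - a for a, c in zip(aars, cars)]
    neg = sum(1 for a, c in zip(aars, cars) if abs(c - 1.0) > abs(a - 1.0))
    return AreaSummary(
        n=n,
        avg_aar=sum(aars) / n,
        avg_car=sum(cars) / n,
        min_increase=min(increases),
        max_increase=max(increases),
        mean_increase=sum(increases) / n,
        negative_optimization_count=neg,
    )


def group_mean(values: list[float], decimals: int = 1) -> float:
    """Arithmetic mean of a group of percentages, half-up rounded.

    Used to summarise per-class recognition confidences by overlap type.
    """
    if not values:
        raise ValueError("empty group")
    return round_half_up(sum(values) / len(values), decimals)
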