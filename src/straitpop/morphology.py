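"""Corolla lobe/tube ratio classification.

The measured lobe-to-tube length ratio (L/T) separates the three regional
forms of *Conandron ramondioides* into non-overlapping ranges:
Taiwan 1.853-3.105, Japan 1.053-1.575, China 0.339-0.37 (closed
intervals).  A ratio falling in a gap between ranges is "unclassified" —
there is no published rule for assigning it to the nearest range.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["RATIO_RANGES", "CorollaMeasurement", "classify_corolla"]

RATIO_RANGES: dict[str, tuple[float, float]] = {
    "Taiwan": (1.853, 3.105),
    "Japan": (1.053, 1.575),
    "China": (0.339, 0.37),
}


def _check_disjoint():
    items = sorted(RATIO_RANGES.values())
    for (a0, a1), (b0, b1) in zip(items, items[1:]):
        if b0 <= a1:
            raise AssertionError("corolla ratio ranges overlap")


_check_disjoint()


@dataclass(frozen=True)
class CorollaMeasurement:
    individual: str
    lobe_mm: float
    tube_mm: float
    lt_ratio: float
    assigned_region: str


def classify_corolla(lobe_mm: float, tube_mm: float,
                     individual: str = "") -> CorollaMeasurement:
    """Compute L/T and assign the region whose closed interval contains it."""
    if lobe_mm <= 0 or tube_mm <= 0:
        raise ValueError("lobe and tube lengths must be > 0")
    ratio = lobe_mm / tube_mm
    hits = [region for region, (lo, hi) in RATIO_RANGES.items()
            if lo <= ratio <= hi]
    region = hits[0] if len(hits) == 1 else "unclassified"
    return CorollaMeasurement(individual, lobe_mm, tube_mm, ratio, region)
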