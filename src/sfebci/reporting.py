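"""Task metrics and table statistics: placement IoU, mean/std summaries."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np


@dataclass(frozen=True)
class PlacementDeviation:
    """Axis-aligned offset (mm) of a placed square object from its target.

    ``side`` defaults to the 40 mm footprint of the 4 cm wooden block.
    """

    dx: float
    dy: float
    side: float = 40.0

    def __post_init__(self) -> None:
        if self.side <= 0:
            raise ValueError("object side must be positive")


def placement_iou(dev: PlacementDeviation) -> float:
    """Intersection over union (percent) of two equal axis-aligned squares
    offset by (dx, dy)."""
    s = dev.side
    overlap = max(0.0, s - abs(dev.dx)) * max(0.0, s - abs(dev.dy))
    union = 2.0 * s * s - overlap
    return 100.0 * overlap / union


def aggregate_stats(values) -> tuple[float, float]:
    """(mean, sample standard deviation) of a list of values.

    The n-1 denominator reproduces the subject-table spreads.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values for a sample std")
    return float(v.mean()), float(v.std(ddof=1))


def round_half_up(value: float, decimals: int = 2) -> float:
    """Half-up rounding to match printed table precision."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
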