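"""Manual two-diameter area measurement (the ImageJ-style protocol).

The manual protocol draws two orthogonal lines across the cleared circle,
reads the two diameters d1 and d2, and reports the circle area
A = pi * (d/2)^2 with d the mean diameter.  It serves as the independent
oracle against which the automated pixel measurement is validated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = ["ManualMeasurement", "manual_area", "append_manual_areas"]


@dataclass(frozen=True)
class ManualMeasurement:
    """Two orthogonal diameters and the circle area they imply (µm, µm²)."""

    d1: float
    d2: float
    d: float
    area: float


def manual_area(d1: float, d2: float) -> ManualMeasurement:
    """Area of the degradation circle from two orthogonal diameters.

    d = (d1 + d2) / 2 and A = π (d/2)²; the arithmetic mean is the standard
    reduction for near-circular regions and reduces to d for true circles.
    """
    if not (d1 > 0 and d2 > 0):
        raise ValueError("diameters must be positive")
    d = (d1 + d2) / 2.0
    return ManualMeasurement(d1=d1, d2=d2, d=d, area=math.pi * (d / 2.0) ** 2)


def append_manual_areas(table: pd.DataFrame) -> pd.DataFrame:
    """Append d_um and area_um2 columns to a (well_id, day, d1_um, d2_um) table."""
    out = table.copy()
    measured = [manual_area(r.d1_um, r.d2_um) for r in out.itertuples()]
    out["d_um"] = [m.d for m in measured]
    out["area_um2"] = [m.area for m in measured]
    return out
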