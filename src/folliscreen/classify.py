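"""Follicle health calls from degradation areas.

The screen is calibrated on control (untreated) follicles: their cleared
areas define a cutoff at mean − 1.5·SD under a normality assumption.  A
treated follicle whose corrected degradation area falls below the cutoff is
called dead ("X", positive toxic effect); above, healthy ("√"); exactly at
the cutoff, or whenever the measurement is edge-truncated and hence an
underestimate, the call is "?" and the well goes to manual review.

Note the statistical meaning of the cutoff: it sits 1.5 SD inside the
healthy distribution, so ≈7% of genuinely healthy follicles are flagged by
construction — the rule trades a known false-flag rate for sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientControlsError
from .segmentation import DegradationMeasurement

__all__ = [
    "HEALTHY",
    "DEAD",
    "INDETERMINATE",
    "ControlStats",
    "HealthCall",
    "GroupTestResult",
    "fit_controls",
    "classify_area",
    "classify_follicle",
    "compare_groups",
]

HEALTHY = "√"  # √
DEAD = "X"
INDETERMINATE = "?"

CUTOFF_SD_FACTOR = 1.5


@dataclass(frozen=True)
class ControlStats:
    """Control-group degradation statistics and the derived cutoff (µm²)."""

    n: int
    mean: float
    sd: float
    cutoff: float


@dataclass(frozen=True)
class HealthCall:
    """One follicle's √/X/? call with the triggering reason."""

    call: str
    reason: str  # above_cutoff | below_cutoff | at_cutoff | truncated
    area: float
    cutoff: float


@dataclass(frozen=True)
class GroupTestResult:
    """Welch t-test of treatment vs control degradation areas."""

    statistic: float
    p_value: float
    alternative: str


def fit_controls(areas: Sequence[float]) -> ControlStats:
    """Fit control statistics; cutoff = mean − 1.5·SD, floored at zero.

    Sample SD (n − 1 denominator).  Requires at least two finite,
    non-negative areas.
    """
    arr = np.asarray(list(areas), dtype=float)
    if arr.size < 2 or not np.isfinite(arr).all():
        raise InsufficientControlsError("insufficient controls: need >= 2 finite areas")
    if (arr < 0).any():
        raise ValueError("control areas must be non-negative")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    cutoff = max(0.0, mean - CUTOFF_SD_FACTOR * sd)
    return ControlStats(n=int(arr.size), mean=mean, sd=sd, cutoff=cutoff)


def classify_area(
    area: float,
    truncated: bool,
    controls: ControlStats,
    epsilon: float = 1e-6,
) -> HealthCall:
    """Apply the cutoff rule to one (area, truncated) pair.

    Truncation wins unconditionally: the measured area is a known
    underestimate, so no call on it can be trusted.  Otherwise the area is
    compared to the cutoff with relative tolerance ``epsilon`` so the
    paper-defined "equal to the cutoff" branch is reachable in floats.
    """
    cutoff = controls.cutoff
    if truncated:
        return HealthCall(INDETERMINATE, "truncated", area, cutoff)
    tol = epsilon * cutoff
    if area < cutoff - tol:
        return HealthCall(DEAD, "below_cutoff", area, cutoff)
    if area > cutoff + tol:
        return HealthCall(HEALTHY, "above_cutoff", area, cutoff)
    return HealthCall(INDETERMINATE, "at_cutoff", area, cutoff)


def classify_follicle(
    measurement: DegradationMeasurement,
    controls: ControlStats,
    epsilon: float = 1e-6,
) -> HealthCall:
    """√/X/? call for one measured follicle (uses the corrected area)."""
    return classify_area(
        measurement.corrected_area, measurement.truncated, controls, epsilon=epsilon
    )


def compare_groups(
    treatment_areas: Sequence[float],
    control_areas: Sequence[float],
    alternative: str = "less",
) -> GroupTestResult:
    """Welch's unequal-variance t-test of treatment vs control.

    ``alternative="less"`` is the one-sided toxicity test (treatment mean
    below control mean); ``"two-sided"`` serves group comparisons of
    diameters or areas where no direction is assumed.
    """
    t = np.asarray(list(treatment_areas), dtype=float)
    c = np.asarray(list(control_areas), dtype=float)
    if t.size < 2 or c.size < 2:
        raise ValueError("each group needs >= 2 values")
    if alternative not in ("less", "two-sided"):
        raise ValueError(f"unsupported alternative: {alternative!r}")
    res = stats.ttest_ind(t, c, equal_var=False, alternative=alternative)
    label = (
        "treatment mean below control mean"
        if alternative == "less"
        else "treatment mean differs from control mean"
    )
    return GroupTestResult(
        statistic=float(res.statistic), p_value=float(res.pvalue), alternative=label
    )
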