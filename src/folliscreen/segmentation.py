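"""Micrograph segmentation and degradation-area measurement.

A live follicle encapsulated in a fibrin-alginate bead secretes proteases
that clear the fibrin around it; in brightfield the cleared zone is bright
while intact fibrin stays dark and dense.  This module turns one calibrated
grayscale micrograph of a single bead into:

1. a global intensity threshold (Otsu's between-class variance criterion),
2. a binary degraded/intact mask (degraded = white by convention),
3. the bead circle and the follicle component,
4. a degradation-area measurement in µm², corrected for the area the
   follicle body occupies inside its own clearance zone, with a flag set
   when the clearance reaches the bead edge (the measured area is then an
   underestimate and the follicle needs manual review).

Coordinates are (row, col), origin top-left, 0-based.  Areas are computed
in px² and scaled by (microns_per_pixel)².
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import convex_hull_image

from .errors import (
    BeadClippedError,
    BeadNotFoundError,
    DegenerateImageError,
    FollicleNotFoundError,
    GeometryError,
    MultipleBeadsError,
    UnevenIlluminationError,
)

__all__ = [
    "Micrograph",
    "BinaryMask",
    "BeadGeometry",
    "FollicleGeometry",
    "DegradationMeasurement",
    "AnalysisResult",
    "estimate_threshold",
    "binarize",
    "locate_bead",
    "locate_follicle",
    "measure_degradation",
    "check_truncation",
    "circles_truncated",
    "analyze_micrograph",
]

_MIN_SIDE = 64


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Micrograph:
    """A calibrated grayscale brightfield image of one bead.

    Parameters
    ----------
    pixels
        2-D integer array, 8- or 16-bit unsigned.
    microns_per_pixel
        Length calibration in µm/px; must be finite and positive.
    well_id, day
        Provenance labels carried through to measurement records.
    """

    pixels: np.ndarray
    microns_per_pixel: float
    well_id: str = ""
    day: int = 0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D image, got shape {px.shape}")
        if min(px.shape) < _MIN_SIDE:
            raise ValueError(
                f"image must be at least {_MIN_SIDE}x{_MIN_SIDE}, got {px.shape}"
            )
        if px.dtype not in (np.dtype(np.uint8), np.dtype(np.uint16)):
            raise ValueError(f"expected uint8 or uint16 pixels, got {px.dtype}")
        if not (np.isfinite(self.microns_per_pixel) and self.microns_per_pixel > 0):
            raise ValueError("microns_per_pixel must be finite and > 0")
        if self.day < 0:
            raise ValueError("day must be >= 0")
        object.__setattr__(self, "pixels", px)

    @property
    def bit_depth(self) -> int:
        return 8 if self.pixels.dtype == np.uint8 else 16

    @property
    def intensity_range(self) -> tuple[int, int]:
        """(min, max) representable intensity for the declared bit depth."""
        return (0, (1 << self.bit_depth) - 1)


@dataclass(frozen=True)
class BinaryMask:
    """Degraded/intact labelling of a micrograph.

    ``degraded`` is boolean; True = degraded fibrin (rendered white),
    False = intact fibrin / follicle / anything dark (rendered black).
    """

    degraded: np.ndarray
    microns_per_pixel: float

    def __post_init__(self) -> None:
        deg = np.asarray(self.degraded, dtype=bool)
        if deg.ndim != 2:
            raise ValueError("mask must be 2-D")
        object.__setattr__(self, "degraded", deg)

    @property
    def shape(self) -> tuple[int, int]:
        return self.degraded.shape

    def to_uint8(self) -> np.ndarray:
        """Render as an 8-bit image: degraded = 255 (white), intact = 0."""
        return np.where(self.degraded, 255, 0).astype(np.uint8)


@dataclass(frozen=True)
class BeadGeometry:
    """Fitted circle of the hydrogel bead, in pixel coordinates."""

    center: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("bead radius must be > 0")


@dataclass(frozen=True)
class FollicleGeometry:
    """Centroid and size of the follicle component."""

    center: tuple[float, float]
    equivalent_radius: float  # px
    area: float  # µm²


@dataclass(frozen=True)
class DegradationMeasurement:
    """Cleared-fibrin area for one follicle image.

    ``raw_area`` counts only degraded pixels of the selected clearance
    component; ``corrected_area`` additionally restores the footprint the
    follicle body occupies inside the clearance (hole filling), so that a
    follicle expanding into its own cleared zone does not deflate the
    health readout.  All areas in µm².
    """

    raw_area: float
    follicle_area: float
    corrected_area: float
    truncated: bool
    threshold_used: float
    well_id: str = ""
    day: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.raw_area <= self.corrected_area + 1e-9):
            raise ValueError("require 0 <= raw_area <= corrected_area")


@dataclass(frozen=True)
class AnalysisResult:
    """Everything the single-image pipeline produces."""

    mask: BinaryMask
    bead: BeadGeometry
    follicle: FollicleGeometry
    measurement: DegradationMeasurement


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------

def _otsu_threshold(values: np.ndarray, n_levels: int) -> float:
    """Otsu's between-class variance maximiser over all integer levels.

    Scans every candidate threshold t (class 0 = intensity <= t); where the
    criterion plateaus, the midpoint of the maximal plateau containing the
    argmax is returned, so a clean two-level image yields a threshold midway
    between the levels rather than hugging the lower one.
    """
    hist = np.bincount(values.ravel(), minlength=n_levels).astype(np.float64)
    levels = np.arange(n_levels, dtype=np.float64)
    w0 = np.cumsum(hist)
    total = w0[-1]
    s0 = np.cumsum(hist * levels)
    w1 = total - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = s0 / w0
        mu1 = (s0[-1] - s0) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between[~np.isfinite(between)] = -1.0
    best = between.max()
    if best <= 0:
        raise DegenerateImageError("no separable classes")
    idx = int(np.argmax(between))
    # walk the plateau of (numerically) equal criterion values around argmax
    tol = best * 1e-12
    lo = idx
    while lo > 0 and abs(between[lo - 1] - best) <= tol:
        lo -= 1
    hi = idx
    while hi < n_levels - 1 and abs(between[hi + 1] - best) <= tol:
        hi += 1
    return (lo + hi) / 2.0


def _background_pixels(image: Micrograph, bead: BeadGeometry) -> np.ndarray:
    """Background annulus just outside the bead, for the illumination gate.

    The ring starts just beyond the outermost dark (fibrin) pixels rather
    than at the fitted radius: with a wide edge truncation the circle fit
    runs small and its centre shifts away from the bite, but the dark rim
    always marks the true bead boundary.
    """
    px = image.pixels
    rr, cc = np.ogrid[: px.shape[0], : px.shape[1]]
    dist = np.hypot(rr - bead.center[0], cc - bead.center[1])
    dark_d = dist[px <= _otsu_threshold(px, 1 << image.bit_depth)]
    rim = float(np.quantile(dark_d, 0.999)) if dark_d.size else bead.radius
    inner = max(rim, bead.radius) + 4
    ring = (dist > inner) & (dist <= inner + 25)
    return px[ring]


def estimate_threshold(
    image: Micrograph,
    bead: BeadGeometry | None = None,
    max_background_cv: float = 0.10,
) -> float:
    """Automatically determine the global degraded/intact threshold.

    Uses Otsu's criterion on the full image histogram.  When a bead
    geometry is supplied, the background annulus outside the bead is
    checked for even exposure (coefficient of variation above
    ``max_background_cv`` raises), since a single global threshold is only
    meaningful for an evenly exposed background; without a bead there is
    no principled background region and the gate is skipped.

    Returns a threshold strictly between the image minimum and maximum;
    deterministic for a fixed image.
    """
    px = image.pixels
    lo, hi = int(px.min()), int(px.max())
    if lo == hi:
        raise DegenerateImageError("no separable classes")
    if bead is not None:
        bg = _background_pixels(image, bead)
        mean = float(bg.mean()) if bg.size else 0.0
        if mean > 0:
            cv = float(bg.std()) / mean
            if cv > max_background_cv:
                raise UnevenIlluminationError(
                    f"uneven illumination: background CV {cv:.3f} > {max_background_cv:.3f}"
                )
    t = _otsu_threshold(px, 1 << image.bit_depth)
    # plateau mid-point already avoids t == min except for adjacent levels
    if not lo < t < hi:
        t = (lo + hi) / 2.0
    return float(t)


def binarize(image: Micrograph, threshold: float, invert: bool = False) -> BinaryMask:
    """Label every pixel degraded (bright clearance) or intact (dark fibrin).

    Pixels strictly above the threshold are degraded; ``invert`` swaps the
    rule for acquisitions where cleared fibrin images dark.
    """
    lo, hi = image.intensity_range
    if not lo <= threshold <= hi:
        raise ValueError(
            f"threshold {threshold} outside the image intensity range [{lo}, {hi}]"
        )
    degraded = image.pixels > threshold
    if invert:
        degraded = ~degraded
    return BinaryMask(degraded=degraded, microns_per_pixel=image.microns_per_pixel)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _distance_grid(shape: tuple[int, int], center: tuple[float, float]) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return np.hypot(rr - center[0], cc - center[1])


def _fit_circle_trimmed(
    points: np.ndarray, n_iter: int = 8, tol: float = 1.5
) -> tuple[tuple[float, float], float]:
    """Algebraic (Kasa) least-squares circle fit with outlier trimming.

    Each round refits and drops points whose radial residual exceeds
    max(tol px, the 75th residual percentile); chord points bridging a
    truncation gap are trimmed away while genuine rim points survive.
    """
    pts = points.astype(np.float64)
    cy = cx = r = float("nan")
    for _ in range(n_iter):
        y, x = pts[:, 0], pts[:, 1]
        a = np.column_stack([2 * y, 2 * x, np.ones(len(pts))])
        b = y * y + x * x
        (cy, cx, c), *_ = np.linalg.lstsq(a, b, rcond=None)
        r = math.sqrt(max(c + cy * cy + cx * cx, 0.0))
        resid = np.abs(np.hypot(y - cy, x - cx) - r)
        keep = resid <= max(tol, float(np.percentile(resid, 75)))
        if keep.all() or keep.sum() < 30:
            break
        pts = pts[keep]
    return (float(cy), float(cx)), float(r)


def locate_bead(image: Micrograph, allow_clipped: bool = False) -> BeadGeometry:
    """Fit a circle to the bead/background boundary.

    The bead presents as the one large dark (fibrin-filled) component; the
    boundary of its convex hull is circle-fit with outlier trimming, so
    the fit stays sub-pixel accurate even when edge truncation bites a gap
    into the fibrin annulus (the hull's chord across the gap is trimmed as
    outliers).
    """
    px = image.pixels
    if int(px.min()) == int(px.max()):
        raise BeadNotFoundError("bead not found: no contrast")
    t = _otsu_threshold(px, 1 << image.bit_depth)
    dark = px <= t
    labels, n = ndimage.label(dark, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        raise BeadNotFoundError("bead not found")
    min_area = math.pi * (0.15 * min(px.shape)) ** 2
    candidates = []
    for i in range(1, n + 1):
        comp = labels == i
        if comp.sum() < 0.1 * min_area:
            continue
        hull = convex_hull_image(comp)
        if hull.sum() >= min_area:
            candidates.append(hull)
    if not candidates:
        raise BeadNotFoundError("bead not found")
    if len(candidates) > 1:
        raise MultipleBeadsError(f"multiple beads: {len(candidates)} candidates")
    hull = candidates[0]
    touches = sum(
        bool(edge.any()) for edge in (hull[0], hull[-1], hull[:, 0], hull[:, -1])
    )
    if touches >= 3 and not allow_clipped:
        raise BeadClippedError("bead clipped: extends beyond the frame")
    area = float(hull.sum())
    r_idx, c_idx = np.nonzero(hull)
    center = (float(r_idx.mean()), float(c_idx.mean()))
    radius = math.sqrt(area / math.pi)
    boundary = np.argwhere(hull & ~ndimage.binary_erosion(hull))
    if len(boundary) >= 30:
        fit_center, fit_radius = _fit_circle_trimmed(boundary)
        diag = math.hypot(*hull.shape)
        if math.isfinite(fit_radius) and 0.5 * radius <= fit_radius <= diag:
            center, radius = fit_center, fit_radius
    return BeadGeometry(center=center, radius=radius)


def _pick_component(
    labels: np.ndarray, n: int, center: tuple[float, float], min_area: int
) -> np.ndarray | None:
    """Component of at least min_area px whose centroid is nearest center."""
    best = None
    best_d = np.inf
    sizes = np.bincount(labels.ravel(), minlength=n + 1)
    centroids = ndimage.center_of_mass(np.ones_like(labels), labels, range(1, n + 1))
    for i, (cr, cc) in enumerate(centroids, start=1):
        if sizes[i] < min_area:
            continue
        d = math.hypot(cr - center[0], cc - center[1])
        if d < best_d:
            best_d = d
            best = i
    if best is None:
        return None
    return labels == best


def locate_follicle(
    image: Micrograph,
    mask: BinaryMask,
    bead: BeadGeometry,
    seed_point: tuple[int, int] | None = None,
) -> FollicleGeometry:
    """Find the follicle: the dark body sitting inside its clearance zone.

    Strategy: the follicle is an intact-labelled hole fully enclosed by the
    degraded clearance, nearest the bead centre.  When no degradation
    exists (dead phenotype, matrix dark and dense everywhere) the follicle
    is recovered as the darkest central blob via a second threshold inside
    the bead.  A manual ``seed_point`` overrides the search and selects the
    intact component containing that pixel.
    """
    if mask.shape != image.pixels.shape:
        raise GeometryError("mask shape differs from image shape")
    dist = _distance_grid(image.pixels.shape, bead.center)
    inside = dist <= bead.radius - 1
    eight = np.ones((3, 3), dtype=int)

    comp = None
    if seed_point is not None:
        sr, sc = int(round(seed_point[0])), int(round(seed_point[1]))
        intact_in = ~mask.degraded & inside
        if not (0 <= sr < inside.shape[0] and 0 <= sc < inside.shape[1]) or not intact_in[sr, sc]:
            raise FollicleNotFoundError("follicle not found at the supplied seed")
        labels, _ = ndimage.label(intact_in, structure=eight)
        comp = labels == labels[sr, sc]
    else:
        degraded_in = mask.degraded & inside
        holes = ndimage.binary_fill_holes(degraded_in) & ~degraded_in
        if holes.any():
            labels, n = ndimage.label(holes, structure=eight)
            comp = _pick_component(labels, n, bead.center, min_area=9)
        if comp is None:
            # dead phenotype: no clearance, the whole bead interior is dark
            # fibrin with the slightly darker follicle body inside.  The
            # follicle class is far too small for a histogram split, so we
            # smooth away the noise and take pixels robustly below the
            # fibrin level (median - 4 * 1.4826 MAD of the smoothed field).
            vals = image.pixels[inside]
            if vals.size == 0 or int(vals.min()) == int(vals.max()):
                raise FollicleNotFoundError("follicle not found")
            smooth = ndimage.gaussian_filter(image.pixels.astype(np.float64), 2.0)
            core = smooth[dist <= bead.radius - 6]
            med = float(np.median(core))
            mad = float(np.median(np.abs(core - med)))
            thr = med - max(4.0 * 1.4826 * mad, 1.0)
            blob = (smooth <= thr) & inside
            blob = ndimage.binary_fill_holes(blob)
            labels, n = ndimage.label(blob, structure=eight)
            comp = _pick_component(labels, n, bead.center, min_area=25)
            if comp is None:
                raise FollicleNotFoundError("follicle not found")

    area_px = float(comp.sum())
    r_idx, c_idx = np.nonzero(comp)
    center = (float(r_idx.mean()), float(c_idx.mean()))
    if math.hypot(center[0] - bead.center[0], center[1] - bead.center[1]) > bead.radius:
        raise GeometryError("geometry inconsistent: follicle centroid outside bead")
    mpp = image.microns_per_pixel
    return FollicleGeometry(
        center=center,
        equivalent_radius=math.sqrt(area_px / math.pi),
        area=area_px * mpp * mpp,
    )


def check_truncation(
    component: np.ndarray, bead: BeadGeometry, margin: float = 3.0
) -> bool:
    """True iff the degradation component reaches the bead edge.

    A component pixel within ``margin`` px of the bead boundary circle
    means part of the true clearance lies beyond the bead and the measured
    area is an underestimate.
    """
    comp = np.asarray(component, dtype=bool)
    if not comp.any():
        return False
    dist = _distance_grid(comp.shape, bead.center)
    return bool((dist[comp] >= bead.radius - margin).any())


def circles_truncated(
    center_distance: float, degradation_radius: float, bead_radius: float,
    margin: float = 3.0,
) -> bool:
    """Analytic truncation predicate for ideal circle geometry.

    The clearance circle (radius ``degradation_radius``, its centre
    ``center_distance`` from the bead centre) reaches the bead edge iff
    ``center_distance + degradation_radius >= bead_radius - margin``.
    """
    return center_distance + degradation_radius >= bead_radius - margin


def measure_degradation(
    mask: BinaryMask,
    follicle: FollicleGeometry,
    bead: BeadGeometry,
    margin: float = 3.0,
    threshold_used: float = float("nan"),
    well_id: str = "",
    day: int = 0,
) -> DegradationMeasurement:
    """Measure the cleared-fibrin area belonging to this follicle.

    Selects the degraded 8-connected component (restricted to the bead
    interior) that encloses the follicle — the one clearance circle around
    the encapsulated follicle; stray degraded specks elsewhere are
    ignored.  The component is identified by its overlap with a thin disc
    just outside the follicle body, falling back to "filled interior
    contains the follicle centroid" (the two agree on clean geometry; the
    overlap test survives clearances cut open at the bead edge).
    ``corrected_area`` fills the component's holes, restoring the follicle
    footprint.  No qualifying component (dead phenotype) gives zero areas.
    """
    fr, fc = follicle.center
    if math.hypot(fr - bead.center[0], fc - bead.center[1]) > bead.radius:
        raise GeometryError("geometry inconsistent: follicle centroid outside bead")
    mpp2 = mask.microns_per_pixel ** 2
    dist = _distance_grid(mask.shape, bead.center)
    degraded_in = mask.degraded & (dist <= bead.radius)
    labels, n = ndimage.label(degraded_in, structure=np.ones((3, 3), dtype=int))
    fi, fj = int(round(fr)), int(round(fc))
    selected = None
    if n:
        fol_dist = _distance_grid(mask.shape, follicle.center)
        ring = fol_dist <= follicle.equivalent_radius + 4
        overlap = np.bincount(labels[ring].ravel(), minlength=n + 1)[1:]
        if overlap.max() > 0:
            selected = labels == (int(np.argmax(overlap)) + 1)
        else:
            order = np.argsort(np.bincount(labels.ravel())[1:])[::-1] + 1
            for i in order:
                comp = labels == i
                if ndimage.binary_fill_holes(comp)[fi, fj]:
                    selected = comp
                    break
    if selected is None:
        return DegradationMeasurement(
            raw_area=0.0,
            follicle_area=follicle.area,
            corrected_area=0.0,
            truncated=False,
            threshold_used=threshold_used,
            well_id=well_id,
            day=day,
        )
    raw_px = float(selected.sum())
    corrected_px = float(ndimage.binary_fill_holes(selected).sum())
    return DegradationMeasurement(
        raw_area=raw_px * mpp2,
        follicle_area=follicle.area,
        corrected_area=corrected_px * mpp2,
        truncated=check_truncation(selected, bead, margin),
        threshold_used=threshold_used,
        well_id=well_id,
        day=day,
    )


def analyze_micrograph(
    image: Micrograph,
    threshold_override: float | None = None,
    invert: bool = False,
    truncation_margin: float = 3.0,
    max_background_cv: float = 0.10,
    follicle_seed: tuple[int, int] | None = None,
    allow_clipped_bead: bool = False,
) -> AnalysisResult:
    """Run the full single-image pipeline: threshold → mask → geometry → area."""
    bead = locate_bead(image, allow_clipped=allow_clipped_bead)
    if threshold_override is not None:
        threshold = float(threshold_override)
    else:
        threshold = estimate_threshold(image, bead=bead, max_background_cv=max_background_cv)
    mask = binarize(image, threshold, invert=invert)
    follicle = locate_follicle(image, mask, bead, seed_point=follicle_seed)
    measurement = measure_degradation(
        mask,
        follicle,
        bead,
        margin=truncation_margin,
        threshold_used=threshold,
        well_id=image.well_id,
        day=image.day,
    )
    return AnalysisResult(mask=mask, bead=bead, follicle=follicle, measurement=measurement)
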