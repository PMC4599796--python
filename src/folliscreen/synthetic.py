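"""Seeded synthetic micrographs and whole simulated screening experiments.

Real bead micrographs show a bright background, a dark fibrin-filled bead,
a bright cleared circle where a live follicle has degraded the fibrin, and
the dark follicle body at the centre of its clearance; a dead follicle's
matrix stays dark and dense.  The generator rasterises exactly that flat
four-level geometry (plus speckle, Gaussian noise and an optional linear
illumination gradient) and returns the analytic ground truth for every
pixel, so each pipeline stage can be tested against known answers.

It deliberately does not model optics (no point-spread blur, no partial
degradation gradients): passing tests demonstrate correctness of the
measurement chain on idealised geometry, not robustness to real-world
focus or staining variation.

Default geometry (chosen once as the simulated study conditions): 512×512
px at 2 µm/px, bead radius 200 px, follicle radius 31 px (124 µm diameter,
a two-layered secondary follicle), live clearance radius 155 px — a cleared
area of ≈3×10⁵ µm², the day-6 control scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .segmentation import Micrograph

__all__ = [
    "SyntheticParams",
    "SyntheticTruth",
    "DoseGroup",
    "ExperimentResult",
    "LIVE_AREA_MEAN",
    "LIVE_AREA_SD",
    "DEAD_AREA_MEAN",
    "DEAD_AREA_SD",
    "DEFAULT_DESIGN",
    "OBSERVATION_DAYS",
    "generate_micrograph",
    "radius_for_area",
    "generate_experiment",
    "build_synthetic_plate",
    "micrograph_params_for_follicle",
]

# per-follicle corrected degradation area (µm²) on day 6
LIVE_AREA_MEAN = 3.0e5
LIVE_AREA_SD = 0.3e5
DEAD_AREA_MEAN = 0.3e5
DEAD_AREA_SD = 0.2e5

# cultures are imaged every 2 days up to day 12
OBSERVATION_DAYS: tuple[int, ...] = (0, 2, 4, 6, 8, 10, 12)

# pixel class labels in the ground-truth map
LABEL_BACKGROUND = 0
LABEL_FIBRIN = 1
LABEL_CLEARANCE = 2
LABEL_FOLLICLE = 3


@dataclass(frozen=True)
class SyntheticParams:
    """Geometry, intensity and noise parameters of one synthetic micrograph.

    ``degradation_radius = 0`` encodes the dead phenotype (no clearance).
    Intensity levels are 8-bit; their default ordering (background 230 >
    clearance 200 > fibrin 60 > follicle 40) mimics brightfield contrast.
    """

    image_size: tuple[int, int] = (512, 512)
    microns_per_pixel: float = 2.0
    bead_center: tuple[float, float] = (256.0, 256.0)
    bead_radius: float = 200.0
    follicle_center: tuple[float, float] = (256.0, 256.0)
    follicle_radius: float = 31.0
    degradation_radius: float = 155.0
    background_level: int = 230
    fibrin_level: int = 60
    clearance_level: int = 200
    follicle_level: int = 40
    noise_sd: float = 8.0
    speckle_sd: float = 5.0
    illumination_gradient: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be > 0")
        if self.bead_radius <= 0 or self.follicle_radius <= 0:
            raise ValueError("radii must be > 0")
        if self.degradation_radius < 0:
            raise ValueError("degradation_radius must be >= 0")
        if 0 < self.degradation_radius <= self.follicle_radius:
            raise ValueError(
                "a live clearance must extend beyond the follicle "
                "(degradation_radius > follicle_radius, or 0 for dead)"
            )
        d = math.hypot(
            self.follicle_center[0] - self.bead_center[0],
            self.follicle_center[1] - self.bead_center[1],
        )
        if d + self.follicle_radius > self.bead_radius:
            raise ValueError("follicle must lie inside the bead")
        for lvl in (
            self.background_level,
            self.fibrin_level,
            self.clearance_level,
            self.follicle_level,
        ):
            if not 0 <= lvl <= 255:
                raise ValueError("intensity levels must be within 0..255")

    @property
    def dead(self) -> bool:
        return self.degradation_radius == 0

    @property
    def offset(self) -> float:
        """Distance between follicle and bead centres (px)."""
        return math.hypot(
            self.follicle_center[0] - self.bead_center[0],
            self.follicle_center[1] - self.bead_center[1],
        )


@dataclass(frozen=True)
class SyntheticTruth:
    """Analytic ground truth for one generated micrograph.

    ``degradation_area`` is the filled clearance disc (clipped to the bead)
    in µm² — exactly what the corrected automated measurement estimates.
    """

    params: SyntheticParams
    label_map: np.ndarray
    degradation_area: float  # µm²
    follicle_area: float  # µm²
    truncated: bool

    def degraded_map(self) -> np.ndarray:
        """Boolean map of pixels a correct mask labels degraded (bright)."""
        return (self.label_map == LABEL_BACKGROUND) | (self.label_map == LABEL_CLEARANCE)


def generate_micrograph(
    params: SyntheticParams, truncation_margin: float = 3.0
) -> tuple[Micrograph, SyntheticTruth]:
    """Rasterise one bead micrograph plus its ground truth.

    Identical params (including seed) produce bit-identical images.
    """
    h, w = params.image_size
    rr, cc = np.ogrid[:h, :w]
    dist_bead = np.hypot(rr - params.bead_center[0], cc - params.bead_center[1])
    dist_fol = np.hypot(rr - params.follicle_center[0], cc - params.follicle_center[1])

    inside_bead = dist_bead <= params.bead_radius
    follicle = dist_fol <= params.follicle_radius
    clearance = (
        (dist_fol <= params.degradation_radius) & inside_bead & ~follicle
        if not params.dead
        else np.zeros((h, w), dtype=bool)
    )
    labels = np.full((h, w), LABEL_BACKGROUND, dtype=np.uint8)
    labels[inside_bead] = LABEL_FIBRIN
    labels[clearance] = LABEL_CLEARANCE
    labels[follicle] = LABEL_FOLLICLE

    rng = np.random.default_rng(params.seed)
    img = np.full((h, w), float(params.background_level))
    img[labels == LABEL_FIBRIN] = params.fibrin_level
    img[labels == LABEL_CLEARANCE] = params.clearance_level
    img[labels == LABEL_FOLLICLE] = params.follicle_level
    if params.speckle_sd > 0:
        speckle = rng.normal(0.0, params.speckle_sd, size=(h, w))
        img[labels == LABEL_FIBRIN] += speckle[labels == LABEL_FIBRIN]
    if params.illumination_gradient != 0.0:
        ramp = 1.0 + params.illumination_gradient * (cc / max(w - 1, 1) - 0.5)
        img = img * ramp
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=(h, w))
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    mpp2 = params.microns_per_pixel ** 2
    if params.dead:
        degradation_area = 0.0
        truncated = False
    else:
        filled_disc = (dist_fol <= params.degradation_radius) & inside_bead
        degradation_area = float(filled_disc.sum()) * mpp2
        truncated = (
            params.offset + params.degradation_radius
            >= params.bead_radius - truncation_margin
        )
    truth = SyntheticTruth(
        params=params,
        label_map=labels,
        degradation_area=degradation_area,
        follicle_area=float(follicle.sum()) * mpp2,
        truncated=truncated,
    )
    image = Micrograph(pixels=pixels, microns_per_pixel=params.microns_per_pixel)
    return image, truth


def radius_for_area(area_um2: float, microns_per_pixel: float) -> float:
    """Clearance-disc radius (px) whose analytic area equals ``area_um2``."""
    return math.sqrt(max(area_um2, 0.0) / math.pi) / microns_per_pixel


# ---------------------------------------------------------------------------
# whole-experiment simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DoseGroup:
    """One simulated culture condition.

    ``outcome_probs`` are the (MII, GV, MI, DG) maturation probabilities
    for survivors subjected to in vitro maturation.
    """

    label: str
    dose_nm: float | None
    survival_prob: float
    n_follicles: int
    is_control: bool = False
    antrum_prob: float = 0.86
    outcome_probs: tuple[float, float, float, float] = (0.78, 0.06, 0.12, 0.04)

    def __post_init__(self) -> None:
        if not 0.0 <= self.survival_prob <= 1.0:
            raise ValueError("survival_prob must be in [0, 1]")
        if self.n_follicles < 1:
            raise ValueError("n_follicles must be >= 1")
        if abs(sum(self.outcome_probs) - 1.0) > 1e-9:
            raise ValueError("outcome_probs must sum to 1")


# The validation screen: an untreated control plus six doxorubicin doses
# spanning therapeutic plasma levels, with survival collapsing above 0.01 nM
# and the half-survival dose at 0.005 nM.
DEFAULT_DESIGN: tuple[DoseGroup, ...] = (
    DoseGroup("control", None, 0.70, 92, is_control=True),
    DoseGroup("DXR 200 nM", 200.0, 0.0, 69),
    DoseGroup("DXR 10 nM", 10.0, 0.0, 52),
    DoseGroup("DXR 1 nM", 1.0, 0.0, 75),
    DoseGroup("DXR 0.1 nM", 0.1, 0.0, 75),
    DoseGroup("DXR 0.01 nM", 0.01, 0.35, 80, antrum_prob=0.27,
              outcome_probs=(0.0, 0.29, 0.0, 0.71)),
    DoseGroup("DXR 0.005 nM", 0.005, 0.48, 92, antrum_prob=0.64,
              outcome_probs=(0.0, 0.0, 0.70, 0.30)),
)

_OUTCOMES = ("MII", "GV", "MI", "DG")


@dataclass(frozen=True)
class ExperimentResult:
    """Per-follicle ground truth plus the long-format observation records."""

    truth: pd.DataFrame
    records: pd.DataFrame
    design: tuple[DoseGroup, ...]
    seed: int


def _follicle_truth(
    group: DoseGroup, idx: int, rng: np.random.Generator, mpp: float,
    n_replicates: int,
) -> dict:
    alive = bool(rng.random() < group.survival_prob)
    death_day = None if alive else int(rng.choice(OBSERVATION_DAYS[1:]))
    if alive:
        area = max(0.0, rng.normal(LIVE_AREA_MEAN, LIVE_AREA_SD))
    else:
        area = max(0.0, rng.normal(DEAD_AREA_MEAN, DEAD_AREA_SD))
    # the dense-matrix dead phenotype: clearance smaller than the follicle
    # body cannot be drawn, so it collapses to no clearance at all
    r_deg = radius_for_area(area, mpp)
    antrum = alive and bool(rng.random() < group.antrum_prob)
    outcome = (
        _OUTCOMES[int(rng.choice(4, p=group.outcome_probs))] if alive else "none"
    )
    d0 = float(rng.uniform(120, 135))
    d12 = float(rng.normal(310, 30))
    return {
        "condition": group.label,
        "dose_nm": group.dose_nm,
        "is_control": group.is_control,
        "replicate": idx % n_replicates + 1,
        "alive": alive,
        "death_day": death_day,
        "area_um2": area,
        "degradation_radius_px": r_deg,
        "antrum": antrum,
        "outcome": outcome,
        "d0_um": d0,
        "d12_um": d12,
    }


def generate_experiment(
    design: Sequence[DoseGroup] | None = None,
    seed: int = 0,
    n_replicates: int = 3,
    microns_per_pixel: float = 2.0,
) -> ExperimentResult:
    """Simulate a full dose–response culture: survival, growth, outcomes.

    Each follicle draws alive/dead from its group's survival probability;
    dead follicles die on a uniformly chosen observation day.  Live day-6
    areas follow N(3.0e5, 0.3e5) µm² and dead areas N(0.3e5, 0.2e5) µm²
    (floored at 0).  Diameters grow linearly from the isolation size
    (120–135 µm) toward the day-12 size; antrum appears from day 8 in a
    per-group fraction of survivors; survivors receive a maturation outcome.

    A single master ``seed`` fans out to per-follicle substreams
    (seed + index), so any subset regenerates identically.
    """
    groups = tuple(design) if design is not None else DEFAULT_DESIGN
    if not groups:
        raise ValueError("design must be non-empty")
    truth_rows: list[dict] = []
    record_rows: list[dict] = []
    follicle_index = 0
    for group in groups:
        for i in range(group.n_follicles):
            sub = np.random.default_rng((seed + follicle_index) % (2**31))
            row = _follicle_truth(group, i, sub, microns_per_pixel, n_replicates)
            fid = f"F{follicle_index:04d}"
            row["follicle_id"] = fid
            row["image_seed"] = (seed + follicle_index) % (2**31)
            truth_rows.append(row)
            last_day = OBSERVATION_DAYS[-1]
            for day in OBSERVATION_DAYS:
                dead_now = row["death_day"] is not None and day >= row["death_day"]
                status = "dead" if dead_now else "alive"
                if dead_now:
                    diameter = np.nan
                else:
                    frac = day / last_day
                    diameter = (
                        row["d0_um"] + (row["d12_um"] - row["d0_um"]) * frac
                        + float(sub.normal(0, 3))
                    )
                record_rows.append(
                    {
                        "follicle_id": fid,
                        "condition": group.label,
                        "replicate": row["replicate"],
                        "day": day,
                        "status": status,
                        "diameter_um": diameter,
                        "antrum": int(row["antrum"] and day >= 8 and not dead_now),
                        "outcome": row["outcome"] if day == last_day else "",
                    }
                )
            follicle_index += 1
    truth = pd.DataFrame(truth_rows)
    cols = ["follicle_id"] + [c for c in truth.columns if c != "follicle_id"]
    return ExperimentResult(
        truth=truth[cols],
        records=pd.DataFrame(record_rows),
        design=groups,
        seed=seed,
    )


def build_synthetic_plate(
    out_dir,
    seed: int = 0,
    n_controls: int = 6,
    n_dead: int = 6,
    n_truncated: int = 2,
    base: SyntheticParams | None = None,
    analysis_day: int = 6,
):
    """Write a small synthetic plate to disk and return its layout.

    Row A holds live control wells with clearance radii evenly spaced
    from 0.75 to 0.85 of the bead radius: the even spacing keeps every
    control's area above its own group's mean − 1.5·SD cutoff (the most
    extreme of n evenly spaced values sits ~1.34 sample SDs from the
    mean), so the expected grid is deterministic.  Row B holds
    dead-phenotype wells (no clearance), row C wells whose follicle sits
    near the bead edge so the clearance is truncated.  Images are written
    as ``{well_id}_d{day}.png`` next to ``plate_layout.csv``.
    """
    from pathlib import Path

    from .io import PlateLayout, WellEntry, write_micrograph, write_plate_layout

    base = base or SyntheticParams()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rb = base.bead_radius
    specs: list[tuple[str, str, bool, SyntheticParams]] = []
    radii = np.linspace(0.75 * rb, 0.85 * rb, n_controls) if n_controls else []
    for i, r in enumerate(radii):
        specs.append(
            (f"A{i + 1}", "control", True, replace(base, degradation_radius=float(r)))
        )
    for i in range(n_dead):
        specs.append((f"B{i + 1}", "dead", False, replace(base, degradation_radius=0.0)))
    for i in range(n_truncated):
        off_center = (base.bead_center[0], base.bead_center[1] + 0.3 * rb)
        specs.append(
            (
                f"C{i + 1}",
                "edge",
                False,
                replace(
                    base,
                    follicle_center=off_center,
                    degradation_radius=0.775 * rb,
                ),
            )
        )
    wells = []
    truths = {}
    for idx, (wid, condition, is_control, params) in enumerate(specs):
        params = replace(params, seed=(seed + idx) % (2**31))
        image, truth = generate_micrograph(params)
        path = out / f"{wid}_d{analysis_day}.png"
        write_micrograph(
            Micrograph(
                pixels=image.pixels,
                microns_per_pixel=image.microns_per_pixel,
                well_id=wid,
                day=analysis_day,
            ),
            path,
        )
        truths[wid] = truth
        wells.append(
            WellEntry(
                well_id=wid,
                condition=condition,
                is_control=is_control,
                image_paths={analysis_day: str(path)},
            )
        )
    layout = PlateLayout(
        name="synthetic_plate",
        microns_per_pixel=base.microns_per_pixel,
        wells=tuple(wells),
    )
    write_plate_layout(layout, out / "plate_layout.csv")
    return layout, truths


def micrograph_params_for_follicle(
    truth_row: pd.Series | dict,
    base: SyntheticParams | None = None,
) -> SyntheticParams:
    """Day-6 image parameters realising one simulated follicle's truth.

    A dead follicle, or one whose sampled area implies a clearance no
    larger than the follicle body, renders as the dense dead phenotype
    (no clearance disc).
    """
    base = base or SyntheticParams()
    r = float(truth_row["degradation_radius_px"])
    if not bool(truth_row["alive"]) or r <= base.follicle_radius:
        r = 0.0
    return replace(base, degradation_radius=r, seed=int(truth_row["image_seed"]))
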