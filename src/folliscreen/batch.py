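"""Batch orchestration: a whole plate from images to the √/X/? grid.

One run: for every well, segment the analysis-day image and measure its
degradation area; fit the control cutoff from this plate's control wells;
classify every well; write measurements.csv, calls.csv, plate_grid.json
(+ .txt) and a log recording thresholds, the cutoff, and every "?" reason.

Controls are plate-local by default (the cutoff is refit per plate, so
imaging-session variation is absorbed); pass precomputed ``controls`` to
reuse a global calibration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .classify import ControlStats, classify_follicle, fit_controls
from .config import RunConfig
from .errors import FolliscreenError, InsufficientControlsError
from .io import (
    PlateLayout,
    calls_to_frame,
    measurements_to_frame,
    read_micrograph,
    write_calls_csv,
    write_measurements_csv,
    write_plate_grid,
)
from .segmentation import DegradationMeasurement, analyze_micrograph

__all__ = ["PlateReport", "measure_plate", "fit_plate_controls", "run_batch"]

logger = logging.getLogger("folliscreen")

FAILED = "!"


@dataclass(frozen=True)
class PlateReport:
    """Everything a plate run produces."""

    plate: str
    measurements: pd.DataFrame
    calls: pd.DataFrame
    grid: dict  # well_id -> call symbol ("√", "X", "?", "!")
    controls: ControlStats
    failed_wells: dict  # well_id -> error message

    def counts(self) -> dict:
        out: dict[str, int] = {}
        for call in self.grid.values():
            out[call] = out.get(call, 0) + 1
        return out


def measure_plate(
    layout: PlateLayout, config: RunConfig | None = None
) -> tuple[dict[str, DegradationMeasurement], dict[str, str]]:
    """Segment and measure every well at the analysis day.

    Returns (well_id -> measurement, well_id -> failure message);
    unreadable or unanalyzable wells land in the failure map and the run
    continues.
    """
    config = config or RunConfig()
    day = config.analysis_day
    measurements: dict[str, DegradationMeasurement] = {}
    failed: dict[str, str] = {}
    for well in layout.wells:
        path = well.image_paths.get(day)
        if path is None:
            failed[well.well_id] = f"no image for day {day}"
            logger.warning("well %s: no image for day %d", well.well_id, day)
            continue
        try:
            image = read_micrograph(
                path, layout.microns_per_pixel, well_id=well.well_id, day=day
            )
            result = analyze_micrograph(
                image,
                threshold_override=config.threshold_override,
                invert=config.invert,
                truncation_margin=config.truncation_margin_px,
                max_background_cv=config.illumination_cv_max,
            )
        except (FolliscreenError, OSError, ValueError) as exc:
            failed[well.well_id] = str(exc)
            logger.warning("well %s failed: %s", well.well_id, exc)
            continue
        m = result.measurement
        measurements[well.well_id] = m
        logger.info(
            "well %s (%s): threshold=%.1f corrected_area=%.0f um^2 truncated=%s",
            well.well_id, path, m.threshold_used, m.corrected_area, m.truncated,
        )
    return measurements, failed


def fit_plate_controls(
    layout: PlateLayout, measurements: dict[str, DegradationMeasurement]
) -> ControlStats:
    """Fit the cutoff from this plate's usable (non-truncated) control wells."""
    control_areas = []
    for well in layout.controls():
        m = measurements.get(well.well_id)
        if m is None:
            continue
        if m.truncated:
            # a truncated control area is a known underestimate
            logger.warning(
                "control well %s truncated; excluded from cutoff fit", well.well_id
            )
            continue
        control_areas.append(m.corrected_area)
    if len(control_areas) < 2:
        raise InsufficientControlsError(
            f"insufficient controls: {len(control_areas)} usable control wells"
        )
    return fit_controls(control_areas)


def run_batch(
    layout: PlateLayout,
    config: RunConfig | None = None,
    output_dir: str | Path | None = None,
    controls: ControlStats | None = None,
) -> PlateReport:
    """Measure and classify every well of a plate at the analysis day.

    Unreadable or unanalyzable wells are marked failed ("!") and the run
    continues; fewer than two usable control wells aborts the run.
    """
    config = config or RunConfig()
    day = config.analysis_day
    measurements, failed = measure_plate(layout, config)
    if controls is None:
        controls = fit_plate_controls(layout, measurements)
    logger.info(
        "controls: n=%d mean=%.0f sd=%.0f cutoff=%.0f um^2",
        controls.n, controls.mean, controls.sd, controls.cutoff,
    )

    call_rows = []
    grid: dict[str, str] = {}
    for well in layout.wells:
        if well.well_id in failed:
            grid[well.well_id] = FAILED
            call_rows.append(
                {
                    "well_id": well.well_id,
                    "day": day,
                    "area_um2": float("nan"),
                    "cutoff_um2": controls.cutoff,
                    "call": FAILED,
                    "reason": f"failed: {failed[well.well_id]}",
                }
            )
            continue
        m = measurements[well.well_id]
        call = classify_follicle(m, controls, epsilon=config.cutoff_epsilon)
        grid[well.well_id] = call.call
        if call.call == "?":
            logger.info("well %s flagged '?': %s", well.well_id, call.reason)
        call_rows.append(
            {
                "well_id": well.well_id,
                "day": day,
                "area_um2": m.corrected_area,
                "cutoff_um2": controls.cutoff,
                "call": call.call,
                "reason": call.reason,
            }
        )

    m_frame = measurements_to_frame([measurements[w] for w in sorted(measurements)])
    c_frame = calls_to_frame(call_rows)
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_measurements_csv(m_frame, out / "measurements.csv")
        write_calls_csv(c_frame, out / "calls.csv")
        write_plate_grid(grid, out / "plate_grid.json", out / "plate_grid.txt")
    return PlateReport(
        plate=layout.name,
        measurements=m_frame,
        calls=c_frame,
        grid=grid,
        controls=controls,
        failed_wells=failed,
    )
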