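"""File I/O: images, measurement/call CSVs, plate layouts, plate grids.

Images: single-image TIFF or PNG, 8- or 16-bit, grayscale or RGB (RGB is
collapsed to grayscale by standard luminance weighting on read).  Masks are
written as 8-bit PNG, degraded = white (255), intact = black (0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import ConfigError
from .segmentation import BinaryMask, DegradationMeasurement, Micrograph
from .synthetic import OBSERVATION_DAYS

__all__ = [
    "read_micrograph",
    "write_micrograph",
    "write_mask_png",
    "measurements_to_frame",
    "write_measurements_csv",
    "read_measurements_csv",
    "calls_to_frame",
    "write_calls_csv",
    "WellEntry",
    "PlateLayout",
    "read_plate_layout",
    "write_plate_layout",
    "render_plate_grid",
    "write_plate_grid",
]

# ITU-R 709 luminance weights, as used by scikit-image's rgb2gray
_LUMA = np.array([0.2125, 0.7154, 0.0721])

MEASUREMENT_COLUMNS = [
    "well_id", "day", "threshold_used",
    "raw_area_um2", "follicle_area_um2", "corrected_area_um2", "truncated",
]
CALL_COLUMNS = ["well_id", "day", "area_um2", "cutoff_um2", "call", "reason"]


def read_micrograph(
    path: str | Path, microns_per_pixel: float, well_id: str = "", day: int = 0
) -> Micrograph:
    """Read a single-image TIFF/PNG as a calibrated grayscale micrograph."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        if arr.shape[2] != 3:
            raise ValueError(f"unsupported channel count {arr.shape[2]} in {path}")
        arr = np.rint(arr.astype(np.float64) @ _LUMA).astype(arr.dtype)
    if arr.dtype not in (np.dtype(np.uint8), np.dtype(np.uint16)):
        raise ValueError(f"unsupported pixel type {arr.dtype} in {path}")
    return Micrograph(
        pixels=arr, microns_per_pixel=microns_per_pixel, well_id=well_id, day=day
    )


def write_micrograph(image: Micrograph, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.pixels)
    else:
        iio.imwrite(path, image.pixels)


def write_mask_png(mask: BinaryMask, path: str | Path) -> None:
    iio.imwrite(Path(path), mask.to_uint8())


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

def measurements_to_frame(measurements: list[DegradationMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "well_id": m.well_id,
                "day": m.day,
                "threshold_used": m.threshold_used,
                "raw_area_um2": m.raw_area,
                "follicle_area_um2": m.follicle_area,
                "corrected_area_um2": m.corrected_area,
                "truncated": m.truncated,
            }
            for m in measurements
        ],
        columns=MEASUREMENT_COLUMNS,
    )


def write_measurements_csv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False, float_format="%.6f")


def read_measurements_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def calls_to_frame(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def write_calls_csv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# plate layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WellEntry:
    well_id: str
    condition: str
    is_control: bool
    image_paths: dict  # day -> path


@dataclass(frozen=True)
class PlateLayout:
    """A plate's wells, each with per-day image paths and a condition label."""

    name: str
    microns_per_pixel: float
    wells: tuple[WellEntry, ...]

    def __post_init__(self) -> None:
        ids = [w.well_id for w in self.wells]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate well ids in plate layout")
        if self.microns_per_pixel <= 0:
            raise ConfigError("microns_per_pixel must be > 0")

    def controls(self) -> tuple[WellEntry, ...]:
        return tuple(w for w in self.wells if w.is_control)


def read_plate_layout(
    path: str | Path, microns_per_pixel: float, name: str = ""
) -> PlateLayout:
    """Read plate_layout.csv (well_id, condition, is_control, image_path_d*)."""
    table = pd.read_csv(path, dtype={"well_id": str})
    required = {"well_id", "condition", "is_control"}
    missing = required - set(table.columns)
    if missing:
        raise ConfigError(f"plate layout missing columns: {sorted(missing)}")
    day_cols = {
        int(c.removeprefix("image_path_d")): c
        for c in table.columns
        if c.startswith("image_path_d")
    }
    wells = []
    base = Path(path).parent
    for row in table.itertuples():
        paths = {}
        for day, col in sorted(day_cols.items()):
            val = getattr(row, col)
            if isinstance(val, str) and val:
                p = Path(val)
                paths[day] = str(p if p.is_absolute() else base / p)
        wells.append(
            WellEntry(
                well_id=str(row.well_id),
                condition=str(row.condition),
                is_control=bool(row.is_control),
                image_paths=paths,
            )
        )
    return PlateLayout(
        name=name or Path(path).stem,
        microns_per_pixel=microns_per_pixel,
        wells=tuple(wells),
    )


def write_plate_layout(layout: PlateLayout, path: str | Path) -> None:
    days = sorted({d for w in layout.wells for d in w.image_paths})
    rows = []
    for w in layout.wells:
        row = {
            "well_id": w.well_id,
            "condition": w.condition,
            "is_control": w.is_control,
        }
        for d in days:
            row[f"image_path_d{d}"] = w.image_paths.get(d, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# plate grid (the √/X/? readout)
# ---------------------------------------------------------------------------

def render_plate_grid(calls: dict[str, str]) -> str:
    """Text render of {well_id: call}; 96-well-style ids become a grid."""
    import re

    parsed = {}
    for wid, call in calls.items():
        m = re.fullmatch(r"([A-Ha-h])0*(\d{1,2})", wid)
        if not m:
            parsed = None
            break
        parsed[(m.group(1).upper(), int(m.group(2)))] = call
    if parsed is None:
        return "\n".join(f"{wid}\t{call}" for wid, call in sorted(calls.items()))
    rows = sorted({k[0] for k in parsed})
    cols = sorted({k[1] for k in parsed})
    header = "    " + " ".join(f"{c:>2d}" for c in cols)
    lines = [header]
    for r in rows:
        lines.append(
            f"{r}   " + " ".join(f"{parsed.get((r, c), '.'):>2s}" for c in cols)
        )
    return "\n".join(lines)


def write_plate_grid(calls: dict[str, str], json_path: str | Path,
                     text_path: str | Path | None = None) -> None:
    with open(json_path, "w") as fh:
        json.dump(calls, fh, indent=2, sort_keys=True, ensure_ascii=False)
        fh.write("\n")
    if text_path is not None:
        Path(text_path).write_text(render_plate_grid(calls) + "\n", encoding="utf-8")
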