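"""Shared fixtures: record builders and small synthetic geometries."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from folliscreen.synthetic import OBSERVATION_DAYS, SyntheticParams


def make_records(
    n: int,
    death_days: dict[int, int] | None = None,
    condition: str = "cond",
    replicate=1,
    antrum: dict[int, bool] | None = None,
    outcome: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Long-format follicle records: n follicles, optional deaths/flags.

    ``death_days`` maps follicle index -> first day observed dead.
    """
    death_days = death_days or {}
    antrum = antrum or {}
    outcome = outcome or {}
    rows = []
    for i in range(n):
        dd = death_days.get(i)
        rep = replicate[i] if isinstance(replicate, (list, tuple)) else replicate
        for day in OBSERVATION_DAYS:
            dead = dd is not None and day >= dd
            rows.append(
                {
                    "follicle_id": f"f{i:03d}",
                    "condition": condition,
                    "replicate": rep,
                    "day": day,
                    "status": "dead" if dead else "alive",
                    "diameter_um": np.nan if dead else 150.0 + 10 * day,
                    "antrum": int(antrum.get(i, False) and day >= 8 and not dead),
                    "outcome": outcome.get(i, "") if day == OBSERVATION_DAYS[-1] else "",
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture
def small_params() -> SyntheticParams:
    """Compact live-follicle geometry for fast image tests."""
    return SyntheticParams(
        image_size=(256, 256),
        bead_center=(128.0, 128.0),
        bead_radius=100.0,
        follicle_center=(128.0, 128.0),
        follicle_radius=16.0,
        degradation_radius=75.0,
        seed=11,
    )
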