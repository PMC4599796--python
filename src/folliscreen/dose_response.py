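"""Condition-level statistics: survival, Kaplan–Meier curves, maturation
outcomes and IC50 selection.

Works on long-format longitudinal records of cultured follicles — one row
per follicle per observation day (every 2 days to day 12), with alive/dead
status, optional diameter, an antrum flag and a terminal oocyte-maturation
outcome (MII / GV / MI / DG / none).

Percentage definitions follow the screening convention:
  %survival = survivors / total cultured × 100
  %antrum   = follicles with antrum / survivors × 100
  %MII etc. = oocytes at that stage / follicles matured × 100
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

__all__ = [
    "SurvivalCurve",
    "ConditionSummary",
    "survival_fraction",
    "km_curve",
    "estimate_ic50",
    "outcome_percentages",
    "summarize_conditions",
    "per_follicle",
]

OUTCOME_STAGES = ("MII", "GV", "MI", "DG")


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate S(t) on the observation grid.

    ``days`` are the observed event days (plus day 0); ``at_risk`` and
    ``n_events`` the risk-set size and deaths at each; ``survival`` the
    step values, starting at S(0) = 1 and non-increasing.
    """

    days: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray

    def survival_at(self, day: float) -> float:
        """S(day): the step value at the last event day <= day."""
        idx = np.searchsorted(self.days, day, side="right") - 1
        if idx < 0:
            return 1.0
        return float(self.survival[idx])


@dataclass(frozen=True)
class ConditionSummary:
    """One condition's row of the screening summary table.

    Percentages are NaN where undefined (no survivors / none matured),
    mirroring the "–" convention of screening tables.
    """

    condition: str
    n_follicles: int
    pct_survival: float
    sem_survival: float
    pct_antrum: float
    mean_diam_d6: float
    sem_diam_d6: float
    mean_diam_d12: float
    sem_diam_d12: float
    pct_mii: float
    pct_gv: float
    pct_mi: float
    pct_dg: float


# ---------------------------------------------------------------------------
# record handling
# ---------------------------------------------------------------------------

def per_follicle(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse long-format records to one row per follicle.

    Derives: survived (alive at the final observed day), death_day (first
    day observed dead, or NaN), last_day, antrum (ever flagged), outcome
    (the terminal maturation outcome, if any), diameters at day 6 and 12.
    Checks status monotonicity — a follicle never returns from dead.
    """
    if records.empty:
        raise ValueError("empty record set")
    rows = []
    for fid, grp in records.sort_values("day").groupby("follicle_id", sort=True):
        dead = (grp["status"] == "dead").to_numpy()
        if np.any(dead[:-1] & ~dead[1:]):
            raise ValueError(f"follicle {fid}: status not monotone (resurrection)")
        death_day = float(grp["day"].to_numpy()[dead][0]) if dead.any() else np.nan
        outcome = ""
        if "outcome" in grp:
            terminal = [o for o in grp["outcome"] if isinstance(o, str) and o]
            outcome = terminal[-1] if terminal else ""
        def _diam(day: int) -> float:
            sel = grp.loc[grp["day"] == day, "diameter_um"] if "diameter_um" in grp else []
            return float(sel.iloc[0]) if len(sel) else np.nan
        rows.append(
            {
                "follicle_id": fid,
                "condition": grp["condition"].iloc[0] if "condition" in grp else "",
                "replicate": grp["replicate"].iloc[0] if "replicate" in grp else 1,
                "survived": not dead[-1],
                "death_day": death_day,
                "last_day": float(grp["day"].iloc[-1]),
                "antrum": bool(grp["antrum"].any()) if "antrum" in grp else False,
                "outcome": outcome,
                "diam_d6": _diam(6),
                "diam_d12": _diam(12),
            }
        )
    return pd.DataFrame(rows)


def _sem(values: np.ndarray) -> float:
    values = values[np.isfinite(values)]
    if values.size < 2:
        return np.nan
    return float(values.std(ddof=1) / math.sqrt(values.size))


def survival_fraction(records: pd.DataFrame) -> tuple[float, float]:
    """%survival at the final observation day, with its SEM.

    The SEM unit is the experiment replicate when a ``replicate`` column
    with >= 2 levels exists (screens report mean ± SEM over experiments);
    otherwise the per-follicle binomial SEM is used, with a warning.
    """
    pf = per_follicle(records)
    pct = 100.0 * pf["survived"].mean()
    if "replicate" in pf and pf["replicate"].nunique() >= 2:
        reps = pf.groupby("replicate")["survived"].mean().to_numpy() * 100.0
        sem = _sem(reps)
    else:
        warnings.warn("no replicate labels; SEM computed per follicle", stacklevel=2)
        p = pf["survived"].mean()
        sem = 100.0 * math.sqrt(p * (1 - p) / len(pf)) if len(pf) else np.nan
    return float(pct), float(sem)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def km_curve(records: pd.DataFrame) -> SurvivalCurve:
    """Kaplan–Meier cumulative survival from interval-observed cultures.

    Deaths are assigned to the first observation day a follicle is seen
    dead (right-endpoint convention of 2-day imaging); follicles alive at
    their last observed day are right-censored there.  With no censoring
    before the final day, S(final) equals the empirical survival fraction.
    """
    pf = per_follicle(records)
    durations = np.where(pf["survived"], pf["last_day"], pf["death_day"])
    events = (~pf["survived"]).to_numpy()
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    table = kmf.event_table
    days = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].reindex(table.index).to_numpy()
    if days.size == 0 or days[0] != 0.0:
        days = np.concatenate([[0.0], days])
        surv = np.concatenate([[1.0], surv])
        table = pd.concat(
            [pd.DataFrame({"at_risk": [len(pf)], "observed": [0]}, index=[0.0]), table]
        )
    return SurvivalCurve(
        days=days,
        at_risk=table["at_risk"].to_numpy(dtype=float),
        n_events=table["observed"].to_numpy(dtype=float),
        survival=np.asarray(surv, dtype=float),
    )


# ---------------------------------------------------------------------------
# dose response
# ---------------------------------------------------------------------------

def estimate_ic50(
    dose_to_survival: Mapping[float, float], mode: str = "nearest"
) -> float:
    """The dose at which ~50% of follicles survive.

    ``mode="nearest"`` (default) returns the *tested* dose whose survival
    percentage is closest to 50, breaking ties toward the lower dose —
    screens identify a tested concentration rather than interpolate.
    ``mode="interpolate"`` does log-linear interpolation between the two
    adjacent doses bracketing 50%, falling back to nearest (with a
    warning) when no bracket exists.
    """
    if not dose_to_survival:
        raise ValueError("empty dose-to-survival map")
    items = sorted(dose_to_survival.items())  # ascending dose
    if mode == "nearest":
        return min(items, key=lambda kv: (abs(kv[1] - 50.0), kv[0]))[0]
    if mode != "interpolate":
        raise ValueError(f"unknown mode: {mode!r}")
    for (d_lo, s_lo), (d_hi, s_hi) in zip(items, items[1:]):
        if (s_lo - 50.0) * (s_hi - 50.0) <= 0 and s_lo != s_hi:
            f = (50.0 - s_lo) / (s_hi - s_lo)
            log_dose = math.log10(d_lo) + f * (math.log10(d_hi) - math.log10(d_lo))
            return 10.0 ** log_dose
    warnings.warn("no dose bracket around 50% survival; falling back to nearest",
                  stacklevel=2)
    return estimate_ic50(dose_to_survival, mode="nearest")


def outcome_percentages(records: pd.DataFrame, condition: str = "") -> ConditionSummary:
    """Summarise one condition's records into the screening-table row.

    With zero survivors, antrum/outcome percentages (and diameters) are
    NaN — the "–" cells of a screening table.  Maturation percentages are
    over follicles matured (survivors with a recorded outcome).
    """
    pf = per_follicle(records)
    if not condition and "condition" in pf:
        uniq = pf["condition"].unique()
        condition = str(uniq[0]) if len(uniq) == 1 else ""
    n = len(pf)
    pct_surv, sem_surv = survival_fraction(records)
    survivors = pf[pf["survived"]]
    if len(survivors):
        pct_antrum = 100.0 * survivors["antrum"].mean()
        d6 = survivors["diam_d6"].to_numpy(dtype=float)
        d12 = survivors["diam_d12"].to_numpy(dtype=float)
        mean_d6 = float(np.nanmean(d6)) if np.isfinite(d6).any() else np.nan
        mean_d12 = float(np.nanmean(d12)) if np.isfinite(d12).any() else np.nan
        sem_d6, sem_d12 = _sem(d6), _sem(d12)
    else:
        pct_antrum = np.nan
        mean_d6 = mean_d12 = sem_d6 = sem_d12 = np.nan
    matured = survivors[survivors["outcome"].isin(OUTCOME_STAGES)]
    if len(matured):
        counts = matured["outcome"].value_counts()
        pct = {s: 100.0 * counts.get(s, 0) / len(matured) for s in OUTCOME_STAGES}
    else:
        pct = {s: np.nan for s in OUTCOME_STAGES}
    return ConditionSummary(
        condition=condition,
        n_follicles=n,
        pct_survival=pct_surv,
        sem_survival=sem_surv,
        pct_antrum=float(pct_antrum),
        mean_diam_d6=mean_d6,
        sem_diam_d6=sem_d6,
        mean_diam_d12=mean_d12,
        sem_diam_d12=sem_d12,
        pct_mii=pct["MII"],
        pct_gv=pct["GV"],
        pct_mi=pct["MI"],
        pct_dg=pct["DG"],
    )


def summarize_conditions(records: pd.DataFrame) -> pd.DataFrame:
    """Screening-table summary, one row per condition."""
    rows = []
    for cond, grp in records.groupby("condition", sort=False):
        s = outcome_percentages(grp, condition=str(cond))
        rows.append(vars(s))
    return pd.DataFrame(rows)
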