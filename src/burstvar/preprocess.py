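"""Wearable and survey preprocessing: wear-time classification and daily aggregates.

A minute counts as valid wear time when it has a non-zero step count or a
heart-rate reading, and the person is not asleep (sleep minutes are excluded
from wear time altogether). The daily physical-activity measure is total
wake steps divided by hours of valid wear time; daily life satisfaction is
the mean of the two 0-100 evening slider items.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "classify_valid_minutes",
    "daily_pa",
    "daily_ls",
    "aggregate_pa",
    "aggregate_ls",
    "build_daily_table",
]


class DailyPa(NamedTuple):
    pa_rate: float        # steps per valid wear-hour (NaN when no wear time)
    wear_hours: float
    n_valid_minutes: int


def _check_duplicates(minutes: pd.DataFrame) -> None:
    dup = minutes.duplicated(subset=["person_id", "timestamp"])
    if dup.any():
        row = minutes.loc[dup.idxmax()]
        raise ValueError(
            "duplicate minute record for person "
            f"{row['person_id']!r} at {row['timestamp']}"
        )


def classify_valid_minutes(minutes: pd.DataFrame) -> pd.Series:
    """Boolean validity flag per minute record.

    valid  <=>  (steps > 0 or hr_present) and not asleep.
    Raises on duplicated (person, minute) keys.
    """
    _check_duplicates(minutes)
    if (minutes["steps"] < 0).any():
        raise ValueError("negative step counts")
    steps = minutes["steps"].to_numpy() > 0
    hr = minutes["hr_present"].astype(bool).to_numpy()
    asleep = minutes["asleep"].astype(bool).to_numpy()
    return pd.Series((steps | hr) & ~asleep, index=minutes.index, name="valid")


def daily_pa(minutes: pd.DataFrame) -> DailyPa:
    """Daily PA summary for one person-day of minute records.

    pa_rate = (sum of steps over valid wake minutes) / wear_hours, with
    wear_hours = n_valid_minutes / 60. Zero valid minutes (including empty
    input) yields a missing rate with wear_hours = 0.
    """
    if len(minutes) == 0:
        return DailyPa(float("nan"), 0.0, 0)
    if minutes["person_id"].nunique() > 1:
        raise ValueError("daily_pa expects records from a single person")
    if pd.to_datetime(minutes["timestamp"]).dt.normalize().nunique() > 1:
        raise ValueError("daily_pa expects records from a single calendar day")
    valid = classify_valid_minutes(minutes)
    n_valid = int(valid.sum())
    wear_hours = n_valid / 60.0
    if n_valid == 0:
        return DailyPa(float("nan"), 0.0, 0)
    steps = int(minutes.loc[valid, "steps"].sum())
    return DailyPa(steps / wear_hours, wear_hours, n_valid)


def daily_ls(item1, item2, single_item_policy: str = "missing") -> float:
    """Two-item LS mean on [0, 100].

    With one item missing, the day is missing by default (the measure is
    defined as a two-item average); ``single_item_policy='use_single'``
    falls back to the observed item.
    """
    if single_item_policy not in ("missing", "use_single"):
        raise ValueError("single_item_policy must be 'missing' or 'use_single'")
    items = [item1, item2]
    observed = [float(v) for v in items if v is not None and not pd.isna(v)]
    for v in observed:
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"LS item out of [0, 100]: {v}")
    if len(observed) == 2:
        return (observed[0] + observed[1]) / 2.0
    if len(observed) == 1 and single_item_policy == "use_single":
        return observed[0]
    return float("nan")


def aggregate_pa(minutes: pd.DataFrame) -> pd.DataFrame:
    """Vectorized daily PA over all person-days in a minute table."""
    _check_duplicates(minutes)
    df = minutes.copy()
    df["date"] = pd.to_datetime(df["timestamp"]).dt.normalize()
    steps = df["steps"].to_numpy()
    valid = ((steps > 0) | df["hr_present"].astype(bool).to_numpy()) \
        & ~df["asleep"].astype(bool).to_numpy()
    df["_valid"] = valid
    df["_valid_steps"] = np.where(valid, steps, 0)
    grp = df.groupby(["person_id", "date"], sort=True)
    out = grp.agg(n_valid_minutes=("_valid", "sum"),
                  _steps=("_valid_steps", "sum")).reset_index()
    out["wear_hours"] = out["n_valid_minutes"] / 60.0
    with np.errstate(invalid="ignore", divide="ignore"):
        out["pa_rate"] = np.where(out["n_valid_minutes"] > 0,
                                  out["_steps"] / out["wear_hours"], np.nan)
    return out[["person_id", "date", "pa_rate", "wear_hours", "n_valid_minutes"]]


def aggregate_ls(surveys: pd.DataFrame, single_item_policy: str = "missing") -> pd.DataFrame:
    """Daily LS means from the evening survey table (ls_item1, ls_item2)."""
    out = surveys.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.normalize()
    out["ls_mean"] = [
        daily_ls(a, b, single_item_policy=single_item_policy)
        for a, b in zip(out["ls_item1"], out["ls_item2"])
    ]
    return out[["person_id", "date", "ls_mean"]]


def build_daily_table(minutes: pd.DataFrame, surveys: pd.DataFrame,
                      min_wear_hours: float | None = None,
                      single_item_policy: str = "missing") -> pd.DataFrame:
    """Merge wearable and survey streams into daily observations.

    ``min_wear_hours`` optionally invalidates the PA rate on days with less
    wear time than the threshold (no threshold by default). Missingness is
    preserved, never imputed.
    """
    pa = aggregate_pa(minutes)
    ls = aggregate_ls(surveys, single_item_policy=single_item_policy)
    daily = pa.merge(ls, on=["person_id", "date"], how="outer")
    daily["wear_hours"] = daily["wear_hours"].fillna(0.0)
    daily["n_valid_minutes"] = daily["n_valid_minutes"].fillna(0).astype(int)
    if min_wear_hours is not None:
        daily.loc[daily["wear_hours"] < min_wear_hours, "pa_rate"] = np.nan
    cols = ["person_id", "date", "ls_mean", "pa_rate", "wear_hours", "n_valid_minutes"]
    return daily[cols].sort_values(["person_id", "date"]).reset_index(drop=True)
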