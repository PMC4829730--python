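"""Mood-diary processing: daily targets, standardization, participant pruning.

Diary ratings (up to five per day) are averaged to one value per
participant-day and then standardized within each participant, separately for
the one-dimensional mood measure and the two circumplex measures (valence,
arousal).  Days without any rating are absent rather than zero-filled.
Participants contributing fewer than ``min_days`` complete days (a day is
complete when it has both a mood target and sensor data) are pruned from the
analysis set.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema import MEASURE_BOUNDS, MOOD_MEASURES

logger = logging.getLogger(__name__)


class RatingValidationError(ValueError):
    """A diary rating is outside its scale; the message identifies the record."""


@dataclass(frozen=True)
class AdherenceSummary:
    """Per-participant diary adherence and inclusion flag."""

    participant_id: str
    days_with_any_rating: int
    days_with_4plus: int
    last_day_rated: int
    complete_days: int
    included: bool


def aggregate_daily(
    ratings: pd.DataFrame, start_date, n_days: int
) -> pd.DataFrame:
    """Average diary ratings to one row per participant-day.

    Parameters
    ----------
    ratings
        Long frame with ``participant_id``, ``timestamp`` and the three
        measure columns on their raw scales.
    start_date, n_days
        Study window; a rating belongs to the calendar day of its timestamp.

    Returns a frame with ``participant_id``, ``day_index``, ``n_ratings`` and
    ``mean_mood/mean_valence/mean_arousal``.  Days with zero ratings have no
    row.  Out-of-scale ratings raise :class:`RatingValidationError`.
    """
    cols = ["participant_id", "day_index", "n_ratings"] + [
        f"mean_{m}" for m in MOOD_MEASURES
    ]
    if len(ratings) == 0:
        return pd.DataFrame(columns=cols)
    for measure in MOOD_MEASURES:
        lo, hi = MEASURE_BOUNDS[measure]
        vals = ratings[measure]
        bad = (vals < lo) | (vals > hi)
        if bad.any():
            rec = ratings.loc[bad].iloc[0]
            raise RatingValidationError(
                f"{measure}={rec[measure]} outside [{lo}, {hi}] for "
                f"participant {rec['participant_id']} at {rec['timestamp']}"
            )
    start = pd.Timestamp(start_date).normalize()
    day = (pd.to_datetime(ratings["timestamp"]).dt.normalize() - start).dt.days + 1
    if ((day < 1) | (day > n_days)).any():
        rec = ratings.loc[(day < 1) | (day > n_days)].iloc[0]
        raise RatingValidationError(
            f"rating outside study window for participant "
            f"{rec['participant_id']} at {rec['timestamp']}"
        )
    grouped = (
        ratings.assign(day_index=day)
        .groupby(["participant_id", "day_index"], sort=True)
        .agg(
            n_ratings=("mood", "size"),
            mean_mood=("mood", "mean"),
            mean_valence=("valence", "mean"),
            mean_arousal=("arousal", "mean"),
        )
        .reset_index()
    )
    return grouped[cols]


def standardize_targets(daily: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Within-participant z-scores of the daily means (sample SD, ddof=1).

    Each participant's ``z_<measure>`` column has mean 0 and sample SD 1 over
    that participant's present days.  Participants with a constant series on
    any measure (SD = 0) or fewer than 2 days are degenerate: they are
    dropped with a logged warning and returned in the second element.
    """
    out = daily.copy()
    degenerate: list[str] = []
    for pid, grp in daily.groupby("participant_id", sort=False):
        bad = len(grp) < 2 or any(
            grp[f"mean_{m}"].std(ddof=1) == 0 for m in MOOD_MEASURES
        )
        if bad:
            degenerate.append(str(pid))
    if degenerate:
        logger.warning(
            "dropping %d participant(s) with constant or single-day mood "
            "series: %s",
            len(degenerate),
            ", ".join(degenerate),
        )
        out = out[~out["participant_id"].isin(degenerate)].copy()
    for measure in MOOD_MEASURES:
        col = out[f"mean_{measure}"]
        grp = out.groupby("participant_id")[f"mean_{measure}"]
        out[f"z_{measure}"] = (col - grp.transform("mean")) / grp.transform(
            lambda s: s.std(ddof=1)
        )
    return out, degenerate


def prune_participants(
    daily: pd.DataFrame,
    feature_table: pd.DataFrame,
    min_days: int = 20,
) -> tuple[list[str], pd.DataFrame]:
    """Exclude participants with fewer than ``min_days`` complete days.

    A day is complete when the participant has a daily mood target and the
    sensor channels produced data that day (``sensor_day`` in the feature
    table).  Participants with exactly ``min_days`` complete days are
    retained.  Returns the included ids and a per-participant adherence
    summary frame.
    """
    sensor = feature_table.set_index(["participant_id", "day_index"])["sensor_day"]
    rows = []
    included: list[str] = []
    for pid, grp in daily.groupby("participant_id", sort=True):
        days = grp["day_index"]
        keys = pd.MultiIndex.from_arrays([np.repeat(pid, len(days)), days])
        has_sensor = sensor.reindex(keys).fillna(False).to_numpy(dtype=bool)
        complete = int(has_sensor.sum())
        ok = complete >= min_days
        rows.append(
            AdherenceSummary(
                participant_id=str(pid),
                days_with_any_rating=int(len(grp)),
                days_with_4plus=int((grp["n_ratings"] >= 4).sum()),
                last_day_rated=int(days.max()),
                complete_days=complete,
                included=bool(ok),
            )
        )
        if ok:
            included.append(str(pid))
    summary = pd.DataFrame([r.__dict__ for r in rows])
    return included, summary
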