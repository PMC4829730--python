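"""Daily predictor engineering from raw smartphone event streams.

Each participant-day is summarized as 53 variables in 13 groups:

* call / SMS top-5 contact histograms (frequency and call duration),
  normalized over a 3-day window ending on the day itself;
* daily high-activity fraction from hourly accelerometer summaries;
* screen-on frequency and total screen time, standardized within participant;
* app top-5 and 11-category usage histograms (frequency and duration),
  3-day-window normalized;
* photos taken, max-normalized within participant;
* lag-1 and lag-2 of the standardized mood target.

Histogram normalization divides by the window total, so each 5-slot or 11-bin
group sums to one or is all zero.  Days with no events in a channel receive
zeros for that channel's variables; only missing mood targets or lags make a
row non-modelable.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import (
    APP_CATEGORIES,
    FEATURE_COLUMNS,
    SENSOR_COLUMNS,
    category_slug,
)

logger = logging.getLogger(__name__)

SECONDS_PER_DAY = 86400


class SchemaError(ValueError):
    """A feature table does not match the 53-variable schema."""


@dataclass(frozen=True)
class Ranking:
    """Top-5 entity ranking for one participant and channel.

    Entities are ranked by total interaction count over the full study;
    ties break by earliest first occurrence, then lexicographic id.
    """

    participant_id: str
    channel: str
    entities: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.entities) > 5:
            raise ValueError("ranking holds at most 5 entities")
        if len(set(self.entities)) != len(self.entities):
            raise ValueError("ranking entities must be unique")


def day_index(timestamps: pd.Series, start_date: pd.Timestamp) -> pd.Series:
    """1-based study-day index of each timestamp (day boundary = local midnight)."""
    start = pd.Timestamp(start_date).normalize()
    return (pd.to_datetime(timestamps).dt.normalize() - start).dt.days + 1


def rank_top5(events: pd.DataFrame, id_col: str, channel: str = "") -> Ranking:
    """Rank a participant's interaction partners (or apps) by total count.

    Ties break by earliest first occurrence in the stream, then by id.
    Fewer than five entities yield a shorter ranking; the unfilled slots
    downstream produce zero-valued variables.
    """
    pid = str(events["participant_id"].iloc[0]) if len(events) else ""
    if len(events) == 0:
        return Ranking(pid, channel, ())
    order = np.arange(len(events))
    tbl = pd.DataFrame({id_col: events[id_col].to_numpy(), "_pos": order})
    grouped = tbl.groupby(id_col, sort=False)["_pos"].agg(["count", "min"])
    grouped = grouped.sort_values(
        by=["count", "min", grouped.index.name],
        ascending=[False, True, True],
        kind="mergesort",
    )
    return Ranking(pid, channel, tuple(str(e) for e in grouped.index[:5]))


def _daily_entity_matrix(
    events: pd.DataFrame,
    id_col: str,
    weight_col: str | None,
    n_days: int,
    start_date: pd.Timestamp,
    columns,
) -> pd.DataFrame:
    """days x entity matrix of per-day counts (weight_col=None) or summed weights."""
    days = pd.RangeIndex(1, n_days + 1, name="day_index")
    if len(events) == 0:
        return pd.DataFrame(0.0, index=days, columns=list(columns))
    d = day_index(events["timestamp"], start_date)
    if weight_col is None:
        mat = (
            pd.crosstab(d, events[id_col].astype(str))
            .reindex(index=days, columns=list(columns))
            .fillna(0.0)
        )
    else:
        mat = (
            events.assign(_day=d)
            .pivot_table(
                index="_day",
                columns=id_col,
                values=weight_col,
                aggfunc="sum",
                fill_value=0.0,
            )
            .reindex(index=days, columns=list(columns))
            .fillna(0.0)
        )
    return mat.astype(float)


def window_histogram(
    events: pd.DataFrame,
    ranking: Ranking,
    weight: str,
    n_days: int,
    start_date: pd.Timestamp,
    window: int = 3,
    id_col: str = "contact_id",
) -> pd.DataFrame:
    """Windowed, sum-to-one normalized top-5 histogram, one row per study day.

    For day ``d`` each slot accumulates the event count (``weight='count'``)
    or total duration (``weight='duration'``) over days ``max(1, d-window+1)..d``
    for the slot's entity; slots are then divided by the 5-slot window total.
    An all-zero window maps to all zeros.  Missing ranking slots are zero.
    """
    if weight not in ("count", "duration"):
        raise ValueError(f"weight must be 'count' or 'duration', got {weight!r}")
    weight_col = None if weight == "count" else "duration_s"
    mat = _daily_entity_matrix(
        events, id_col, weight_col, n_days, start_date, ranking.entities
    )
    windowed = mat.rolling(window=window, min_periods=1).sum()
    # pad to 5 slots before normalizing (absent slots contribute 0 to totals)
    out = pd.DataFrame(0.0, index=windowed.index, columns=range(1, 6))
    for slot, entity in enumerate(ranking.entities, start=1):
        out[slot] = windowed[entity].to_numpy()
    totals = out.sum(axis=1)
    nz = totals > 0
    out.loc[nz] = out.loc[nz].div(totals[nz], axis=0)
    return out


def _zscore(x: np.ndarray) -> np.ndarray:
    """Within-participant z-score with sample SD; constant series -> zeros."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        return np.zeros_like(x)
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def pair_screen_sessions(
    screen: pd.DataFrame,
) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Pair on/off events into sessions.

    A leading unmatched ``off`` is dropped; an ``on`` followed by another
    ``on`` closes the first session at the second's timestamp; a trailing
    unmatched ``on`` is closed at the next midnight after it.
    """
    sessions: list[tuple[pd.Timestamp, pd.Timestamp]] = []
    pending: pd.Timestamp | None = None
    for ts, state in zip(pd.to_datetime(screen["timestamp"]), screen["state"]):
        if state == "on":
            if pending is not None and ts > pending:
                sessions.append((pending, ts))
            pending = ts
        else:
            if pending is not None:
                if ts > pending:
                    sessions.append((pending, ts))
                pending = None
            # leading / duplicate "off": dropped
    if pending is not None:
        midnight = (pending.normalize() + pd.Timedelta(days=1))
        if midnight > pending:
            sessions.append((pending, midnight))
    return sessions


def _split_session_by_day(
    on: pd.Timestamp, off: pd.Timestamp
) -> list[tuple[pd.Timestamp, float]]:
    """Split a session at midnight boundaries -> [(day-start timestamp, seconds)]."""
    parts: list[tuple[pd.Timestamp, float]] = []
    cur = on
    while cur < off:
        boundary = cur.normalize() + pd.Timedelta(days=1)
        end = min(off, boundary)
        parts.append((cur, (end - cur).total_seconds()))
        cur = end
    return parts


def screen_features(
    screen: pd.DataFrame, n_days: int, start_date: pd.Timestamp
) -> pd.DataFrame:
    """Daily screen-on count and total screen seconds, plus within-participant z.

    Returns a frame indexed by day with columns ``screen_count``,
    ``screen_seconds``, ``screen_freq_z``, ``screen_dur_z``.  Sessions spanning
    midnight contribute seconds to each day they touch.
    """
    days = pd.RangeIndex(1, n_days + 1, name="day_index")
    counts = pd.Series(0.0, index=days)
    if len(screen):
        on_events = screen[screen["state"] == "on"]
        if len(on_events):
            d = day_index(on_events["timestamp"], start_date)
            c = d.value_counts()
            c = c[(c.index >= 1) & (c.index <= n_days)]
            counts.loc[c.index] = c.astype(float)
    seconds = pd.Series(0.0, index=days)
    start = pd.Timestamp(start_date).normalize()
    for on, off in pair_screen_sessions(screen):
        for part_start, secs in _split_session_by_day(on, off):
            d = (part_start.normalize() - start).days + 1
            if 1 <= d <= n_days:
                seconds.iloc[d - 1] += secs
    return pd.DataFrame(
        {
            "screen_count": counts,
            "screen_seconds": seconds,
            "screen_freq_z": _zscore(counts.to_numpy()),
            "screen_dur_z": _zscore(seconds.to_numpy()),
        },
        index=days,
    )


def activity_feature(
    activity: pd.DataFrame, n_days: int, start_date: pd.Timestamp
) -> pd.Series:
    """Sample-count-weighted daily mean of hourly high-activity fractions.

    Days with no accelerometer summaries get 0 (the gap is logged).
    """
    days = pd.RangeIndex(1, n_days + 1, name="day_index")
    out = pd.Series(0.0, index=days, name="activity_high_pct")
    if len(activity) == 0:
        logger.debug("no activity summaries at all; activity_high_pct = 0")
        return out
    frac = activity["fraction_high"].astype(float)
    if ((frac < 0) | (frac > 1)).any():
        bad = activity.loc[(frac < 0) | (frac > 1)].iloc[0]
        raise ValueError(
            f"fraction_high outside [0, 1] at hour_start={bad['hour_start']}"
        )
    d = day_index(activity["hour_start"], start_date)
    w = activity["n_samples"].astype(float)
    num = (frac * w).groupby(d.to_numpy()).sum()
    den = w.groupby(d.to_numpy()).sum()
    daily = (num / den).dropna()
    daily = daily[(daily.index >= 1) & (daily.index <= n_days)]
    out.loc[daily.index] = daily
    missing = int(n_days - len(daily))
    if missing:
        logger.debug("%d day(s) without activity summaries set to 0", missing)
    return out


def image_feature(
    camera: pd.DataFrame, n_days: int, start_date: pd.Timestamp
) -> pd.Series:
    """Daily photo count divided by the participant's maximum daily count."""
    days = pd.RangeIndex(1, n_days + 1, name="day_index")
    counts = pd.Series(0.0, index=days, name="images_norm")
    if len(camera):
        d = day_index(camera["timestamp"], start_date)
        c = d.value_counts()
        c = c[(c.index >= 1) & (c.index <= n_days)]
        counts.loc[c.index] = c.astype(float)
    peak = counts.max()
    return counts / peak if peak > 0 else counts


def app_features(
    apps: pd.DataFrame,
    ranking: Ranking,
    categories: pd.Series,
    n_days: int,
    start_date: pd.Timestamp,
    window: int = 3,
) -> pd.DataFrame:
    """All 32 app variables: top-5 freq/duration + 11-category freq/duration.

    ``categories`` maps app_id -> category name; unmapped apps fall into
    ``unknown``.  Both the top-5 and the category histograms use the same
    3-day-window, sum-to-one normalization.
    """
    top_freq = window_histogram(
        apps, ranking, "count", n_days, start_date, window, id_col="app_id"
    )
    top_dur = window_histogram(
        apps, ranking, "duration", n_days, start_date, window, id_col="app_id"
    )
    out = pd.DataFrame(index=pd.RangeIndex(1, n_days + 1, name="day_index"))
    for i in range(1, 6):
        out[f"app_top5_freq_{i}"] = top_freq[i]
        out[f"app_top5_dur_{i}"] = top_dur[i]

    if len(apps):
        cat = (
            apps["app_id"]
            .astype(str)
            .map(categories)
            .where(lambda s: s.isin(APP_CATEGORIES), "unknown")
            .fillna("unknown")
        )
        cat_events = apps.assign(_cat=cat.to_numpy())
    else:
        cat_events = apps.assign(_cat=pd.Series(dtype=str))
    for weight, prefix in (("count", "app_cat_freq"), ("duration", "app_cat_dur")):
        weight_col = None if weight == "count" else "duration_s"
        mat = _daily_entity_matrix(
            cat_events, "_cat", weight_col, n_days, start_date, APP_CATEGORIES
        )
        windowed = mat.rolling(window=window, min_periods=1).sum()
        totals = windowed.sum(axis=1)
        nz = totals > 0
        windowed.loc[nz] = windowed.loc[nz].div(totals[nz], axis=0)
        for c in APP_CATEGORIES:
            out[f"{prefix}_{category_slug(c)}"] = windowed[c]
    return out


def mood_lags(z_targets: pd.Series, n_days: int) -> pd.DataFrame:
    """Lag-1 and lag-2 of a participant's standardized daily target.

    ``z_targets`` is indexed by day_index and may have gaps; a lag referring
    to an absent day is NaN, which flags the row as non-modelable downstream.
    """
    days = pd.RangeIndex(1, n_days + 1, name="day_index")
    full = z_targets.reindex(days)
    return pd.DataFrame(
        {"mood_lag1": full.shift(1), "mood_lag2": full.shift(2)}, index=days
    )


def sensor_feature_frame(
    streams: dict[str, pd.DataFrame],
    categories: pd.Series,
    n_days: int,
    start_date: pd.Timestamp,
    window: int = 3,
) -> pd.DataFrame:
    """All 51 sensor-derived variables for one participant, plus ``sensor_day``.

    ``streams`` maps channel name (calls, sms, screen, apps, camera, activity)
    to that participant's event frame.  ``sensor_day`` is True when the day
    has at least one record in any channel; it feeds the completeness rule
    used for participant pruning.
    """
    calls, sms = streams["calls"], streams["sms"]
    days = pd.RangeIndex(1, n_days + 1, name="day_index")
    out = pd.DataFrame(index=days)

    call_rank = rank_top5(calls, "contact_id", "calls")
    call_freq = window_histogram(calls, call_rank, "count", n_days, start_date, window)
    call_dur = window_histogram(calls, call_rank, "duration", n_days, start_date, window)
    sms_rank = rank_top5(sms, "contact_id", "sms")
    sms_freq = window_histogram(sms, sms_rank, "count", n_days, start_date, window)
    for i in range(1, 6):
        out[f"call_top5_freq_{i}"] = call_freq[i]
        out[f"call_top5_dur_{i}"] = call_dur[i]
        out[f"sms_top5_freq_{i}"] = sms_freq[i]

    out["activity_high_pct"] = activity_feature(streams["activity"], n_days, start_date)
    scr = screen_features(streams["screen"], n_days, start_date)
    out["screen_freq_z"] = scr["screen_freq_z"]
    out["screen_dur_z"] = scr["screen_dur_z"]

    app_rank = rank_top5(streams["apps"], "app_id", "apps")
    out = out.join(
        app_features(streams["apps"], app_rank, categories, n_days, start_date, window)
    )
    out["images_norm"] = image_feature(streams["camera"], n_days, start_date)

    present = pd.Series(False, index=days)
    for name, df in streams.items():
        if len(df) == 0:
            continue
        ts_col = "hour_start" if name == "activity" else "timestamp"
        d = day_index(df[ts_col], start_date)
        d = d[(d >= 1) & (d <= n_days)]
        present.loc[d.unique()] = True
    out["sensor_day"] = present
    return out[list(SENSOR_COLUMNS) + ["sensor_day"]]


def build_feature_table(
    bundle,
    targets: pd.DataFrame,
    measure: str,
    window: int = 3,
    sensor_cache: dict | None = None,
) -> pd.DataFrame:
    """Assemble the full 53-variable modeling table for one mood measure.

    Parameters
    ----------
    bundle
        A :class:`uema.synthetic.StudyBundle` (or anything with the same
        stream attributes, ``app_categories``, ``start_date``,
        ``participants`` and ``n_days``).
    targets
        Standardized daily targets (``uema.ema.standardize_targets`` output).
    measure
        Which measure's z-scores drive the lag features and ``target_z``.
    sensor_cache
        Optional dict reused across calls for different measures: the
        measure-independent sensor variables are computed once per
        participant and cached here.

    Returns one row per participant-day with the 53 schema columns in order,
    plus ``participant_id``, ``day_index``, ``target_z``, ``sensor_day`` and
    ``modelable``.  A row is modelable when the day and both lag days have
    targets and the day index is at least 3.
    """
    if measure not in ("mood", "valence", "arousal"):
        raise ValueError(f"unknown measure {measure!r}")
    n_days = bundle.n_days
    cat_map = bundle.app_categories.set_index("app_id")["category"]
    frames = []
    for pid in bundle.participants:
        if sensor_cache is not None and pid in sensor_cache:
            sens = sensor_cache[pid]
        else:
            streams = {}
            for name in ("calls", "sms", "screen", "apps", "camera", "activity"):
                df = getattr(bundle, name)
                streams[name] = df[df["participant_id"] == pid]
            sens = sensor_feature_frame(
                streams, cat_map, n_days, bundle.start_date, window
            )
            if sensor_cache is not None:
                sensor_cache[pid] = sens
        tp = targets[targets["participant_id"] == pid].set_index("day_index")
        z = tp[f"z_{measure}"] if len(tp) else pd.Series(dtype=float)
        lags = mood_lags(z, n_days)
        frame = sens.drop(columns=["sensor_day"]).join(lags)
        frame["target_z"] = z.reindex(frame.index)
        frame["sensor_day"] = sens["sensor_day"]
        frame["modelable"] = (
            (frame.index >= 3)
            & frame["target_z"].notna()
            & frame["mood_lag1"].notna()
            & frame["mood_lag2"].notna()
        )
        frame.insert(0, "participant_id", pid)
        frames.append(frame.reset_index())
    table = pd.concat(frames, ignore_index=True)
    expected = ["participant_id", "day_index", *FEATURE_COLUMNS,
                "target_z", "sensor_day", "modelable"]
    missing = set(expected) - set(table.columns)
    if missing:
        raise SchemaError(f"feature table missing columns: {sorted(missing)}")
    return table[expected]
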