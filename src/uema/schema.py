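"""Canonical predictor schema: 53 daily variables in 13 feature groups.

The daily predictor table summarizes six smartphone sensor channels
(calls, SMS, screen, app usage, camera, accelerometer) plus two mood-history
lags.  Histogram-style groups (top-5 contacts/apps, 11 app categories) are
normalized to sum to one within a 3-day window; screen and mood-history
variables are standardized within participant; activity and image variables
live on a 0-1 scale.
"""
from __future__ import annotations

from collections import OrderedDict

#: The 11 app-store categories used for the categorized-app histograms.
APP_CATEGORIES: tuple[str, ...] = (
    "built-in",
    "communication",
    "entertainment",
    "finance",
    "games",
    "office",
    "social",
    "travel",
    "utilities",
    "other",
    "unknown",
)


def _slug(category: str) -> str:
    return category.replace("-", "_")


#: Ordered feature groups (13 groups -> 53 variables).
FEATURE_GROUPS: "OrderedDict[str, tuple[str, ...]]" = OrderedDict(
    [
        ("call_top5_freq", tuple(f"call_top5_freq_{i}" for i in range(1, 6))),
        ("call_top5_dur", tuple(f"call_top5_dur_{i}" for i in range(1, 6))),
        ("sms_top5_freq", tuple(f"sms_top5_freq_{i}" for i in range(1, 6))),
        ("activity_high_pct", ("activity_high_pct",)),
        ("screen_freq_z", ("screen_freq_z",)),
        ("screen_dur_z", ("screen_dur_z",)),
        ("app_top5_freq", tuple(f"app_top5_freq_{i}" for i in range(1, 6))),
        ("app_top5_dur", tuple(f"app_top5_dur_{i}" for i in range(1, 6))),
        ("app_cat_freq", tuple(f"app_cat_freq_{_slug(c)}" for c in APP_CATEGORIES)),
        ("app_cat_dur", tuple(f"app_cat_dur_{_slug(c)}" for c in APP_CATEGORIES)),
        ("images_norm", ("images_norm",)),
        ("mood_lag1", ("mood_lag1",)),
        ("mood_lag2", ("mood_lag2",)),
    ]
)

#: Flat, ordered list of all 53 predictor variables.
FEATURE_COLUMNS: tuple[str, ...] = tuple(
    name for cols in FEATURE_GROUPS.values() for name in cols
)

#: Sensor-derived variables (everything except the mood-history lags).
SENSOR_COLUMNS: tuple[str, ...] = tuple(
    c for c in FEATURE_COLUMNS if not c.startswith("mood_lag")
)

#: Variables whose values are, by construction, normalized histogram bins in [0, 1].
HISTOGRAM_COLUMNS: tuple[str, ...] = tuple(
    name
    for group, cols in FEATURE_GROUPS.items()
    for name in cols
    if group
    in (
        "call_top5_freq",
        "call_top5_dur",
        "sms_top5_freq",
        "app_top5_freq",
        "app_top5_dur",
        "app_cat_freq",
        "app_cat_dur",
    )
)

#: The three self-report mood measures.
MOOD_MEASURES: tuple[str, ...] = ("mood", "valence", "arousal")

#: Raw-scale bounds for each measure (inclusive).
MEASURE_BOUNDS: dict[str, tuple[int, int]] = {
    "mood": (1, 10),
    "valence": (-2, 2),
    "arousal": (-2, 2),
}


def category_slug(category: str) -> str:
    """Column-name-safe identifier for an app category."""
    if category not in APP_CATEGORIES:
        raise ValueError(f"unknown app category: {category!r}")
    return _slug(category)
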