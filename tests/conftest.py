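"""Shared fixtures: small synthetic studies reused across test modules."""
from __future__ import annotations

import pandas as pd
import pytest

import uema
from uema import ema, features
from uema.config import CouplingSpec, StudyConfig


@pytest.fixture(scope="session")
def small_bundle():
    """Three participants, two weeks, full adherence."""
    cfg = StudyConfig(
        n_participants=3,
        n_days=14,
        seed=42,
        missing_day_prob=0.0,
        missing_rating_prob=0.05,
    )
    return uema.generate_study(cfg)


@pytest.fixture(scope="session")
def small_targets(small_bundle):
    daily = ema.aggregate_daily(
        small_bundle.mood, small_bundle.start_date, small_bundle.n_days
    )
    targets, dropped = ema.standardize_targets(daily)
    assert not dropped
    return targets


@pytest.fixture(scope="session")
def small_table(small_bundle, small_targets):
    return features.build_feature_table(small_bundle, small_targets, "mood")


@pytest.fixture(scope="session")
def null_42day_table():
    """One-measure modeling table for a 42-day null-coupling cohort of 8."""
    cfg = StudyConfig(n_participants=8, n_days=42, seed=7)
    bundle = uema.generate_study(cfg)
    daily = ema.aggregate_daily(bundle.mood, bundle.start_date, bundle.n_days)
    targets, _ = ema.standardize_targets(daily)
    return features.build_feature_table(bundle, targets, "mood")


def make_mood_frame(rows):
    """Helper: mood-rating frame from (pid, iso-timestamp, mood, valence, arousal)."""
    df = pd.DataFrame(
        rows, columns=["participant_id", "timestamp", "mood", "valence", "arousal"]
    )
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df
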