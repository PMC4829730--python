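"""Feature engineering: rankings, window histograms, per-channel features."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from uema import features
from uema.features import (
    Ranking,
    activity_feature,
    app_features,
    build_feature_table,
    image_feature,
    mood_lags,
    rank_top5,
    screen_features,
    window_histogram,
)
from uema.schema import APP_CATEGORIES, FEATURE_COLUMNS, FEATURE_GROUPS

START = pd.Timestamp("2016-01-04")


def _events(pid, specs, id_col="contact_id", extra=None):
    """specs: list of (day, second-of-day, entity[, duration])."""
    rows = []
    for spec in specs:
        day, sec, ent = spec[0], spec[1], spec[2]
        ts = START + pd.Timedelta(days=day - 1, seconds=sec)
        row = {"participant_id": pid, "timestamp": ts, id_col: ent}
        if len(spec) > 3:
            row["duration_s"] = spec[3]
        rows.append(row)
    return pd.DataFrame(rows)


class TestRanking:
    def test_ranked_by_count_with_short_ranking(self):
        ev = _events("P01", [(1, i, "A") for i in range(10)]
                     + [(1, 100 + i, "B") for i in range(5)]
                     + [(2, 0, "C")])
        r = rank_top5(ev, "contact_id")
        assert r.entities == ("A", "B", "C")

    def test_tie_broken_by_first_occurrence(self):
        ev = _events("P01", [(1, 0, "A"), (1, 1, "B"), (1, 2, "B"),
                             (1, 3, "A"), (1, 4, "B"), (1, 5, "A")])
        assert rank_top5(ev, "contact_id").entities == ("A", "B")

    def test_empty_ranking_gives_zero_variables(self):
        empty = pd.DataFrame(columns=["participant_id", "timestamp", "contact_id"])
        r = rank_top5(empty, "contact_id")
        assert r.entities == ()
        hist = window_histogram(empty, r, "count", 5, START)
        assert (hist.to_numpy() == 0).all()

    def test_duplicate_entities_rejected(self):
        with pytest.raises(ValueError):
            Ranking("P01", "calls", ("A", "A"))


class TestWindowHistogram:
    def test_sum_to_one_normalization(self):
        # day-3 window contains counts (2,1,0,1,0) across the five slots
        r = Ranking("P01", "calls", ("A", "B", "C", "D", "E"))
        ev = _events("P01", [(1, 0, "A"), (2, 0, "A"), (3, 0, "B"), (2, 10, "D")])
        hist = window_histogram(ev, r, "count", 5, START)
        assert np.allclose(hist.loc[3], [0.5, 0.25, 0.0, 0.25, 0.0])

    def test_all_zero_window_stays_zero(self):
        r = Ranking("P01", "calls", ("A", "B"))
        ev = _events("P01", [(1, 0, "A")])
        hist = window_histogram(ev, r, "count", 10, START)
        assert (hist.loc[6] == 0).all()  # window days 4-6 empty

    def test_window_ends_on_current_day(self):
        r = Ranking("P01", "calls", ("A", "B"))
        ev = _events("P01", [(4, 0, "B")])
        hist = window_histogram(ev, r, "count", 6, START)
        assert hist.loc[3, 2] == 0.0  # day-4 event invisible on day 3
        assert hist.loc[4, 2] == 1.0
        assert hist.loc[6, 2] == 1.0  # still inside days 4..6
        assert (hist.loc[5] == [0.0, 1.0, 0.0, 0.0, 0.0]).all()

    def test_duration_weighting(self):
        r = Ranking("P01", "calls", ("A", "B"))
        ev = _events("P01", [(1, 0, "A", 30), (1, 10, "B", 90)])
        hist = window_histogram(ev, r, "duration", 3, START)
        assert np.allclose(hist.loc[1], [0.25, 0.75, 0, 0, 0])

    def test_matches_naive_rescan_oracle(self, small_bundle):
        """Windowed pipeline equals a brute-force re-count from raw events."""
        rng = np.random.default_rng(0)
        calls = small_bundle.calls
        n_days = small_bundle.n_days
        for _ in range(50):
            pid = rng.choice(small_bundle.participants)
            day = int(rng.integers(1, n_days + 1))
            ev = calls[calls["participant_id"] == pid]
            ranking = rank_top5(ev, "contact_id")
            hist = window_histogram(ev, ranking, "count", n_days, START)
            # naive: directly count events in the 3-day window per entity
            d = features.day_index(ev["timestamp"], START)
            in_win = ev[(d >= max(1, day - 2)) & (d <= day)]
            raw = np.array(
                [
                    (in_win["contact_id"] == e).sum()
                    for e in ranking.entities
                ]
                + [0] * (5 - len(ranking.entities)),
                dtype=float,
            )
            expected = raw / raw.sum() if raw.sum() else raw
            assert np.allclose(hist.loc[day].to_numpy(), expected)


class TestScreen:
    def _frame(self, specs):
        rows = [
            {
                "participant_id": "P01",
                "timestamp": START + pd.Timedelta(days=d - 1, seconds=s),
                "state": state,
            }
            for d, s, state in specs
        ]
        return pd.DataFrame(rows)

    def test_daily_count_and_duration(self):
        scr = self._frame(
            [(1, 36000, "on"), (1, 36300, "off"), (1, 43200, "on"), (1, 43800, "off")]
        )
        out = screen_features(scr, 3, START)
        assert out.loc[1, "screen_count"] == 2
        assert out.loc[1, "screen_seconds"] == 900.0

    def test_midnight_session_split(self):
        scr = self._frame([(1, 85800, "on"), (2, 600, "off")])  # 23:50 -> 00:10
        out = screen_features(scr, 3, START)
        assert out.loc[1, "screen_seconds"] == 600.0
        assert out.loc[2, "screen_seconds"] == 600.0
        assert out.loc[1, "screen_count"] == 1
        assert out.loc[2, "screen_count"] == 0

    def test_trailing_on_closed_at_midnight_and_leading_off_dropped(self):
        scr = self._frame([(1, 100, "off"), (2, 86100, "on")])  # 23:55 day 2
        out = screen_features(scr, 3, START)
        assert out.loc[1, "screen_seconds"] == 0.0
        assert out.loc[2, "screen_seconds"] == 300.0

    def test_counts_z_scored_within_participant(self):
        specs = []
        for day, k in ((1, 1), (2, 2), (3, 3)):
            for i in range(k):
                specs += [(day, 1000 * i, "on"), (day, 1000 * i + 60, "off")]
        out = screen_features(self._frame(specs), 3, START)
        assert np.allclose(out["screen_freq_z"], [-1.0, 0.0, 1.0])


class TestActivity:
    def _frame(self, specs):
        return pd.DataFrame(
            [
                {
                    "participant_id": "P01",
                    "hour_start": START + pd.Timedelta(days=d - 1, hours=h),
                    "fraction_high": f,
                    "n_samples": n,
                }
                for d, h, f, n in specs
            ]
        )

    def test_equal_weight_mean(self):
        out = activity_feature(self._frame([(1, 9, 0.2, 60), (1, 10, 0.4, 60)]), 2, START)
        assert out.loc[1] == pytest.approx(0.3)
        assert out.loc[2] == 0.0  # no summaries -> 0

    def test_sample_count_weighting(self):
        out = activity_feature(self._frame([(1, 9, 0.2, 300), (1, 10, 0.6, 100)]), 1, START)
        assert out.loc[1] == pytest.approx(0.3)

    def test_single_zero_hour(self):
        out = activity_feature(self._frame([(1, 0, 0.0, 60)]), 1, START)
        assert out.loc[1] == 0.0

    def test_fraction_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="fraction_high"):
            activity_feature(self._frame([(1, 9, 1.2, 60)]), 1, START)


class TestImagesAndLags:
    def test_max_normalization(self):
        cam = _events("P01", [(2, i, "x") for i in range(5)]
                      + [(3, i, "x") for i in range(10)], id_col="ignore")
        out = image_feature(cam, 3, START)
        assert np.allclose(out, [0.0, 0.5, 1.0])

    def test_all_zero_and_constant_counts(self):
        empty = pd.DataFrame(columns=["participant_id", "timestamp"])
        assert (image_feature(empty, 4, START) == 0).all()
        cam = _events("P01", [(d, 0, "x") for d in (1, 2, 3)], id_col="ignore")
        assert (image_feature(cam, 3, START) == 1.0).all()

    def test_lag_alignment(self):
        z = pd.Series([0.3, -1.2, 0.9], index=pd.RangeIndex(1, 4, name="day_index"))
        lags = mood_lags(z, 4)
        assert lags.loc[3, "mood_lag1"] == -1.2
        assert lags.loc[3, "mood_lag2"] == 0.3
        assert np.isnan(lags.loc[1, "mood_lag1"])
        assert np.isnan(lags.loc[2, "mood_lag2"])
        # lagged series equals the unshifted values, one/two days later
        assert np.allclose(lags["mood_lag1"].iloc[1:3], z.iloc[0:2])


class TestAppFeatures:
    def test_single_category_monopoly(self):
        apps = _events(
            "P01", [(1, i, "app_a", 10) for i in range(4)], id_col="app_id"
        )
        cats = pd.Series({"app_a": "social"})
        out = app_features(apps, rank_top5(apps, "app_id"), cats, 2, START)
        assert out.loc[1, "app_cat_freq_social"] == 1.0
        assert out.loc[1, "app_cat_dur_social"] == 1.0
        assert out.loc[1, [f"app_cat_freq_{c}" for c in
                           ("games", "office", "travel")]].sum() == 0

    def test_unknown_fallback_and_output_width(self):
        apps = _events("P01", [(1, 0, "mystery", 5)], id_col="app_id")
        out = app_features(apps, rank_top5(apps, "app_id"), pd.Series(dtype=str), 1, START)
        assert out.shape[1] == 32
        assert out.loc[1, "app_cat_freq_unknown"] == 1.0

    def test_category_histogram_sums_to_one_with_usage(self, small_bundle):
        apps = small_bundle.apps[
            small_bundle.apps["participant_id"] == small_bundle.participants[0]
        ]
        cats = small_bundle.app_categories.set_index("app_id")["category"]
        out = app_features(apps, rank_top5(apps, "app_id"), cats,
                           small_bundle.n_days, START)
        freq = out[[f"app_cat_freq_{c.replace('-', '_')}" for c in APP_CATEGORIES]]
        sums = freq.sum(axis=1)
        assert np.all((np.abs(sums - 1) < 1e-9) | (sums == 0))


class TestFeatureTable:
    def test_schema_counts(self):
        assert len(FEATURE_COLUMNS) == 53
        assert len(FEATURE_GROUPS) == 13
        calls_sms = sum(
            len(v) for k, v in FEATURE_GROUPS.items()
            if k.startswith(("call_", "sms_"))
        )
        apps = sum(
            len(v) for k, v in FEATURE_GROUPS.items() if k.startswith("app_")
        )
        assert calls_sms == 15
        assert apps == 32

    def test_table_columns_and_modelable_flag(self, small_table):
        assert list(small_table.columns[2:55]) == list(FEATURE_COLUMNS)
        early = small_table[small_table["day_index"] < 3]
        assert not early["modelable"].any(), "lags unavailable before day 3"
        ok = small_table[small_table["modelable"]]
        assert ok["target_z"].notna().all()
        assert ok["mood_lag2"].notna().all()

    def test_histogram_variables_in_unit_interval(self, small_table):
        from uema.schema import HISTOGRAM_COLUMNS

        vals = small_table[list(HISTOGRAM_COLUMNS)].to_numpy()
        assert vals.min() >= 0.0 and vals.max() <= 1.0 + 1e-12

    def test_five_slot_groups_sum_to_one_or_zero(self, small_table):
        for group in ("call_top5_freq", "sms_top5_freq", "app_top5_dur"):
            cols = list(FEATURE_GROUPS[group])
            sums = small_table[cols].sum(axis=1).to_numpy()
            assert np.all((np.abs(sums - 1) < 1e-9) | (sums == 0))

    def test_screen_z_moments(self, small_table):
        for pid, grp in small_table.groupby("participant_id"):
            z = grp["screen_freq_z"].to_numpy()
            assert abs(z.mean()) < 1e-9
            assert abs(z.std(ddof=1) - 1) < 1e-9
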