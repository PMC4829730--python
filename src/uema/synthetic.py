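"""Synthetic smartphone event streams and mood diaries.

Emulates a six-week data-collection wave: per participant, six passive sensor
channels (calls, SMS, screen on/off, app launches, camera, hourly
accelerometer activity summaries) plus a prompted mood diary (up to five
ratings per day: one-dimensional mood 1-10 and circumplex valence/arousal
-2..2).

Behavioral structure worth knowing about:

* contact and app popularity is Zipf-like, so "top 5" entities are well
  defined and dominate interaction counts;
* whole days go missing with ``missing_day_prob`` (no sensor data and no
  ratings that day), individual diary prompts with ``missing_rating_prob``;
* latent daily mood follows an AR(1) process optionally coupled to the
  participant's own standardized daily sensor features (see
  :class:`uema.config.CouplingSpec`), giving ground truth for
  parameter-recovery tests; ratings are the latent value plus rating noise,
  rounded and clipped to each scale.

One global seed drives per-participant child generators, so any single
participant is reproducible in isolation.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ConfigError, StudyConfig
from .features import sensor_feature_frame
from .schema import APP_CATEGORIES, MEASURE_BOUNDS

#: Fixed first study day (a Monday); day_index 1 corresponds to this date.
START_DATE = pd.Timestamp("2016-01-04")

#: Raw-scale location/scale of the three measures' latents.  Mood follows the
#: coupling formula exactly; valence and arousal share the same latent
#: deviation, rescaled to typical dispersions for their 5-point scale.
MEASURE_LATENTS = {
    "mood": (7.0, 1.0),
    "valence": (0.7, 0.66),
    "arousal": (-0.1, 1.05),
}

STREAM_NAMES = ("calls", "sms", "screen", "apps", "camera", "activity")

_STREAM_COLUMNS = {
    "calls": ["participant_id", "timestamp", "direction", "contact_id", "duration_s"],
    "sms": ["participant_id", "timestamp", "contact_id"],
    "screen": ["participant_id", "timestamp", "state"],
    "apps": ["participant_id", "timestamp", "app_id", "duration_s"],
    "camera": ["participant_id", "timestamp"],
    "activity": ["participant_id", "hour_start", "fraction_high", "n_samples"],
    "mood": ["participant_id", "timestamp", "mood", "valence", "arousal"],
}

_INT_COLUMNS = {"duration_s", "n_samples", "mood", "valence", "arousal"}


@dataclass
class StudyBundle:
    """All generated streams for one study, in long (participant_id) form."""

    config: StudyConfig | None
    start_date: pd.Timestamp
    n_days: int
    participants: list[str]
    calls: pd.DataFrame
    sms: pd.DataFrame
    screen: pd.DataFrame
    apps: pd.DataFrame
    camera: pd.DataFrame
    activity: pd.DataFrame
    mood: pd.DataFrame
    app_categories: pd.DataFrame

    def streams(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in (*STREAM_NAMES, "mood")}


def _zipf_weights(n: int, exponent: float = 1.2) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1) ** exponent
    return w / w.sum()


def _day_start(day: int) -> pd.Timestamp:
    return START_DATE + pd.Timedelta(days=day - 1)


def _ts(day: int, second: int) -> pd.Timestamp:
    return _day_start(day) + pd.Timedelta(seconds=int(second))


def app_category_table(n_apps: int) -> pd.DataFrame:
    """Static app-id -> category lookup (cycles through the 11 categories)."""
    ids = [f"app_{i:03d}" for i in range(n_apps)]
    cats = [APP_CATEGORIES[i % len(APP_CATEGORIES)] for i in range(n_apps)]
    return pd.DataFrame({"app_id": ids, "category": cats})


def _generate_sensor_days(
    pid: str, cfg: StudyConfig, rng: np.random.Generator, active_days: np.ndarray
) -> dict[str, pd.DataFrame]:
    """Generate the six sensor streams for one participant."""
    contact_w = _zipf_weights(cfg.n_contacts)
    app_w = _zipf_weights(cfg.n_apps)
    contacts = np.array([f"c_{i:03d}" for i in range(cfg.n_contacts)])
    app_ids = np.array([f"app_{i:03d}" for i in range(cfg.n_apps)])

    calls, sms, screen, apps, camera, activity = [], [], [], [], [], []
    for day in active_days:
        # calls
        k = rng.poisson(cfg.call_rate)
        secs = np.sort(rng.integers(6 * 3600, SECONDS - 1, size=k))
        for s in secs:
            calls.append(
                (
                    pid,
                    _ts(day, s),
                    "incoming" if rng.random() < 0.45 else "outgoing",
                    rng.choice(contacts, p=contact_w),
                    int(np.rint(rng.lognormal(4.3, 1.0))),  # median ~74 s
                )
            )
        # sms
        k = rng.poisson(cfg.sms_rate)
        secs = np.sort(rng.integers(7 * 3600, SECONDS - 1, size=k))
        for s in secs:
            sms.append((pid, _ts(day, s), rng.choice(contacts, p=contact_w)))
        # screen sessions: sorted starts, durations truncated to the gap and
        # to the end of the day so on/off events stay ordered within the day
        k = max(1, rng.poisson(cfg.screen_rate))
        starts = np.sort(rng.choice(SECONDS - 2, size=k, replace=False))
        durations = np.maximum(1, np.rint(rng.exponential(150.0, size=k))).astype(int)
        bounds = np.append(starts[1:], SECONDS)
        for s, d, b in zip(starts, durations, bounds):
            end = min(s + d, b - 1, SECONDS - 1)
            if end <= s:
                continue
            screen.append((pid, _ts(day, s), "on"))
            screen.append((pid, _ts(day, end), "off"))
        # app launches
        k = rng.poisson(cfg.app_rate)
        secs = np.sort(rng.integers(0, SECONDS - 1, size=k))
        chosen = rng.choice(app_ids, p=app_w, size=k)
        durs = np.maximum(1, np.rint(rng.exponential(60.0, size=k))).astype(int)
        for s, a, d in zip(secs, chosen, durs):
            apps.append((pid, _ts(day, s), a, int(d)))
        # camera
        k = rng.poisson(cfg.camera_rate)
        secs = np.sort(rng.integers(8 * 3600, SECONDS - 1, size=k))
        for s in secs:
            camera.append((pid, _ts(day, s)))
        # hourly accelerometer summaries
        base = rng.beta(2.0, 9.0)  # participant-day activity level
        for hour in range(24):
            frac = float(np.clip(base * DIURNAL[hour] + rng.normal(0, 0.02), 0, 1))
            activity.append(
                (
                    pid,
                    _day_start(day) + pd.Timedelta(hours=hour),
                    round(frac, 4),
                    int(rng.integers(50, 61)),
                )
            )

    def frame(rows, name):
        df = pd.DataFrame(rows, columns=_STREAM_COLUMNS[name])
        return df

    return {
        "calls": frame(calls, "calls"),
        "sms": frame(sms, "sms"),
        "screen": frame(screen, "screen"),
        "apps": frame(apps, "apps"),
        "camera": frame(camera, "camera"),
        "activity": frame(activity, "activity"),
    }


SECONDS = 86400
#: Hour-of-day multiplier for activity (sleep trough, daytime plateau).
DIURNAL = np.concatenate(
    [np.full(7, 0.15), np.linspace(0.3, 1.0, 5), np.full(9, 1.0), np.linspace(0.9, 0.3, 3)]
)


def _standardized_effect_features(
    streams: dict[str, pd.DataFrame],
    categories: pd.Series,
    cfg: StudyConfig,
    active_days: np.ndarray,
) -> pd.DataFrame:
    """Standardized day-level values of the coupled sensor features.

    Uses the same feature pipeline the analysis applies, then z-scores each
    coupled column across the participant's active days (idempotent for
    already-standardized variables up to the day subset).
    """
    keys = list(cfg.coupling.effect_vector)
    if not keys:
        return pd.DataFrame(index=pd.Index(active_days, name="day_index"))
    sens = sensor_feature_frame(streams, categories, cfg.n_days, START_DATE)
    sub = sens.loc[active_days, keys].astype(float)
    for col in keys:
        x = sub[col].to_numpy()
        sd = x.std(ddof=1) if len(x) > 1 else 0.0
        sub[col] = (x - x.mean()) / sd if sd > 0 else 0.0
    return sub


def _generate_mood(
    pid: str,
    cfg: StudyConfig,
    rng: np.random.Generator,
    active_days: np.ndarray,
    f_std: pd.DataFrame,
) -> pd.DataFrame:
    """Latent AR(1)+coupling mood process and the diary ratings it produces."""
    cp = cfg.coupling
    effect = np.array([cp.effect_vector[k] for k in f_std.columns])
    active = set(int(d) for d in active_days)

    rows = []
    dev = 0.0  # latent deviation from the mood mean, mood-scale points
    for day in range(1, cfg.n_days + 1):
        drive = float(f_std.loc[day].to_numpy() @ effect) if day in active and len(effect) else 0.0
        dev = cp.ar_coefficient * dev + drive + rng.normal(0.0, cp.noise_sd)
        if day not in active:
            continue
        for hour in cfg.rating_times:
            jitter = int(rng.integers(-900, 901))
            if rng.random() < cfg.missing_rating_prob:
                continue
            ts = _ts(day, hour * 3600 + 1800 + jitter)
            values = {}
            for measure, (mu, scale) in MEASURE_LATENTS.items():
                lo, hi = MEASURE_BOUNDS[measure]
                latent = mu + scale * dev
                noisy = latent + scale * rng.normal(0.0, cp.measurement_sd)
                values[measure] = int(np.clip(np.rint(noisy), lo, hi))
            rows.append((pid, ts, values["mood"], values["valence"], values["arousal"]))
    return pd.DataFrame(rows, columns=_STREAM_COLUMNS["mood"])


def generate_study(config: StudyConfig) -> StudyBundle:
    """Generate all event and diary streams for every participant.

    Deterministic given ``config.seed``: participant ``i`` uses the child
    generator ``default_rng([seed, i])``, so the same participant regenerates
    identically regardless of cohort size.
    """
    if not isinstance(config, StudyConfig):
        raise ConfigError("generate_study expects a StudyConfig")
    width = max(2, len(str(config.n_participants)))
    participants = [f"P{i + 1:0{width}d}" for i in range(config.n_participants)]
    categories = app_category_table(config.n_apps)
    cat_map = categories.set_index("app_id")["category"]

    collected: dict[str, list[pd.DataFrame]] = {n: [] for n in (*STREAM_NAMES, "mood")}
    for i, pid in enumerate(participants):
        rng = np.random.default_rng([config.seed, i])
        missing = rng.random(config.n_days) < config.missing_day_prob
        active_days = np.flatnonzero(~missing) + 1
        streams = _generate_sensor_days(pid, config, rng, active_days)
        f_std = _standardized_effect_features(streams, cat_map, config, active_days)
        mood = _generate_mood(pid, config, rng, active_days, f_std)
        for name, df in streams.items():
            collected[name].append(df)
        collected["mood"].append(mood)

    def cat(name):
        parts = [df for df in collected[name] if len(df)]
        if not parts:
            return pd.DataFrame(columns=_STREAM_COLUMNS[name])
        return pd.concat(parts, ignore_index=True)

    return StudyBundle(
        config=config,
        start_date=START_DATE,
        n_days=config.n_days,
        participants=participants,
        calls=cat("calls"),
        sms=cat("sms"),
        screen=cat("screen"),
        apps=cat("apps"),
        camera=cat("camera"),
        activity=cat("activity"),
        mood=cat("mood"),
        app_categories=categories,
    )


# ---------------------------------------------------------------------------
# CSV round-trip


def _format_ts(series: pd.Series) -> pd.Series:
    return pd.to_datetime(series).dt.strftime("%Y-%m-%dT%H:%M:%S")


def write_streams(bundle: StudyBundle, directory) -> list[Path]:
    """Write one CSV per stream per participant plus study metadata.

    Layout: ``<dir>/study.json``, ``<dir>/app_categories.csv`` and, per
    participant, ``<dir>/<pid>/{calls,sms,screen,apps,camera,activity,mood}.csv``
    with UTF-8, header rows and ISO-8601 timestamps.  Participants without
    events in a channel get a header-only file, so re-reading reproduces the
    bundle exactly.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - environment dependent
        raise OSError(f"cannot create output directory {directory}: {exc}") from exc
    written: list[Path] = []

    meta = {
        "start_date": str(bundle.start_date.date()),
        "n_days": int(bundle.n_days),
        "participants": list(bundle.participants),
    }
    meta_path = directory / "study.json"
    meta_path.write_text(json.dumps(meta, indent=2) + "\n", encoding="utf-8")
    written.append(meta_path)
    cat_path = directory / "app_categories.csv"
    bundle.app_categories.to_csv(cat_path, index=False)
    written.append(cat_path)

    for pid in bundle.participants:
        pdir = directory / pid
        pdir.mkdir(exist_ok=True)
        for name, df in bundle.streams().items():
            sub = df[df["participant_id"] == pid].copy() if len(df) else df.copy()
            cols = [c for c in _STREAM_COLUMNS[name] if c != "participant_id"]
            if len(sub):
                for c in ("timestamp", "hour_start"):
                    if c in sub.columns:
                        sub[c] = _format_ts(sub[c])
                sub = sub[cols]
            else:
                sub = pd.DataFrame(columns=cols)
            path = pdir / f"{name}.csv"
            try:
                sub.to_csv(path, index=False)
            except OSError as exc:  # pragma: no cover
                raise OSError(f"failed writing {path}: {exc}") from exc
            written.append(path)
    return written


def read_streams(directory) -> StudyBundle:
    """Re-read a :func:`write_streams` directory into a StudyBundle."""
    directory = Path(directory)
    meta = json.loads((directory / "study.json").read_text(encoding="utf-8"))
    participants = list(meta["participants"])
    categories = pd.read_csv(directory / "app_categories.csv")

    collected: dict[str, list[pd.DataFrame]] = {n: [] for n in (*STREAM_NAMES, "mood")}
    for pid in participants:
        for name in (*STREAM_NAMES, "mood"):
            path = directory / pid / f"{name}.csv"
            df = pd.read_csv(path)
            df.insert(0, "participant_id", pid)
            for c in ("timestamp", "hour_start"):
                if c in df.columns:
                    df[c] = pd.to_datetime(df[c], format="ISO8601")
            for c in df.columns:
                if c in _INT_COLUMNS:
                    df[c] = df[c].astype("int64") if len(df) else df[c].astype("int64")
            if len(df):
                collected[name].append(df)

    def cat(name):
        if not collected[name]:
            return pd.DataFrame(columns=_STREAM_COLUMNS[name])
        return pd.concat(collected[name], ignore_index=True)

    return StudyBundle(
        config=None,
        start_date=pd.Timestamp(meta["start_date"]),
        n_days=int(meta["n_days"]),
        participants=participants,
        calls=cat("calls"),
        sms=cat("sms"),
        screen=cat("screen"),
        apps=cat("apps"),
        camera=cat("camera"),
        activity=cat("activity"),
        mood=cat("mood"),
        app_categories=categories,
    )
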