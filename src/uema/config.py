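"""Configuration objects for the synthetic study and the pipeline.

A :class:`StudyConfig` describes one simulated data-collection wave: how many
participants, how many days, the diary prompt schedule, missingness, and the
latent coupling between smartphone behavior and mood.  Validation failures
raise :class:`ConfigError` with the offending field named in the message.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import yaml

from .schema import FEATURE_COLUMNS, MOOD_MEASURES, SENSOR_COLUMNS


class ConfigError(ValueError):
    """A configuration field failed validation; the message names the field."""


@dataclass(frozen=True)
class CouplingSpec:
    """Ground-truth latent model linking daily behavior features to mood.

    The latent daily mood of each participant follows an AR(1) process with a
    linear contribution from that day's standardized sensor features:

        m_d = mu + ar_coefficient * (m_{d-1} - mu) + effect . f_d + N(0, noise_sd)

    Individual diary ratings are the latent value plus rating noise
    ``N(0, measurement_sd)``, rounded and clipped to the rating scale.

    Parameters
    ----------
    effect_vector
        Map from sensor variable name (see ``schema.SENSOR_COLUMNS``) to its
        coefficient on the latent mood, in standardized-feature units (one
        coefficient unit = one mood-scale point per feature SD).  Empty map =
        null coupling: behavior carries no mood signal.
    ar_coefficient
        Day-to-day autocorrelation of latent mood, in (-1, 1).
    noise_sd
        SD of the daily latent innovation, mood-scale points.
    measurement_sd
        SD of per-rating noise before rounding, mood-scale points.
    """

    effect_vector: Mapping[str, float] = field(default_factory=dict)
    ar_coefficient: float = 0.3
    noise_sd: float = 0.8
    measurement_sd: float = 0.7

    def __post_init__(self) -> None:
        for key in self.effect_vector:
            if key not in FEATURE_COLUMNS:
                raise ConfigError(
                    f"coupling.effect_vector: {key!r} is not a feature variable"
                )
            if key not in SENSOR_COLUMNS:
                raise ConfigError(
                    "coupling.effect_vector: mood-history lags cannot be "
                    f"coupling targets (got {key!r})"
                )
        if not -1.0 < self.ar_coefficient < 1.0:
            raise ConfigError(
                f"coupling.ar_coefficient must be in (-1, 1), got {self.ar_coefficient}"
            )
        if not self.noise_sd > 0:
            raise ConfigError(f"coupling.noise_sd must be > 0, got {self.noise_sd}")
        if not self.measurement_sd > 0:
            raise ConfigError(
                f"coupling.measurement_sd must be > 0, got {self.measurement_sd}"
            )


@dataclass(frozen=True)
class StudyConfig:
    """Design of one synthetic study wave.

    Defaults mirror a 6-week diary study with five prompts per day and
    adherence comparable to a well-run student sample; event-rate defaults
    are of the order of magnitude seen in real smartphone-log studies.
    """

    n_participants: int = 27
    n_days: int = 42
    ratings_per_day: int = 5
    rating_times: Sequence[int] = (9, 12, 15, 18, 21)
    seed: int = 0
    missing_day_prob: float = 0.10
    missing_rating_prob: float = 0.08
    n_contacts: int = 15
    n_apps: int = 40
    coupling: CouplingSpec = field(default_factory=CouplingSpec)
    # mean events per participant-day, by channel
    call_rate: float = 5.0
    sms_rate: float = 2.0
    screen_rate: float = 60.0
    app_rate: float = 120.0
    camera_rate: float = 3.0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigError(f"n_participants must be >= 1, got {self.n_participants}")
        if self.n_days < 8:
            raise ConfigError(f"n_days must be >= 8, got {self.n_days}")
        if self.ratings_per_day < 1:
            raise ConfigError(
                f"ratings_per_day must be >= 1, got {self.ratings_per_day}"
            )
        if len(self.rating_times) != self.ratings_per_day:
            raise ConfigError(
                "rating_times must list one clock hour per rating "
                f"({self.ratings_per_day} expected, got {len(self.rating_times)})"
            )
        if any(not 0 <= h <= 23 for h in self.rating_times):
            raise ConfigError(f"rating_times must be clock hours 0-23: {self.rating_times}")
        for name in ("missing_day_prob", "missing_rating_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be a probability in [0, 1], got {p}")
        if self.n_contacts < 1:
            raise ConfigError(f"n_contacts must be >= 1, got {self.n_contacts}")
        if self.n_apps < 1:
            raise ConfigError(f"n_apps must be >= 1, got {self.n_apps}")
        for name in ("call_rate", "sms_rate", "screen_rate", "app_rate", "camera_rate"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")

    def with_seed(self, seed: int) -> "StudyConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end pipeline settings: study design plus analysis options."""

    study: StudyConfig = field(default_factory=StudyConfig)
    window_days: int = 3
    margin: float = 0.5
    measures: Sequence[str] = MOOD_MEASURES
    families: Sequence[str] = ("mean", "history", "stepAIC", "stepCV")
    min_complete_days: int = 20
    out_dir: str = "uema_out"
    verbosity: int = 1

    def __post_init__(self) -> None:
        if self.window_days < 1:
            raise ConfigError(f"window_days must be >= 1, got {self.window_days}")
        if not self.margin > 0:
            raise ConfigError(f"margin must be > 0, got {self.margin}")
        for m in self.measures:
            if m not in MOOD_MEASURES:
                raise ConfigError(f"measures: unknown measure {m!r}")
        for f in self.families:
            if f not in ("mean", "history", "stepAIC", "stepCV"):
                raise ConfigError(f"families: unknown model family {f!r}")
        if self.min_complete_days < 1:
            raise ConfigError(
                f"min_complete_days must be >= 1, got {self.min_complete_days}"
            )


def _build_coupling(raw: Mapping) -> CouplingSpec:
    known = {"effect_vector", "ar_coefficient", "noise_sd", "measurement_sd"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"coupling: unknown field {sorted(unknown)[0]!r}")
    return CouplingSpec(**raw)


def _build_study(raw: Mapping) -> StudyConfig:
    raw = dict(raw)
    coupling = raw.pop("coupling", None)
    known = {f for f in StudyConfig.__dataclass_fields__ if f != "coupling"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"study: unknown field {sorted(unknown)[0]!r}")
    if "rating_times" in raw:
        raw["rating_times"] = tuple(raw["rating_times"])
    kwargs = dict(raw)
    if coupling is not None:
        kwargs["coupling"] = _build_coupling(coupling)
    return StudyConfig(**kwargs)


def load_config(path) -> PipelineConfig:
    """Parse a YAML pipeline configuration file.

    Top-level keys: ``study`` (StudyConfig fields, with nested ``coupling``),
    plus the PipelineConfig fields (``window_days``, ``margin``, ``measures``,
    ``families``, ``min_complete_days``, ``out_dir``, ``verbosity``).
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping at the top level")
    raw = dict(raw)
    study_raw = raw.pop("study", {})
    known = {f for f in PipelineConfig.__dataclass_fields__ if f != "study"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config field {sorted(unknown)[0]!r}")
    if "measures" in raw:
        raw["measures"] = tuple(raw["measures"])
    if "families" in raw:
        raw["families"] = tuple(raw["families"])
    return PipelineConfig(study=_build_study(study_raw), **raw)
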