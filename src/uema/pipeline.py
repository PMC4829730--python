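"""End-to-end pipeline: simulate -> targets -> features -> models -> report.

Each stage reads the previous stage's CSV artifacts from the output
directory and writes its own atomically (temp file + rename), so a crashed
run leaves no half-written files; a ``MANIFEST.json`` records stage status.
Given the same configuration (seed included) the whole artifact directory is
byte-identical across runs.
"""
from __future__ import annotations

import json
import logging
import os
import tempfile
import time
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import ema, evaluation, features, models, synthetic
from .config import PipelineConfig
from .schema import FEATURE_COLUMNS

logger = logging.getLogger(__name__)

STAGES = ("simulate", "targets", "featurize", "evaluate", "report")


def _atomic_write_text(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _atomic_write_csv(df: pd.DataFrame, path: Path, **kwargs) -> None:
    _atomic_write_text(path, df.to_csv(index=False, **kwargs))


def _update_manifest(outdir: Path, stage: str, status: str, seconds: float) -> None:
    path = outdir / "MANIFEST.json"
    manifest = {}
    if path.exists():
        manifest = json.loads(path.read_text(encoding="utf-8"))
    manifest[stage] = {"status": status, "seconds": round(seconds, 3)}
    _atomic_write_text(path, json.dumps(manifest, indent=2) + "\n")


def stage_simulate(config: PipelineConfig, outdir: Path) -> synthetic.StudyBundle:
    bundle = synthetic.generate_study(config.study)
    synthetic.write_streams(bundle, outdir / "streams")
    return bundle


def stage_targets(config: PipelineConfig, outdir: Path, bundle=None) -> pd.DataFrame:
    if bundle is None:
        bundle = synthetic.read_streams(outdir / "streams")
    daily = ema.aggregate_daily(bundle.mood, bundle.start_date, bundle.n_days)
    targets, _dropped = ema.standardize_targets(daily)
    _atomic_write_csv(targets, outdir / "daily_targets.csv")
    return targets


def stage_featurize(
    config: PipelineConfig, outdir: Path, bundle=None, targets=None
) -> dict[str, pd.DataFrame]:
    if bundle is None:
        bundle = synthetic.read_streams(outdir / "streams")
    if targets is None:
        targets = pd.read_csv(outdir / "daily_targets.csv")
    tables = {}
    sensor_cache: dict = {}
    for measure in config.measures:
        table = features.build_feature_table(
            bundle, targets, measure, window=config.window_days,
            sensor_cache=sensor_cache,
        )
        _atomic_write_csv(table, outdir / f"features_{measure}.csv")
        tables[measure] = table

    # participant pruning on the first measure's completeness view
    first = tables[config.measures[0]]
    daily = targets
    included, adherence = ema.prune_participants(
        daily, first, min_days=config.min_complete_days
    )
    _atomic_write_csv(adherence, outdir / "adherence.csv")
    for measure, table in tables.items():
        pruned = table[table["participant_id"].isin(included)].reset_index(drop=True)
        tables[measure] = pruned
        _atomic_write_csv(pruned, outdir / f"features_{measure}.csv")
    return tables


def stage_evaluate(config: PipelineConfig, outdir: Path, tables=None):
    if tables is None:
        tables = {
            m: pd.read_csv(outdir / f"features_{m}.csv") for m in config.measures
        }
    all_preds, all_perf, comparisons, all_inc, trends = [], [], [], [], []
    model_records = []
    for measure, table in tables.items():
        for family in config.families:
            preds, perf = evaluation.loocv_evaluate(
                table, measure, family, margin=config.margin
            )
            all_preds.append(preds)
            all_perf.append(perf)
            # full-data fits, serialized for inspection
            for pid, rows in table[table["modelable"]].groupby("participant_id"):
                y = rows["target_z"].to_numpy(dtype=float)
                if len(y) < evaluation.MIN_TRAIN_ROWS:
                    continue
                model = models.fit_family(family, rows[list(FEATURE_COLUMNS)], y)
                rec = model.to_record()
                rec.update({"participant_id": pid, "measure": measure})
                model_records.append(rec)
        perf_m = pd.concat(all_perf, ignore_index=True)
        perf_m = perf_m[perf_m["measure"] == measure]
        for fam in config.families:
            if fam in ("mean", "history"):
                continue
            for bench in ("mean", "history"):
                if bench not in config.families:
                    continue
                for metric in ("cv_mse", "pct_correct"):
                    try:
                        comparisons.append(
                            evaluation.compare_families(
                                perf_m, fam, bench, metric, measure
                            )
                        )
                    except models.InsufficientDataError:
                        logger.warning(
                            "comparison %s vs %s (%s, %s) skipped: too few pairs",
                            fam, bench, measure, metric,
                        )
        per_day, tr = evaluation.incremental_evaluate(
            table, measure, tuple(config.families), margin=config.margin
        )
        per_day.insert(0, "measure", measure)
        all_inc.append(per_day)
        trends.extend(tr)

    predictions = pd.concat(all_preds, ignore_index=True)
    performance = pd.concat(all_perf, ignore_index=True)
    incremental = (
        pd.concat(all_inc, ignore_index=True) if all_inc else pd.DataFrame()
    )
    _atomic_write_csv(predictions, outdir / "predictions.csv")
    _atomic_write_csv(performance, outdir / "performance.csv")
    _atomic_write_csv(
        pd.DataFrame([asdict(c) for c in comparisons]), outdir / "comparisons.csv"
    )
    _atomic_write_csv(incremental, outdir / "incremental.csv")
    _atomic_write_csv(
        pd.DataFrame([asdict(t) for t in trends]), outdir / "incremental_trends.csv"
    )
    models.models_to_jsonl(model_records, outdir / "models.jsonl")
    return performance, comparisons, trends


def _read_csv_or_empty(path: Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def stage_report(config: PipelineConfig, outdir: Path, results=None) -> str:
    if results is None:
        performance = pd.read_csv(outdir / "performance.csv")
        comp_df = _read_csv_or_empty(outdir / "comparisons.csv")
        comparisons = [
            evaluation.ComparisonResult(**row) for row in comp_df.to_dict("records")
        ]
        trends_df = _read_csv_or_empty(outdir / "incremental_trends.csv")
        trends = [
            evaluation.IncrementalTrend(**row) for row in trends_df.to_dict("records")
        ]
    else:
        performance, comparisons, trends = results
    summary, markdown = evaluation.summarize_report(performance, comparisons, trends)
    _atomic_write_csv(summary, outdir / "summary.csv")
    _atomic_write_text(outdir / "report.md", markdown)
    return markdown


def run_all(config: PipelineConfig, outdir=None) -> Path:
    """Run every stage in order; returns the artifact directory.

    A stage failure is recorded in ``MANIFEST.json`` (with earlier stages'
    outputs retained) and re-raised.
    """
    outdir = Path(outdir if outdir is not None else config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    state: dict = {}
    runners = {
        "simulate": lambda: state.update(bundle=stage_simulate(config, outdir)),
        "targets": lambda: state.update(
            targets=stage_targets(config, outdir, state.get("bundle"))
        ),
        "featurize": lambda: state.update(
            tables=stage_featurize(
                config, outdir, state.get("bundle"), state.get("targets")
            )
        ),
        "evaluate": lambda: state.update(
            results=stage_evaluate(config, outdir, state.get("tables"))
        ),
        "report": lambda: stage_report(config, outdir, state.get("results")),
    }
    for stage in STAGES:
        t0 = time.perf_counter()
        try:
            runners[stage]()
        except Exception:
            _update_manifest(outdir, stage, "failed", time.perf_counter() - t0)
            logger.error("stage %s failed", stage)
            raise
        dt = time.perf_counter() - t0
        _update_manifest(outdir, stage, "ok", dt)
        logger.info("stage %-9s done in %.2f s", stage, dt)
    return outdir
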