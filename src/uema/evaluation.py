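"""Predictive-performance assessment of the personalized and benchmark models.

Three procedures:

* :func:`loocv_evaluate` — full-data leave-one-out evaluation: for each
  modelable day the entire fitting procedure (including variable selection
  for the step families) is rerun on all other modelable days and the
  held-out day is predicted.  Performance per participant is the
  cross-validated MSE and the percentage of predictions whose absolute error
  is within a tolerated margin (0.5 standardized units, inclusive).
* :func:`compare_families` — paired Wilcoxon signed-rank tests of
  per-participant performance between two model families.
* :func:`incremental_evaluate` — growing-training-window assessment: days
  before day d train the models that predict day d, for d = 8..n_days; the
  per-day gap between a personalized family and the mean model is regressed
  on study day to estimate how relative performance develops as data accrue.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .models import FAMILIES, InsufficientDataError, fit_family
from .schema import FEATURE_COLUMNS

logger = logging.getLogger(__name__)

MARGIN_DEFAULT = 0.5
MIN_TRAIN_ROWS = 4
INCREMENTAL_START_DAY = 8


@dataclass(frozen=True)
class ComparisonResult:
    """Wilcoxon signed-rank comparison of two families on one metric."""

    family_a: str
    family_b: str
    measure: str
    metric: str
    statistic: float
    p_value: float
    n_pairs: int
    degenerate: bool = False


@dataclass(frozen=True)
class IncrementalTrend:
    """OLS of (family metric - mean-model metric) on intercept + study day."""

    measure: str
    family: str
    metric: str
    intercept_estimate: float
    intercept_se: float
    slope_estimate: float
    slope_se: float
    n_days: int


def _model_frames(table: pd.DataFrame):
    for pid, grp in table.groupby("participant_id", sort=True):
        rows = grp[grp["modelable"]].sort_values("day_index")
        yield pid, rows


def loocv_evaluate(
    table: pd.DataFrame,
    measure: str,
    family: str,
    margin: float = MARGIN_DEFAULT,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Leave-one-out evaluation of one family on one measure.

    ``table`` is a :func:`uema.features.build_feature_table` output.  For
    every modelable day of every participant the family is refit from scratch
    — variable selection included — on the participant's other modelable
    days, then predicts the held-out day.

    Returns ``(predictions, performance)``: per-day prediction records
    (observed/predicted z, absolute error, correctness under the inclusive
    margin) and the per-participant summary (cv_mse, pct_correct,
    n_predictions).  Participants with fewer than 4 modelable rows are
    skipped with a warning.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown model family {family!r}")
    pred_rows = []
    perf_rows = []
    feat_cols = list(FEATURE_COLUMNS)
    min_rows = 3 if family == "mean" else MIN_TRAIN_ROWS
    for pid, rows in _model_frames(table):
        if len(rows) < min_rows:
            logger.warning(
                "participant %s: only %d modelable day(s); skipped", pid, len(rows)
            )
            continue
        X = rows[feat_cols]
        y = rows["target_z"].to_numpy(dtype=float)
        days = rows["day_index"].to_numpy()
        errors = np.empty(len(rows))
        preds = np.empty(len(rows))
        for i in range(len(rows)):
            mask = np.ones(len(rows), dtype=bool)
            mask[i] = False
            model = fit_family(family, X.iloc[mask], y[mask])
            preds[i] = float(model.predict(X.iloc[[i]])[0])
            errors[i] = abs(preds[i] - y[i])
        correct = errors <= margin
        for i in range(len(rows)):
            pred_rows.append(
                (
                    pid,
                    int(days[i]),
                    measure,
                    family,
                    float(y[i]),
                    float(preds[i]),
                    float(errors[i]),
                    bool(correct[i]),
                )
            )
        perf_rows.append(
            (
                pid,
                measure,
                family,
                float(np.mean((preds - y) ** 2)),
                100.0 * float(np.mean(correct)),
                int(len(rows)),
            )
        )
    predictions = pd.DataFrame(
        pred_rows,
        columns=[
            "participant_id",
            "day_index",
            "measure",
            "family",
            "observed_z",
            "predicted_z",
            "abs_error",
            "correct",
        ],
    )
    performance = pd.DataFrame(
        perf_rows,
        columns=[
            "participant_id",
            "measure",
            "family",
            "cv_mse",
            "pct_correct",
            "n_predictions",
        ],
    )
    return predictions, performance


def compare_families(
    performance: pd.DataFrame,
    family_a: str,
    family_b: str,
    metric: str,
    measure: str | None = None,
) -> ComparisonResult:
    """Two-sided Wilcoxon signed-rank test on paired per-participant values.

    Zero differences are dropped (classic Wilcoxon convention).  The exact
    null distribution is used for 12 or fewer informative pairs when ranks
    are untied; otherwise the normal approximation with tie correction.
    All-zero differences yield a degenerate result with p = 1.
    """
    if metric not in ("cv_mse", "pct_correct"):
        raise ValueError(f"metric must be 'cv_mse' or 'pct_correct', got {metric!r}")
    sub = performance if measure is None else performance[performance["measure"] == measure]
    a = sub[sub["family"] == family_a].set_index("participant_id")[metric]
    b = sub[sub["family"] == family_b].set_index("participant_id")[metric]
    common = a.index.intersection(b.index)
    if len(common) < 6:
        raise InsufficientDataError(
            f"need >= 6 paired participants, got {len(common)}"
        )
    diff = (a.loc[common] - b.loc[common]).to_numpy(dtype=float)
    nonzero = diff[diff != 0]
    measure_name = measure if measure is not None else str(sub["measure"].iloc[0])
    if len(nonzero) == 0:
        return ComparisonResult(
            family_a, family_b, measure_name, metric,
            statistic=0.0, p_value=1.0, n_pairs=0, degenerate=True,
        )
    ranks_tied = len(np.unique(np.abs(nonzero))) < len(nonzero)
    method = "exact" if (len(nonzero) <= 12 and not ranks_tied) else "approx"
    res = stats.wilcoxon(
        nonzero, zero_method="wilcox", alternative="two-sided", method=method
    )
    return ComparisonResult(
        family_a,
        family_b,
        measure_name,
        metric,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_pairs=int(len(nonzero)),
    )


def incremental_evaluate(
    table: pd.DataFrame,
    measure: str,
    families: tuple[str, ...] = FAMILIES,
    margin: float = MARGIN_DEFAULT,
    start_day: int = INCREMENTAL_START_DAY,
) -> tuple[pd.DataFrame, list[IncrementalTrend]]:
    """Growing-training-window evaluation and relative-performance trends.

    For each day d from ``start_day`` to the end of the study, each family is
    trained on the participant's modelable days strictly before d and
    predicts day d (if that day is modelable).  Metrics are aggregated across
    participants per day; for every non-mean family, the per-day difference
    to the mean model in each metric is regressed on intercept + study day
    (the intercept locates relative performance at the start, the slope its
    change as training data accrue).

    Returns ``(per_day, trends)``: a frame with columns day_index, family,
    mse, pct_correct, n, and a list of :class:`IncrementalTrend`.
    """
    n_days = int(table["day_index"].max())
    feat_cols = list(FEATURE_COLUMNS)
    records: dict[tuple[int, str], list[tuple[float, bool]]] = {}
    for pid, rows in _model_frames(table):
        X = rows[feat_cols]
        y = rows["target_z"].to_numpy(dtype=float)
        days = rows["day_index"].to_numpy()
        for d in range(start_day, n_days + 1):
            (test_i,) = np.where(days == d)
            if len(test_i) == 0:
                continue
            train = days < d
            if train.sum() < MIN_TRAIN_ROWS:
                continue
            i = int(test_i[0])
            for family in families:
                try:
                    model = fit_family(family, X.iloc[train], y[train])
                except InsufficientDataError:
                    continue
                pred = float(model.predict(X.iloc[[i]])[0])
                err = pred - y[i]
                records.setdefault((d, family), []).append(
                    (err**2, abs(err) <= margin)
                )
    per_day_rows = []
    for (d, family), vals in sorted(records.items()):
        sq = np.array([v[0] for v in vals])
        ok = np.array([v[1] for v in vals])
        per_day_rows.append(
            (d, family, float(sq.mean()), 100.0 * float(ok.mean()), len(vals))
        )
    per_day = pd.DataFrame(
        per_day_rows, columns=["day_index", "family", "mse", "pct_correct", "n"]
    )

    trends: list[IncrementalTrend] = []
    if "mean" in families and len(per_day):
        base = per_day[per_day["family"] == "mean"].set_index("day_index")
        for family in families:
            if family == "mean":
                continue
            fam = per_day[per_day["family"] == family].set_index("day_index")
            common = fam.index.intersection(base.index)
            if len(common) < 3:
                continue
            for metric in ("mse", "pct_correct"):
                diff = (fam.loc[common, metric] - base.loc[common, metric]).to_numpy()
                Xd = sm.add_constant(common.to_numpy(dtype=float))
                fit = sm.OLS(diff, Xd).fit()
                trends.append(
                    IncrementalTrend(
                        measure=measure,
                        family=family,
                        metric=metric,
                        intercept_estimate=float(fit.params[0]),
                        intercept_se=float(fit.bse[0]),
                        slope_estimate=float(fit.params[1]),
                        slope_se=float(fit.bse[1]),
                        n_days=int(len(common)),
                    )
                )
    return per_day, trends


def summarize_report(
    performance: pd.DataFrame,
    comparisons: list[ComparisonResult],
    trends: list[IncrementalTrend],
) -> tuple[pd.DataFrame, str]:
    """Across-participant summary tables and a Markdown report.

    Per measure x family: mean cv_mse and mean pct_correct with
    normal-approximation 95% CIs (mean +/- 1.96 SE) across participants.
    Single-participant cells have undefined CIs and are flagged NaN.
    """
    rows = []
    for (measure, family), grp in performance.groupby(["measure", "family"]):
        for metric in ("cv_mse", "pct_correct"):
            vals = grp[metric].to_numpy(dtype=float)
            mean = float(vals.mean())
            if len(vals) > 1:
                se = float(vals.std(ddof=1) / np.sqrt(len(vals)))
                lo, hi = mean - 1.96 * se, mean + 1.96 * se
            else:
                lo = hi = float("nan")
            rows.append((measure, family, metric, mean, lo, hi, len(vals)))
    summary = pd.DataFrame(
        rows,
        columns=["measure", "family", "metric", "mean", "ci_low", "ci_high", "n"],
    )

    lines = ["# Mood-prediction evaluation report", ""]
    lines.append("## Cross-validated performance (across participants)")
    lines.append("")
    lines.append("| measure | family | metric | mean | 95% CI | n |")
    lines.append("|---|---|---|---|---|---|")
    for r in summary.itertuples(index=False):
        ci = "n/a" if np.isnan(r.ci_low) else f"{r.ci_low:.3f} to {r.ci_high:.3f}"
        lines.append(
            f"| {r.measure} | {r.family} | {r.metric} | {r.mean:.3f} | {ci} | {r.n} |"
        )
    if comparisons:
        lines += ["", "## Benchmark comparisons (Wilcoxon signed rank)", ""]
        lines.append("| measure | A | B | metric | W | p | n |")
        lines.append("|---|---|---|---|---|---|---|")
        for c in comparisons:
            p = "1 (degenerate)" if c.degenerate else f"{c.p_value:.4g}"
            lines.append(
                f"| {c.measure} | {c.family_a} | {c.family_b} | {c.metric} "
                f"| {c.statistic:.1f} | {p} | {c.n_pairs} |"
            )
    if trends:
        lines += ["", "## Incremental relative performance vs mean model", ""]
        lines.append(
            "| measure | family | metric | intercept (SE) | study day (SE) | days |"
        )
        lines.append("|---|---|---|---|---|---|")
        for t in trends:
            lines.append(
                f"| {t.measure} | {t.family} | {t.metric} "
                f"| {t.intercept_estimate:.4f} ({t.intercept_se:.4f}) "
                f"| {t.slope_estimate:.4f} ({t.slope_se:.4f}) | {t.n_days} |"
            )
    return summary, "\n".join(lines) + "\n"
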