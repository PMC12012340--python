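"""Screening-metric evaluation and population-level surveillance scoring.

Point estimates for the five screening metrics (PPV, sensitivity,
specificity, NPV, F1) are reported as percentages with percentile
bootstrap confidence intervals.  Resampling is at the patient level with
replacement; because every metric is a function of the four confusion
counts alone, resamples are drawn as multinomial counts over the
(tp, fn, fp, tn) categories — distributionally identical to resampling
patient indices, and fast enough for the default 10 000 resamples.

Surveillance compares actual and predicted incidence *proportions* per
calendar period (year, year-quarter, or year-month of the admission
date) via mean squared error, Pearson r, and R² (the squared Pearson r
of the two series).
"""

from __future__ import annotations

import datetime as dt
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator
from scipy import stats

from .corpus import Corpus, PatientChart

METRIC_NAMES = ["ppv", "sensitivity", "specificity", "npv", "f1"]


class ConfusionCounts(BaseModel):
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @field_validator("tp", "fp", "tn", "fn")
    @classmethod
    def _non_negative(cls, v: int) -> int:
        if v < 0:
            raise ValueError("confusion counts must be non-negative")
        return v

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


class MetricEstimate(BaseModel):
    """One metric on the percentage scale, optionally with a bootstrap CI."""

    name: str
    point: Optional[float] = None
    boot_mean: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    degenerate: bool = False
    n_degenerate_resamples: int = 0


class EvalConfig(BaseModel):
    n_boot: int = 10_000
    ci_level: float = 0.95
    seed: int = 0

    @field_validator("n_boot")
    @classmethod
    def _at_least_one(cls, v: int) -> int:
        if v < 1:
            raise ValueError("n_boot must be >= 1")
        return v


class SurveillanceReport(BaseModel):
    granularity: str
    periods: list[str] = Field(default_factory=list)
    actual: list[float] = Field(default_factory=list)
    predicted: list[float] = Field(default_factory=list)
    mse: Optional[float] = None
    pearson_r: Optional[float] = None
    r_squared: Optional[float] = None
    flags: list[str] = Field(default_factory=list)


def confusion(preds: Sequence[int], golds: Sequence[int]) -> ConfusionCounts:
    """Standard 2×2 tally of aligned binary predictions and gold labels."""
    preds = np.asarray(preds, dtype=int)
    golds = np.asarray(golds, dtype=int)
    if preds.shape != golds.shape:
        raise ValueError(f"length mismatch: {preds.shape} vs {golds.shape}")
    if preds.size == 0:
        raise ValueError("cannot score an empty prediction set")
    if not (np.isin(preds, (0, 1)).all() and np.isin(golds, (0, 1)).all()):
        raise ValueError("labels must be binary")
    return ConfusionCounts(
        tp=int(((preds == 1) & (golds == 1)).sum()),
        fp=int(((preds == 1) & (golds == 0)).sum()),
        tn=int(((preds == 0) & (golds == 0)).sum()),
        fn=int(((preds == 0) & (golds == 1)).sum()),
    )


def _ratio_pct(num: int, den: int) -> tuple[Optional[float], bool]:
    """num/den as a percentage; (0, degenerate) when the denominator is 0."""
    if den == 0:
        return 0.0, True
    return 100.0 * num / den, False


def metrics(c: ConfusionCounts) -> dict[str, MetricEstimate]:
    """The five screening metrics as point estimates (percent scale).

    0/0 denominators yield 0 with the ``degenerate`` flag set.
    """
    if c.total < 1:
        raise ValueError("confusion counts are empty")
    out: dict[str, MetricEstimate] = {}
    pairs = {
        "ppv": (c.tp, c.tp + c.fp),
        "sensitivity": (c.tp, c.tp + c.fn),
        "specificity": (c.tn, c.tn + c.fp),
        "npv": (c.tn, c.tn + c.fn),
    }
    for name, (num, den) in pairs.items():
        val, deg = _ratio_pct(num, den)
        out[name] = MetricEstimate(name=name, point=val, degenerate=deg)
    p, s = out["ppv"].point, out["sensitivity"].point
    if (p + s) == 0:
        out["f1"] = MetricEstimate(name="f1", point=0.0, degenerate=True)
    else:
        out["f1"] = MetricEstimate(name="f1", point=2 * p * s / (p + s))
    return out


def f1_score(ppv: float, sensitivity: float) -> float:
    """Harmonic mean of PPV and sensitivity (percent in, percent out).

    Rounded to two decimals, the reporting convention for metric tables.
    """
    for v in (ppv, sensitivity):
        if not 0 <= v <= 100:
            raise ValueError("inputs must be percentages in [0, 100]")
    if ppv == 0 and sensitivity == 0:
        raise ValueError("F1 undefined when both inputs are zero")
    return round(2 * ppv * sensitivity / (ppv + sensitivity), 2)


def bootstrap_metrics(
    preds: Sequence[int], golds: Sequence[int], config: Optional[EvalConfig] = None
) -> dict[str, MetricEstimate]:
    """Percentile-bootstrap estimates of the five metrics.

    Patients are resampled with replacement ``n_boot`` times at the
    original corpus size; each metric is summarized by the mean over
    non-degenerate resamples and the percentile interval at
    ``ci_level``.  Degenerate (0/0) resamples are skipped and counted;
    if every resample is degenerate the estimate is flagged missing.
    Fully reproducible under ``seed``.
    """
    config = config or EvalConfig()
    c = confusion(preds, golds)
    n = c.total
    probs = np.array([c.tp, c.fn, c.fp, c.tn], dtype=float) / n
    rng = np.random.default_rng(config.seed)
    draws = rng.multinomial(n, probs, size=config.n_boot).astype(float)
    tp, fn, fp, tn = draws[:, 0], draws[:, 1], draws[:, 2], draws[:, 3]

    with np.errstate(divide="ignore", invalid="ignore"):
        series = {
            "ppv": tp / (tp + fp),
            "sensitivity": tp / (tp + fn),
            "specificity": tn / (tn + fp),
            "npv": tn / (tn + fn),
        }
        series["f1"] = (
            2 * series["ppv"] * series["sensitivity"]
            / (series["ppv"] + series["sensitivity"])
        )

    points = metrics(c)
    alpha = (1.0 - config.ci_level) / 2.0
    out: dict[str, MetricEstimate] = {}
    for name in METRIC_NAMES:
        vals = series[name] * 100.0
        valid = np.isfinite(vals)
        n_deg = int(config.n_boot - valid.sum())
        est = MetricEstimate(
            name=name,
            point=points[name].point,
            degenerate=points[name].degenerate,
            n_degenerate_resamples=n_deg,
        )
        if valid.any():
            good = vals[valid]
            est.boot_mean = float(good.mean())
            est.ci_low = float(np.percentile(good, 100 * alpha))
            est.ci_high = float(np.percentile(good, 100 * (1 - alpha)))
        else:
            est.degenerate = True
        out[name] = est
    return out


_GRANULARITIES = ("year", "year_quarter", "year_month")


def _period_key(d: dt.date, granularity: str) -> str:
    if granularity == "year":
        return f"{d.year}"
    if granularity == "year_quarter":
        return f"{d.year}-Q{(d.month - 1) // 3 + 1}"
    if granularity == "year_month":
        return f"{d.year}-{d.month:02d}"
    raise ValueError(f"unknown granularity {granularity!r}; know {_GRANULARITIES}")


def surveillance(
    preds: Sequence[int],
    golds: Sequence[int],
    charts: Sequence[PatientChart],
    granularity: str = "year",
    assign_by: str = "admission",
) -> SurveillanceReport:
    """Score the predicted incidence trend against the actual trend.

    Patients are binned by admission date (or discharge date with
    ``assign_by="discharge"``); per period the actual and predicted
    incidence proportions are positives over admissions.  With fewer
    than two periods the trend metrics are undefined (flagged), as is
    Pearson r when the actual series has zero variance.
    """
    preds = np.asarray(preds, dtype=int)
    golds = np.asarray(golds, dtype=int)
    if not (len(preds) == len(golds) == len(charts)):
        raise ValueError("preds, golds and charts must align")
    if assign_by not in ("admission", "discharge"):
        raise ValueError("assign_by must be 'admission' or 'discharge'")
    dates = [
        c.admission_date if assign_by == "admission" else c.discharge_date
        for c in charts
    ]
    if any(d is None for d in dates):
        raise ValueError("every scored patient needs an assignment date")
    keys = [_period_key(d, granularity) for d in dates]
    df = pd.DataFrame({"period": keys, "actual": golds, "predicted": preds})
    grouped = df.groupby("period", sort=True).mean()

    report = SurveillanceReport(
        granularity=granularity,
        periods=list(grouped.index),
        actual=[float(x) for x in grouped["actual"]],
        predicted=[float(x) for x in grouped["predicted"]],
    )
    a = grouped["actual"].to_numpy()
    p = grouped["predicted"].to_numpy()
    report.mse = float(np.mean((a - p) ** 2))
    if len(grouped) < 2:
        report.flags.append("single_period")
        return report
    if np.std(a) == 0 or np.std(p) == 0:
        report.flags.append("constant_series")
        return report
    r = float(stats.pearsonr(a, p).statistic)
    report.pearson_r = r
    report.r_squared = r * r
    return report


def icd_baseline(
    chart: PatientChart,
    code_prefixes: Sequence[str] = ("I26",),
    require_not_poa: bool = True,
) -> int:
    """Rule baseline over coded diagnoses (Discharge Abstract style).

    Returns 1 iff any diagnosis code matches a configured prefix and —
    when ``require_not_poa`` — was not flagged present-on-admission.
    The default prefix I26 is the ICD-10 pulmonary-embolism family; the
    deployed code list is configurable.
    """
    codes = chart.diagnosis_codes or []
    for code in codes:
        if any(code.code.startswith(p) for p in code_prefixes):
            if require_not_poa and code.present_on_admission:
                continue
            return 1
    return 0


def two_by_two_test(
    table: Sequence[Sequence[float]], method: str = "chi2"
) -> tuple[float, float]:
    """Independence test on a contingency table → (statistic, p).

    ``chi2`` is Pearson's test without continuity correction; ``fisher``
    (2×2 only) returns the odds ratio as the statistic.
    """
    arr = np.asarray(table, dtype=float)
    if method == "chi2":
        res = stats.chi2_contingency(arr, correction=False)
        return float(res.statistic), float(res.pvalue)
    if method == "fisher":
        res = stats.fisher_exact(arr)
        return float(res.statistic), float(res.pvalue)
    raise ValueError("method must be 'chi2' or 'fisher'")


def format_p(p: float) -> str:
    """Cohort-table convention: values below 0.001 print as '<.001'."""
    if p < 0.001:
        return "<.001"
    return f"{p:.3f}".lstrip("0") or "0"


def _banded(value, bands: list[tuple[str, float, float]]) -> Optional[str]:
    if value is None:
        return None
    for name, lo, hi in bands:
        if lo <= value < hi:
            return name
    return None


def summarize_cohort(corpus: Corpus, method: str = "chi2") -> pd.DataFrame:
    """Cohort characteristics by PEAE status, with per-variable tests.

    Variables: age bands (<50, 50-64, 65-74, ≥75), sex, in-hospital
    death, comorbidity-count bands (0, 1, ≥2) and length-of-stay bands
    (1-4, ≥5 days) — each only when the underlying field is populated.
    The test is chi-square without continuity correction by default
    (``method="fisher"`` for 2×2 tables).  P-values below 0.001 render
    as "<.001" in the ``p_display`` column.
    """
    labels = [c.gold_label for c in corpus.charts]
    if any(l is None for l in labels) or not labels:
        raise ValueError("summarize_cohort requires gold labels on every chart")

    inf = float("inf")
    variables: dict[str, list[Optional[str]]] = {}
    variables["age"] = [
        _banded(c.age, [("<50", 0, 50), ("50-64", 50, 65), ("65-74", 65, 75), ("≥75", 75, inf)])
        for c in corpus.charts
    ]
    variables["sex"] = [c.sex for c in corpus.charts]
    variables["death_in_hospital"] = [
        None if c.died_in_hospital is None else ("yes" if c.died_in_hospital else "no")
        for c in corpus.charts
    ]
    variables["n_comorbidities"] = [
        _banded(c.n_comorbidities, [("0", 0, 1), ("1", 1, 2), ("≥2", 2, inf)])
        for c in corpus.charts
    ]
    variables["length_of_stay"] = [
        _banded(max(c.length_of_stay_days, 1), [("1-4 days", 1, 5), ("≥5 days", 5, inf)])
        for c in corpus.charts
    ]

    golds = np.asarray(labels, dtype=int)
    rows = []
    for var, values in variables.items():
        mask = np.array([v is not None for v in values])
        if not mask.any():
            continue
        vals = np.asarray([v if v is not None else "" for v in values])[mask]
        g = golds[mask]
        cats = sorted(set(vals))
        table = np.array(
            [[(vals[g == lab] == cat).sum() for cat in cats] for lab in (1, 0)]
        )
        use = "fisher" if (method == "fisher" and table.shape == (2, 2)) else "chi2"
        stat, p = two_by_two_test(table.T, use)
        n_pos, n_neg = (g == 1).sum(), (g == 0).sum()
        for j, cat in enumerate(cats):
            rows.append(
                {
                    "variable": var,
                    "band": cat,
                    "peae_n": int(table[0, j]),
                    "peae_pct": round(100 * table[0, j] / n_pos, 1) if n_pos else None,
                    "non_peae_n": int(table[1, j]),
                    "non_peae_pct": round(100 * table[1, j] / n_neg, 1) if n_neg else None,
                    "statistic": stat,
                    "p_value": p,
                    "p_display": format_p(p),
                }
            )
    return pd.DataFrame(rows)


def render_metric_table(estimates: dict[str, MetricEstimate]) -> str:
    """Human-readable one-row table in PPV/Sens/Spec/NPV/F1 column order."""
    cols = ["ppv", "sensitivity", "specificity", "npv", "f1"]
    cells = []
    for c in cols:
        e = estimates[c]
        if e.point is None:
            cells.append("--")
        elif e.ci_low is not None:
            cells.append(f"{e.boot_mean:.2f} ({e.ci_low:.2f}-{e.ci_high:.2f})")
        else:
            cells.append(f"{e.point:.2f}")
    header = "PPV\tSensitivity\tSpecificity\tNPV\tF1 score"
    return header + "\n" + "\t".join(cells)
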