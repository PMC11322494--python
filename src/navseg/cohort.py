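"""Cohort-level statistics for residual-tumor assessment studies.

Works on per-patient records (demographics, tumor type/location, volumes, and
boolean residual-tumor calls on post-resection ultrasound and intraoperative
MRI, the reference standard). Provides:

* diagnostic accuracy (confusion table, sensitivity/specificity in percent)
  of the ultrasound residual call against the MRI call, restricted to records
  flagged evaluable;
* median/IQR summaries of agreement metrics (linear-interpolation quartiles,
  the single convention used package-wide);
* Pearson correlation and ordinary least-squares regression of paired volume
  measurements;
* Bland-Altman analysis with quartile limits (first/third quartiles of the
  differences, not 1.96*SD);
* extent of resection, (preop - residual) / preop * 100;
* a demographics summary (mean/SD age, category counts, volume quartiles).

A 24-patient pediatric neurosurgery cohort table is bundled as an example and
test fixture (see :func:`load_example_cohort`); its ultrasound calls reproduce
a 10/0/2/11 TP/FN/FP/TN split on 23 evaluable patients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .agreement import UndefinedMetricError

__all__ = [
    "PatientRecord",
    "ConfusionTable",
    "MetricSummary",
    "CorrelationResult",
    "BlandAltmanResult",
    "records_from_csv",
    "records_to_csv",
    "load_example_cohort",
    "diagnostic_accuracy",
    "summarize_metric",
    "volume_correlation",
    "bland_altman",
    "extent_of_resection",
    "cohort_summary",
]


@dataclass(frozen=True)
class PatientRecord:
    """One cohort row: demographics, tumor, volumes, and residual calls.

    ``residual_on_ius2`` may be None when the post-resection ultrasound was
    not evaluable; such records never enter the diagnostic counts.
    """

    id: str
    sex: str
    age_years: float
    tumor_type: str
    tumor_location: str
    preop_volume_cm3: float
    residual_on_imri: bool
    residual_on_ius2: bool | None = None
    evaluable_ius: bool = True
    evaluable_quantitative: bool = True
    ius1_volume_cm3: float | None = None
    imri_residual_volume_cm3: float | None = None
    ius2_residual_volume_cm3: float | None = None

    def __post_init__(self):
        if self.age_years <= 0:
            raise ValueError("age must be positive")
        for name in (
            "preop_volume_cm3",
            "ius1_volume_cm3",
            "imri_residual_volume_cm3",
            "ius2_residual_volume_cm3",
        ):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")


_BOOL_COLS = ("residual_on_imri", "residual_on_ius2", "evaluable_ius", "evaluable_quantitative")
_OPT_FLOAT_COLS = ("ius1_volume_cm3", "imri_residual_volume_cm3", "ius2_residual_volume_cm3")


def _parse_optional_bool(v) -> bool | None:
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("y", "yes", "true", "1"):
        return True
    if s in ("n", "no", "false", "0"):
        return False
    raise ValueError(f"cannot parse boolean value {v!r}")


def records_from_dataframe(df: pd.DataFrame) -> list[PatientRecord]:
    records = []
    for _, row in df.iterrows():
        kwargs = {
            "id": str(row["id"]),
            "sex": str(row["sex"]),
            "age_years": float(row["age_years"]),
            "tumor_type": str(row["tumor_type"]),
            "tumor_location": str(row["tumor_location"]),
            "preop_volume_cm3": float(row["preop_volume_cm3"]),
        }
        for col in _BOOL_COLS:
            val = _parse_optional_bool(row.get(col))
            if col == "residual_on_imri" and val is None:
                raise ValueError(f"record {row['id']}: residual_on_imri is required")
            if col in ("evaluable_ius", "evaluable_quantitative") and val is None:
                val = True
            kwargs[col] = val
        for col in _OPT_FLOAT_COLS:
            v = row.get(col)
            kwargs[col] = None if v is None or pd.isna(v) else float(v)
        records.append(PatientRecord(**kwargs))
    return records


def records_to_dataframe(records: Iterable[PatientRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


def records_from_csv(path) -> list[PatientRecord]:
    return records_from_dataframe(pd.read_csv(path))


def records_to_csv(records: Iterable[PatientRecord], path) -> None:
    records_to_dataframe(records).to_csv(path, index=False)


def load_example_cohort() -> list[PatientRecord]:
    """Bundled 24-patient pediatric brain-tumor cohort (example/test fixture)."""
    with resources.files("navseg.data").joinpath("example_cohort.csv").open("r") as fh:
        return records_from_dataframe(pd.read_csv(fh))


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 confusion counts for a binary index test vs reference."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity_pct(self) -> float:
        """TP / (TP + FN) * 100."""
        if self.tp + self.fn == 0:
            raise UndefinedMetricError("sensitivity undefined: no reference positives")
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def specificity_pct(self) -> float:
        """TN / (TN + FP) * 100."""
        if self.tn + self.fp == 0:
            raise UndefinedMetricError("specificity undefined: no reference negatives")
        return 100.0 * self.tn / (self.tn + self.fp)


def diagnostic_accuracy(records: Iterable[PatientRecord]) -> ConfusionTable:
    """Confusion table of the ultrasound residual call vs the MRI reference.

    Only records flagged ``evaluable_ius`` with a known ultrasound call are
    counted. Sensitivity/specificity (percent) are exposed on the returned
    table; each raises :class:`UndefinedMetricError` only if its own
    denominator is empty.
    """
    tp = fp = tn = fn = 0
    for r in records:
        if not r.evaluable_ius or r.residual_on_ius2 is None:
            continue
        if r.residual_on_imri:
            if r.residual_on_ius2:
                tp += 1
            else:
                fn += 1
        else:
            if r.residual_on_ius2:
                fp += 1
            else:
                tn += 1
    return ConfusionTable(tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass(frozen=True)
class MetricSummary:
    median: float
    iqr: float
    q1: float
    q3: float
    n: int


def summarize_metric(values: Sequence[float]) -> MetricSummary:
    """Median and IQR (Q3 - Q1, linear-interpolation quartiles)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot summarize an empty list")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return MetricSummary(median=float(med), iqr=float(q3 - q1), q1=float(q1), q3=float(q3), n=values.size)


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r plus OLS line for paired volume measurements.

    ``slope``/``intercept`` regress the reference (MRI) volume on the
    ultrasound volume; ``axis`` records that orientation.
    """

    r: float
    slope: float
    intercept: float
    n: int
    axis: str = "mri_on_ius"


def volume_correlation(pairs: Sequence[tuple[float, float]]) -> CorrelationResult:
    """Pearson correlation and OLS regression of (ultrasound, MRI) volume pairs."""
    from scipy import stats

    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (ius, mri) pairs")
    ius, mri = arr[:, 0], arr[:, 1]
    if np.ptp(ius) == 0 or np.ptp(mri) == 0:
        raise UndefinedMetricError("correlation undefined: zero variance in one axis")
    fit = stats.linregress(ius, mri)
    return CorrelationResult(
        r=float(fit.rvalue), slope=float(fit.slope), intercept=float(fit.intercept), n=arr.shape[0]
    )


@dataclass(frozen=True)
class BlandAltmanResult:
    """Paired-difference agreement with quartile limits.

    Differences are ultrasound minus MRI; limits are the first and third
    quartiles of the differences rather than mean +/- 1.96 SD.
    """

    differences: np.ndarray
    averages: np.ndarray
    median_difference: float
    q1: float
    q3: float
    median_abs_difference: float

    def __post_init__(self):
        if not self.q1 <= self.median_difference <= self.q3:
            raise ValueError("quartiles must bracket the median difference")


def bland_altman(pairs: Sequence[tuple[float, float]]) -> BlandAltmanResult:
    """Bland-Altman analysis of (ultrasound, MRI) pairs with quartile limits."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 (ius, mri) pairs")
    diffs = arr[:, 0] - arr[:, 1]
    avgs = arr.mean(axis=1)
    q1, med, q3 = np.percentile(diffs, [25, 50, 75])
    return BlandAltmanResult(
        differences=diffs,
        averages=avgs,
        median_difference=float(med),
        q1=float(q1),
        q3=float(q3),
        median_abs_difference=float(np.median(np.abs(diffs))),
    )


def extent_of_resection(preop_cm3: float, residual_cm3: float) -> float:
    """Extent of resection in percent: (preop - residual) / preop * 100."""
    if preop_cm3 <= 0:
        raise ValueError("preoperative volume must be positive")
    if residual_cm3 < 0 or residual_cm3 > preop_cm3:
        warnings.warn(
            f"residual volume {residual_cm3} outside [0, preop={preop_cm3}]; "
            "value reported as-is",
            stacklevel=2,
        )
    return (preop_cm3 - residual_cm3) / preop_cm3 * 100.0


def cohort_summary(records: Sequence[PatientRecord], age_sd_divisor: str = "n") -> dict:
    """Demographics report: mean/SD age, category counts, volume quartiles.

    ``age_sd_divisor`` selects the population ('n', default) or sample
    ('n-1') standard deviation of age.
    """
    records = list(records)
    if not records:
        raise ValueError("cohort is empty")
    if age_sd_divisor not in ("n", "n-1"):
        raise ValueError("age_sd_divisor must be 'n' or 'n-1'")
    ages = np.array([r.age_years for r in records], dtype=float)
    ddof = 0 if age_sd_divisor == "n" else 1
    sd = float(ages.std(ddof=ddof)) if ages.size > ddof else 0.0
    volumes = [r.preop_volume_cm3 for r in records]
    vol = summarize_metric(volumes)

    def counts(attr):
        out: dict[str, int] = {}
        for r in records:
            key = getattr(r, attr)
            out[key] = out.get(key, 0) + 1
        return dict(sorted(out.items(), key=lambda kv: (-kv[1], kv[0])))

    return {
        "n": len(records),
        "mean_age_years": float(ages.mean()),
        "sd_age_years": sd,
        "sex_counts": counts("sex"),
        "tumor_type_counts": counts("tumor_type"),
        "tumor_location_counts": counts("tumor_location"),
        "median_preop_volume_cm3": vol.median,
        "iqr_preop_volume_cm3": vol.iqr,
        "residual_on_imri_count": sum(r.residual_on_imri for r in records),
    }
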