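"""Eligibility, young height, shrinkage and the corrected/excess BMI quantities.

The central construction: a subject's *young height* is the mean of their
height measurements at age <= 40 (smoothed values when the subject could be
smoothed, outlier-flagged points excluded).  The *corrected BMI* at an exam
is current weight over young height squared; the *excess BMI* is current BMI
minus corrected BMI — the BMI inflation attributable to age-related height
loss.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .errors import DomainError, IneligibleSubjectError
from .smoothing import SmoothedSeries, bmi_consistency_filter, smooth_with_rejection

SUMMARY_COLUMNS = [
    "subject_id", "sex", "age", "current_height", "young_height", "shrinkage",
    "weight", "current_bmi", "corrected_bmi", "excess_bmi",
    "height_outlier", "bmi_outlier", "bmi_excluded",
]

QC_COLUMNS = [
    "subject_id", "n_points", "height_smoothed", "n_height_outliers",
    "bmi_smoothed", "n_bmi_outliers", "n_bmi_excluded",
]


def bmi(weight_kg, height_cm):
    """Quetelet index: weight (kg) / height (m)²."""
    weight = np.asarray(weight_kg, dtype=float)
    height = np.asarray(height_cm, dtype=float)
    if np.any(height <= 0):
        raise DomainError("height must be positive")
    if np.any(weight <= 0):
        raise DomainError("weight must be positive")
    out = weight / (height / 100.0) ** 2
    return float(out) if np.isscalar(weight_kg) and np.isscalar(height_cm) else out


def corrected_bmi(weight_kg, young_height_cm):
    """BMI from current weight and young height."""
    return bmi(weight_kg, young_height_cm)


def excess_bmi(current, corrected):
    """Current BMI minus corrected BMI (non-negative under height loss)."""
    return np.asarray(current, dtype=float) - np.asarray(corrected, dtype=float)


def eligibility_filter(exams: pd.DataFrame, age_cutoff: float = 40.0) -> np.ndarray:
    """Subject ids with >= 1 exam at age <= cutoff and >= 1 exam after it."""
    grouped = exams.groupby("subject_id")["age"]
    young = grouped.apply(lambda a: bool((a <= age_cutoff).any()))
    old = grouped.apply(lambda a: bool((a > age_cutoff).any()))
    mask = young & old
    return mask.index[mask].to_numpy()


def young_height(series: SmoothedSeries, age_cutoff: float = 40.0) -> float:
    """Mean height at ages <= cutoff, smoothed values when available and
    outlier-flagged points excluded."""
    values = series.values()
    mask = (series.ages <= age_cutoff) & ~series.outlier_flags
    if not mask.any():
        raise IneligibleSubjectError(
            f"no usable height measurement at age <= {age_cutoff}")
    return float(np.mean(values[mask]))


def shrinkage(young_height_cm, current_height_cm):
    """Height lost since young adulthood (cm); may be slightly negative
    under measurement noise and is reported as-is."""
    return np.asarray(young_height_cm, dtype=float) - np.asarray(current_height_cm, dtype=float)


def summarize_subject(sub: pd.DataFrame, cfg: AnalysisConfig) -> tuple[pd.DataFrame, dict]:
    """Run smoothing + filters for one subject's exams (sorted by age).

    Returns the per-exam summary rows and a QC record.  Exams whose recorded
    BMI fails the consistency filter keep their height-derived columns but
    have NaN current/excess BMI.
    """
    sub = sub.sort_values("age")
    ages = sub["age"].to_numpy(dtype=float)
    heights = sub["height_cm"].to_numpy(dtype=float)
    weights = sub["weight_kg"].to_numpy(dtype=float)
    bmi_rec = sub["bmi"].to_numpy(dtype=float)
    n = ages.size

    hs = smooth_with_rejection(ages, heights, cfg.height_outlier_floor, cfg.lowess_frac)
    current_height = hs.fitted  # equals raw when unsmoothed
    height_for_check = hs.values()
    keep = bmi_consistency_filter(bmi_rec, weights, height_for_check,
                                  cfg.bmi_consistency_cutoff)

    yh = young_height(hs, cfg.young_age_cutoff)
    shr = shrinkage(yh, current_height)

    current = np.full(n, np.nan)
    bmi_flags = np.zeros(n, dtype=bool)
    bmi_smoothed = False
    n_bmi_outliers = 0
    if keep.any():
        bs = smooth_with_rejection(ages[keep], bmi_rec[keep],
                                   cfg.bmi_outlier_floor, cfg.lowess_frac)
        current[keep] = bs.fitted
        bmi_flags[np.flatnonzero(keep)[bs.outlier_flags]] = True
        bmi_smoothed = bs.smoothed
        n_bmi_outliers = int(bs.outlier_flags.sum())

    corrected = corrected_bmi(weights, yh)
    rows = pd.DataFrame({
        "subject_id": sub["subject_id"].iloc[0],
        "sex": sub["sex"].iloc[0],
        "age": ages,
        "current_height": current_height,
        "young_height": yh,
        "shrinkage": shr,
        "weight": weights,
        "current_bmi": current,
        "corrected_bmi": corrected,
        "excess_bmi": current - corrected,
        "height_outlier": hs.outlier_flags,
        "bmi_outlier": bmi_flags,
        "bmi_excluded": ~keep,
    })
    qc = {
        "subject_id": sub["subject_id"].iloc[0],
        "n_points": n,
        "height_smoothed": hs.smoothed,
        "n_height_outliers": int(hs.outlier_flags.sum()),
        "bmi_smoothed": bmi_smoothed,
        "n_bmi_outliers": n_bmi_outliers,
        "n_bmi_excluded": int((~keep).sum()),
    }
    return rows, qc


def summarize_cohort(exams: pd.DataFrame,
                     cfg: AnalysisConfig | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the eligibility filter and per-subject pipeline to a cohort.

    Returns ``(summaries, qc)``: one summary row per eligible subject-exam
    and one QC row per eligible subject.
    """
    cfg = cfg or AnalysisConfig()
    eligible = set(eligibility_filter(exams, cfg.young_age_cutoff))
    summary_frames = []
    qc_rows = []
    for sid, sub in exams.groupby("subject_id", sort=True):
        if sid not in eligible:
            continue
        try:
            rows, qc = summarize_subject(sub, cfg)
        except IneligibleSubjectError:
            continue
        summary_frames.append(rows)
        qc_rows.append(qc)
    if not summary_frames:
        return (pd.DataFrame(columns=SUMMARY_COLUMNS),
                pd.DataFrame(columns=QC_COLUMNS))
    summaries = pd.concat(summary_frames, ignore_index=True)[SUMMARY_COLUMNS]
    qc = pd.DataFrame(qc_rows)[QC_COLUMNS]
    return summaries, qc
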