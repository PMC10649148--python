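"""Synthetic longitudinal cohort generator.

Emulates the measurement structure of a mid-century population cohort
(biennial exams, heights floored to the next lower quarter inch, weights to
the nearest 5 lbs, occasional gross height-recording errors) together with
the biology the analysis targets: adult height constant until an onset age
(default 40), then linear loss at a subject-specific rate; BMI defined on
the subject's *young* height, drifting slowly upward after the onset age;
and glucose / blood-pressure outcomes whose prevalence is elevated in truly
obese subjects by a configured risk ratio.

Every subject enrolls before age 40 and is followed to ``final_age``, so the
entire simulated cohort passes the downstream eligibility rule (at least one
exam at age <= 40 and one after).

Alongside the exam table the generator returns a :class:`TruthTable` of
latent per-subject and per-exam quantities for parameter-recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import SEX_FEMALE, SEX_MALE, SimConfig
from .errors import DomainError

CM_PER_INCH = 2.54
KG_PER_LB = 0.45359237

EXAM_COLUMNS = [
    "subject_id", "sex", "age", "height_cm", "weight_kg", "bmi",
    "glucose_mgdl", "sbp_mmhg", "dbp_mmhg", "med_flag",
]


@dataclass
class TruthTable:
    """Latent ground truth of a simulated cohort.

    ``subjects`` has one row per subject (true young height, shrink rate,
    young BMI); ``exams`` one row per subject-exam (true height, true BMI on
    the young-height scale, true obesity status and the drawn disease
    states).
    """

    subjects: pd.DataFrame
    exams: pd.DataFrame


def measurement_model(height_cm, weight_kg, rounding_enabled: bool = True):
    """Apply the recording conventions: height floored to the next lower
    quarter inch, weight rounded (half-up) to the nearest 5 lbs.

    Accepts scalars or arrays; returns ``(height_recorded, weight_recorded)``
    in cm / kg.  Identity when ``rounding_enabled`` is false.
    """
    h = np.asarray(height_cm, dtype=float)
    w = np.asarray(weight_kg, dtype=float)
    if np.any(h <= 0) or np.any(w <= 0):
        raise DomainError("height and weight must be positive")
    if not rounding_enabled:
        return height_cm, weight_kg
    inches = h / CM_PER_INCH
    h_rec = np.floor(inches / 0.25) * 0.25 * CM_PER_INCH
    pounds = w / KG_PER_LB
    w_rec = np.floor(pounds / 5.0 + 0.5) * 5.0 * KG_PER_LB
    if np.isscalar(height_cm):
        return float(h_rec), float(w_rec)
    return h_rec, w_rec


def inject_outliers(heights, prob: float, magnitude_range: Tuple[float, float],
                    rng: np.random.Generator):
    """Replace each height independently with probability ``prob`` by the
    value shifted up or down by a uniform draw from ``magnitude_range``.

    Returns ``(new_heights, n_replaced)``.  The rng consumption is constant
    in the number of points regardless of how many replacements occur, so
    runs with the same seed stay draw-aligned across configurations.
    """
    if not 0.0 <= prob <= 1.0:
        raise DomainError("outlier probability must lie in [0, 1]")
    h = np.asarray(heights, dtype=float).copy()
    n = h.size
    hit = rng.random(n) < prob
    mags = rng.uniform(magnitude_range[0], magnitude_range[1], n)
    signs = np.where(rng.random(n) < 0.5, -1.0, 1.0)
    h[hit] = h[hit] + signs[hit] * mags[hit]
    return h, int(hit.sum())


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      low: float, high: float, size: int) -> np.ndarray:
    """Inverse-CDF truncated normal with a fixed draw count."""
    u = rng.random(size)
    if sd == 0:
        return np.clip(np.full(size, mean), low, high)
    a = norm.cdf((low - mean) / sd) if np.isfinite(low) else 0.0
    b = norm.cdf((high - mean) / sd) if np.isfinite(high) else 1.0
    return mean + sd * norm.ppf(a + u * (b - a))


def _exam_ages(enroll_age: float, interval: float, final_age: float) -> np.ndarray:
    n_exams = int(np.floor((final_age - enroll_age) / interval)) + 1
    return enroll_age + interval * np.arange(n_exams)


def simulate_cohort(config: SimConfig) -> Tuple[pd.DataFrame, TruthTable]:
    """Simulate a cohort; returns the long-format exam table and the truth.

    Deterministic given ``config`` (including its ``seed``).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    exam_rows = []
    truth_subject_rows = []
    truth_exam_rows = []

    id_width = max(5, len(str(config.n_subjects)))
    for i in range(config.n_subjects):
        sid = f"S{i:0{id_width}d}"
        sex = SEX_FEMALE if rng.random() < config.female_fraction else SEX_MALE
        enroll = rng.uniform(config.enroll_age_min, config.enroll_age_max)
        young_height = rng.normal(config.young_height_mean(sex), config.young_height_sd)
        shrink_rate = float(_truncated_normal(
            rng, config.shrink_rate(sex), config.shrink_rate_sd, 0.0, np.inf, 1)[0])
        bmi_lo, bmi_hi = config.young_bmi_range(sex)
        young_bmi = float(_truncated_normal(
            rng, config.young_bmi_mean(sex), config.young_bmi_sd, bmi_lo, bmi_hi, 1)[0])

        ages = _exam_ages(enroll, config.exam_interval, config.final_age)
        m = ages.size
        years_past = np.clip(ages - config.shrink_onset_age, 0.0, None)
        true_height = young_height - shrink_rate * years_past
        true_bmi = (young_bmi + config.bmi_age_drift * years_past
                    + rng.normal(0.0, config.bmi_noise_sd, m))
        true_weight = true_bmi * (young_height / 100.0) ** 2
        true_obese = true_bmi >= 30.0

        h_noisy = true_height + rng.normal(0.0, config.height_noise_sd, m)
        h_noisy, _ = inject_outliers(h_noisy, config.outlier_prob,
                                     config.outlier_magnitude, rng)
        h_rec, w_rec = measurement_model(h_noisy, true_weight, config.rounding_enabled)
        h_rec = np.asarray(h_rec, dtype=float)
        w_rec = np.asarray(w_rec, dtype=float)
        bmi_rec = w_rec / (h_rec / 100.0) ** 2

        # disease states: one categorical draw per exam keeps the configured
        # prevalence ratio exact for both glycemic states
        rr_exp = true_obese.astype(float)
        p_diab = config.base_prevalence("diab", ages) * config.risk_ratio("diab", sex) ** rr_exp
        p_pre = config.base_prevalence("prediab", ages) * config.risk_ratio("prediab", sex) ** rr_exp
        p_diab = np.clip(p_diab, 0.0, 1.0)
        p_pre = np.clip(p_pre, 0.0, 1.0 - p_diab)
        u = rng.random(m)
        diabetes = u < p_diab
        prediabetes = ~diabetes & (u < p_diab + p_pre)

        p_htn = np.clip(config.base_prevalence("htn", ages)
                        * config.risk_ratio("htn", sex) ** rr_exp, 0.0, 1.0)
        hypertension = rng.random(m) < p_htn
        med_flag = hypertension & (rng.random(m) < config.med_fraction)

        ug = rng.random(m)
        glucose = np.where(diabetes, 200.0 + 100.0 * ug,
                           np.where(prediabetes, 140.0 + 60.0 * ug, 70.0 + 70.0 * ug))
        us, ud = rng.random(m), rng.random(m)
        unmedicated_htn = hypertension & ~med_flag
        sbp = np.where(unmedicated_htn, 140.0 + 50.0 * us,
                       np.where(med_flag, 110.0 + 70.0 * us, 100.0 + 39.0 * us))
        dbp = np.where(unmedicated_htn, 85.0 + 20.0 * ud,
                       np.where(med_flag, 65.0 + 35.0 * ud, 60.0 + 29.0 * ud))

        exam_rows.append(pd.DataFrame({
            "subject_id": sid, "sex": sex, "age": ages,
            "height_cm": h_rec, "weight_kg": w_rec, "bmi": bmi_rec,
            "glucose_mgdl": glucose, "sbp_mmhg": sbp, "dbp_mmhg": dbp,
            "med_flag": med_flag,
        }))
        truth_subject_rows.append({
            "subject_id": sid, "sex": sex,
            "true_young_height": young_height,
            "true_shrink_rate": shrink_rate,
            "true_young_bmi": young_bmi,
        })
        truth_exam_rows.append(pd.DataFrame({
            "subject_id": sid, "age": ages,
            "true_height": true_height, "true_bmi": true_bmi,
            "true_obese": true_obese,
            "prediabetes": prediabetes, "diabetes": diabetes,
            "hypertension": hypertension,
        }))

    exams = pd.concat(exam_rows, ignore_index=True)[EXAM_COLUMNS]
    truth = TruthTable(
        subjects=pd.DataFrame(truth_subject_rows),
        exams=pd.concat(truth_exam_rows, ignore_index=True),
    )
    return exams, truth
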