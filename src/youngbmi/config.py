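"""Configuration objects for the cohort simulator and the analysis pipeline.

``SimConfig`` holds every knob of the synthetic longitudinal cohort generator;
its defaults are the calibrated study conditions used throughout the test
suite and the acceptance analyses.  ``AnalysisConfig`` holds the (few) knobs
of the analysis itself: the LOWESS span, the outlier-rule floors, the BMI
consistency cutoff and the age-bin width.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Tuple

from .errors import ConfigError

SEX_FEMALE = "F"
SEX_MALE = "M"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic longitudinal cohort.

    Heights are cm, weights kg, BMI kg/m², ages years.  Disease prevalence
    in the non-obese stratum rises linearly with age past 40:
    ``base(age) = intercept + slope * (age - 40)``; in the truly obese
    stratum the prevalence is multiplied by the sex-specific risk ratio
    (clamped to [0, 1]).
    """

    n_subjects: int = 1000
    female_fraction: float = 0.5
    enroll_age_min: float = 30.0
    enroll_age_max: float = 38.0
    exam_interval: float = 2.0
    final_age: float = 80.0

    young_height_mean_f: float = 160.5
    young_height_mean_m: float = 174.0
    young_height_sd: float = 6.0

    shrink_onset_age: float = 40.0
    shrink_rate_f: float = 0.12        # cm/year lost after onset; 0.12*40 = 4.8 cm by 80
    shrink_rate_m: float = 0.09        # 0.09*40 = 3.6 cm by 80
    shrink_rate_sd: float = 0.02       # between-subject sd, truncated at 0

    young_bmi_mean_f: float = 25.5
    young_bmi_mean_m: float = 26.0
    young_bmi_sd: float = 3.5
    young_bmi_range_f: Tuple[float, float] = (17.0, 35.0)
    young_bmi_range_m: Tuple[float, float] = (19.0, 35.0)
    bmi_age_drift: float = 0.05        # kg/m² per year past onset
    bmi_noise_sd: float = 0.3          # per-exam within-person BMI noise

    height_noise_sd: float = 0.5       # cm measurement noise per exam
    outlier_prob: float = 0.01         # per-exam probability of a gross height error
    outlier_magnitude: Tuple[float, float] = (2.5, 10.0)  # cm, random sign

    prediab_base_intercept: float = 0.05
    prediab_base_slope: float = 0.004
    rr_prediab_f: float = 2.8
    rr_prediab_m: float = 2.4
    diab_base_intercept: float = 0.01
    diab_base_slope: float = 0.002
    rr_diab_f: float = 3.5
    rr_diab_m: float = 2.8
    htn_base_intercept: float = 0.10
    htn_base_slope: float = 0.008
    rr_htn_f: float = 1.5
    rr_htn_m: float = 1.8
    med_fraction: float = 0.5          # fraction of hypertensive exams coded as medicated

    rounding_enabled: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        numeric = {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if f.name not in ("rounding_enabled", "outlier_magnitude",
                              "young_bmi_range_f", "young_bmi_range_m")
        }
        for name, value in numeric.items():
            if not math.isfinite(float(value)):
                raise ConfigError(f"{name} must be finite, got {value!r}")
        if self.n_subjects <= 0:
            raise ConfigError("n_subjects must be positive")
        for name in ("female_fraction", "med_fraction", "outlier_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        for name in ("young_height_sd", "shrink_rate_sd", "young_bmi_sd",
                     "bmi_noise_sd", "height_noise_sd", "shrink_rate_f",
                     "shrink_rate_m", "exam_interval"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        for name in ("young_height_mean_f", "young_height_mean_m",
                     "young_bmi_mean_f", "young_bmi_mean_m",
                     "rr_prediab_f", "rr_prediab_m", "rr_diab_f", "rr_diab_m",
                     "rr_htn_f", "rr_htn_m"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not self.shrink_onset_age < self.final_age:
            raise ConfigError("shrink_onset_age must be below final_age")
        if not self.enroll_age_min <= self.enroll_age_max:
            raise ConfigError("enroll_age_min must not exceed enroll_age_max")
        lo, hi = self.outlier_magnitude
        if not (0 <= lo <= hi):
            raise ConfigError("outlier_magnitude must be an ordered non-negative range")
        for name in ("young_bmi_range_f", "young_bmi_range_m"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ConfigError(f"{name} must be an increasing range")

    # -- sex-resolved accessors -------------------------------------------
    def young_height_mean(self, sex: str) -> float:
        return self.young_height_mean_f if sex == SEX_FEMALE else self.young_height_mean_m

    def shrink_rate(self, sex: str) -> float:
        return self.shrink_rate_f if sex == SEX_FEMALE else self.shrink_rate_m

    def young_bmi_mean(self, sex: str) -> float:
        return self.young_bmi_mean_f if sex == SEX_FEMALE else self.young_bmi_mean_m

    def young_bmi_range(self, sex: str) -> Tuple[float, float]:
        return self.young_bmi_range_f if sex == SEX_FEMALE else self.young_bmi_range_m

    def risk_ratio(self, disease: str, sex: str) -> float:
        key = f"rr_{disease}_{'f' if sex == SEX_FEMALE else 'm'}"
        return float(getattr(self, key))

    def base_prevalence(self, disease: str, age) -> "float":
        import numpy as np

        intercept = getattr(self, f"{disease}_base_intercept")
        slope = getattr(self, f"{disease}_base_slope")
        return np.clip(intercept + slope * (np.asarray(age, dtype=float) - 40.0), 0.0, 1.0)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("outlier_magnitude", "young_bmi_range_f", "young_bmi_range_m"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("outlier_magnitude", "young_bmi_range_f", "young_bmi_range_m"):
            if key in d and d[key] is not None:
                d[key] = tuple(float(x) for x in d[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown simulation config keys: {sorted(unknown)}")
        try:
            return cls(**d)
        except TypeError as exc:  # pragma: no cover - defensive
            raise ConfigError(str(exc)) from exc


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the analysis pipeline (smoothing, filters, binning)."""

    lowess_frac: float = 0.6           # LOWESS span as a fraction of each subject's points
    height_outlier_floor: float = 1.0  # cm — absolute floor of the height outlier rule
    bmi_outlier_floor: float = 0.2     # kg/m² — floor of the BMI outlier rule
    bmi_consistency_cutoff: float = 5.0  # kg/m² — recorded vs computed BMI exclusion
    young_age_cutoff: float = 40.0     # "young" height = mean of measurements at age <= this
    age_bin_width: float = 5.0         # bins centered on multiples of this width
    overweight_cutoff: float = 25.0
    obese_cutoff: float = 30.0
    trend_reference_age: float = 35.0  # shrinkage trends fit against years past this age

    def __post_init__(self) -> None:
        if not 0.0 < self.lowess_frac <= 1.0:
            raise ConfigError("lowess_frac must lie in (0, 1]")
        for name in ("height_outlier_floor", "bmi_outlier_floor",
                     "bmi_consistency_cutoff", "age_bin_width"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not self.overweight_cutoff < self.obese_cutoff:
            raise ConfigError("overweight_cutoff must be below obese_cutoff")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown analysis config keys: {sorted(unknown)}")
        return cls(**d)


def config_hash(sim: SimConfig | None, analysis: AnalysisConfig) -> str:
    """Stable SHA-256 of the full configuration, for run manifests."""
    payload = {
        "sim": sim.to_dict() if sim is not None else None,
        "analysis": analysis.to_dict(),
    }
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()
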