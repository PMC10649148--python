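"""Disease definitions and obese-vs-non-obese relative risk by age.

Operational definitions: pre-diabetes = non-fasting glucose in (140, 200]
mg/dL, diabetes = glucose > 200 mg/dL (mutually exclusive), hypertension =
antihypertensive medication OR SBP >= 140 mmHg OR DBP >= 90 mmHg.

The relative risk in an age bin is the diseased fraction of the obese
stratum divided by the diseased fraction of the non-obese stratum, with
obesity (BMI >= 30) defined either by the current BMI or by the corrected
(young-height) BMI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError
from .misclassification import one_exam_per_bin

DISEASES = ("prediabetes", "diabetes", "hypertension")
BMI_MODES = ("current", "corrected")


def glycemic_flags(glucose_mgdl):
    """(prediabetes, diabetes) flags from non-fasting glucose."""
    g = np.asarray(glucose_mgdl, dtype=float)
    if np.any(g < 0):
        raise DomainError("glucose must be non-negative")
    diabetes = g > 200.0
    prediabetes = (g > 140.0) & ~diabetes
    if np.isscalar(glucose_mgdl):
        return bool(prediabetes), bool(diabetes)
    return prediabetes, diabetes


def hypertension_flag(sbp_mmhg, dbp_mmhg, med_flag):
    """Medication OR SBP >= 140 OR DBP >= 90."""
    sbp = np.asarray(sbp_mmhg, dtype=float)
    dbp = np.asarray(dbp_mmhg, dtype=float)
    if np.any(sbp < 0) or np.any(dbp < 0):
        raise DomainError("blood pressures must be non-negative")
    out = np.asarray(med_flag, dtype=bool) | (sbp >= 140.0) | (dbp >= 90.0)
    if np.isscalar(sbp_mmhg):
        return bool(out)
    return out


def add_disease_flags(exams: pd.DataFrame) -> pd.DataFrame:
    """Attach prediabetes/diabetes/hypertension columns to an exam table."""
    out = exams.copy()
    pre, dia = glycemic_flags(out["glucose_mgdl"].to_numpy())
    out["prediabetes"] = pre
    out["diabetes"] = dia
    out["hypertension"] = hypertension_flag(out["sbp_mmhg"].to_numpy(),
                                            out["dbp_mmhg"].to_numpy(),
                                            out["med_flag"].to_numpy())
    return out


@dataclass(frozen=True)
class RRResult:
    """A 2x2-table relative risk with its counts.

    ``rr`` is ``None`` when undefined (an empty stratum, or zero events in
    the non-obese stratum); ``reason`` says why.
    """

    n_obese: int
    n_nonobese: int
    events_obese: int
    events_nonobese: int

    @property
    def rr(self):
        if self.n_obese == 0 or self.n_nonobese == 0 or self.events_nonobese == 0:
            return None
        return (self.events_obese / self.n_obese) / (self.events_nonobese / self.n_nonobese)

    @property
    def defined(self) -> bool:
        return self.rr is not None

    @property
    def reason(self):
        if self.n_obese == 0:
            return "no obese records"
        if self.n_nonobese == 0:
            return "no non-obese records"
        if self.events_nonobese == 0:
            return "no events in the non-obese stratum"
        return None

    def log_rr_wald_ci(self, z: float = 1.96):
        """(lo, hi) Wald interval on the RR (plotting aid); None when the
        interval is undefined (any empty cell)."""
        if not self.defined or self.events_obese == 0:
            return None
        se = math.sqrt(1.0 / self.events_obese - 1.0 / self.n_obese
                       + 1.0 / self.events_nonobese - 1.0 / self.n_nonobese)
        log_rr = math.log(self.rr)
        return math.exp(log_rr - z * se), math.exp(log_rr + z * se)


def relative_risk(disease_flags, obese_flags) -> RRResult:
    """RR from parallel boolean arrays of disease state and obesity."""
    disease = np.asarray(disease_flags, dtype=bool)
    obese = np.asarray(obese_flags, dtype=bool)
    if disease.size != obese.size:
        raise DomainError("flag arrays must have equal length")
    return RRResult(
        n_obese=int(obese.sum()),
        n_nonobese=int((~obese).sum()),
        events_obese=int((disease & obese).sum()),
        events_nonobese=int((disease & ~obese).sum()),
    )


def _obesity(df: pd.DataFrame, bmi_mode: str, obese_cutoff: float = 30.0) -> np.ndarray:
    if bmi_mode not in BMI_MODES:
        raise DomainError(f"bmi_mode must be one of {BMI_MODES}, got {bmi_mode!r}")
    col = "current_bmi" if bmi_mode == "current" else "corrected_bmi"
    return df[col].to_numpy(dtype=float) >= obese_cutoff


def rr_by_age(summaries: pd.DataFrame, bmi_mode: str, disease: str,
              sex: str, bin_width: float = 5.0,
              obese_cutoff: float = 30.0) -> pd.DataFrame:
    """RR per age bin for one sex/disease/BMI-definition combination.

    ``summaries`` must carry the BMI columns and the disease flag columns
    (see :func:`add_disease_flags`).  Rows with missing BMI are dropped; a
    subject contributes one exam per bin.
    """
    if disease not in DISEASES:
        raise DomainError(f"disease must be one of {DISEASES}, got {disease!r}")
    df = summaries.dropna(subset=["current_bmi", "corrected_bmi"])
    df = df[df["sex"] == sex]
    df = one_exam_per_bin(df, bin_width)
    records = []
    for age_bin, cell in df.groupby("age_bin"):
        res = relative_risk(cell[disease].to_numpy(),
                            _obesity(cell, bmi_mode, obese_cutoff))
        ci = res.log_rr_wald_ci()
        records.append({
            "sex": sex, "age_bin": age_bin, "disease": disease,
            "bmi_mode": bmi_mode, "rr": res.rr if res.defined else np.nan,
            "rr_lo": ci[0] if ci else np.nan, "rr_hi": ci[1] if ci else np.nan,
            "n_obese": res.n_obese, "n_nonobese": res.n_nonobese,
            "events_obese": res.events_obese,
            "events_nonobese": res.events_nonobese,
        })
    return pd.DataFrame.from_records(records)


def rr_curves(summaries: pd.DataFrame, bin_width: float = 5.0,
              obese_cutoff: float = 30.0) -> pd.DataFrame:
    """Tidy RR table over all sexes, diseases and BMI definitions."""
    frames = []
    for sex in sorted(summaries["sex"].unique()):
        for disease in DISEASES:
            for mode in BMI_MODES:
                frames.append(rr_by_age(summaries, mode, disease, sex,
                                        bin_width, obese_cutoff))
    return pd.concat(frames, ignore_index=True)
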