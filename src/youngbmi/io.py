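"""Cohort CSV reading/writing and YAML configuration files.

The long-format exam CSV has one row per subject-exam with the header
``subject_id,sex,age,height_cm,weight_kg,bmi,glucose_mgdl,sbp_mmhg,
dbp_mmhg,med_flag``.  Validation is strict: missing columns, non-numeric
fields and duplicate (subject, age) pairs are reported with their location.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import AnalysisConfig, SimConfig
from .errors import CohortLoadError
from .simulate import EXAM_COLUMNS, TruthTable

_NUMERIC_COLUMNS = ["age", "height_cm", "weight_kg", "bmi",
                    "glucose_mgdl", "sbp_mmhg", "dbp_mmhg"]
_TRUE_STRINGS = {"true", "1", "1.0", "t", "yes"}
_FALSE_STRINGS = {"false", "0", "0.0", "f", "no"}


def read_cohort(path) -> pd.DataFrame:
    """Load and validate an exam table CSV.

    Raises :class:`CohortLoadError` listing offending columns/rows (line
    numbers refer to the file, header = line 1).
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:
        raise CohortLoadError(f"cannot read {path}: {exc}") from exc
    missing = [c for c in EXAM_COLUMNS if c not in raw.columns]
    if missing:
        raise CohortLoadError(f"{path}: missing required column(s) {missing}")

    df = raw[EXAM_COLUMNS].copy()
    problems = []
    for col in _NUMERIC_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna()
        for idx in df.index[bad][:10]:
            problems.append(f"line {idx + 2}: non-numeric {col}={df.at[idx, col]!r}")
        df[col] = coerced

    med = df["med_flag"].str.strip().str.lower()
    bad_med = ~(med.isin(_TRUE_STRINGS) | med.isin(_FALSE_STRINGS))
    for idx in df.index[bad_med][:10]:
        problems.append(f"line {idx + 2}: non-boolean med_flag={df.at[idx, 'med_flag']!r}")
    df["med_flag"] = med.isin(_TRUE_STRINGS)

    bad_sex = ~df["sex"].isin(["F", "M"])
    for idx in df.index[bad_sex][:10]:
        problems.append(f"line {idx + 2}: sex must be F or M, got {df.at[idx, 'sex']!r}")

    if not problems:
        nonpos = (df["height_cm"] <= 0) | (df["weight_kg"] <= 0)
        for idx in df.index[nonpos][:10]:
            problems.append(f"line {idx + 2}: non-positive height/weight")
        dup = df.duplicated(subset=["subject_id", "age"], keep=False)
        for (sid, age), grp in df[dup].groupby(["subject_id", "age"]):
            lines = [str(i + 2) for i in grp.index]
            problems.append(
                f"duplicate (subject_id={sid}, age={age}) at lines {', '.join(lines)}")
    if problems:
        raise CohortLoadError(f"{path}: " + "; ".join(problems))
    return df.sort_values(["subject_id", "age"]).reset_index(drop=True)


def write_cohort(exams: pd.DataFrame, path) -> None:
    exams.to_csv(path, index=False, float_format="%.6f")


def write_truth(truth: TruthTable, subjects_path, exams_path) -> None:
    truth.subjects.to_csv(subjects_path, index=False, float_format="%.6f")
    truth.exams.to_csv(exams_path, index=False, float_format="%.6f")


def read_truth(subjects_path, exams_path) -> TruthTable:
    subjects = pd.read_csv(subjects_path)
    exams = pd.read_csv(exams_path)
    for col in ("true_obese", "prediabetes", "diabetes", "hypertension"):
        exams[col] = exams[col].astype(bool)
    return TruthTable(subjects=subjects, exams=exams)


def load_config_yaml(path) -> tuple[SimConfig, AnalysisConfig]:
    """Load a flat YAML config; keys split between SimConfig and
    AnalysisConfig, unknown keys rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise CohortLoadError(f"{path}: config must be a mapping")
    sim_keys = set(SimConfig().to_dict())
    ana_keys = set(AnalysisConfig().to_dict())
    sim_d = {k: v for k, v in data.items() if k in sim_keys}
    ana_d = {k: v for k, v in data.items() if k in ana_keys}
    unknown = set(data) - sim_keys - ana_keys
    if unknown:
        raise CohortLoadError(f"{path}: unknown config keys {sorted(unknown)}")
    return SimConfig.from_dict(sim_d), AnalysisConfig.from_dict(ana_d)


def dump_config_yaml(sim: SimConfig, analysis: AnalysisConfig, path) -> None:
    merged = {**sim.to_dict(), **analysis.to_dict()}
    with open(path, "w") as fh:
        yaml.safe_dump(merged, fh, sort_keys=True)
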