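"""BMI category labels and age-resolved misclassification fractions.

A subject-exam is *wrong overweight* when the current BMI sits in
[25, 30) but the corrected BMI is below 25, and *wrong obese* when the
current BMI is >= 30 but the corrected BMI is below 30 — i.e. the category
assignment is an artifact of age-related height loss.

Fractions are reported per sex and 5-year age bin under two denominators:
the whole population in the bin, or only the exams currently in the
category.  Each subject contributes at most one exam per bin (the exam
closest to the bin center).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError

CAT_BELOW = "below"          # underweight/normal, BMI < 25
CAT_OVERWEIGHT = "overweight"  # 25 <= BMI < 30
CAT_OBESE = "obese"          # BMI >= 30


def categorize(bmi_values, overweight_cutoff: float = 25.0,
               obese_cutoff: float = 30.0):
    """Map BMI to {below, overweight, obese}."""
    b = np.asarray(bmi_values, dtype=float)
    if np.any(b[~np.isnan(b)] <= 0):
        raise DomainError("BMI must be positive")
    out = np.select(
        [b >= obese_cutoff, b >= overweight_cutoff],
        [CAT_OBESE, CAT_OVERWEIGHT],
        default=CAT_BELOW,
    )
    if np.isscalar(bmi_values):
        return str(out)
    return out


def label(current_bmi, corrected_bmi, overweight_cutoff: float = 25.0,
          obese_cutoff: float = 30.0) -> pd.DataFrame:
    """Category labels plus the two 'wrong' flags for each exam."""
    cur = np.asarray(current_bmi, dtype=float)
    cor = np.asarray(corrected_bmi, dtype=float)
    cur_cat = categorize(cur, overweight_cutoff, obese_cutoff)
    cor_cat = categorize(cor, overweight_cutoff, obese_cutoff)
    wrong_obese = (cur >= obese_cutoff) & (cor < obese_cutoff)
    wrong_overweight = ((cur >= overweight_cutoff) & (cur < obese_cutoff)
                        & (cor < overweight_cutoff))
    return pd.DataFrame({
        "current_category": cur_cat,
        "corrected_category": cor_cat,
        "wrong_overweight": wrong_overweight,
        "wrong_obese": wrong_obese,
    })


def assign_age_bin(ages, width: float = 5.0) -> np.ndarray:
    """Bin centers at multiples of ``width`` (bin 80 covers [77.5, 82.5))."""
    return width * np.round(np.asarray(ages, dtype=float) / width)


def one_exam_per_bin(df: pd.DataFrame, width: float = 5.0) -> pd.DataFrame:
    """Attach an ``age_bin`` column and keep, per subject and bin, the exam
    closest to the bin center."""
    out = df.copy()
    out["age_bin"] = assign_age_bin(out["age"].to_numpy(), width)
    out["_dist"] = np.abs(out["age"] - out["age_bin"])
    out = (out.sort_values(["subject_id", "age_bin", "_dist", "age"])
              .drop_duplicates(["subject_id", "age_bin"], keep="first")
              .drop(columns="_dist")
              .reset_index(drop=True))
    return out


@dataclass(frozen=True)
class FractionResult:
    """A misclassification fraction with its counts.

    ``fraction`` is ``None`` (undefined, distinct from 0) when the
    denominator is empty.
    """

    n_wrong: int
    n_denominator: int

    @property
    def fraction(self):
        if self.n_denominator == 0:
            return None
        return self.n_wrong / self.n_denominator

    @property
    def defined(self) -> bool:
        return self.n_denominator > 0


def _labelled(summaries: pd.DataFrame, overweight_cutoff: float = 25.0,
              obese_cutoff: float = 30.0) -> pd.DataFrame:
    usable = summaries.dropna(subset=["current_bmi", "corrected_bmi"]).copy()
    lab = label(usable["current_bmi"].to_numpy(),
                usable["corrected_bmi"].to_numpy(),
                overweight_cutoff, obese_cutoff)
    usable = usable.reset_index(drop=True)
    return pd.concat([usable, lab.reset_index(drop=True)], axis=1)


def misclassification_fraction(summaries: pd.DataFrame, sex: str,
                               age_bin: float, category: str,
                               denominator: str = "population",
                               bin_width: float = 5.0) -> FractionResult:
    """Fraction of exams in (sex, age bin) that are 'wrong <category>'.

    ``denominator='population'`` divides by all exams of that sex in the
    bin; ``denominator='category'`` by only those currently in the category.
    """
    if category not in (CAT_OVERWEIGHT, CAT_OBESE):
        raise DomainError(f"category must be overweight or obese, got {category!r}")
    if denominator not in ("population", "category"):
        raise DomainError(f"unknown denominator mode {denominator!r}")
    lab = _labelled(summaries)
    lab = one_exam_per_bin(lab, bin_width)
    cell = lab[(lab["sex"] == sex) & (lab["age_bin"] == age_bin)]
    wrong_col = "wrong_obese" if category == CAT_OBESE else "wrong_overweight"
    n_wrong = int(cell[wrong_col].sum())
    if denominator == "population":
        n_den = len(cell)
    else:
        n_den = int((cell["current_category"] == category).sum())
    return FractionResult(n_wrong=n_wrong, n_denominator=n_den)


def misclassification_curves(summaries: pd.DataFrame,
                             bin_width: float = 5.0) -> pd.DataFrame:
    """Tidy table of misclassification fractions by sex, age bin, category
    and denominator mode (plus an 'either' union row per population)."""
    lab = one_exam_per_bin(_labelled(summaries), bin_width)
    records = []
    for (sex, age_bin), cell in lab.groupby(["sex", "age_bin"]):
        n_pop = len(cell)
        counts = {
            CAT_OVERWEIGHT: int(cell["wrong_overweight"].sum()),
            CAT_OBESE: int(cell["wrong_obese"].sum()),
        }
        in_cat = {
            CAT_OVERWEIGHT: int((cell["current_category"] == CAT_OVERWEIGHT).sum()),
            CAT_OBESE: int((cell["current_category"] == CAT_OBESE).sum()),
        }
        for cat in (CAT_OVERWEIGHT, CAT_OBESE):
            for mode, n_den in (("population", n_pop), ("category", in_cat[cat])):
                frac = counts[cat] / n_den if n_den else np.nan
                records.append({
                    "sex": sex, "age_bin": age_bin, "category": cat,
                    "denominator_mode": mode, "n_wrong": counts[cat],
                    "n_denominator": n_den, "fraction": frac,
                })
        n_either = counts[CAT_OVERWEIGHT] + counts[CAT_OBESE]  # flags are exclusive
        n_classified = in_cat[CAT_OVERWEIGHT] + in_cat[CAT_OBESE]
        for mode, n_den in (("population", n_pop), ("category", n_classified)):
            records.append({
                "sex": sex, "age_bin": age_bin, "category": "either",
                "denominator_mode": mode, "n_wrong": n_either,
                "n_denominator": n_den,
                "fraction": n_either / n_den if n_den else np.nan,
            })
    return pd.DataFrame.from_records(records).sort_values(
        ["sex", "age_bin", "category", "denominator_mode"]).reset_index(drop=True)
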