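"""Population-level trend fits.

Height loss (shrinkage) is described by linear and quadratic ordinary
least-squares fits against years past a reference age (default 35), pooled
over all eligible subject-exams.  Excess BMI is described by a linear fit
against age (and, secondarily, against shrinkage itself).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .errors import FitError


@dataclass(frozen=True)
class TrendFit:
    """Polynomial OLS fit y = c0 + c1*x (+ c2*x²).

    ``coefficients`` are in ascending powers; ``predictor`` names the x
    variable ("years_past_35", "age" or "shrinkage").
    """

    predictor: str
    degree: int
    coefficients: Tuple[float, ...]
    n_points: int
    residual_variance: float
    sex: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.coefficients) != self.degree + 1:
            raise FitError("coefficient count must equal degree + 1")

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for power, c in enumerate(self.coefficients):
            out = out + c * x ** power
        return float(out) if out.ndim == 0 else out

    def to_dict(self) -> dict:
        return {
            "predictor": self.predictor, "degree": self.degree,
            "coefficients": list(self.coefficients),
            "n_points": self.n_points,
            "residual_variance": self.residual_variance,
            "sex": self.sex,
        }


def fit_trend(x, y, degree: int = 1, predictor: str = "years_past_35",
              sex: Optional[str] = None) -> TrendFit:
    """Ordinary least-squares polynomial fit of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise FitError("x and y must have equal length")
    if degree not in (1, 2):
        raise FitError("degree must be 1 or 2")
    if x.size <= degree + 1:
        raise FitError(f"need more than {degree + 1} points, got {x.size}")
    design = np.vander(x, degree + 1, increasing=True)
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < degree + 1:
        raise FitError("rank-deficient design (degenerate x values)")
    resid = y - design @ coef
    dof = x.size - (degree + 1)
    return TrendFit(predictor=predictor, degree=degree,
                    coefficients=tuple(float(c) for c in coef),
                    n_points=int(x.size),
                    residual_variance=float(resid @ resid / dof),
                    sex=sex)


def fit_shrinkage_trend(summaries: pd.DataFrame, sex: str, degree: int = 1,
                        reference_age: float = 35.0) -> TrendFit:
    """Fit shrinkage (cm) vs years past the reference age for one sex."""
    df = summaries[summaries["sex"] == sex]
    x = df["age"].to_numpy(dtype=float) - reference_age
    y = df["shrinkage"].to_numpy(dtype=float)
    return fit_trend(x, y, degree=degree, predictor=f"years_past_{reference_age:g}",
                     sex=sex)


def total_loss_40_80(fit: TrendFit, reference_age: float = 35.0) -> float:
    """Predicted shrinkage at age 80 minus predicted shrinkage at age 40."""
    return float(fit.predict(80.0 - reference_age) - fit.predict(40.0 - reference_age))


def fit_excess_bmi_trend(ages, excess, shrinkage=None,
                         sex: Optional[str] = None):
    """Linear fit of excess BMI vs age; optionally also vs shrinkage.

    Returns ``(fit_vs_age, fit_vs_shrinkage | None)``.  Rows with missing
    excess BMI are dropped.
    """
    ages = np.asarray(ages, dtype=float)
    excess = np.asarray(excess, dtype=float)
    ok = ~np.isnan(excess)
    fit_age = fit_trend(ages[ok], excess[ok], degree=1, predictor="age", sex=sex)
    fit_shr = None
    if shrinkage is not None:
        shr = np.asarray(shrinkage, dtype=float)
        ok2 = ok & ~np.isnan(shr)
        try:
            fit_shr = fit_trend(shr[ok2], excess[ok2], degree=1,
                                predictor="shrinkage", sex=sex)
        except FitError:
            # e.g. a zero-shrinkage cohort: the predictor is degenerate
            fit_shr = None
    return fit_age, fit_shr
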