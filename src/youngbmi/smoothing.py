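"""Per-subject LOWESS trajectory smoothing with outlier rejection.

Height-vs-age (and BMI-vs-age) series are smoothed with locally weighted
linear regression (tricube weights).  Points are then flagged as outliers by
a two-threshold rule — a residual more than six times the median absolute
residual of the subject's own series AND at least an absolute floor (1 cm
for height, 0.2 kg/m² for BMI) — and the regression is recalculated once
without the flagged points, evaluated at every original observation age.

Series with fewer than 4 points cannot be smoothed and are passed through
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .errors import DomainError, TooFewPointsError

MIN_POINTS = 4


@dataclass
class SmoothedSeries:
    """A per-subject series with its fitted values and QC flags.

    ``fitted`` is defined at every observation age (equal to ``raw`` when the
    series was too short to smooth).  ``outlier_flags`` marks points excluded
    from the refit; ``excluded_flags`` is reserved for the downstream BMI
    consistency filter.
    """

    ages: np.ndarray
    raw: np.ndarray
    fitted: np.ndarray
    outlier_flags: np.ndarray
    excluded_flags: np.ndarray = field(default=None)  # type: ignore[assignment]
    smoothed: bool = True

    def __post_init__(self) -> None:
        if self.excluded_flags is None:
            self.excluded_flags = np.zeros(self.ages.size, dtype=bool)
        n = self.ages.size
        if not (self.raw.size == self.fitted.size == self.outlier_flags.size == n):
            raise DomainError("SmoothedSeries arrays must have equal length")
        if not self.smoothed and self.outlier_flags.any():
            raise DomainError("outlier flags may only be set on smoothed series")

    @property
    def n_points(self) -> int:
        return int(self.ages.size)

    def values(self) -> np.ndarray:
        """Fitted values when smoothed, raw values otherwise."""
        return self.fitted if self.smoothed else self.raw


def _validate_series(ages: np.ndarray, values: np.ndarray) -> None:
    if ages.size != values.size:
        raise DomainError("ages and values must have equal length")
    if ages.size == 0:
        raise DomainError("empty series")
    if np.any(np.diff(ages) <= 0):
        raise DomainError("ages must be strictly increasing")


def lowess_fit(ages, values, frac: float = 0.6) -> np.ndarray:
    """Locally weighted linear (tricube) fit evaluated at the observation ages.

    Requires at least 4 points; raises :class:`TooFewPointsError` otherwise
    so the caller can fall back to the raw values.
    """
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    _validate_series(ages, values)
    if not 0.0 < frac <= 1.0:
        raise DomainError("frac must lie in (0, 1]")
    if ages.size < MIN_POINTS:
        raise TooFewPointsError(f"need >= {MIN_POINTS} points, got {ages.size}")
    fitted = _sm_lowess(values, ages, frac=frac, it=0, return_sorted=False)
    return np.asarray(fitted, dtype=float)


def lowess_eval(ages, values, xvals, frac: float = 0.6) -> np.ndarray:
    """LOWESS fit on (ages, values), evaluated at arbitrary ``xvals``."""
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    _validate_series(ages, values)
    if ages.size < MIN_POINTS:
        raise TooFewPointsError(f"need >= {MIN_POINTS} points, got {ages.size}")
    fitted = _sm_lowess(values, ages, frac=frac, it=0,
                        xvals=np.asarray(xvals, dtype=float))
    return np.asarray(fitted, dtype=float)


def reject_outliers(raw, fitted, abs_floor: float) -> np.ndarray:
    """Two-threshold outlier rule.

    Point *i* is flagged iff ``|raw_i - fitted_i| > 6 * median(|raw - fitted|)``
    (strict) and ``|raw_i - fitted_i| >= abs_floor``.
    """
    raw = np.asarray(raw, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if raw.size != fitted.size:
        raise DomainError("raw and fitted must have equal length")
    if abs_floor <= 0:
        raise DomainError("abs_floor must be positive")
    resid = np.abs(raw - fitted)
    med = np.median(resid)
    return (resid > 6.0 * med) & (resid >= abs_floor)


def smooth_with_rejection(ages, values, abs_floor: float,
                          frac: float = 0.6) -> SmoothedSeries:
    """Fit, flag outliers, and refit once on the retained points.

    The refit is evaluated at *all* original ages (flagged points keep a
    fitted value for downstream per-age metrics).  If fewer than 4 points
    would remain after rejection, rejection is abandoned: flags are cleared
    and the first fit is kept.  Series with fewer than 4 points are returned
    unsmoothed (``fitted == raw``).
    """
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    _validate_series(ages, values)
    n = ages.size
    if n < MIN_POINTS:
        return SmoothedSeries(ages=ages, raw=values, fitted=values.copy(),
                              outlier_flags=np.zeros(n, dtype=bool),
                              smoothed=False)
    fit1 = lowess_fit(ages, values, frac=frac)
    flags = reject_outliers(values, fit1, abs_floor)
    if not flags.any():
        return SmoothedSeries(ages=ages, raw=values, fitted=fit1,
                              outlier_flags=flags)
    keep = ~flags
    if keep.sum() < MIN_POINTS:
        return SmoothedSeries(ages=ages, raw=values, fitted=fit1,
                              outlier_flags=np.zeros(n, dtype=bool))
    refit = lowess_eval(ages[keep], values[keep], ages, frac=frac)
    return SmoothedSeries(ages=ages, raw=values, fitted=refit,
                          outlier_flags=flags)


def bmi_consistency_filter(bmi_recorded, weight_kg, height_cm,
                           cutoff: float = 5.0) -> np.ndarray:
    """Keep a BMI record iff it agrees with weight/height² to within ``cutoff``.

    ``height_cm`` should be the smoothed height when available.  Returns a
    boolean keep mask (vectorized).
    """
    bmi_recorded = np.asarray(bmi_recorded, dtype=float)
    weight = np.asarray(weight_kg, dtype=float)
    height = np.asarray(height_cm, dtype=float)
    if np.any(weight <= 0) or np.any(height <= 0) or np.any(bmi_recorded <= 0):
        raise DomainError("BMI consistency filter requires positive inputs")
    computed = weight / (height / 100.0) ** 2
    return np.abs(bmi_recorded - computed) < cutoff
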