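"""Single-descriptor linear QSAR: log LC50 regressed on log KOW.

The baseline-toxicity (narcosis) model is an ordinary least-squares line
``log LC50 = intercept + slope * log KOW``. Fit quality is summarised by
the coefficient of determination R² and by SDEP, the standard deviation
of the errors of prediction (root-mean-square residual, population
denominator).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm

from .exceptions import (
    DegenerateDesignError,
    InsufficientDataError,
    InvalidInputError,
    NotFittedError,
)

__all__ = [
    "QSARModel",
    "ImprovementResult",
    "fit_linear_qsar",
    "predict",
    "improvement_percent",
]

#: Fits below this sample size carry a SMALL_SAMPLE warning.
SMALL_SAMPLE_N = 5


@dataclass(frozen=True)
class QSARModel:
    """A fitted 2D-QSAR line with its goodness-of-fit statistics.

    slope      change in log LC50 per unit log KOW (dimensionless)
    intercept  log10 mg/L
    r_squared  coefficient of determination, in [0, 1]
    sdep       standard deviation of errors of prediction, log10 mg/L
    n          number of training records
    residuals  observed - fitted, log10 mg/L (training order)
    """

    slope: float
    intercept: float
    r_squared: float
    sdep: float
    n: int
    residuals: tuple = ()
    x_mean: float = float("nan")
    y_mean: float = float("nan")
    warnings: tuple = ()

    def predict(self, x: float) -> float:
        return predict(self, x)

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "sdep": self.sdep,
            "n": self.n,
            "warnings": list(self.warnings),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, payload: dict) -> "QSARModel":
        return cls(
            slope=float(payload["slope"]),
            intercept=float(payload["intercept"]),
            r_squared=float(payload["r_squared"]),
            sdep=float(payload["sdep"]),
            n=int(payload["n"]),
            warnings=tuple(payload.get("warnings", ())),
        )

    @classmethod
    def from_json(cls, text: str) -> "QSARModel":
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class ImprovementResult:
    """Percentage R² improvement under the two denominator conventions.

    ``pct_initial_denominator`` divides the R² gain by the initial R²
    ("as defined"); ``pct_improved_denominator`` divides by the improved
    R² ("as reported" in the worked comparison this package reproduces).
    """

    r2_initial: float
    r2_improved: float
    pct_initial_denominator: float
    pct_improved_denominator: float

    def to_dict(self) -> dict:
        return {
            "r2_initial": self.r2_initial,
            "r2_improved": self.r2_improved,
            "as_defined_pct": self.pct_initial_denominator,
            "as_reported_pct": self.pct_improved_denominator,
        }


def fit_linear_qsar(x: Sequence[float], y: Sequence[float]) -> QSARModel:
    """Ordinary least squares of y (log LC50) on x (log KOW), with intercept.

    Raises InsufficientDataError for n < 2, DegenerateDesignError for a
    constant descriptor, InvalidInputError for non-finite values or
    mismatched lengths. A zero-variance response yields r_squared = 0
    with a ZERO_VARIANCE_RESPONSE warning rather than an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise InvalidInputError(
            f"x and y must be 1-D sequences of equal length; got {x.shape} and {y.shape}"
        )
    if x.size < 2:
        raise InsufficientDataError(f"need at least 2 records to fit, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InvalidInputError("x and y must be finite")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("descriptor x is constant; slope is undefined")

    result = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = map(float, result.params)
    fitted = intercept + slope * x
    residuals = y - fitted
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))

    warn_codes = []
    if ss_tot <= 0.0:
        warnings.warn(
            "response has zero variance; R^2 defined as 0", stacklevel=2
        )
        warn_codes.append("ZERO_VARIANCE_RESPONSE")
        r_squared = 0.0
    else:
        r_squared = 1.0 - ss_res / ss_tot
    if x.size < SMALL_SAMPLE_N:
        warn_codes.append("SMALL_SAMPLE")

    return QSARModel(
        slope=slope,
        intercept=intercept,
        r_squared=r_squared,
        sdep=float(np.sqrt(np.mean(residuals**2))),
        n=int(x.size),
        residuals=tuple(float(r) for r in residuals),
        x_mean=float(x.mean()),
        y_mean=float(y.mean()),
        warnings=tuple(warn_codes),
    )


def predict(model: QSARModel, x: float) -> float:
    """Evaluate the fitted line at log KOW = x (returns log LC50, mg/L)."""
    if model is None or not isinstance(model, QSARModel):
        raise NotFittedError("predict requires a fitted QSARModel")
    if not (math.isfinite(model.slope) and math.isfinite(model.intercept)):
        raise NotFittedError("model parameters are not finite; fit before predicting")
    if not math.isfinite(float(x)):
        raise InvalidInputError(f"x must be finite, got {x!r}")
    return model.intercept + model.slope * float(x)


def improvement_percent(r2_initial: float, r2_improved: float) -> ImprovementResult:
    """Percentage increase of R² after screening, both conventions.

    The "as defined" figure is (R²_improved - R²_initial) / R²_initial x 100;
    the "as reported" figure divides by R²_improved instead (the convention
    the published worked example is numerically consistent with). Both
    require r2_initial in (0, 1].
    """
    r2_initial = float(r2_initial)
    r2_improved = float(r2_improved)
    if not (0 < r2_initial <= 1):
        raise InvalidInputError(f"r2_initial must be in (0, 1], got {r2_initial}")
    if not (0 < r2_improved <= 1):
        raise InvalidInputError(f"r2_improved must be in (0, 1], got {r2_improved}")
    gain = r2_improved - r2_initial
    return ImprovementResult(
        r2_initial=r2_initial,
        r2_improved=r2_improved,
        pct_initial_denominator=gain / r2_initial * 100.0,
        pct_improved_denominator=gain / r2_improved * 100.0,
    )
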