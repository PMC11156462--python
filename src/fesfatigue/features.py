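"""Fatigue features: windowed RMS curves, min–max normalization, curve fits.

The fatigue feature is the per-window root mean square

    RMS = sqrt((x_1^2 + ... + x_n^2) / n),

computed over non-overlapping windows of ``n`` samples (default 1000, i.e.
1 s at a 1 kHz sampling rate; the hop equals the window length).  Curves are
min–max standardized to [0, 1] to remove between-subject strength
differences, then summarized by a fitted trend — a two-parameter power law
``a * t**b`` for voluntary contractions, a polynomial for FES-evoked
responses.  Fitted values on the curve's time grid form the fatigue index
iRMS.

Fits follow a Model → Results layout: :class:`PowerLawModel` and
:class:`PolynomialTrendModel` expose ``fit()`` returning a
:class:`FittedCurve` results object with coefficients, fit statistics and a
``summary()``.  The functional wrappers :func:`fit_power_curve` and
:func:`fit_polynomial_curve` are shorthands for the same path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial import Polynomial
from scipy import stats

from .core import SignalRecord
from .exceptions import (DegenerateCurveError, DomainError,
                         InsufficientDataError, LengthError, ParameterError)

__all__ = ["RMSCurve", "windowed_rms", "minmax_normalize", "FittedCurve",
           "PowerLawModel", "PolynomialTrendModel", "fit_power_curve",
           "fit_polynomial_curve"]


@dataclass
class RMSCurve:
    """Windowed-RMS fatigue characteristic curve.

    ``times`` are window-center seconds; ``values`` the per-window RMS.
    When ``normalized`` the values span [0, 1] and ``a_min``/``a_max``
    record the pre-normalization extrema.
    """

    times: np.ndarray
    values: np.ndarray
    window_samples: int = 1000
    normalized: bool = False
    a_min: float | None = None
    a_max: float | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ParameterError("times and values must be 1-D and equally long")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ParameterError("times must be strictly increasing")
        if np.any(self.values < 0):
            raise ParameterError("RMS values must be non-negative")

    def __len__(self) -> int:
        return int(self.values.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "rms": self.values})


def windowed_rms(record: SignalRecord, window_samples: int = 1000) -> RMSCurve:
    """Non-overlapping windowed RMS of a signal record.

    The hop equals the window length; a trailing partial window is
    discarded; each window is stamped with its center time.
    """
    if window_samples < 1:
        raise ParameterError(f"window_samples must be >= 1, got {window_samples}")
    n = record.n_samples
    if n < window_samples:
        raise LengthError(
            f"record of {n} samples is shorter than one window of {window_samples}"
        )
    m = n // window_samples
    x = record.samples[: m * window_samples].reshape(m, window_samples)
    values = np.sqrt(np.mean(x * x, axis=1))
    starts = np.arange(m) * window_samples
    times = (starts + window_samples / 2.0) / record.sampling_rate
    return RMSCurve(times=times, values=values, window_samples=window_samples)


def minmax_normalize(curve: RMSCurve) -> RMSCurve:
    """Min–max standardization r' = (r - A_min) / (A_max - A_min).

    Maps the curve onto [0, 1] with both endpoints attained.  Raises
    :class:`DegenerateCurveError` for constant curves (zero denominator).
    """
    if len(curve) < 2:
        raise DegenerateCurveError("need at least 2 values to normalize")
    a_min = float(curve.values.min())
    a_max = float(curve.values.max())
    if a_max <= a_min:
        raise DegenerateCurveError(
            f"curve is constant at {a_min}; min-max normalization undefined"
        )
    values = (curve.values - a_min) / (a_max - a_min)
    return RMSCurve(times=curve.times.copy(), values=values,
                    window_samples=curve.window_samples, normalized=True,
                    a_min=a_min, a_max=a_max)


# --------------------------------------------------------------------------
# curve fitting


@dataclass
class FittedCurve:
    """Results of a fatigue-curve fit.

    ``family`` is ``"power"`` (coefficients ``(a, b)`` of ``a * t**b``) or
    ``"polynomial"`` (power-basis coefficients, ascending degree).
    ``fitted_values`` is the fatigue index iRMS on the curve's time grid.
    """

    family: str
    coefficients: np.ndarray
    times: np.ndarray
    fitted_values: np.ndarray
    r_squared: float
    p_value: float
    degree: int | None = None
    _poly: Polynomial | None = field(default=None, repr=False, compare=False)

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=np.float64)
        if self.family == "power":
            a, b = self.coefficients
            if np.any(t <= 0):
                raise DomainError("power-law prediction requires t > 0")
            return a * t ** b
        return self._poly(t)

    def summary(self) -> str:
        lines = [f"Fatigue curve fit ({self.family})",
                 "-" * 34]
        if self.family == "power":
            a, b = self.coefficients
            lines.append(f"model        iRMS = a * t^b")
            lines.append(f"a            {a:.6g}")
            lines.append(f"b            {b:.6g}")
        else:
            lines.append(f"degree       {self.degree}")
            for i, c in enumerate(self.coefficients):
                lines.append(f"c{i:<12}{c:.6g}")
        lines.append(f"n points     {len(self.times)}")
        lines.append(f"R^2          {self.r_squared:.4f}")
        lines.append(f"P (F-test)   {self.p_value:.3g}")
        return "\n".join(lines)


def _goodness(y: np.ndarray, yhat: np.ndarray, n_params: int) -> tuple[float, float]:
    """Original-scale R^2 (clipped to [0, 1]) and overall F-test P value."""
    n = y.size
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        # constant data: a perfect constant fit gets R^2=1, anything else 0
        return (1.0 if ss_res <= 1e-20 else 0.0), float("nan")
    r2 = 1.0 - ss_res / ss_tot
    k = n_params - 1  # slope-like parameters beyond the intercept analogue
    dof = n - n_params
    if dof <= 0 or k <= 0:
        return float(np.clip(r2, 0.0, 1.0)), float("nan")
    if ss_res <= 0:
        return 1.0, 0.0
    r2c = min(max(r2, 0.0), 1.0)
    f = (r2c / k) / ((1.0 - r2c) / dof) if r2c < 1.0 else np.inf
    p = float(stats.f.sf(f, k, dof))
    return float(np.clip(r2, 0.0, 1.0)), p


class PowerLawModel:
    """Two-parameter power-law trend ``value = a * t**b``.

    Solved in log–log space by ordinary least squares — deterministic and
    closed-form.  Non-positive values (min–max normalization always maps
    one point to exactly zero) are excluded from the log–log regression
    with a warning; flooring them instead would hand a single point
    log(eps) ≈ −36 of leverage and wreck the fit.
    """

    def __init__(self, curve: RMSCurve):
        if len(curve) < 3:
            raise InsufficientDataError("power fit needs at least 3 points")
        if np.any(curve.times <= 0):
            raise DomainError("power fit requires all times > 0")
        self.curve = curve

    def fit(self) -> FittedCurve:
        t = self.curve.times
        y = self.curve.values
        eps = np.finfo(np.float64).eps
        keep = y >= eps
        if not np.all(keep):
            warnings.warn(f"{int((~keep).sum())} non-positive RMS value(s) "
                          "excluded from the log-log regression", stacklevel=2)
            if keep.sum() < 3:
                raise InsufficientDataError(
                    "fewer than 3 positive values remain for the power fit"
                )
            t_fit, y_fit = t[keep], y[keep]
        else:
            t_fit, y_fit = t, y
        lt, ly = np.log(t_fit), np.log(y_fit)
        # closed-form simple linear regression in log-log space
        vt = lt - lt.mean()
        denom = float(np.sum(vt * vt))
        if denom == 0:
            raise DegenerateCurveError("times collapse under log; fit undefined")
        b = float(np.sum(vt * (ly - ly.mean())) / denom)
        loga = float(ly.mean() - b * lt.mean())
        a = float(np.exp(loga))
        yhat = a * t ** b
        r2, p = _goodness(self.curve.values, yhat, n_params=2)
        return FittedCurve(family="power", coefficients=np.array([a, b]),
                           times=t.copy(), fitted_values=yhat,
                           r_squared=r2, p_value=p)


class PolynomialTrendModel:
    """Ordinary least-squares polynomial trend of an RMS curve.

    Default degree 6: the four-stage evoked response has three interior
    critical points, needing degree >= 4; 6 leaves slack for asymmetry.
    Fitting uses a scaled domain internally for conditioning; reported
    coefficients are in the ordinary power basis, ascending degree.
    """

    def __init__(self, curve: RMSCurve, degree: int = 6):
        if degree < 0:
            raise ParameterError(f"degree must be >= 0, got {degree}")
        if len(curve) <= degree + 1:
            raise InsufficientDataError(
                f"polynomial of degree {degree} needs more than {degree + 1} "
                f"points, got {len(curve)}"
            )
        self.curve = curve
        self.degree = degree

    def fit(self) -> FittedCurve:
        t = self.curve.times
        y = self.curve.values
        poly = Polynomial.fit(t, y, deg=self.degree)
        yhat = poly(t)
        r2, p = _goodness(y, yhat, n_params=self.degree + 1)
        coeffs = poly.convert().coef
        return FittedCurve(family="polynomial", coefficients=coeffs,
                           times=t.copy(), fitted_values=yhat,
                           r_squared=r2, p_value=p, degree=self.degree,
                           _poly=poly)


def fit_power_curve(curve: RMSCurve) -> FittedCurve:
    """Fit ``value = a * t**b`` to an RMS curve (log–log least squares)."""
    return PowerLawModel(curve).fit()


def fit_polynomial_curve(curve: RMSCurve, degree: int = 6) -> FittedCurve:
    """Fit an OLS polynomial of the given degree to an RMS curve."""
    return PolynomialTrendModel(curve, degree=degree).fit()
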