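"""Four-stage decomposition of the FES-evoked response and dose–duration fits.

The normalized RMS envelope of the evoked sEMG over a stimulation session is
"M"-shaped and decomposes into four stages:

1. activation — the muscle moves from rest to an active state (rise to the
   first local maximum of the fitted curve);
2. recovery — activity settles back (fall to the following local minimum);
3. fatigue — activity climbs to the session's global maximum as the muscle
   works against the stimulus; the time of that maximum is the *maximum
   stimulation time* t_max, the safe stimulation duration at that current;
4. excessive fatigue — activity decays; continued stimulation is damaging.

Stage boundaries are placed at critical points of the FITTED polynomial
(raw RMS curves are too noisy for extrema placement).  Across currents,
t_max follows an inverse-proportional law t = k / (I - i0) with an optional
rheobase-like offset i0 >= 0; :class:`InverseTimeModel` fits it by nonlinear
least squares with a closed-form i0 = 0 fallback.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .core import StimulationProtocol
from .exceptions import (ConfoundedDesignError, DomainError,
                         InsufficientDataError, ParameterError, ShapeError)
from .features import FittedCurve, RMSCurve

__all__ = ["STAGE_LABELS", "StageSegmentation", "segment_mwave_stages",
           "max_stimulation_time", "RelationshipFit", "InverseTimeModel",
           "fit_current_time_relationship", "AgreementReport",
           "crossvalidate_relationship", "EffectTrend", "EffectReport",
           "parameter_effect_summary", "REFERENCE_PROTOCOL"]

STAGE_LABELS = ("activation", "recovery", "fatigue", "excessive_fatigue")
REFERENCE_PROTOCOL = StimulationProtocol(current_amplitude=12.0,
                                         frequency=24.0, pulse_width=200.0)


@dataclass
class StageSegmentation:
    """Four labelled stage intervals of a fitted FES response curve."""

    start: float
    end: float
    boundaries: tuple[float, float, float]
    t_max: float
    peak_value: float
    labels: tuple[str, str, str, str] = STAGE_LABELS

    def __post_init__(self):
        b1, b2, b3 = self.boundaries
        if not (self.start < b1 < b2 < b3 < self.end):
            raise ShapeError(
                f"boundaries {self.boundaries} must be strictly increasing and "
                f"interior to ({self.start}, {self.end})"
            )
        if not (b2 < self.t_max <= b3):
            raise ShapeError(
                f"t_max={self.t_max} must lie in the third (fatigue) stage "
                f"({b2}, {b3}]"
            )

    @property
    def intervals(self) -> list[tuple[float, float]]:
        b1, b2, b3 = self.boundaries
        return [(self.start, b1), (b1, b2), (b2, b3), (b3, self.end)]

    @property
    def n_stages(self) -> int:
        return len(self.intervals)

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return dict(zip(self.labels, self.intervals))


def _critical_points(fit: FittedCurve, lo: float, hi: float,
                     ) -> list[tuple[float, str]]:
    """Interior critical points of the fitted polynomial, sorted by time.

    Each point is classified "max"/"min" by the sign of the derivative on
    either side (robust to near-zero second derivatives).
    """
    poly = fit._poly
    deriv = poly.deriv()
    roots = deriv.roots()
    real = np.sort(np.unique(np.real(roots[np.abs(np.imag(roots)) < 1e-8])))
    interior = [float(r) for r in real if lo < r < hi]
    points = []
    for r in interior:
        left = max(lo, r - 1e-6 * (hi - lo))
        right = min(hi, r + 1e-6 * (hi - lo))
        dl, dr = float(deriv(left)), float(deriv(right))
        if dl > 0 and dr < 0:
            points.append((r, "max"))
        elif dl < 0 and dr > 0:
            points.append((r, "min"))
        # saddle points (no sign change) are not stage boundaries
    return points


def segment_mwave_stages(fit: FittedCurve, curve: RMSCurve) -> StageSegmentation:
    """Segment a fitted, normalized evoked RMS curve into the four stages.

    Boundaries: the first local maximum of the fitted curve (end of
    activation), the following local minimum (end of recovery), and the
    global maximum (end of the fatigue stage, = t_max).  Ties between
    equal-height maxima break toward the earlier time.  Raises
    :class:`ShapeError`, carrying the critical points found, when the curve
    is not M-shaped.
    """
    if fit.family != "polynomial" or fit._poly is None:
        raise ParameterError("stage segmentation requires a polynomial fit")
    if not curve.normalized:
        raise ParameterError("stage segmentation requires a normalized curve")
    lo, hi = float(curve.times[0]), float(curve.times[-1])
    points = _critical_points(fit, lo, hi)
    if len(points) < 3:
        raise ShapeError(
            f"curve is not M-shaped: only {len(points)} interior critical "
            f"point(s) found", critical_points=points
        )
    maxima = [t for t, kind in points if kind == "max"]
    if not maxima:
        raise ShapeError("curve is not M-shaped: no interior local maximum",
                         critical_points=points)
    b1 = maxima[0]
    minima_after = [t for t, kind in points if kind == "min" and t > b1]
    if not minima_after:
        raise ShapeError("curve is not M-shaped: no local minimum after the "
                         "first maximum", critical_points=points)
    b2 = minima_after[0]
    late_maxima = [t for t in maxima if t > b2]
    if not late_maxima:
        raise ShapeError("curve is not M-shaped: no fatigue-stage maximum "
                         "after the recovery minimum", critical_points=points)
    heights = fit.predict(np.array(late_maxima))
    # earlier time wins ties: argmax returns the first of equal heights
    b3 = float(late_maxima[int(np.argmax(heights))])
    peak = float(fit.predict([b3])[0])
    first_peak = float(fit.predict([b1])[0])
    if peak < first_peak:
        raise ShapeError(
            "curve is not M-shaped: fatigue-stage maximum is below the "
            "activation peak", critical_points=points
        )
    return StageSegmentation(start=lo, end=hi, boundaries=(b1, b2, b3),
                             t_max=b3, peak_value=peak)


def max_stimulation_time(seg: StageSegmentation) -> float:
    """Maximum stimulation time: the stage-3 global-maximum time (seconds)."""
    return seg.t_max


# --------------------------------------------------------------------------
# current -> maximum-stimulation-time relationship


@dataclass
class RelationshipFit:
    """Results of the inverse-proportional current→time fit t = k/(I - i0)."""

    k: float
    i0: float
    currents: np.ndarray
    t_observed: np.ndarray
    residuals: np.ndarray
    r_squared: float
    p_value: float

    def predict(self, currents) -> np.ndarray:
        i = np.asarray(currents, dtype=np.float64)
        if np.any(i <= self.i0):
            raise DomainError(
                f"prediction requires current > i0 = {self.i0:.4g} mA"
            )
        return self.k / (i - self.i0)

    def summary(self) -> str:
        lines = [
            "Inverse-proportional current -> max stimulation time fit",
            "-" * 56,
            "model        t_max = k / (I - i0)",
            f"k            {self.k:.6g} mA*s",
            f"i0           {self.i0:.6g} mA",
            f"n points     {self.currents.size}",
            f"R^2          {self.r_squared:.4f}",
            f"P (F-test)   {self.p_value:.3g}",
        ]
        return "\n".join(lines)


class InverseTimeModel:
    """Fit the dose–duration law t_max = k / (I - i0), i0 >= 0.

    Nonlinear least squares (trust-region, bounded so i0 < min(I)); when it
    fails to converge, falls back to the closed-form one-parameter model
    with i0 = 0, k = sum(t/I) / sum(1/I^2).
    """

    def __init__(self, currents, t_max):
        i = np.asarray(currents, dtype=np.float64)
        t = np.asarray(t_max, dtype=np.float64)
        if i.shape != t.shape or i.ndim != 1:
            raise ParameterError("currents and t_max must be 1-D and equally long")
        if np.unique(i).size < 3:
            raise InsufficientDataError(
                "inverse-proportional fit needs >= 3 distinct currents"
            )
        if np.any(t <= 0):
            raise DomainError("all t_max must be positive")
        if np.any(i <= 0):
            raise DomainError("all currents must be positive")
        self.currents = i
        self.t = t

    @staticmethod
    def _closed_form_k(i: np.ndarray, t: np.ndarray) -> float:
        return float(np.sum(t / i) / np.sum(1.0 / i ** 2))

    def fit(self) -> RelationshipFit:
        i, t = self.currents, self.t
        rho = stats.spearmanr(i, t).statistic
        if not np.isnan(rho) and rho >= 0:
            warnings.warn(
                "t_max does not decrease with current (rank correlation "
                f"{rho:.2f} >= 0); the inverse-proportional model may be "
                "inappropriate", stacklevel=2,
            )
        k0 = self._closed_form_k(i, t)
        i0_hi = float(i.min()) * (1.0 - 1e-9)
        n_params = 2
        try:
            popt, _ = optimize.curve_fit(
                lambda x, k, i0: k / (x - i0), i, t, p0=(k0, 0.0),
                bounds=([0.0, 0.0], [np.inf, i0_hi]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14, maxfev=20000,
            )
            k, i0 = float(popt[0]), float(popt[1])
        except (RuntimeError, optimize.OptimizeWarning):
            k, i0, n_params = k0, 0.0, 1
        pred = k / (i - i0)
        residuals = t - pred
        ss_res = float(np.sum(residuals ** 2))
        ss_tot = float(np.sum((t - t.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        r2 = float(np.clip(r2, 0.0, 1.0))
        dof = i.size - n_params - 1
        if dof > 0 and r2 < 1.0:
            f = (r2 / n_params) / ((1.0 - r2) / dof)
            p = float(stats.f.sf(f, n_params, dof))
        else:
            p = 0.0 if r2 >= 1.0 else float("nan")
        return RelationshipFit(k=k, i0=i0, currents=i, t_observed=t,
                               residuals=residuals, r_squared=r2, p_value=p)


def fit_current_time_relationship(points) -> RelationshipFit:
    """Fit t = k/(I - i0) to (current_mA, t_max_s) pairs."""
    pts = list(points)
    if len(pts) < 3:
        raise InsufficientDataError(
            f"inverse-proportional fit needs >= 3 points, got {len(pts)}"
        )
    currents = [p[0] for p in pts]
    t_max = [p[1] for p in pts]
    return InverseTimeModel(currents, t_max).fit()


@dataclass
class AgreementReport:
    """Agreement between two dose–duration fits over a current grid."""

    currents: np.ndarray
    max_abs_diff_s: float
    mean_abs_diff_s: float
    relative_k_diff: float

    def summary(self) -> str:
        return (
            "Cross-group agreement of current -> t_max fits\n"
            f"currents           {np.array2string(self.currents, precision=3)}\n"
            f"max |dt| (s)       {self.max_abs_diff_s:.4g}\n"
            f"mean |dt| (s)      {self.mean_abs_diff_s:.4g}\n"
            f"relative k diff    {self.relative_k_diff:.4g}"
        )


def crossvalidate_relationship(fit_a: RelationshipFit, fit_b: RelationshipFit,
                               currents) -> AgreementReport:
    """Compare predicted t_max of two fits over shared currents.

    ``relative_k_diff`` is |k_a - k_b| / min(k_a, k_b), so fits whose k
    differ by a factor of 2 report 1.0.
    """
    i = np.asarray(currents, dtype=np.float64)
    lim = max(fit_a.i0, fit_b.i0)
    if np.any(i <= lim):
        raise DomainError(f"all currents must exceed max(i0_a, i0_b) = {lim:.4g} mA")
    diff = np.abs(fit_a.predict(i) - fit_b.predict(i))
    return AgreementReport(
        currents=i,
        max_abs_diff_s=float(diff.max()),
        mean_abs_diff_s=float(diff.mean()),
        relative_k_diff=float(abs(fit_a.k - fit_b.k) / min(fit_a.k, fit_b.k)),
    )


# --------------------------------------------------------------------------
# one-factor protocol effects


@dataclass
class EffectTrend:
    """Monotone-trend summary of t_max against one protocol field."""

    field: str
    n: int
    sign: int | None          # -1, 0, +1; None when undefined
    rho: float | None         # Spearman rank correlation
    p_value: float | None

    @property
    def defined(self) -> bool:
        return self.sign is not None


@dataclass
class EffectReport:
    """Per-field trend of the maximum stimulation time.

    Physiological expectation: raising current or frequency shortens the
    maximum stimulation time (sign −), widening the pulse prolongs it (+).
    """

    trends: dict[str, EffectTrend]

    def signs(self) -> dict[str, int | None]:
        return {f: t.sign for f, t in self.trends.items()}

    def summary(self) -> str:
        lines = ["Protocol-field effects on maximum stimulation time",
                 "-" * 52]
        for f, tr in self.trends.items():
            if tr.defined:
                lines.append(
                    f"{f:<18} n={tr.n:<3} sign={tr.sign:+d} "
                    f"rho={tr.rho:+.3f} P={tr.p_value:.3g}"
                )
            else:
                lines.append(f"{f:<18} n={tr.n:<3} trend undefined")
        return "\n".join(lines)


_FIELDS = ("current_amplitude", "frequency", "pulse_width")


def parameter_effect_summary(trials,
                             reference: StimulationProtocol = REFERENCE_PROTOCOL,
                             ) -> EffectReport:
    """Trend of t_max against each protocol field varied one at a time.

    ``trials`` is an iterable of ``(StimulationProtocol, t_max)``.  Each
    trial must match the reference protocol in all but (at most) one field;
    a trial departing in two or more fields raises
    :class:`ConfoundedDesignError`.  Trials identical to the reference
    anchor every field's comparison group.
    """
    groups: dict[str, list[tuple[float, float]]] = {f: [] for f in _FIELDS}
    for protocol, t_max in trials:
        diffs = [f for f in _FIELDS
                 if getattr(protocol, f) != getattr(reference, f)]
        if len(diffs) > 1:
            raise ConfoundedDesignError(
                f"trial {protocol} varies {diffs} simultaneously relative to "
                f"the reference {reference}"
            )
        if len(diffs) == 1:
            f = diffs[0]
            groups[f].append((getattr(protocol, f), float(t_max)))
        else:  # reference trial anchors all groups
            for f in _FIELDS:
                groups[f].append((getattr(reference, f), float(t_max)))

    trends: dict[str, EffectTrend] = {}
    for f, pts in groups.items():
        values = np.array([v for v, _ in pts])
        times = np.array([t for _, t in pts])
        if np.unique(values).size < 2:
            trends[f] = EffectTrend(field=f, n=len(pts), sign=None,
                                    rho=None, p_value=None)
            continue
        res = stats.spearmanr(values, times)
        rho = float(res.statistic)
        sign = 0 if rho == 0 else int(np.sign(rho))
        trends[f] = EffectTrend(field=f, n=len(pts), sign=sign, rho=rho,
                                p_value=float(res.pvalue))
    return EffectReport(trends=trends)
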