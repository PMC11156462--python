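"""Windowed RMS, min-max normalization, and the power/polynomial fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fesfatigue import (DegenerateCurveError, DomainError,
                        InsufficientDataError, LengthError, RMSCurve,
                        SignalRecord, fit_polynomial_curve, fit_power_curve,
                        minmax_normalize, windowed_rms)

FS = 1000.0


# ---------------------------------------------------------------- RMS

def direct_rms(x, n):
    """Independent oracle: literal evaluation of sqrt(sum(x_i^2)/n) per window."""
    out = []
    for s in range(0, len(x) - n + 1, n):
        w = x[s:s + n]
        out.append(np.sqrt(sum(v * v for v in w) / n))
    return np.array(out)


def test_windowed_rms_matches_hand_values():
    rec = SignalRecord(np.array([3.0, 4.0]), FS)
    curve = windowed_rms(rec, window_samples=2)
    assert np.isclose(curve.values[0], np.sqrt(12.5))
    const = windowed_rms(SignalRecord(np.full(5000, -2.5), FS))
    assert np.allclose(const.values, 2.5)


def test_windowed_rms_matches_direct_oracle(rng):
    x = rng.standard_normal(5500)
    curve = windowed_rms(SignalRecord(x, FS), window_samples=1000)
    assert len(curve) == 5  # trailing partial window discarded
    assert np.allclose(curve.values, direct_rms(x, 1000), rtol=1e-12)
    # window centre times
    assert np.allclose(curve.times, (np.arange(5) * 1000 + 500.0) / FS)


def test_windowed_rms_window_count():
    curve = windowed_rms(SignalRecord(np.ones(2500), FS), window_samples=1000)
    assert len(curve) == 2


def test_windowed_rms_too_short_rejected():
    with pytest.raises(LengthError):
        windowed_rms(SignalRecord(np.ones(999), FS), window_samples=1000)


@settings(deadline=None, max_examples=30)
@given(alpha=st.floats(min_value=-10, max_value=10,
                       allow_nan=False).filter(lambda a: abs(a) > 1e-6),
       seed=st.integers(0, 2 ** 16))
def test_rms_is_scale_equivariant(alpha, seed):
    """windowed_rms(alpha * x) == |alpha| * windowed_rms(x)."""
    x = np.random.default_rng(seed).standard_normal(3000)
    base = windowed_rms(SignalRecord(x, FS)).values
    scaled = windowed_rms(SignalRecord(alpha * x, FS)).values
    assert np.allclose(scaled, np.abs(alpha) * base, rtol=1e-10)


# ---------------------------------------------------------------- normalization

def test_minmax_normalize_hand_values():
    c = RMSCurve(times=np.array([1.0, 2.0, 3.0]),
                 values=np.array([2.0, 4.0, 6.0]))
    out = minmax_normalize(c)
    assert np.allclose(out.values, [0.0, 0.5, 1.0])
    assert out.normalized and out.a_min == 2.0 and out.a_max == 6.0


def test_minmax_normalize_idempotent():
    c = RMSCurve(times=np.arange(1.0, 6.0),
                 values=np.array([0.0, 0.25, 0.5, 0.75, 1.0]))
    out = minmax_normalize(c)
    assert np.allclose(out.values, c.values)


def test_minmax_normalize_constant_curve_rejected():
    c = RMSCurve(times=np.arange(1.0, 4.0), values=np.full(3, 2.0))
    with pytest.raises(DegenerateCurveError):
        minmax_normalize(c)


@settings(deadline=None, max_examples=30)
@given(scale=st.floats(min_value=1e-3, max_value=1e3),
       offset=st.floats(min_value=0, max_value=1e3),
       seed=st.integers(0, 2 ** 16))
def test_normalization_invariant_to_positive_affine_maps(scale, offset, seed):
    vals = np.random.default_rng(seed).uniform(0.0, 5.0, size=20)
    vals[0], vals[1] = 0.0, 5.0  # guarantee spread
    t = np.arange(1.0, 21.0)
    a = minmax_normalize(RMSCurve(times=t, values=vals)).values
    b = minmax_normalize(RMSCurve(times=t, values=scale * vals + offset)).values
    assert np.allclose(a, b, atol=1e-9)


# ---------------------------------------------------------------- power fit

def loglog_oracle(t, y):
    """Closed-form log-log simple linear regression."""
    slope, intercept = np.polyfit(np.log(t), np.log(y), 1)
    return np.exp(intercept), slope


def test_power_fit_exact_recovery():
    t = np.arange(1.0, 61.0)
    fit = fit_power_curve(RMSCurve(times=t, values=2.0 * t ** 0.5))
    a, b = fit.coefficients
    assert abs(a - 2.0) < 1e-6 and abs(b - 0.5) < 1e-6
    assert fit.r_squared > 0.999999


def test_power_fit_constant_limit():
    t = np.arange(1.0, 61.0)
    fit = fit_power_curve(RMSCurve(times=t, values=np.full(60, 5.0)))
    assert abs(fit.coefficients[1]) < 1e-6
    assert abs(fit.coefficients[0] - 5.0) < 1e-6


def test_power_fit_equals_loglog_oracle(rng):
    t = np.arange(1.0, 61.0)
    y = np.abs(t ** 0.7 * (1 + 0.05 * rng.standard_normal(60)))
    fit = fit_power_curve(RMSCurve(times=t, values=y))
    a_o, b_o = loglog_oracle(t, y)
    assert np.allclose(fit.coefficients, [a_o, b_o], rtol=1e-6)


def test_power_fit_recovers_planted_exponent_under_noise():
    """b = 0.8 planted with 5% noise: recovered within +/-0.1 in >=95% of 200 runs."""
    rng = np.random.default_rng(123)
    t = np.arange(1.0, 61.0)
    hits = 0
    for _ in range(200):
        y = np.abs(t ** 0.8 * (1 + 0.05 * rng.standard_normal(60)))
        b = fit_power_curve(RMSCurve(times=t, values=y)).coefficients[1]
        hits += abs(b - 0.8) <= 0.1
    assert hits >= 190


def test_power_fit_excludes_normalized_zero_with_warning():
    t = np.arange(1.0, 61.0)
    norm = minmax_normalize(RMSCurve(times=t, values=t ** 0.6))
    with pytest.warns(UserWarning, match="excluded"):
        fit = fit_power_curve(norm)
    # the affine shift of normalization means the result is only nearly a
    # power law; the fit must still explain nearly all the variance
    assert fit.r_squared > 0.95


def test_power_fit_domain_and_size_errors():
    with pytest.raises(DomainError):
        fit_power_curve(RMSCurve(times=np.array([0.0, 1.0, 2.0]),
                                 values=np.ones(3)))
    with pytest.raises(InsufficientDataError):
        fit_power_curve(RMSCurve(times=np.array([1.0, 2.0]),
                                 values=np.array([1.0, 2.0])))


# ---------------------------------------------------------------- polynomial fit

def test_polynomial_fit_interpolates_own_family(rng):
    t = np.linspace(0.5, 59.5, 60)
    y = 0.1 + 0.05 * t + 0.002 * t ** 2 - 3e-5 * t ** 3
    fit = fit_polynomial_curve(RMSCurve(times=t, values=np.abs(y)), degree=3)
    assert np.max(np.abs(fit.fitted_values - np.abs(y))) < 1e-9
    assert fit.r_squared > 0.999999


def test_polynomial_degree_zero_is_mean(rng):
    t = np.arange(1.0, 11.0)
    y = rng.uniform(0.5, 2.0, 10)
    fit = fit_polynomial_curve(RMSCurve(times=t, values=y), degree=0)
    assert np.allclose(fit.fitted_values, y.mean())


def test_polynomial_underdetermined_rejected():
    t = np.arange(1.0, 8.0)
    with pytest.raises(InsufficientDataError):
        fit_polynomial_curve(RMSCurve(times=t, values=np.ones(7) + 0.1 * t),
                             degree=6)


def test_canonical_mwave_polynomial_fit_quality(canonical_fes_result):
    """Degree-6 iRMS fit of the canonical evoked envelope explains >90% variance."""
    assert canonical_fes_result.fit.r_squared > 0.9
    assert canonical_fes_result.fit.p_value < 0.05
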