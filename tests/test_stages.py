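"""Four-stage segmentation, t_max extraction, and the dose-duration fits."""

import numpy as np
import pytest
from numpy.polynomial import Polynomial

from fesfatigue import (ConfoundedDesignError, DomainError,
                        InsufficientDataError, PlantedGroundTruth, RMSCurve,
                        ShapeError, StimulationProtocol, analyze_fes_trial,
                        crossvalidate_relationship,
                        fit_current_time_relationship, fit_polynomial_curve,
                        generate_cohort, max_stimulation_time,
                        minmax_normalize, parameter_effect_summary,
                        segment_mwave_stages)
from fesfatigue.features import FittedCurve
from fesfatigue.stages import STAGE_LABELS
from fesfatigue.synthetic import StageShape


def grid_scan_critical_points(fit, lo, hi, n=60001):
    """Brute-force oracle: extrema of the fitted polynomial on a fine grid."""
    grid = np.linspace(lo, hi, n)
    y = fit.predict(grid)
    d = np.diff(y)
    out = []
    for i in range(len(d) - 1):
        if d[i] > 0 and d[i + 1] < 0:
            out.append((grid[i + 1], "max"))
        elif d[i] < 0 and d[i + 1] > 0:
            out.append((grid[i + 1], "min"))
    return out


def _envelope_curve(shape, duration=None):
    duration = duration or shape.total_duration
    times = np.arange(int(duration)) + 0.5
    return minmax_normalize(RMSCurve(times=times, values=shape.envelope(times)))


def test_canonical_curve_segments_into_four_labelled_stages(canonical_fes_result):
    seg = canonical_fes_result.segmentation
    assert seg.n_stages == 4
    assert seg.labels == STAGE_LABELS
    b1, b2, b3 = seg.boundaries
    assert seg.start < b1 < b2 < b3 < seg.end
    assert seg.t_max == b3
    assert max_stimulation_time(seg) == seg.t_max


def test_monotone_curve_raises_shape_error():
    t = np.arange(60) + 0.5
    curve = minmax_normalize(RMSCurve(times=t, values=0.1 + 0.01 * t))
    fit = fit_polynomial_curve(curve, degree=6)
    with pytest.raises(ShapeError, match="not M-shaped"):
        segment_mwave_stages(fit, curve)


def test_segmentation_requires_normalized_polynomial_input():
    t = np.arange(60) + 0.5
    raw = RMSCurve(times=t, values=StageShape().envelope(t))
    fit = fit_polynomial_curve(minmax_normalize(raw), degree=6)
    with pytest.raises(Exception, match="normalized"):
        segment_mwave_stages(fit, raw)


def test_boundaries_match_grid_scan_on_planted_fixture():
    """Fixture with critical points planted at 5, 12, 40 s."""
    curve = _envelope_curve(StageShape(durations=(5.0, 7.0, 28.0, 20.0)))
    fit = fit_polynomial_curve(curve, degree=6)
    seg = segment_mwave_stages(fit, curve)
    oracle = grid_scan_critical_points(fit, curve.times[0], curve.times[-1])
    step = (curve.times[-1] - curve.times[0]) / 60000
    kinds = [k for _, k in oracle]
    assert kinds == ["max", "min", "max"]
    for b, (t_o, _) in zip(seg.boundaries, oracle):
        assert abs(b - t_o) <= step
    # the two maxima sit within 1 s of the planted knots
    assert abs(seg.boundaries[0] - 5.0) < 1.0
    assert abs(seg.boundaries[2] - 40.0) < 1.0


def test_boundaries_match_grid_scan_for_random_admissible_polynomials(rng):
    """Root-finding equals the brute-force extrema scan for 50 random M-shaped polynomials."""
    lo, hi = 0.5, 59.5
    checked = 0
    while checked < 50:
        c1, c2, c3 = np.sort(rng.uniform(lo + 2, hi - 2, size=3))
        if c2 - c1 < 3 or c3 - c2 < 3:
            continue
        deriv = -np.polynomial.polynomial.polyfromroots([c1, c2, c3])
        p = Polynomial(deriv).integ()
        t = np.linspace(lo, hi, 80)
        v = p(t)
        if p(c3) <= p(c1):  # global maximum must be the late one
            continue
        curve = minmax_normalize(RMSCurve(times=t, values=v - v.min() + 0.05))
        fit = fit_polynomial_curve(curve, degree=4)
        seg = segment_mwave_stages(fit, curve)
        oracle = grid_scan_critical_points(fit, lo, hi)
        step = (hi - lo) / 60000
        assert len(oracle) == 3
        for b, (t_o, _) in zip(seg.boundaries, oracle):
            assert abs(b - t_o) <= 2 * step
        checked += 1


def test_t_max_is_shift_covariant():
    shape = StageShape()
    base = _envelope_curve(shape)
    shift = 7.0
    shifted = RMSCurve(times=base.times + shift, values=base.values,
                       normalized=True, a_min=base.a_min, a_max=base.a_max)
    seg_a = segment_mwave_stages(fit_polynomial_curve(base, 6), base)
    seg_b = segment_mwave_stages(fit_polynomial_curve(shifted, 6), shifted)
    assert abs((seg_b.t_max - seg_a.t_max) - shift) < 1e-6


# ---------------------------------------------------------------- inverse fit

def test_inverse_fit_noiseless_no_offset():
    i = np.arange(2.0, 16.0)
    fit = fit_current_time_relationship(list(zip(i, 120.0 / i)))
    assert abs(fit.k - 120.0) < 1e-6
    assert abs(fit.i0) < 1e-6
    assert fit.r_squared > 0.999999


def test_inverse_fit_noiseless_with_offset():
    i = np.arange(2.0, 16.0)
    fit = fit_current_time_relationship(list(zip(i, 100.0 / (i - 1.0))))
    assert abs(fit.k - 100.0) < 1e-4
    assert abs(fit.i0 - 1.0) < 1e-4


def test_inverse_fit_prediction_is_strictly_decreasing():
    i = np.arange(2.0, 16.0)
    fit = fit_current_time_relationship(list(zip(i, 120.0 / i)))
    pred = fit.predict(np.linspace(2, 15, 50))
    assert np.all(np.diff(pred) < 0)
    assert fit.k > 0


def test_inverse_fit_insufficient_points_rejected():
    with pytest.raises(InsufficientDataError):
        fit_current_time_relationship([(2.0, 60.0), (4.0, 30.0)])


def test_inverse_fit_warns_on_non_decreasing_trend():
    i = np.arange(2.0, 7.0)
    with pytest.warns(UserWarning, match="rank correlation"):
        fit_current_time_relationship(list(zip(i, 10.0 + i)))


def test_crossvalidation_identity_and_arithmetic():
    i = np.arange(2.0, 16.0)
    fit = fit_current_time_relationship(list(zip(i, 120.0 / i)))
    rep = crossvalidate_relationship(fit, fit, i)
    assert rep.max_abs_diff_s == 0.0
    assert rep.mean_abs_diff_s == 0.0
    assert rep.relative_k_diff == 0.0
    double = fit_current_time_relationship(list(zip(i, 240.0 / i)))
    rep2 = crossvalidate_relationship(fit, double, i)
    assert np.isclose(rep2.relative_k_diff, 1.0, rtol=1e-6)
    with pytest.raises(DomainError):
        crossvalidate_relationship(fit, double, [0.0, 5.0])


def test_split_cohort_fits_agree():
    """Train/test subject groups (10% jitter) predict t_max within 15% of its mean."""
    truth = PlantedGroundTruth(k=120.0, i0=0.0)
    currents = list(range(2, 16))
    cohort = generate_cohort(6, currents, truth, seed=31, jitter=0.10)
    pts = {}
    for trial in cohort.trials:
        t_max = analyze_fes_trial(trial.record).t_max
        pts.setdefault(trial.subject_id, []).append(
            (trial.spec.protocol.current_amplitude, t_max))
    subjects = sorted(pts)
    train = [p for s in subjects[:3] for p in pts[s]]
    test = [p for s in subjects[3:] for p in pts[s]]
    fit_a = fit_current_time_relationship(train)
    fit_b = fit_current_time_relationship(test)
    rep = crossvalidate_relationship(fit_a, fit_b, currents)
    mean_t = np.mean([t for _, t in train + test])
    assert rep.mean_abs_diff_s < 0.15 * mean_t


# ---------------------------------------------------------------- effect report

def test_effect_summary_recovers_planted_signs():
    ref = StimulationProtocol(12.0, 24.0, 200.0)
    truth = PlantedGroundTruth()
    trials = []
    for c in (8.0, 10.0, 12.0, 14.0):
        trials.append((StimulationProtocol(c, 24.0, 200.0), truth.t_max(c)))
    for f in (16.0, 32.0, 40.0):
        trials.append((StimulationProtocol(12.0, f, 200.0),
                       truth.t_max(12.0, frequency=f)))
    for w in (100.0, 300.0, 400.0):
        trials.append((StimulationProtocol(12.0, 24.0, w),
                       truth.t_max(12.0, pulse_width=w)))
    rep = parameter_effect_summary(trials, reference=ref)
    assert rep.signs() == {"current_amplitude": -1, "frequency": -1,
                           "pulse_width": 1}


def test_effect_summary_single_level_is_undefined():
    trials = [(StimulationProtocol(12.0, 24.0, 200.0), 10.0)]
    rep = parameter_effect_summary(trials)
    assert all(t.sign is None for t in rep.trends.values())
    assert "undefined" in rep.summary()


def test_effect_summary_rejects_confounded_trials():
    trials = [(StimulationProtocol(10.0, 30.0, 200.0), 9.0)]
    with pytest.raises(ConfoundedDesignError):
        parameter_effect_summary(trials)
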