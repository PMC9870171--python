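import numpy as np
import pytest

from trawlsel import (
    MotionSimConfig,
    SensorSeries,
    amplitude_ratio,
    detect_extrema,
    load_flume_moving_angles,
    ols_trend,
    periods,
    simulate_depth,
    stable_segments,
    summarize_values,
    total_acceleration,
    trim_haul,
)
from trawlsel.motion import FLUME_TRIM_S, OscillationSummary


def test_total_acceleration_is_euclidean_norm():
    assert total_acceleration(3.0, 4.0, 0.0) == 5.0
    assert total_acceleration(0.0, 0.0, 0.0) == 0.0
    with pytest.warns(RuntimeWarning):
        out = total_acceleration(np.nan, 1.0, 1.0)
    assert np.isnan(out)


def test_gravity_dominated_trace_averages_to_g():
    rng = np.random.default_rng(1)
    g = 9.81
    n = 2000
    jitter = 0.05
    ta = total_acceleration(
        rng.normal(0, jitter, n), rng.normal(0, jitter, n), g + rng.normal(0, jitter, n)
    )
    assert ta.mean() == pytest.approx(g, abs=3 * jitter)


def test_sinusoid_amplitude_and_period_recovery():
    series, truth = simulate_depth(
        MotionSimConfig(amplitude=0.125, period=8.0, duration=200.0)
    )
    summ = detect_extrema(series)
    amps = summ.peak_to_peak_amplitudes_cm
    assert np.allclose(amps, 2 * truth.amplitude * 100.0, atol=1e-9)
    assert np.all(np.abs(periods(summ) - truth.period) <= 1.0)


def test_monotone_ramp_has_no_extrema():
    s = SensorSeries(np.arange(50.0), np.linspace(100, 105, 50))
    summ = detect_extrema(s)
    assert summ.peak_times.size == 0 and summ.valley_times.size == 0


def test_plateau_extremum_at_midpoint_time():
    t = np.arange(12.0)
    v = np.array([0, 1, 2, 3, 3, 3, 2, 1, 0, 1, 2, 3.0])
    summ = detect_extrema(SensorSeries(t, v), min_prominence=0.5)
    assert summ.peak_times.tolist() == [4.0]


def test_flipping_the_trace_swaps_peaks_and_valleys():
    series, _ = simulate_depth(
        MotionSimConfig(amplitude=0.1, period=10.0, duration=120.0, noise_sd=0.01, seed=3)
    )
    up = detect_extrema(series)
    down = detect_extrema(SensorSeries(series.t, -series.values))
    assert np.allclose(up.peak_times, down.valley_times)
    assert np.allclose(up.peak_values, -down.valley_values)


def test_amplitude_ratio_scale_equivariant():
    summ = OscillationSummary(
        peak_times=np.array([4.0, 12.0]),
        peak_values=np.array([300.25, 300.25]),
        valley_times=np.array([8.0]),
        valley_values=np.array([300.0]),
        panel_length_cm=99.6,
    )
    r1 = amplitude_ratio(summ)
    summ2 = OscillationSummary(
        peak_times=summ.peak_times,
        peak_values=2 * summ.peak_values,
        valley_times=summ.valley_times,
        valley_values=2 * summ.valley_values,
        panel_length_cm=2 * 99.6,
    )
    assert np.allclose(amplitude_ratio(summ2), r1)
    assert r1[0] == pytest.approx(25.0 / 99.6)


def test_periods_are_successive_peak_gaps():
    summ = OscillationSummary(
        peak_times=np.array([0.0, 8.0, 16.0]),
        peak_values=np.array([1.0, 1.0, 1.0]),
        valley_times=np.array([4.0, 12.0]),
        valley_values=np.array([0.0, 0.0]),
    )
    assert periods(summ).tolist() == [8.0, 8.0]


def test_trim_haul_drops_first_and_last_minute():
    s = SensorSeries(np.arange(600.0), np.zeros(600))
    trimmed = trim_haul(s)
    assert len(trimmed) == 480
    assert trimmed.t[0] == 60.0 and trimmed.t[-1] == 539.0
    with pytest.warns(RuntimeWarning):
        empty = trim_haul(SensorSeries(np.arange(100.0), np.zeros(100)))
    assert len(empty) == 0
    flume = trim_haul(
        SensorSeries(np.arange(1800.0), np.zeros(1800)), lead_s=FLUME_TRIM_S, tail_s=0.0
    )
    assert flume.t[0] == 300.0 and flume.t[-1] == 1799.0


def test_constant_depth_is_one_segment():
    s = SensorSeries(np.arange(120.0), np.full(120, 300.0))
    segs = stable_segments(s)
    assert len(segs) == 1 and len(segs[0]) == 120


def test_linear_descent_segments_bounded_by_depth_cap():
    # 1 m/min descent: a 0.5 m window can span at most 30 s
    t = np.arange(600.0)
    segs = stable_segments(SensorSeries(t, 300.0 + t / 60.0), min_duration=10.0)
    assert segs
    for seg in segs:
        assert seg.t[-1] - seg.t[0] <= 30.0


def test_three_plateaus_give_three_segments():
    t = np.arange(300.0)
    v = np.concatenate([np.full(100, 300.0), np.full(100, 305.0), np.full(100, 310.0)])
    segs = stable_segments(SensorSeries(t, v), min_duration=30.0)
    assert len(segs) == 3


def test_segments_never_exceed_max_range():
    rng = np.random.default_rng(7)
    for _ in range(20):
        v = 300.0 + np.cumsum(rng.normal(0, 0.1, 400))
        segs = stable_segments(SensorSeries(np.arange(400.0), v), min_duration=20.0)
        for seg in segs:
            assert np.ptp(seg.values) <= 0.5


def test_ols_exact_line_and_oracle():
    x = np.array([1.0, 1.2, 1.4, 1.6, 1.8])
    res = ols_trend(x, 2.0 * x + 19.0)
    assert res.slope == pytest.approx(2.0, abs=1e-12)
    assert res.intercept == pytest.approx(19.0, abs=1e-12)

    rng = np.random.default_rng(2)
    xr, yr = rng.normal(size=40), rng.normal(size=40)
    res = ols_trend(xr, yr)
    # normal-equations oracle
    X = np.column_stack([np.ones_like(xr), xr])
    beta = np.linalg.solve(X.T @ X, X.T @ yr)
    assert res.intercept == pytest.approx(beta[0], abs=1e-10)
    assert res.slope == pytest.approx(beta[1], abs=1e-10)

    with pytest.raises(ValueError):
        ols_trend([1.0, 2.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        ols_trend([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_moving_angle_trend_on_flume_means():
    """OLS on the five per-velocity mean angles: slope 2.05 deg/kt
    (computed by hand from the normal equations on those means)."""
    df = load_flume_moving_angles()
    res = ols_trend(df["flow_velocity_kt"], df["moving_angle_deg"])
    assert res.slope == pytest.approx(2.05, abs=1e-10)
    assert res.intercept == pytest.approx(19.07, abs=1e-10)
    assert res.pvalue < 0.01


def test_summarize_values_reports_sem():
    s = summarize_values([1.0, 2.0, 3.0])
    assert s["mean"] == 2.0
    assert s["sd"] == pytest.approx(1.0)
    assert s["sem"] == pytest.approx(1.0 / np.sqrt(3))
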