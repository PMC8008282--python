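"""Velocity estimation, thresholding, detection, main sequence, summaries."""

import math

import numpy as np
import pytest

from oculoeffort import (
    DetectorConfig,
    GazeValidationError,
    InsufficientDataError,
    Microsaccade,
    compute_velocity,
    detect_microsaccades,
    epoch_summaries,
    estimate_thresholds,
    fit_main_sequence,
)


class TestVelocity:
    def test_constant_position_zero_velocity(self):
        x = np.full(50, 3.0)
        vx, vy = compute_velocity(x, x)
        assert np.allclose(vx[2:-2], 0.0) and np.isnan(vx[:2]).all()

    def test_linear_ramp_is_exact(self):
        # the 5-point estimator reproduces linear motion exactly
        delta = 0.01
        x = np.arange(100) * delta
        vx, _ = compute_velocity(x, np.zeros(100), dt_ms=1.0)
        assert np.allclose(vx[2:-2], delta * 1000.0)

    def test_matches_direct_formula_on_random_trace(self, rng):
        x = rng.normal(0, 0.1, 50)
        y = rng.normal(0, 0.1, 50)
        vx, vy = compute_velocity(x, y, dt_ms=2.0)
        for n in range(2, 48):
            expect = (x[n + 2] + x[n + 1] - x[n - 1] - x[n - 2]) / (6 * 0.002)
            assert vx[n] == pytest.approx(expect, abs=1e-12)
        assert np.isnan(vy[[0, 1, -2, -1]]).all()

    def test_short_series_all_undefined(self):
        vx, vy = compute_velocity(np.zeros(3), np.zeros(3))
        assert np.isnan(vx).all() and len(vx) == 3


class TestThresholds:
    def test_degenerate_equal_velocities_floored(self):
        v = np.full(100, 7.0)
        ex, ey = estimate_thresholds(v, v, lambda_mult=6.0)
        assert ex == pytest.approx(6.0 * 1e-6) and ey == ex

    def test_linearity_in_lambda(self, rng):
        v = rng.normal(0, 10, 1000)
        e1 = estimate_thresholds(v, v, 6.0)
        e2 = estimate_thresholds(v, v, 12.0)
        assert e2[0] == pytest.approx(2 * e1[0])

    def test_median_estimator_consistency(self):
        # Monte-Carlo oracle: median(v^2) - median(v)^2 converges to
        # median(chi2_1) * sigma^2, i.e. the median-based sigma estimate of
        # a Gaussian with sd 10 converges to 0.6745 * 10 (the deliberate
        # robustness discount of the median noise estimator)
        r = np.random.default_rng(42)
        v = r.normal(0, 10, 10_000)
        ex, _ = estimate_thresholds(v, v, 1.0)
        assert ex == pytest.approx(0.6745 * 10, rel=0.05)

    def test_too_few_samples_raise(self):
        with pytest.raises(InsufficientDataError):
            estimate_thresholds(np.ones(5), np.ones(5), 6.0)


def _pulse_trace(n=1200, onset=400, mag=0.3, v_peak=125.0, noise=0.002, seed=0, angle=0.3):
    """Drifting trace with one injected displacement pulse."""
    from oculoeffort.synthetic import _saccade_pulse

    r = np.random.default_rng(seed)
    t = np.arange(n, dtype=float)
    x = np.cumsum(r.normal(0, noise / 10, n)) + r.normal(0, noise, n)
    y = np.cumsum(r.normal(0, noise / 10, n)) + r.normal(0, noise, n)
    tau = t - onset
    s = _saccade_pulse(tau, mag, v_peak)
    s[tau < 0] = 0.0
    x = x + math.cos(angle) * s
    y = y + math.sin(angle) * s
    return t, x, y


def detector_oracle(t, x, y, cfg, thresholds):
    """Literal re-implementation with explicit loops (independent oracle)."""
    n = len(t)
    dt = float(np.median(np.diff(t)))
    vx = [float("nan")] * n
    vy = [float("nan")] * n
    for i in range(2, n - 2):
        vx[i] = (x[i + 2] + x[i + 1] - x[i - 1] - x[i - 2]) / (6 * dt / 1000.0)
        vy[i] = (y[i + 2] + y[i + 1] - y[i - 1] - y[i - 2]) / (6 * dt / 1000.0)
    ex, ey = thresholds
    above = [
        (not math.isnan(vx[i]))
        and (not math.isnan(vy[i]))
        and (vx[i] / ex) ** 2 + (vy[i] / ey) ** 2 > 1
        for i in range(n)
    ]
    runs = []
    i = 0
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            if (j - i + 1) * dt >= cfg.min_dur_ms:
                runs.append([i, j])
            i = j + 1
        else:
            i += 1
    merged = []
    for run in runs:
        if merged and (run[0] - merged[-1][1]) * dt < cfg.merge_gap_ms:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    events = []
    for a, b in merged:
        d = math.hypot(x[b] - x[a], y[b] - y[a])
        if d > cfg.max_magnitude_deg or d <= 0:
            continue
        peak = max(
            math.hypot(vx[i], vy[i])
            for i in range(a, b + 1)
            if not math.isnan(vx[i])
        )
        events.append((t[a], t[b], d, peak))
    return events


class TestDetector:
    CFG = DetectorConfig()

    def test_pure_noise_rarely_triggers(self):
        # false-positive Monte-Carlo: lambda=6 on sub-threshold noise
        n_events = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            x = np.cumsum(r.normal(0, 0.0002, 1200)) + r.normal(0, 0.002, 1200)
            y = np.cumsum(r.normal(0, 0.0002, 1200)) + r.normal(0, 0.002, 1200)
            n_events += bool(detect_microsaccades(np.arange(1200.0), x, y, self.CFG))
        assert n_events <= 1

    def test_injected_pulse_recovered_with_magnitude(self):
        t, x, y = _pulse_trace(mag=0.3)
        events = detect_microsaccades(t, x, y, self.CFG)
        assert len(events) == 1
        assert events[0].magnitude_deg == pytest.approx(0.3, abs=0.05)
        assert abs(events[0].onset_ms - 400) <= 10

    def test_unbounded_lambda_empty(self):
        t, x, y = _pulse_trace()
        cfg = DetectorConfig(lambda_mult=1e6)
        assert detect_microsaccades(t, x, y, cfg) == []

    def test_translation_invariance(self):
        t, x, y = _pulse_trace(seed=3)
        base = detect_microsaccades(t, x, y, self.CFG)
        shifted = detect_microsaccades(t, x + 13.7, y - 5.2, self.CFG)
        assert len(base) == len(shifted) == 1
        assert base[0].onset_ms == shifted[0].onset_ms
        assert base[0].magnitude_deg == pytest.approx(shifted[0].magnitude_deg, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_lambda_monotone_event_shrinkage(self, seed):
        # before merging: event set at larger lambda nests inside smaller
        t, x, y = _pulse_trace(seed=seed, mag=0.4, v_peak=170.0)
        cfg1 = DetectorConfig(lambda_mult=4.0, merge_gap_ms=1e-6, min_dur_ms=3)
        cfg2 = DetectorConfig(lambda_mult=8.0, merge_gap_ms=1e-6, min_dur_ms=3)
        vxy = compute_velocity(x, y)
        thr1 = estimate_thresholds(*vxy, 4.0)
        thr2 = estimate_thresholds(*vxy, 8.0)
        ev1 = detect_microsaccades(t, x, y, cfg1, thresholds=thr1)
        ev2 = detect_microsaccades(t, x, y, cfg2, thresholds=thr2)
        for e2 in ev2:
            assert any(
                e1.onset_ms <= e2.onset_ms and e2.offset_ms <= e1.offset_ms
                for e1 in ev1
            )

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        r = np.random.default_rng(100 + seed)
        n = 1800
        t = np.arange(n, dtype=float)
        x = np.cumsum(r.normal(0, 0.001, n)) + r.normal(0, 0.003, n)
        y = np.cumsum(r.normal(0, 0.001, n)) + r.normal(0, 0.003, n)
        for onset, mag, vp in [(300, 0.2, 90.0), (700, 0.35, 140.0), (1300, 0.5, 200.0)]:
            tt, xx, yy = _pulse_trace(n=n, onset=onset, mag=mag, v_peak=vp,
                                      noise=0.0, seed=seed, angle=seed)
            x += xx
            y += yy
        vx, vy = compute_velocity(x, y)
        thr = estimate_thresholds(vx, vy, 6.0)
        got = detect_microsaccades(t, x, y, self.CFG, thresholds=thr)
        want = detector_oracle(t, x, y, self.CFG, thr)
        assert len(got) == len(want)
        for g, w in zip(got, want):
            assert g.onset_ms == w[0] and g.offset_ms == w[1]
            assert g.magnitude_deg == pytest.approx(w[2], abs=1e-9)
            assert g.peak_velocity_dps == pytest.approx(w[3], abs=1e-9)


class TestMainSequence:
    def test_exact_line_recovered_to_1e9(self, rng):
        m = rng.uniform(0.05, 1.0, 200)
        v = 376.37 * m + 12.91
        events = [
            Microsaccade(i * 100.0, i * 100.0 + 20, mag, vel)
            for i, (mag, vel) in enumerate(zip(m, v))
        ]
        fit = fit_main_sequence(events)
        assert fit.slope == pytest.approx(376.37, abs=1e-9)
        assert fit.intercept == pytest.approx(12.91, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_two_points_r2_is_one(self):
        events = [
            Microsaccade(0.0, 20.0, 0.2, 80.0),
            Microsaccade(100.0, 120.0, 0.5, 200.0),
        ]
        assert fit_main_sequence(events).r_squared == pytest.approx(1.0)

    def test_equal_magnitudes_degenerate(self):
        events = [Microsaccade(i * 50.0, i * 50.0 + 10, 0.3, 100.0 + i) for i in range(5)]
        with pytest.raises(GazeValidationError):
            fit_main_sequence(events)

    def test_noisy_events_recover_generator_slope(self, rng):
        m = rng.lognormal(-1.3, 0.45, 10_000)
        v = 376.37 * m + 12.91 + rng.normal(0, 22, 10_000)
        events = [
            Microsaccade(i * 40.0, i * 40.0 + 15, mag, max(vel, 1.0))
            for i, (mag, vel) in enumerate(zip(m, v))
        ]
        fit = fit_main_sequence(events)
        assert abs(fit.slope - 376.37) / 376.37 < 0.02


class TestEpochSummaries:
    def test_rate_is_count_over_duration(self):
        events = [Microsaccade(o, o + 20, 0.3, 100.0) for o in (100.0, 900.0, 1500.0)]
        (rate, mag), = epoch_summaries(events, [(0.0, 2000.0)])
        assert rate == pytest.approx(1.5)
        assert mag == pytest.approx(0.3)

    def test_empty_epoch_rate_zero_magnitude_missing(self):
        (rate, mag), = epoch_summaries([], [(0.0, 1000.0)])
        assert rate == 0.0 and math.isnan(mag)

    def test_zero_duration_epoch_rejected(self):
        with pytest.raises(GazeValidationError):
            epoch_summaries([], [(100.0, 100.0)])

    def test_counts_conserved_across_epochs(self, rng):
        onsets = rng.uniform(0, 6000, 40)
        events = [Microsaccade(o, o + 10, 0.3, 100.0) for o in onsets]
        epochs = [(0.0, 2000.0), (2000.0, 3500.0), (3500.0, 6000.0)]
        rates = epoch_summaries(events, epochs)
        total = sum(r * (off - on) / 1000.0 for (r, _), (on, off) in zip(rates, epochs))
        inside = sum(1 for o in onsets if 0 <= o < 6000)
        assert round(total) == inside

    def test_usable_time_overrides_duration(self):
        events = [Microsaccade(100.0, 120.0, 0.3, 100.0)]
        (rate, _), = epoch_summaries(events, [(0.0, 2000.0)], usable_ms=[500.0])
        assert rate == pytest.approx(2.0)
        (rate0, mag0), = epoch_summaries(events, [(0.0, 2000.0)], usable_ms=[0.0])
        assert math.isnan(rate0)
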