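"""Blink handling, binocular averaging, unit conversion, smoothing, I-DT."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oculoeffort import (
    CyclopeanSeries,
    GazeRecording,
    PreprocessConfig,
    average_eyes,
    detect_blinks,
    detect_fixations,
    mask_blinks,
    pixels_to_degrees,
    smooth_pupil,
)


def _rec(pl, pr=None, n=None, **overrides):
    pl = np.asarray(pl, dtype=float)
    n = n or len(pl)
    pr = pl.copy() if pr is None else np.asarray(pr, dtype=float)
    base = dict(
        t=np.arange(n, dtype=float),
        xl=np.full(n, 100.0),
        yl=np.full(n, 100.0),
        xr=np.full(n, 100.0),
        yr=np.full(n, 100.0),
        pl=pl,
        pr=pr,
    )
    base.update(overrides)
    return GazeRecording("P", 1, **base)


def _series(x, y, t=None, pupil=None):
    x = np.asarray(x, dtype=float)
    t = np.arange(len(x), dtype=float) if t is None else t
    pupil = np.full(len(x), 4000.0) if pupil is None else pupil
    return CyclopeanSeries(t=t, x_deg=x, y_deg=np.asarray(y, dtype=float), pupil=pupil)


class TestBlinks:
    def test_no_missing_no_blinks(self):
        rec = _rec(np.full(500, 4000.0))
        assert detect_blinks(rec, pad_ms=50) == []

    def test_padding_arithmetic(self):
        p = np.full(400, 4000.0)
        p[100:151] = np.nan
        blinks = detect_blinks(_rec(p), pad_ms=50)
        assert len(blinks) == 1
        assert blinks[0].onset_ms == 50 and blinks[0].offset_ms == 200

    def test_close_runs_merge(self):
        # brute-force oracle: padded intervals [50,200] and [202,352] overlap
        p = np.full(500, 4000.0)
        p[100:151] = np.nan
        p[153:201] = np.nan  # raw runs 2 ms apart
        blinks = detect_blinks(_rec(p), pad_ms=50)
        assert len(blinks) == 1
        assert (blinks[0].onset_ms, blinks[0].offset_ms) == (50, 250)

    def test_mask_empty_list_is_identity(self):
        rec = _rec(np.full(300, 4000.0))
        out = mask_blinks(rec, [])
        assert np.array_equal(out.pl, rec.pl)

    def test_full_span_blink_masks_everything(self):
        p = np.full(300, 4000.0)
        p[0] = np.nan
        p[-1] = np.nan
        rec = _rec(p)
        out = mask_blinks(rec, detect_blinks(rec, pad_ms=300))
        assert np.isnan(out.xl).all() and np.isnan(out.pr).all()

    def test_masked_fraction_matches_summed_length(self):
        p = np.full(1000, 4000.0)
        p[100:200] = np.nan
        p[500:550] = np.nan
        rec = _rec(p)
        blinks = detect_blinks(rec, pad_ms=20)
        out = mask_blinks(rec, blinks)
        expected = sum(
            np.sum((rec.t >= b.onset_ms) & (rec.t <= b.offset_ms)) for b in blinks
        )
        assert np.isnan(out.pl).sum() == expected

    def test_masking_is_idempotent(self):
        p = np.full(600, 4000.0)
        p[200:260] = np.nan
        rec = _rec(p)
        blinks = detect_blinks(rec, pad_ms=40)
        once = mask_blinks(rec, blinks)
        twice = mask_blinks(once, blinks)
        for ch in ("xl", "pl", "yr"):
            assert np.array_equal(
                getattr(once, ch), getattr(twice, ch), equal_nan=True
            )


class TestAverageEyes:
    def test_mean_and_single_eye_fallback(self):
        rec = _rec(
            np.full(5, 4000.0),
            xl=np.array([100.0, np.nan, 100, 100, np.nan]),
            xr=np.array([110.0, 110, np.nan, 110, np.nan]),
        )
        out = average_eyes(rec)
        assert out.x_deg[0] == 105.0
        assert out.x_deg[1] == 110.0 and out.x_deg[2] == 100.0
        assert np.isnan(out.x_deg[4])

    def test_identical_eyes_identity(self, rng):
        x = rng.normal(500, 5, 50)
        rec = _rec(np.full(50, 4000.0), xl=x.copy(), xr=x.copy())
        assert np.array_equal(average_eyes(rec).x_deg, x)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_swapping_eyes_leaves_output_unchanged(self, seed):
        r = np.random.default_rng(seed)
        n = 30
        kw = dict(
            xl=r.normal(500, 5, n), yl=r.normal(400, 5, n),
            xr=r.normal(500, 5, n), yr=r.normal(400, 5, n),
            pl=np.abs(r.normal(4000, 10, n)) + 1, pr=np.abs(r.normal(4000, 10, n)) + 1,
        )
        a = average_eyes(GazeRecording("P", 1, t=np.arange(n, dtype=float), **kw))
        swapped = dict(xl=kw["xr"], yl=kw["yr"], xr=kw["xl"], yr=kw["yl"],
                       pl=kw["pr"], pr=kw["pl"])
        b = average_eyes(GazeRecording("P", 1, t=np.arange(n, dtype=float), **swapped))
        assert np.allclose(a.x_deg, b.x_deg) and np.allclose(a.pupil, b.pupil)


class TestPixelsToDegrees:
    def test_center_pixel_is_zero(self, geometry):
        s = _series([geometry.screen_width_px / 2], [geometry.screen_height_px / 2])
        out = pixels_to_degrees(s, geometry)
        assert out.x_deg[0] == pytest.approx(0.0) and out.y_deg[0] == pytest.approx(0.0)

    def test_one_cm_at_57cm_is_one_degree(self, geometry):
        # atan(1/57) = 1.00494 degrees (hand calculation)
        px_per_cm = 1.0 / geometry.pitch_x_cm
        s = _series([geometry.screen_width_px / 2 + px_per_cm], [geometry.screen_height_px / 2])
        out = pixels_to_degrees(s, geometry)
        assert out.x_deg[0] == pytest.approx(math.degrees(math.atan(1 / 57)), abs=1e-6)
        assert out.x_deg[0] == pytest.approx(1.0049, abs=1e-3)

    def test_monotone_in_offset(self, geometry):
        xs = geometry.screen_width_px / 2 + np.array([0, 10, 50, 200, 400])
        out = pixels_to_degrees(_series(xs, np.full(5, geometry.screen_height_px / 2)), geometry)
        assert np.all(np.diff(np.abs(out.x_deg)) > 0)


class TestSmoothPupil:
    def test_constant_is_fixed_point(self):
        p = np.full(500, 4321.0)
        assert np.allclose(smooth_pupil(p, 100), p)

    def test_impulse_becomes_plateau(self):
        # convolution oracle: unit impulse, window w -> plateau of 1/w
        w = 11
        p = np.zeros(201)
        p[100] = 1.0
        out = smooth_pupil(p, float(w))
        assert out[100] == pytest.approx(1.0 / w)
        assert out[100 - w // 2] == pytest.approx(1.0 / w)
        assert out[100 + w // 2 + 1] == pytest.approx(0.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_smoothing_contracts_variance(self, seed):
        r = np.random.default_rng(seed)
        p = r.normal(4000, 50, 400)
        out = smooth_pupil(p, 51)
        assert np.var(out) <= np.var(p) + 1e-9

    def test_missing_samples_ignored_not_propagated(self):
        p = np.full(300, 4000.0)
        p[150] = np.nan
        out = smooth_pupil(p, 21)
        assert np.isfinite(out[150]) and out[150] == pytest.approx(4000.0)

    def test_all_missing_window_stays_missing(self):
        p = np.full(300, np.nan)
        assert np.isnan(smooth_pupil(p, 21)).all()


def idt_oracle(x, y, t, max_disp, min_dur):
    """Exhaustive I-DT: greedy maximal windows via direct O(n^2) scanning."""
    fixations = []
    n = len(x)
    dt = np.median(np.diff(t)) if n > 1 else 1.0
    min_len = max(2, int(np.ceil(min_dur / dt)))
    valid = ~(np.isnan(x) | np.isnan(y))
    i = 0
    while i < n:
        if not valid[i]:
            i += 1
            continue
        # longest valid window starting at i with dispersion <= max_disp
        end = i
        while end + 1 < n and valid[end + 1]:
            xs = x[i : end + 2]
            ys = y[i : end + 2]
            if (xs.max() - xs.min()) + (ys.max() - ys.min()) > max_disp:
                break
            end += 1
        seg = x[i : end + 1]
        if len(seg) >= min_len:
            disp = (x[i : end + 1].max() - x[i : end + 1].min()) + (
                y[i : end + 1].max() - y[i : end + 1].min()
            )
            if disp <= max_disp:
                fixations.append((t[i], t[end]))
                i = end + 1
                continue
        i += 1
    return fixations


class TestFixations:
    CFG = PreprocessConfig(fixation_dispersion_deg=1.0, fixation_min_dur_ms=100)

    def test_stationary_trace_is_one_fixation(self):
        s = _series(np.zeros(3000), np.zeros(3000))
        fx = detect_fixations(s, self.CFG)
        assert len(fx) == 1
        assert fx[0].onset_ms == 0 and fx[0].offset_ms == 2999

    def test_two_clusters_give_two_fixations(self):
        x = np.concatenate([np.zeros(1000), np.linspace(0, 5, 40), np.full(1000, 5.0)])
        s = _series(x, np.zeros_like(x))
        fx = detect_fixations(s, self.CFG)
        assert len(fx) == 2
        assert abs(fx[0].centroid_deg[0]) < 0.1 and abs(fx[1].centroid_deg[0] - 5) < 0.1

    def test_all_missing_trace_yields_nothing(self):
        s = _series(np.full(500, np.nan), np.full(500, np.nan))
        assert detect_fixations(s, self.CFG) == []

    def test_blink_gap_terminates_fixations(self):
        x = np.zeros(2000)
        x[900:1100] = np.nan
        s = _series(x, np.zeros(2000))
        fx = detect_fixations(s, self.CFG)
        assert len(fx) == 2
        assert fx[0].offset_ms < 900 and fx[1].onset_ms >= 1100

    def test_fixation_time_bounded_by_trace(self):
        r = np.random.default_rng(5)
        x = np.cumsum(r.normal(0, 0.01, 4000))
        s = _series(x, np.zeros_like(x))
        fx = detect_fixations(s, self.CFG)
        assert sum(f.duration_ms for f in fx) <= s.t[-1] - s.t[0]

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_scan_oracle(self, seed):
        r = np.random.default_rng(seed)
        n = 1500
        x = np.cumsum(r.normal(0, 0.02, n))
        y = np.cumsum(r.normal(0, 0.02, n))
        if seed % 2:
            x[700:760] = np.nan
            y[700:760] = np.nan
        s = _series(x, y)
        got = [(f.onset_ms, f.offset_ms) for f in detect_fixations(s, self.CFG)]
        want = idt_oracle(x, y, s.t, 1.0, 100)
        assert got == want


def test_write_cyclopean_round_trips(tmp_path):
    import pandas as pd
    from oculoeffort.preprocess import write_cyclopean

    s = _series(np.array([0.1, 0.2, np.nan]), np.array([0.0, -0.1, 0.3]))
    write_cyclopean(s, np.array([4000.0, 4001.0, np.nan]), tmp_path / "cyc.csv")
    back = pd.read_csv(tmp_path / "cyc.csv", na_values=["NA"], keep_default_na=False)
    assert list(back.columns) == ["t", "x_deg", "y_deg", "pupil_smooth"]
    assert np.allclose(back.x_deg, s.x_deg, atol=1e-9, equal_nan=True)
    assert np.isnan(back.pupil_smooth[2])
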