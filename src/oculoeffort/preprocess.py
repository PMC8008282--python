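"""Preprocessing between raw binocular samples and event/metric extraction.

Stages (in pipeline order): blink detection and masking, binocular (cyclopean)
averaging, pixel -> visual-angle conversion, pupil smoothing, and I-DT
fixation segmentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .gaze_io import GazeRecording, GazeValidationError, ScreenGeometry

__all__ = [
    "BlinkInterval",
    "Fixation",
    "PreprocessConfig",
    "CyclopeanSeries",
    "detect_blinks",
    "mask_blinks",
    "average_eyes",
    "pixels_to_degrees",
    "smooth_pupil",
    "detect_fixations",
    "write_cyclopean",
]


@dataclass(frozen=True)
class BlinkInterval:
    """A padded blink: [onset_ms, offset_ms], with the eye(s) that closed."""

    onset_ms: float
    offset_ms: float
    eye: str = "both"  # "left" | "right" | "both"

    def __post_init__(self) -> None:
        if self.offset_ms <= self.onset_ms:
            raise GazeValidationError("blink offset must exceed onset")


@dataclass(frozen=True)
class Fixation:
    onset_ms: float
    offset_ms: float
    centroid_deg: tuple[float, float]
    dispersion_deg: float

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass(frozen=True)
class PreprocessConfig:
    """Knobs the source literature leaves open; all strictly positive.

    ``fixation_dispersion_deg`` is the I-DT limit on (max-min) summed over the
    two axes. The default is deliberately permissive (4.0 deg): microsaccades
    on a steep main sequence carry a fast transient excursion well beyond
    their net displacement, and successive events wander the window's
    extremes further; a tight dispersion limit would truncate fixations
    exactly at the events the detector must see. Saccades between distinct
    screen regions are still far larger than this.
    """

    blink_pad_ms: float = 100.0
    pupil_smooth_window_ms: float = 100.0
    fixation_dispersion_deg: float = 4.0
    fixation_min_dur_ms: float = 100.0
    #: width of the median filter applied to gaze *only* as input to the
    #: fixation segmentation, so that brief saccadic transients do not count
    #: toward the I-DT dispersion; the detector itself always sees the
    #: unfiltered trace. <= 1 sample disables it.
    fixation_smooth_ms: float = 41.0

    def __post_init__(self) -> None:
        for name in (
            "blink_pad_ms",
            "pupil_smooth_window_ms",
            "fixation_dispersion_deg",
            "fixation_min_dur_ms",
        ):
            if getattr(self, name) <= 0:
                raise GazeValidationError(f"PreprocessConfig.{name} must be > 0")
        if self.fixation_smooth_ms < 0:
            raise GazeValidationError("fixation_smooth_ms must be >= 0")


@dataclass
class CyclopeanSeries:
    """Averaged-eye series in degrees of visual angle about screen centre."""

    t: np.ndarray
    x_deg: np.ndarray
    y_deg: np.ndarray
    pupil: np.ndarray

    def __len__(self) -> int:
        return len(self.t)


def _missing_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of ``mask`` as (start, stop) index pairs, stop inclusive."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(int))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1) - 1
    return list(zip(starts.tolist(), stops.tolist()))


def detect_blinks(rec: GazeRecording, pad_ms: float = 100.0) -> list[BlinkInterval]:
    """Blinks = maximal missing-pupil runs (either eye), padded and merged.

    Each run is extended by ``pad_ms`` on both sides (to cover lid-closure
    pupil artifacts) and overlapping padded intervals are merged.
    """
    missing_l = np.isnan(rec.pl)
    missing_r = np.isnan(rec.pr)
    raw: list[tuple[float, float, str]] = []
    for eye, mask in (("left", missing_l), ("right", missing_r)):
        for start, stop in _missing_runs(mask):
            raw.append((rec.t[start] - pad_ms, rec.t[stop] + pad_ms, eye))
    if not raw:
        return []
    raw.sort()
    merged: list[list] = [list(raw[0])]
    for onset, offset, eye in raw[1:]:
        last = merged[-1]
        if onset <= last[1]:
            last[1] = max(last[1], offset)
            if eye != last[2]:
                last[2] = "both"
        else:
            merged.append([onset, offset, eye])
    return [BlinkInterval(on, off, eye) for on, off, eye in merged]


def mask_blinks(rec: GazeRecording, blinks: list[BlinkInterval]) -> GazeRecording:
    """Return a copy with every channel set missing inside blink intervals."""
    bad = np.zeros(len(rec), dtype=bool)
    for b in blinks:
        bad |= (rec.t >= b.onset_ms) & (rec.t <= b.offset_ms)
    out = {}
    for name in ("xl", "yl", "xr", "yr", "pl", "pr"):
        a = getattr(rec, name).copy()
        a[bad] = np.nan
        out[name] = a
    return GazeRecording(
        participant_id=rec.participant_id,
        trial_id=rec.trial_id,
        t=rec.t.copy(),
        **out,
    )


def _nanmean_pair(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-sample mean of two channels; one missing -> the other; both -> NaN."""
    with np.errstate(invalid="ignore"):
        out = np.where(
            np.isnan(a), b, np.where(np.isnan(b), a, 0.5 * (a + b))
        )
    return out


def average_eyes(rec: GazeRecording) -> CyclopeanSeries:
    """Cyclopean series: (x, y) = ((xl+xr)/2, (yl+yr)/2), pupil likewise.

    A sample where exactly one eye is missing falls back to the present eye;
    both missing stays missing. Output x/y are still in pixels here.
    """
    return CyclopeanSeries(
        t=rec.t.copy(),
        x_deg=_nanmean_pair(rec.xl, rec.xr),
        y_deg=_nanmean_pair(rec.yl, rec.yr),
        pupil=_nanmean_pair(rec.pl, rec.pr),
    )


def pixels_to_degrees(series: CyclopeanSeries, geometry: ScreenGeometry) -> CyclopeanSeries:
    """Convert pixel coordinates to degrees of visual angle about screen centre.

    Per axis: deg = atan(displacement_cm / distance_cm) * 180 / pi, where the
    displacement is measured from the screen centre in physical units.
    """
    if geometry.distance_cm <= 0:
        raise GazeValidationError("viewing distance must be > 0")
    cx = geometry.screen_width_px / 2.0
    cy = geometry.screen_height_px / 2.0
    x_cm = (series.x_deg - cx) * geometry.pitch_x_cm
    y_cm = (series.y_deg - cy) * geometry.pitch_y_cm
    return CyclopeanSeries(
        t=series.t,
        x_deg=np.degrees(np.arctan2(x_cm, geometry.distance_cm)),
        y_deg=np.degrees(np.arctan2(y_cm, geometry.distance_cm)),
        pupil=series.pupil,
    )


def degrees_per_pixel(geometry: ScreenGeometry) -> float:
    """Small-angle scale (deg/px) at screen centre, mean of the two axes."""
    dx = math.degrees(math.atan2(geometry.pitch_x_cm, geometry.distance_cm))
    dy = math.degrees(math.atan2(geometry.pitch_y_cm, geometry.distance_cm))
    return 0.5 * (dx + dy)


def smooth_pupil(pupil: np.ndarray, window_ms: float, dt_ms: float = 1.0) -> np.ndarray:
    """Centred moving average that ignores missing samples.

    Output is missing only where every sample in the window is missing;
    length is preserved. ``window_ms`` must cover at least 3 samples.
    """
    pupil = np.asarray(pupil, dtype=float)
    w = int(round(window_ms / dt_ms))
    w = max(w, 3)
    if w % 2 == 0:
        w += 1
    valid = ~np.isnan(pupil)
    filled = np.where(valid, pupil, 0.0)
    kernel = np.ones(w)
    sums = np.convolve(filled, kernel, mode="same")
    counts = np.convolve(valid.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = sums / counts
    out[counts == 0] = np.nan
    return out


def _idt_scan(
    x: np.ndarray,
    y: np.ndarray,
    start: int,
    min_len: int,
    max_disp: float,
) -> int | None:
    """Greedy I-DT window expansion from ``start``.

    Returns the exclusive end index of the maximal window with dispersion
    (max-min summed over axes) <= max_disp, or None if even the minimal
    window exceeds the dispersion limit.
    """
    n = len(x)
    if start + min_len > n:
        return None
    seg_x = x[start:]
    seg_y = y[start:]
    disp = (
        np.maximum.accumulate(seg_x) - np.minimum.accumulate(seg_x)
        + np.maximum.accumulate(seg_y) - np.minimum.accumulate(seg_y)
    )
    if disp[min_len - 1] > max_disp:
        return None
    over = np.flatnonzero(disp > max_disp)
    end = n if over.size == 0 else start + int(over[0])
    return end


def median_smooth_gaze(series: CyclopeanSeries, window_ms: float, dt_ms: float = 1.0) -> CyclopeanSeries:
    """Median-filtered copy of the gaze channels (segmentation input only).

    Missing samples are bridged by linear interpolation before filtering and
    re-imposed afterwards, so blink gaps stay gaps.
    """
    from scipy.ndimage import median_filter

    w = int(round(window_ms / dt_ms))
    if w <= 1:
        return series
    if w % 2 == 0:
        w += 1

    def _filt(a: np.ndarray) -> np.ndarray:
        bad = np.isnan(a)
        if bad.all():
            return a.copy()
        filled = a.copy()
        if bad.any():
            idx = np.arange(len(a))
            filled[bad] = np.interp(idx[bad], idx[~bad], a[~bad])
        out = median_filter(filled, size=w, mode="nearest")
        out[bad] = np.nan
        return out

    return CyclopeanSeries(
        t=series.t, x_deg=_filt(series.x_deg), y_deg=_filt(series.y_deg), pupil=series.pupil
    )


def detect_fixations(series: CyclopeanSeries, cfg: PreprocessConfig) -> list[Fixation]:
    """Dispersion-threshold (I-DT) fixation segmentation.

    Maximal windows whose dispersion (max-min summed over the two axes) stays
    within ``fixation_dispersion_deg`` and whose duration reaches
    ``fixation_min_dur_ms`` become fixations. Missing samples (blink gaps)
    terminate any open window.
    """
    t, x, y = series.t, series.x_deg, series.y_deg
    n = len(t)
    if n == 0:
        return []
    dt = float(np.median(np.diff(t))) if n > 1 else 1.0
    min_len = max(2, int(math.ceil(cfg.fixation_min_dur_ms / dt)))
    valid = ~(np.isnan(x) | np.isnan(y))
    fixations: list[Fixation] = []
    for seg_start, seg_stop in _missing_runs(valid):  # runs of *valid* samples
        i = seg_start
        while i <= seg_stop - min_len + 1:
            end = _idt_scan(x[: seg_stop + 1], y[: seg_stop + 1], i, min_len, cfg.fixation_dispersion_deg)
            if end is None:
                i += 1
                continue
            xs, ys = x[i:end], y[i:end]
            disp = float((xs.max() - xs.min()) + (ys.max() - ys.min()))
            fixations.append(
                Fixation(
                    onset_ms=float(t[i]),
                    offset_ms=float(t[end - 1]),
                    centroid_deg=(float(xs.mean()), float(ys.mean())),
                    dispersion_deg=disp,
                )
            )
            i = end
    return fixations


def write_cyclopean(series: CyclopeanSeries, pupil_smooth: np.ndarray, path) -> None:
    """Write a processed cyclopean series as CSV (t,x_deg,y_deg,pupil_smooth)."""
    import pandas as pd

    pd.DataFrame(
        {
            "t": series.t,
            "x_deg": series.x_deg,
            "y_deg": series.y_deg,
            "pupil_smooth": pupil_smooth,
        }
    ).to_csv(path, index=False, na_rep="NA", float_format="%.9g")


def slice_indices(t: np.ndarray, onset_ms: float, offset_ms: float) -> slice:
    """Index slice of samples with onset <= t <= offset."""
    i0 = int(np.searchsorted(t, onset_ms, side="left"))
    i1 = int(np.searchsorted(t, offset_ms, side="right"))
    return slice(i0, i1)
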