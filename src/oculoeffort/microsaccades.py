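"""Velocity-threshold microsaccade detection and main-sequence regression.

Detection follows the classic velocity-threshold scheme for fixational eye
movements: a smoothed 5-point velocity estimate, a median-based (robust)
noise level per axis, an elliptic threshold criterion at lambda times that
noise level, minimum-duration filtering, and merging of events separated by
short gaps. Detection runs on the cyclopean (averaged-eye) position signal,
within fixations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .gaze_io import GazeValidationError

__all__ = [
    "DetectorConfig",
    "Microsaccade",
    "MainSequenceFit",
    "InsufficientDataError",
    "compute_velocity",
    "estimate_thresholds",
    "detect_microsaccades",
    "fit_main_sequence",
    "epoch_summaries",
]

_SIGMA_EPS = 1e-6


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class DetectorConfig:
    """Detector settings; the de-facto standards of the velocity-threshold
    algorithm family, all exposed for override."""

    lambda_mult: float = 6.0
    velocity_window: int = 5
    min_dur_ms: float = 6.0
    merge_gap_ms: float = 20.0
    max_magnitude_deg: float = 1.0
    #: per-fixation threshold estimation needs at least this many samples,
    #: otherwise thresholds fall back to the whole trial
    min_threshold_samples: int = 50

    def __post_init__(self) -> None:
        if self.lambda_mult <= 0:
            raise GazeValidationError("lambda_mult must be > 0")
        if self.velocity_window < 5 or self.velocity_window % 2 == 0:
            raise GazeValidationError("velocity_window must be odd and >= 5")
        if self.min_dur_ms < 3:
            raise GazeValidationError("min_dur_ms must be >= 3 ms")


@dataclass(frozen=True)
class Microsaccade:
    onset_ms: float
    offset_ms: float
    magnitude_deg: float
    peak_velocity_dps: float
    fixation_id: int = -1
    epoch_id: int = -1

    def __post_init__(self) -> None:
        if self.offset_ms <= self.onset_ms:
            raise GazeValidationError("microsaccade offset must exceed onset")
        if self.peak_velocity_dps <= 0:
            raise GazeValidationError("peak velocity must be > 0")


@dataclass(frozen=True)
class MainSequenceFit:
    slope: float
    intercept: float
    r_squared: float
    n_events: int
    slope_se: float
    intercept_se: float

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.r_squared <= 1 + 1e-9):
            raise GazeValidationError("r_squared outside [0, 1]")
        if self.n_events < 2:
            raise GazeValidationError("main-sequence fit needs >= 2 events")


def compute_velocity(
    x: np.ndarray, y: np.ndarray, dt_ms: float = 1.0, window: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed 5-point velocity estimate per axis (deg/s).

    v_n = (x_{n+2} + x_{n+1} - x_{n-1} - x_{n-2}) / (6 dt); the first and
    last two samples are undefined (NaN). A series shorter than the window
    yields all-NaN output of the same length.
    """
    if window != 5:
        raise GazeValidationError("only the 5-point velocity estimator is supported")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    vx = np.full(n, np.nan)
    vy = np.full(n, np.nan)
    if n < window:
        return vx, vy
    dt_s = dt_ms / 1000.0
    denom = 6.0 * dt_s
    vx[2:-2] = (x[4:] + x[3:-1] - x[1:-3] - x[:-4]) / denom
    vy[2:-2] = (y[4:] + y[3:-1] - y[1:-3] - y[:-4]) / denom
    return vx, vy


def estimate_thresholds(
    vx: np.ndarray, vy: np.ndarray, lambda_mult: float
) -> tuple[float, float]:
    """Median-based robust noise thresholds (eta_x, eta_y).

    sigma_a^2 = median(v_a^2) - median(v_a)^2 per axis, floored at a small
    epsilon; eta_a = lambda * sigma_a. Needs >= 10 defined velocity samples.
    """
    out = []
    for v in (vx, vy):
        v = np.asarray(v, dtype=float)
        v = v[~np.isnan(v)]
        if len(v) < 10:
            raise InsufficientDataError(
                f"threshold estimation needs >= 10 velocity samples, got {len(v)}"
            )
        var = float(np.median(v**2) - np.median(v) ** 2)
        sigma = math.sqrt(max(var, 0.0))
        out.append(lambda_mult * max(sigma, _SIGMA_EPS))
    return out[0], out[1]


def _candidate_runs(above: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs as (first, last) inclusive index pairs."""
    if not above.any():
        return []
    padded = np.concatenate(([False], above, [False]))
    d = np.diff(padded.astype(int))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1) - 1
    return list(zip(starts.tolist(), stops.tolist()))


def detect_microsaccades(
    t: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    cfg: DetectorConfig,
    thresholds: tuple[float, float] | None = None,
    fixation_id: int = -1,
) -> list[Microsaccade]:
    """Detect microsaccades on one fixation slice of the cyclopean signal.

    Candidate samples satisfy the elliptic criterion
    (vx/eta_x)^2 + (vy/eta_y)^2 > 1; maximal candidate runs lasting at least
    ``min_dur_ms`` become events; events separated by less than
    ``merge_gap_ms`` are merged; events whose start-to-end displacement
    exceeds ``max_magnitude_deg`` are discarded. Magnitude is the
    start-to-end displacement; peak velocity the maximum instantaneous speed
    from the same smoothed velocity series used for detection.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < cfg.velocity_window:
        return []
    dt = float(np.median(np.diff(t)))
    vx, vy = compute_velocity(x, y, dt_ms=dt, window=cfg.velocity_window)
    if thresholds is None:
        try:
            thresholds = estimate_thresholds(vx, vy, cfg.lambda_mult)
        except InsufficientDataError:
            return []
    eta_x, eta_y = thresholds
    with np.errstate(invalid="ignore"):
        crit = (vx / eta_x) ** 2 + (vy / eta_y) ** 2 > 1.0
    crit &= ~(np.isnan(vx) | np.isnan(vy))

    # duration filter on maximal runs (inclusive sample count)
    runs = [
        (a, b)
        for a, b in _candidate_runs(crit)
        if (b - a + 1) * dt >= cfg.min_dur_ms
    ]
    if not runs:
        return []

    # merge events separated by short gaps
    merged = [list(runs[0])]
    for a, b in runs[1:]:
        if (a - merged[-1][1]) * dt < cfg.merge_gap_ms:
            merged[-1][1] = b
        else:
            merged.append([a, b])

    events: list[Microsaccade] = []
    for a, b in merged:
        dxy = math.hypot(x[b] - x[a], y[b] - y[a])
        if dxy > cfg.max_magnitude_deg:
            continue
        speed = np.hypot(vx[a : b + 1], vy[a : b + 1])
        peak = float(np.nanmax(speed))
        if not (peak > 0) or not (dxy > 0):
            continue
        events.append(
            Microsaccade(
                onset_ms=float(t[a]),
                offset_ms=float(t[b]),
                magnitude_deg=float(dxy),
                peak_velocity_dps=peak,
                fixation_id=fixation_id,
            )
        )
    return events


def fit_main_sequence(events: list[Microsaccade]) -> MainSequenceFit:
    """OLS of peak velocity on magnitude over all events (the main sequence)."""
    if len(events) < 2:
        raise InsufficientDataError("main-sequence fit needs >= 2 events")
    m = np.array([e.magnitude_deg for e in events])
    v = np.array([e.peak_velocity_dps for e in events])
    if np.ptp(m) == 0:
        raise GazeValidationError("degenerate design: all magnitudes equal")
    n = len(m)
    mx, vy_ = m.mean(), v.mean()
    sxx = float(np.sum((m - mx) ** 2))
    sxy = float(np.sum((m - mx) * (v - vy_)))
    slope = sxy / sxx
    intercept = vy_ - slope * mx
    resid = v - (intercept + slope * m)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((v - vy_) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    if n > 2:
        sigma2 = ss_res / (n - 2)
        slope_se = math.sqrt(sigma2 / sxx)
        intercept_se = math.sqrt(sigma2 * (1.0 / n + mx**2 / sxx))
    else:
        slope_se = intercept_se = 0.0
    return MainSequenceFit(
        slope=slope,
        intercept=intercept,
        r_squared=min(max(r2, 0.0), 1.0),
        n_events=n,
        slope_se=slope_se,
        intercept_se=intercept_se,
    )


def epoch_summaries(
    events: list[Microsaccade],
    epochs: list[tuple[float, float]],
    usable_ms: list[float] | None = None,
) -> list[tuple[float, float]]:
    """Per-epoch (rate in events/s, mean magnitude in deg).

    Rate counts events whose onset falls inside the epoch, divided by the
    epoch's exposure in seconds; mean magnitude is NaN for event-free epochs.
    Exposure defaults to the full epoch duration; ``usable_ms`` overrides it
    with the time during which events were actually detectable (fixation
    time net of blink masking), which keeps the rate unbiased when part of
    the epoch carries no usable signal. A zero usable time yields a missing
    rate.
    """
    if usable_ms is not None and len(usable_ms) != len(epochs):
        raise GazeValidationError("usable_ms must match epochs in length")
    out = []
    for i, (onset, offset) in enumerate(epochs):
        dur_s = (offset - onset) / 1000.0
        if dur_s <= 0:
            raise GazeValidationError(f"zero-duration epoch ({onset}, {offset})")
        if usable_ms is not None:
            dur_s = usable_ms[i] / 1000.0
            if dur_s <= 0:
                out.append((float("nan"), float("nan")))
                continue
        # half-open [onset, offset) so contiguous epochs never double-count
        inside = [e for e in events if onset <= e.onset_ms < offset]
        rate = len(inside) / dur_s
        mag = float(np.mean([e.magnitude_deg for e in inside])) if inside else float("nan")
        out.append((rate, mag))
    return out
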