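"""Synthetic experiment generator.

Produces complete :class:`~oculoeffort.gaze_io.ExperimentDataset` objects with
the behavioral and signal structure the downstream analysis assumes:

* the 21-participant (7 aversive / 6 erotic / 8 neutral) x 24-trial (+3
  training) design;
* a bimodal cue-acquisition distribution per condition;
* fixational drift (a bounded Ornstein-Uhlenbeck walk) plus microsaccades
  generated as a Poisson process whose rate falls linearly with cue index,
  with lognormal magnitudes and peak velocities on a linear main sequence;
* pupil traces whose epoch means rise linearly with cue index at
  condition-specific slopes, on top of a participant baseline, a slow hippus
  oscillation, and an effort-scaled broadband noise component, reported in
  integer tracker units (quantization is the resting high-frequency noise
  floor, as in video eye trackers);
* blinks as missing runs; both eyes as the common signal plus small
  independent per-eye noise.

Every injected event and latent epoch mean is recorded in a ground-truth
ledger so recovery tests have an oracle.

Microsaccade waveform
---------------------
The waveform is a smooth displacement pulse whose *sampled* peak velocity is
set analytically: an out-leg trapezoidal speed profile (0.5 ms ramps around a
7 ms plateau at the target peak velocity) followed by a slower corrective
return leg at 40% of peak speed, leaving a net start-to-end displacement
equal to the drawn magnitude. The plateau is long enough that the smoothed
5-point velocity estimator reads the plateau speed exactly, so the injected
(magnitude, peak velocity) pair is recoverable by detection without bias.
The corrective return also keeps gaze bounded within the fixation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .gaze_io import (
    CONDITIONS,
    ExperimentDataset,
    GazeRecording,
    GazeValidationError,
    ScreenGeometry,
    TaskSpec,
    TrialRecord,
)

__all__ = [
    "EffectParams",
    "SimulationConfig",
    "GroundTruth",
    "default_geometry",
    "sample_cue_counts",
    "simulate_trial",
    "generate_dataset",
]

#: expected event rate never falls below this (events/s)
RATE_FLOOR = 0.05
#: minimal separation between injected microsaccade onsets (ms)
MIN_EVENT_SEPARATION_MS = 100.0
#: injected events keep this margin from epoch boundaries (ms)
EVENT_EDGE_MARGIN_MS = 60.0
# out-leg speed profile (ms): ramp / plateau / ramp
_RISE_MS, _PLATEAU_MS, _FALL_MS = 0.5, 6.0, 0.5
_OUT_LEG_MS = _RISE_MS + _PLATEAU_MS + _FALL_MS
# displacement of the out leg is v * (rise/2 + plateau + fall/2)
_OUT_DISP_FACTOR_MS = _RISE_MS / 2 + _PLATEAU_MS + _FALL_MS / 2
#: return-leg speed as a fraction of peak speed
_RETURN_SPEED_FRAC = 0.4


def default_geometry() -> ScreenGeometry:
    """57 cm viewing distance, 1024x768 on a 22-inch 4:3 panel (44.7x33.5 cm)."""
    return ScreenGeometry(
        distance_cm=57.0,
        screen_width_px=1024,
        screen_height_px=768,
        screen_width_cm=44.7,
        screen_height_cm=33.5,
    )


def _per_condition(neutral: float, aversive: float, erotic: float) -> dict[str, float]:
    return {"neutral": neutral, "aversive": aversive, "erotic": erotic}


@dataclass(frozen=True)
class EffectParams:
    """Generator truths. Defaults encode the study's effect structure."""

    cue_count_probs: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "neutral": (0.41, 0.10, 0.06, 0.08, 0.35, 0.00),
            "aversive": (0.54, 0.12, 0.04, 0.01, 0.29, 0.00),
            "erotic": (0.56, 0.10, 0.07, 0.02, 0.25, 0.00),
        }
    )
    ms_rate_base: float = 2.0
    ms_rate_slope_per_cue: dict[str, float] = field(
        default_factory=lambda: _per_condition(-0.355, -0.657, -0.355)
    )
    ms_magnitude_mean_deg: float = 0.3
    ms_magnitude_sd_deg: float = 0.15
    main_seq_slope: float = 376.37
    main_seq_intercept: float = 12.91
    main_seq_noise_sd: float = 22.0
    pupil_baseline_mean: float = 4000.0
    pupil_baseline_sd_between: float = 128.6  # sqrt(16542.80)
    bcpd_slope_per_cue: dict[str, float] = field(
        default_factory=lambda: _per_condition(37.00, 98.79, -28.86)
    )
    hippus_amp: float = 20.0
    hippus_freq_hz: float = 0.2
    pupil_hf_sd_base: float = 0.0
    pupil_hf_sd_per_cue: float = 10.0
    drift_sd_deg: float = 0.001
    blink_rate_per_s: float = 0.1
    blink_dur_ms: float = 150.0
    epoch_dur_ms_mean: float = 1500.0
    epoch_dur_ms_sd: float = 500.0
    eye_noise_deg: float = 0.005
    pupil_eye_noise: float = 0.2
    #: pupil channels are reported in integer tracker units (quantization is
    #: the resting noise floor of the high-frequency band)
    pupil_quantum: float = 1.0

    def __post_init__(self) -> None:
        for cond, probs in self.cue_count_probs.items():
            if cond not in CONDITIONS:
                raise GazeValidationError(f"unknown condition {cond!r}")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise GazeValidationError(
                    f"cue_count_probs[{cond!r}] must sum to 1 (got {sum(probs)})"
                )
        if self.main_seq_slope <= 0:
            raise GazeValidationError("main_seq_slope must be > 0")

    def event_rate(self, condition: str, cue_index: int) -> float:
        """Expected microsaccade rate (events/s) in a condition x cue cell."""
        r = self.ms_rate_base + self.ms_rate_slope_per_cue[condition] * (cue_index - 1)
        return max(r, RATE_FLOOR)


@dataclass(frozen=True)
class SimulationConfig:
    n_participants_per_condition: dict[str, int] = field(
        default_factory=lambda: {"neutral": 8, "aversive": 7, "erotic": 6}
    )
    task: TaskSpec = field(default_factory=TaskSpec)
    geometry: ScreenGeometry = field(default_factory=default_geometry)
    effects: EffectParams = field(default_factory=EffectParams)
    seed: int = 0

    def __post_init__(self) -> None:
        for cond, n in self.n_participants_per_condition.items():
            if cond not in CONDITIONS:
                raise GazeValidationError(f"unknown condition {cond!r}")
            if n < 1:
                raise GazeValidationError("participant counts must be >= 1")


@dataclass
class GroundTruth:
    """Ledger of injected latents, keyed by (participant_id, trial_id)."""

    baselines: dict[str, float] = field(default_factory=dict)
    #: (pid, trial) -> list of dicts with onset_ms, magnitude_deg,
    #: peak_velocity_dps, duration_ms, epoch_index
    events: dict[tuple[str, int], list[dict]] = field(default_factory=dict)
    #: (pid, trial) -> latent pupil mean per epoch (pre-noise)
    epoch_pupil_means: dict[tuple[str, int], list[float]] = field(default_factory=dict)
    #: (pid, trial) -> nominal event rate per epoch (events/s)
    epoch_rates: dict[tuple[str, int], list[float]] = field(default_factory=dict)


def sample_cue_counts(
    n_trials: int, probs: tuple[float, ...], rng: np.random.Generator
) -> np.ndarray:
    """Draw cue counts in 1..6 from a probability vector over 1..6."""
    probs = np.asarray(probs, dtype=float)
    if len(probs) != 6 or abs(probs.sum() - 1.0) > 1e-9 or np.any(probs < 0):
        raise GazeValidationError("probs must be a length-6 probability vector")
    if n_trials == 0:
        return np.array([], dtype=int)
    return rng.choice(np.arange(1, 7), size=n_trials, p=probs / probs.sum())


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given mean and sd."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def _place_event_times(
    n: int, lo: float, hi: float, rng: np.random.Generator
) -> np.ndarray:
    """n onset times in [lo, hi] at least MIN_EVENT_SEPARATION_MS apart."""
    if n == 0:
        return np.array([])
    span = hi - lo
    max_fit = int(span // MIN_EVENT_SEPARATION_MS) + 1
    n = min(n, max_fit)
    # sorted uniforms in the "compressed" interval, then re-inflate the gaps
    free = span - (n - 1) * MIN_EVENT_SEPARATION_MS
    u = np.sort(rng.uniform(0.0, free, size=n))
    return lo + u + MIN_EVENT_SEPARATION_MS * np.arange(n)


def _leg_displacement(tau: np.ndarray, v_ms: float, rise: float, plateau: float, fall: float) -> np.ndarray:
    """Displacement along one trapezoidal-speed leg at times tau (ms) from leg start."""
    t1, t2, t3 = rise, rise + plateau, rise + plateau + fall
    d1 = v_ms * rise / 2.0
    d2 = d1 + v_ms * plateau
    total = d2 + v_ms * fall / 2.0
    out = np.empty_like(tau)
    a = tau <= t1
    out[a] = v_ms * tau[a] ** 2 / (2.0 * rise)
    b = (tau > t1) & (tau <= t2)
    out[b] = d1 + v_ms * (tau[b] - t1)
    c = (tau > t2) & (tau <= t3)
    tc = tau[c] - t2
    out[c] = d2 + v_ms * (tc - tc**2 / (2.0 * fall))
    out[tau > t3] = total
    return out


def _saccade_pulse(tau_ms: np.ndarray, magnitude: float, v_peak_dps: float) -> np.ndarray:
    """Along-direction displacement of one microsaccade at offsets tau (ms).

    Out leg at plateau speed v_peak, return leg at _RETURN_SPEED_FRAC*v_peak;
    the return length is chosen so the permanent displacement is `magnitude`.
    """
    v_ms = v_peak_dps / 1000.0
    d_out = _OUT_DISP_FACTOR_MS * v_ms
    d_ret = d_out - magnitude
    v_ret = _RETURN_SPEED_FRAC * v_ms
    ret_plateau = max(d_ret / v_ret - (_RISE_MS / 2 + _FALL_MS / 2), 0.0)
    out = _leg_displacement(np.maximum(tau_ms, 0.0), v_ms, _RISE_MS, _PLATEAU_MS, _FALL_MS)
    tau_ret = tau_ms - _OUT_LEG_MS
    back = _leg_displacement(
        np.maximum(tau_ret, 0.0), v_ret, _RISE_MS, ret_plateau, _FALL_MS
    )
    return out - back


def event_duration_ms(magnitude: float, v_peak_dps: float) -> float:
    v_ms = v_peak_dps / 1000.0
    d_ret = _OUT_DISP_FACTOR_MS * v_ms - magnitude
    ret_plateau = max(d_ret / (_RETURN_SPEED_FRAC * v_ms) - (_RISE_MS / 2 + _FALL_MS / 2), 0.0)
    return _OUT_LEG_MS + _RISE_MS + ret_plateau + _FALL_MS


def _ou_drift(n: int, step_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Bounded fixational drift: Ornstein-Uhlenbeck walk (stationary sd ~0.1
    deg at the default step size)."""
    theta = 5e-5
    steps = rng.normal(0.0, step_sd, size=n)
    decay = 1.0 - theta
    return lfilter([1.0], [1.0, -decay], steps)


def _deg_to_px(
    deg_x: np.ndarray, deg_y: np.ndarray, geometry: ScreenGeometry
) -> tuple[np.ndarray, np.ndarray]:
    """Exact inverse of the pixel -> degree conversion used downstream."""
    cx = geometry.screen_width_px / 2.0
    cy = geometry.screen_height_px / 2.0
    x_cm = np.tan(np.radians(deg_x)) * geometry.distance_cm
    y_cm = np.tan(np.radians(deg_y)) * geometry.distance_cm
    return cx + x_cm / geometry.pitch_x_cm, cy + y_cm / geometry.pitch_y_cm


def simulate_trial(
    participant_id: str,
    baseline_pupil: float,
    condition: str,
    trial_id: int,
    n_cues: int,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    is_training: bool = False,
) -> tuple[GazeRecording, TrialRecord, dict]:
    """Simulate one trial; returns (recording, trial record, truth dict).

    The recording starts at the first cue onset (t = 0) and ends at the last
    cue offset. Training trials have one cue epoch and no evoked dilation.
    """
    if not (1 <= n_cues <= cfg.task.n_cues_max):
        raise GazeValidationError("n_cues out of range")
    if cfg.geometry.screen_width_cm <= 0:
        raise GazeValidationError("geometry missing physical size")
    eff = cfg.effects

    # --- epoch layout: first cue fixed, later epochs self-paced (lognormal)
    durations = [float(cfg.task.first_cue_ms)]
    if n_cues > 1:
        mu, sigma = _lognormal_params(eff.epoch_dur_ms_mean, eff.epoch_dur_ms_sd)
        extra = np.round(np.clip(rng.lognormal(mu, sigma, size=n_cues - 1), 600, 6000))
        durations += [float(d) for d in extra]
    onsets = np.concatenate(([0.0], np.cumsum(durations)[:-1]))
    offsets = np.cumsum(durations)
    epochs = list(zip(onsets.tolist(), offsets.tolist()))
    n = int(offsets[-1]) + 1
    t = np.arange(n, dtype=float)

    # --- fixational drift + microsaccades (degrees, screen-centre origin)
    x = _ou_drift(n, eff.drift_sd_deg, rng)
    y = _ou_drift(n, eff.drift_sd_deg, rng)
    mu_m, sigma_m = _lognormal_params(eff.ms_magnitude_mean_deg, eff.ms_magnitude_sd_deg)
    events: list[dict] = []
    rates: list[float] = []
    net = np.zeros(2)  # accumulated saccadic offset, for corrective aiming
    sac_x = np.zeros(n)
    sac_y = np.zeros(n)
    for k, (on, off) in enumerate(epochs, start=1):
        cue_index = 1 if is_training else k
        rate = eff.event_rate(condition, cue_index)
        rates.append(rate)
        if rate <= 0:
            continue
        count = rng.poisson(rate * (off - on) / 1000.0)
        lo, hi = on + EVENT_EDGE_MARGIN_MS, off - EVENT_EDGE_MARGIN_MS
        if hi <= lo:
            continue
        for onset in _place_event_times(count, lo, hi, rng):
            m = float(np.clip(rng.lognormal(mu_m, sigma_m), 0.03, 1.2))
            v = eff.main_seq_slope * m + eff.main_seq_intercept + rng.normal(
                0.0, eff.main_seq_noise_sd
            )
            v = max(v, magnitude_floor_velocity(m))
            if np.linalg.norm(net) < 1e-6:
                angle = rng.uniform(0.0, 2.0 * math.pi)
            else:  # corrective: aim back toward fixation centre
                angle = math.atan2(-net[1], -net[0]) + rng.normal(0.0, 0.25)
            u = np.array([math.cos(angle), math.sin(angle)])
            dur = event_duration_ms(m, v)
            i0 = int(onset)
            i1 = min(int(onset + dur) + 2, n)
            tau = t[i0:i1] - onset
            s = _saccade_pulse(tau, m, v)
            sac_x[i0:i1] += u[0] * s
            sac_y[i0:i1] += u[1] * s
            sac_x[i1:] += u[0] * m
            sac_y[i1:] += u[1] * m
            net += u * m
            events.append(
                {
                    "onset_ms": float(onset),
                    "duration_ms": float(dur),
                    "magnitude_deg": m,
                    "peak_velocity_dps": float(v),
                    "epoch_index": k,
                }
            )
    x += sac_x
    y += sac_y

    # --- pupil: baseline + evoked level per epoch + hippus + noise
    pupil = np.full(n, baseline_pupil)
    latent_means: list[float] = []
    slope = eff.bcpd_slope_per_cue[condition]
    for k, (on, off) in enumerate(epochs, start=1):
        evoked = 0.0 if is_training else slope * (k - 1)
        latent_means.append(baseline_pupil + evoked)
        sl = slice(int(on), int(off) + 1)
        pupil[sl] += evoked
        hf_sd = eff.pupil_hf_sd_base
        if not is_training:
            hf_sd += eff.pupil_hf_sd_per_cue * (k - 1)
        if hf_sd > 0:
            pupil[sl] += hf_sd * rng.normal(0.0, 1.0, sl.stop - sl.start)
    phase = rng.uniform(0.0, 2.0 * math.pi)
    pupil += eff.hippus_amp * np.sin(2.0 * math.pi * eff.hippus_freq_hz * t / 1000.0 + phase)

    # --- two eyes: common signal + small independent per-eye noise (pixels)
    xl_deg = x + rng.normal(0.0, eff.eye_noise_deg, n)
    yl_deg = y + rng.normal(0.0, eff.eye_noise_deg, n)
    xr_deg = x + rng.normal(0.0, eff.eye_noise_deg, n)
    yr_deg = y + rng.normal(0.0, eff.eye_noise_deg, n)
    xl, yl = _deg_to_px(xl_deg, yl_deg, cfg.geometry)
    xr, yr = _deg_to_px(xr_deg, yr_deg, cfg.geometry)
    pl = pupil + rng.normal(0.0, eff.pupil_eye_noise, n)
    pr = pupil + rng.normal(0.0, eff.pupil_eye_noise, n)
    if eff.pupil_quantum > 0:  # trackers report pupil size in integer units
        q = eff.pupil_quantum
        pl = np.round(pl / q) * q
        pr = np.round(pr / q) * q

    # --- blinks as missing runs on all channels
    n_blinks = rng.poisson(eff.blink_rate_per_s * n / 1000.0)
    for _ in range(n_blinks):
        b0 = int(rng.uniform(0, n))
        b1 = min(b0 + int(max(rng.normal(eff.blink_dur_ms, 30.0), 50.0)), n)
        for a in (xl, yl, xr, yr, pl, pr):
            a[b0:b1] = np.nan

    rec = GazeRecording(
        participant_id=participant_id,
        trial_id=trial_id,
        t=t,
        xl=xl,
        yl=yl,
        xr=xr,
        yr=yr,
        pl=pl,
        pr=pr,
    )
    # cosmetic behavioral model: accuracy from the best discriminating cue
    discr = rng.random(n_cues) < 0.5
    if discr.any():
        p_correct = cfg.task.cue_validities[int(np.argmax(discr))]
    else:
        p_correct = 0.5
    accuracy = int(rng.random() < p_correct)
    choice = "A" if rng.random() < 0.5 else "B"
    trial = TrialRecord(
        participant_id=participant_id,
        condition=condition,
        trial_id=trial_id,
        is_training=is_training,
        cue_epochs=epochs,
        n_cues=n_cues,
        choice=choice,
        accuracy=accuracy,
    )
    truth = {
        "events": events,
        "epoch_pupil_means": latent_means,
        "epoch_rates": rates,
    }
    return rec, trial, truth


def magnitude_floor_velocity(magnitude: float) -> float:
    """Smallest admissible peak velocity for a given magnitude.

    The out leg must displace more than the magnitude itself so a corrective
    return exists; 10% headroom on top of magnitude / out-leg time.
    """
    return max(1.1 * magnitude / (_OUT_DISP_FACTOR_MS / 1000.0), 20.0)


def generate_dataset(cfg: SimulationConfig) -> tuple[ExperimentDataset, GroundTruth]:
    """Generate the full experiment; deterministic in ``cfg.seed``.

    Training trials (cue index fixed at 1, zero evoked dilation) define each
    participant's pupil baseline. Ground truth records every injected event
    and latent epoch mean.
    """
    rng = np.random.default_rng(cfg.seed)
    eff = cfg.effects
    ds = ExperimentDataset(geometry=cfg.geometry, task=cfg.task)
    truth = GroundTruth()
    for condition in CONDITIONS:  # fixed order for determinism
        n_participants = cfg.n_participants_per_condition.get(condition, 0)
        probs = eff.cue_count_probs[condition]
        for i in range(n_participants):
            pid = f"{condition[:3]}{i + 1:02d}"
            baseline = rng.normal(eff.pupil_baseline_mean, eff.pupil_baseline_sd_between)
            baseline = max(baseline, 100.0)
            truth.baselines[pid] = baseline
            cue_counts = sample_cue_counts(cfg.task.n_trials, probs, rng)
            for trial_id in range(1, cfg.task.n_training + cfg.task.n_trials + 1):
                training = trial_id <= cfg.task.n_training
                n_cues = 1 if training else int(cue_counts[trial_id - cfg.task.n_training - 1])
                rec, trial, tr_truth = simulate_trial(
                    pid, baseline, condition, trial_id, n_cues, cfg, rng, is_training=training
                )
                ds.recordings.append(rec)
                ds.trials.append(trial)
                key = (pid, trial_id)
                truth.events[key] = tr_truth["events"]
                truth.epoch_pupil_means[key] = tr_truth["epoch_pupil_means"]
                truth.epoch_rates[key] = tr_truth["epoch_rates"]
    return ds, truth
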