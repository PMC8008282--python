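"""End-to-end orchestration: simulate/load -> preprocess -> detect -> metrics
-> models -> report, plus YAML configuration for every stage."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .gaze_io import (
    CONDITIONS,
    ExperimentDataset,
    GazeRecording,
    GazeValidationError,
    ScreenGeometry,
    TaskSpec,
    TrialRecord,
    read_samples,
    read_trials,
    write_samples,
    write_trials,
)
from .microsaccades import (
    DetectorConfig,
    Microsaccade,
    MainSequenceFit,
    detect_microsaccades,
    estimate_thresholds,
    compute_velocity,
    fit_main_sequence,
)
from .preprocess import (
    CyclopeanSeries,
    Fixation,
    PreprocessConfig,
    average_eyes,
    detect_blinks,
    detect_fixations,
    mask_blinks,
    median_smooth_gaze,
    pixels_to_degrees,
    slice_indices,
    smooth_pupil,
)
from .pupillometry import PupilBaseline, PupilIndexConfig, compute_baseline
from .stats import LMMResult, chisq_gof, fit_lmm, pearson_with_t
from .synthetic import EffectParams, GroundTruth, SimulationConfig, generate_dataset
from .trial_metrics import (
    EpochMetrics,
    compute_deltas,
    compute_epoch_metrics,
    deltas_to_frame,
    metrics_to_frame,
)

__all__ = [
    "PipelineConfig",
    "ReportBundle",
    "load_config",
    "preprocess_recording",
    "detect_trial_events",
    "analyze_dataset",
    "run_pipeline",
    "save_truth",
]

log = logging.getLogger(__name__)

LMM_DVS = ("d_bcpd", "d_lhipa", "d_ms_rate", "d_ms_mag")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one analysis run needs, assembled from YAML or defaults."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    pupil_index: PupilIndexConfig = field(default_factory=PupilIndexConfig)
    #: dependent variable for the microsaccade-rate model: per-trial delta
    #: ("delta", default) or per-epoch raw rate ("per_epoch")
    ms_rate_dv: str = "delta"

    def __post_init__(self) -> None:
        if self.ms_rate_dv not in ("delta", "per_epoch"):
            raise GazeValidationError("ms_rate_dv must be 'delta' or 'per_epoch'")


def _build(cls, block: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - known
    if unknown:
        raise GazeValidationError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**block)


def load_config(path: str | Path | None = None, seed: int | None = None) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file; absent blocks use defaults.

    Recognized top-level blocks: geometry, task, effects, participants,
    preprocess, detector, pupil_index; scalars: seed, ms_rate_dv. A ``seed``
    argument overrides the file.
    """
    raw: dict = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    geometry = _build(ScreenGeometry, raw["geometry"]) if "geometry" in raw else None
    task = _build(TaskSpec, {**raw.get("task", {})}) if "task" in raw else None
    effects = None
    if "effects" in raw:
        block = dict(raw["effects"])
        for key in ("cue_count_probs", "ms_rate_slope_per_cue", "bcpd_slope_per_cue"):
            if key in block and isinstance(block[key], dict):
                block[key] = {
                    c: tuple(v) if isinstance(v, (list, tuple)) else v
                    for c, v in block[key].items()
                }
        effects = _build(EffectParams, block)
    sim_kwargs = {}
    if geometry is not None:
        sim_kwargs["geometry"] = geometry
    if task is not None:
        sim_kwargs["task"] = task
    if effects is not None:
        sim_kwargs["effects"] = effects
    if "participants" in raw:
        sim_kwargs["n_participants_per_condition"] = dict(raw["participants"])
    sim_kwargs["seed"] = int(seed if seed is not None else raw.get("seed", 0))
    return PipelineConfig(
        simulation=SimulationConfig(**sim_kwargs),
        preprocess=_build(PreprocessConfig, raw.get("preprocess", {})),
        detector=_build(DetectorConfig, raw.get("detector", {})),
        pupil_index=_build(PupilIndexConfig, raw.get("pupil_index", {})),
        ms_rate_dv=raw.get("ms_rate_dv", "delta"),
    )


@dataclass
class PreprocessedTrial:
    series: CyclopeanSeries  # degrees; raw (unsmoothed) masked pupil
    pupil_smooth: np.ndarray
    fixations: list[Fixation]
    dt_ms: float


@dataclass
class ReportBundle:
    cue_distribution: pd.DataFrame
    correlations: pd.DataFrame
    main_sequence: MainSequenceFit
    lmm: dict[str, LMMResult]
    metrics: pd.DataFrame
    deltas: pd.DataFrame
    events: pd.DataFrame
    summary: dict


def preprocess_recording(
    rec: GazeRecording,
    geometry: ScreenGeometry,
    cfg: PreprocessConfig,
    with_fixations: bool = True,
) -> PreprocessedTrial:
    """Blink masking, binocular averaging, degree conversion, smoothing,
    fixation segmentation for one recording."""
    blinks = detect_blinks(rec, cfg.blink_pad_ms)
    masked = mask_blinks(rec, blinks) if blinks else rec
    series = pixels_to_degrees(average_eyes(masked), geometry)
    dt = float(np.median(np.diff(series.t))) if len(series) > 1 else 1.0
    pupil_smooth = smooth_pupil(series.pupil, cfg.pupil_smooth_window_ms, dt)
    if with_fixations:
        seg_input = median_smooth_gaze(series, cfg.fixation_smooth_ms, dt)
        fixations = detect_fixations(seg_input, cfg)
    else:
        fixations = []
    return PreprocessedTrial(
        series=series, pupil_smooth=pupil_smooth, fixations=fixations, dt_ms=dt
    )


def detect_trial_events(
    pre: PreprocessedTrial, cfg: DetectorConfig
) -> list[Microsaccade]:
    """Detect microsaccades within each fixation of a preprocessed trial.

    Thresholds are estimated per fixation slice when it has at least
    ``cfg.min_threshold_samples`` samples, else from the whole trial.
    """
    t, x, y = pre.series.t, pre.series.x_deg, pre.series.y_deg
    trial_thresholds = None
    events: list[Microsaccade] = []
    for fid, fx in enumerate(pre.fixations):
        sl = slice_indices(t, fx.onset_ms, fx.offset_ms)
        n_samples = sl.stop - sl.start
        thresholds = None
        if n_samples < cfg.min_threshold_samples:
            if trial_thresholds is None:
                vx, vy = compute_velocity(x, y, dt_ms=pre.dt_ms)
                try:
                    trial_thresholds = estimate_thresholds(vx, vy, cfg.lambda_mult)
                except Exception:
                    continue
            thresholds = trial_thresholds
        events.extend(
            detect_microsaccades(
                t[sl], x[sl], y[sl], cfg, thresholds=thresholds, fixation_id=fid
            )
        )
    return events


def _participant_baselines(
    ds: ExperimentDataset, cfg: PipelineConfig
) -> dict[str, PupilBaseline]:
    by_pid: dict[str, list[np.ndarray]] = {}
    training_keys = {
        (tr.participant_id, tr.trial_id) for tr in ds.trials if tr.is_training
    }
    for rec in ds.recordings:
        if (rec.participant_id, rec.trial_id) in training_keys:
            pre = preprocess_recording(
                rec, ds.geometry, cfg.preprocess, with_fixations=False
            )
            by_pid.setdefault(rec.participant_id, []).append(pre.pupil_smooth)
    return {
        pid: compute_baseline(chunks, pid) for pid, chunks in sorted(by_pid.items())
    }


def analyze_dataset(
    ds: ExperimentDataset,
    cfg: PipelineConfig | None = None,
    lmm_dvs: tuple[str, ...] = LMM_DVS,
) -> ReportBundle:
    """Run every analysis stage on a dataset and assemble the report bundle."""
    cfg = cfg or PipelineConfig()
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    baselines = _participant_baselines(ds, cfg)
    timings["baselines"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    rec_index = {(r.participant_id, r.trial_id): r for r in ds.recordings}
    all_metrics: list[EpochMetrics] = []
    all_events: list[tuple[str, int, Microsaccade]] = []
    n_excluded = 0
    for trial in ds.trials:
        if trial.is_training:
            continue
        rec = rec_index.get((trial.participant_id, trial.trial_id))
        if rec is None:
            raise GazeValidationError(
                f"stage metrics: no recording for trial {trial.trial_id} of "
                f"{trial.participant_id}"
            )
        baseline = baselines.get(trial.participant_id)
        if baseline is None:
            n_excluded += 1
            log.warning("no baseline for participant %s; trial skipped", trial.participant_id)
            continue
        pre = preprocess_recording(rec, ds.geometry, cfg.preprocess)
        events = detect_trial_events(pre, cfg.detector)
        all_events.extend((trial.participant_id, trial.trial_id, e) for e in events)
        all_metrics.extend(
            compute_epoch_metrics(
                trial,
                pre.series,
                pre.pupil_smooth,
                events,
                baseline,
                cfg.pupil_index,
                dt_ms=pre.dt_ms,
                edge_guard_ms=cfg.preprocess.pupil_smooth_window_ms / 2.0,
                fixations=pre.fixations,
            )
        )
    timings["metrics"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    metrics_df = metrics_to_frame(all_metrics)
    deltas = compute_deltas(all_metrics)
    deltas_df = deltas_to_frame(deltas)
    trials_df = pd.DataFrame(
        [
            {
                "participant": tr.participant_id,
                "condition": tr.condition,
                "n_cues": tr.n_cues,
            }
            for tr in ds.trials
            if not tr.is_training
        ]
    )

    # cue-count distribution + goodness of fit against equal proportions
    k = ds.task.n_cues_max
    uniform = np.full(k, 1.0 / k)
    dist_rows = []
    for label, sub in [("overall", trials_df)] + [
        (c, trials_df[trials_df.condition == c]) for c in CONDITIONS
    ]:
        if len(sub) == 0:
            continue
        counts = np.array([(sub.n_cues == i).sum() for i in range(1, k + 1)], dtype=float)
        gof = chisq_gof(counts, uniform)
        row = {"condition": label, "n_trials": int(counts.sum())}
        row.update({f"p{i}": counts[i - 1] / counts.sum() for i in range(1, k + 1)})
        row.update({"chi2": gof.chi2, "df": gof.df, "p": gof.p})
        dist_rows.append(row)
    cue_distribution = pd.DataFrame(dist_rows)

    # zero-order correlations at participant level
    per_participant = (
        deltas_df.groupby("participant")
        .agg(n_cues=("n_cues", "mean"), d_bcpd=("d_bcpd", "mean"), d_ms_rate=("d_ms_rate", "mean"))
        .reset_index()
    )
    corr_rows = []
    for name, col in (("d_bcpd", "d_bcpd"), ("d_ms_rate", "d_ms_rate")):
        try:
            ct = pearson_with_t(per_participant["n_cues"], per_participant[col])
            corr_rows.append(
                {"measure": name, "r": ct.r, "n": ct.n, "df": ct.df, "t": ct.t, "p": ct.p}
            )
        except GazeValidationError as exc:
            log.warning("correlation for %s skipped: %s", name, exc)
    correlations = pd.DataFrame(corr_rows)

    # main sequence over all detected events
    events_df = pd.DataFrame(
        [
            {
                "participant": pid,
                "trial": tid,
                "epoch": e.epoch_id,
                "onset": e.onset_ms,
                "offset": e.offset_ms,
                "magnitude_deg": e.magnitude_deg,
                "peak_vel_dps": e.peak_velocity_dps,
            }
            for pid, tid, e in all_events
        ]
    )
    ms_fit = fit_main_sequence([e for _, _, e in all_events])
    timings["summaries"] = time.perf_counter() - t0

    # mixed models
    t0 = time.perf_counter()
    analysis_df = deltas_df.copy()
    if cfg.ms_rate_dv == "per_epoch":
        per_epoch = metrics_df.rename(columns={"epoch": "n_cues", "ms_rate": "rate"})
        rate_dv, rate_rows = "rate", per_epoch
    else:
        rate_dv, rate_rows = "d_ms_rate", analysis_df
    lmm_results: dict[str, LMMResult] = {}
    for dv in lmm_dvs:
        rows, name = (rate_rows, rate_dv) if dv == "d_ms_rate" else (analysis_df, dv)
        try:
            lmm_results[dv] = fit_lmm(rows, name)
        except Exception as exc:
            raise RuntimeError(f"stage lmm[{dv}] failed: {exc}") from exc
    timings["lmm"] = time.perf_counter() - t0
    for stage, sec in timings.items():
        log.info("stage %-10s %6.2f s", stage, sec)

    summary = {
        "n_participants": int(trials_df.participant.nunique()),
        "n_trials": int(len(trials_df)),
        "n_events": int(len(events_df)),
        "n_excluded_trials": n_excluded,
        "main_sequence": {
            "slope": ms_fit.slope,
            "intercept": ms_fit.intercept,
            "r_squared": ms_fit.r_squared,
            "n_events": ms_fit.n_events,
        },
        "correlations": corr_rows,
        "cue_distribution": dist_rows,
        "lmm": {
            dv: {
                "fixed_effects": [dataclasses.asdict(fe) for fe in res.fixed_effects],
                "var_participant": res.var_participant,
                "var_condition": res.var_condition,
                "var_residual": res.var_residual,
                "loglik": res.loglik,
                "lrt_chi2": res.lrt_chi2,
                "lrt_df": res.lrt_df,
                "lrt_p": res.lrt_p,
                "pseudo_r2_total": res.pseudo_r2_total,
                "n_obs": res.n_obs,
            }
            for dv, res in lmm_results.items()
        },
    }
    return ReportBundle(
        cue_distribution=cue_distribution,
        correlations=correlations,
        main_sequence=ms_fit,
        lmm=lmm_results,
        metrics=metrics_df,
        deltas=deltas_df,
        events=events_df,
        summary=summary,
    )


def _round_floats(obj, ndigits: int = 8):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def write_report(bundle: ReportBundle, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.cue_distribution.to_csv(out / "cue_distribution.csv", index=False)
    bundle.correlations.to_csv(out / "correlations.csv", index=False)
    pd.DataFrame([dataclasses.asdict(bundle.main_sequence)]).to_csv(
        out / "main_sequence.csv", index=False
    )
    for dv, res in bundle.lmm.items():
        pd.DataFrame([dataclasses.asdict(fe) for fe in res.fixed_effects]).to_csv(
            out / f"lmm_{dv}.csv", index=False
        )
    bundle.events.to_csv(out / "events.csv", index=False)
    bundle.metrics.to_csv(out / "metrics.csv", index=False)
    bundle.deltas.to_csv(out / "deltas.csv", index=False)
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(_round_floats(bundle.summary), fh, indent=2, sort_keys=True)
    return out


def save_truth(truth: GroundTruth, path: str | Path) -> Path:
    payload = {
        "baselines": truth.baselines,
        "events": {f"{pid}:{tid}": ev for (pid, tid), ev in truth.events.items()},
        "epoch_pupil_means": {
            f"{pid}:{tid}": m for (pid, tid), m in truth.epoch_pupil_means.items()
        },
        "epoch_rates": {f"{pid}:{tid}": r for (pid, tid), r in truth.epoch_rates.items()},
    }
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_round_floats(payload), fh, sort_keys=True)
    return path


def load_dataset_dir(data_dir: str | Path, cfg: PipelineConfig) -> ExperimentDataset:
    data_dir = Path(data_dir)
    recordings = read_samples(data_dir / "samples.csv", cfg.simulation.geometry)
    trials = read_trials(data_dir / "trials.csv")
    return ExperimentDataset(
        geometry=cfg.simulation.geometry,
        task=cfg.simulation.task,
        recordings=recordings,
        trials=trials,
    )


def run_pipeline(
    cfg: PipelineConfig,
    data_dir: str | Path | None = None,
    out_dir: str | Path | None = None,
) -> ReportBundle:
    """Full simulate/load -> report run.

    With ``data_dir`` the dataset is read from samples.csv/trials.csv there;
    otherwise it is simulated from ``cfg.simulation`` (seed included).
    """
    if data_dir is not None:
        ds = load_dataset_dir(data_dir, cfg)
    else:
        ds, _ = generate_dataset(cfg.simulation)
    bundle = analyze_dataset(ds, cfg)
    if out_dir is not None:
        write_report(bundle, out_dir)
    return bundle
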