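"""Cue-epoch segmentation and per-trial differential (delta) measures.

Each trial contributes one row per acquired cue (epoch metrics) and one
analysis row of last-minus-first differences. Single-cue trials are retained
with all deltas exactly 0 (last epoch = first epoch), so the analysis spans
the full 1..6 range of acquired cues.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gaze_io import GazeValidationError, TrialRecord
from .microsaccades import InsufficientDataError, Microsaccade, epoch_summaries
from .preprocess import CyclopeanSeries, slice_indices
from .pupillometry import PupilBaseline, PupilIndexConfig, bcpd, lhipa

__all__ = [
    "EpochMetrics",
    "DeltaMeasures",
    "segment_cue_epochs",
    "compute_epoch_metrics",
    "compute_deltas",
    "metrics_to_frame",
    "deltas_to_frame",
]

log = logging.getLogger(__name__)

MEASURES = ("bcpd", "lhipa", "ms_rate", "ms_magnitude")


@dataclass(frozen=True)
class EpochMetrics:
    participant_id: str
    condition: str
    trial_id: int
    epoch_index: int  # 1..n_cues
    bcpd: float
    lhipa: float
    ms_rate: float
    ms_magnitude: float

    def __post_init__(self) -> None:
        if not math.isnan(self.ms_rate) and self.ms_rate < 0:
            raise GazeValidationError("ms_rate must be >= 0")


@dataclass(frozen=True)
class DeltaMeasures:
    participant_id: str
    condition: str
    trial_id: int
    n_cues: int
    d_bcpd: float
    d_lhipa: float
    d_ms_rate: float
    d_ms_magnitude: float


def segment_cue_epochs(
    trial: TrialRecord, series: CyclopeanSeries
) -> list[tuple[slice, tuple[float, float]]]:
    """One (index slice, (onset, offset)) per acquired cue, in order.

    Raises a validation error naming the trial when an epoch boundary lies
    outside the recording span.
    """
    t = series.t
    t0, t1 = float(t[0]), float(t[-1])
    out = []
    for onset, offset in trial.cue_epochs:
        if onset < t0 - 1e-9 or offset > t1 + 1e-9:
            raise GazeValidationError(
                f"trial {trial.trial_id} of {trial.participant_id}: cue epoch "
                f"({onset}, {offset}) outside recording span ({t0}, {t1})"
            )
        out.append((slice_indices(t, onset, offset), (onset, offset)))
    return out


def compute_epoch_metrics(
    trial: TrialRecord,
    series: CyclopeanSeries,
    pupil_smooth: np.ndarray,
    events: list[Microsaccade],
    baseline: PupilBaseline,
    pupil_cfg: PupilIndexConfig = PupilIndexConfig(),
    dt_ms: float = 1.0,
    edge_guard_ms: float = 0.0,
    fixations: list | None = None,
) -> list[EpochMetrics]:
    """All four per-epoch measures for one trial.

    Metric failures (too few usable samples, too much missing) yield NaN in
    that cell, never a dropped row; missingness is data.

    ``edge_guard_ms`` trims that margin from both ends of the epoch before
    the BCPD mean is taken, so a centred pupil-smoothing window cannot leak
    the neighbouring epoch's level into the epoch mean; half the smoothing
    window is the natural choice.

    When ``fixations`` are given, the microsaccade rate divides by the
    fixation time overlapping each epoch (exposure correction) instead of
    the raw epoch duration, since events are only detectable within
    fixations.
    """
    rows = []
    t = series.t
    for k, (sl, (onset, offset)) in enumerate(segment_cue_epochs(trial, series), start=1):
        if edge_guard_ms > 0 and (offset - onset) > 4 * edge_guard_ms:
            gsl = slice_indices(t, onset + edge_guard_ms, offset - edge_guard_ms)
        else:
            gsl = sl
        b = bcpd(pupil_smooth[gsl], baseline)
        try:
            lh = lhipa(series.pupil[sl], dt_ms=dt_ms, cfg=pupil_cfg)
        except InsufficientDataError as exc:
            log.warning(
                "lhipa missing for trial %s/%s epoch %d: %s",
                trial.participant_id,
                trial.trial_id,
                k,
                exc,
            )
            lh = float("nan")
        usable = None
        if fixations is not None:
            usable = [
                sum(
                    max(0.0, min(fx.offset_ms, offset) - max(fx.onset_ms, onset))
                    for fx in fixations
                )
            ]
        (rate, mag), = epoch_summaries(events, [(onset, offset)], usable_ms=usable)
        rows.append(
            EpochMetrics(
                participant_id=trial.participant_id,
                condition=trial.condition,
                trial_id=trial.trial_id,
                epoch_index=k,
                bcpd=b,
                lhipa=lh,
                ms_rate=rate,
                ms_magnitude=mag,
            )
        )
    return rows


def compute_deltas(metrics: list[EpochMetrics]) -> list[DeltaMeasures]:
    """Last-epoch minus first-epoch difference of each measure, per trial.

    Single-cue trials have last = first, hence deltas of exactly 0; a delta
    is NaN when either endpoint metric is NaN.
    """
    by_trial: dict[tuple[str, int], list[EpochMetrics]] = {}
    for m in metrics:
        by_trial.setdefault((m.participant_id, m.trial_id), []).append(m)
    out = []
    for (pid, tid), rows in sorted(by_trial.items()):
        rows = sorted(rows, key=lambda r: r.epoch_index)
        first, last = rows[0], rows[-1]
        deltas = {}
        for name in MEASURES:
            a, b = getattr(first, name), getattr(last, name)
            deltas["d_" + name] = b - a  # NaN propagates
        out.append(
            DeltaMeasures(
                participant_id=pid,
                condition=first.condition,
                trial_id=tid,
                n_cues=len(rows),
                d_bcpd=deltas["d_bcpd"],
                d_lhipa=deltas["d_lhipa"],
                d_ms_rate=deltas["d_ms_rate"],
                d_ms_magnitude=deltas["d_ms_magnitude"],
            )
        )
    return out


def metrics_to_frame(metrics: list[EpochMetrics]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "participant": m.participant_id,
                "condition": m.condition,
                "trial": m.trial_id,
                "epoch": m.epoch_index,
                "bcpd": m.bcpd,
                "lhipa": m.lhipa,
                "ms_rate": m.ms_rate,
                "ms_magnitude": m.ms_magnitude,
            }
            for m in metrics
        ]
    )


def deltas_to_frame(deltas: list[DeltaMeasures]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "participant": d.participant_id,
                "condition": d.condition,
                "trial": d.trial_id,
                "n_cues": d.n_cues,
                "d_bcpd": d.d_bcpd,
                "d_lhipa": d.d_lhipa,
                "d_ms_rate": d.d_ms_rate,
                "d_ms_mag": d.d_ms_magnitude,
            }
            for d in deltas
        ]
    )
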