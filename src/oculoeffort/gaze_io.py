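"""Data model and delimited-text I/O for binocular gaze/pupil recordings.

Conventions used throughout the package (declared once, here):

* gaze coordinates are screen pixels, origin at the top-left corner, y axis
  pointing down;
* timestamps are milliseconds, strictly increasing within a trial, nominally
  sampled at 1 kHz;
* pupil size is in arbitrary tracker units; a recorded value of 0 is the
  closed-eye convention of common video trackers and is coerced to missing on
  input;
* missing samples are NaN, never sentinel values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "ScreenGeometry",
    "TaskSpec",
    "GazeRecording",
    "TrialRecord",
    "ExperimentDataset",
    "GazeFormatError",
    "GazeValidationError",
    "read_samples",
    "write_samples",
    "read_trials",
    "write_trials",
    "validate_dataset",
]

#: Allowed affective-priming condition labels (strict, lower-case).
CONDITIONS = ("neutral", "aversive", "erotic")

SAMPLE_COLUMNS = ["participant", "trial", "t", "xl", "yl", "xr", "yr", "pl", "pr"]
TRIAL_COLUMNS = [
    "participant",
    "condition",
    "trial",
    "is_training",
    "n_cues",
    "cue_onsets",
    "cue_offsets",
    "choice",
    "accuracy",
]


class GazeFormatError(ValueError):
    """Malformed interchange file (bad header, unparseable rows)."""


class GazeValidationError(ValueError):
    """Semantically invalid record (non-monotone time, bad labels, ...)."""


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical display setup needed for pixel -> visual-angle conversion.

    The pixel pitch must be (nearly) square; a mismatch above 5% between the
    horizontal and vertical cm/px raises a warning because downstream degree
    conversion treats the axes independently about the screen centre.
    """

    distance_cm: float
    screen_width_px: int
    screen_height_px: int
    screen_width_cm: float
    screen_height_cm: float

    def __post_init__(self) -> None:
        for name in (
            "distance_cm",
            "screen_width_px",
            "screen_height_px",
            "screen_width_cm",
            "screen_height_cm",
        ):
            if getattr(self, name) <= 0:
                raise GazeValidationError(f"ScreenGeometry.{name} must be > 0")
        px = self.pitch_x_cm
        py = self.pitch_y_cm
        if abs(px - py) / max(px, py) > 0.05:
            warnings.warn(
                "anisotropic pixel pitch: "
                f"{px:.5f} cm/px horizontal vs {py:.5f} cm/px vertical",
                stacklevel=2,
            )

    @property
    def pitch_x_cm(self) -> float:
        return self.screen_width_cm / self.screen_width_px

    @property
    def pitch_y_cm(self) -> float:
        return self.screen_height_cm / self.screen_height_px


@dataclass(frozen=True)
class TaskSpec:
    """Multi-attribute decision task structure.

    ``cue_validities`` are the conditional probabilities that each cue, when
    it discriminates, points at the correct alternative; they are presented to
    participants in strictly decreasing order, so the vector must be strictly
    decreasing with every entry in (0.5, 1).
    """

    n_cues_max: int = 6
    cue_validities: tuple[float, ...] = (0.706, 0.688, 0.667, 0.647, 0.625, 0.62)
    fixation_ms: int = 1000
    prime_ms: int = 3000
    first_cue_ms: int = 2000
    n_trials: int = 24
    n_training: int = 3

    def __post_init__(self) -> None:
        if self.n_cues_max != len(self.cue_validities):
            raise GazeValidationError("n_cues_max must equal len(cue_validities)")
        v = self.cue_validities
        if any(not (0.5 < x < 1.0) for x in v):
            raise GazeValidationError("cue validities must lie in (0.5, 1)")
        if any(a >= b for a, b in zip(v[1:], v[:-1])):
            raise GazeValidationError("cue validities must be strictly decreasing")
        for name in ("fixation_ms", "prime_ms", "first_cue_ms", "n_trials", "n_training"):
            if getattr(self, name) <= 0:
                raise GazeValidationError(f"TaskSpec.{name} must be > 0")


@dataclass
class GazeRecording:
    """One trial's binocular sample stream at a nominal 1 kHz."""

    participant_id: str
    trial_id: int
    t: np.ndarray
    xl: np.ndarray
    yl: np.ndarray
    xr: np.ndarray
    yr: np.ndarray
    pl: np.ndarray
    pr: np.ndarray

    def __post_init__(self) -> None:
        arrays = [self.t, self.xl, self.yl, self.xr, self.yr, self.pl, self.pr]
        n = len(self.t)
        if any(len(a) != n for a in arrays):
            raise GazeValidationError(
                f"trial {self.trial_id} of {self.participant_id}: channel lengths differ"
            )
        for name in ("t", "xl", "yl", "xr", "yr", "pl", "pr"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if n > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise GazeValidationError(
                    f"trial {self.trial_id} of {self.participant_id}: "
                    "timestamps not strictly increasing"
                )
            med = float(np.median(dt))
            if not (0.9 <= med <= 1.1):
                raise GazeValidationError(
                    f"trial {self.trial_id} of {self.participant_id}: median "
                    f"inter-sample interval {med:.3f} ms outside 1 ms +/- 10%"
                )
        # closed-eye convention: pupil 0 -> missing; negatives are invalid
        for name in ("pl", "pr"):
            p = getattr(self, name)
            p[p == 0] = np.nan
            if np.any(p[~np.isnan(p)] < 0):
                raise GazeValidationError(
                    f"trial {self.trial_id} of {self.participant_id}: negative pupil"
                )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration_ms(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) > 1 else 0.0


@dataclass
class TrialRecord:
    """Behavioral record of one decision trial."""

    participant_id: str
    condition: str
    trial_id: int
    is_training: bool
    cue_epochs: list[tuple[float, float]]
    n_cues: int
    choice: str
    accuracy: int

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise GazeValidationError(
                f"unknown condition {self.condition!r}; allowed: {list(CONDITIONS)}"
            )
        if not (1 <= self.n_cues <= 6):
            raise GazeValidationError(
                f"trial {self.trial_id} of {self.participant_id}: n_cues out of 1..6"
            )
        if self.n_cues != len(self.cue_epochs):
            raise GazeValidationError(
                f"trial {self.trial_id} of {self.participant_id}: "
                "n_cues != number of cue epochs"
            )
        prev_off = -np.inf
        for onset, offset in self.cue_epochs:
            if offset <= onset or onset < prev_off:
                raise GazeValidationError(
                    f"trial {self.trial_id} of {self.participant_id}: "
                    "cue epochs must be increasing and non-overlapping"
                )
            prev_off = offset
        if self.choice not in ("A", "B"):
            raise GazeValidationError("choice must be 'A' or 'B'")
        if self.accuracy not in (0, 1):
            raise GazeValidationError("accuracy must be 0 or 1")


@dataclass
class ExperimentDataset:
    """A full experiment: geometry + task + all recordings and trials."""

    geometry: ScreenGeometry
    task: TaskSpec
    recordings: list[GazeRecording] = field(default_factory=list)
    trials: list[TrialRecord] = field(default_factory=list)

    def recording_for(self, participant_id: str, trial_id: int) -> GazeRecording | None:
        for rec in self.recordings:
            if rec.participant_id == participant_id and rec.trial_id == trial_id:
                return rec
        return None


# ---------------------------------------------------------------------------
# Readers / writers (comma-delimited UTF-8, "." decimal, "NA" missing token)
# ---------------------------------------------------------------------------


def read_samples(path: str | Path, geometry: ScreenGeometry) -> list[GazeRecording]:
    """Read a samples.csv file into one GazeRecording per (participant, trial).

    Missing tokens (empty field or "NA") become NaN samples. Raises
    :class:`GazeFormatError` on a malformed header and
    :class:`GazeValidationError` (naming the trial) on non-monotone timestamps.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header = pd.read_csv(path, nrows=0)
    if list(header.columns) != SAMPLE_COLUMNS:
        raise GazeFormatError(
            f"{path}: expected header {SAMPLE_COLUMNS}, got {list(header.columns)}"
        )
    df = pd.read_csv(
        path,
        na_values=["NA"],
        keep_default_na=False,
        dtype={"participant": str},
    )
    recordings = []
    for (pid, trial), g in df.groupby(["participant", "trial"], sort=True):
        recordings.append(
            GazeRecording(
                participant_id=str(pid),
                trial_id=int(trial),
                t=g["t"].to_numpy(float),
                xl=g["xl"].to_numpy(float),
                yl=g["yl"].to_numpy(float),
                xr=g["xr"].to_numpy(float),
                yr=g["yr"].to_numpy(float),
                pl=g["pl"].to_numpy(float),
                pr=g["pr"].to_numpy(float),
            )
        )
    return recordings


def write_samples(recordings: Iterable[GazeRecording], path: str | Path) -> Path:
    """Write recordings to samples.csv (lossless numeric round trip)."""
    path = Path(path)
    frames = []
    for rec in recordings:
        frames.append(
            pd.DataFrame(
                {
                    "participant": rec.participant_id,
                    "trial": rec.trial_id,
                    "t": rec.t,
                    "xl": rec.xl,
                    "yl": rec.yl,
                    "xr": rec.xr,
                    "yr": rec.yr,
                    "pl": rec.pl,
                    "pr": rec.pr,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=SAMPLE_COLUMNS)
    df.to_csv(path, index=False, na_rep="NA", float_format="%.9g", encoding="utf-8")
    return path


def _join_epochs(values: Sequence[float]) -> str:
    return ";".join(str(int(round(v))) for v in values)


def read_trials(path: str | Path) -> list[TrialRecord]:
    """Read trials.csv into TrialRecord objects (strict condition vocabulary)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header = pd.read_csv(path, nrows=0)
    if list(header.columns) != TRIAL_COLUMNS:
        raise GazeFormatError(
            f"{path}: expected header {TRIAL_COLUMNS}, got {list(header.columns)}"
        )
    df = pd.read_csv(path, dtype={"participant": str, "cue_onsets": str, "cue_offsets": str})
    trials = []
    for row in df.itertuples(index=False):
        onsets = [float(x) for x in str(row.cue_onsets).split(";")]
        offsets = [float(x) for x in str(row.cue_offsets).split(";")]
        if len(onsets) != len(offsets):
            raise GazeFormatError(
                f"{path}: trial {row.trial} of {row.participant}: "
                "cue_onsets and cue_offsets length mismatch"
            )
        trials.append(
            TrialRecord(
                participant_id=str(row.participant),
                condition=str(row.condition),
                trial_id=int(row.trial),
                is_training=bool(row.is_training),
                cue_epochs=list(zip(onsets, offsets)),
                n_cues=int(row.n_cues),
                choice=str(row.choice),
                accuracy=int(row.accuracy),
            )
        )
    return trials


def write_trials(trials: Iterable[TrialRecord], path: str | Path) -> Path:
    """Write TrialRecords to trials.csv with ";"-joined epoch boundary lists."""
    path = Path(path)
    rows = []
    for tr in trials:
        rows.append(
            {
                "participant": tr.participant_id,
                "condition": tr.condition,
                "trial": tr.trial_id,
                "is_training": int(tr.is_training),
                "n_cues": tr.n_cues,
                "cue_onsets": _join_epochs([on for on, _ in tr.cue_epochs]),
                "cue_offsets": _join_epochs([off for _, off in tr.cue_epochs]),
                "choice": tr.choice,
                "accuracy": tr.accuracy,
            }
        )
    pd.DataFrame(rows, columns=TRIAL_COLUMNS).to_csv(path, index=False, encoding="utf-8")
    return path


def validate_dataset(ds: ExperimentDataset) -> list[str]:
    """Cross-record consistency report; empty list iff the dataset is sound.

    Checks: every trial has exactly one recording and vice versa (matched on
    participant/trial), and each participant appears in exactly one condition.
    """
    report: list[str] = []
    rec_keys = [(r.participant_id, r.trial_id) for r in ds.recordings]
    trial_keys = [(t.participant_id, t.trial_id) for t in ds.trials]
    rec_set, trial_set = set(rec_keys), set(trial_keys)
    if len(rec_keys) != len(rec_set):
        report.append("duplicate recordings present")
    if len(trial_keys) != len(trial_set):
        report.append("duplicate trials present")
    for pid, tid in sorted(trial_set - rec_set):
        report.append(f"orphan trial: no recording for participant {pid} trial {tid}")
    for pid, tid in sorted(rec_set - trial_set):
        report.append(f"orphan recording: no trial for participant {pid} trial {tid}")
    cond_by_pid: dict[str, set[str]] = {}
    for tr in ds.trials:
        cond_by_pid.setdefault(tr.participant_id, set()).add(tr.condition)
    for pid, conds in sorted(cond_by_pid.items()):
        if len(conds) > 1:
            report.append(
                f"condition conflict: participant {pid} appears in {sorted(conds)}"
            )
    return report
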