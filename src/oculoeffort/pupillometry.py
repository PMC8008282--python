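"""Task-evoked pupillometry: baseline, BCPD, and the LHIPA index.

BCPD (baseline / inter-trial change in pupil diameter) is the mean smoothed
pupil during a cue epoch minus a participant baseline taken from the training
trials; positive values mean dilation.

LHIPA (low/high index of pupillary activity) is the duration-normalized count
of thresholded modulus maxima of the ratio between low- and high-frequency
wavelet detail coefficients of the pupil signal. High-frequency pupillary
activity rises with cognitive effort, so LHIPA is expected to fall with
effort.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pywt

from .gaze_io import GazeValidationError
from .microsaccades import InsufficientDataError

__all__ = [
    "PupilBaseline",
    "PupilIndexConfig",
    "compute_baseline",
    "bcpd",
    "lhipa",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PupilBaseline:
    participant_id: str
    baseline_value: float
    n_samples_used: int

    def __post_init__(self) -> None:
        if not (self.baseline_value > 0):
            raise GazeValidationError("baseline must be > 0")
        if self.n_samples_used <= 0:
            raise GazeValidationError("baseline needs > 0 samples")


@dataclass(frozen=True)
class PupilIndexConfig:
    """LHIPA internals; every constant of the index in one place.

    * ``wavelet_name``: symlet of order 16 by default;
    * ``hf_level``: decomposition level of the high-frequency detail band;
    * the low-frequency band sits at half the maximal decomposition depth for
      the given slice length (rule, not a constant);
    * the universal threshold sigma_hat * sqrt(2 ln n) suppresses
      large-amplitude artifacts: maxima with |m| <= threshold survive.
    """

    wavelet_name: str = "sym16"
    hf_level: int = 1
    max_missing_fraction: float = 0.3

    def lf_level(self, n_samples: int) -> int:
        wavelet = pywt.Wavelet(self.wavelet_name)
        maxlevel = pywt.dwt_max_level(n_samples, filter_len=wavelet.dec_len)
        return maxlevel // 2


def compute_baseline(
    training_pupils: list[np.ndarray], participant_id: str
) -> PupilBaseline:
    """Pooled mean of smoothed, blink-masked pupil over all training trials.

    Pooling weights by sample (every usable sample counts once). Requires at
    least 100 usable samples overall.
    """
    values = [np.asarray(p, dtype=float) for p in training_pupils]
    pooled = np.concatenate(values) if values else np.array([])
    pooled = pooled[~np.isnan(pooled)]
    if len(pooled) < 100:
        raise InsufficientDataError(
            f"participant {participant_id}: only {len(pooled)} usable "
            "training pupil samples (need >= 100)"
        )
    return PupilBaseline(
        participant_id=participant_id,
        baseline_value=float(pooled.mean()),
        n_samples_used=int(len(pooled)),
    )


def bcpd(epoch_pupil: np.ndarray, baseline: PupilBaseline) -> float:
    """Mean smoothed epoch pupil minus baseline (positive = dilation).

    Returns NaN (with a logged warning) when fewer than 100 usable samples
    remain in the epoch.
    """
    p = np.asarray(epoch_pupil, dtype=float)
    p = p[~np.isnan(p)]
    if len(p) < 100:
        log.warning(
            "bcpd: epoch has %d usable samples (< 100) for participant %s; "
            "returning missing",
            len(p),
            baseline.participant_id,
        )
        return float("nan")
    return float(p.mean() - baseline.baseline_value)


def _interpolate_missing(p: np.ndarray) -> np.ndarray:
    """Linear interpolation over NaN runs (edges held at nearest value)."""
    p = np.asarray(p, dtype=float).copy()
    bad = np.isnan(p)
    if bad.all():
        raise InsufficientDataError("pupil slice entirely missing")
    if bad.any():
        idx = np.arange(len(p))
        p[bad] = np.interp(idx[bad], idx[~bad], p[~bad])
    return p


def _modulus_maxima(r: np.ndarray) -> np.ndarray:
    """Array of |r_i| at strict local maxima of |r|, zero elsewhere."""
    out = np.zeros_like(r)
    if len(r) < 3:
        return out
    a = np.abs(r)
    inner = (a[1:-1] > a[:-2]) & (a[1:-1] > a[2:])
    out[1:-1][inner] = a[1:-1][inner]
    return out


def lhipa(
    epoch_pupil: np.ndarray,
    dt_ms: float = 1.0,
    cfg: PupilIndexConfig = PupilIndexConfig(),
) -> float:
    """Low/High Index of Pupillary Activity of one epoch slice (1/s).

    Steps: wavelet decomposition (symlet-16 by default); detail coefficients
    at the high-frequency level and at half the maximal decomposition depth;
    amplitude normalization of each set by 2^(level/2); low/high ratio formed
    by pairing each low-frequency coefficient with the high-frequency
    coefficient at the same time position; modulus maxima of the ratio;
    universal threshold sigma_hat*sqrt(2 ln n) with a robust (median
    absolute deviation) sigma_hat in ratio units; count of maxima exceeding
    the threshold divided by slice duration in seconds.

    A maximum exceeding the threshold marks an instant where low-frequency
    pupillary activity dominates the high-frequency band. Cognitive effort
    raises high-frequency activity, which both depresses the ratio and
    regularizes its distribution, so the exceedance count -- and with it the
    index -- falls with effort.

    Missing samples are linearly interpolated first; a slice with more than
    ``max_missing_fraction`` missing, or too short for the two decomposition
    levels, raises :class:`InsufficientDataError`.
    """
    p = np.asarray(epoch_pupil, dtype=float)
    if len(p) == 0:
        raise InsufficientDataError("empty pupil slice")
    frac_missing = float(np.mean(np.isnan(p)))
    if frac_missing > cfg.max_missing_fraction:
        raise InsufficientDataError(
            f"pupil slice {frac_missing:.0%} missing exceeds "
            f"{cfg.max_missing_fraction:.0%}"
        )
    p = _interpolate_missing(p)

    lof = cfg.lf_level(len(p))
    hif = cfg.hf_level
    if lof <= hif:
        raise InsufficientDataError(
            f"slice of {len(p)} samples too short: low-frequency level {lof} "
            f"must exceed high-frequency level {hif}"
        )
    cd_h = pywt.downcoef("d", p, cfg.wavelet_name, mode="periodization", level=hif)
    cd_l = pywt.downcoef("d", p, cfg.wavelet_name, mode="periodization", level=lof)
    cd_h = cd_h / math.sqrt(2.0**hif)
    cd_l = cd_l / math.sqrt(2.0**lof)

    # align the sparser low-frequency coefficients onto the high-frequency
    # grid: LF coefficient i sits at HF index 2^(lof-hif) * i
    stride = 2 ** (lof - hif)
    idx = np.minimum(np.arange(len(cd_l)) * stride, len(cd_h) - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = cd_l / cd_h[idx]
    ratio[~np.isfinite(ratio)] = 0.0

    maxima = _modulus_maxima(ratio)
    n = len(maxima)
    if n == 0:
        return 0.0
    # robust sigma in ratio units: keeps the index invariant to rescaling
    # of the pupil signal (the ratio is self-normalized)
    sigma_hat = float(np.median(np.abs(ratio - np.median(ratio))) / 0.6745)
    lam = sigma_hat * math.sqrt(2.0 * math.log(n))
    surviving = maxima > lam
    duration_s = len(p) * dt_ms / 1000.0
    return float(np.count_nonzero(surviving) / duration_s)
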