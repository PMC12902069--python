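"""Pupil dilation-velocity peak detection.

A preprocessed trace is linearly interpolated over interior missing runs,
smoothed with a Savitzky-Golay filter (window 11 samples, order 3),
differentiated, and scanned for strict local maxima of the derivative
exceeding mean + 2.5 SD of the derivative over the analysed segment. A
non-maximal suppression pass (1500 ms) keeps only the strongest peak in any
suppression neighbourhood. Peak times are the moments of fastest dilation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .recording_model import PhaseWindow, PupilTrace
from .pupil_preprocessing import InsufficientDataError

logger = logging.getLogger("dyadsync")

__all__ = [
    "PeakConfig",
    "PeakTrain",
    "fill_and_smooth",
    "velocity",
    "detect_velocity_peaks",
    "detect_peaks_for_trace",
    "peaks_per_phase",
    "mean_pupil_size_per_phase",
]


@dataclass(frozen=True)
class PeakConfig:
    """Peak-detection parameters (field-standard defaults)."""

    sg_window: int = 11  # samples
    sg_order: int = 3
    threshold_sd: float = 2.5
    nms_interval: float = 1500.0  # ms
    #: the SD threshold is centred on the derivative mean by default; set to
    #: "zero" for a zero-centred threshold.
    threshold_center: str = "mean"

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_order:
            raise ValueError("sg_window must be odd and greater than sg_order")
        if self.threshold_sd <= 0:
            raise ValueError("threshold_sd must be positive")
        if self.nms_interval < 0:
            raise ValueError("nms_interval must be non-negative")
        if self.threshold_center not in ("mean", "zero"):
            raise ValueError("threshold_center must be 'mean' or 'zero'")


@dataclass
class PeakTrain:
    """Sorted dilation-velocity peak times (s) with their derivative values."""

    peak_times: np.ndarray
    peak_velocities: np.ndarray

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        self.peak_velocities = np.asarray(self.peak_velocities, dtype=float)

    def __len__(self) -> int:
        return len(self.peak_times)


def fill_and_smooth(trace: PupilTrace, config: PeakConfig = PeakConfig()) -> np.ndarray:
    """Linearly interpolate interior missing samples and Savitzky-Golay
    smooth; leading/trailing missing runs stay NaN (never extrapolated).

    Returns the smoothed diameter series aligned with ``trace.timestamps``.
    """
    valid = trace.valid
    n_valid = int(valid.sum())
    if n_valid < config.sg_window:
        raise InsufficientDataError(
            f"need >= {config.sg_window} valid samples to smooth, got {n_valid}"
        )
    t = trace.timestamps
    vidx = np.nonzero(valid)[0]
    lo, hi = int(vidx[0]), int(vidx[-1])
    filled = np.full(len(trace), np.nan)
    seg = slice(lo, hi + 1)
    filled[seg] = np.interp(t[seg], t[vidx], trace.diameter[vidx])
    filled[seg] = savgol_filter(filled[seg], config.sg_window, config.sg_order)
    return filled


def velocity(series: np.ndarray, timestamps: np.ndarray) -> np.ndarray:
    """First derivative (units/s): central differences on interior samples,
    one-sided at the segment ends, honouring actual sample spacing. NaN
    regions propagate."""
    series = np.asarray(series, dtype=float)
    finite = np.isfinite(series)
    out = np.full(len(series), np.nan)
    if finite.sum() < 2:
        return out
    idx = np.nonzero(finite)[0]
    lo, hi = int(idx[0]), int(idx[-1])
    seg = slice(lo, hi + 1)
    out[seg] = np.gradient(series[seg], timestamps[seg])
    return out


def detect_velocity_peaks(
    derivative: np.ndarray,
    timestamps: np.ndarray,
    config: PeakConfig = PeakConfig(),
) -> PeakTrain:
    """Threshold strict local maxima of the derivative and apply non-maximal
    suppression.

    Candidates are strict local maxima (a flat plateau contributes its
    midpoint) with value > centre + ``threshold_sd`` × SD of the derivative
    over the finite part of the segment. NMS processes candidates in
    descending derivative value and accepts a candidate only if it lies at
    least ``nms_interval`` ms from every already accepted peak.
    """
    derivative = np.asarray(derivative, dtype=float)
    finite = np.isfinite(derivative)
    if not finite.any():
        logger.warning("all-missing segment: no peaks detectable")
        return PeakTrain(np.empty(0), np.empty(0))
    center = float(np.mean(derivative[finite])) if config.threshold_center == "mean" else 0.0
    sd = float(np.std(derivative[finite]))
    threshold = center + config.threshold_sd * sd

    cand_idx = _strict_local_maxima(derivative)
    cand_idx = cand_idx[derivative[cand_idx] > threshold]
    if cand_idx.size == 0:
        return PeakTrain(np.empty(0), np.empty(0))

    # NMS: strongest first; ties resolve to the earlier sample (stable sort).
    order = cand_idx[np.argsort(-derivative[cand_idx], kind="stable")]
    min_sep = config.nms_interval / 1000.0
    accepted_times: list[float] = []
    accepted_idx: list[int] = []
    for i in order:
        t = timestamps[i]
        if all(abs(t - at) >= min_sep for at in accepted_times):
            accepted_times.append(float(t))
            accepted_idx.append(int(i))
    accepted = np.sort(np.asarray(accepted_idx, dtype=int))
    return PeakTrain(timestamps[accepted], derivative[accepted])


def _strict_local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima; a flat plateau that is higher than
    both neighbours contributes its midpoint sample."""
    n = len(x)
    if n < 3:
        return np.empty(0, dtype=int)
    out: list[int] = []
    i = 1
    while i < n - 1:
        if not np.isfinite(x[i]):
            i += 1
            continue
        if np.isfinite(x[i - 1]) and x[i] > x[i - 1]:
            j = i
            while j + 1 < n and np.isfinite(x[j + 1]) and x[j + 1] == x[i]:
                j += 1
            if j < n - 1 and np.isfinite(x[j + 1]) and x[j + 1] < x[i]:
                out.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    return np.asarray(out, dtype=int)


def detect_peaks_for_trace(
    trace: PupilTrace,
    config: PeakConfig = PeakConfig(),
) -> PeakTrain:
    """Fill, smooth, differentiate and detect peaks over one continuous
    segment (call per trial to scope the SD threshold per trial)."""
    smoothed = fill_and_smooth(trace, config)
    deriv = velocity(smoothed, trace.timestamps)
    return detect_velocity_peaks(deriv, trace.timestamps, config)


def peaks_per_phase(peaks: PeakTrain, window: PhaseWindow) -> int:
    """Number of peak times falling in [start, end)."""
    return int(np.count_nonzero((peaks.peak_times >= window.start) & (peaks.peak_times < window.end)))


def mean_pupil_size_per_phase(trace: PupilTrace, window: PhaseWindow) -> float:
    """Mean diameter over the phase's usable (valid or interpolated) samples;
    NaN with a warning when the phase holds no usable sample."""
    sel = (trace.timestamps >= window.start) & (trace.timestamps < window.end) & trace.valid
    if not sel.any():
        logger.warning("phase %s@%g: no usable samples for mean pupil size", window.label, window.start)
        return float("nan")
    return float(np.mean(trace.diameter[sel]))
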