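"""Hemodynamic-response quantification on ΔI traces.

Six per-trace descriptors: peak amplitude, area under the curve (composite
Simpson rule over the stimulus window), time to peak, response length,
full-width at half-maximum and time point of half-maximum.  Time to peak
and response length are computed on a zero-phase order-2 Butterworth
low-pass of the trace (nominal 1 Hz cutoff, clipped below Nyquist); the
other four metrics use the unfiltered ΔI trace.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import simpson, trapezoid
from scipy.signal import butter, filtfilt

from .core import RelativeTrace, TrialSet
from .errors import DegenerateBaselineError, ParameterError

log = logging.getLogger(__name__)

DEFAULT_LOWPASS_ORDER = 2
DEFAULT_LOWPASS_CUTOFF_HZ = 1.0
# The nominal 1 Hz cutoff exceeds the 0.833 Hz Nyquist at 0.6 s sampling;
# clip to 99% of Nyquist so the filter remains realizable.
NYQUIST_SAFETY = 0.99
DERIVATIVE_SD_FACTOR = 2.0


@dataclass(frozen=True)
class HRMetrics:
    """The six response descriptors; ``None`` marks an undefined metric."""

    ttp_s: Optional[float]
    rl_s: Optional[float]
    peak_percent: float
    auc_au: float
    fwhm_s: Optional[float]
    tphm_s: Optional[float]


def to_relative(trace: np.ndarray, ts: TrialSet) -> RelativeTrace:
    """Convert a raw intensity trace to ΔI in percent of the baseline mean.

    ΔI[f] = 100 · (I[f] − mean(I over baseline)) / mean(I over baseline),
    with the baseline window being every frame before stimulus onset.

    Raises
    ------
    DegenerateBaselineError
        If the baseline mean is nonpositive (the voxel carries no signal).
    """
    trace = np.asarray(trace, dtype=float)
    onset = ts.stimulus_onset_frame
    if onset < 2:
        raise ParameterError("baseline window must contain at least 2 frames")
    base = float(trace[:onset].mean())
    if base <= 0:
        raise DegenerateBaselineError(f"baseline mean {base} is nonpositive")
    return RelativeTrace(values=100.0 * (trace - base) / base, time_s=ts.frame_times_s)


def to_relative_map(averaged: np.ndarray, ts: TrialSet) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized ΔI conversion of a ``(nz, nx, n_frames)`` volume.

    Degenerate voxels (nonpositive baseline mean) are flagged instead of
    raising: their traces are NaN and they are reported in the returned
    boolean mask.
    """
    averaged = np.asarray(averaged, dtype=float)
    onset = ts.stimulus_onset_frame
    base = averaged[:, :, :onset].mean(axis=2)
    degenerate = base <= 0
    if np.any(degenerate):
        log.warning("%d degenerate voxel(s) with nonpositive baseline flagged",
                    int(degenerate.sum()))
    safe = np.where(degenerate, np.nan, base)
    rel = 100.0 * (averaged - safe[:, :, None]) / safe[:, :, None]
    return rel, degenerate


def effective_cutoff_hz(frame_interval_s: float,
                        cutoff_hz: float = DEFAULT_LOWPASS_CUTOFF_HZ) -> float:
    nyquist = 0.5 / frame_interval_s
    eff = min(cutoff_hz, NYQUIST_SAFETY * nyquist)
    if eff < cutoff_hz:
        log.warning("low-pass cutoff clipped from %.3f Hz to %.3f Hz (Nyquist %.3f Hz)",
                    cutoff_hz, eff, nyquist)
    return eff


def lowpass(trace: RelativeTrace, frame_interval_s: float,
            order: int = DEFAULT_LOWPASS_ORDER,
            cutoff_hz: float = DEFAULT_LOWPASS_CUTOFF_HZ) -> RelativeTrace:
    """Zero-phase Butterworth low-pass (forward-backward, DC gain 1)."""
    fs = 1.0 / frame_interval_s
    eff = effective_cutoff_hz(frame_interval_s, cutoff_hz)
    b, a = butter(order, eff, fs=fs)
    padlen = 3 * max(len(a), len(b))  # scipy filtfilt default
    if len(trace.values) <= padlen:
        raise ParameterError(
            f"trace of length {len(trace.values)} too short for filtfilt padding {padlen}"
        )
    return RelativeTrace(values=filtfilt(b, a, trace.values), time_s=trace.time_s)


def _window(trace: RelativeTrace, onset: int, offset: int) -> np.ndarray:
    if not (0 <= onset < offset <= len(trace.values)):
        raise ParameterError(f"invalid stimulus window [{onset}, {offset})")
    return trace.values[onset:offset]


def peak_amplitude(trace: RelativeTrace, onset: int, offset: int) -> float:
    """Maximum ΔI over the half-open stimulus window [onset, offset)."""
    return float(_window(trace, onset, offset).max())


def auc(trace: RelativeTrace, onset: int, offset: int,
        frame_interval_s: float) -> float:
    """Composite-Simpson integral of ΔI over the stimulus window.

    Falls back to the trapezoid rule (with a warning) when the window has
    fewer than 3 frames.
    """
    w = _window(trace, onset, offset)
    if len(w) < 3:
        warnings.warn("stimulus window has <3 frames; AUC falls back to trapezoid",
                      stacklevel=2)
        return float(trapezoid(w, dx=frame_interval_s))
    return float(simpson(w, dx=frame_interval_s))


def time_to_peak(trace: RelativeTrace, onset: int,
                 frame_interval_s: float,
                 sd_factor: float = DERIVATIVE_SD_FACTOR) -> Optional[float]:
    """Time of the first significant post-onset change in the derivative.

    The first difference d[f] = x[f] − x[f−1] is compared against
    mean + ``sd_factor``·SD of the baseline-window first differences; the
    first frame at time ≥ 0 exceeding that threshold gives the TTP.
    Expects an already low-pass-filtered trace.  Returns ``None`` when the
    threshold is never exceeded.
    """
    x = trace.values
    d = np.diff(x)  # d[f-1] is the change into frame f
    base_d = d[: onset - 1]  # differences fully inside the baseline window
    if len(base_d) < 1:
        raise ParameterError("baseline window too short for a derivative baseline")
    thr = float(base_d.mean() + sd_factor * base_d.std())
    post = d[onset - 1:]  # changes into frames onset, onset+1, ...
    above = np.nonzero(post > thr)[0]
    if len(above) == 0:
        return None
    return float(above[0] * frame_interval_s)


def response_length(trace: RelativeTrace, onset: int,
                    frame_interval_s: float) -> Optional[float]:
    """End time of the longest post-onset run of negative derivatives.

    Runs of strictly negative first differences at frames ≥ onset are
    found; the longest (ties resolved to the latest) ends the response,
    and its last frame's time from onset is returned.  Expects an already
    filtered trace; ``None`` when no negative difference exists.
    """
    x = trace.values
    d = np.diff(x)
    start = max(onset, 1)  # neg[i] is the change into frame start + i
    neg = d[start - 1:] < 0
    best_len, best_end = 0, -1
    run = 0
    for i, flag in enumerate(neg):
        run = run + 1 if flag else 0
        if flag and run >= best_len:  # >= : ties go to the latest run
            best_len, best_end = run, i
    if best_len == 0:
        return None
    return float((start - onset + best_end) * frame_interval_s)


def _half_max(trace: RelativeTrace, onset: int, offset: int) -> Optional[float]:
    peak = peak_amplitude(trace, onset, offset)
    if peak <= 0:
        return None
    return peak / 2.0


def fwhm(trace: RelativeTrace, onset: int, offset: int,
         frame_interval_s: float) -> Optional[float]:
    """Duration of the longest post-onset run of values above half-peak.

    Half-maximum is half the in-window peak; run membership requires the
    value to be strictly greater than it.  Length = frame count × frame
    interval.  ``None`` when the peak is nonpositive.
    """
    half = _half_max(trace, onset, offset)
    if half is None:
        return None
    above = trace.values[onset:] > half
    best, run = 0, 0
    for flag in above:
        run = run + 1 if flag else 0
        best = max(best, run)
    return float(best * frame_interval_s)


def tphm(trace: RelativeTrace, onset: int, offset: int,
         frame_interval_s: float) -> Optional[float]:
    """Time from onset of the first frame strictly above half-peak."""
    half = _half_max(trace, onset, offset)
    if half is None:
        return None
    above = np.nonzero(trace.values[onset:] > half)[0]
    if len(above) == 0:
        return None
    return float(above[0] * frame_interval_s)


def compute_all(trace: RelativeTrace, ts: TrialSet,
                filter_all: bool = False) -> HRMetrics:
    """All six metrics of one ΔI trace.

    The low-pass prefilter is applied only for TTP and RL; pass
    ``filter_all=True`` to filter every metric's input instead.
    """
    onset, offset = ts.stimulus_onset_frame, ts.stimulus_offset_frame
    dt = ts.frame_interval_s
    smoothed = lowpass(trace, dt)
    amp_trace = smoothed if filter_all else trace
    return HRMetrics(
        ttp_s=time_to_peak(smoothed, onset, dt),
        rl_s=response_length(smoothed, onset, dt),
        peak_percent=peak_amplitude(amp_trace, onset, offset),
        auc_au=auc(amp_trace, onset, offset, dt),
        fwhm_s=fwhm(amp_trace, onset, offset, dt),
        tphm_s=tphm(amp_trace, onset, offset, dt),
    )
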