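"""Stimulus-correlation mapping and threshold-based activation analysis.

Each voxel's trial-averaged ΔI trace is correlated with a boxcar regressor
replicating the stimulus on/off pattern.  The resulting Pearson map is
binarized at a critical value derived from the Fisher z-transform (a
one-sided test of positive correlation), yielding an active-voxel mask
from which per-region active fractions and active-area mean traces are
extracted.  Active areas covering less than ``min_fraction`` of a region
are excluded from trace extraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import ndtri

from .core import RegionLabelMap, RelativeTrace, TrialSet, select_region
from .errors import EmptyRegionError, ParameterError, ShapeError

log = logging.getLogger(__name__)

#: Default exclusion rule: active areas below 1% of a structure are dropped.
DEFAULT_MIN_FRACTION = 0.01


@dataclass(frozen=True)
class CorrelationResult:
    """Per-voxel Pearson map with its binarization provenance."""

    r_map: np.ndarray  # NaN where the voxel trace has zero variance
    n_samples: int
    threshold: Optional[float] = None
    alpha: Optional[float] = None
    active_mask: Optional[np.ndarray] = None

    def binarize(self, threshold: float, alpha: Optional[float] = None
                 ) -> "CorrelationResult":
        """Return a copy with ``active_mask = r_map > threshold``.

        Undefined (NaN) correlations count as inactive.
        """
        with np.errstate(invalid="ignore"):
            mask = self.r_map > threshold
        return CorrelationResult(
            r_map=self.r_map, n_samples=self.n_samples,
            threshold=float(threshold), alpha=alpha, active_mask=mask,
        )


def stimulus_regressor(ts: TrialSet) -> np.ndarray:
    """0/1 boxcar replicating the stimulus: 1 on [onset, offset), else 0."""
    onset, offset = ts.stimulus_onset_frame, ts.stimulus_offset_frame
    if not (0 <= onset < offset <= ts.n_frames):
        raise ParameterError(f"degenerate stimulus window [{onset}, {offset})")
    box = np.zeros(ts.n_frames)
    box[onset:offset] = 1.0
    return box


def pearson_map(traces: np.ndarray, regressor: np.ndarray) -> CorrelationResult:
    """Pearson correlation of each voxel trace with the regressor.

    ``traces`` has shape ``(nz, nx, n_frames)``.  Voxels whose trace has
    zero variance (or contains NaN) get an undefined (NaN) coefficient and
    are logged.
    """
    traces = np.asarray(traces, dtype=float)
    regressor = np.asarray(regressor, dtype=float)
    if traces.shape[-1] != len(regressor):
        raise ShapeError(
            f"trace length {traces.shape[-1]} != regressor length {len(regressor)}")
    x = traces - traces.mean(axis=-1, keepdims=True)
    y = regressor - regressor.mean()
    sy = float(np.sqrt((y ** 2).sum()))
    if sy == 0:
        raise ParameterError("regressor has zero variance")
    sx = np.sqrt((x ** 2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (x @ y) / (sx * sy)
    undefined = ~np.isfinite(r)
    if np.any(undefined):
        log.warning("%d voxel(s) with undefined correlation (zero variance or NaN)",
                    int(undefined.sum()))
        r = np.where(undefined, np.nan, r)
    return CorrelationResult(r_map=r, n_samples=len(regressor))


def fisher_threshold(alpha: float, n_samples: int) -> float:
    """Critical Pearson r for a one-sided positive-correlation test.

    r* = tanh(z_{1-alpha} / sqrt(n - 3)) via the Fisher z-transform.
    At alpha=0.01 and n=50 this evaluates to 0.327 (3 decimals).
    """
    if n_samples <= 3:
        raise ParameterError("Fisher threshold requires n_samples > 3")
    if not 0 < alpha < 1:
        raise ParameterError("alpha must lie in (0, 1)")
    return float(np.tanh(ndtri(1.0 - alpha) / np.sqrt(n_samples - 3)))


def correlate(traces: np.ndarray, ts: TrialSet, alpha: float = 0.01,
              threshold: Optional[float] = None) -> CorrelationResult:
    """Pearson map + binarization in one step.

    The threshold defaults to the alpha-derived Fisher critical value but
    a literal threshold (e.g. a printed 0.327) may be passed instead.
    """
    result = pearson_map(traces, stimulus_regressor(ts))
    if threshold is None:
        threshold = fisher_threshold(alpha, result.n_samples)
    return result.binarize(threshold, alpha=alpha)


def active_fraction(result: CorrelationResult, labels: RegionLabelMap,
                    acronym: str) -> float:
    """Share of a region's voxels whose correlation exceeds the threshold."""
    if result.active_mask is None:
        raise ParameterError("CorrelationResult has not been binarized")
    coords = select_region(labels, acronym)
    if not coords:
        raise EmptyRegionError(f"region {acronym!r} has no voxels")
    zz = np.array([c[0] for c in coords])
    xx = np.array([c[1] for c in coords])
    return float(result.active_mask[zz, xx].mean())


def active_region_trace(
    rel_traces: np.ndarray,
    result: CorrelationResult,
    labels: RegionLabelMap,
    acronym: str,
    ts: TrialSet,
    min_fraction: float = DEFAULT_MIN_FRACTION,
) -> Optional[RelativeTrace]:
    """Mean ΔI trace over a region's active voxels.

    Returns ``None`` (the region is excluded) when the active fraction is
    below ``min_fraction``.  ``rel_traces`` is the ``(nz, nx, n_frames)``
    ΔI volume the correlation was computed on.
    """
    frac = active_fraction(result, labels, acronym)
    if frac < min_fraction:
        log.info("region %s excluded: active fraction %.4f < %.4f",
                 acronym, frac, min_fraction)
        return None
    coords = select_region(labels, acronym)
    zz = np.array([c[0] for c in coords])
    xx = np.array([c[1] for c in coords])
    active = result.active_mask[zz, xx]
    values = rel_traces[zz[active], xx[active], :].mean(axis=0)
    return RelativeTrace(values=values, time_s=ts.frame_times_s)
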