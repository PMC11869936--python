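"""Region-based averaging: one mean ΔI trace per region and contrast, and
contrast-response curves of peak amplitude across subjects.

Averaging happens on ΔI traces rather than raw intensity so that voxels
with a large baseline do not dominate the regional mean; degenerate voxels
(nonpositive baseline) are excluded with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import RegionLabelMap, RelativeTrace, TrialSet, trial_average, select_region
from .errors import EmptyRegionError
from . import hrmetrics

log = logging.getLogger(__name__)

CI95_Z = 1.96


@dataclass(frozen=True)
class ContrastResponseCurve:
    """Peak amplitude vs luminance contrast, summarized across subjects."""

    region: str
    contrasts: tuple[float, ...]
    mean_peak: np.ndarray
    sd_peak: np.ndarray
    ci95_halfwidth: np.ndarray  # NaN when a single subject makes the CI undefined
    n_subjects: int


def region_trace(ts: TrialSet, labels: RegionLabelMap, acronym: str,
                 condition: float) -> RelativeTrace:
    """Unweighted mean ΔI trace over all voxels of one region.

    Trials of ``condition`` are averaged first, each voxel is converted to
    ΔI%, and the region's voxel traces are averaged framewise.
    """
    coords = select_region(labels, acronym)
    if not coords:
        raise EmptyRegionError(f"region {acronym!r} has no voxels")
    averaged = trial_average(ts, condition)
    rel, degenerate = hrmetrics.to_relative_map(averaged, ts)
    zz = np.array([c[0] for c in coords])
    xx = np.array([c[1] for c in coords])
    good = ~degenerate[zz, xx]
    if not good.any():
        raise EmptyRegionError(f"region {acronym!r} has only degenerate voxels")
    if not good.all():
        log.warning("region %s: %d degenerate voxel(s) excluded from the mean",
                    acronym, int((~good).sum()))
    values = rel[zz[good], xx[good], :].mean(axis=0)
    return RelativeTrace(values=values, time_s=ts.frame_times_s)


def contrast_response(
    subject_traces: Sequence[dict[float, RelativeTrace]],
    ts: TrialSet,
    region: str = "",
) -> ContrastResponseCurve:
    """Contrast-response curve from per-subject region traces.

    ``subject_traces`` maps, for each subject, contrast -> region ΔI trace.
    Per contrast the in-stimulus peak amplitude of each subject's trace is
    taken, then mean, SD (ddof=1) and a normal-approximation 95% CI
    half-width (1.96·SD/√n) across subjects.  With a single subject the
    dispersion is undefined and returned as NaN.
    """
    if len(subject_traces) < 1:
        raise EmptyRegionError("at least one subject is required")
    contrasts = ts.conditions
    onset, offset = ts.stimulus_onset_frame, ts.stimulus_offset_frame
    peaks = np.array([
        [hrmetrics.peak_amplitude(traces[c], onset, offset) for c in contrasts]
        for traces in subject_traces
    ])  # (n_subjects, n_contrasts)
    n = peaks.shape[0]
    mean = peaks.mean(axis=0)
    if n > 1:
        sd = peaks.std(axis=0, ddof=1)
        ci = CI95_Z * sd / np.sqrt(n)
    else:
        log.warning("single subject: SD and 95%% CI undefined")
        sd = np.full(len(contrasts), np.nan)
        ci = np.full(len(contrasts), np.nan)
    return ContrastResponseCurve(
        region=region, contrasts=contrasts, mean_peak=mean,
        sd_peak=sd, ci95_halfwidth=ci, n_subjects=n,
    )
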