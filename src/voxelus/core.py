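"""Data model and I/O for µDoppler trial data and region label maps.

The central container is :class:`TrialSet`: a 5-D nonnegative intensity
array indexed ``(voxel_z, voxel_x, frame, trial, condition)`` together with
the trial timing (frame interval, baseline / stimulus / post durations) and
the ordered list of contrast conditions.  A :class:`RegionLabelMap` carries
per-voxel integer region identifiers with an acronym lookup, standing in
for the output of an atlas registration step performed upstream.

Storage format: one HDF5 file per subject holding a single ``intensity``
dataset, with a JSON sidecar for the timing metadata; label maps as 2-D
integer TIFF plus a ``label,acronym`` CSV.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
import tifffile

from .errors import (
    EmptyRegionError,
    LookupError_,
    SchemaError,
    ValidationError,
)

SIDECAR_FIELDS = (
    "frame_interval_s",
    "baseline_s",
    "stimulus_s",
    "post_s",
    "conditions",
    "subject_id",
)


def n_frames_for(baseline_s: float, stimulus_s: float, post_s: float,
                 frame_interval_s: float) -> int:
    """Frame count of one trial: round(total duration / frame interval)."""
    return int(round((baseline_s + stimulus_s + post_s) / frame_interval_s))


@dataclass(frozen=True)
class TrialSet:
    """4-D µDoppler intensity data for one subject plus timing metadata.

    Parameters
    ----------
    intensity
        Nonnegative array of shape ``(nz, nx, n_frames, n_trials,
        n_conditions)`` in arbitrary power-Doppler units.
    frame_interval_s
        Sampling interval in seconds (default 0.6).
    baseline_s, stimulus_s, post_s
        Trial phase durations in seconds (defaults 10, 4, 20).
    conditions
        Strictly increasing luminance-contrast percentages in (0, 100].
    subject_id
        Opaque subject identifier.
    """

    intensity: np.ndarray
    frame_interval_s: float = 0.6
    baseline_s: float = 10.0
    stimulus_s: float = 4.0
    post_s: float = 20.0
    conditions: tuple[float, ...] = ()
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "intensity", arr)
        object.__setattr__(self, "conditions", tuple(float(c) for c in self.conditions))
        if arr.ndim != 5:
            raise ValidationError(
                f"intensity must be 5-D (z, x, frame, trial, condition); got {arr.ndim}-D"
            )
        if self.frame_interval_s <= 0:
            raise ValidationError("frame_interval_s must be positive")
        for name in ("baseline_s", "stimulus_s", "post_s"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative")
        expected = n_frames_for(self.baseline_s, self.stimulus_s, self.post_s,
                                self.frame_interval_s)
        if expected < 3:
            raise ValidationError("trial must span at least 3 frames")
        if arr.shape[2] != expected:
            raise ValidationError(
                f"intensity has {arr.shape[2]} frames; timing implies {expected}"
            )
        if arr.shape[4] != len(self.conditions):
            raise ValidationError(
                f"intensity has {arr.shape[4]} conditions; sidecar lists {len(self.conditions)}"
            )
        conds = np.asarray(self.conditions)
        if len(conds) and (np.any(conds <= 0) or np.any(conds > 100)):
            raise ValidationError("conditions must lie in (0, 100]")
        if np.any(np.diff(conds) <= 0):
            raise ValidationError("conditions must be strictly increasing")
        bad = ~np.isfinite(arr) | (arr < 0)
        if np.any(bad):
            idx = tuple(int(i) for i in np.argwhere(bad)[0])
            raise ValidationError(
                f"intensity must be finite and >= 0; first offender at index {idx}"
            )
        if not (0 <= self.stimulus_onset_frame < self.stimulus_offset_frame
                <= self.n_frames) and self.stimulus_s > 0:
            raise ValidationError("stimulus window does not fit inside the trial")

    # -- derived timing ----------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.intensity.shape[2]

    @property
    def n_trials(self) -> int:
        return self.intensity.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.intensity.shape[:2]

    @property
    def stimulus_onset_frame(self) -> int:
        """First stimulated frame; window is half-open [onset, offset)."""
        return int(np.floor(self.baseline_s / self.frame_interval_s))

    @property
    def stimulus_offset_frame(self) -> int:
        return int(np.floor((self.baseline_s + self.stimulus_s) / self.frame_interval_s))

    @property
    def frame_times_s(self) -> np.ndarray:
        """Frame times in seconds relative to stimulus onset (onset = 0 s)."""
        return (np.arange(self.n_frames) - self.stimulus_onset_frame) * self.frame_interval_s

    def condition_index(self, condition: float) -> int:
        try:
            return self.conditions.index(float(condition))
        except ValueError:
            raise LookupError_(
                f"condition {condition} not in {self.conditions}"
            ) from None


@dataclass(frozen=True)
class RegionLabelMap:
    """Per-voxel integer region labels (0 = unassigned) with acronym lookup."""

    labels: np.ndarray
    lookup: Mapping[int, str]

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValidationError("labels must be an integer array")
        if arr.ndim != 2:
            raise ValidationError("labels must be 2-D (z, x)")
        object.__setattr__(self, "labels", arr)
        object.__setattr__(self, "lookup", dict(self.lookup))
        present = set(np.unique(arr).tolist()) - {0}
        missing = present - set(self.lookup)
        if missing:
            raise ValidationError(f"labels {sorted(missing)} missing from lookup")

    def label_for(self, acronym: str) -> int:
        for lbl, acr in self.lookup.items():
            if acr == acronym:
                return int(lbl)
        raise LookupError_(f"acronym {acronym!r} not in lookup")

    @property
    def acronyms(self) -> tuple[str, ...]:
        return tuple(self.lookup.values())


@dataclass(frozen=True)
class RelativeTrace:
    """A ΔI trace in percent with frame times relative to stimulus onset."""

    values: np.ndarray
    time_s: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        t = np.asarray(self.time_s, dtype=float)
        if v.shape != t.shape or v.ndim != 1:
            raise ValidationError("values and time_s must be equal-length 1-D vectors")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "time_s", t)

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# I/O


def save_trialset(ts: TrialSet, path: Path | str) -> Path:
    """Write ``<path>.h5`` (dataset ``intensity``) and ``<path>.json`` sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    h5 = path.with_suffix(".h5")
    with h5py.File(h5, "w") as f:
        f.create_dataset("intensity", data=ts.intensity)
        f["intensity"].attrs["dims"] = "voxel_z,voxel_x,frame,trial,condition"
    sidecar = {
        "frame_interval_s": ts.frame_interval_s,
        "baseline_s": ts.baseline_s,
        "stimulus_s": ts.stimulus_s,
        "post_s": ts.post_s,
        "conditions": list(ts.conditions),
        "subject_id": ts.subject_id,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return h5


def load_trialset(path: Path | str) -> TrialSet:
    """Load a TrialSet from an HDF5 container + JSON sidecar.

    ``path`` may point at the ``.h5``, the ``.json``, or the common stem.
    All TrialSet invariants are re-checked on load.
    """
    path = Path(path)
    stem = path.with_suffix("")
    h5, sidecar_path = stem.with_suffix(".h5"), stem.with_suffix(".json")
    if not h5.exists():
        raise SchemaError(f"array container not found: {h5}")
    if not sidecar_path.exists():
        raise SchemaError(f"JSON sidecar not found: {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    missing = [k for k in SIDECAR_FIELDS if k not in meta]
    if missing:
        raise SchemaError(f"sidecar missing required fields: {missing}")
    with h5py.File(h5, "r") as f:
        if "intensity" not in f:
            raise SchemaError("HDF5 container lacks an 'intensity' dataset")
        intensity = f["intensity"][()]
    return TrialSet(
        intensity=intensity,
        frame_interval_s=float(meta["frame_interval_s"]),
        baseline_s=float(meta["baseline_s"]),
        stimulus_s=float(meta["stimulus_s"]),
        post_s=float(meta["post_s"]),
        conditions=tuple(float(c) for c in meta["conditions"]),
        subject_id=str(meta["subject_id"]),
    )


def save_labelmap(lm: RegionLabelMap, path: Path | str) -> Path:
    """Write ``<path>.tiff`` (int32 labels) and ``<path>.csv`` lookup."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tiff = path.with_suffix(".tiff")
    tifffile.imwrite(tiff, lm.labels.astype(np.int32))
    with path.with_suffix(".csv").open("w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["label", "acronym"])
        for lbl, acr in sorted(lm.lookup.items()):
            w.writerow([lbl, acr])
    return tiff


def load_labelmap(path: Path | str) -> RegionLabelMap:
    path = Path(path)
    stem = path.with_suffix("")
    tiff, lut = stem.with_suffix(".tiff"), stem.with_suffix(".csv")
    if not tiff.exists():
        raise SchemaError(f"label image not found: {tiff}")
    if not lut.exists():
        raise SchemaError(f"lookup CSV not found: {lut}")
    labels = tifffile.imread(tiff)
    lookup: dict[int, str] = {}
    with lut.open() as f:
        for row in csv.DictReader(f):
            lookup[int(row["label"])] = row["acronym"]
    return RegionLabelMap(labels=labels, lookup=lookup)


# ---------------------------------------------------------------------------
# Shared operations


def trial_average(ts: TrialSet, condition: float) -> np.ndarray:
    """Mean raw-intensity trace over trials of one condition.

    Returns an array of shape ``(nz, nx, n_frames)``.
    """
    ci = ts.condition_index(condition)
    return ts.intensity[:, :, :, :, ci].mean(axis=3)


def select_region(labels: RegionLabelMap, acronym: str) -> list[tuple[int, int]]:
    """Row-major (z, x) coordinates of voxels carrying ``acronym``'s label."""
    target = labels.label_for(acronym)
    zz, xx = np.nonzero(labels.labels == target)
    return [(int(z), int(x)) for z, x in zip(zz, xx)]


def dedup_traces(traces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Remove exactly duplicated rows, keeping a back-index.

    Nearest-neighbor upsampling onto a finer grid copies voxel traces
    verbatim; fitting on those copies would overweight them, so exact
    duplicates are dropped before model fitting and restored afterwards
    through the back-index.

    Parameters
    ----------
    traces
        Array of shape ``(n_samples, n_frames)``.

    Returns
    -------
    unique : ``(n_unique, n_frames)`` array, first occurrences in original order.
    back_index : ``(n_samples,)`` int array with ``unique[back_index[i]] == traces[i]``.
    """
    traces = np.asarray(traces)
    if traces.size == 0:
        return traces.reshape(0, traces.shape[-1] if traces.ndim == 2 else 0), \
            np.zeros(0, dtype=np.intp)
    _, first_idx, inverse = np.unique(
        traces, axis=0, return_index=True, return_inverse=True
    )
    # np.unique sorts; remap to first-occurrence order for determinism.
    order = np.argsort(first_idx, kind="stable")
    unique = traces[np.sort(first_idx)]
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    return unique, rank[inverse]


def region_voxel_traces(
    averaged: np.ndarray, labels: RegionLabelMap, acronym: str
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Stack the per-voxel traces of one region from a trial-averaged volume.

    ``averaged`` has shape ``(nz, nx, n_frames)``; returns ``(n_voxels,
    n_frames)`` in the deterministic ordering of :func:`select_region`.
    """
    coords = select_region(labels, acronym)
    if not coords:
        raise EmptyRegionError(f"region {acronym!r} has no voxels")
    zz = np.array([c[0] for c in coords])
    xx = np.array([c[1] for c in coords])
    return averaged[zz, xx, :], coords
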