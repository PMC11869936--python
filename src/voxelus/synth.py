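"""Synthetic µDoppler trial generator with planted ground truth.

Produces :class:`~voxelus.core.TrialSet` instances whose statistical
structure matches what the downstream analyses assume: horizontal layer
bands (superficial / intermediate / deep plus background), spatially
contiguous response classes of strictly increasing amplitude, a saturating
contrast-response function, and a trial/frame noise model whose recovery
behavior is analyzable.

Signal model per voxel, frame, trial and condition::

    I = baseline_mean * ( gain_trial * (1 + dI/100) + eps_frame/100 )

with ``gain_trial`` lognormal around 1 (multiplicative per-trial gain) and
``eps_frame`` Gaussian with SD ``frame_noise_sd_percent`` (additive noise
expressed in ΔI-percent units).  Because the ΔI conversion normalizes by
the per-voxel baseline mean, the planted templates are recovered exactly
when both noise SDs are zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import RegionLabelMap, TrialSet, n_frames_for
from .errors import ParameterError, ValidationError

#: Contrast conditions used throughout (percent).
DEFAULT_CONDITIONS = (1.0, 2.0, 3.0, 5.0, 10.0, 20.0, 50.0, 90.0, 100.0)

#: Region band labels.
REGION_LOOKUP = {1: "SCs", 2: "SCi", 3: "SCd"}


@dataclass(frozen=True)
class ResponseClass:
    """One planted hemodynamic response shape.

    ``amplitude_percent`` is the ΔI peak at 100% contrast; the temporal
    profile is zero until ``onset_delay_s`` after stimulus onset, rises
    linearly over ``rise_time_s``, holds for ``plateau_s`` and then decays
    exponentially with time constant ``decay_time_s``.
    """

    amplitude_percent: float
    onset_delay_s: float = 0.6
    rise_time_s: float = 1.2
    plateau_s: float = 3.0
    decay_time_s: float = 4.0

    def __post_init__(self) -> None:
        for name in ("onset_delay_s", "rise_time_s", "plateau_s", "decay_time_s"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class SynthConfig:
    """Full description of one synthetic dataset."""

    grid_shape: tuple[int, int] = (60, 60)
    # fractional row extents of the bands, top to bottom; remainder = background
    band_fractions: tuple[float, float, float] = (0.3, 0.4, 0.2)
    response_classes: tuple[ResponseClass, ...] = (
        ResponseClass(3.9), ResponseClass(9.7),
        ResponseClass(16.9), ResponseClass(27.6),
    )
    c50: float = 10.0  # semi-saturation constant of the contrast response
    baseline_mean: float = 100.0
    trial_gain_sd: float = 0.0  # lognormal sigma of the per-trial gain
    frame_noise_sd_percent: float = 0.0
    n_trials: int = 50
    conditions: tuple[float, ...] = DEFAULT_CONDITIONS
    frame_interval_s: float = 0.6
    baseline_s: float = 10.0
    stimulus_s: float = 4.0
    post_s: float = 20.0
    active_fraction_scs: float = 0.6  # share of SCs rows covered by responsive classes
    rng_seed: int = 0
    subject_id: str = "synth"

    def __post_init__(self) -> None:
        if sum(self.band_fractions) > 1.0 + 1e-9:
            raise ParameterError("band fractions must sum to at most 1")
        amps = [c.amplitude_percent for c in self.response_classes]
        if any(a2 <= a1 for a1, a2 in zip(amps, amps[1:])):
            raise ParameterError("class amplitudes must be strictly increasing")
        if not 0 < self.active_fraction_scs <= 1:
            raise ParameterError("active_fraction_scs must lie in (0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure aligned to the generated grid."""

    class_map: np.ndarray  # 0 = non-responsive, 1..n = response class index
    active_mask: np.ndarray  # True where a responsive class was planted
    labelmap: RegionLabelMap
    templates: dict  # (class index, condition) -> noiseless ΔI template


def hr_template(cls: ResponseClass, time_s: np.ndarray) -> np.ndarray:
    """Noiseless ΔI% template of one response class on a frame-time grid.

    Zero before ``onset_delay_s``, linear rise to ``amplitude_percent``
    over ``rise_time_s``, constant plateau, then exponential decay.  The
    peak equals the class amplitude exactly whenever any frame falls in
    the plateau (or at/after the rise end for an instantaneous rise).
    """
    t = np.asarray(time_s, dtype=float)
    a = cls.amplitude_percent
    t0 = cls.onset_delay_s
    t_rise_end = t0 + cls.rise_time_s
    t_plateau_end = t_rise_end + cls.plateau_s
    out = np.zeros_like(t)
    if a == 0:
        return out
    if cls.rise_time_s > 0:
        rising = (t >= t0) & (t < t_rise_end)
        out[rising] = a * (t[rising] - t0) / cls.rise_time_s
    plateau = (t >= t_rise_end) & (t <= t_plateau_end)
    out[plateau] = a
    decay = t > t_plateau_end
    if cls.decay_time_s > 0:
        out[decay] = a * np.exp(-(t[decay] - t_plateau_end) / cls.decay_time_s)
    return out


def contrast_scale(contrast: float, c50: float = 10.0) -> float:
    """Saturating (Naka-Rushton-style) contrast multiplier, 1 at 100%.

    ``c/(c + c50)`` renormalized so that 100% contrast maps to 1; strictly
    increasing in contrast on (0, 100].
    """
    if contrast <= 0:
        raise ParameterError("contrast must be positive")
    raw = contrast / (contrast + c50)
    return raw / (100.0 / (100.0 + c50))


def build_geometry(config: SynthConfig) -> tuple[RegionLabelMap, np.ndarray]:
    """Band label map and contiguous response-class map for ``config``.

    The grid is split into horizontal bands SCs / SCi / SCd (remaining
    rows are background, label 0).  Responsive classes are planted as
    vertical column blocks inside the top fraction of the SCs band — each
    block is a solid rectangle, hence 4-connected — ordered left to right
    by ascending class index.  The highest class also extends thin tongues
    into SCi so layer mixtures exist.
    """
    nz, nx = config.grid_shape
    labels = np.zeros((nz, nx), dtype=np.int32)
    rows = [int(round(f * nz)) for f in config.band_fractions]
    z0 = 0
    for lbl, height in zip(REGION_LOOKUP, rows):
        labels[z0:z0 + height, :] = lbl
        z0 += height

    class_map = np.zeros((nz, nx), dtype=np.int32)
    scs_rows = np.nonzero(np.any(labels == 1, axis=1))[0]
    n_active_rows = max(1, int(round(config.active_fraction_scs * len(scs_rows))))
    # bottom rows of the band, so the SCi tongue stays 4-connected
    active_rows = scs_rows[-n_active_rows:]
    n_classes = len(config.response_classes)
    col_edges = np.linspace(0, nx, n_classes + 1).astype(int)
    for ci in range(n_classes):
        block = np.ix_(active_rows, np.arange(col_edges[ci], col_edges[ci + 1]))
        class_map[block] = ci + 1
    # top class dips into the first SCi row to create cross-layer membership
    sci_rows = np.nonzero(np.any(labels == 2, axis=1))[0]
    if len(sci_rows) and n_classes:
        class_map[sci_rows[0], col_edges[-2]:col_edges[-1]] = n_classes
    return RegionLabelMap(labels=labels, lookup=dict(REGION_LOOKUP)), class_map


def generate(config: SynthConfig) -> tuple[TrialSet, GroundTruth]:
    """Generate a TrialSet plus its planted ground truth.

    Identical ``config.rng_seed`` yields bit-identical output.
    """
    rng = np.random.default_rng(config.rng_seed)
    labelmap, class_map = build_geometry(config)
    nz, nx = config.grid_shape
    n_frames = n_frames_for(config.baseline_s, config.stimulus_s, config.post_s,
                            config.frame_interval_s)
    onset = int(np.floor(config.baseline_s / config.frame_interval_s))
    time_s = (np.arange(n_frames) - onset) * config.frame_interval_s
    n_cond = len(config.conditions)
    n_trials = config.n_trials

    # noiseless ΔI templates per (class, condition)
    templates: dict = {}
    for ci, cls in enumerate(config.response_classes, start=1):
        base = hr_template(cls, time_s)
        for cond in config.conditions:
            templates[(ci, cond)] = base * contrast_scale(cond, config.c50)

    # ΔI volume (nz, nx, frames, conditions)
    delta = np.zeros((nz, nx, n_frames, n_cond))
    for ci in range(1, len(config.response_classes) + 1):
        mask = class_map == ci
        if not mask.any():
            raise ValidationError(f"response class {ci} covers no voxels")
        for ki, cond in enumerate(config.conditions):
            delta[mask, :, ki] = templates[(ci, cond)]

    shape = (nz, nx, n_frames, n_trials, n_cond)
    base = 1.0 + delta[:, :, :, None, :] / 100.0
    if config.trial_gain_sd > 0:
        gains = rng.lognormal(mean=0.0, sigma=config.trial_gain_sd,
                              size=(n_trials, n_cond))
        signal = base * gains[None, None, None, :, :]
    else:
        signal = np.broadcast_to(base, shape).copy()
    if config.frame_noise_sd_percent > 0:
        noise = rng.normal(0.0, config.frame_noise_sd_percent / 100.0, size=shape)
        signal += noise
        del noise
    signal *= config.baseline_mean
    np.clip(signal, 0.0, None, out=signal)
    intensity = signal

    ts = TrialSet(
        intensity=intensity,
        frame_interval_s=config.frame_interval_s,
        baseline_s=config.baseline_s,
        stimulus_s=config.stimulus_s,
        post_s=config.post_s,
        conditions=config.conditions,
        subject_id=config.subject_id,
    )
    gt = GroundTruth(class_map=class_map, active_mask=class_map > 0,
                     labelmap=labelmap, templates=templates)
    return ts, gt


def config_from_json(path: Path | str) -> SynthConfig:
    raw = json.loads(Path(path).read_text())
    if "response_classes" in raw:
        raw["response_classes"] = tuple(
            ResponseClass(**rc) for rc in raw["response_classes"])
    for key in ("grid_shape", "band_fractions", "conditions"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return SynthConfig(**raw)


def config_to_json(config: SynthConfig, path: Path | str) -> None:
    Path(path).write_text(json.dumps(asdict(config), indent=1))
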