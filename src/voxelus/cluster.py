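"""Single-voxel spatiotemporal clustering.

Pipeline: pool trial-averaged single-voxel ΔI traces across subjects and
contrast conditions into a feature matrix (exact duplicates removed),
reduce dimensionality with a mean-centered PCA (components chosen to reach
a cumulative explained-variance target, 50% by default), cluster with the
Elkan variant of K-Means (best of 100 initializations by inertia), then
relabel clusters in ascending order of the in-stimulus peak amplitude of
their PCA-reconstructed centroid traces so that cluster 1 is the least and
cluster K the most responsive.  The number of clusters is suggested by the
elbow (maximum curvature) of the inertia curve, and run-to-run robustness
is scored as the mean pairwise fraction of samples keeping the same
amplitude-ordered label over repeated fits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .core import RegionLabelMap, TrialSet, dedup_traces, region_voxel_traces, trial_average
from .errors import ComparabilityError, EmptyRegionError, LookupError_, ParameterError
from . import hrmetrics

log = logging.getLogger(__name__)

DEFAULT_VARIANCE_TARGET = 0.50
DEFAULT_N_INIT = 100
DEFAULT_STABILITY_RUNS = 10


@dataclass(frozen=True)
class SampleIndex:
    """Bookkeeping for one feature-matrix row set.

    ``entries[i] = (subject_id, condition, voxel_z, voxel_x)`` describes
    original sample ``i``; ``back_index[i]`` is the row of the deduplicated
    matrix representing it.
    """

    entries: tuple[tuple[str, float, int, int], ...]
    back_index: np.ndarray
    grid_shape: tuple[int, int]

    def rows_for(self, subject: str, condition: float) -> np.ndarray:
        sel = [i for i, (s, c, _, _) in enumerate(self.entries)
               if s == subject and c == condition]
        if not sel:
            raise LookupError_(
                f"no samples for subject {subject!r} at condition {condition}")
        return np.asarray(sel, dtype=np.intp)


@dataclass(frozen=True)
class ClusterModel:
    """Fitted PCA + K-Means model with amplitude-ordered labels."""

    pca_mean: np.ndarray
    pca_basis: np.ndarray  # (n_components, n_frames)
    explained_ratio: np.ndarray  # cumulative, length n_components
    centroids: np.ndarray  # (k, n_components), amplitude order
    labels: np.ndarray  # per deduplicated sample, ids 1..k
    inertia: float
    k: int
    seed: Optional[int] = None

    @property
    def n_components(self) -> int:
        return self.pca_basis.shape[0]

    def centroid_traces(self) -> np.ndarray:
        """Centroids mapped back to ΔI trace space, shape (k, n_frames)."""
        return self.centroids @ self.pca_basis + self.pca_mean

    def full_labels(self, index: SampleIndex) -> np.ndarray:
        """Labels of every original sample, duplicates restored."""
        return self.labels[index.back_index]


@dataclass(frozen=True)
class ClusterMap:
    """Per-voxel cluster attribution for one subject and condition."""

    ids: np.ndarray  # 0 = outside the analyzed set
    subject: str
    condition: float
    k: int


def build_feature_matrix(
    trialsets: Sequence[TrialSet],
    labels: RegionLabelMap,
    acronym: str,
) -> tuple[np.ndarray, SampleIndex]:
    """Pool per-voxel trial-averaged ΔI traces over subjects and conditions.

    One row per (voxel, subject, condition), in deterministic order
    (subjects in input order, conditions ascending, voxels row-major);
    exact duplicate rows are removed, with the back-index retained in the
    returned :class:`SampleIndex`.  Degenerate voxels are skipped.
    """
    if not trialsets:
        raise EmptyRegionError("at least one TrialSet is required")
    rows: list[np.ndarray] = []
    entries: list[tuple[str, float, int, int]] = []
    grid_shape = trialsets[0].grid_shape
    for ts in trialsets:
        if ts.grid_shape != grid_shape:
            raise ComparabilityError("all TrialSets must share one voxel grid")
        for cond in ts.conditions:
            averaged = trial_average(ts, cond)
            rel, degenerate = hrmetrics.to_relative_map(averaged, ts)
            traces, coords = region_voxel_traces(rel, labels, acronym)
            for (z, x), tr in zip(coords, traces):
                if degenerate[z, x]:
                    continue
                rows.append(tr)
                entries.append((ts.subject_id, cond, z, x))
    if not rows:
        raise EmptyRegionError(f"region {acronym!r} yielded no usable traces")
    matrix = np.asarray(rows)
    unique, back = dedup_traces(matrix)
    if len(unique) < len(matrix):
        log.info("removed %d duplicate trace(s) before fitting",
                 len(matrix) - len(unique))
    return unique, SampleIndex(entries=tuple(entries), back_index=back,
                               grid_shape=grid_shape)


def fit_pca(matrix: np.ndarray,
            variance_target: Optional[float] = DEFAULT_VARIANCE_TARGET,
            n_components: Optional[int] = None) -> tuple[np.ndarray, PCA]:
    """Mean-centered PCA keeping the fewest components reaching the target.

    Either ``variance_target`` (smallest m with cumulative explained
    variance ≥ target) or an explicit ``n_components`` may be given.
    Returns the reduced features and the fitted estimator.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] < 2:
        raise ParameterError("PCA requires at least 2 samples")
    if n_components is None:
        if variance_target is None or not 0 < variance_target <= 1:
            raise ParameterError("variance_target must lie in (0, 1]")
        probe = PCA().fit(matrix)
        cum = np.cumsum(probe.explained_variance_ratio_)
        n_components = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    pca = PCA(n_components=n_components)
    features = pca.fit_transform(matrix)
    log.info("PCA kept %d component(s), cumulative explained variance %.3f",
             n_components, float(np.sum(pca.explained_variance_ratio_)))
    return features, pca


def _best_kmeans(features: np.ndarray, k: int, n_init: int, seed) -> KMeans:
    km = KMeans(n_clusters=k, n_init=n_init, init="k-means++",
                algorithm="elkan", random_state=seed)
    km.fit(features)
    return km


def elbow_k(features: np.ndarray, k_range: Sequence[int] = range(2, 11),
            n_init_small: int = 10, seed: Optional[int] = 0,
            ) -> tuple[np.ndarray, Optional[int]]:
    """Inertia curve over ``k_range`` and its maximum-curvature elbow.

    The curve (best of ``n_init_small`` initializations per k) is min-max
    normalized on both axes and the interior point of maximum discrete
    curvature is suggested; the raw curve is always returned so a human
    can override.  A flat curve yields ``(curve, None)`` (no-elbow flag).
    """
    ks = list(k_range)
    n = len(features)
    if any(k < 1 or k > n for k in ks):
        raise ParameterError(f"k_range must lie within [1, {n}]")
    inertias = np.array([
        _best_kmeans(features, k, n_init_small, seed).inertia_ for k in ks
    ])
    if np.ptp(inertias) == 0 or len(ks) < 3:
        log.warning("inertia curve is degenerate; no elbow suggested")
        return inertias, None
    xs = (np.asarray(ks, dtype=float) - ks[0]) / (ks[-1] - ks[0])
    ys = (inertias - inertias.min()) / np.ptp(inertias)
    # exact central differences on interior points (double np.gradient
    # smears the curvature peak one point to the right)
    h = xs[1] - xs[0]
    dy = (ys[2:] - ys[:-2]) / (2 * h)
    d2y = (ys[2:] - 2 * ys[1:-1] + ys[:-2]) / h ** 2
    curvature = np.abs(d2y) / (1.0 + dy ** 2) ** 1.5
    best = 1 + int(np.argmax(curvature))
    return inertias, int(ks[best])


def _amplitude_order(km: KMeans, pca: PCA, onset: int, offset: int) -> np.ndarray:
    """Cluster indices sorted by in-stimulus peak of reconstructed centroids."""
    traces = pca.inverse_transform(km.cluster_centers_)
    peaks = traces[:, onset:offset].max(axis=1)
    return np.argsort(peaks, kind="stable")


def fit_kmeans(features: np.ndarray, pca: PCA, ts: TrialSet, k: int,
               n_init: int = DEFAULT_N_INIT,
               seed: Optional[int] = None) -> ClusterModel:
    """Best-of-``n_init`` Elkan K-Means with amplitude-ordered relabeling.

    Cluster ids are 1..k, assigned so that the in-stimulus peak amplitude
    of the PCA-reconstructed centroid trace is nondecreasing in id.
    """
    if k > len(features):
        raise ParameterError(f"k={k} exceeds the {len(features)} samples")
    km = _best_kmeans(features, k, n_init, seed)
    order = _amplitude_order(km, pca, ts.stimulus_onset_frame,
                             ts.stimulus_offset_frame)
    # order[j] = original cluster index with rank j; relabel to rank+1
    relabel = np.empty(k, dtype=np.intp)
    relabel[order] = np.arange(1, k + 1)
    return ClusterModel(
        pca_mean=pca.mean_,
        pca_basis=pca.components_,
        explained_ratio=np.cumsum(pca.explained_variance_ratio_),
        centroids=km.cluster_centers_[order],
        labels=relabel[km.labels_],
        inertia=float(km.inertia_),
        k=k,
        seed=seed,
    )


def cluster_traces(model: ClusterModel, matrix: np.ndarray,
                   index: Optional[SampleIndex] = None
                   ) -> dict[int, tuple[Optional[np.ndarray], Optional[np.ndarray]]]:
    """Framewise mean ± SD ΔI trace per cluster.

    ``matrix`` must be the deduplicated feature-source matrix the model was
    fitted on; when ``index`` is given the statistics are taken over the
    full back-projected sample set instead (duplicates restored).  Empty
    clusters map to ``(None, None)``.
    """
    if index is not None:
        rows = np.asarray(matrix)[index.back_index]
        labels = model.full_labels(index)
    else:
        rows = np.asarray(matrix)
        labels = model.labels
    out: dict[int, tuple[Optional[np.ndarray], Optional[np.ndarray]]] = {}
    for cid in range(1, model.k + 1):
        members = rows[labels == cid]
        if len(members) == 0:
            log.warning("cluster %d is empty; trace undefined", cid)
            out[cid] = (None, None)
        else:
            out[cid] = (members.mean(axis=0), members.std(axis=0))
    return out


def cluster_map(model: ClusterModel, index: SampleIndex, subject: str,
                condition: float) -> ClusterMap:
    """Voxel-grid cluster attribution for one subject and condition.

    Duplicate voxels receive their unique representative's label through
    the back-index; voxels outside the analyzed set stay 0.
    """
    ids = np.zeros(index.grid_shape, dtype=np.int32)
    full = model.full_labels(index)
    for i in index.rows_for(subject, condition):
        _, _, z, x = index.entries[i]
        ids[z, x] = full[i]
    return ClusterMap(ids=ids, subject=subject, condition=condition, k=model.k)


def map_similarity(map_a: ClusterMap, map_b: ClusterMap) -> float:
    """Fraction of analyzed voxels sharing the same cluster id.

    Both maps must cover the identical analyzed-voxel set; labels are
    assumed already amplitude-ordered (they are, by construction of
    :func:`fit_kmeans`).
    """
    a, b = map_a.ids, map_b.ids
    if a.shape != b.shape:
        raise ComparabilityError("maps have different grids")
    analyzed_a, analyzed_b = a > 0, b > 0
    if not np.array_equal(analyzed_a, analyzed_b):
        raise ComparabilityError("maps cover different analyzed-voxel sets")
    if not analyzed_a.any():
        raise ComparabilityError("maps contain no analyzed voxels")
    return float((a[analyzed_a] == b[analyzed_a]).mean())


def label_agreement(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Fraction of samples with identical amplitude-ordered labels."""
    labels_a, labels_b = np.asarray(labels_a), np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ComparabilityError("label vectors differ in length")
    return float((labels_a == labels_b).mean())


def stability(features: np.ndarray, pca: PCA, ts: TrialSet, k: int,
              index: Optional[SampleIndex] = None,
              n_runs: int = DEFAULT_STABILITY_RUNS,
              n_init: int = DEFAULT_N_INIT,
              seed: Optional[int] = None) -> tuple[float, float]:
    """Mean ± SD pairwise label agreement over repeated independent fits.

    Each of the ``n_runs`` fits is itself a best-of-``n_init`` model; all
    n·(n−1)/2 pairs are compared on amplitude-ordered labels (restored to
    the full sample set when ``index`` is given).
    """
    if n_runs < 2:
        raise ParameterError("stability needs at least 2 runs")
    rng = np.random.default_rng(seed)
    run_labels = []
    for _ in range(n_runs):
        model = fit_kmeans(features, pca, ts, k, n_init=n_init,
                           seed=int(rng.integers(2 ** 31)))
        run_labels.append(model.full_labels(index) if index is not None
                          else model.labels)
    sims = np.array([
        label_agreement(run_labels[i], run_labels[j])
        for i, j in combinations(range(n_runs), 2)
    ])
    return float(sims.mean()), float(sims.std())


def cluster_region_distribution(
    maps: Sequence[ClusterMap], labels: RegionLabelMap
) -> tuple[dict[int, dict[str, float]], dict[str, dict[float, dict[int, float]]]]:
    """Layer-wise cluster composition.

    Returns two views: per cluster id, the percentage of its voxels inside
    each region (rows sum to 100); and per region, per condition, the
    percentage of the region's analyzed voxels attributed to each cluster.
    """
    if not maps:
        raise ParameterError("at least one map is required")
    k = maps[0].k
    acronyms = list(labels.lookup.values())
    region_of = {labels.label_for(a): a for a in acronyms}

    per_cluster_counts: dict[int, dict[str, int]] = {
        cid: {a: 0 for a in acronyms} for cid in range(1, k + 1)}
    # (region, condition) -> per-cluster voxel counts, pooled over maps
    rc_counts: dict[tuple[str, float], np.ndarray] = {}

    for m in maps:
        for lbl, acr in region_of.items():
            ids_here = m.ids[labels.labels == lbl]
            counts = np.array([(ids_here == cid).sum() for cid in range(1, k + 1)])
            for cid in range(1, k + 1):
                per_cluster_counts[cid][acr] += int(counts[cid - 1])
            if counts.sum() > 0:
                key = (acr, m.condition)
                rc_counts[key] = rc_counts.get(key, np.zeros(k, dtype=int)) + counts

    per_region: dict[str, dict[float, dict[int, float]]] = {a: {} for a in acronyms}
    for (acr, cond), counts in rc_counts.items():
        total = counts.sum()
        per_region[acr][cond] = {
            cid: 100.0 * counts[cid - 1] / total for cid in range(1, k + 1)}

    per_cluster: dict[int, dict[str, float]] = {}
    for cid, counts in per_cluster_counts.items():
        total = sum(counts.values())
        if total == 0:
            per_cluster[cid] = {a: float("nan") for a in acronyms}
        else:
            per_cluster[cid] = {a: 100.0 * c / total for a, c in counts.items()}
    return per_cluster, per_region
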