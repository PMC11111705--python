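"""Step 1: topology-informed K-means segmentation.

Voxels are clustered in the 4-D space ``(I, D²x, D²y, D²z)``. The number of
classes K is found automatically as the smallest K for which three *distinct*
classes encode the positive-derivative outer borders along x, y and z.
Classes are then sorted by mean intensity (class 1 = dimmest) and the neuron
body is the union of the classes whose mean second derivative is negative
along all three axes — bright, convex-profile interiors.

Clustering can run at several smoothing scales; the per-scale binary masks
are merged by voxelwise OR, after which enclosed cavities are filled and
clusters below 7 voxels (the smallest 3-D-symmetric structure) are removed.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
from scipy import ndimage
from skimage.morphology import remove_small_objects
from sklearn.cluster import KMeans

from .features import FeatureVolume, background_mask, build_features, log_transform
from .io import ImageStack, PipelineConfig

logger = logging.getLogger("senpai")

#: 26-connectivity structuring element for foreground components.
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


class NoNeuronalClassError(ValueError):
    """Raised when no cluster has all-negative mean second derivatives."""


class NoBorderEncodingError(ValueError):
    """Raised when no K in range yields distinct positive-D² border classes."""


@dataclasses.dataclass
class ClusterModel:
    """A fitted, intensity-sorted K-means partition of the feature space.

    ``labels`` are per-foreground-voxel class ids in ``1..K`` after sorting
    classes by mean raw intensity (ascending). ``class_stats`` rows are
    ``(mean I, mean D²x, mean D²y, mean D²z)`` per class in original units.
    """

    K: int
    centroids: np.ndarray        # (K, 4) in the (possibly standardized) space
    class_stats: np.ndarray      # (K, 4) original units, row i = class i+1
    labels: np.ndarray           # (n_foreground,), values 1..K
    inertia: float
    seed: int
    replicates: int
    max_iter: int

    def class_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.K + 1)[1:]


@dataclasses.dataclass
class SegmentationMask:
    """Binary segmentation plus the per-scale provenance that produced it."""

    mask: np.ndarray
    provenance: list[dict]


def fit_kmeans(
    features: FeatureVolume,
    K: int,
    replicates: int = 10,
    max_iter: int = 1000,
    seed: int = 0,
) -> ClusterModel:
    """Best-of-`replicates` Lloyd K-means on the feature matrix.

    Each replicate restarts from fresh k-means++ centres; the partition with
    the lowest within-cluster sum of squares wins. Deterministic given
    `seed`. Classes are relabelled so mean raw intensity is non-decreasing
    in the class id.
    """
    if K < 2:
        raise ValueError(f"K must be >= 2, got {K}")
    n = features.n_voxels
    if n < K:
        raise ValueError(f"K={K} exceeds the {n} foreground voxels")
    km = KMeans(
        n_clusters=K,
        n_init=replicates,
        max_iter=max_iter,
        random_state=seed % (2**31),
        algorithm="lloyd",
    )
    raw_labels = km.fit_predict(features.matrix)
    # sort classes by mean raw intensity, dimmest first
    means_I = np.array([
        features.raw_matrix[raw_labels == k, 0].mean() if (raw_labels == k).any() else np.inf
        for k in range(K)
    ])
    order = np.argsort(means_I, kind="stable")
    remap = np.empty(K, dtype=np.int64)
    remap[order] = np.arange(1, K + 1)
    labels = remap[raw_labels]
    centroids = km.cluster_centers_[order]
    class_stats = np.full((K, 4), np.nan)
    for k in range(1, K + 1):
        sel = labels == k
        if sel.any():
            class_stats[k - 1] = features.raw_matrix[sel].mean(axis=0)
    return ClusterModel(
        K=K,
        centroids=centroids,
        class_stats=class_stats,
        labels=labels,
        inertia=float(km.inertia_),
        seed=seed,
        replicates=replicates,
        max_iter=max_iter,
    )


def _border_classes(model: ClusterModel) -> tuple[tuple[int, int, int], bool]:
    """Per-axis argmax-D² classes and whether they qualify as border encoders.

    Qualification: the class with the largest mean D² along each axis has a
    strictly positive mean there, and the three classes are pairwise
    distinct.
    """
    stats = model.class_stats
    cx, cy, cz = (int(np.nanargmax(stats[:, j])) + 1 for j in (1, 2, 3))
    positive = all(stats[c - 1, j] > 0 for c, j in ((cx, 1), (cy, 2), (cz, 3)))
    distinct = len({cx, cy, cz}) == 3
    return (cx, cy, cz), (positive and distinct)


def auto_select_K(
    features: FeatureVolume,
    K_min: int = 2,
    K_max: int = 10,
    replicates: int = 10,
    max_iter: int = 1000,
    seed: int = 0,
) -> tuple[int, ClusterModel, list[dict]]:
    """Smallest K whose partition encodes each spatial border direction separately.

    For each K ascending, fit K-means and test: the classes attaining the
    maximal mean D²x, D²y, D²z must have strictly positive means there and
    must be three different classes. Returns ``(K, model, diagnostics)``;
    raises :class:`NoBorderEncodingError` when no K in range qualifies
    (e.g. structureless input).
    """
    if not (2 <= K_min <= K_max):
        raise ValueError(f"need 2 <= K_min <= K_max, got {K_min}, {K_max}")
    diagnostics: list[dict] = []
    for K in range(K_min, K_max + 1):
        model = fit_kmeans(features, K, replicates=replicates, max_iter=max_iter, seed=seed)
        axes_cls, ok = _border_classes(model)
        diagnostics.append({
            "K": K,
            "border_classes_xyz": axes_cls,
            "border_means": [float(model.class_stats[c - 1, j]) for c, j in zip(axes_cls, (1, 2, 3))],
            "accepted": ok,
        })
        logger.info("auto_select_K: K=%d border classes %s accepted=%s", K, axes_cls, ok)
        if ok:
            return K, model, diagnostics
    raise NoBorderEncodingError(
        f"no border-encoding partition found for K in [{K_min}, {K_max}]; "
        f"diagnostics: {diagnostics}"
    )


def select_neuronal_classes(model: ClusterModel) -> set[int]:
    """Classes whose mean second derivatives are negative along all three axes.

    These are the bright convex-profile interiors — the neuron body. The
    dimmest class (class 1) collects background and is never returned. A
    warning is emitted when the selection is not simply the top of the
    intensity ranking, since that usually signals an unusual histogram.
    """
    stats = model.class_stats
    selected = {
        k for k in range(2, model.K + 1)
        if np.all(stats[k - 1, 1:] < 0)
    }
    if not selected:
        raise NoNeuronalClassError(
            "no neuronal class found: no cluster has all-negative mean second derivatives"
        )
    suffix = set(range(min(selected), model.K + 1))
    if selected != suffix:
        warnings.warn(
            f"selected classes {sorted(selected)} are not the top-intensity suffix "
            f"of the ranking (K={model.K}); inspect class_stats",
            stacklevel=2,
        )
    return selected


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill background cavities not 6-connected to the volume border.

    Intensity inhomogeneities inside thick structures (somata) read as
    borders and punch holes in the class-selected mask; those enclosed
    cavities are genuine neuron interior. Foreground voxels are never
    removed.
    """
    return ndimage.binary_fill_holes(np.asarray(mask, dtype=bool))


def remove_small_clusters(mask: np.ndarray, min_voxels: int = 7) -> np.ndarray:
    """Drop 26-connected components smaller than `min_voxels` (default 7)."""
    if min_voxels < 1:
        raise ValueError("min_voxels must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    if min_voxels == 1 or not mask.any():
        return mask.copy()
    # max_size removes components <= its value, so components < min_voxels go
    return remove_small_objects(mask, max_size=min_voxels - 1, connectivity=3)


def _binarize(model: ClusterModel, features: FeatureVolume, classes: set[int]) -> np.ndarray:
    mask = np.zeros(features.foreground.shape, dtype=bool)
    sel = np.isin(model.labels, sorted(classes))
    mask[features.foreground] = sel
    return mask


def _segment_one_scale(
    stack: ImageStack,
    sigma: float,
    foreground: np.ndarray,
    config: PipelineConfig,
) -> tuple[np.ndarray, dict]:
    features = build_features(stack, sigma=sigma, foreground=foreground,
                              standardize=config.standardize_features)
    if config.K == "auto":
        K, model, diag = auto_select_K(
            features, config.K_min, config.K_max,
            replicates=config.kmeans_replicates, max_iter=config.kmeans_max_iter,
            seed=config.random_seed,
        )
    else:
        K = int(config.K)
        model = fit_kmeans(features, K, replicates=config.kmeans_replicates,
                           max_iter=config.kmeans_max_iter, seed=config.random_seed)
        diag = []
    classes = select_neuronal_classes(model)
    mask = _binarize(model, features, classes)
    prov = {
        "sigma": sigma,
        "K": K,
        "selected_classes": sorted(classes),
        "class_stats": model.class_stats.tolist(),
        "inertia": model.inertia,
        "auto_K_diagnostics": diag,
    }
    return mask, prov


def segment(stack: ImageStack, config: PipelineConfig) -> SegmentationMask:
    """Full step-1 segmentation: per-scale clustering, OR-merge, postprocessing.

    For every sigma in ``config.sigmas`` the 4-D features are built, K is
    chosen (auto or fixed), the neuronal classes are selected and binarized;
    the per-scale masks are merged by voxelwise OR. Hole filling and
    small-cluster pruning run once, after the merge, so pruned noise cannot
    be resurrected by another scale.
    """
    work = log_transform(stack) if config.log_transform else stack
    method, value = config.background_threshold
    foreground = background_mask(work, method, value)
    merged = np.zeros(stack.shape, dtype=bool)
    provenance = []
    for sigma in config.sigmas:
        mask, prov = _segment_one_scale(work, sigma, foreground, config)
        merged |= mask
        provenance.append(prov)
    merged = fill_holes(merged)
    merged = remove_small_clusters(merged, config.min_cluster_voxels)
    return SegmentationMask(mask=merged, provenance=provenance)


def fit_on_crop_apply_full(
    stack: ImageStack,
    config: PipelineConfig,
    crop_bounds: tuple[slice, slice, slice],
) -> SegmentationMask:
    """Learn centroids and class selection on a crop; label the full volume.

    Memory-saving mode for large stacks: the K-means (the expensive part)
    sees only the crop; every full-volume foreground voxel is then assigned
    to its nearest learned centroid and the crop's class selection is
    applied, followed by the usual OR-merge and postprocessing.
    """
    work = log_transform(stack) if config.log_transform else stack
    method, value = config.background_threshold
    foreground = background_mask(work, method, value)
    crop_stack = ImageStack(
        data=np.ascontiguousarray(work.data[crop_bounds]),
        voxel_size=work.voxel_size,
        dtype_range=work.dtype_range,
    )
    crop_fg = foreground[crop_bounds]
    merged = np.zeros(stack.shape, dtype=bool)
    provenance = []
    for sigma in config.sigmas:
        crop_features = build_features(crop_stack, sigma=sigma, foreground=crop_fg,
                                       standardize=config.standardize_features)
        if config.K == "auto":
            K, model, diag = auto_select_K(
                crop_features, config.K_min, config.K_max,
                replicates=config.kmeans_replicates, max_iter=config.kmeans_max_iter,
                seed=config.random_seed,
            )
        else:
            K = int(config.K)
            model = fit_kmeans(crop_features, K, replicates=config.kmeans_replicates,
                               max_iter=config.kmeans_max_iter, seed=config.random_seed)
            diag = []
        classes = select_neuronal_classes(model)
        # full-volume features, standardized with the crop's parameters so
        # the learned centroids live in the same space
        full = build_features(work, sigma=sigma, foreground=foreground, standardize=False)
        full_matrix = (full.raw_matrix - crop_features.channel_mean) / crop_features.channel_std
        d = ((full_matrix[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2) \
            if full_matrix.shape[0] * K <= 5_000_000 else None
        if d is not None:
            assign = d.argmin(axis=1) + 1
        else:  # chunked nearest-centroid for big volumes
            assign = np.empty(full_matrix.shape[0], dtype=np.int64)
            step = 500_000
            for i in range(0, full_matrix.shape[0], step):
                blk = full_matrix[i:i + step]
                dd = ((blk[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
                assign[i:i + step] = dd.argmin(axis=1) + 1
        mask = np.zeros(stack.shape, dtype=bool)
        mask[foreground] = np.isin(assign, sorted(classes))
        merged |= mask
        provenance.append({
            "sigma": sigma, "K": K, "selected_classes": sorted(classes),
            "class_stats": model.class_stats.tolist(),
            "crop_bounds": [[s.start, s.stop] for s in crop_bounds],
            "auto_K_diagnostics": diag,
        })
    merged = fill_holes(merged)
    merged = remove_small_clusters(merged, config.min_cluster_voxels)
    return SegmentationMask(mask=merged, provenance=provenance)
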