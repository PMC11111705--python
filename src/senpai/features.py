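"""Per-voxel features for topology-informed clustering.

Each foreground voxel is described by a 4-vector: the raw image intensity
``I`` and the three axial second derivatives ``(D²x, D²y, D²z)`` of the
(optionally Gaussian-smoothed) intensity. Inside a bright structure the
second derivative is negative along every axis; at the outer border it is
positive. Clustering in this space therefore separates neuron interiors,
borders and background without any explicit signal or noise model.

Intensity is always taken from the unsmoothed stack; only the derivative
channels see the smoothing, so the same voxel can participate in several
clustering scales with a shared intensity coordinate.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .io import ImageStack

logger = logging.getLogger("senpai")


@dataclasses.dataclass
class FeatureVolume:
    """4-channel feature description of a stack restricted to a foreground mask.

    ``matrix`` holds the (possibly standardized) features of the foreground
    voxels, one row per voxel, columns ``(I, D²x, D²y, D²z)``.
    ``channel_mean``/``channel_std`` are the standardization parameters over
    foreground (ones/zeros when standardization is off), so class statistics
    can always be reported in original units.
    """

    intensity: np.ndarray            # raw I, full volume
    d2: tuple[np.ndarray, np.ndarray, np.ndarray]  # (D²x, D²y, D²z), full volume
    foreground: np.ndarray           # bool mask of voxels entering clustering
    sigma: float
    matrix: np.ndarray               # (n_foreground, 4), clustering space
    raw_matrix: np.ndarray           # (n_foreground, 4), original units
    channel_mean: np.ndarray
    channel_std: np.ndarray

    @property
    def n_voxels(self) -> int:
        return int(self.matrix.shape[0])


def log_transform(stack: ImageStack) -> ImageStack:
    """Pointwise ``log(1 + I)`` rescaled back to the input range.

    Monotone and order-preserving; useful to compress very bright somata so
    that dim processes are not swamped. Negative inputs are clamped to 0
    first (with a log record) so the transform is defined everywhere.
    """
    data = np.asarray(stack.data, dtype=np.float64)
    if data.min() < 0:
        logger.info("log_transform: clamping %d negative voxels to 0", int((data < 0).sum()))
        data = np.clip(data, 0, None)
    lo, hi = data.min(), data.max()
    if hi == lo:  # constant volume: the monotone rescale is the identity
        return ImageStack(data=data, voxel_size=stack.voxel_size,
                          dtype_range=stack.dtype_range)
    out = np.log1p(data)
    out = lo + (out - out.min()) * (hi - lo) / (out.max() - out.min())
    return ImageStack(data=out, voxel_size=stack.voxel_size, dtype_range=stack.dtype_range)


def gaussian_smooth(stack: ImageStack, sigma: float) -> ImageStack:
    """Isotropic Gaussian smoothing in voxel units; ``sigma=0`` is the identity.

    Reflective boundaries keep total intensity conserved up to edge effects.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return stack
    sm = ndimage.gaussian_filter(np.asarray(stack.data, dtype=np.float64), sigma=sigma, mode="reflect")
    return ImageStack(data=sm, voxel_size=stack.voxel_size, dtype_range=stack.dtype_range)


def second_derivatives(stack: ImageStack) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Central second differences along x, y, z (in that return order).

    The [1, -2, 1] stencil is applied per axis in voxel units; boundary
    slices replicate the nearest edge value, so the stencil never reaches
    outside the volume. Returned as ``(D²x, D²y, D²z)`` where x is the
    fastest-varying (last) array axis.
    """
    data = np.asarray(stack.data, dtype=np.float64)
    for ax, name in zip(range(3), "zyx"):
        if data.shape[ax] < 3:
            raise ValueError(f"axis {name} has length {data.shape[ax]} < 3; cannot form a second difference")
    d2 = []
    for ax in (2, 1, 0):  # x, y, z
        d2.append(ndimage.correlate1d(data, np.array([1.0, -2.0, 1.0]), axis=ax, mode="nearest"))
    return tuple(d2)


def background_mask(
    stack: ImageStack, method: str = "otsu", value: float | None = None
) -> np.ndarray:
    """Boolean foreground mask: intensity strictly above a global threshold.

    ``method`` is one of ``otsu`` (between-class variance maximization),
    ``percentile`` (``value`` in [0, 100]) or ``absolute`` (``value`` in
    intensity units). Excluding the thresholded-out background keeps the
    clustering problem small without deciding the segmentation — the
    clustering itself draws the final boundary.
    """
    data = np.asarray(stack.data)
    if data.max() == data.min():
        raise ValueError("no foreground separable: stack is constant")
    if method == "otsu":
        thr = threshold_otsu(data)
    elif method == "percentile":
        if value is None:
            raise ValueError("percentile threshold requires a value")
        thr = np.percentile(data, value)
    elif method == "absolute":
        if value is None:
            raise ValueError("absolute threshold requires a value")
        thr = value
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    mask = data > thr
    if not mask.any():
        # strictly-greater can empty the mask when the threshold hits the max
        mask = data >= thr
    logger.info("background_mask(%s): threshold %.6g keeps %d/%d voxels",
                method, float(thr), int(mask.sum()), data.size)
    return mask


def build_features(
    stack: ImageStack,
    sigma: float = 0.0,
    foreground: np.ndarray | None = None,
    standardize: bool = True,
) -> FeatureVolume:
    """Assemble the 4-D clustering space for one smoothing scale.

    Intensity comes from the raw stack; derivatives from the stack smoothed
    with `sigma` (``0`` = unsmoothed). When `standardize` is on, each channel
    is z-scored over the foreground so the intensity range cannot dominate
    the squared-Euclidean metric; the raw-unit matrix is kept alongside for
    class statistics.
    """
    if foreground is None:
        foreground = np.ones(stack.shape, dtype=bool)
    foreground = np.asarray(foreground, dtype=bool)
    if foreground.shape != stack.shape:
        raise ValueError("foreground mask shape mismatch")
    if not foreground.any():
        raise ValueError("foreground is empty")
    smoothed = gaussian_smooth(stack, sigma)
    d2x, d2y, d2z = second_derivatives(smoothed)
    intensity = np.asarray(stack.data, dtype=np.float64)
    raw = np.stack(
        [intensity[foreground], d2x[foreground], d2y[foreground], d2z[foreground]], axis=1
    )
    if standardize:
        mean = raw.mean(axis=0)
        std = raw.std(axis=0)
        std = np.where(std == 0, 1.0, std)
        matrix = (raw - mean) / std
    else:
        mean = np.zeros(4)
        std = np.ones(4)
        matrix = raw.copy()
    return FeatureVolume(
        intensity=intensity,
        d2=(d2x, d2y, d2z),
        foreground=foreground,
        sigma=float(sigma),
        matrix=matrix,
        raw_matrix=raw,
        channel_mean=mean,
        channel_std=std,
    )
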