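"""Data model and file I/O for volumetric neuron reconstruction.

Conventions enforced at every boundary:

* volumes are indexed ``(z, y, x)``, 0-based;
* ``voxel_size`` is ``(dz, dy, dx)`` in micrometres, strictly positive;
* marker CSV files carry 0-based voxel coordinates with header
  ``label,z,y,x``.

SWC reading/writing lives in :mod:`senpai.skeleton` next to the tree
construction code.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("senpai")

#: dtype ranges recorded for integer stacks; floats keep their observed range.
_INT_RANGES = {
    np.dtype(k): (np.iinfo(k).min, np.iinfo(k).max)
    for k in ("uint8", "uint16", "uint32", "int8", "int16", "int32")
}


@dataclasses.dataclass
class ImageStack:
    """A 3-D grayscale volume with physical voxel size.

    Attributes
    ----------
    data:
        Scalar grid indexed ``(z, y, x)``.
    voxel_size:
        ``(dz, dy, dx)`` in µm; every component finite and > 0.
    dtype_range:
        ``(min, max)`` representable by the source bit depth (for floats,
        the observed data range).
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    dtype_range: tuple[float, float] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(
                f"stack must be 3-D with every axis >= 1, got shape {self.data.shape}"
            )
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or not all(np.isfinite(v) and v > 0 for v in vs):
            raise ValueError(f"voxel_size must be 3 positive finite values, got {self.voxel_size}")
        self.voxel_size = vs
        if self.dtype_range is None:
            if self.data.dtype in _INT_RANGES:
                self.dtype_range = tuple(float(v) for v in _INT_RANGES[self.data.dtype])
            else:
                self.dtype_range = (float(self.data.min()), float(self.data.max()))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclasses.dataclass
class MarkerSet:
    """Labelled voxel coordinates (soma / core / spine-centre markers)."""

    markers: list[tuple[int, int, int, int]]  # (label, z, y, x)
    kind: str = "soma"

    VALID_KINDS = ("soma", "core", "spine_center")

    def __post_init__(self) -> None:
        if self.kind not in self.VALID_KINDS:
            raise ValueError(f"kind must be one of {self.VALID_KINDS}, got {self.kind!r}")
        labels = [m[0] for m in self.markers]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate marker labels: {dupes}")
        if any(l < 1 for l in labels):
            raise ValueError("marker labels must be positive integers")

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)

    def validate_bounds(self, shape: Sequence[int]) -> None:
        """Raise if any marker falls outside a ``(z, y, x)`` grid of `shape`."""
        for label, z, y, x in self.markers:
            if not (0 <= z < shape[0] and 0 <= y < shape[1] and 0 <= x < shape[2]):
                raise ValueError(
                    f"marker {label} at (z={z}, y={y}, x={x}) outside volume of shape {tuple(shape)}"
                )


@dataclasses.dataclass
class PipelineConfig:
    """Parameters driving the full segmentation/parcellation pipeline.

    ``sigmas`` are Gaussian standard deviations in voxels; ``0`` means the
    derivatives are taken on the unsmoothed stack. Defaults mirror the
    published protocol: 10 k-means replicates, at most 1000 iterations each,
    and removal of connected clusters below 7 voxels (the smallest
    3-D-symmetric structure).
    """

    sigmas: list[float] = dataclasses.field(default_factory=lambda: [0.0])
    kmeans_replicates: int = 10
    kmeans_max_iter: int = 1000
    background_threshold: tuple[str, float | None] = ("percentile", 75.0)
    min_cluster_voxels: int = 7
    core_size_threshold: int = 500
    log_transform: bool = False
    standardize_features: bool = True
    K: int | str = "auto"
    K_min: int = 2
    K_max: int = 10
    core_radius: int = 2
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not self.sigmas:
            raise ValueError("sigmas must be non-empty")
        if self.kmeans_replicates < 1 or self.kmeans_max_iter < 1:
            raise ValueError("kmeans_replicates and kmeans_max_iter must be positive")
        if self.min_cluster_voxels < 1:
            raise ValueError("min_cluster_voxels must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "background_threshold" in raw and isinstance(raw["background_threshold"], list):
            raw["background_threshold"] = tuple(raw["background_threshold"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["background_threshold"] = list(d["background_threshold"])
        return d


# ---------------------------------------------------------------------------
# TIFF stacks


def read_stack(path: str | Path, voxel_size: Sequence[float] | None = None) -> ImageStack:
    """Read a single- or multi-page grayscale TIFF as an ``ImageStack``.

    `voxel_size` is ``(dz, dy, dx)`` in µm. When omitted, the TIFF's
    resolution metadata is consulted; if that is absent too, (1, 1, 1) µm is
    assumed with a logged warning — metric morphometrics depend on it.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        if tf.pages[0].samplesperpixel > 1:
            raise ValueError("multi-channel input not supported")
        data = tf.asarray()
        meta_vs = _voxel_size_from_tiff(tf)
    if data.ndim == 2:
        logger.warning("%s is a single 2-D image; treating it as a one-slice volume", path)
        data = data[np.newaxis]
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3-D grayscale volume (z, y, x) but found "
            f"{data.ndim} axes; drop the extra channel/time axis (axis 0 of shape "
            f"{data.shape})"
        )
    if voxel_size is None:
        voxel_size = meta_vs
    if voxel_size is None:
        logger.warning("%s: no voxel size given or found in metadata; assuming 1 µm isotropic", path)
        voxel_size = (1.0, 1.0, 1.0)
    return ImageStack(data=data, voxel_size=tuple(voxel_size))


def _voxel_size_from_tiff(tf: "tifffile.TiffFile") -> tuple[float, float, float] | None:
    """Best-effort ``(dz, dy, dx)`` µm from ImageJ-style metadata."""
    try:
        meta = tf.imagej_metadata or {}
        page = tf.pages[0]
        xres = page.tags.get("XResolution")
        yres = page.tags.get("YResolution")
        if xres and yres and "spacing" in meta:
            dx = xres.value[1] / xres.value[0]
            dy = yres.value[1] / yres.value[0]
            dz = float(meta["spacing"])
            if dx > 0 and dy > 0 and dz > 0:
                return (dz, dy, dx)
    except Exception:  # pragma: no cover - metadata oddities
        pass
    return None


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as multi-page TIFF, preserving integer values losslessly."""
    # explicit photometric: a leading axis of length <= 4 must not be read as color
    tifffile.imwrite(Path(path), stack.data, photometric="minisblack")


def write_labels(labels: np.ndarray, path: str | Path) -> None:
    """Write a non-negative integer label volume as multi-page TIFF.

    The smallest unsigned integer type holding ``max(labels)`` is used, so
    round-trips through :func:`read_labels` are exact.
    """
    labels = np.asarray(labels)
    if labels.ndim != 3:
        raise ValueError(f"labels must be 3-D, got shape {labels.shape}")
    if not np.issubdtype(labels.dtype, np.integer):
        raise ValueError("labels must be an integer volume")
    if labels.size and labels.min() < 0:
        raise ValueError("labels must be non-negative (0 = background)")
    mx = int(labels.max()) if labels.size else 0
    for dt in (np.uint8, np.uint16, np.uint32, np.uint64):
        if mx <= np.iinfo(dt).max:
            tifffile.imwrite(Path(path), labels.astype(dt), photometric="minisblack")
            return


def read_labels(path: str | Path) -> np.ndarray:
    data = tifffile.imread(Path(path))
    if data.ndim == 2:
        data = data[np.newaxis]
    return data


# ---------------------------------------------------------------------------
# Marker CSV


def read_markers(path: str | Path, kind: str = "soma") -> MarkerSet:
    """Read a ``label,z,y,x`` CSV (0-based voxel coordinates) into a MarkerSet.

    Exact duplicate rows are dropped; two rows sharing a label but differing
    in coordinates are an error. Bounds are checked at use time against the
    stack the markers are applied to.
    """
    df = pd.read_csv(path)
    required = ["label", "z", "y", "x"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"marker CSV missing columns {missing}; need header label,z,y,x")
    df = df[required].drop_duplicates()
    markers = [(int(r.label), int(r.z), int(r.y), int(r.x)) for r in df.itertuples()]
    return MarkerSet(markers=markers, kind=kind)


def write_markers(markers: MarkerSet, path: str | Path) -> None:
    df = pd.DataFrame(markers.markers, columns=["label", "z", "y", "x"])
    df.to_csv(path, index=False)
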