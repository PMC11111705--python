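"""Step 2: marker-controlled watershed parcellation.

The binary segmentation says which voxels are neuron; it does not say
*which* neuron. Two situations require a second step: touching neurons
merged into one component must be split, and detached structures — spine
heads whose necks are too dim to segment — must be grouped with their
parent dendrite.

Both are solved topographically. The grayscale stack is median-filtered
(3×3×3), complemented so bright structures become valleys, and all regional
minima except those at the neuronal cores are erased by morphological
reconstruction. The watershed transform of the imposed surface then yields
exactly one catchment basin per core; each segmented voxel inherits the
label of its basin's core, with whole detached clusters assigned to the
basin holding the majority of their voxels.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
from scipy import ndimage
from skimage.morphology import reconstruction
from skimage.segmentation import find_boundaries, watershed

from .io import ImageStack, MarkerSet
from .segmentation import STRUCT_26

logger = logging.getLogger("senpai")


@dataclasses.dataclass
class CoreSet:
    """Seed regions for catchment basins, one positive label per neuronal core.

    A core is the most discernible portion of a neuron — soma or thickest
    trunk. ``seeds`` is a full-volume integer label image (0 elsewhere);
    cores are disjoint by construction.
    """

    seeds: np.ndarray
    origin: str  # "manual" | "auto"
    size_threshold: int | None = None

    @property
    def labels(self) -> list[int]:
        vals = np.unique(self.seeds)
        return [int(v) for v in vals if v > 0]


@dataclasses.dataclass
class ParcellationResult:
    """Outcome of the watershed parcellation.

    ``labels`` carries a core label on every segmented voxel (0 on
    background); ``basins`` tiles the whole volume with basin ids equal to
    core labels; ``assignments`` records, per non-core cluster, which core
    won and by which rule; ``watershed_lines`` marks inter-basin boundaries.
    """

    labels: np.ndarray
    basins: np.ndarray
    assignments: list[dict]
    watershed_lines: np.ndarray
    cores: CoreSet


def define_cores_auto(mask: np.ndarray, size_threshold: int) -> tuple[CoreSet, list[np.ndarray]]:
    """Split mask components into cores (large) and spine clusters (small).

    In super-resolution imagery the dendrite branch is by far the largest
    connected component and the detached spine heads are small; a size
    threshold separates the two roles. Returns the core seed volume and the
    list of spine-cluster voxel masks awaiting assignment.
    """
    mask = np.asarray(mask, dtype=bool)
    if size_threshold < 1:
        raise ValueError("size_threshold must be >= 1")
    if not mask.any():
        raise ValueError("mask is empty")
    comp, n = ndimage.label(mask, structure=STRUCT_26)
    sizes = ndimage.sum_labels(mask, comp, index=np.arange(1, n + 1))
    core_ids = [i + 1 for i, s in enumerate(sizes) if s >= size_threshold]
    if not core_ids:
        raise ValueError(
            f"no core found: largest component has {int(sizes.max())} voxels "
            f"< threshold {size_threshold}"
        )
    seeds = np.zeros(mask.shape, dtype=np.int32)
    for new, cid in enumerate(core_ids, start=1):
        seeds[comp == cid] = new
    spine_clusters = [comp == (i + 1) for i, s in enumerate(sizes) if s < size_threshold]
    logger.info("define_cores_auto: %d cores, %d spine clusters (threshold %d)",
                len(core_ids), len(spine_clusters), size_threshold)
    return CoreSet(seeds=seeds, origin="auto", size_threshold=size_threshold), spine_clusters


def define_cores_manual(
    mask: np.ndarray, markers: MarkerSet, radius: int = 2
) -> CoreSet:
    """Seed one core per user marker: a ball of `radius` voxels, clipped.

    A single-click marker would make a fragile one-voxel minimum; dilating
    it to a small ball makes the imposed well robust. Marker labels become
    core labels. Markers outside the mask are accepted with a warning (the
    soma may simply be under-segmented), overlapping seed balls are an
    error.
    """
    mask = np.asarray(mask, dtype=bool)
    markers.validate_bounds(mask.shape)
    seeds = np.zeros(mask.shape, dtype=np.int32)
    ball_offsets = _ball_offsets(radius)
    for label, z, y, x in markers:
        if not mask[z, y, x]:
            warnings.warn(
                f"marker {label} at (z={z}, y={y}, x={x}) lies outside the segmentation "
                "mask; the soma may be under-segmented", stacklevel=2,
            )
        for dz, dy, dx in ball_offsets:
            zz, yy, xx = z + dz, y + dy, x + dx
            if 0 <= zz < mask.shape[0] and 0 <= yy < mask.shape[1] and 0 <= xx < mask.shape[2]:
                prev = seeds[zz, yy, xx]
                if prev and prev != label:
                    raise ValueError(
                        f"seed regions of markers {prev} and {label} overlap at "
                        f"(z={zz}, y={yy}, x={xx}); increase marker spacing or reduce radius"
                    )
                seeds[zz, yy, xx] = label
    return CoreSet(seeds=seeds, origin="manual")


def _ball_offsets(radius: int) -> list[tuple[int, int, int]]:
    r = int(radius)
    out = []
    for dz in range(-r, r + 1):
        for dy in range(-r, r + 1):
            for dx in range(-r, r + 1):
                if dz * dz + dy * dy + dx * dx <= r * r:
                    out.append((dz, dy, dx))
    return out


def impose_minima(surface: np.ndarray, core_mask: np.ndarray) -> np.ndarray:
    """Erase every regional minimum of `surface` except those at `core_mask`.

    Classic minima imposition by erosion-type morphological reconstruction:
    a marker image sits at the global floor on cores and at the ceiling
    elsewhere, and is reconstructed under ``min(surface + 1, marker)``. The
    result has regional minima exactly at the core regions, so the watershed
    floods one basin per core.
    """
    surface = np.asarray(surface, dtype=np.float64)
    core_mask = np.asarray(core_mask, dtype=bool)
    rng = surface.max() - surface.min()
    h = 1.0 if rng == 0 else max(1.0, rng * 1e-3)
    lo = surface.min() - h
    hi = surface.max() + h
    marker = np.where(core_mask, lo, hi)
    mask_img = np.where(core_mask, lo, np.minimum(surface + h, hi))
    return reconstruction(marker, mask_img, method="erosion", footprint=STRUCT_26)


def parcellate(stack: ImageStack, mask: np.ndarray, cores: CoreSet) -> ParcellationResult:
    """Watershed parcellation of the segmentation given the core seeds.

    Pipeline: 3×3×3 median filter on the grayscale (reflection padding) →
    complement (``max − filtered``) → impose minima at the core voxels →
    priority-flood watershed with 26-connectivity, seeded at the cores so
    every voxel of the volume joins exactly one basin (no unlabeled ridge
    voxels). Whole non-core clusters of the mask are then assigned to a
    single core by majority basin; components containing two or more cores
    are split voxelwise along the watershed lines.
    """
    mask = np.asarray(mask, dtype=bool)
    labels_list = cores.labels
    if not labels_list:
        raise ValueError("cores is empty")
    if cores.seeds.shape != mask.shape or stack.shape != mask.shape:
        raise ValueError("stack, mask and cores must share one grid")
    filtered = ndimage.median_filter(np.asarray(stack.data, dtype=np.float64),
                                     size=3, mode="reflect")
    complement = filtered.max() - filtered
    core_mask = cores.seeds > 0
    imposed = impose_minima(complement, core_mask)
    basins = watershed(imposed, markers=cores.seeds, connectivity=STRUCT_26)
    # imposition guarantees every basin is seeded by a core
    assert set(np.unique(basins)) <= set(labels_list) | {0}
    assert (basins > 0).all(), "unseeded basin voxels after minima imposition"
    watershed_lines = find_boundaries(basins, connectivity=3, mode="thick") & (basins > 0)

    comp, n = ndimage.label(mask, structure=STRUCT_26)
    labels = np.zeros(mask.shape, dtype=np.int32)
    assignments: list[dict] = []
    for cid in range(1, n + 1):
        cluster = comp == cid
        cores_inside = {int(v) for v in np.unique(cores.seeds[cluster]) if v > 0}
        if len(cores_inside) >= 2:
            # merged neurons: split voxelwise along basin boundaries
            labels[cluster] = basins[cluster]
            assignments.append({"cluster": cid, "core": sorted(cores_inside),
                                "rule": "voxelwise-split", "tie": False})
        elif len(cores_inside) == 1:
            core = cores_inside.pop()
            labels[cluster] = core
            assignments.append({"cluster": cid, "core": core, "rule": "contains-core",
                                "tie": False})
        else:
            core, rule, tie = _majority_core(cluster, basins)
            labels[cluster] = core
            assignments.append({"cluster": cid, "core": core, "rule": rule, "tie": tie})
    return ParcellationResult(labels=labels, basins=basins, assignments=assignments,
                              watershed_lines=watershed_lines, cores=cores)


def _majority_core(cluster: np.ndarray, basins: np.ndarray) -> tuple[int, str, bool]:
    """Majority-basin rule with centroid then lowest-label tie-breaks."""
    vals, counts = np.unique(basins[cluster], return_counts=True)
    best = counts.max()
    winners = sorted(int(v) for v, c in zip(vals, counts) if c == best)
    if len(winners) == 1:
        return winners[0], "majority", False
    zyx = np.argwhere(cluster)
    cz, cy, cx = np.round(zyx.mean(axis=0)).astype(int)
    centroid_basin = int(basins[cz, cy, cx])
    if centroid_basin in winners:
        return centroid_basin, "centroid-tiebreak", True
    return winners[0], "lowest-label-tiebreak", True


def assign_clusters(mask: np.ndarray, basins: np.ndarray,
                    cores: CoreSet) -> list[dict]:
    """Assignment table for every non-core 26-connected cluster of `mask`.

    Each cluster goes, whole, to the core whose basin holds the majority of
    its voxels; ties fall to the basin containing the cluster centroid, then
    to the lowest core label. Exposed separately from :func:`parcellate` for
    reporting and testing.
    """
    mask = np.asarray(mask, dtype=bool)
    comp, n = ndimage.label(mask, structure=STRUCT_26)
    table = []
    for cid in range(1, n + 1):
        cluster = comp == cid
        cores_inside = {int(v) for v in np.unique(cores.seeds[cluster]) if v > 0}
        if cores_inside:
            continue
        core, rule, tie = _majority_core(cluster, basins)
        table.append({"cluster": cid, "core": core, "rule": rule, "tie": tie})
    return table


def correct_parcellation(
    result: ParcellationResult,
    stack: ImageStack,
    mask: np.ndarray,
    extra_markers: MarkerSet,
    radius: int = 2,
) -> ParcellationResult:
    """Re-parcellate with additional cores for misassigned branches.

    Typical use: a branch whose soma lies outside the acquired volume was
    swallowed by a neighbouring core; marking it adds a core of its own and
    the watershed re-runs with the enlarged core set. With no extra markers
    the result is unchanged.
    """
    if len(extra_markers) == 0:
        return result
    extra_markers.validate_bounds(mask.shape)
    old_labels = set(result.cores.labels)
    seeds = result.cores.seeds.copy()
    extra = define_cores_manual(mask, _relabel_clear(extra_markers, old_labels), radius=radius)
    overlap = (seeds > 0) & (extra.seeds > 0)
    if overlap.any():
        z, y, x = np.argwhere(overlap)[0]
        raise ValueError(
            f"extra marker seed overlaps existing core {int(seeds[z, y, x])} at "
            f"(z={z}, y={y}, x={x})"
        )
    seeds[extra.seeds > 0] = extra.seeds[extra.seeds > 0]
    merged = CoreSet(seeds=seeds, origin=result.cores.origin,
                     size_threshold=result.cores.size_threshold)
    return parcellate(stack, mask, merged)


def _relabel_clear(markers: MarkerSet, taken: set[int]) -> MarkerSet:
    """Shift extra-marker labels above any existing core label if they collide."""
    if not any(m[0] in taken for m in markers):
        return markers
    base = max(taken)
    shifted = [(base + i, z, y, x) for i, (_, z, y, x) in enumerate(markers, start=1)]
    return MarkerSet(markers=shifted, kind=markers.kind)
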