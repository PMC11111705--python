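"""End-to-end orchestration: segment → parcellate → skeletonize → morphometrics.

Each stage is the public module function called with the shared
:class:`~senpai.io.PipelineConfig`; the pipeline adds only sequencing,
persistence of intermediates and a provenance record sufficient to re-run
the deterministic stages bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd

from . import morphometrics as mm
from .io import ImageStack, MarkerSet, PipelineConfig, write_labels, write_stack
from .parcellation import ParcellationResult, define_cores_auto, define_cores_manual, parcellate
from .segmentation import SegmentationMask, segment
from .skeleton import skeleton_to_swc, write_swc

logger = logging.getLogger("senpai")


def _tool_version() -> str:
    try:
        return version("senpai")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


@dataclasses.dataclass
class RunProvenance:
    config: dict
    stages: dict
    tool_version: str
    started: float
    finished: float | None = None

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return str(obj)


@dataclasses.dataclass
class PipelineResult:
    segmentation: SegmentationMask
    parcellation: ParcellationResult
    swc: dict[int, pd.DataFrame]
    morphometry: dict[int, dict]
    provenance: RunProvenance


def run_pipeline(
    config: PipelineConfig,
    stack: ImageStack,
    markers: MarkerSet | None = None,
    auto_cores: bool = False,
    outdir: str | Path | None = None,
    sholl_step: float = 1.0,
) -> PipelineResult:
    """Run the full reconstruction on one stack.

    `markers` seeds the cores manually (standard-microscopy mode); with
    ``auto_cores`` the cores are instead the mask components larger than
    ``config.core_size_threshold`` (super-resolution mode). Validation runs
    before any computation; stage failures surface with the stage named.
    Intermediates and provenance are written under `outdir` when given.
    """
    if markers is None and not auto_cores:
        raise ValueError("markers are required unless auto_cores is enabled")
    if markers is not None:
        markers.validate_bounds(stack.shape)
    prov = RunProvenance(config=config.to_dict(), stages={},
                         tool_version=_tool_version(), started=time.time())
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    seg = _stage("segment", segment, stack, config)
    prov.stages["segment"] = {"provenance": seg.provenance,
                              "mask_voxels": int(seg.mask.sum())}
    if outdir is not None:
        write_labels(seg.mask.astype(np.uint8), outdir / "mask.tif")

    if auto_cores:
        cores, spine_clusters = _stage("define_cores", define_cores_auto,
                                       seg.mask, config.core_size_threshold)
        prov.stages["cores"] = {"origin": "auto", "n_cores": len(cores.labels),
                                "n_spine_clusters": len(spine_clusters),
                                "size_threshold": config.core_size_threshold}
    else:
        cores = _stage("define_cores", define_cores_manual, seg.mask, markers,
                       config.core_radius)
        prov.stages["cores"] = {"origin": "manual", "n_cores": len(cores.labels)}

    parc = _stage("parcellate", parcellate, stack, seg.mask, cores)
    prov.stages["parcellate"] = {"assignments": parc.assignments,
                                 "labels": cores.labels}
    if outdir is not None:
        write_labels(parc.labels, outdir / "labels.tif")

    marker_pos = {label: (z, y, x) for label, z, y, x in markers} if markers else {}
    swc_tables: dict[int, pd.DataFrame] = {}
    morpho: dict[int, dict] = {}
    for label in cores.labels:
        neuron_mask = _largest_component(parc.labels == label)
        if neuron_mask is None:
            logger.warning("core %d has no voxels in the parcellation; skipping", label)
            continue
        soma = marker_pos.get(label) or tuple(
            int(v) for v in np.argwhere(cores.seeds == label).mean(axis=0).round())
        try:
            swc = skeleton_to_swc(neuron_mask, stack, soma)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage 'skeletonize' failed on neuron {label}: {exc}") from exc
        swc_tables[label] = swc
        if outdir is not None:
            write_swc(swc, outdir / f"neuron_{label}.swc")
        morpho[label] = _stage("morphometrics", _neuron_morphometry, swc,
                               neuron_mask, stack.voxel_size, sholl_step)
    prov.stages["morphometrics"] = {k: {kk: vv for kk, vv in v.items() if kk != "sholl_profile"}
                                    for k, v in morpho.items()}
    prov.finished = time.time()
    if outdir is not None:
        prov.to_json(outdir / "provenance.json")
    return PipelineResult(segmentation=seg, parcellation=parc, swc=swc_tables,
                          morphometry=morpho, provenance=prov)


def _largest_component(mask: np.ndarray) -> np.ndarray | None:
    from scipy import ndimage

    from .segmentation import STRUCT_26
    if not mask.any():
        return None
    comp, n = ndimage.label(mask, structure=STRUCT_26)
    if n == 1:
        return mask
    sizes = ndimage.sum_labels(mask, comp, index=np.arange(1, n + 1))
    return comp == (int(np.argmax(sizes)) + 1)


def _neuron_morphometry(swc: pd.DataFrame, mask: np.ndarray,
                        voxel_size: tuple[float, float, float],
                        sholl_step: float) -> dict:
    area, volume, ratio = mm.area_volume(mask, voxel_size)
    out = {"surface_area_um2": area, "volume_um3": volume, "area_volume_ratio": ratio,
           "cable_length_um": None, "strahler": None, "sholl_auc": None}
    from .skeleton import swc_cable_length
    out["cable_length_um"] = swc_cable_length(swc)
    if len(swc) > 1:
        table = mm.strahler_stats(swc)
        out["strahler"] = table.to_dict()
        root = swc[swc["parent"] == -1].iloc[0]
        pos = swc[["x", "y", "z"]].to_numpy()
        max_r = float(np.linalg.norm(pos - np.array([root.x, root.y, root.z]), axis=1).max())
        if max_r > sholl_step:
            radii = np.arange(sholl_step, max_r + sholl_step, sholl_step)
            profile = mm.sholl(swc, radii)
            out["sholl_auc"] = profile.auc
            out["sholl_profile"] = {"radii": profile.radii.tolist(),
                                    "crossings": profile.crossings.tolist()}
    return out
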