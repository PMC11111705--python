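"""Reduce a single-neuron binary segmentation to a rooted tree and SWC.

The volumetric mask is thinned to 1-voxel-wide centerlines
(topology-preserving 3-D thinning), every skeleton voxel becomes a graph
node connected to its 26-neighbours, cycles are cut where the image
intensity is lowest, and the tree is rooted at the node nearest the soma
marker. The result is written as standard 7-column SWC with coordinates and
radii in micrometres.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import skeletonize as _sk_skeletonize

from .io import ImageStack
from .segmentation import STRUCT_26

logger = logging.getLogger("senpai")


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Topology-preserving 3-D thinning of a single connected component.

    The skeleton is a subset of the mask. Multi-component input is refused
    with the component sizes listed — skeletonize one separated neuron at a
    time.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    comp, n = ndimage.label(mask, structure=STRUCT_26)
    if n > 1:
        sizes = ndimage.sum_labels(mask, comp, index=np.arange(1, n + 1)).astype(int)
        raise ValueError(
            f"mask has {n} 26-connected components (sizes {sizes.tolist()}); "
            "skeletonize one component at a time"
        )
    if mask.sum() == 1:
        return mask.copy()
    skel = _sk_skeletonize(mask)  # Lee thinning for 3-D input
    if not skel.any():  # degenerate tiny blobs can thin away entirely
        z, y, x = np.argwhere(mask).mean(axis=0).round().astype(int)
        skel = np.zeros_like(mask)
        idx = np.argwhere(mask)
        nearest = idx[np.argmin(((idx - (z, y, x)) ** 2).sum(axis=1))]
        skel[tuple(nearest)] = True
    return skel


_NEIGHBOR_OFFSETS = [
    (dz, dy, dx)
    for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]


def graph_from_skeleton(
    skel: np.ndarray,
    stack: ImageStack,
    mask: np.ndarray,
    radius_mode: str = "edt",
    radius_calibration: float = 1.0,
) -> nx.Graph:
    """Undirected graph over skeleton voxels with physical edge lengths.

    One node per skeleton voxel (ids 1..N in lexicographic (z, y, x) order),
    an edge between every 26-neighbouring pair, edge length
    ``sqrt((Δz·dz)² + (Δy·dy)² + (Δx·dx)²)`` µm. Node attributes: ``pos``
    (voxel), ``intensity`` (raw stack at the node) and ``radius`` (µm).

    ``radius_mode="edt"`` takes the Euclidean distance transform of the mask
    (anisotropy-aware) at the node — a geometric local half-thickness.
    ``radius_mode="intensity"`` scales the node intensity by
    ``radius_calibration / max intensity on the skeleton``, for workflows
    calibrated against intensity instead of geometry.
    """
    skel = np.asarray(skel, dtype=bool)
    if not skel.any():
        raise ValueError("skeleton is empty")
    dz, dy, dx = stack.voxel_size
    coords = np.argwhere(skel)  # lexicographic by construction
    index = {tuple(c): i + 1 for i, c in enumerate(coords)}
    data = np.asarray(stack.data, dtype=np.float64)
    if radius_mode == "edt":
        edt = ndimage.distance_transform_edt(np.asarray(mask, dtype=bool),
                                             sampling=stack.voxel_size)
        radii = edt[skel]
    elif radius_mode == "intensity":
        vals = data[skel]
        mx = vals.max() if vals.max() > 0 else 1.0
        radii = vals / mx * radius_calibration
    else:
        raise ValueError(f"unknown radius_mode {radius_mode!r}")
    g = nx.Graph()
    for i, (c, r) in enumerate(zip(coords, radii), start=1):
        g.add_node(i, pos=tuple(int(v) for v in c), intensity=float(data[tuple(c)]),
                   radius=float(r))
    cset = set(map(tuple, coords))
    for c in coords:
        cz, cy, cx = (int(v) for v in c)
        for oz, oy, ox in _NEIGHBOR_OFFSETS:
            nb = (cz + oz, cy + oy, cx + ox)
            if nb in cset:
                a, b = index[(cz, cy, cx)], index[nb]
                if a < b:
                    length = math.sqrt((oz * dz) ** 2 + (oy * dy) ** 2 + (ox * dx) ** 2)
                    g.add_edge(a, b, length=length)
    return g


def break_cycles(graph: nx.Graph) -> nx.Graph:
    """Cut cycles where the image intensity is lowest.

    Equivalent to keeping the maximum-weight spanning tree with edge weight
    ``min(intensity of the two endpoints)``: any edge dropped from a cycle
    is (one of) its lowest-intensity edges. Deterministic tie-breaks: among
    equal weights the shorter edge is kept (longer removed first), then
    lexicographically smaller node ids win.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if not nx.is_connected(graph):
        raise ValueError("graph is disconnected; skeletonize one component at a time")
    edges = []
    for a, b, d in graph.edges(data=True):
        a, b = (a, b) if a < b else (b, a)
        w = min(graph.nodes[a]["intensity"], graph.nodes[b]["intensity"])
        edges.append((-w, d.get("length", 1.0), a, b, d))
    edges.sort(key=lambda e: (e[0], e[1], e[2], e[3]))
    uf = nx.utils.UnionFind(graph.nodes)
    tree = nx.Graph()
    tree.add_nodes_from(graph.nodes(data=True))
    for _, _, a, b, d in edges:
        if uf[a] != uf[b]:
            uf.union(a, b)
            tree.add_edge(a, b, **d)
    return tree


def root_tree(tree: nx.Graph, soma_marker: tuple[int, int, int],
              voxel_size: tuple[float, float, float]) -> tuple[nx.DiGraph, int]:
    """Orient the tree away from the node nearest the soma marker.

    `soma_marker` is a (z, y, x) voxel coordinate; distances are physical.
    Returns the directed tree (edges parent → child) and the root id.
    """
    dz, dy, dx = voxel_size
    mz, my, mx = soma_marker
    best, best_d = None, math.inf
    for n, d in tree.nodes(data=True):
        pz, py, px = d["pos"]
        dist = ((pz - mz) * dz) ** 2 + ((py - my) * dy) ** 2 + ((px - mx) * dx) ** 2
        if dist < best_d or (dist == best_d and (best is None or n < best)):
            best, best_d = n, dist
    rooted = nx.bfs_tree(tree, best)
    for n, d in tree.nodes(data=True):
        rooted.nodes[n].update(d)
    for a, b in rooted.edges():
        rooted.edges[a, b].update(tree.edges[a, b])
    return rooted, best


# ---------------------------------------------------------------------------
# SWC


def tree_to_swc(rooted: nx.DiGraph, root: int,
                voxel_size: tuple[float, float, float]) -> pd.DataFrame:
    """Rooted tree → SWC table (id, type, x, y, z, radius, parent), µm.

    Nodes are renumbered in BFS order so every parent id precedes its
    children, as most SWC consumers expect. The root gets structure type 1
    (soma), all other nodes type 3 (dendrite); voxel indices are scaled by
    the voxel size into physical coordinates.
    """
    dz, dy, dx = voxel_size
    order = list(nx.bfs_tree(rooted, root).nodes())
    renum = {n: i + 1 for i, n in enumerate(order)}
    rows = []
    for n in order:
        pz, py, px = rooted.nodes[n]["pos"]
        preds = list(rooted.predecessors(n))
        parent = renum[preds[0]] if preds else -1
        rows.append({
            "id": renum[n],
            "type": 1 if n == root else 3,
            "x": px * dx, "y": py * dy, "z": pz * dz,
            "radius": rooted.nodes[n]["radius"],
            "parent": parent,
        })
    return pd.DataFrame(rows, columns=["id", "type", "x", "y", "z", "radius", "parent"])


def write_swc(swc: pd.DataFrame, path: str | Path, comment: str = "") -> None:
    """Write a standard whitespace-separated 7-column SWC file."""
    validate_swc(swc)
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("# id type x y z radius parent\n")
        for r in swc.itertuples(index=False):
            fh.write(f"{int(r.id)} {int(r.type)} {r.x:.6f} {r.y:.6f} {r.z:.6f} "
                     f"{r.radius:.6f} {int(r.parent)}\n")


def read_swc(path: str | Path) -> pd.DataFrame:
    """Parse an SWC file, validating structure and reporting the line on error."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ValueError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
            try:
                rows.append({
                    "id": int(parts[0]), "type": int(parts[1]),
                    "x": float(parts[2]), "y": float(parts[3]), "z": float(parts[4]),
                    "radius": float(parts[5]), "parent": int(parts[6]),
                })
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    swc = pd.DataFrame(rows, columns=["id", "type", "x", "y", "z", "radius", "parent"])
    validate_swc(swc)
    return swc


def validate_swc(swc: pd.DataFrame) -> None:
    """Check the SWC tree contract: one root, valid parents, acyclic."""
    if swc.empty:
        raise ValueError("SWC table is empty")
    ids = set(swc["id"].astype(int))
    if len(ids) != len(swc):
        raise ValueError("duplicate SWC node ids")
    roots = swc[swc["parent"] == -1]
    if len(roots) != 1:
        raise ValueError(f"SWC must have exactly one root, found {len(roots)}")
    parent = dict(zip(swc["id"].astype(int), swc["parent"].astype(int)))
    for i, p in parent.items():
        if p != -1 and p not in ids:
            raise ValueError(f"node {i} references missing parent {p}")
    # cycle check by walking to the root with a visited budget
    for i in parent:
        seen = set()
        j = i
        while j != -1:
            if j in seen:
                raise ValueError(f"cycle detected through node {i}")
            seen.add(j)
            j = parent[j]


def swc_cable_length(swc: pd.DataFrame) -> float:
    """Total cable length: sum of parent-edge Euclidean lengths in µm."""
    pos = {int(r.id): np.array([r.x, r.y, r.z]) for r in swc.itertuples(index=False)}
    total = 0.0
    for r in swc.itertuples(index=False):
        if int(r.parent) != -1:
            total += float(np.linalg.norm(pos[int(r.id)] - pos[int(r.parent)]))
    return total


def skeleton_to_swc(
    mask: np.ndarray,
    stack: ImageStack,
    soma_marker: tuple[int, int, int],
    radius_mode: str = "edt",
    radius_calibration: float = 1.0,
) -> pd.DataFrame:
    """End-to-end: binary mask + soma marker → SWC table.

    Convenience wrapper chaining :func:`skeletonize`,
    :func:`graph_from_skeleton`, :func:`break_cycles`, :func:`root_tree` and
    :func:`tree_to_swc`.
    """
    skel = skeletonize(mask)
    graph = graph_from_skeleton(skel, stack, mask, radius_mode=radius_mode,
                                radius_calibration=radius_calibration)
    tree = break_cycles(graph)
    rooted, root = root_tree(tree, soma_marker, stack.voxel_size)
    return tree_to_swc(rooted, root, stack.voxel_size)
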