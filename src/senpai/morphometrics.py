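"""Morphometric validation: Strahler ordering, Sholl analysis, overlap and
spine-detection metrics.

All tree-based quantities operate on an SWC table (id, type, x, y, z,
radius, parent; µm) as produced by :mod:`senpai.skeleton`. The tree is first
decomposed into *segments* — maximal node chains between topological points
(root, branch points, terminations) — and *branches* — maximal runs of
consecutive segments sharing one Strahler order.

Centripetal Horton-Strahler ordering: terminal segments have order 1; at a
junction the parent's order is ``s + 1`` when two or more children attain
the maximal child order ``s``, else the maximal child order. The Strahler
number SN is the largest order in the tree.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger("senpai")


# ---------------------------------------------------------------------------
# Tree / segment decomposition


@dataclasses.dataclass
class Segment:
    """Maximal chain between topological points, owned-node convention.

    ``nodes`` runs distal → proximal and *excludes* the proximal anchor
    (which belongs to its own rootward segment); ``anchor`` is that proximal
    topological point (the root for stem segments). ``length`` covers the
    edges from the distal end up to and including the edge into the anchor.
    """

    nodes: list[int]
    anchor: int
    length: float
    mean_diameter: float
    so: int = 0


@dataclasses.dataclass
class SegmentDecomposition:
    segments: list[Segment]
    children: dict[int, list[int]]   # segment index -> child segment indices
    roots: list[int]                 # stem segment indices (anchored at the tree root)
    node_so: dict[int, int]
    root_id: int


@dataclasses.dataclass
class StrahlerTable:
    """Per-order morphometric summary of one neuronal tree.

    Vectors are indexed by order ``1..SN`` (position 0 = order 1). The fit
    coefficients ``PSnum``/``PBnum`` are (slope, intercept) of the
    normalized segment/branch counts against order, on the configured scale
    (log10 by default); they are ``None`` when only one order exists.
    """

    SN: int
    numSegSO: np.ndarray
    numSegSOnorm: np.ndarray
    numBrSO: np.ndarray
    numBrSOnorm: np.ndarray
    bifurcation_ratio: np.ndarray    # length SN-1: numBr(i)/numBr(i+1)
    TopoSubLAve: np.ndarray
    segDAve: np.ndarray
    brDAve: np.ndarray
    segLAve: np.ndarray
    brLAve: np.ndarray
    TOTL: float
    normTotL: np.ndarray
    PSnum: tuple[float, float] | None
    PBnum: tuple[float, float] | None

    def to_dict(self) -> dict:
        d = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            d[f.name] = v.tolist() if isinstance(v, np.ndarray) else v
        return d


def _tree_maps(swc: pd.DataFrame):
    ids = swc["id"].astype(int).to_numpy()
    parents = swc["parent"].astype(int).to_numpy()
    pos = {i: np.array([x, y, z]) for i, x, y, z in
           zip(ids, swc["x"], swc["y"], swc["z"])}
    radius = dict(zip(ids, swc["radius"].astype(float)))
    parent = dict(zip(ids, parents))
    children: dict[int, list[int]] = {i: [] for i in ids}
    root = None
    for i, p in zip(ids, parents):
        if p == -1:
            root = i
        else:
            children[p].append(i)
    if root is None:
        raise ValueError("SWC has no root")
    return pos, radius, parent, children, root


def decompose(swc: pd.DataFrame) -> SegmentDecomposition:
    """Split the tree into segments and compute Strahler orders.

    Topological points are the root, every branch point (≥ 2 children) and
    every termination. Each non-root topological point defines one segment
    reaching rootward to its nearest topological ancestor. Node order = the
    order of the owning segment; the root node takes the maximal order of
    its stem segments.
    """
    pos, radius, parent, children, root = _tree_maps(swc)
    topo = {root} | {i for i, ch in children.items() if len(ch) >= 2} \
        | {i for i, ch in children.items() if len(ch) == 0}
    segments: list[Segment] = []
    seg_of_distal: dict[int, int] = {}
    for d in sorted(topo - {root}):
        nodes = [d]
        length = 0.0
        cur = d
        while True:
            p = parent[cur]
            length += float(np.linalg.norm(pos[cur] - pos[p]))
            if p in topo:
                anchor = p
                break
            nodes.append(p)
            cur = p
        diam = float(np.mean([2.0 * radius[n] for n in nodes]))
        seg_of_distal[d] = len(segments)
        segments.append(Segment(nodes=nodes, anchor=anchor, length=length,
                                mean_diameter=diam))
    # segment tree: a segment's children are the segments anchored at its distal end
    seg_children: dict[int, list[int]] = {i: [] for i in range(len(segments))}
    roots: list[int] = []
    for idx, seg in enumerate(segments):
        if seg.anchor == root:
            roots.append(idx)
        else:
            seg_children[seg_of_distal[seg.anchor]].append(idx)

    # centripetal orders, iterative post-order (deep trees are common)
    post: list[int] = []
    stack = list(roots)
    while stack:
        i = stack.pop()
        post.append(i)
        stack.extend(seg_children[i])
    for i in reversed(post):
        ch = seg_children[i]
        if not ch:
            segments[i].so = 1
        else:
            orders = [segments[c].so for c in ch]
            mx = max(orders)
            segments[i].so = mx + 1 if orders.count(mx) >= 2 else mx

    node_so = {}
    for seg in segments:
        for n in seg.nodes:
            node_so[n] = seg.so
    node_so[root] = max((segments[r].so for r in roots), default=1)
    return SegmentDecomposition(segments=segments, children=seg_children,
                                roots=roots, node_so=node_so, root_id=root)


def strahler_order(swc: pd.DataFrame) -> tuple[dict[int, int], list[int]]:
    """Per-node and per-segment Strahler orders of an SWC tree."""
    dec = decompose(swc)
    return dec.node_so, [s.so for s in dec.segments]


def _count_fit(norm_counts: np.ndarray, scale: str) -> tuple[float, float] | None:
    orders = np.arange(1, len(norm_counts) + 1, dtype=float)
    keep = norm_counts > 0
    if keep.sum() < 2:
        return None
    y = norm_counts[keep]
    if scale == "log10":
        y = np.log10(y)
    elif scale == "natural":
        y = np.log(y)
    elif scale != "linear":
        raise ValueError(f"unknown fit scale {scale!r}")
    slope, intercept = np.polyfit(orders[keep], y, 1)
    return float(slope), float(intercept)


def strahler_stats(swc: pd.DataFrame, fit_scale: str = "log10") -> StrahlerTable:
    """Full per-order Strahler summary (counts, lengths, diameters, fits).

    Branches are maximal chains of same-order segments (a segment joins its
    parent's branch when their orders coincide, which happens exactly when
    the junction did not increment the order). ``TopoSubLAve[s]`` is the
    mean number of segments in the subtree hanging from (and including)
    each order-``s`` segment, normalized by the total segment count. With a
    single order the count fits are undefined and reported as ``None``.
    """
    dec = decompose(swc)
    segs = dec.segments
    if not segs:
        raise ValueError("tree has no segments (single-node SWC)")
    sn = max(s.so for s in segs)
    n_orders = sn

    num_seg = np.zeros(n_orders)
    seg_len = np.zeros(n_orders)
    seg_d = [[] for _ in range(n_orders)]
    for s in segs:
        num_seg[s.so - 1] += 1
        seg_len[s.so - 1] += s.length
        seg_d[s.so - 1].append(s.mean_diameter)

    # branches: union-find segments with their parent when orders match
    branch_of = list(range(len(segs)))

    def find(i):
        while branch_of[i] != i:
            branch_of[i] = branch_of[branch_of[i]]
            i = branch_of[i]
        return i

    seg_parent = {c: p for p, cs in dec.children.items() for c in cs}
    for c, p in seg_parent.items():
        if segs[c].so == segs[p].so:
            branch_of[find(c)] = find(p)
    branch_groups: dict[int, list[int]] = {}
    for i in range(len(segs)):
        branch_groups.setdefault(find(i), []).append(i)
    num_br = np.zeros(n_orders)
    br_len_acc = [[] for _ in range(n_orders)]
    br_d_acc = [[] for _ in range(n_orders)]
    for members in branch_groups.values():
        so = segs[members[0]].so
        num_br[so - 1] += 1
        br_len_acc[so - 1].append(sum(segs[m].length for m in members))
        n_nodes = sum(len(segs[m].nodes) for m in members)
        br_d_acc[so - 1].append(
            sum(segs[m].mean_diameter * len(segs[m].nodes) for m in members) / n_nodes
        )

    # subtree segment counts (inclusive), iterative post-order
    sub = np.ones(len(segs))
    order_stack = []
    visit = list(dec.roots)
    while visit:
        i = visit.pop()
        order_stack.append(i)
        visit.extend(dec.children[i])
    for i in reversed(order_stack):
        for c in dec.children[i]:
            sub[i] += sub[c]
    topo_sub = np.zeros(n_orders)
    for so in range(1, n_orders + 1):
        vals = [sub[i] for i, s in enumerate(segs) if s.so == so]
        topo_sub[so - 1] = np.mean(vals) / len(segs) if vals else 0.0

    totl = float(seg_len.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        bif = num_br[:-1] / num_br[1:] if n_orders > 1 else np.array([])
    table = StrahlerTable(
        SN=sn,
        numSegSO=num_seg,
        numSegSOnorm=num_seg / num_seg.sum(),
        numBrSO=num_br,
        numBrSOnorm=num_br / num_br.sum(),
        bifurcation_ratio=bif,
        TopoSubLAve=topo_sub,
        segDAve=np.array([np.mean(d) if d else np.nan for d in seg_d]),
        brDAve=np.array([np.mean(d) if d else np.nan for d in br_d_acc]),
        segLAve=np.array([seg_len[i] / num_seg[i] if num_seg[i] else np.nan
                          for i in range(n_orders)]),
        brLAve=np.array([np.mean(l) if l else np.nan for l in br_len_acc]),
        TOTL=totl,
        normTotL=seg_len / totl if totl > 0 else seg_len,
        PSnum=_count_fit(num_seg / num_seg.sum(), fit_scale),
        PBnum=_count_fit(num_br / num_br.sum(), fit_scale),
    )
    if table.PSnum is None:
        logger.info("strahler_stats: single order (SN=1); count fits undefined")
    return table


# ---------------------------------------------------------------------------
# Sholl


@dataclasses.dataclass
class ShollProfile:
    radii: np.ndarray
    crossings: np.ndarray
    auc: float


def sholl(swc: pd.DataFrame, radii: np.ndarray) -> ShollProfile:
    """Crossing counts of concentric spheres about the root, plus the AUC.

    An edge crosses the sphere of radius ``r`` when its endpoint distances
    to the root straddle ``r``: ``d_near ≤ r < d_far``. A sphere passing
    exactly through a node therefore crosses the node's outgoing edge once,
    and an arbor tip lying exactly at ``r`` does not count — so a straight
    10 µm path probed at radii 1..10 µm reads 1, 1, ..., 1, 0. The AUC is
    the trapezoidal integral of the crossing profile over the radii.
    """
    radii = np.asarray(radii, dtype=float)
    if len(radii) == 0 or np.any(np.diff(radii) <= 0) or radii[0] <= 0:
        raise ValueError("radii must be strictly increasing and start > 0")
    pos, _, parent, _, root = _tree_maps(swc)
    rpos = pos[root]
    dist = {i: float(np.linalg.norm(p - rpos)) for i, p in pos.items()}
    crossings = np.zeros(len(radii), dtype=int)
    for i, p in parent.items():
        if p == -1:
            continue
        lo, hi = sorted((dist[i], dist[p]))
        crossings += (lo <= radii) & (radii < hi)
    auc = float(np.trapezoid(crossings, radii))
    return ShollProfile(radii=radii, crossings=crossings, auc=auc)


# ---------------------------------------------------------------------------
# Mask metrics


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap ``2|A∩B| / (|A| + |B|)``; two empty masks count as 1."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        warnings.warn("dice of two empty masks defined as 1.0", stacklevel=2)
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def area_volume(mask: np.ndarray,
                voxel_size: tuple[float, float, float]) -> tuple[float, float, float]:
    """Surface area (µm²), volume (µm³) and their ratio for a voxel mask.

    Volume is the voxel count times the voxel volume; area sums the exposed
    voxel faces (faces against background or the volume border), each with
    its physical face area — exact for blocky shapes, slightly above the
    smooth-surface area for curved ones.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    dz, dy, dx = voxel_size
    volume = float(mask.sum()) * dz * dy * dx
    face_areas = (dy * dx, dz * dx, dz * dy)  # faces normal to z, y, x
    area = 0.0
    for axis, fa in enumerate(face_areas):
        diff = np.diff(mask.astype(np.int8), axis=axis)
        internal = int(np.abs(diff).sum())
        first = int(mask.take(0, axis=axis).sum())
        last = int(mask.take(-1, axis=axis).sum())
        area += fa * (internal + first + last)
    return area, volume, area / volume


# ---------------------------------------------------------------------------
# Spine detection metrics


def spine_metrics(
    predicted_clusters: list[tuple[np.ndarray, int]],
    truth_markers: list[tuple[tuple[int, int, int], int]],
) -> dict:
    """Sensitivity/precision of spine detection *and* assignment.

    `predicted_clusters` are ``(boolean voxel mask, assigned core label)``
    pairs; `truth_markers` are ``((z, y, x) centre, true parent core
    label)``. A truth spine is a true positive iff some predicted cluster
    contains its centre and carries the same core label; each predicted
    cluster can redeem at most one truth centre (the one nearest its
    centroid). A detected spine assigned to the wrong core counts as both a
    miss (FN) and a false alarm (FP).

    Returns TP/FN/FP and ``S%`` = 100·TP/(TP+FN), ``P%`` = 100·TP/(TP+FP).
    """
    matched_truth: set[int] = set()
    tp = fp = 0
    for mask, core in predicted_clusters:
        mask = np.asarray(mask, dtype=bool)
        inside = [t for t, ((z, y, x), _) in enumerate(truth_markers)
                  if t not in matched_truth and mask[z, y, x]]
        if not inside:
            fp += 1
            continue
        centroid = np.argwhere(mask).mean(axis=0)
        best = min(inside, key=lambda t: float(
            np.sum((np.array(truth_markers[t][0]) - centroid) ** 2)))
        matched_truth.add(best)
        if truth_markers[best][1] == core:
            tp += 1
        else:
            fp += 1  # the matched truth centre stays unredeemed -> FN below
    fn = len(truth_markers) - tp
    sens = 100.0 * tp / (tp + fn) if (tp + fn) else 100.0
    prec = 100.0 * tp / (tp + fp) if (tp + fp) else 100.0
    return {"TP": tp, "FN": fn, "FP": fp,
            "sensitivity_pct": sens, "precision_pct": prec}
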