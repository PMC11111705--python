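"""Seeded synthetic 3-D stacks with exact ground truth.

Phantoms emulate fluorescence stacks of sparsely labelled neurons: tube-like
dendrites and blob somata rasterized at a bright plateau over a dim
background, spine heads with faint or absent necks, anisotropic Gaussian
PSF blur (axially elongated, as in confocal/STED optics) and mixed
Poisson–Gaussian noise. Every ground-truth product — per-neuron masks, core
markers, spine centres with their parent labels, centerline SWC — derives
from the pre-noise geometry, so segmentation, parcellation, skeletonization
and the morphometric suite can each be scored exactly.

Geometry is specified in voxel units (centres and radii); physical metadata
enters only through ``voxel_size``. The noise model is
``Poisson(I / gain) · gain + N(0, read_noise)``: ``gain`` scales the
signal-dependent shot-noise variance (variance ``I · gain``), ``read_noise``
is the additive detector term.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import ImageStack, MarkerSet


@dataclasses.dataclass
class Tube:
    """Cylindrical structure along a polyline, radius in voxels."""

    points: list[tuple[float, float, float]]  # (z, y, x) voxel coords
    radius: float
    intensity: float | None = None  # None -> neuron default


@dataclasses.dataclass
class Ellipsoid:
    center: tuple[float, float, float]
    semiaxes: tuple[float, float, float]  # (az, ay, ax) voxels
    intensity: float | None = None


@dataclasses.dataclass
class Spine:
    """Spine head, optionally with a (dimmer) neck to an attachment point."""

    head_center: tuple[float, float, float]
    head_radius: float
    parent_neuron: int
    attachment: tuple[float, float, float] | None = None
    neck_radius: float | None = None  # None -> no neck (STED-like regime)


@dataclasses.dataclass
class NeuronSpec:
    tubes: list[Tube] = dataclasses.field(default_factory=list)
    somata: list[Ellipsoid] = dataclasses.field(default_factory=list)
    root: tuple[float, float, float] | None = None  # SWC root; default: first soma centre


@dataclasses.dataclass
class PhantomSpec:
    shape: tuple[int, int, int]
    neurons: list[NeuronSpec]
    spines: list[Spine] = dataclasses.field(default_factory=list)
    voxel_size: tuple[float, float, float] = (0.5, 0.25, 0.25)
    intensity: float = 200.0          # structure plateau
    background: float = 20.0
    neck_intensity_factor: float = 0.3
    psf_sigma: tuple[float, float, float] = (1.2, 0.8, 0.8)  # (σz, σy, σx) voxels
    gain: float = 4.0                 # shot-noise variance scale
    read_noise: float = 3.0           # additive Gaussian std
    target_snr: float | None = None   # overrides read_noise to hit a contrast/noise ratio
    seed: int = 0


@dataclasses.dataclass
class PhantomOutput:
    stack: ImageStack
    clean: np.ndarray                         # pre-noise, post-PSF image
    truth_masks: dict[int, np.ndarray]        # neuron id -> boolean mask (with spines)
    neuron_masks: dict[int, np.ndarray]       # neuron id -> mask without spines
    spine_masks: list[np.ndarray]
    spine_truth: list[tuple[tuple[int, int, int], int]]  # (centre voxel, parent label)
    core_markers: MarkerSet
    spine_markers: MarkerSet
    swc: dict[int, pd.DataFrame]
    contact_map: list[tuple[int, int, int]]   # (neuron a, neuron b, overlap voxels)
    spec: PhantomSpec

    @property
    def truth_mask(self) -> np.ndarray:
        out = np.zeros(self.stack.shape, dtype=bool)
        for m in self.truth_masks.values():
            out |= m
        return out


# ---------------------------------------------------------------------------
# Rasterization


def _paint_segment(canvas: np.ndarray, p: np.ndarray, q: np.ndarray, r: float) -> None:
    """Set voxels within distance `r` of segment pq (voxel space) to True."""
    lo = np.maximum(np.floor(np.minimum(p, q) - r - 1).astype(int), 0)
    hi = np.minimum(np.ceil(np.maximum(p, q) + r + 1).astype(int) + 1,
                    np.array(canvas.shape))
    if np.any(lo >= hi):
        return
    grids = np.meshgrid(*[np.arange(a, b) for a, b in zip(lo, hi)], indexing="ij")
    pts = np.stack([g.astype(float) for g in grids], axis=-1)
    d = q - p
    ll = float(d @ d)
    if ll == 0:
        dist2 = ((pts - p) ** 2).sum(axis=-1)
    else:
        t = np.clip(((pts - p) @ d) / ll, 0.0, 1.0)
        proj = p + t[..., None] * d
        dist2 = ((pts - proj) ** 2).sum(axis=-1)
    sub = canvas[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    sub |= dist2 <= r * r


def _paint_tube(canvas: np.ndarray, tube: Tube) -> None:
    pts = [np.asarray(p, dtype=float) for p in tube.points]
    if len(pts) == 1:
        _paint_segment(canvas, pts[0], pts[0], tube.radius)
    for p, q in zip(pts[:-1], pts[1:]):
        _paint_segment(canvas, p, q, tube.radius)


def _paint_ellipsoid(canvas: np.ndarray, ell: Ellipsoid) -> None:
    c = np.asarray(ell.center, dtype=float)
    a = np.asarray(ell.semiaxes, dtype=float)
    lo = np.maximum(np.floor(c - a - 1).astype(int), 0)
    hi = np.minimum(np.ceil(c + a + 1).astype(int) + 1, np.array(canvas.shape))
    grids = np.meshgrid(*[np.arange(x, y) for x, y in zip(lo, hi)], indexing="ij")
    pts = np.stack([g.astype(float) for g in grids], axis=-1)
    q = (((pts - c) / a) ** 2).sum(axis=-1)
    sub = canvas[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    sub |= q <= 1.0


# ---------------------------------------------------------------------------
# Ground-truth SWC


def _truth_swc(neuron: NeuronSpec, voxel_size: tuple[float, float, float]) -> pd.DataFrame:
    """Centerline SWC from the generating polylines (root = soma centre)."""
    dz, dy, dx = voxel_size
    if neuron.root is not None:
        root = np.asarray(neuron.root, dtype=float)
    elif neuron.somata:
        root = np.asarray(neuron.somata[0].center, dtype=float)
    elif neuron.tubes:
        root = np.asarray(neuron.tubes[0].points[0], dtype=float)
    else:
        raise ValueError("neuron has no geometry")
    nodes: list[np.ndarray] = [root]
    radii: list[float] = [float(neuron.somata[0].semiaxes[2] * dx) if neuron.somata
                          else float(neuron.tubes[0].radius * dx)]
    parents: list[int] = [-1]

    def phys(p: np.ndarray) -> np.ndarray:
        return p * np.array([dz, dy, dx])

    for tube in neuron.tubes:
        pts = [np.asarray(p, dtype=float) for p in tube.points]
        # attach the tube's first vertex to the nearest existing node
        d = [float(np.linalg.norm(phys(pts[0]) - phys(n))) for n in nodes]
        parent_idx = int(np.argmin(d))
        prev = parent_idx
        start = 0
        if np.allclose(pts[0], nodes[parent_idx]):
            start = 1
        for p in pts[start:]:
            nodes.append(p)
            radii.append(float(tube.radius * dx))
            parents.append(prev + 1)  # SWC ids are 1-based
            prev = len(nodes) - 1
    rows = []
    for i, (p, r, par) in enumerate(zip(nodes, radii, parents), start=1):
        rows.append({"id": i, "type": 1 if par == -1 else 3,
                     "x": p[2] * dx, "y": p[1] * dy, "z": p[0] * dz,
                     "radius": r, "parent": par if par == -1 else par})
    swc = pd.DataFrame(rows, columns=["id", "type", "x", "y", "z", "radius", "parent"])
    return swc


# ---------------------------------------------------------------------------
# Rendering


def render_phantom(spec: PhantomSpec) -> PhantomOutput:
    """Rasterize, blur, add noise; return the stack with all truth products.

    The seed fully determines the output. Structures from different neurons
    may overlap; overlaps are recorded in the contact map (they are exactly
    what the separation step is tested on).
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.shape)
    image = np.full(shape, float(spec.background))
    neuron_masks: dict[int, np.ndarray] = {}
    truth_masks: dict[int, np.ndarray] = {}
    core_rows = []
    for nid, neuron in enumerate(spec.neurons, start=1):
        m = np.zeros(shape, dtype=bool)
        for tube in neuron.tubes:
            sub = np.zeros(shape, dtype=bool)
            _paint_tube(sub, tube)
            image[sub] = np.maximum(image[sub], tube.intensity or spec.intensity)
            m |= sub
        for ell in neuron.somata:
            sub = np.zeros(shape, dtype=bool)
            _paint_ellipsoid(sub, ell)
            image[sub] = np.maximum(image[sub], ell.intensity or spec.intensity)
            m |= sub
        neuron_masks[nid] = m
        truth_masks[nid] = m.copy()
        root = neuron.root or (neuron.somata[0].center if neuron.somata
                               else neuron.tubes[0].points[0])
        core_rows.append((nid, *(int(round(v)) for v in root)))

    spine_masks: list[np.ndarray] = []
    spine_truth: list[tuple[tuple[int, int, int], int]] = []
    spine_rows = []
    for sid, spine in enumerate(spec.spines, start=1):
        sub = np.zeros(shape, dtype=bool)
        _paint_ellipsoid(sub, Ellipsoid(center=spine.head_center,
                                        semiaxes=(spine.head_radius,) * 3))
        image[sub] = np.maximum(image[sub], spec.intensity)
        if spine.neck_radius is not None and spine.attachment is not None:
            neck = np.zeros(shape, dtype=bool)
            _paint_segment(neck, np.asarray(spine.head_center, float),
                           np.asarray(spine.attachment, float), spine.neck_radius)
            neck &= ~sub
            image[neck] = np.maximum(
                image[neck], spec.background
                + spec.neck_intensity_factor * (spec.intensity - spec.background))
            sub |= neck
        spine_masks.append(sub)
        centre = tuple(int(round(v)) for v in spine.head_center)
        spine_truth.append((centre, spine.parent_neuron))
        truth_masks[spine.parent_neuron] |= sub
        spine_rows.append((sid, *centre))

    contact_map = []
    for a, b in itertools.combinations(sorted(truth_masks), 2):
        ov = int((truth_masks[a] & truth_masks[b]).sum())
        if ov:
            contact_map.append((a, b, ov))

    clean = image
    if any(s > 0 for s in spec.psf_sigma):
        clean = ndimage.gaussian_filter(image, sigma=spec.psf_sigma, mode="reflect")

    truth_all = np.zeros(shape, dtype=bool)
    for m in truth_masks.values():
        truth_all |= m

    def apply_noise(read: float) -> np.ndarray:
        local = np.random.default_rng(spec.seed)
        noisy = clean
        if spec.gain > 0:
            noisy = local.poisson(np.clip(clean, 0, None) / spec.gain) * spec.gain
        if read > 0:
            noisy = noisy + local.normal(0.0, read, size=shape)
        return np.clip(np.round(noisy), 0, 65535).astype(np.uint16)

    read_noise = spec.read_noise
    if spec.target_snr is not None:
        # analytic start, then a short fixed-point loop: clipping at zero
        # shrinks the observed background std, so the closed form undershoots
        want_var = ((spec.intensity - spec.background) / spec.target_snr) ** 2
        shot_var = spec.background * spec.gain
        read_noise = float(np.sqrt(max(want_var - shot_var, 1.0)))
        for _ in range(6):
            got = _snr(apply_noise(read_noise), truth_all)
            if abs(got - spec.target_snr) <= 0.02 * spec.target_snr:
                break
            read_noise *= got / spec.target_snr
    data = apply_noise(read_noise)

    stack = ImageStack(data=data, voxel_size=spec.voxel_size)
    swc = {nid: _truth_swc(n, spec.voxel_size) for nid, n in
           enumerate(spec.neurons, start=1) if (n.tubes or n.somata)}
    return PhantomOutput(
        stack=stack,
        clean=clean,
        truth_masks=truth_masks,
        neuron_masks=neuron_masks,
        spine_masks=spine_masks,
        spine_truth=spine_truth,
        core_markers=MarkerSet(markers=core_rows, kind="soma"),
        spine_markers=MarkerSet(markers=spine_rows, kind="spine_center"),
        swc=swc,
        contact_map=contact_map,
        spec=spec,
    )


def _snr(data: np.ndarray, fg: np.ndarray) -> float:
    """Contrast-to-noise: (interior mean − background mean) / background std."""
    data = data.astype(float)
    interior = ndimage.binary_erosion(fg, iterations=1)
    if not interior.any():
        interior = fg
    bg = ~ndimage.binary_dilation(fg, iterations=3)
    return float((data[interior].mean() - data[bg].mean()) / data[bg].std())


def measured_snr(output: PhantomOutput) -> float:
    """Empirical contrast-to-noise ratio of a rendered phantom."""
    return _snr(output.stack.data, output.truth_mask)


# ---------------------------------------------------------------------------
# Standard test battery


def standard_suite(seed: int = 0) -> dict[str, PhantomOutput]:
    """The fixed phantom battery exercising every pipeline stage.

    ``sphere`` — one bright soma (basic segmentation); ``tube`` — straight
    dendrite (skeleton axis check); ``y_tree`` — one bifurcation (topology);
    ``two_neurons`` — touching somata+dendrites (separation); ``spines`` —
    dendrite with detached spine heads, no necks (assignment); ``loop`` —
    closed circuit with an intensity dip (cycle breaking); ``two_scale`` —
    thick trunk plus thin processes (multi-scale merge).
    """
    suite: dict[str, PhantomOutput] = {}

    suite["sphere"] = render_phantom(PhantomSpec(
        shape=(40, 40, 40),
        neurons=[NeuronSpec(somata=[Ellipsoid((20, 20, 20), (8, 9, 9))])],
        seed=seed,
    ))

    suite["tube"] = render_phantom(PhantomSpec(
        shape=(24, 24, 64),
        neurons=[NeuronSpec(tubes=[Tube([(12, 12, 4), (12, 12, 59)], radius=3.0)])],
        seed=seed + 1,
    ))

    suite["y_tree"] = render_phantom(PhantomSpec(
        shape=(32, 48, 48),
        neurons=[NeuronSpec(tubes=[
            Tube([(16, 40, 24), (16, 24, 24)], radius=2.5),
            Tube([(16, 24, 24), (16, 8, 10)], radius=2.0),
            Tube([(16, 24, 24), (16, 8, 38)], radius=2.0),
        ])],
        seed=seed + 2,
    ))

    suite["two_neurons"] = render_phantom(PhantomSpec(
        shape=(32, 48, 72),
        neurons=[
            NeuronSpec(somata=[Ellipsoid((16, 24, 16), (6, 7, 7))],
                       tubes=[Tube([(16, 24, 16), (16, 24, 36)], radius=3.5)]),
            NeuronSpec(somata=[Ellipsoid((16, 24, 56), (6, 7, 7))],
                       tubes=[Tube([(16, 24, 56), (16, 24, 37)], radius=3.5)]),
        ],
        seed=seed + 3,
    ))

    spine_centres = [(10, 9, x) for x in (10, 22, 34, 46)] + \
                    [(22, 23, x) for x in (16, 28, 40, 52)]
    suite["spines"] = render_phantom(PhantomSpec(
        shape=(32, 32, 64),
        neurons=[NeuronSpec(tubes=[Tube([(16, 16, 4), (16, 16, 59)], radius=3.0)])],
        spines=[Spine(head_center=c, head_radius=2.0, parent_neuron=1)
                for c in spine_centres],
        seed=seed + 4,
    ))

    suite["loop"] = render_phantom(PhantomSpec(
        shape=(24, 48, 48),
        neurons=[NeuronSpec(tubes=[
            Tube([(12, 12, 12), (12, 12, 36), (12, 36, 36), (12, 36, 12), (12, 12, 12)],
                 radius=2.0),
            Tube([(12, 36, 12), (12, 44, 6)], radius=2.0),
            # dim chord closing the circuit: the preferred cut site
            Tube([(12, 12, 36), (12, 20, 40)], radius=2.0, intensity=90.0),
        ])],
        seed=seed + 5,
    ))

    suite["axis_tubes"] = render_phantom(PhantomSpec(
        shape=(64, 64, 64),
        neurons=[NeuronSpec(tubes=[
            Tube([(16, 16, 4), (16, 16, 60)], radius=7.0),
            Tube([(16, 4, 48), (16, 60, 48)], radius=7.0),
            Tube([(4, 48, 16), (60, 48, 16)], radius=7.0),
        ], root=(16, 16, 4))],
        seed=seed + 7,
    ))

    suite["two_scale"] = render_phantom(PhantomSpec(
        shape=(32, 40, 64),
        neurons=[NeuronSpec(tubes=[
            Tube([(16, 20, 4), (16, 20, 40)], radius=6.0),
            Tube([(16, 20, 40), (16, 8, 58)], radius=1.5),
            Tube([(16, 20, 40), (16, 32, 58)], radius=1.5),
        ])],
        seed=seed + 6,
    ))

    return suite


def random_neuron_phantom(seed: int, n_neurons: int = 2,
                          shape: tuple[int, int, int] = (48, 64, 64)) -> PhantomOutput:
    """Seeded stack of `n_neurons` somata with radiating dendrites.

    The end-to-end recovery testbed: each neuron is one ellipsoidal soma
    (semiaxes 5.5–7.5 voxels) with three straight dendrites of random
    orientation and radius 2.5–3.5 voxels. Neurons sit far enough apart that
    the ground truth stays unambiguous, close enough that their processes
    can touch — the case the parcellation has to untangle.
    """
    rng = np.random.default_rng(seed)
    centres = [(shape[0] // 2, 20, 20), (shape[0] // 2, shape[1] - 20, shape[2] - 20),
               (shape[0] // 2, 20, shape[2] - 20), (shape[0] // 2, shape[1] - 20, 20)]
    neurons = []
    for c in centres[:n_neurons]:
        c = np.asarray(c, dtype=float) + rng.uniform(-3, 3, 3)
        tubes = []
        for _ in range(3):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            end = np.clip(c + d * rng.uniform(18, 26), 3, np.asarray(shape) - 4.0)
            tubes.append(Tube([tuple(c), tuple(end)], radius=float(rng.uniform(2.5, 3.5))))
        neurons.append(NeuronSpec(
            somata=[Ellipsoid(tuple(c), tuple(rng.uniform(5.5, 7.5, 3)))],
            tubes=tubes, root=tuple(c)))
    return render_phantom(PhantomSpec(shape=shape, neurons=neurons, seed=seed))


def two_dendrite_spine_phantom(seed: int = 0, n_spines_per_side: int = 4) -> PhantomOutput:
    """Two parallel dendrites, each decorated with detached spine heads.

    Spine necks are absent (super-resolution regime); each head floats a few
    voxels off its parent dendrite's surface. The parent labels in
    ``spine_truth`` are the assignment ground truth: every head is much
    closer to its own dendrite than to the other, so the topographic
    assignment has an unambiguous right answer.
    """
    rng = np.random.default_rng(seed)
    shape = (32, 48, 64)
    d1_y, d2_y = 14, 34
    neurons = [
        NeuronSpec(tubes=[Tube([(16, d1_y, 4), (16, d1_y, 59)], radius=3.0)],
                   root=(16, d1_y, 4)),
        NeuronSpec(tubes=[Tube([(16, d2_y, 4), (16, d2_y, 59)], radius=3.0)],
                   root=(16, d2_y, 4)),
    ]
    spines = []
    for parent, base_y, side in ((1, d1_y, -1), (2, d2_y, +1)):
        xs = rng.choice(np.arange(10, 54, 6), size=n_spines_per_side, replace=False)
        for x in xs:
            # heads stay >= 2 voxels clear of the dendrite surface: detached
            off_y = base_y + side * (8 + rng.integers(0, 2))
            off_z = 16 + rng.integers(-4, 5)
            spines.append(Spine(head_center=(float(off_z), float(off_y), float(x)),
                                head_radius=2.0, parent_neuron=parent))
    return render_phantom(PhantomSpec(shape=shape, neurons=neurons, spines=spines,
                                      seed=seed))
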