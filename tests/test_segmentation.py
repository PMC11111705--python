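import numpy as np
import pytest
from scipy import ndimage

import senpai
from senpai import ImageStack, PipelineConfig
from senpai.features import FeatureVolume
from senpai.segmentation import STRUCT_26, NoBorderEncodingError, _border_classes


def feature_volume_from_matrix(matrix):
    """Wrap an (n, 4) matrix as a FeatureVolume for direct clustering tests."""
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    shape = (1, 1, n)
    mean = matrix.mean(axis=0)
    std = np.where(matrix.std(axis=0) == 0, 1.0, matrix.std(axis=0))
    return FeatureVolume(
        intensity=matrix[:, 0].reshape(shape),
        d2=tuple(matrix[:, j].reshape(shape) for j in (1, 2, 3)),
        foreground=np.ones(shape, dtype=bool),
        sigma=0.0,
        matrix=(matrix - mean) / std,
        raw_matrix=matrix,
        channel_mean=mean,
        channel_std=std,
    )


def make_model(class_stats):
    """ClusterModel stub with prescribed per-class statistics."""
    stats = np.asarray(class_stats, dtype=float)
    K = len(stats)
    return senpai.ClusterModel(K=K, centroids=np.zeros((K, 4)), class_stats=stats,
                               labels=np.arange(1, K + 1), inertia=0.0, seed=0,
                               replicates=1, max_iter=10)


class TestFitKmeans:
    def test_recovers_separated_clouds(self, rng):
        means = np.array([[10, -5, -5, -5], [100, 0, 0, 0], [250, 5, 5, 5]], float)
        pts = np.concatenate([rng.normal(m, 0.01, size=(50, 4)) for m in means])
        fv = feature_volume_from_matrix(pts)
        model = senpai.fit_kmeans(fv, K=3, seed=0)
        # classes are intensity-sorted, so class k matches means row k-1
        np.testing.assert_allclose(model.class_stats, means, atol=0.02)
        expected = np.repeat([1, 2, 3], 50)
        np.testing.assert_array_equal(model.labels, expected)

    def test_assignment_is_nearest_centroid_fixed_point(self, rng):
        # brute-force oracle: no point is strictly closer to a foreign centroid
        pts = rng.normal(size=(800, 4)) * [50, 10, 10, 10] + [120, 0, 0, 0]
        fv = feature_volume_from_matrix(pts)
        model = senpai.fit_kmeans(fv, K=5, seed=3)
        d = ((fv.matrix[:, None, :] - model.centroids[None]) ** 2).sum(axis=2)
        np.testing.assert_array_equal(d.argmin(axis=1) + 1, model.labels)

    def test_intensity_sorting_invariant(self, rng):
        pts = rng.uniform(0, 255, size=(500, 4))
        model = senpai.fit_kmeans(feature_volume_from_matrix(pts), K=6, seed=1)
        assert np.all(np.diff(model.class_stats[:, 0]) >= 0)

    def test_deterministic_given_seed(self, rng):
        pts = rng.uniform(0, 255, size=(300, 4))
        fv = feature_volume_from_matrix(pts)
        a = senpai.fit_kmeans(fv, K=4, seed=9)
        b = senpai.fit_kmeans(fv, K=4, seed=9)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_k_exceeding_points_rejected(self, rng):
        fv = feature_volume_from_matrix(rng.uniform(size=(5, 4)))
        with pytest.raises(ValueError, match="exceeds"):
            senpai.fit_kmeans(fv, K=10)


class TestAutoSelectK:
    def test_structureless_noise_raises(self, rng):
        noise = ImageStack(rng.uniform(99, 101, (12, 12, 12)), (1, 1, 1))
        fv = senpai.build_features(noise, sigma=0.0)
        with pytest.raises(NoBorderEncodingError, match="no border-encoding"):
            senpai.auto_select_K(fv, 2, 4, replicates=3)

    def test_matches_exhaustive_sweep(self, suite, phantom_config):
        out = suite["axis_tubes"]
        fg = senpai.background_mask(out.stack, "percentile", 85)
        fv = senpai.build_features(out.stack, sigma=1.5, foreground=fg)
        K, model, diag = senpai.auto_select_K(fv, 2, 10, seed=0)
        # independent sweep: refit each K and apply the acceptance rule directly
        smallest = None
        for k in range(2, 11):
            m = senpai.fit_kmeans(fv, k, seed=0)
            _, ok = _border_classes(m)
            if ok:
                smallest = k
                break
        assert K == smallest


class TestSelectNeuronalClasses:
    def test_single_top_negative_class(self):
        stats = [[10, 1, 2, 3], [50, 2, -1, 1], [90, 5, 5, 5],
                 [130, -1, 1, -1], [180, -2, -3, -1], [220, -9, -8, -7]]
        model = make_model(stats)
        assert senpai.select_neuronal_classes(model) == {5, 6}

    def test_non_suffix_selection_warns(self):
        stats = [[10, 1, 1, 1], [50, -2, -1, -1], [90, 5, 5, 5],
                 [130, -1, -1, -1], [180, 2, 3, 1], [220, -9, -8, -7]]
        with pytest.warns(UserWarning, match="not the top-intensity suffix"):
            got = senpai.select_neuronal_classes(make_model(stats))
        assert got == {2, 4, 6}

    def test_class_one_never_selected(self):
        stats = [[10, -1, -1, -1], [50, 1, 1, 1]]
        with pytest.raises(senpai.NoNeuronalClassError):
            senpai.select_neuronal_classes(make_model(stats))

    def test_no_negative_class_raises(self):
        stats = [[10, 1, 1, 1], [50, 1, -1, 1], [90, 5, 5, 5]]
        with pytest.raises(senpai.NoNeuronalClassError, match="no neuronal class"):
            senpai.select_neuronal_classes(make_model(stats))


class TestFillHoles:
    def test_centre_voxel_restored(self):
        m = np.zeros((7, 7, 7), bool)
        m[1:6, 1:6, 1:6] = True
        m[3, 3, 3] = False
        out = senpai.fill_holes(m)
        assert out[3, 3, 3]
        assert out.sum() == 125

    def test_no_cavity_is_identity(self, rng):
        m = rng.uniform(size=(6, 6, 6)) > 0.7
        m = senpai.fill_holes(m)  # idempotent baseline
        np.testing.assert_array_equal(senpai.fill_holes(m), m)

    def test_hollow_shell_filled_matches_flood_fill_oracle(self):
        zz, yy, xx = np.mgrid[0:15, 0:15, 0:15]
        r = np.sqrt((zz - 7) ** 2 + (yy - 7) ** 2 + (xx - 7) ** 2)
        shell = (r >= 4) & (r <= 6)
        filled = senpai.fill_holes(shell)
        # oracle: 6-connected flood fill of background from the border
        bg = ~shell
        seeds = np.zeros_like(bg)
        seeds[0], seeds[-1] = bg[0], bg[-1]
        seeds[:, 0], seeds[:, -1] = bg[:, 0], bg[:, -1]
        seeds[:, :, 0], seeds[:, :, -1] = bg[:, :, 0], bg[:, :, -1]
        lbl, _ = ndimage.label(bg)  # 6-connectivity
        outside = np.isin(lbl, np.unique(lbl[seeds & (lbl > 0)]))
        expected_filled = shell | (bg & ~outside)
        np.testing.assert_array_equal(filled, expected_filled)
        assert filled.sum() > shell.sum()

    def test_never_removes_foreground(self, rng):
        m = rng.uniform(size=(8, 8, 8)) > 0.5
        assert not (m & ~senpai.fill_holes(m)).any()


class TestRemoveSmallClusters:
    @staticmethod
    def _mask_with_component_sizes(sizes, shape=(3, 50, 50)):
        m = np.zeros(shape, bool)
        y = 1
        for s in sizes:
            m[1, y, 1:1 + s] = True  # rows spaced two apart: 26-disconnected
            y += 2
        return m

    def test_default_filter_keeps_seven_and_larger(self):
        m = self._mask_with_component_sizes(range(1, 21))
        out = senpai.remove_small_clusters(m, 7)
        _, n = ndimage.label(out, structure=STRUCT_26)
        sizes = sorted(ndimage.sum_labels(
            out, *ndimage.label(out, structure=STRUCT_26)[:1],
            index=range(1, n + 1)).astype(int))
        assert sizes == list(range(7, 21))

    def test_empty_mask_unchanged(self):
        m = np.zeros((4, 4, 4), bool)
        assert not senpai.remove_small_clusters(m, 7).any()

    def test_matches_label_and_filter_oracle(self, rng):
        m = rng.uniform(size=(12, 12, 12)) > 0.82
        out = senpai.remove_small_clusters(m, 5)
        lbl, n = ndimage.label(m, structure=STRUCT_26)
        keep = np.zeros_like(m)
        for i in range(1, n + 1):
            comp = lbl == i
            if comp.sum() >= 5:
                keep |= comp
        np.testing.assert_array_equal(out, keep)

    def test_idempotent(self, rng):
        m = rng.uniform(size=(10, 10, 10)) > 0.8
        once = senpai.remove_small_clusters(m, 7)
        np.testing.assert_array_equal(senpai.remove_small_clusters(once, 7), once)


class TestSegment:
    def test_bright_sphere_recovered(self, suite):
        out = suite["sphere"]
        cfg = PipelineConfig(sigmas=[0.0], K=4,
                             background_threshold=("percentile", 85.0), random_seed=0)
        seg = senpai.segment(out.stack, cfg)
        assert senpai.dice(seg.mask, out.truth_mask) >= 0.85
        assert [p["sigma"] for p in seg.provenance] == [0.0]

    def test_or_merge_is_superset_of_single_scales(self, suite):
        out = suite["axis_tubes"]
        base = dict(K=6, background_threshold=("percentile", 85.0),
                    min_cluster_voxels=1, random_seed=0)
        merged = senpai.segment(out.stack, PipelineConfig(sigmas=[1.0, 2.5], **base))
        for s in (1.0, 2.5):
            single = senpai.segment(out.stack, PipelineConfig(sigmas=[s], **base))
            assert not (single.mask & ~merged.mask).any()

    def test_two_scale_merge_recovers_both_structures(self, suite):
        from senpai.phantoms import Tube, _paint_tube
        out = suite["two_scale"]
        trunk = np.zeros(out.stack.shape, bool)
        thin = np.zeros_like(trunk)
        _paint_tube(trunk, Tube([(16, 20, 4), (16, 20, 40)], radius=6.0))
        _paint_tube(thin, Tube([(16, 20, 40), (16, 8, 58)], radius=1.5))
        _paint_tube(thin, Tube([(16, 20, 40), (16, 32, 58)], radius=1.5))
        thin &= ~trunk
        base = dict(K=5, background_threshold=("percentile", 75.0), random_seed=0)

        def recalls(sigmas):
            seg = senpai.segment(out.stack, PipelineConfig(sigmas=sigmas, **base))
            return ((seg.mask & trunk).sum() / trunk.sum(),
                    (seg.mask & thin).sum() / thin.sum())

        fine_trunk, fine_thin = recalls([1.0])
        coarse_trunk, coarse_thin = recalls([3.0])
        both_trunk, both_thin = recalls([1.0, 3.0])
        assert fine_thin > 0.7 and fine_trunk < 0.6      # fine scale misses trunk body
        assert coarse_trunk > 0.7 and coarse_thin < 0.6  # coarse scale misses thin arms
        assert both_trunk > 0.7 and both_thin > 0.7      # the merge keeps both

    def test_provenance_records_each_scale(self, suite, phantom_config):
        out = suite["axis_tubes"]
        seg = senpai.segment(out.stack, phantom_config)
        assert len(seg.provenance) == len(phantom_config.sigmas)
        assert all("K" in p and "selected_classes" in p for p in seg.provenance)


class TestFitOnCropApplyFull:
    def test_full_volume_crop_identical_to_segment(self, phantom_config):
        out = senpai.random_neuron_phantom(11)
        full = senpai.segment(out.stack, phantom_config)
        crop = tuple(slice(None) for _ in range(3))
        same = senpai.fit_on_crop_apply_full(out.stack, phantom_config, crop)
        np.testing.assert_array_equal(same.mask, full.mask)

    def test_half_crop_close_to_full_fit(self, phantom_config):
        out = senpai.random_neuron_phantom(12)
        full = senpai.segment(out.stack, phantom_config)
        part = senpai.fit_on_crop_apply_full(
            out.stack, phantom_config, (slice(None), slice(None), slice(0, 40)))
        assert senpai.dice(part.mask, full.mask) >= 0.95

    def test_structureless_crop_raises(self):
        # noise-free phantom: a pure-background crop has no foreground at all
        from senpai.phantoms import Ellipsoid, NeuronSpec, PhantomSpec, render_phantom
        out = render_phantom(PhantomSpec(
            shape=(24, 24, 48),
            neurons=[NeuronSpec(somata=[Ellipsoid((12, 12, 36), (6, 6, 6))])],
            gain=0.0, read_noise=0.0, seed=0))
        cfg = PipelineConfig(sigmas=[1.0], K=4,
                             background_threshold=("percentile", 85.0), random_seed=0)
        corner = (slice(0, 16), slice(0, 16), slice(0, 16))  # background only
        with pytest.raises(ValueError):
            senpai.fit_on_crop_apply_full(out.stack, cfg, corner)


class TestPhantomRecovery:
    def test_median_dice_over_seeded_phantoms(self, phantom_config):
        dices = []
        for seed in range(8):
            out = senpai.random_neuron_phantom(seed)
            assert senpai.measured_snr(out) >= 5
            seg = senpai.segment(out.stack, phantom_config)
            dices.append(senpai.dice(seg.mask, out.truth_mask))
        assert np.median(dices) >= 0.8
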