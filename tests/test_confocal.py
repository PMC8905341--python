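"""3D confocal pipeline: thresholds, opening, deconvolution, attenuation
correction, watershed partitioning and volume fractions."""

import numpy as np
import pandas as pd
import pytest

from trabkit import confocal, simulate
from trabkit.confocal import VolumeStack


class TestGlobalThreshold:
    def test_bimodal_image_separates_objects(self):
        rng = np.random.default_rng(0)
        img = rng.normal(100, 10, (20, 40, 40))
        obj = np.zeros(img.shape, bool)
        obj[8:12, 10:30, 10:30] = True
        img[obj] += 100.0
        mask = confocal.global_threshold(img, 3.0)
        assert (mask & obj).sum() / obj.sum() > 0.99
        assert (mask & ~obj).sum() / (~obj).sum() < 0.01

    def test_constant_image_gives_empty_mask(self):
        assert not confocal.global_threshold(np.full((8, 8, 8), 5.0), 1.0).any()

    def test_k_zero_selects_strictly_above_mode(self):
        img = np.zeros((8, 8, 8))
        img[0, 0, :3] = 10.0
        mask = confocal.global_threshold(img, 0.0)
        assert mask.sum() == 3

    def test_offset_invariance(self):
        rng = np.random.default_rng(1)
        img = rng.normal(50, 5, (16, 16, 16))
        img[4:8] += 100
        m1 = confocal.global_threshold(img, 2.0)
        m2 = confocal.global_threshold(img + 500.0, 2.0)
        np.testing.assert_array_equal(m1, m2)


class TestLocalThresholdAact:
    def test_constant_image_gives_empty_mask(self):
        assert not confocal.local_threshold_aact(np.full((8, 32, 32), 9.0)).any()

    def test_striation_pattern_recovered(self):
        z, y, x = np.meshgrid(np.arange(8), np.arange(64), np.arange(64),
                              indexing="ij")
        stripes = (x % 10) < 3
        img = 20.0 + 160.0 * stripes
        mask = confocal.local_threshold_aact(img.astype(float))
        iou = (mask & stripes).sum() / (mask | stripes).sum()
        assert iou > 0.9

    def test_mask_insensitive_to_multiplicative_shading(self):
        z, y, x = np.meshgrid(np.arange(8), np.arange(64), np.arange(64),
                              indexing="ij")
        stripes = (x % 10) < 3
        img = (20.0 + 160.0 * stripes).astype(float)
        shaded = img * (1.0 + 0.4 * y / 63.0)
        m1 = confocal.local_threshold_aact(img)
        m2 = confocal.local_threshold_aact(shaded)
        agree = (m1 == m2).mean()
        assert agree > 0.95

    def test_smaller_than_box_refused(self):
        with pytest.raises(ValueError):
            confocal.local_threshold_aact(np.zeros((1, 10, 10)))


class TestOpening:
    def test_isolated_voxel_removed(self):
        m = np.zeros((16, 16, 16), bool)
        m[8, 8, 8] = True
        assert not confocal.opening3d(m, 0.2, (0.2, 0.2, 0.2)).any()

    def test_solid_block_mostly_preserved(self):
        m = np.zeros((20, 20, 20), bool)
        m[5:15, 5:15, 5:15] = True
        out = confocal.opening3d(m, 0.2, (0.2, 0.2, 0.2))
        assert out[6:14, 6:14, 6:14].all()
        assert not out[~m].any()

    def test_empty_mask_stays_empty(self):
        assert not confocal.opening3d(np.zeros((8, 8, 8), bool)).any()

    def test_opening_never_adds_voxels(self):
        rng = np.random.default_rng(3)
        m = rng.random((16, 16, 16)) < 0.3
        out = confocal.opening3d(m, 0.2, (0.2, 0.2, 0.2))
        assert not (out & ~m).any()

    def test_element_in_plane_only_when_z_voxel_exceeds_radius(self):
        el = confocal._ellipsoid_element(0.2, (0.3, 0.1, 0.1))
        assert el.shape[0] == 1          # no z extent
        assert el.shape[1] == el.shape[2] == 5


class TestDeconvolution:
    def test_delta_psf_is_identity(self):
        rng = np.random.default_rng(0)
        img = rng.random((12, 12, 12)) + 1.0
        psf = np.zeros((3, 3, 3))
        psf[1, 1, 1] = 1.0
        out = confocal.rl_deconvolve(img, psf, iterations=5)
        np.testing.assert_allclose(out, img, rtol=1e-6)

    def test_sharpens_blurred_point_source(self):
        from scipy import ndimage as ndi

        img = np.zeros((24, 24, 24))
        img[12, 12, 12] = 1000.0
        blurred = ndi.gaussian_filter(img, 1.5)
        psf = np.zeros((15, 15, 15))
        psf[7, 7, 7] = 1.0
        psf = ndi.gaussian_filter(psf, 1.5)
        psf /= psf.sum()
        out = confocal.rl_deconvolve(blurred, psf, iterations=20)
        assert out.max() > blurred.max() * 2
        assert out.sum() == pytest.approx(blurred.sum(), rel=0.01)
        assert out.min() >= -1e-9

    def test_zero_stack_stays_zero(self):
        psf = np.full((3, 3, 3), 1 / 27)
        assert not confocal.rl_deconvolve(np.zeros((8, 8, 8)), psf, 5).any()

    def test_oversized_or_unnormalized_psf_refused(self):
        with pytest.raises(ValueError):
            confocal.rl_deconvolve(np.ones((4, 4, 4)), np.full((8, 8, 8), 1 / 512), 5)
        with pytest.raises(ValueError):
            confocal.rl_deconvolve(np.ones((8, 8, 8)), np.ones((3, 3, 3)), 5)


class TestAttenuationCorrection:
    def texture(self, seed=0, nz=16):
        rng = np.random.default_rng(seed)
        img = rng.normal(30, 3, (nz, 64, 64))
        obj = rng.random((nz, 64, 64)) < 0.2
        img[obj] += 150.0
        return img

    def test_uniform_stack_gains_are_one(self):
        stack = VolumeStack({"WGA": np.full((10, 16, 16), 40.0)})
        _, gains = confocal.correct_depth_attenuation(stack)
        np.testing.assert_allclose(gains["WGA"], 1.0)

    def test_exponential_decay_corrected_within_two_percent(self):
        img = self.texture()
        z = np.arange(img.shape[0])
        decayed = img * np.exp(-z / 20.0)[:, None, None]
        stack = VolumeStack({"WGA": decayed})
        corrected, gains = confocal.correct_depth_attenuation(stack)
        out = corrected.channels["WGA"]
        stats = [np.median(p[p > np.percentile(p, 70)]) for p in out]
        assert np.ptp(stats) / np.mean(stats) < 0.04
        np.testing.assert_allclose(gains["WGA"], np.exp(z / 20.0), rtol=0.02)

    def test_monotone_attenuation_gives_monotone_gains(self):
        img = self.texture(seed=1)
        z = np.arange(img.shape[0])
        stack = VolumeStack({"WGA": img * np.exp(-z / 10.0)[:, None, None]})
        _, gains = confocal.correct_depth_attenuation(stack)
        assert np.all(np.diff(gains["WGA"]) > -0.02)

    def test_too_few_planes_refused(self):
        with pytest.raises(ValueError):
            confocal.correct_depth_attenuation(VolumeStack({"WGA": np.ones((4, 8, 8))}))


class TestWatershed:
    def test_two_cavities_give_two_segments(self):
        wga = np.zeros((16, 16, 32), bool)
        wga[:, :, 15:17] = True    # dividing wall
        wga[:, :, [0, -1]] = wga[:, [0, -1], :] = wga[[0, -1], :, :] = True
        labels = confocal.watershed_segments(wga, (0.2, 0.2, 0.2), 2.0)
        ids = np.unique(labels[labels > 0])
        assert len(ids) == 2
        left = labels[8, 8, 5]
        right = labels[8, 8, 25]
        assert left != right and left > 0 and right > 0

    def test_no_wga_is_single_segment(self):
        labels = confocal.watershed_segments(np.zeros((8, 8, 8), bool))
        assert set(np.unique(labels)) == {1}

    def test_segment_volumes_sum_to_interior(self):
        stack, truth = simulate.simulate_volume(
            simulate.VolumeConfig(shape=(32, 64, 64)), seed=2)
        wga = confocal.global_threshold(stack.channels["WGA"], 1.0)
        labels = confocal.watershed_segments(wga, (0.2, 0.2, 0.2))
        assert (labels > 0).sum() == (~wga).sum()

    def test_brick_lattice_segment_count_near_cell_count(self):
        cfg = simulate.VolumeConfig(shape=(32, 64, 64), psf_sigma_um=(0, 0, 0),
                                    attenuation_lambda_um=None,
                                    poisson_noise=False, gaussian_noise_sd=0.0)
        stack, truth = simulate.simulate_volume(cfg, seed=3)
        wga = confocal.global_threshold(stack.channels["WGA"], 1.0)
        labels = confocal.watershed_segments(wga, cfg.voxel_size_um)
        n = len(np.unique(labels)) - 1
        assert abs(n - truth.n_cells) <= 0.15 * truth.n_cells


class TestClassification:
    def segments_with_contents(self, contents, seg_vox=200):
        """One 200-voxel segment per requested aACT content."""
        n = len(contents)
        labels = np.zeros((n, 10, 20), dtype=np.int32)
        aact = np.zeros((n, 10, 20), bool)
        for i, c in enumerate(contents):
            labels[i] = i + 1
            k = int(round(c * seg_vox))
            aact[i].flat[:k] = True
        return labels, aact

    def test_boundary_content_is_inclusive(self):
        labels, aact = self.segments_with_contents([0.075])
        seg = confocal.classify_myocytes(labels, aact)
        assert bool(seg.loc[0, "myocyte"])

    def test_zero_content_is_non_myocyte(self):
        labels, aact = self.segments_with_contents([0.0])
        assert not bool(confocal.classify_myocytes(labels, aact).loc[0, "myocyte"])

    def test_sweep_boundary_is_exactly_7p5_percent(self):
        contents = [c / 1000 for c in range(10, 155, 5)]   # 1% .. 15% in 0.5% steps
        labels, aact = self.segments_with_contents(contents)
        seg = confocal.classify_myocytes(labels, aact)
        classified = seg.loc[seg["myocyte"], "aact_content"]
        assert classified.min() == pytest.approx(0.075)

    def test_mismatched_shapes_refused(self):
        with pytest.raises(ValueError):
            confocal.classify_myocytes(np.zeros((4, 4, 4), int), np.zeros((4, 4, 5), bool))


class TestVolumeFractions:
    def test_all_myocyte_phantom_has_fraction_one(self):
        labels = np.ones((8, 8, 8), dtype=np.int32)
        aact = np.ones((8, 8, 8), bool)
        masks = dict(WGA=np.zeros((8, 8, 8), bool), Cx43=np.zeros((8, 8, 8), bool),
                     aACT=aact)
        seg = confocal.classify_myocytes(labels, aact)
        fr = confocal.volume_fractions(masks, labels, seg)
        assert fr["myocyte"] == 1.0
        assert fr["ecm"] == 0.0

    def test_fractions_bounded(self):
        stack, truth = simulate.simulate_volume(
            simulate.VolumeConfig(shape=(32, 64, 64)), seed=4)
        seg = confocal.segment_stack(stack)
        for v in seg.fractions.values():
            assert 0.0 <= v <= 1.0

    def test_ecm_recovery_within_three_points(self):
        stack, truth = simulate.simulate_volume(
            simulate.VolumeConfig(shape=(48, 96, 96)), seed=5)
        seg = confocal.segment_stack(stack)
        assert seg.fractions["ecm"] == pytest.approx(truth.fractions["ecm"], abs=0.03)

    def test_zero_volume_refused(self):
        with pytest.raises(ValueError):
            confocal.volume_fractions({"WGA": np.zeros((0,), bool)},
                                      np.zeros((0,), int), pd.DataFrame(columns=["label", "myocyte"]))

    def test_average_over_stacks(self):
        avg = confocal.average_fractions([dict(ecm=0.2), dict(ecm=0.4)])
        assert avg["ecm"] == pytest.approx(0.3)


def test_pipeline_recovers_fractions_on_default_volumes():
    """End-to-end: all four structure fractions within ±10% relative."""
    for seed in (0, 1, 2):
        stack, truth = simulate.simulate_volume(
            simulate.VolumeConfig(shape=(48, 96, 96)), seed=seed)
        seg = confocal.segment_stack(stack)
        for k in ("ecm", "myocyte", "aact", "cx43"):
            rel = abs(seg.fractions[k] - truth.fractions[k]) / truth.fractions[k]
            assert rel <= 0.10, (seed, k, rel)


def test_tiff_roundtrip(tmp_path):
    stack, _ = simulate.simulate_volume(simulate.VolumeConfig(shape=(32, 64, 64)), seed=6)
    path = tmp_path / "vol.tiff"
    stack.write_tiff(path)
    names = tuple(sorted(stack.channels))
    back = VolumeStack.read_tiff(path, names)
    for ch in names:
        np.testing.assert_allclose(back.channels[ch], stack.channels[ch], rtol=1e-6)
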