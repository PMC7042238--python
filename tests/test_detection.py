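"""Soma detection chain: bit conversion, background removal,
thresholding, watershed splitting, measurement and gating."""

import numpy as np
import pytest
from skimage import draw

import rgcmosaic as rm
from rgcmosaic.detection import (
    DetectionParams,
    LabelMap,
    Particle,
    RawImage,
    apply_threshold,
    filter_particles,
    high_pass,
    measure_particles,
    region_mean_intensity,
    to_8bit,
    watershed_split,
)


class TestTo8bit:
    def test_uint8_passthrough(self):
        img = RawImage(np.arange(100, dtype=np.uint8).reshape(10, 10), 1.0)
        assert to_8bit(img) is img

    def test_16bit_endpoints(self):
        px = np.array([[0, 65535]], dtype=np.uint16)
        out = to_8bit(RawImage(px, 1.0)).pixels
        assert out[0, 0] == 0 and out[0, 1] == 255

    def test_linear_map_round_half_up(self):
        px = np.array([[100, 200, 300]], dtype=np.uint16)
        out = to_8bit(RawImage(px, 1.0)).pixels
        assert out.tolist() == [[0, 128, 255]]

    def test_constant_image_maps_to_zero(self):
        px = np.full((5, 5), 777, dtype=np.uint16)
        assert np.all(to_8bit(RawImage(px, 1.0)).pixels == 0)


class TestHighPass:
    def test_linear_gradient_removed(self):
        spec = rm.SceneSpec(
            target_density_cells_per_mm2=0.0, background_level=40.0,
            background_gradient_amp=60.0, noise_sd=0.0,
        )
        scene = rm.render_scene([], spec)
        out = high_pass(RawImage(scene.pixels, 1.0), 50.0)
        assert out.pixels.max() <= 5

    def test_flat_image_zeroed(self):
        img = RawImage(np.full((64, 64), 120, dtype=np.uint8), 1.0)
        assert np.all(high_pass(img, 50.0).pixels == 0)

    def test_blob_amplitude_preserved(self):
        spec = rm.SceneSpec(
            field_width_um=200.0, field_height_um=200.0,
            target_density_cells_per_mm2=0.0, background_level=20.0,
            background_gradient_amp=0.0, noise_sd=0.0,
        )
        cell = rm.GroundTruthCell((100.0, 100.0), 14.0, "superior", True)
        scene = rm.render_scene([cell], spec)
        amp_in = int(scene.pixels.max()) - 20
        out = high_pass(RawImage(scene.pixels, 1.0), 50.0)
        assert out.pixels.max() >= 0.9 * amp_in

    def test_subpixel_radius_rejected(self):
        img = RawImage(np.zeros((10, 10), dtype=np.uint8), pixel_size_um=5.0)
        with pytest.raises(ValueError, match="below one pixel"):
            high_pass(img, 2.0)


class TestThreshold:
    def test_just_below_level_is_empty(self):
        img = RawImage(np.full((8, 8), 129, dtype=np.uint8), 1.0)
        assert not apply_threshold(img, 130).any()

    def test_at_level_is_full(self):
        img = RawImage(np.full((8, 8), 130, dtype=np.uint8), 1.0)
        assert apply_threshold(img, 130).all()

    def test_checkerboard_half_foreground(self):
        px = np.indices((16, 16)).sum(axis=0) % 2 * 255
        mask = apply_threshold(RawImage(px.astype(np.uint8), 1.0), 130)
        assert mask.sum() == 128


class TestWatershed:
    def test_empty_mask(self):
        lm = watershed_split(np.zeros((20, 20), bool), 1.0)
        assert lm.n_labels == 0 and not lm.labels.any()

    def test_single_disk_single_label(self):
        mask = np.zeros((40, 40), bool)
        rr, cc = draw.disk((20, 20), 8)
        mask[rr, cc] = True
        assert watershed_split(mask, 1.0).n_labels == 1

    def test_touching_disks_split(self):
        # two 14 um disks with centres 12 um apart overlap yet split in two
        mask = np.zeros((60, 60), bool)
        for cx in (24, 36):
            rr, cc = draw.disk((30, cx), 7)
            mask[rr, cc] = True
        assert watershed_split(mask, 1.0).n_labels == 2

    def test_label_conservation(self, clean_scene):
        img = high_pass(RawImage(clean_scene.pixels, 1.0), 50.0)
        mask = apply_threshold(img, 130)
        lm = watershed_split(mask, 1.0)
        assert (lm.labels > 0).sum() == mask.sum()
        assert set(np.unique(lm.labels)) == set(range(lm.n_labels + 1))


class TestMeasure:
    def _measure_mask(self, mask, value=200):
        labels = LabelMap(mask.astype(np.int32), 1)
        img = RawImage(np.where(mask, value, 0).astype(np.uint8), 1.0)
        return measure_particles(labels, img)[0]

    def test_square_circularity_approaches_pi_over_4(self):
        mask = np.zeros((220, 220), bool)
        mask[10:210, 10:210] = True
        p = self._measure_mask(mask)
        assert p.circularity == pytest.approx(np.pi / 4, rel=0.02)

    def test_large_disk_circularity(self):
        mask = np.zeros((120, 120), bool)
        rr, cc = draw.disk((60, 60), 30)
        mask[rr, cc] = True
        p = self._measure_mask(mask)
        assert 0.9 <= p.circularity <= 1.0

    def test_mean_intensity_uniform_region(self):
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        p = self._measure_mask(mask, value=200)
        assert p.mean_intensity == 200.0
        assert p.area_um2 == 100.0

    def test_circularity_decreases_with_aspect_ratio(self):
        circs = []
        for ar in (1, 2, 4, 8):
            mask = np.zeros((300, 300), bool)
            rr, cc = draw.ellipse(150, 150, 20 / np.sqrt(ar), 20 * np.sqrt(ar))
            mask[rr, cc] = True
            circs.append(self._measure_mask(mask).circularity)
        assert all(a > b for a, b in zip(circs, circs[1:]))

    def test_shape_mismatch_rejected(self):
        labels = LabelMap(np.ones((5, 5), np.int32), 1)
        img = RawImage(np.zeros((6, 6), dtype=np.uint8), 1.0)
        with pytest.raises(ValueError, match="shapes differ"):
            measure_particles(labels, img)

    def test_physical_scaling(self):
        # same mask at 2 um/px has 4x the area and 2x the diameter
        mask = np.zeros((40, 40), bool)
        rr, cc = draw.disk((20, 20), 10)
        mask[rr, cc] = True
        labels = LabelMap(mask.astype(np.int32), 1)
        p1 = measure_particles(labels, RawImage(np.where(mask, 200, 0).astype(np.uint8), 1.0))[0]
        p2 = measure_particles(labels, RawImage(np.where(mask, 200, 0).astype(np.uint8), 2.0))[0]
        assert p2.area_um2 == pytest.approx(4 * p1.area_um2)
        assert p2.equiv_diam_um == pytest.approx(2 * p1.equiv_diam_um)
        assert p2.circularity == pytest.approx(p1.circularity)


def _particle(diam, circ):
    area = np.pi * (diam / 2) ** 2
    return Particle(1, (0.0, 0.0), area, 1.0, diam, circ, 100.0)


@pytest.mark.parametrize(
    "diam,circ,kept",
    [
        (14.0, 0.9, True),   # inside band, round
        (5.0, 0.9, False),   # below 7 um
        (25.0, 0.9, False),  # above 21 um
        (14.0, 0.7, False),  # gate is strictly > 0.7
        (7.0, 0.71, True),   # inclusive size bounds
        (21.0, 0.71, True),
    ],
)
def test_filter_particles_gates(diam, circ, kept):
    out = filter_particles([_particle(diam, circ)], DetectionParams())
    assert bool(out) is kept


def test_filter_area_mode():
    p = _particle(14.0, 0.9)  # area ~153.9 um^2
    params = DetectionParams(min_diam_um=100.0, max_diam_um=200.0, size_mode="area")
    assert filter_particles([p], params)


class TestDetectSomas:
    def test_blank_image_empty_result(self):
        img = RawImage(np.zeros((100, 100), dtype=np.uint8), 1.0)
        res = rm.detect_somas(img)
        assert res.accepted == [] and res.rejected == []

    def test_determinism(self, clean_scene):
        img = RawImage(clean_scene.pixels, 1.0)
        a = rm.detect_somas(img)
        b = rm.detect_somas(img)
        assert a.accepted == b.accepted and a.rejected == b.rejected

    def test_translation_equivariance(self):
        spec = rm.SceneSpec(
            field_width_um=300.0, field_height_um=300.0,
            target_density_cells_per_mm2=0.0, noise_sd=0.0,
            background_gradient_amp=0.0,
        )
        cells = [
            rm.GroundTruthCell((100.0, 120.0), 14.0, "superior", True),
            rm.GroundTruthCell((180.0, 200.0), 12.0, "inferior", True),
        ]
        scene = rm.render_scene(cells, spec)
        shifted = np.roll(scene.pixels, (7, 13), axis=(0, 1))
        a = rm.detect_somas(RawImage(scene.pixels, 1.0))
        b = rm.detect_somas(RawImage(shifted, 1.0))
        ca = sorted(p.centroid_xy_um for p in a.accepted)
        cb = sorted((x - 13.0, y - 7.0) for x, y in (p.centroid_xy_um for p in b.accepted))
        assert len(ca) == len(cb) == 2
        np.testing.assert_allclose(ca, cb, atol=1e-9)

    def test_recall_precision_on_ground_truth(self, clean_scene):
        res = rm.detect_somas(RawImage(clean_scene.pixels, 1.0))
        gt = np.array([c.centroid_xy_um for c in clean_scene.surviving_cells])
        det = np.array([p.centroid_xy_um for p in res.accepted])
        tp, fp, fn = rm.match_points(gt, det, 3.0)
        assert tp / (tp + fn) >= 0.95
        assert tp / (tp + fp) >= 0.95


class TestRegionMeanIntensity:
    def test_uniform(self):
        img = RawImage(np.full((10, 10), 73, dtype=np.uint8), 1.0)
        assert region_mean_intensity(img, np.ones((10, 10), bool)) == 73.0

    def test_half_and_half(self):
        px = np.zeros((10, 10), dtype=np.uint8)
        px[:5] = 100
        assert region_mean_intensity(RawImage(px, 1.0), np.ones((10, 10), bool)) == 50.0

    def test_matches_brute_force(self, rng):
        px = rng.integers(0, 256, (30, 30)).astype(np.uint8)
        mask = rng.random((30, 30)) > 0.6
        expected = px[mask].astype(float).sum() / mask.sum()
        assert region_mean_intensity(RawImage(px, 1.0), mask) == pytest.approx(expected)

    def test_empty_mask_rejected(self):
        img = RawImage(np.zeros((5, 5), dtype=np.uint8), 1.0)
        with pytest.raises(ValueError, match="empty mask"):
            region_mean_intensity(img, np.zeros((5, 5), bool))


def test_params_validation():
    with pytest.raises(ValueError):
        DetectionParams(threshold_level=300)
    with pytest.raises(ValueError):
        DetectionParams(min_diam_um=21.0, max_diam_um=7.0)
    with pytest.raises(ValueError):
        DetectionParams(size_mode="volume")
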