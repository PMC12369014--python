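"""SEM quantification pipeline: preprocessing, segmentation, morphometrics,
classification and coverage scaling."""

import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage.draw import disk as skdisk

from bacadhere.errors import ParameterError
from bacadhere.sem_quant import (
    ImageRecord,
    ParticleRecord,
    binarize,
    classify,
    measure,
    preprocess,
    quantify_image,
    split_touching,
    summarize,
)
from bacadhere.synthetic_data import SyntheticImageSpec, generate_image


def disk_mask(shape, center, radius):
    m = np.zeros(shape, bool)
    rr, cc = skdisk(center, radius, shape=shape)
    m[rr, cc] = True
    return m


@pytest.fixture(scope="module")
def default_image():
    return generate_image(SyntheticImageSpec(seed=101))


class TestPreprocess:
    def test_constant_image_stays_constant(self):
        img = ImageRecord(np.full((128, 128), 0.4), pixel_size=0.05)
        out = preprocess(img, bg_radius=20)
        assert np.ptp(out.pixels) == 0.0

    def test_output_range_contract(self, default_image):
        out = preprocess(default_image[0])
        assert out.pixels.min() >= 0.0 and out.pixels.max() <= 1.0

    def test_illumination_gradient_flattened(self):
        """Background variance after preprocessing drops >= 10x when the
        input carries a strong smooth illumination ramp."""
        img, gt = generate_image(
            SyntheticImageSpec(seed=5, noise_sd=0.0, gradient_amplitude=0.4)
        )
        bg = ~ndi.binary_dilation(gt.mask, iterations=5)
        raw = (img.pixels - img.pixels.min()) / np.ptp(img.pixels)
        out = preprocess(img)
        assert raw[bg].var() / out.pixels[bg].var() >= 10.0

    def test_oversized_background_window_rejected(self):
        img = ImageRecord(np.zeros((64, 64)), pixel_size=0.05)
        with pytest.raises(ParameterError):
            preprocess(img, bg_radius=64)


class TestBinarize:
    def test_noise_below_offset_gives_empty_mask(self, rng):
        noise = 0.5 + 0.02 * rng.standard_normal((256, 256))
        mask = binarize(ImageRecord(noise, 0.05), offset=0.15)
        assert not mask.any()

    def test_area_filter_keeps_only_real_particles(self, rng):
        """20 disks of ~120 px plus 30 3-px speckles, min_area=20 -> 20 regions."""
        img = np.full((512, 512), 0.1)
        centers = [(40 + 60 * (i // 5), 40 + 60 * (i % 5)) for i in range(20)]
        for cy, cx in centers:
            rr, cc = skdisk((cy, cx), 6.2)
            img[rr, cc] = 0.9
        speckles = rng.integers(360, 500, size=(30, 2))
        for sy, sx in speckles:
            img[sy, sx] = img[sy, sx + 1] = img[sy + 1, sx] = 0.9
        mask = binarize(ImageRecord(img, 0.05), min_area=20)
        assert ndi.label(mask)[1] == 20

    def test_polarity_symmetry(self, default_image):
        pre = preprocess(default_image[0])
        mask = binarize(pre)
        inverted = ImageRecord(1.0 - pre.pixels, pre.pixel_size)
        np.testing.assert_array_equal(binarize(inverted, dark_objects=True), mask)

    @pytest.mark.parametrize("block_size", [2, 50, 1])
    def test_bad_block_size_rejected(self, block_size):
        with pytest.raises(ParameterError):
            binarize(ImageRecord(np.zeros((64, 64)), 0.05), block_size=block_size)


class TestSplitTouching:
    def test_disjoint_disks_unchanged(self):
        m = disk_mask((200, 200), (50, 50), 12) | disk_mask((200, 200), (150, 150), 12)
        labels = split_touching(m, min_distance=7)
        assert labels.max() == 2

    def test_overlapping_pair_split_along_neck(self):
        m = disk_mask((200, 200), (100, 80), 12) | disk_mask(
            (200, 200), (100, 80 + int(1.2 * 12)), 12
        )
        assert ndi.label(m)[1] == 1  # genuinely fused before the split
        labels = split_touching(m, min_distance=7)
        assert labels.max() == 2

    def test_single_convex_disk_not_split(self):
        labels = split_touching(disk_mask((100, 100), (50, 50), 15), min_distance=7)
        assert labels.max() == 1

    def test_every_foreground_pixel_labeled_once(self, default_image):
        img, _ = default_image
        mask = binarize(preprocess(img))
        labels = split_touching(mask)
        np.testing.assert_array_equal(labels > 0, mask)

    def test_empty_mask(self):
        assert split_touching(np.zeros((32, 32), bool)).max() == 0


class TestMeasure:
    def test_disk_morphometrics(self):
        labels, _ = ndi.label(disk_mask((100, 100), (50, 50), 20))
        rec = measure(labels, pixel_size=0.05)[0]
        assert 0.9 <= rec.circularity <= 1.1
        assert rec.solidity >= 0.95
        assert rec.area_um2 == pytest.approx(rec.area_px * 0.05**2)

    def test_dumbbell_has_low_solidity(self):
        m = disk_mask((120, 160), (60, 50), 12) | disk_mask((120, 160), (60, 110), 12)
        m[58:62, 50:110] = True  # thin bridge joining the lobes
        rec = measure(ndi.label(m)[0], pixel_size=0.05)[0]
        assert rec.solidity < 0.9

    def test_empty_mask_gives_empty_list(self):
        assert measure(np.zeros((32, 32), int), pixel_size=0.05) == []

    def test_scale_equivariance(self):
        """Pixel metrics are scale-free; um^2 area follows pixel_size**2."""
        labels, _ = ndi.label(disk_mask((100, 100), (50, 50), 10))
        a = measure(labels, pixel_size=0.05)[0]
        b = measure(labels, pixel_size=0.10)[0]
        assert a.area_px == b.area_px
        assert b.area_um2 == pytest.approx(4 * a.area_um2)


def _record(area_um2, circ, solid):
    return ParticleRecord(
        label=1, area_px=1, area_um2=area_um2, perimeter_px=1.0,
        circularity=circ, solidity=solid, centroid=(0.0, 0.0),
    )


class TestClassify:
    def test_ideal_single_cell(self):
        # one cocci cross-section: pi * 0.4^2 ~= 0.50 um^2
        out = classify([_record(0.50, 0.95, 0.98)])
        assert out[0].morphology_class == "single"

    def test_cluster_is_aggregate(self):
        out = classify([_record(2.4, 0.5, 0.8)])
        assert out[0].morphology_class == "aggregate"

    def test_boundary_values_count_as_single(self):
        area_max = 1.5 * np.pi * 0.4**2
        out = classify([_record(area_max, 0.7, 0.9)])
        assert out[0].morphology_class == "single"

    @pytest.mark.parametrize("area,circ,solid", [
        (1.5 * np.pi * 0.4**2 + 1e-9, 0.95, 0.98),  # too large
        (0.5, 0.69, 0.98),                           # too irregular
        (0.5, 0.95, 0.89),                           # too lobed
    ])
    def test_any_failed_criterion_means_aggregate(self, area, circ, solid):
        assert classify([_record(area, circ, solid)])[0].morphology_class == "aggregate"


class TestSummarize:
    def test_printed_scaling_constant(self):
        # one bacterium occupies ~0.0077% of the surface
        mask = np.zeros((1000, 1000), bool)
        mask.ravel()[:77] = True  # coverage exactly 7.7e-5
        s = summarize([], mask)
        assert s.scaled_count == pytest.approx(1.0, abs=1e-12)

    def test_tenfold_coverage(self):
        mask = np.zeros((1000, 1000), bool)
        mask.ravel()[:770] = True  # coverage 0.077%
        assert summarize([], mask).scaled_count == pytest.approx(10.0, abs=1e-12)

    def test_empty_mask_counts_zero(self):
        s = summarize([], np.zeros((64, 64), bool))
        assert s.scaled_count == 0.0 and s.coverage_fraction == 0.0

    def test_class_counts_add_up(self):
        parts = classify([_record(0.5, 0.95, 0.98), _record(3.0, 0.4, 0.7)])
        s = summarize(parts, np.zeros((64, 64), bool))
        assert s.n_total == s.n_single + s.n_aggregate == 2

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ParameterError):
            summarize([], np.zeros((8, 8), bool), per_bacterium_fraction=0.0)


class TestEndToEnd:
    def test_recovery_on_one_synthetic_image(self, default_image):
        img, gt = default_image
        particles, summary = quantify_image(img)
        # touching single pairs merge into one detected object
        assert abs(summary.n_total - gt.n_objects) / gt.n_objects <= 0.10
        assert summary.n_aggregate >= gt.n_clusters
        # detected coverage in the same regime as the generative truth
        assert summary.coverage_fraction == pytest.approx(
            gt.coverage_fraction, rel=0.35
        )

    def test_blank_image_detects_nothing(self):
        img, _ = generate_image(
            SyntheticImageSpec(seed=0, n_singles=0, n_clusters=0, image_size=512)
        )
        particles, summary = quantify_image(img)
        assert summary.n_total == 0 and particles == []
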