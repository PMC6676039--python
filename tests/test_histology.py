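import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scatterhist.histology import (
    BinaryStainMap,
    FractionMap,
    RoiMask,
    SlideImage,
    StainChannels,
    StainLabel,
    binarize_stains,
    color_deconvolve,
    compute_fractions,
    default_stain_vectors,
    roi_statistics,
    stain_saturation,
    white_balance,
)
from scatterhist.synthetic import generate_hne_image


def make_slide(pixels, resolution=500.0):
    return SlideImage(np.asarray(pixels), resolution, specimen_id="t")


class TestWhiteBalance:
    def test_white_image_unchanged(self):
        img = make_slide(np.full((10, 10, 3), 255, dtype=np.uint8))
        out = white_balance(img)
        assert np.array_equal(out.pixels, img.pixels)

    def test_uniform_image_maps_to_white(self):
        # gains 255/200, 255/220, 255/240 take each channel to 255
        img = make_slide(np.tile([200, 220, 240], (8, 8, 1)).astype(np.uint8))
        out = white_balance(img)
        assert np.array_equal(out.pixels, np.full((8, 8, 3), 255, dtype=np.uint8))

    def test_background_reference_scaling(self):
        pixels = np.full((20, 20, 3), 250, dtype=np.uint8)
        pixels[8:12, 8:12] = 100  # darker lesion, well under 1% ... 4% of area
        pixels[:2] = 250  # keep background dominant
        img = make_slide(pixels)
        out = white_balance(img)
        assert np.all(out.pixels[0, 0] == 255)
        expected = round(100 * 255 / 250)
        assert np.all(out.pixels[9, 9] == expected)

    def test_black_image_raises(self):
        img = make_slide(np.zeros((5, 5, 3), dtype=np.uint8))
        with pytest.raises(ValueError, match="no white reference"):
            white_balance(img)


class TestColorDeconvolve:
    def test_white_pixel_zero_od(self):
        img = make_slide(np.full((4, 4, 3), 255, dtype=np.uint8))
        channels = color_deconvolve(img)
        assert np.allclose(channels.hematoxylin_od, 0)
        assert np.allclose(channels.eosin_od, 0)
        assert np.allclose(channels.residual_od, 0)

    def test_single_stain_round_trip(self):
        vectors = default_stain_vectors()
        d = 0.5
        pixels = 255.0 * 10.0 ** (-d * vectors[0])
        img = make_slide(np.tile(pixels, (3, 3, 1)))
        channels = color_deconvolve(img)
        assert np.allclose(channels.hematoxylin_od, 0.5, atol=1e-6)
        assert np.allclose(channels.eosin_od, 0.0, atol=1e-6)
        assert np.allclose(channels.residual_od, 0.0, atol=1e-6)

    def test_two_stain_linearity(self):
        vectors = default_stain_vectors()
        od = 0.3 * vectors[0] + 0.3 * vectors[1]
        img = make_slide(np.tile(255.0 * 10.0**-od, (2, 2, 1)))
        channels = color_deconvolve(img)
        assert np.allclose(channels.hematoxylin_od, 0.3, atol=1e-6)
        assert np.allclose(channels.eosin_od, 0.3, atol=1e-6)

    def test_singular_basis_rejected(self):
        v = default_stain_vectors()
        v[2] = v[0]
        img = make_slide(np.full((2, 2, 3), 200, dtype=np.uint8))
        with pytest.raises(ValueError, match="degenerate stain basis"):
            color_deconvolve(img, v)

    @settings(max_examples=30, deadline=None)
    @given(
        dh=st.floats(0.0, 1.5),
        de=st.floats(0.0, 1.5),
        dr=st.floats(0.0, 0.5),
    )
    def test_unmixing_round_trip_property(self, dh, de, dr):
        # noiseless forward synthesis is recovered to < 1e-6 OD
        vectors = default_stain_vectors()
        od = dh * vectors[0] + de * vectors[1] + dr * vectors[2]
        pixels = 255.0 * 10.0**-od
        # the residual direction has a negative component, so keep pixels in
        # the representable range; the OD floor makes very dark pixels lossy
        if pixels.min() < 1.0 or pixels.max() > 255.0:
            return
        channels = color_deconvolve(make_slide(np.tile(pixels, (1, 1, 1))))
        assert abs(float(channels.hematoxylin_od[0, 0]) - dh) < 1e-6
        assert abs(float(channels.eosin_od[0, 0]) - de) < 1e-6
        assert abs(float(channels.residual_od[0, 0]) - dr) < 1e-6


def channels_from_od(od_h, od_e):
    vectors = default_stain_vectors()
    shape = np.asarray(od_h).shape
    return StainChannels(
        hematoxylin_od=np.asarray(od_h, float),
        eosin_od=np.asarray(od_e, float),
        residual_od=np.zeros(shape),
        stain_vectors=vectors,
    )


def od_for_saturation(stain_index, target):
    """Invert the rendered-saturation curve for one stain by bisection."""
    vectors = default_stain_vectors()
    lo, hi = 0.0, 5.0
    for _ in range(60):
        mid = (lo + hi) / 2
        sat = float(stain_saturation(np.array([[mid]]), vectors[stain_index])[0, 0])
        if sat < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


class TestBinarizeStains:
    def test_both_below_threshold_is_no_stain(self):
        # saturations (0.05, 0.04) with threshold fraction 0.1 -> no stain
        od_h = od_for_saturation(0, 0.05)
        od_e = od_for_saturation(1, 0.04)
        labels = binarize_stains(channels_from_od([[od_h]], [[od_e]]))
        assert labels.labels[0, 0] == StainLabel.NO_STAIN

    def test_greater_hematoxylin_wins(self):
        od_h = od_for_saturation(0, 0.5)
        od_e = od_for_saturation(1, 0.2)
        labels = binarize_stains(channels_from_od([[od_h]], [[od_e]]))
        assert labels.labels[0, 0] == StainLabel.HEMATOXYLIN

    def test_greater_eosin_wins(self):
        od_h = od_for_saturation(0, 0.2)
        od_e = od_for_saturation(1, 0.5)
        labels = binarize_stains(channels_from_od([[od_h]], [[od_e]]))
        assert labels.labels[0, 0] == StainLabel.EOSIN

    def test_unstained_is_no_stain(self):
        labels = binarize_stains(channels_from_od([[0.0]], [[0.0]]))
        assert labels.labels[0, 0] == StainLabel.NO_STAIN

    def test_partition(self):
        rng = np.random.default_rng(0)
        od_h = rng.uniform(0, 1.2, (16, 16))
        od_e = rng.uniform(0, 1.2, (16, 16))
        labels = binarize_stains(channels_from_od(od_h, od_e))
        assert np.isin(labels.labels, [0, 1, 2]).all()

    @settings(max_examples=40, deadline=None)
    @given(
        od_h=st.floats(0.0, 2.0),
        od_e=st.floats(0.0, 2.0),
        bump=st.floats(0.01, 1.0),
    )
    def test_label_monotonicity(self, od_h, od_e, bump):
        # raising hematoxylin OD never flips HEMATOXYLIN -> EOSIN
        before = binarize_stains(channels_from_od([[od_h]], [[od_e]])).labels[0, 0]
        after = binarize_stains(channels_from_od([[od_h + bump]], [[od_e]])).labels[0, 0]
        if before == StainLabel.HEMATOXYLIN:
            assert after == StainLabel.HEMATOXYLIN

    def test_per_image_max_reference(self):
        od_h = od_for_saturation(0, 0.05)
        channels = channels_from_od([[od_h]], [[0.0]])
        absolute = binarize_stains(channels)  # 0.05 < 0.1 -> no stain
        relative = binarize_stains(channels, per_image_max=True)  # 0.05 >= 0.1*0.05
        assert absolute.labels[0, 0] == StainLabel.NO_STAIN
        assert relative.labels[0, 0] == StainLabel.HEMATOXYLIN


class TestComputeFractions:
    def test_counted_fractions(self):
        # one 100x100 voxel at 500 px/mm: 2500 H, 5000 E, 2500 N
        labels = np.full((100, 100), int(StainLabel.EOSIN), dtype=np.int8)
        labels[:25, :] = int(StainLabel.HEMATOXYLIN)
        labels[75:, :] = int(StainLabel.NO_STAIN)
        fm = compute_fractions(BinaryStainMap(labels), resolution=500, voxel_size=200)
        assert fm.shape == (1, 1)
        assert fm.epithelium[0, 0] == 0.25
        assert fm.stroma[0, 0] == 0.50
        assert fm.adipose[0, 0] == 0.25

    def test_pure_voxel(self):
        labels = np.full((100, 100), int(StainLabel.HEMATOXYLIN), dtype=np.int8)
        fm = compute_fractions(BinaryStainMap(labels), resolution=500)
        assert (fm.epithelium == 1).all() and (fm.stroma == 0).all()

    def test_voxel_side_at_1000px_per_mm(self):
        labels = np.zeros((400, 400), dtype=np.int8)
        fm = compute_fractions(BinaryStainMap(labels), resolution=1000, voxel_size=200)
        assert fm.pixels_per_voxel == 200
        assert fm.shape == (2, 2)

    def test_edge_voxels_partial(self):
        labels = np.zeros((150, 130), dtype=np.int8)
        fm = compute_fractions(BinaryStainMap(labels), resolution=500, voxel_size=200)
        assert fm.shape == (2, 2)
        assert np.allclose(fm.epithelium + fm.stroma + fm.adipose, 1.0)

    def test_fractions_sum_to_one_exactly(self, rng):
        labels = rng.integers(0, 3, size=(137, 211)).astype(np.int8)
        fm = compute_fractions(BinaryStainMap(labels), resolution=500, voxel_size=200)
        assert np.all(fm.epithelium + fm.stroma + fm.adipose == 1.0)

    def test_empty_map_raises(self):
        with pytest.raises(ValueError):
            compute_fractions(BinaryStainMap(np.zeros((0, 0), dtype=np.int8)), 500)

    def test_subpixel_voxel_raises(self):
        labels = np.zeros((10, 10), dtype=np.int8)
        with pytest.raises(ValueError):
            compute_fractions(BinaryStainMap(labels), resolution=1, voxel_size=200)


class TestRoiStatistics:
    def test_constant_field(self):
        fm = FractionMap(
            epithelium=np.full((5, 5), 0.25),
            stroma=np.full((5, 5), 0.5),
            adipose=np.full((5, 5), 0.25),
        )
        stats = roi_statistics(fm, RoiMask(np.ones((5, 5), bool)))
        assert stats["epithelium"][0] == pytest.approx(0.25)
        assert stats["epithelium"][1] == pytest.approx(0.0)

    def test_two_point_formula(self):
        fm = FractionMap(
            epithelium=np.array([[0.2, 0.4]]),
            stroma=np.array([[0.8, 0.6]]),
            adipose=np.array([[0.0, 0.0]]),
        )
        stats = roi_statistics(fm, RoiMask(np.ones((1, 2), bool)))
        mean, std, n = stats["epithelium"]
        assert mean == pytest.approx(0.3)
        assert std == pytest.approx(0.14142135, abs=1e-6)
        assert n == 2

    def test_full_mask_equals_global_stats(self, rng):
        values = rng.uniform(0, 1, (9, 9))
        fm = FractionMap(epithelium=values, stroma=1 - values, adipose=np.zeros((9, 9)))
        stats = roi_statistics(fm, RoiMask(np.ones((9, 9), bool)))
        assert stats["epithelium"][0] == pytest.approx(values.mean())
        assert stats["epithelium"][1] == pytest.approx(values.std(ddof=1))

    def test_optical_map_respects_validity(self):
        from scatterhist.models import OpticalPropertyMap

        mus = np.ones((4, 4))
        mus[0, 0] = 100.0
        valid = np.ones((4, 4), bool)
        valid[0, 0] = False
        pmap = OpticalPropertyMap(
            mus_prime=mus, gamma=np.ones((4, 4)), b_power=np.ones((4, 4)),
            pixel_size=0.5, valid_mask=valid,
        )
        stats = roi_statistics(pmap, RoiMask(np.ones((4, 4), bool)))
        assert stats["mus_prime"][0] == pytest.approx(1.0)
        assert stats["mus_prime"][2] == 15

    def test_empty_intersection_raises(self):
        from scatterhist.models import OpticalPropertyMap

        pmap = OpticalPropertyMap(
            mus_prime=np.ones((3, 3)), gamma=np.ones((3, 3)), b_power=np.ones((3, 3)),
            pixel_size=0.5, valid_mask=np.zeros((3, 3), bool),
        )
        with pytest.raises(ValueError, match="empty ROI"):
            roi_statistics(pmap, RoiMask(np.ones((3, 3), bool)))


class TestResolutionEquivariance:
    def test_same_tissue_at_500_and_1000(self):
        layout = [
            ({"type": "rect", "row0": 0, "col0": 0, "row1": 200, "col1": 200}, "epithelial"),
            ({"type": "rect", "row0": 0, "col0": 200, "row1": 200, "col1": 400}, "stromal"),
        ]
        results = {}
        for res, canvas in ((500.0, (200, 400)), (1000.0, (400, 800))):
            scale = int(res / 500)
            scaled = [
                (
                    {k: (v * scale if isinstance(v, int) else v) for k, v in s.items()},
                    t,
                )
                for s, t in layout
            ]
            pixels, _, _ = generate_hne_image(
                scaled, resolution=res, noise_sd=0.0, seed=0, canvas_shape=canvas
            )
            slide = SlideImage(pixels, res)
            channels = color_deconvolve(slide)
            labels = binarize_stains(channels)
            fm = compute_fractions(labels, res, voxel_size=200)
            results[res] = fm.stack().mean(axis=(0, 1))
        assert np.allclose(results[500.0], results[1000.0], atol=0.01)
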