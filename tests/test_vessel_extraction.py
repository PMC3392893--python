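import numpy as np
import pytest

from odfind.kernels import build_bank
from odfind.synthetic import SceneSpec, VesselSpec, generate
from odfind.vessel_extraction import (
    NormalizedImage,
    combine_pairs,
    directional_map,
    double_threshold,
    normalize_green,
    respond,
    scale_production,
    thin,
)

from oracles import hysteresis_flood_fill, make_vessel_image, skeletons_match_up_to_endpoints, zhang_suen


def _rgb_disc(green_fill=128, size=60, radius=25):
    """Tiny synthetic frame: bright red disc defines the FOV."""
    rgb = np.zeros((size, size, 3), dtype=np.uint8)
    rows, cols = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    fov = (rows - size // 2) ** 2 + (cols - size // 2) ** 2 <= radius**2
    rgb[..., 0][fov] = 200
    rgb[..., 1][fov] = green_fill
    return rgb, fov


class TestNormalizeGreen:
    def test_constant_green_maps_to_zero(self):
        rgb, fov = _rgb_disc(128)
        out = normalize_green(rgb)
        assert np.array_equal(out.fov_mask, fov)
        assert np.all(out.values == 0.0)

    def test_minmax_endpoints(self):
        rgb, fov = _rgb_disc(128)
        rr, cc = np.nonzero(fov)
        rgb[rr[0], cc[0], 1] = 12
        rgb[rr[-1], cc[-1], 1] = 250
        out = normalize_green(rgb)
        assert out.values[rr[0], cc[0]] == 0.0
        assert out.values[rr[-1], cc[-1]] == 1.0
        assert out.values.min() >= 0.0 and out.values.max() <= 1.0

    def test_grayscale_warns(self):
        rgb, _ = _rgb_disc()
        with pytest.warns(UserWarning, match="grayscale"):
            normalize_green(rgb[..., 1])

    def test_empty_fov_raises(self):
        with pytest.raises(ValueError, match="field of view"):
            normalize_green(np.zeros((20, 20, 3), dtype=np.uint8))


class TestRespond:
    def test_vertical_vessel_orientation_and_contrast(self, reference_bank):
        size = 151
        im = NormalizedImage(make_vessel_image(size), np.ones((size, size), bool))
        stacks = respond(im, reference_bank)
        center = (size - 1) // 2
        # vertical orientation bin (theta = 0 -> bin 1) along the centerline
        resp = np.stack([s.response for s in stacks])
        oris = np.stack([s.orientation for s in stacks])
        w = np.argmax(resp, axis=0)
        chosen = np.take_along_axis(oris, w[None], axis=0)[0]
        assert (chosen[30:-30, center] == 1).all()
        # response on the vessel strictly beats response 10 px out
        for s in stacks:
            assert (s.response[30:-30, center] > s.response[30:-30, center + 10]).all()


class TestScaleProduction:
    def test_elementwise_product_and_commutativity(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(20, 20)), rng.normal(size=(20, 20))
        P = scale_production(a, b)
        assert np.array_equal(P, a * b)
        assert np.array_equal(P, scale_production(b, a))
        assert np.all(scale_production(np.zeros_like(a), b) == 0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            scale_production(np.zeros((4, 4)), np.zeros((5, 5)))

    def test_product_improves_vessel_contrast(self, reference_bank):
        """On a noisy vessel, the scale product separates vessel from
        background better than either single-scale response."""
        size = 151
        rng = np.random.default_rng(1)
        vals = make_vessel_image(size) + rng.normal(0.0, 0.05, (size, size))
        im = NormalizedImage(np.clip(vals, 0, 1), np.ones((size, size), bool))
        stacks = respond(im, reference_bank)
        center = (size - 1) // 2
        on = np.s_[30:-30, center]
        off = np.s_[30:-30, 40:60]

        def contrast(x):
            return x[on].mean() / np.abs(x[off]).mean()

        P = scale_production(stacks[0], stacks[1])
        assert contrast(P) > contrast(stacks[0].response)
        assert contrast(P) > contrast(stacks[1].response)


class TestDoubleThreshold:
    def test_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            P = rng.random((10, 10))
            got = double_threshold(P, 0.8, 0.4)
            want = hysteresis_flood_fill(P, 0.8, 0.4)
            assert np.array_equal(got, want)

    def test_weak_plateau_kept_island_dropped(self):
        """A weak plateau touching a strong one survives; a separated weak
        island does not."""
        P = np.zeros((10, 10))
        P[4, 1:4] = 1.0      # strong plateau
        P[4, 4:7] = 0.55     # weak plateau, 8-connected to strong
        P[8, 8] = 0.55       # weak island
        # the 0.98 quantile falls on the strong plateau value
        out = double_threshold(P, t_high_quantile=0.98, t_low_fraction=0.5)
        assert np.array_equal(out, hysteresis_flood_fill(P, 0.98, 0.5))
        assert out[4, 1:7].all()
        assert not out[8, 8]

    def test_monotone_in_high_quantile(self):
        rng = np.random.default_rng(7)
        P = rng.random((40, 40))
        prev = None
        for hq in (0.80, 0.90, 0.95, 0.99):
            cur = double_threshold(P, hq, 0.5)
            if prev is not None:
                assert (cur <= prev).all()
            prev = cur

    def test_degenerate_input_all_background(self):
        assert not double_threshold(np.zeros((8, 8)), 0.9, 0.5).any()
        assert not double_threshold(np.full((8, 8), 3.3), 0.9, 0.5).any()

    @pytest.mark.parametrize("hq,lf", [(0.0, 0.5), (1.0, 0.5), (0.9, 0.0), (0.9, 1.0)])
    def test_parameter_validation(self, hq, lf):
        with pytest.raises(ValueError):
            double_threshold(np.zeros((4, 4)), hq, lf)


class TestCombinePairs:
    def test_or_algebra(self):
        rng = np.random.default_rng(3)
        a = rng.random((9, 9)) > 0.5
        empty = np.zeros_like(a)
        assert np.array_equal(combine_pairs(a, empty), a)
        b = rng.random((9, 9)) > 0.5
        assert np.array_equal(combine_pairs(a, b), combine_pairs(b, a))
        assert np.array_equal(combine_pairs(a, a), a)

    def test_or_recovers_thick_vessel_pixels(self, reference_bank):
        """With low contrast, the small-scale product misses thick-vessel
        pixels that the OR with the large-scale product recovers."""
        spec = SceneSpec(
            vessels=(
                VesselSpec(-1, +1, 0.0, 90.0, 260.0, "thick"),
                VesselSpec(+1, -1, 0.0, 90.0, 260.0, "thin"),
            ),
            exudate_center=None,
            vessel_depth=8.0,
            noise_std=6.0,
            seed=3,
        )
        rgb, truth = generate(spec)
        im = normalize_green(rgb)
        stacks = respond(im, reference_bank)
        b12 = double_threshold(scale_production(stacks[0], stacks[1]), fov_mask=im.fov_mask)
        b34 = double_threshold(scale_production(stacks[2], stacks[3]), fov_mask=im.fov_mask)
        both = combine_pairs(b12, b34)
        thick = truth.vessel_centerlines[0]
        recovered = (~b12) & both & thick
        assert recovered.sum() > 0
        assert both[thick].mean() > b12[thick].mean()


class TestThin:
    def test_trivial_inputs(self):
        empty = np.zeros((10, 10), bool)
        assert not thin(empty).any()
        single = np.zeros((10, 10), bool)
        single[4, 5] = True
        assert np.array_equal(thin(single), single)

    def test_bar_reduces_to_centerline(self):
        bar = np.zeros((11, 27), bool)
        bar[3:8, 3:24] = True
        sk = thin(bar)
        rows = np.nonzero(sk)[0]
        assert len(np.unique(rows)) == 1  # single-pixel-wide horizontal line
        assert sk.sum() >= (24 - 3) - 4   # endpoint erosion <= 2 px per end
        assert (sk <= bar).all()

    def test_matches_reference_thinning(self):
        bar = np.zeros((11, 27), bool)
        bar[3:8, 3:24] = True
        cross = np.zeros((21, 21), bool)
        cross[8:13, 2:19] = True
        cross[2:19, 8:13] = True
        for fixture in (bar, cross):
            assert skeletons_match_up_to_endpoints(thin(fixture), zhang_suen(fixture))

    def test_no_2x2_block_and_subset(self, default_result):
        sk = default_result.dmap.centerline_mask
        assert (sk <= default_result.binary).all()
        assert not (sk[:-1, :-1] & sk[1:, :-1] & sk[:-1, 1:] & sk[1:, 1:]).any()


class TestDirectionalMap:
    def _two_vessel_stacks(self, reference_bank, size=121):
        rows = np.arange(size, dtype=float)[:, None]
        cols = np.arange(size, dtype=float)[None, :]
        c = (size - 1) / 2.0
        vals = (
            0.8
            - 0.5 * np.exp(-((cols - c) ** 2) / (2 * 1.5**2))
            - 0.5 * np.exp(-((rows - c) ** 2) / (2 * 1.5**2))
        )
        im = NormalizedImage(np.clip(vals, 0, 1), np.ones((size, size), bool))
        return respond(im, reference_bank)

    def test_empty_centerline_all_zero(self, reference_bank):
        stacks = self._two_vessel_stacks(reference_bank)
        dmap = directional_map(stacks, np.zeros_like(stacks[0].response, dtype=bool))
        assert not dmap.orientation_index.any()

    def test_crossing_vessels_keep_own_bins(self, reference_bank):
        size = 121
        stacks = self._two_vessel_stacks(reference_bank, size)
        center = (size - 1) // 2
        centerline = np.zeros((size, size), bool)
        centerline[20:-20, center] = True
        centerline[center, 20:-20] = True
        dmap = directional_map(stacks, centerline)
        # orientation defined exactly on the centerline
        assert ((dmap.orientation_index > 0) == centerline).all()
        # away from the crossing each branch carries its own orientation:
        # vertical branch -> bin 1, horizontal branch -> bin 5
        assert (dmap.orientation_index[20:center - 10, center] == 1).all()
        assert (dmap.orientation_index[center, 20:center - 10] == 5).all()
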