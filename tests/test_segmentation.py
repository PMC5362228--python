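"""Graph shortest-path segmentation tests, including the brute-force oracle."""

import itertools

import numpy as np
import pytest

from octfovea import (
    BoundarySet,
    GradientMaps,
    InfeasibleRegionError,
    PhantomSpec,
    SearchRegion,
    SegmentationConfig,
    boundary_error,
    compute_gradient_maps,
    generate_bscan,
    segment_layers,
    shortest_boundary,
)
from octfovea.core import BOUNDARIES, BScan


# ---------------------------------------------------------------------------
# gradient maps


class TestGradientMaps:
    def test_constant_image_gives_zero_maps(self):
        maps = compute_gradient_maps(np.full((10, 8), 37.0), smoothing_sigma=0)
        assert not maps.dark_to_light.any()
        assert not maps.light_to_dark.any()

    def test_single_step_lights_up_dark_to_light_only(self):
        image = np.zeros((12, 6))
        image[6:, :] = 255.0
        maps = compute_gradient_maps(image, smoothing_sigma=0)
        assert not maps.light_to_dark.any()
        assert maps.dark_to_light[5:7].max() == pytest.approx(1.0)
        rest = np.delete(maps.dark_to_light, [5, 6], axis=0)
        assert not rest.any()

    def test_inverting_the_image_swaps_the_maps(self):
        rng = np.random.default_rng(0)
        image = rng.uniform(0, 255, size=(20, 15))
        maps = compute_gradient_maps(image, smoothing_sigma=1.0)
        flipped = compute_gradient_maps(255.0 - image, smoothing_sigma=1.0)
        assert np.allclose(maps.dark_to_light, flipped.light_to_dark)
        assert np.allclose(maps.light_to_dark, flipped.dark_to_light)

    def test_tiny_images_rejected(self):
        with pytest.raises(ValueError):
            compute_gradient_maps(np.zeros((2, 10)))


# ---------------------------------------------------------------------------
# shortest path vs exhaustive enumeration


def _brute_force_cost(weight_map, max_jump, row_min=None, row_max=None):
    """Exhaustive minimum path cost under the edge-cost definition
    w(a) + w(b) per edge, with virtual zero-cost end columns."""
    height, width = weight_map.shape
    row_min = np.zeros(width, dtype=int) if row_min is None else row_min
    row_max = np.full(width, height - 1) if row_max is None else row_max
    best = np.inf
    choices = [range(row_min[c], row_max[c] + 1) for c in range(width)]
    for path in itertools.product(*choices):
        if any(abs(path[i + 1] - path[i]) > max_jump for i in range(width - 1)):
            continue
        w = [weight_map[r, c] for c, r in enumerate(path)]
        cost = w[0] + sum(w[i] + w[i + 1] for i in range(width - 1)) + w[-1]
        best = min(best, cost)
    return best


def _maps_from_gradient(g):
    return GradientMaps(dark_to_light=g, light_to_dark=np.zeros_like(g))


class TestShortestBoundaryOracle:
    def test_single_bright_row_is_followed_exactly(self):
        g = np.zeros((8, 10))
        g[5] = 1.0
        path = shortest_boundary(_maps_from_gradient(g), "dark_to_light")
        assert np.allclose(path.rows, 5.0)

    @pytest.mark.parametrize("instance", range(120))
    def test_cost_matches_exhaustive_enumeration(self, instance):
        rng = np.random.default_rng(instance)
        height, width = rng.integers(3, 7, size=2)
        g = rng.uniform(0, 1, size=(height, width))
        config = SegmentationConfig(subpixel=False, w_min=1e-5)
        path = shortest_boundary(_maps_from_gradient(g), "dark_to_light", config=config)
        expected = _brute_force_cost(1.0 - g + config.w_min, config.max_jump)
        assert path.cost == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("instance", range(120))
    def test_restricted_region_matches_restricted_enumeration(self, instance):
        """Excluding rows (possibly the globally best ones) still returns the
        optimum within the region."""
        rng = np.random.default_rng(10_000 + instance)
        height, width = int(rng.integers(4, 7)), int(rng.integers(3, 7))
        g = rng.uniform(0, 1, size=(height, width))
        row_min = rng.integers(0, 2, size=width)
        row_max = height - 1 - rng.integers(0, 2, size=width)
        config = SegmentationConfig(subpixel=False, w_min=1e-5)
        path = shortest_boundary(
            _maps_from_gradient(g), "dark_to_light",
            SearchRegion(row_min, row_max), config=config,
        )
        expected = _brute_force_cost(1.0 - g + config.w_min, config.max_jump, row_min, row_max)
        assert path.cost == pytest.approx(expected, abs=1e-10)
        assert np.all(path.rows >= row_min) and np.all(path.rows <= row_max)

    def test_infeasible_region_names_first_bad_column(self):
        g = np.zeros((10, 5))
        row_min = np.array([0, 0, 8, 8, 8])
        row_max = np.array([1, 1, 9, 9, 9])  # jump of 7 rows between cols 1 and 2
        with pytest.raises(InfeasibleRegionError) as err:
            shortest_boundary(_maps_from_gradient(g), "dark_to_light",
                              SearchRegion(row_min, row_max))
        assert err.value.column == 2


# ---------------------------------------------------------------------------
# full sequential segmentation


class TestSegmentLayers:
    def test_noiseless_phantom_recovered_below_half_pixel(self, noiseless_case):
        _, scan, truth, estimate = noiseless_case
        mae_px = boundary_error(truth, estimate, 1.0)["mae_um"]
        assert (mae_px < 0.5).all(), mae_px.to_dict()

    def test_always_nine_ordered_boundaries(self, noiseless_case):
        _, _, _, estimate = noiseless_case
        assert len(list(estimate)) == 9
        assert estimate.is_ordered()

    def test_noisy_phantoms_stay_ordered_with_nine_boundaries(self):
        for seed in (0, 1):
            scan, _ = generate_bscan(PhantomSpec(noise_level=0.4, seed=seed))
            estimate = segment_layers(scan)
            assert len(list(estimate)) == 9
            assert estimate.is_ordered()

    def test_noise_degrades_accuracy_monotonically(self, noiseless_case, noisy_mae_batch):
        """Median per-scan mean MAE is non-decreasing across speckle levels."""
        _, _, truth, estimate = noiseless_case
        mae0 = boundary_error(truth, estimate, 1.0)["mae_um"].mean()
        mae15 = float(np.median(noisy_mae_batch.mean(axis=1)))
        high = []
        for seed in range(5):
            scan, tr = generate_bscan(PhantomSpec(noise_level=0.35, seed=seed))
            high.append(boundary_error(tr, segment_layers(scan), 1.0)["mae_um"].mean())
        mae35 = float(np.median(high))
        assert mae0 <= mae15 <= mae35

    def test_contrast_flip_with_swapped_polarities_is_equivariant(self, noiseless_case):
        _, scan, _, estimate = noiseless_case
        flipped_scan = BScan(
            image=255.0 - scan.image, eye=scan.eye, meridian=scan.meridian,
            axial_scale=scan.axial_scale, lateral_scale=scan.lateral_scale,
            axial_length_mm=scan.axial_length_mm,
            positive_column_direction=scan.positive_column_direction,
        )
        config = SegmentationConfig()
        swapped = {
            b: ("light_to_dark" if p == "dark_to_light" else "dark_to_light")
            for b, p in config.polarity.items()
        }
        flipped = segment_layers(flipped_scan, SegmentationConfig(polarity=swapped))
        diff = np.abs(flipped.rows_array() - estimate.rows_array())
        assert diff.max() < 0.5

    def test_infeasible_error_carries_boundary_name(self):
        err = InfeasibleRegionError(column=17, boundary="B4")
        assert "B4" in str(err) and "column 17" in str(err)

    def test_degenerate_shallow_image_still_returns_ordered_set(self):
        """Margins that cannot fit collapse instead of failing, so even a
        featureless sliver of an image yields nine ordered boundaries."""
        scan = BScan(image=np.zeros((6, 200)))
        boundaries = segment_layers(scan, SegmentationConfig(margin_um=400.0))
        assert len(list(boundaries)) == 9
        assert boundaries.is_ordered()


class TestBoundaryError:
    def test_identical_sets_have_zero_error(self, noiseless_case):
        _, _, truth, _ = noiseless_case
        err = boundary_error(truth, truth, 3.87)
        assert np.allclose(err.to_numpy(), 0.0)

    def test_constant_shift_converts_to_microns(self, noiseless_case):
        _, _, truth, _ = noiseless_case
        shifted = BoundarySet.from_array(truth.rows_array() + 2.0)
        err = boundary_error(truth, shifted, 3.87)
        assert np.allclose(err["mae_um"], 7.74)
        assert np.allclose(err["rmse_um"], 7.74)
        assert np.allclose(err["max_um"], 7.74)

    def test_mae_rmse_max_ordering_holds(self):
        rng = np.random.default_rng(3)
        a = BoundarySet.from_array(np.sort(rng.uniform(0, 100, size=(9, 30)), axis=0))
        b = BoundarySet.from_array(np.sort(rng.uniform(0, 100, size=(9, 30)), axis=0))
        err = boundary_error(a, b, 3.87)
        assert (err["mae_um"] <= err["rmse_um"] + 1e-12).all()
        assert (err["rmse_um"] <= err["max_um"] + 1e-12).all()

    def test_width_mismatch_rejected(self, noiseless_case):
        _, _, truth, _ = noiseless_case
        narrow = BoundarySet.from_array(truth.rows_array()[:, :100])
        with pytest.raises(ValueError, match="column count"):
            boundary_error(truth, narrow, 3.87)


class TestConfigValidation:
    def test_order_must_be_permutation(self):
        config = SegmentationConfig(order=("B1",) * 9)
        with pytest.raises(ValueError, match="permutation"):
            config.validate()

    def test_boundary_set_requires_all_nine(self):
        with pytest.raises(ValueError, match="missing boundaries"):
            BoundarySet({b: None for b in BOUNDARIES[:5]})
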