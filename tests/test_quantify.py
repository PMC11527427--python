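"""Segmentation, mask algebra, and intensity-to-molecule conversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from conftest import flood_fill_components
from filoquant import quantify, synthetic
from filoquant.errors import InvalidParameterError, UndefinedStatisticError
from filoquant.quantify import (
    FluorescenceScale,
    MaskSet,
    PunctumRecord,
    convex_hull_mask,
    group_puncta_into_filopodia,
    intensity_to_molecules,
    label_puncta,
    make_cell_body_mask,
    make_filopodia_mask,
    make_total_cell_mask,
    percent_filopodial,
    punctum_length,
    subtract_background_rolling_ball,
    subtract_background_square,
)


def punctum_at(pixels, molecules=None, label=0):
    pixels = np.asarray(pixels)
    return PunctumRecord(
        label=label,
        pixels=pixels,
        integrated_intensity=float(len(pixels)),
        centroid=tuple(pixels.mean(axis=0)),
        molecules=molecules,
    )


class TestBackgroundSquare:
    def test_constant_image_goes_to_zero(self):
        image = np.full((100, 100), 37.5)
        out = subtract_background_square(image, (10, 10), size=56)
        assert np.all(out == 0.0)

    def test_additive_offset_removed_exactly(self):
        rng = np.random.default_rng(0)
        truth = np.zeros((120, 120))
        truth[80:90, 80:90] = rng.uniform(50, 100, (10, 10))
        out = subtract_background_square(truth + 10.0, (0, 0), size=56)
        np.testing.assert_allclose(out, truth, atol=1e-12)

    def test_square_outside_image_rejected(self):
        image = np.zeros((60, 60))
        with pytest.raises(InvalidParameterError):
            subtract_background_square(image, (10, 10), size=56)


class TestRollingBall:
    def test_constant_image_goes_to_zero(self):
        out = subtract_background_rolling_ball(np.full((64, 64), 12.0), radius=50)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_small_spot_preserved(self):
        image = np.full((128, 128), 20.0)
        image[60:63, 60:63] += 500.0
        out = subtract_background_rolling_ball(image, radius=50)
        assert out[61, 61] == pytest.approx(500.0, rel=0.05)

    def test_ramp_background_removed_under_spot(self):
        cols = np.arange(128, dtype=float)[None, :]
        image = 20.0 + 0.1 * np.broadcast_to(cols, (128, 128)).copy()
        image[60:63, 60:63] += 300.0
        out = subtract_background_rolling_ball(image, radius=50)
        residual = out.copy()
        residual[58:65, 58:65] = 0.0  # ignore the spot itself
        assert residual.max() < 2.0  # below typical read noise


class TestMasks:
    def test_blank_image_yields_no_cells(self):
        assert make_total_cell_mask(np.zeros((64, 64))) == []

    def test_scene_total_mask_covers_truth_support(self, quantified_scene, scene):
        _, _, truth = scene
        total = quantified_scene.masks.total_cell_mask
        support = truth.support
        assert (total & support).sum() / support.sum() >= 0.95

    def test_two_separated_cells_two_masks(self, default_camera):
        a, _, _ = synthetic.make_cell_scene(
            n_filopodia=5, rng_seed=1, shape=(320, 320), camera=default_camera
        )
        canvas = np.full((320, 672), default_camera.background_level)
        canvas[:, :320] = a
        canvas[:, 352:] = a
        corrected = subtract_background_square(canvas, (0, 140), size=56)
        masks = make_total_cell_mask(
            corrected, method="sigma", noise_sd=default_camera.read_noise_sd
        )
        assert len(masks) == 2

    def test_body_mask_matches_truth_body(self, scene):
        _, phalloidin, truth = scene
        corrected = subtract_background_square(phalloidin, (0, 0), size=56)
        body = make_cell_body_mask(corrected, erosion_radius=1, opening_radius=2)
        inter = (body & truth.cell_body_mask).sum()
        union = (body | truth.cell_body_mask).sum()
        assert inter / union >= 0.9

    def test_no_filopodium_pixels_in_body_mask(self, scene):
        _, phalloidin, truth = scene
        corrected = subtract_background_square(phalloidin, (0, 0), size=56)
        body = make_cell_body_mask(corrected, erosion_radius=1, opening_radius=2)
        assert not np.any(body & truth.filopodia_support)

    def test_zero_radii_equal_threshold_mask(self):
        image = np.zeros((32, 32))
        image[10:20, 10:20] = 100.0
        mask = make_cell_body_mask(image, erosion_radius=0, opening_radius=0, threshold=50.0)
        np.testing.assert_array_equal(mask, image > 50.0)

    def test_filopodia_mask_set_difference_identities(self):
        total = np.zeros((16, 16), bool)
        total[4:12, 4:12] = True
        assert not make_filopodia_mask(total, total).any()
        np.testing.assert_array_equal(
            make_filopodia_mask(total, np.zeros_like(total)), total
        )
        with pytest.raises(InvalidParameterError):
            make_filopodia_mask(total, np.zeros((8, 8), bool))

    def test_scene_filopodia_mask_covers_truth(self, quantified_scene, scene):
        _, _, truth = scene
        filo = quantified_scene.masks.filopodia_mask
        fsup = truth.filopodia_support
        assert (filo & fsup).sum() / fsup.sum() >= 0.9

    def test_maskset_invariant_enforced(self):
        total = np.zeros((8, 8), bool)
        total[2:6, 2:6] = True
        body = np.zeros_like(total)
        body[3:5, 3:5] = True
        MaskSet(total, body, total & ~body)  # valid
        with pytest.raises(InvalidParameterError):
            MaskSet(total, body, total)  # not the set difference


class TestLabelPuncta:
    def test_diagonal_pixels_are_one_component(self):
        mask = np.zeros((4, 4), bool)
        mask[0, 0] = mask[1, 1] = True
        assert len(label_puncta(mask)) == 1

    def test_gap_of_one_pixel_splits(self):
        mask = np.zeros((4, 4), bool)
        mask[0, 0] = mask[0, 2] = True
        assert len(label_puncta(mask)) == 2

    @settings(derandomize=True, max_examples=30)
    @given(
        mask=arrays(bool, (20, 20), elements=st.booleans()),
    )
    def test_component_count_matches_flood_fill_oracle(self, mask):
        assert len(label_puncta(mask)) == flood_fill_components(mask)

    def test_integrated_intensity_sums_pixels(self):
        mask = np.zeros((6, 6), bool)
        mask[2:4, 2:4] = True
        image = np.arange(36, dtype=float).reshape(6, 6)
        (rec,) = label_puncta(mask, intensity_image=image)
        assert rec.integrated_intensity == pytest.approx(image[mask].sum())
        assert rec.area == 4


class TestGrouping:
    def test_close_puncta_share_filopodium(self):
        # 0.2 um apart at 0.108 um/px is < 2 px
        a = punctum_at([[0, 0]])
        b = punctum_at([[0, 2]], label=1)
        out = group_puncta_into_filopodia([a, b], max_gap_um=0.5)
        assert out[0].filopodium_id == out[1].filopodium_id

    def test_zero_gap_keeps_puncta_separate(self):
        a = punctum_at([[0, 0]])
        b = punctum_at([[0, 1]], label=1)
        out = group_puncta_into_filopodia([a, b], max_gap_um=0.0)
        assert out[0].filopodium_id != out[1].filopodium_id

    def test_single_linkage_chains_transitively(self):
        a = punctum_at([[0, 0]])
        b = punctum_at([[0, 4]], label=1)
        c = punctum_at([[0, 8]], label=2)
        out = group_puncta_into_filopodia([a, b, c], max_gap_um=0.5)
        assert len({p.filopodium_id for p in out}) == 1


class TestConvexHull:
    def test_three_corners_fill_triangle(self):
        puncta = [punctum_at([[0, 0]]), punctum_at([[0, 10]]), punctum_at([[10, 0]])]
        mask, degenerate = convex_hull_mask(puncta, (12, 12))
        assert not degenerate
        assert mask[0, 5] and mask[5, 0] and mask[3, 3]
        assert not mask[10, 10]

    def test_hull_superset_of_punctum_pixels(self):
        rng = np.random.default_rng(0)
        pts = rng.integers(0, 30, (12, 2))
        puncta = [punctum_at([p]) for p in pts]
        mask, _ = convex_hull_mask(puncta, (30, 30))
        assert all(mask[r, c] for r, c in pts)

    def test_collinear_falls_back_to_bounding_box(self):
        puncta = [punctum_at([[2, c]]) for c in (1, 4, 9)]
        mask, degenerate = convex_hull_mask(puncta, (12, 12))
        assert degenerate
        assert mask[2, 1] and mask[2, 9]

    def test_scene_hull_contains_cell(self, quantified_scene, scene):
        _, _, truth = scene
        mask, degenerate = convex_hull_mask(
            quantified_scene.puncta, truth.cell_body_mask.shape
        )
        assert not degenerate
        support = truth.support
        assert (mask & support).sum() / support.sum() >= 0.99


class TestMoleculeConversion:
    def test_identity_on_calibration_total(self):
        scale = FluorescenceScale(n_cells=50, mean_molecules=1e6, total_signal=1e8)
        assert intensity_to_molecules(1e8, scale) == pytest.approx(50e6, rel=1e-14)

    def test_per_cell_share_returns_mean(self):
        scale = FluorescenceScale(n_cells=50, mean_molecules=1e6, total_signal=1e8)
        assert intensity_to_molecules(1e8 / 50, scale) == pytest.approx(1e6)

    def test_hand_arithmetic(self):
        scale = FluorescenceScale(n_cells=50, mean_molecules=1e6, total_signal=1e8)
        assert intensity_to_molecules(2e3, scale) == pytest.approx(1000.0)

    @settings(derandomize=True, max_examples=30)
    @given(i_roi=st.floats(0.0, 1e9), k=st.floats(0.1, 10.0))
    def test_linearity(self, i_roi, k):
        scale = FluorescenceScale(n_cells=10, mean_molecules=5e5, total_signal=3e7)
        assert intensity_to_molecules(i_roi * k, scale) == pytest.approx(
            intensity_to_molecules(i_roi, scale) * k, rel=1e-12
        )

    def test_percent_filopodial(self):
        assert percent_filopodial(100.0, 100.0) == 100.0
        assert percent_filopodial(5.35, 100.0) == pytest.approx(5.35)
        assert percent_filopodial(0.0, 10.0) == 0.0
        with pytest.raises(UndefinedStatisticError):
            percent_filopodial(0.0, 0.0)


class TestPunctumLength:
    def test_single_pixel_floors_at_pixel_size(self):
        assert punctum_length(punctum_at([[5, 5]]), 0.108) == pytest.approx(0.108)

    def test_straight_line_length(self):
        pixels = [[0, c] for c in range(10)]
        assert punctum_length(punctum_at(pixels), 0.108) == pytest.approx(1.08)

    def test_diffraction_limited_blob(self):
        pixels = [[0, 0], [0, 1], [1, 0], [1, 1]]
        length = punctum_length(punctum_at(pixels), 0.108)
        assert 0.2 <= length <= 0.3  # ~250 nm


class TestParameterRecoverySmall:
    def test_cell_total_recovered_within_five_percent(self, quantified_scene, scene):
        _, _, truth = scene
        est = quantified_scene.cell_total_molecules
        assert est == pytest.approx(truth.total_molecules, rel=0.05)

    def test_percent_filopodial_recovered(self, quantified_scene, scene):
        _, _, truth = scene
        truth_pct = 100 * truth.filopodial_molecules / truth.total_molecules
        assert quantified_scene.percent_filopodial == pytest.approx(truth_pct, rel=0.15)

    def test_one_group_per_truth_filopodium(self, quantified_scene, scene):
        _, _, truth = scene
        n_groups = len(quantified_scene.filopodium_totals)
        assert abs(n_groups - len(truth.filopodia)) <= 2
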