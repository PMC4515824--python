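"""Rendering ground truth and the detection/counting pipeline."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from leukopan.render import RenderParams, place_cells, render_field, render_spot
from leukopan.segment import estimate_density, radial_profile, segment_cells


def _roster(n, morphotype="small_lymphocyte"):
    return pd.DataFrame({"morphotype": [morphotype] * n, "diameter_um": np.nan})


class TestPlacement:
    def test_no_overlap_in_ground_truth(self, mixed_field):
        gt = mixed_field.ground_truth
        pts = np.c_[gt.x_um, gt.y_um]
        radii = gt.diameter_um.to_numpy() / 2.0
        tree = cKDTree(pts)
        for i, j in tree.query_pairs(2 * radii.max()):
            d = np.hypot(*(pts[i] - pts[j]))
            assert d >= 0.95 * (radii[i] + radii[j]) - 1e-6

    def test_near_saturated_density_realised_within_3pct(self):
        """7500 cells/mm^2 of ~11 um cells needs lattice placement."""
        rng = np.random.default_rng(0)
        w = h = 300.0  # um
        n = int(round(7500 * (w / 1000) * (h / 1000)))
        radii = rng.uniform(4.5, 5.25, n)
        pos = place_cells(radii, w, h, rng)
        assert len(pos) == n
        assert np.isfinite(pos).all()
        d = cKDTree(pos).query_pairs(2 * radii.max())
        for i, j in d:
            assert np.hypot(*(pos[i] - pos[j])) >= 0.95 * (radii[i] + radii[j]) - 1e-6

    def test_impossible_density_raises(self):
        rng = np.random.default_rng(0)
        radii = np.full(2000, 5.5)  # ~22000/mm^2 in a 0.3x0.3 mm field
        with pytest.raises(ValueError, match="capacity|density"):
            place_cells(radii, 300.0, 300.0, rng)


class TestRendering:
    def test_same_seed_bit_identical(self):
        a = render_field(_roster(40), 0.25, 0.25, seed=3)
        b = render_field(_roster(40), 0.25, 0.25, seed=3)
        assert np.array_equal(a.image, b.image)
        pd.testing.assert_frame_equal(a.ground_truth, b.ground_truth)

    def test_empty_roster_blank_image(self):
        img = render_field(_roster(0), 0.2, 0.2, seed=0)
        assert len(img.ground_truth) == 0
        assert segment_cells(img).n_cells == 0

    def test_too_coarse_pixel_scale_rejected(self):
        with pytest.raises(ValueError, match="pixel scale"):
            render_field(_roster(5), 0.2, 0.2, RenderParams(pixel_scale_um=0.6), seed=0)


class TestDetection:
    def test_count_recall_precision(self, mixed_field, mixed_field_segmentation):
        gt = mixed_field.ground_truth
        seg = mixed_field_segmentation
        assert seg.n_cells == pytest.approx(len(gt), rel=0.02)
        tree = cKDTree(np.c_[gt.x_um, gt.y_um])
        d, _ = tree.query(seg.centers_um)
        matched = (d < 4.0).sum()
        assert matched / seg.n_cells >= 0.98  # precision
        assert matched / len(gt) >= 0.98  # recall

    def test_rotation_and_translation_invariance(self):
        img = render_field(_roster(60), 0.3, 0.3, seed=9)
        base = segment_cells(img).n_cells
        rot = np.rot90(img.image, axes=(1, 2)).copy()
        assert segment_cells(rot, img.pixel_scale_um).n_cells == base
        shifted = np.roll(img.image, 37, axis=2)
        # rolling wraps content; counts stay within one cell of the original
        assert abs(segment_cells(shifted, img.pixel_scale_um).n_cells - base) <= 1

    def test_blank_image_zero_detections(self):
        blank = np.zeros((2, 400, 400), dtype=np.float32)
        assert segment_cells(blank, 0.25).n_cells == 0

    @pytest.mark.parametrize("density", [300, 3000, 6000])
    def test_counting_consistent_across_density_range(self, density):
        """Detected density tracks placed density within 3%."""
        side = 0.25  # mm
        n = int(round(density * side * side))
        img = render_field(_roster(n), side, side,
                           RenderParams(pixel_scale_um=0.35), seed=density)
        seg = segment_cells(img)
        assert seg.n_cells == pytest.approx(n, rel=0.03, abs=1)


class TestDensityEstimate:
    def test_hand_arithmetic(self):
        est = estimate_density([980, 1000, 1020], 0.25)
        assert est.density == pytest.approx(4000.0)
        assert est.relative_sd_percent == pytest.approx(2.0, abs=0.01)

    def test_single_field_has_no_sd(self):
        est = estimate_density([1000], 0.25)
        assert est.relative_sd_percent is None

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            estimate_density([10], 0.0)


@pytest.fixture(scope="module")
def uniform_spot():
    img = render_spot(_roster(450), 0.4, RenderParams(pixel_scale_um=0.3), seed=2)
    return img, segment_cells(img)


class TestRadialProfile:

    def test_uniform_spot_ratio_near_one(self, uniform_spot):
        """Averaged over seeds: the inner 20% of radius holds only 4% of
        the spot area, so a single render's ratio is noisy."""
        img, seg = uniform_spot
        prof = radial_profile(seg, img.spot_center_um, img.spot_diameter_um)
        assert prof.reliable
        ratios = [prof.uniformity_ratio]
        for seed in (3, 4):
            im = render_spot(_roster(450), 0.4, RenderParams(pixel_scale_um=0.3),
                             seed=seed)
            p = radial_profile(segment_cells(im), im.spot_center_um, im.spot_diameter_um)
            ratios.append(p.uniformity_ratio)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.3)

    def test_donut_mode_recovered(self):
        img = render_spot(
            _roster(450), 0.4, RenderParams(pixel_scale_um=0.3, mode="donut"), seed=2
        )
        seg = segment_cells(img)
        prof = radial_profile(seg, img.spot_center_um, img.spot_diameter_um)
        assert prof.uniformity_ratio > 1.5
        assert prof.is_donut

    def test_few_detections_flagged_unreliable(self):
        img = render_spot(_roster(20), 0.4, RenderParams(pixel_scale_um=0.3), seed=2)
        seg = segment_cells(img)
        prof = radial_profile(seg, img.spot_center_um, img.spot_diameter_um)
        assert not prof.reliable

    def test_detections_outside_spot_error(self, uniform_spot):
        _, seg = uniform_spot
        with pytest.raises(ValueError):
            radial_profile(seg, (10_000.0, 10_000.0), 400.0)
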