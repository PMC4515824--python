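"""Analytic nucleus-contour families: areas, perimeters, NCI, cleft depths."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import ellipe
from skimage.draw import polygon as draw_polygon

from leukopan import geometry as G


class TestShapeMetrics:
    def test_disk_nci_is_minimum(self):
        s = G.ellipse_shape(1.0)
        assert s.nci == pytest.approx(G.DISK_NCI, rel=1e-5)
        assert s.area == pytest.approx(np.pi, rel=1e-5)
        assert s.perimeter == pytest.approx(2 * np.pi, rel=1e-5)

    @pytest.mark.parametrize("ratio", [1.2, 1.5, 2.0, 3.0])
    def test_ellipse_matches_closed_form(self, ratio):
        s = G.ellipse_shape(ratio, area=np.pi)
        q = np.sqrt(ratio)
        # closed-form perimeter via the complete elliptic integral
        per = 4 * q * ellipe(1 - 1 / ratio**2)
        assert s.perimeter == pytest.approx(per, rel=1e-4)
        assert s.area == pytest.approx(np.pi, rel=1e-4)

    def test_moderate_ellipse_stays_well_below_lobed_range(self):
        # an eccentric but smooth nucleus outline is far from the lobed band
        assert G.ellipse_nci(1.3) == pytest.approx(3.59, abs=0.03)
        assert G.ellipse_nci(1.3) < 4.1

    def test_nci_solvers_round_trip(self):
        for target in (3.6, 3.75, 4.0):
            q = G.ellipse_ratio_for_nci(target)
            assert G.ellipse_nci(q) == pytest.approx(target, abs=1e-6)
        for target in (4.2, 4.4, 4.8, 5.0):
            amp = G.lobed_amp_for_nci(target, k=2, sigma=0.12)
            assert G.lobed_nci(2, amp, 0.12) == pytest.approx(target, abs=1e-4)

    def test_lobed_spec_errors(self):
        with pytest.raises(ValueError):
            G.lobed_shape(1, 0.5)
        with pytest.raises(ValueError):
            G.lobed_shape(2, 1.2)
        with pytest.raises(ValueError):
            G.ellipse_ratio_for_nci(3.0)

    def test_scaling_preserves_dimensionless_metrics(self):
        s = G.lobed_shape(2, 0.6, 0.12)
        t = s.scaled(137.0)
        assert t.area == pytest.approx(137.0)
        assert t.nci == pytest.approx(s.nci, rel=1e-12)
        assert t.cleft_depths == s.cleft_depths


class TestCleftGroundTruth:
    def test_convex_shapes_have_no_clefts(self):
        assert G.ellipse_shape(1.0).cleft_depths == ()
        # even a strongly eccentric ellipse is convex: hull-based depth zero
        assert G.contour_cleft_depths(G.ellipse_shape(2.2).vertices) == []

    def test_lobed_depth_solver_round_trip(self):
        for depth in (0.5, 0.6, 0.7):
            amp = G.lobed_amp_for_depth(depth, k=2, sigma=0.12)
            s = G.lobed_shape(2, amp, 0.12)
            assert len(s.cleft_depths) == 2
            assert s.cleft_depths[0] == pytest.approx(depth, abs=0.02)

    def test_four_lobe_ground_truth(self):
        amp = G.lobed_amp_for_depth(0.6, k=4, sigma=0.25)
        s = G.lobed_shape(4, amp, 0.25)
        assert len(s.cleft_depths) == 4
        for d in s.cleft_depths:
            assert d == pytest.approx(0.6, abs=0.05)

    def test_kidney_is_single_shallow_indentation(self):
        amp = G.kidney_amp_for_depth(0.3, 0.3)
        s = G.kidney_shape(amp, 0.3)
        assert len(s.cleft_depths) == 1
        assert 0.1 <= s.cleft_depths[0] < 0.5


class TestRasterSelfCheck:
    @pytest.mark.parametrize(
        "shape",
        [
            G.ellipse_shape(1.0),
            G.ellipse_shape(1.74),
            G.lobed_shape(2, 0.65, 0.12),
            G.kidney_shape(0.5, 0.3),
        ],
        ids=["disk", "ellipse", "lobed", "kidney"],
    )
    def test_pixel_area_matches_analytic_within_1pct(self, shape):
        s = shape.scaled(np.pi * 4.0**2)  # equivalent radius 4 um
        scale = 0.1  # um/px
        ext = np.abs(s.vertices).max() * 1.2
        n = int(2 * ext / scale) + 4
        rr, cc = draw_polygon(
            (s.vertices[:, 1] + ext) / scale, (s.vertices[:, 0] + ext) / scale, shape=(n, n)
        )
        pixel_area = len(rr) * scale**2
        assert pixel_area == pytest.approx(s.area, rel=0.01)


class TestPopulationSamplers:
    def test_lobed_nci_distribution(self):
        rng = np.random.default_rng(0)
        vals = G.sample_lobed_nci(rng, 4000)
        assert vals.min() >= 4.2 and vals.max() <= 5.0
        assert np.median(vals) == pytest.approx(4.4, abs=0.03)

    def test_nonlobed_nci_distribution(self):
        rng = np.random.default_rng(0)
        vals = G.sample_nonlobed_nci(rng, 4000)
        assert vals.min() >= 2 * np.sqrt(np.pi)
        assert np.median(vals) == pytest.approx(3.75, abs=0.03)


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 10_000))
def test_sampled_cell_geometry_is_consistent(seed):
    """Any sampled cell: nucleus fits the cell, NCI >= disk bound."""
    rng = np.random.default_rng(seed)
    name = list(G.MORPHOTYPE_GEOMETRY)[seed % len(G.MORPHOTYPE_GEOMETRY)]
    g = G.sample_cell_geometry(name, rng)
    assert g.nuclear_area_um2 < g.cell_area_um2
    for n in g.nuclei:
        assert n.nci >= G.DISK_NCI - 1e-6
        assert n.area > 0 and n.perimeter > 0
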